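# Methods

## Scope and model

`hxfold` reconciles two measurements of a protein's conformational
stability — the unfolding free energy ΔG_U from an equilibrium denaturation
melt and the exchange free energy ΔG_HX from native-state H/D exchange
under EX2 conditions — and, when a discrepancy survives the accountable
corrections, predicts where it comes from: distinct, weakly stabilized
cryptic unfolding intermediates (which depress ΔG_U) or higher-energy
metastable denatured ensembles (which inflate ΔG_HX). All energies are in
kcal/mol, rates in min⁻¹, lengths in Å; R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹
throughout.

The EX2 assumption is taken from the caller, not tested: refolding must be
fast against intrinsic exchange so that k_ex = K_op·k_rc and
ΔG_HX = −RT ln(k_ex/k_rc). EX1 kinetics, side-chain exchange and the
denaturant dependence of residue ΔG_HX are out of scope.

## Stage I — intrinsic rates

Random-coil rates per amide are the sum of acid-, base- and water-catalysed
channels evaluated at 293 K from a bundled model-compound reference table
(poly-DL-alanine convention for D2O: log₁₀ k_a = 1.62 M⁻¹min⁻¹,
log₁₀ k_b = 10.05 M⁻¹min⁻¹, log₁₀ k_w = −1.5 min⁻¹, pK_D = 15.05), each
channel then scaled to the working temperature with its own activation
energy (14/17/19 kcal/mol). The closed-form single-expression variant of
this computation is mathematically the composition of the two steps, so the
package evaluates them sequentially. Side-chain neighbour factors multiply
in log space: the residue owning the NH contributes its own-peptide (λ)
factors, the preceding residue its following-peptide (ρ) factors; cystine,
cis- and trans-proline carry distinct entries, residue 2 receives the
protonated-amine terminal factor and the last residue the carboxylate
factor. Residue 1 (free amine) and prolines have no amide NH.

Choices worth knowing:

- **Titratable neighbours.** Asp/Glu/His factors are mixed between their
  protonated and deprotonated entries by a Henderson–Hasselbalch fraction
  at fixed reference pKa values (4.48/4.93/7.42 on the D2O scale). The
  mixing is linear in the multiplicative factor.
- **pK_D** is held at its 293 K value at all temperatures; at physiological
  pD and moderate temperature offsets the error is small against the
  factor-table uncertainty, but rates far from 293 K inherit it.
- **Ionic strength** is recorded in provenance and applies no correction;
  the bundled table's convention (low salt) is the operative one.
- The table is a versioned TSV that users can replace wholesale (other
  solvent conventions, updated factor sets).

## Stage II — proline correction

In the unfolded state an Xaa-Pro imide samples cis and trans with a cis
fraction f_cis of roughly 6–38 % depending on Xaa, whereas exchange samples
only the fast first unfolding step; slow isomerisation then stabilizes U
beyond what ΔG_HX sees. The comparable quantity is

    ΔG_HX* = ΔG_HX − RT·Σᵢ ln(1 + Kᵢ),

with Kᵢ = f/(1−f) for a native-trans proline and (1−f)/f for native-cis.
The correction is always a decrease, is additive over prolines, and is
large only for native-cis prolines. Native conformations come from the
structure via the distance rule (trans iff Cα–Cα > Cα–Cδ to the preceding
residue); f_cis defaults are bundled per preceding-residue type from
model-compound peptide work (aromatic Xaa high, β-branched low) and can be
replaced by protein-derived values. Corrected and uncorrected energies are
compared at an inclusive 0.4 kcal/mol tolerance — roughly the aggregate
contribution of the prevalent trans prolines — with values reported to
0.1 kcal/mol and full precision kept internally.

## Stage III — melting fits

Observed signal follows the two-state Santoro–Bolen form with pluggable
baselines. The exponential pre-baseline is S_n(C) = I_c + I_0·e^(−C/s)
with I_0 tied to the zero-denaturant signal (I_0 = S_n(0) − I_c) and the
decay scale s fitted; this captures a folded-state signal that settles to
a constant before the transition. Polynomial baselines are quadratic;
higher degrees are refused to keep the baseline from absorbing the
transition. Fitting is trust-region least squares over all parameters with
a deterministic multi-start (midpoint grid × m ladder, 20 starts, best
residual wins). A fit is rejected as degenerate when the midpoint leaves
the observed concentration range or the fitted transition amplitude falls
below 10 % of the signal span or 5× the residual RMS. m is constrained
positive; C_m = ΔG_U/m by construction. AIC is reported for information
only — baseline choice stays with the user.

Identifiability, measured on this package's own synthetic curves (40
points, half uniform over 0–6 M and half within ±1 M of the midpoint):
with linear baselines and 1 % (of signal span) Gaussian noise the median
recovery error of ΔG_U and m is below 2 %, individual noise draws can
exceed it. An exponential pre-baseline whose decay overlaps the transition
is markedly weaker — at 1 % noise expect ~5 % typical error; the 2 % level
needs scan-averaged data quality (~0.25 % noise). This is a property of
the model, not the optimizer: noiseless curves are recovered to machine
precision.

## Stage IV — intermediate prediction

Backbone H-bonds use heavy atoms only (PDB depositions usually lack
hydrogens): N···O ≤ 3.28 Å with the N–O=C angle at the acceptor oxygen and
the O–N–Cα angle at the donor nitrogen both within [90°, 180°], all bounds
inclusive. Donor and acceptor must be ≥ 2 positions apart in sequence, and
a donor keeps only its shortest qualifying acceptor (one amide proton).
Secondary structure requires both a pattern and torsions: runs of ≥ 2
consecutive i→i+4 (α) or i→i+3 (3₁₀) bonds, or sheet ladders of ≥ 2
registered rungs (antiparallel rung: Nᵢ→Oⱼ and Nⱼ→Oᵢ; parallel:
Nᵢ→O_{j−1} and N_{j+1}→Oᵢ, stepping by two along each strand), with the
residue's (φ,ψ) inside the class window — (−57±30, −47±30) α,
(−60±30, −30±30) 3₁₀, (−119±30, −113±30) parallel, (−139±30, 135±30)
antiparallel. Overlapping patterns resolve in that order.

Candidates are H-bond donors in regular secondary structure holding a
measured ΔG_HX; H-bonded loop/surface amides are excluded because they
exchange through local fluctuations (a relaxed all-donors mode exists for
proteins whose slow amides include ordered loops). The contact-order
matrix is binary over backbone-nitrogen distances with an inclusive 7 Å
cutoff; clusters are connected components, ordered by descending size then
smallest residue number. Singletons are listed separately and are not
intermediates. Two or more clusters → cryptic-intermediate mode, each
cluster reported with its free-energy coverage [min, max] of member ΔG_HX
and written as a PDB subset; clusters whose coverage endpoints each agree
within the 0.4 kcal/mol tolerance are flagged cooperative. Exactly one
cluster → the metastable search: residues with ΔG_HX strictly above
ΔG_X = ΔG_U* + (ΔG_HX − ΔG_HX*), re-clustered the same way.

Structure handling: first model of multi-model (NMR) files, altloc
' '/'A' only, HETATM and waters dropped, author residue numbering kept
verbatim so reports read against published tables.

## Synthetic data

The fixtures module builds every test input programmatically:

- **Ideal backbones** (helix, extended chain, two-strand antiparallel
  pair) from standard bond geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329,
  C=O 1.231 Å; ω = 180°) at exact target torsions via sequential atom
  placement; the strand partner is rigidly posed by a deterministic local
  optimisation that sets the ladder N···O distances to 2.95 Å. Poly-Ala
  with Cβ only — no real side chains, no solvent, no crystallographic
  noise, so structural tests certify the geometric criteria, not
  robustness to messy coordinates.
- **Two-island structures**: two helices at a chosen centroid separation
  with island-disjoint planted ΔG_HX ranges (4–6 vs 1.5–3.5 kcal/mol),
  giving known cluster truth.
- **Melting curves**: the two-state model plus seeded Gaussian noise at
  the sampling design described above. Real melts add correlated drift
  and concentration error that the generator does not emulate; recovery
  results bound the favourable case.
- **Exchange tables** in the pipeline's TSV formats, optionally as k_ex
  consistent with a common k_rc for round-trip checks.

All builders are byte-deterministic under a fixed seed.

## Known limitations

- Factor-table entries are a transcription of the standard model-compound
  scheme; users wanting exact agreement with a specific published
  calculator should load that calculator's table via the replacement hook.
- No mmCIF input (convert externally), no hydrogen placement, and the
  secondary-structure assignment implements exactly the printed criteria
  rather than a full DSSP.
- The cooperative-unit rule (both coverage endpoints within tolerance) is
  one reasonable operationalisation of "same free energy coverage";
  the tolerance is configurable.
- Global ΔG_HX is the arithmetic mean of the four largest residue values;
  with fewer than four residues it averages what exists and warns.
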
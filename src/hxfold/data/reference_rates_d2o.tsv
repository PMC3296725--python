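# Random-coil amide exchange reference table, D2O solvent, 293 K.
# Poly-DL-alanine reference scheme with additive log10 side-chain factors
# (model-compound convention of Bai, Milne, Mayne & Englander, Proteins
# 17:75-86, 1993), as used for H -> D exchange followed by NMR.
#
# Scalars (log10):
#   log_ka   acid-catalysed reference rate, per molar per minute
#   log_kb   base-catalysed reference rate, per molar per minute
#   log_kw   water-catalysed reference rate, per minute
#   pKD      molar ionization constant of D2O at 293 K
#   Ea/Eb/Ew activation energies, kcal/mol (acid/base/water channels)
#   pKa_*    reference side-chain pKa values (D2O scale) for titratable
#            residues, used to mix protonated/deprotonated factors
#! log_ka	1.62
#! log_kb	10.05
#! log_kw	-1.5
#! pKD	15.05
#! Ea	14.0
#! Eb	17.0
#! Ew	19.0
#! pKa_D	4.48
#! pKa_E	4.93
#! pKa_H	7.42
#
# Per-residue log10 factors. lam_* act on the residue's own amide NH
# (the peptide group on the left of the side chain); rho_* act on the
# following residue's NH (peptide group on the right). Water catalysis
# uses the base-channel factors. Special codes:
#   D0/E0/H+  protonated forms of Asp/Glu/His
#   C2        cystine (disulfide-bonded cysteine)
#   Pt/Pc     trans-/cis-proline (no lam: proline has no amide NH)
#   NT        extra rho factors from a protonated N-terminal amine
#   CT        extra lam factors from a C-terminal carboxylate
# code	lam_acid	rho_acid	lam_base	rho_base
A	0.00	0.00	0.00	0.00
R	-0.59	-0.32	0.08	0.22
N	-0.58	-0.13	0.49	0.32
D	0.90	0.58	0.10	-0.18
D0	-0.90	-0.12	0.69	0.60
C	-0.54	-0.46	0.62	0.55
C2	-0.74	-0.58	0.55	0.46
G	-0.22	0.22	0.27	0.17
Q	-0.47	-0.27	0.06	0.20
E	-0.90	0.31	-0.11	-0.15
E0	-0.60	-0.27	0.24	0.39
H	0.00	0.00	-0.10	0.14
H+	-0.80	-0.51	0.80	0.83
I	-0.91	-0.59	-0.73	-0.23
L	-0.57	-0.13	-0.58	-0.21
K	-0.56	-0.29	-0.04	0.12
M	-0.64	-0.28	-0.01	0.11
F	-0.52	-0.43	-0.24	0.06
Pt	0.00	-0.19	0.00	-0.24
Pc	0.00	-0.85	0.00	0.60
S	-0.44	-0.39	0.37	0.30
T	-0.79	-0.47	-0.07	0.20
W	-0.40	-0.44	-0.41	-0.11
Y	-0.41	-0.37	-0.27	0.05
V	-0.74	-0.30	-0.70	-0.14
NT	0.00	-1.32	0.00	1.62
CT	0.96	0.00	-1.80	0.00
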
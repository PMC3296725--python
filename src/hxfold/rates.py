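"""Intrinsic (random-coil) amide exchange rates, k_rc.

The rate of a backbone amide proton in a fully solvent-exposed chain is
modelled as the sum of acid-, base- and water-catalysed channels:

    k_rc = k_a * R_a * 10^(-pD)  +  k_b * R_b * 10^(pD - pKD)  +  k_w * R_w

where k_a, k_b, k_w are poly-DL-alanine reference rates at 293 K and the
R factors are products of side-chain contributions of the residue bearing
the NH and the residue preceding it (the two residues flanking the amide
proton). Each channel is then scaled to the working temperature with its
own activation energy:

    k(T) = k(293) * exp(-(E / R) * (1/T - 1/293))

The reference constants and neighbour factors are bundled as a versioned
TSV (see ``data/reference_rates_d2o.tsv``) and can be replaced by the user
to adopt a different convention or solvent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .constants import R_KCAL, T_REFERENCE
from .structure import (DisulfideAssignment, ProlineAssignment,
                        ProteinStructure, ResidueKey)

_STANDARD = set("ARNDCQEGHILKMFPSTWYV")


class RateError(ValueError):
    """Raised for unusable exchange-rate input."""


@dataclass(frozen=True)
class ExchangeConditions:
    """Solution conditions of the exchange experiment.

    ``pD`` is the pH-meter reading + 0.4 in D2O (deuterium isotope
    correction); in H2O the reading is used as-is. Ionic strength is
    recorded for provenance but applies no correction beyond the bundled
    table's convention.
    """

    pH_read: float
    temperature: float = 293.0
    ionic_strength: float = 0.0
    solvent: str = "D2O"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise RateError("temperature must be positive (kelvin)")
        if self.solvent not in ("D2O", "H2O"):
            raise RateError(f"unknown solvent {self.solvent!r}")

    @property
    def pD(self) -> float:
        return self.pH_read + 0.4 if self.solvent == "D2O" else self.pH_read


@dataclass
class ReferenceRateTable:
    """Reference rate constants plus per-residue neighbour factors (log10)."""

    log_ka: float
    log_kb: float
    log_kw: float
    pKD: float
    Ea: float
    Eb: float
    Ew: float
    pKa: dict[str, float]
    factors: dict[str, tuple[float, float, float, float]]  # lamA, rhoA, lamB, rhoB
    version: str = "bundled-d2o"

    @classmethod
    def load(cls, path=None) -> "ReferenceRateTable":
        """Load the bundled D2O table, or a user TSV in the same format."""
        if path is None:
            text = (resources.files("hxfold.data")
                    / "reference_rates_d2o.tsv").read_text()
            version = "bundled-d2o"
        else:
            with open(path) as fh:
                text = fh.read()
            version = str(path)
        scalars: dict[str, float] = {}
        factors: dict[str, tuple[float, float, float, float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("#!"):
                key, value = line[2:].split()
                scalars[key] = float(value)
            elif line and not line.startswith("#"):
                parts = line.split("\t")
                factors[parts[0]] = tuple(float(x) for x in parts[1:5])  # type: ignore[assignment]
        missing = (_STANDARD - {"P"}) - set(factors)
        if not {"Pt", "Pc"} <= set(factors):
            missing |= {"Pt", "Pc"} - set(factors)
        if missing:
            raise RateError(f"reference table lacks residues: {sorted(missing)}")
        return cls(
            log_ka=scalars["log_ka"], log_kb=scalars["log_kb"],
            log_kw=scalars["log_kw"], pKD=scalars["pKD"],
            Ea=scalars["Ea"], Eb=scalars["Eb"], Ew=scalars["Ew"],
            pKa={"D": scalars["pKa_D"], "E": scalars["pKa_E"],
                 "H": scalars["pKa_H"]},
            factors=factors, version=version,
        )

    def _factor_pair(self, code: str, pD: float) -> tuple[float, float, float, float]:
        """Linear (lamA mult, rhoA mult, lamB mult, rhoB mult) for one
        residue code, Henderson-Hasselbalch-mixed for titratable residues."""
        if code in ("D", "E", "H"):
            prot = self.factors[code + "0" if code != "H" else "H+"]
            deprot = self.factors[code]
            f_prot = 1.0 / (1.0 + 10.0 ** (pD - self.pKa[code]))
            return tuple(
                f_prot * 10.0 ** p + (1.0 - f_prot) * 10.0 ** d
                for p, d in zip(prot, deprot)
            )  # type: ignore[return-value]
        if code == "P":          # unspecified proline defaults to trans
            code = "Pt"
        if code not in self.factors:
            raise RateError(f"unknown residue code {code!r} in reference table")
        return tuple(10.0 ** x for x in self.factors[code])  # type: ignore[return-value]


@dataclass
class IntrinsicRateResult:
    """k_rc of one amide NH with its per-channel decomposition."""

    residue: ResidueKey
    k_rc: float                     # min^-1, at the working temperature
    acid: float
    base: float
    water: float
    left_code: str                  # variant code of the preceding residue
    right_code: str                 # variant code of the NH-bearing residue
    notes: list[str] = field(default_factory=list)


def krc_channels_at_reference(left_residue: str, right_residue: str,
                              conditions: ExchangeConditions,
                              table: ReferenceRateTable,
                              n_terminal_left: bool = False,
                              c_terminal_right: bool = False,
                              ) -> tuple[float, float, float]:
    """Per-channel (acid, base, water) k_rc at 293 K, min^-1.

    ``left_residue`` is the residue preceding the amide NH (it contributes
    its right-side ``rho`` factors); ``right_residue`` is the residue whose
    NH exchanges (its own ``lam`` factors). Variant codes: ``Pt``/``Pc``
    for trans/cis proline, ``C2`` for cystine. A proline on the right has
    no exchangeable NH.
    """
    if right_residue in ("Pt", "Pc", "P"):
        raise RateError("proline has no exchangeable backbone amide NH")
    pD = conditions.pD
    _, rho_a, _, rho_b = table._factor_pair(left_residue, pD)
    lam_a, _, lam_b, _ = table._factor_pair(right_residue, pD)
    if n_terminal_left:
        _, nt_rho_a, _, nt_rho_b = table._factor_pair("NT", pD)
        rho_a *= nt_rho_a
        rho_b *= nt_rho_b
    if c_terminal_right:
        ct_lam_a, _, ct_lam_b, _ = table._factor_pair("CT", pD)
        lam_a *= ct_lam_a
        lam_b *= ct_lam_b
    acid = 10.0 ** table.log_ka * lam_a * rho_a * 10.0 ** (-pD)
    base = 10.0 ** table.log_kb * lam_b * rho_b * 10.0 ** (pD - table.pKD)
    water = 10.0 ** table.log_kw * lam_b * rho_b
    return acid, base, water


def krc_at_reference(left_residue: str, right_residue: str,
                     conditions: ExchangeConditions,
                     table: ReferenceRateTable, **kw) -> float:
    """Total k_rc at 293 K (min^-1): sum of the three catalysis channels."""
    return sum(krc_channels_at_reference(left_residue, right_residue,
                                         conditions, table, **kw))


def temperature_scale(k_293: float, E: float, T: float) -> float:
    """Arrhenius scaling of one catalysis channel from 293 K to T.

    ``E`` is the channel's activation energy in kcal/mol; R is the gas
    constant in kcal/mol/K.
    """
    if T <= 0:
        raise RateError("temperature must be positive (kelvin)")
    return k_293 * math.exp(-(E / R_KCAL) * (1.0 / T - 1.0 / T_REFERENCE))


def krc_single(left_residue: str, right_residue: str,
               conditions: ExchangeConditions, table: ReferenceRateTable,
               **kw) -> float:
    """k_rc (min^-1) at the working temperature for one NH context."""
    acid, base, water = krc_channels_at_reference(left_residue, right_residue,
                                                  conditions, table, **kw)
    return (temperature_scale(acid, table.Ea, conditions.temperature)
            + temperature_scale(base, table.Eb, conditions.temperature)
            + temperature_scale(water, table.Ew, conditions.temperature))


def _variant_codes(sequence: str, position: int,
                   cystine_positions: set[int],
                   cis_proline_positions: set[int]) -> str:
    aa = sequence[position]
    if aa == "C" and position in cystine_positions:
        return "C2"
    if aa == "P":
        return "Pc" if position in cis_proline_positions else "Pt"
    return aa


def krc_sequence_profile(sequence: str, conditions: ExchangeConditions,
                         table: ReferenceRateTable | None = None,
                         cystine_positions: set[int] = frozenset(),
                         cis_proline_positions: set[int] = frozenset(),
                         ) -> list[tuple[int, float]]:
    """k_rc per exchangeable NH from a one-letter sequence.

    Positions are 0-based indices into ``sequence``; the returned list is
    (position, k_rc). Residue 0 (free amine) and prolines carry no NH.
    """
    table = table or ReferenceRateTable.load()
    bad = set(sequence) - _STANDARD
    if bad:
        raise RateError(f"unknown residue code(s) {sorted(bad)}")
    out = []
    for i in range(1, len(sequence)):
        if sequence[i] == "P":
            continue
        left = _variant_codes(sequence, i - 1, cystine_positions,
                              cis_proline_positions)
        right = _variant_codes(sequence, i, cystine_positions,
                               cis_proline_positions)
        k = krc_single(left, right, conditions, table,
                       n_terminal_left=(i == 1),
                       c_terminal_right=(i == len(sequence) - 1))
        out.append((i, k))
    return out


def krc_profile(s: ProteinStructure, conditions: ExchangeConditions,
                disulfides: DisulfideAssignment | None = None,
                prolines: list[ProlineAssignment] | None = None,
                table: ReferenceRateTable | None = None,
                ) -> list[IntrinsicRateResult]:
    """k_rc for every exchangeable backbone NH of a parsed structure.

    Cystine neighbour factors are applied to disulfide-bonded cysteines and
    cis/trans proline factors follow the structural assignment. The first
    residue of each chain (fast-exchanging free amine) and prolines are
    skipped.
    """
    table = table or ReferenceRateTable.load()
    cystine = {k for pair in (disulfides.pairs if disulfides else [])
               for k in pair[:2]}
    cis = {p.residue for p in (prolines or []) if p.conformation == "cis"}

    results: list[IntrinsicRateResult] = []
    for chain_id in s.chain_ids():
        chain = s.chain(chain_id)
        for i in range(1, len(chain)):
            res, prev = chain[i], chain[i - 1]
            if res.name == "PRO":
                continue
            if res.one_letter == "X" or prev.one_letter == "X":
                warnings.warn(f"non-standard residue near {res!r}; skipped")
                continue

            def code(r) -> str:
                if r.name == "CYS" and r.key in cystine:
                    return "C2"
                if r.name == "PRO":
                    return "Pc" if r.key in cis else "Pt"
                return r.one_letter

            left, right = code(prev), code(res)
            acid, base, water = krc_channels_at_reference(
                left, right, conditions, table,
                n_terminal_left=(i == 1),
                c_terminal_right=(i == len(chain) - 1))
            acid = temperature_scale(acid, table.Ea, conditions.temperature)
            base = temperature_scale(base, table.Eb, conditions.temperature)
            water = temperature_scale(water, table.Ew, conditions.temperature)
            notes = []
            if conditions.ionic_strength:
                notes.append("ionic strength recorded but uncorrected")
            results.append(IntrinsicRateResult(
                res.key, acid + base + water, acid, base, water,
                left, right, notes))
    return results
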
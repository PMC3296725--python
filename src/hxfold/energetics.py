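"""EX2 exchange energetics and the free-energy ledger.

Under EX2 conditions an observed amide exchange rate k_ex reports the
opening equilibrium of its NH: the protection factor is P = k_rc / k_ex
and the residue-specific exchange free energy is

    dG_HX = -RT ln(k_ex / k_rc) = RT ln P .

The protein's global dG_HX is the mean of its four largest residue values.
Because unfolded-state cis-trans proline isomerisation stabilizes the
unfolded ensemble beyond what exchange sees (exchange samples only the
first, fast unfolding step), the exchange free energy comparable with a
melting-curve dG_U subtracts RT ln(1 + K) per proline, giving dG_HX*.
The metastable-state threshold combines the corrected quantities:

    dG_X = dG_U* + (dG_HX - dG_HX*).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .constants import ENERGY_TOLERANCE, R_KCAL
from .structure import ResidueKey


class EnergeticsError(ValueError):
    """Raised for unusable energetic input."""


@dataclass
class ResidueExchangeRecord:
    """Per-residue exchange bookkeeping (rates in min^-1, energies kcal/mol)."""

    residue: ResidueKey
    k_rc: float | None = None
    k_ex: float | None = None
    protection_factor: float | None = None
    dg_hx: float | None = None


def protection_factor(k_ex: float, k_rc: float) -> float:
    """P = k_rc / k_ex (dimensionless)."""
    if k_ex <= 0 or k_rc <= 0:
        raise EnergeticsError("rates must be positive")
    return k_rc / k_ex


def dg_hx(k_ex: float, k_rc: float, T: float) -> float:
    """Residue-specific exchange free energy, kcal/mol.

    dG_HX = -RT ln(k_ex / k_rc); positive whenever the NH is protected
    (k_ex < k_rc).
    """
    if k_ex <= 0 or k_rc <= 0:
        raise EnergeticsError("rates must be positive")
    return -R_KCAL * T * math.log(k_ex / k_rc)


def global_dg_hx(values) -> float:
    """Global exchange free energy: mean of the four largest residue values.

    Accepts an iterable of dG_HX floats or of ResidueExchangeRecord.
    With fewer than four values the mean of all is returned with a warning.
    """
    vals = [v.dg_hx if isinstance(v, ResidueExchangeRecord) else float(v)
            for v in values]
    vals = [v for v in vals if v is not None]
    if not vals:
        raise EnergeticsError("no residue-specific dG_HX values")
    top = sorted(vals, reverse=True)[:4]
    if len(vals) < 4:
        warnings.warn(f"only {len(vals)} residue dG_HX values available; "
                      "global dG_HX averages all of them")
    return sum(top) / len(top)


@dataclass
class ProlineContext:
    """What the correction needs to know about one proline: the residue
    type preceding it and its native conformation."""

    preceding: str       # one-letter code of Xaa in Xaa-Pro
    conformation: str    # "cis" | "trans" in the native structure


@dataclass
class ProlineIsomerTable:
    """Unfolded-state cis fractions of Xaa-Pro per preceding residue type."""

    f_cis: dict[str, float]
    source: str = "bundled-model-compound"

    @classmethod
    def load(cls, path=None) -> "ProlineIsomerTable":
        if path is None:
            text = (resources.files("hxfold.data")
                    / "proline_cis_fractions.tsv").read_text()
            source = "bundled-model-compound"
        else:
            with open(path) as fh:
                text = fh.read()
            source = str(path)
        f_cis: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                code, value = line.split("\t")
                f_cis[code] = float(value)
        for code, f in f_cis.items():
            if not 0.0 < f < 1.0:
                raise EnergeticsError(f"f_cis for {code!r} outside (0, 1)")
        return cls(f_cis, source)

    def K(self, preceding: str, conformation: str) -> float:
        """Unfolded-state isomer equilibrium constant opposing the native
        conformation: f/(1-f) for native-trans, (1-f)/f for native-cis."""
        if preceding not in self.f_cis:
            raise EnergeticsError(f"no cis fraction for preceding residue "
                                  f"{preceding!r}")
        f = self.f_cis[preceding]
        if conformation == "trans":
            return f / (1.0 - f)
        if conformation == "cis":
            return (1.0 - f) / f
        raise EnergeticsError(f"unknown proline conformation {conformation!r}")


def proline_correction(dg_hx_value: float,
                       prolines: list[ProlineContext],
                       table: ProlineIsomerTable | None = None,
                       T: float = 298.0) -> float:
    """dG_HX* = dG_HX - RT * sum_i ln(1 + K_i).

    The unfolded-state isomer equilibrium stabilizes U relative to what
    exchange measures, so the correction always decreases dG_HX; it is
    large only for native-cis prolines (K >> 1).
    """
    table = table or ProlineIsomerTable.load()
    correction = sum(math.log1p(table.K(p.preceding, p.conformation))
                     for p in prolines)
    return dg_hx_value - R_KCAL * T * correction


def dg_x(dgu_star: float, dghx: float, dghx_star: float) -> float:
    """Metastable-state threshold: dG_X = dG_U* + (dG_HX - dG_HX*)."""
    for v in (dgu_star, dghx, dghx_star):
        if not math.isfinite(v):
            raise EnergeticsError("free energies must be finite")
    return dgu_star + (dghx - dghx_star)


def compare_energies(a: float, b: float,
                     tolerance: float = ENERGY_TOLERANCE) -> str:
    """'consistent' iff |a - b| <= tolerance (inclusive), else 'discrepant'."""
    return "consistent" if abs(a - b) <= tolerance else "discrepant"


@dataclass
class EnergyLedger:
    """The scalar free energies of one protein and their verdicts."""

    dg_u: float | None = None
    dg_u_star: float | None = None
    dg_hx: float | None = None
    dg_hx_star: float | None = None
    tolerance: float = ENERGY_TOLERANCE
    verdicts: dict[str, str] = field(default_factory=dict)

    @property
    def dg_x(self) -> float:
        if None in (self.dg_u_star, self.dg_hx, self.dg_hx_star):
            raise EnergeticsError("ledger incomplete: need dG_U*, dG_HX and "
                                  "dG_HX* to form dG_X")
        return dg_x(self.dg_u_star, self.dg_hx, self.dg_hx_star)

    def compare(self, name_a: str, name_b: str) -> str:
        a, b = getattr(self, name_a), getattr(self, name_b)
        if a is None or b is None:
            raise EnergeticsError(f"ledger missing {name_a} or {name_b}")
        verdict = compare_energies(a, b, self.tolerance)
        self.verdicts[f"{name_a}_vs_{name_b}"] = verdict
        return verdict
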
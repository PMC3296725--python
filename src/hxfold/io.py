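"""Reading and writing the pipeline's tab-separated table formats."""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .melting import MeltingCurve, MeltingError
from .rates import IntrinsicRateResult
from .structure import ResidueKey


class TableError(ValueError):
    """Raised for malformed tabular input."""


def _read_tsv(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    # the header row may itself be behind a comment marker
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines and lines[0].lstrip().startswith("#"):
        lines[0] = lines[0].lstrip().lstrip("#").strip()
    body = "\n".join(ln for ln in lines if not ln.lstrip().startswith("#"))
    return pd.read_csv(_io.StringIO(body), sep="\t")


def read_exchange_table(source) -> pd.DataFrame:
    """Residue exchange input: columns ``residue`` (author number),
    optional ``chain``, and exactly one of ``k_ex`` (min^-1) or ``dG_hx``
    (kcal/mol). '#' marks comments; the header may be commented.
    """
    df = _read_tsv(source)
    df.columns = [c.strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    if "residue" not in lower:
        raise TableError("exchange table needs a 'residue' column")
    has_kex = "k_ex" in lower
    has_dg = "dg_hx" in lower
    if has_kex == has_dg:
        raise TableError("exchange table needs exactly one of 'k_ex' or 'dG_hx'")
    out = pd.DataFrame({"residue": df[lower["residue"]].astype(int)})
    out["chain"] = (df[lower["chain"]].astype(str).str.strip()
                    if "chain" in lower else "A")
    if has_kex:
        out["k_ex"] = df[lower["k_ex"]].astype(float)
        if (out["k_ex"] <= 0).any():
            raise TableError("k_ex values must be positive")
    else:
        out["dG_hx"] = df[lower["dg_hx"]].astype(float)
    return out


def exchange_keys(df: pd.DataFrame, icode: str = " ") -> dict[ResidueKey, float]:
    """Map (chain, residue, icode) -> dG_hx for a table carrying dG_hx."""
    if "dG_hx" not in df.columns:
        raise TableError("table has no dG_hx column (convert k_ex first)")
    return {(row.chain, int(row.residue), icode): float(row.dG_hx)
            for row in df.itertuples()}


def read_melting_curve(source) -> MeltingCurve:
    """Two-column tab-separated melting data (concentration M, signal)."""
    df = _read_tsv(source)
    if df.shape[1] < 2:
        raise MeltingError("melting data needs two tab-separated columns")
    return MeltingCurve(df.iloc[:, 0].astype(float).to_numpy(),
                        df.iloc[:, 1].astype(float).to_numpy())


def rates_table(results: list[IntrinsicRateResult]) -> pd.DataFrame:
    """Tidy per-NH intrinsic-rate table (one row per exchangeable amide)."""
    return pd.DataFrame({
        "chain": [r.residue[0] for r in results],
        "residue": [r.residue[1] for r in results],
        "k_rc_per_min": [r.k_rc for r in results],
        "acid": [r.acid for r in results],
        "base": [r.base for r in results],
        "water": [r.water for r in results],
        "left_code": [r.left_code for r in results],
        "right_code": [r.right_code for r in results],
    })


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
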
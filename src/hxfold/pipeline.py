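"""Four-stage orchestration: rates -> proline correction -> melting fit ->
intermediate prediction, with machine-readable reports.

Stage I computes intrinsic exchange rates (and, given observed k_ex,
protection factors and residue dG_HX). Stage II corrects the global dG_HX
for unfolded-state proline isomerisation and compares it with dG_U.
Stage III refits the melting curve with user-chosen baselines to obtain
dG_U* (or accepts it directly). Stage IV clusters slow, structured amides
into candidate cryptic intermediates, falling back to the metastable-state
search when a single cluster results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .constants import (CONTACT_CUTOFF, DISULFIDE_CUTOFF, ENERGY_TOLERANCE,
                        HBOND_DISTANCE_CUTOFF, R_KCAL)
from .energetics import (EnergyLedger, ProlineContext, ProlineIsomerTable,
                         dg_hx, global_dg_hx, proline_correction,
                         protection_factor)
from .io import exchange_keys, rates_table, read_exchange_table, read_melting_curve
from .melting import TwoStateFit, fit_melting
from .predictor import IntermediatePrediction, predict
from .rates import ExchangeConditions, ReferenceRateTable, krc_profile
from .structure import (ProteinStructure, assign_secondary_structure,
                        classify_prolines, detect_backbone_hbonds,
                        detect_disulfides, parse_pdb)

log = logging.getLogger("hxfold")


@dataclass
class RunConfig:
    """Inputs and knobs of one end-to-end run."""

    pdb_path: str | None = None
    exchange_path: str | None = None
    melt_path: str | None = None
    dg_u: float | None = None
    dg_u_star: float | None = None
    ph_read: float = 7.0
    temperature: float = 298.0
    ionic_strength: float = 0.0
    solvent: str = "D2O"
    tolerance: float = ENERGY_TOLERANCE
    disulfide_cutoff: float = DISULFIDE_CUTOFF
    hbond_cutoff: float = HBOND_DISTANCE_CUTOFF
    contact_cutoff: float = CONTACT_CUTOFF
    kpro_path: str | None = None
    rates_path: str | None = None
    pre_baseline: str = "linear"
    post_baseline: str = "linear"
    require_secondary_structure: bool = True

    def conditions(self) -> ExchangeConditions:
        return ExchangeConditions(self.ph_read, self.temperature,
                                  self.ionic_strength, self.solvent)

    def provenance(self) -> dict:
        return {
            "package_version": __version__,
            "inputs": {"pdb": self.pdb_path, "exchange": self.exchange_path,
                       "melt": self.melt_path, "dG_U": self.dg_u,
                       "dG_U_star": self.dg_u_star},
            "conditions": {"pH_read": self.ph_read,
                           "temperature_K": self.temperature,
                           "ionic_strength_M": self.ionic_strength,
                           "solvent": self.solvent},
            "cutoffs": {"disulfide_A": self.disulfide_cutoff,
                        "hbond_A": self.hbond_cutoff,
                        "contact_A": self.contact_cutoff,
                        "tolerance_kcal_mol": self.tolerance},
            "baselines": {"pre": self.pre_baseline, "post": self.post_baseline},
        }


@dataclass
class StageOneResult:
    structure: ProteinStructure
    disulfides: object
    prolines: list
    rates: pd.DataFrame
    exchange: pd.DataFrame | None
    dg_map: dict
    global_dg_hx: float | None


def run_stage1(config: RunConfig) -> StageOneResult:
    """Structure geometry + intrinsic rates (+ dG_HX when k_ex is given)."""
    if config.pdb_path is None:
        raise ValueError("stage I needs a structure file")
    s = parse_pdb(Path(config.pdb_path).read_text(),
                  Path(config.pdb_path).stem)
    disulfides = detect_disulfides(s, config.disulfide_cutoff)
    prolines = classify_prolines(s)
    conditions = config.conditions()
    table = ReferenceRateTable.load(config.rates_path)
    results = krc_profile(s, conditions, disulfides, prolines, table)
    rates = rates_table(results)
    log.info("stage I: %d exchangeable NHs, %d disulfides, %d prolines",
             len(rates), len(disulfides.pairs), len(prolines))

    exchange = None
    dg_map: dict = {}
    g_dghx = None
    if config.exchange_path is not None:
        exchange = read_exchange_table(Path(config.exchange_path).read_text())
        if "k_ex" in exchange.columns:
            krc_by_key = {r.residue: r.k_rc for r in results}
            dgs, ps, krcs = [], [], []
            for row in exchange.itertuples():
                key = (row.chain, int(row.residue), " ")
                k_rc = krc_by_key.get(key)
                if k_rc is None:
                    dgs.append(float("nan")); ps.append(float("nan")); krcs.append(float("nan"))
                    continue
                ps.append(protection_factor(row.k_ex, k_rc))
                dgs.append(dg_hx(row.k_ex, k_rc, conditions.temperature))
                krcs.append(k_rc)
            exchange = exchange.assign(k_rc=krcs, P=ps, dG_hx=dgs)
        dg_col = exchange["dG_hx"].dropna()
        dg_map = exchange_keys(exchange.dropna(subset=["dG_hx"]))
        g_dghx = global_dg_hx(dg_col.tolist())
        log.info("stage I: global dG_HX (mean of four largest) = %.2f kcal/mol",
                 g_dghx)
    else:
        log.info("stage I: no exchange table given; rates-only output")
    return StageOneResult(s, disulfides, prolines, rates, exchange,
                          dg_map, g_dghx)


def run_stage2(config: RunConfig, stage1: StageOneResult) -> EnergyLedger:
    """Proline-isomerisation correction and the dG_HX* vs dG_U verdict."""
    if stage1.global_dg_hx is None:
        raise ValueError("stage II needs residue exchange data (stage I)")
    if config.dg_u is None:
        raise ValueError("stage II needs dG_U")
    kpro = ProlineIsomerTable.load(config.kpro_path)
    contexts = [ProlineContext(stage1.structure.get(p.preceding).one_letter,
                               p.conformation)
                for p in stage1.prolines]
    dghx_star = proline_correction(stage1.global_dg_hx, contexts, kpro,
                                   config.temperature)
    ledger = EnergyLedger(dg_u=config.dg_u, dg_u_star=config.dg_u_star,
                          dg_hx=stage1.global_dg_hx, dg_hx_star=dghx_star,
                          tolerance=config.tolerance)
    verdict = ledger.compare("dg_hx_star", "dg_u")
    if verdict == "consistent":
        log.info("stage II: discrepancy accounted by proline isomerisation "
                 "(dG_HX* %.2f vs dG_U %.2f)", dghx_star, config.dg_u)
    else:
        log.info("stage II: discrepant (dG_HX* %.2f vs dG_U %.2f); proceed",
                 dghx_star, config.dg_u)
    return ledger


def run_stage3(config: RunConfig, ledger: EnergyLedger) -> TwoStateFit | None:
    """Melting-curve refit for dG_U*; pass-through when given directly."""
    if config.melt_path is None:
        if config.dg_u_star is None:
            # a curve already well fitted by linear baselines needs no refit
            ledger.dg_u_star = ledger.dg_u
            log.info("stage III: no curve and no dG_U* given; using dG_U")
        else:
            ledger.dg_u_star = config.dg_u_star
            log.info("stage III: dG_U* given directly (%.2f)", config.dg_u_star)
        return None
    curve = read_melting_curve(Path(config.melt_path).read_text())
    fit = fit_melting(curve, config.pre_baseline, config.post_baseline,
                      config.temperature)
    ledger.dg_u_star = fit.dg_u
    log.info("stage III: fitted dG_U* = %.2f kcal/mol, m = %.2f, C_m = %.2f M",
             fit.dg_u, fit.m, fit.cm)
    if ledger.dg_hx_star is not None:
        ledger.compare("dg_hx_star", "dg_u_star")
    return fit


def run_stage4(config: RunConfig, stage1: StageOneResult,
               ledger: EnergyLedger) -> IntermediatePrediction:
    """Cryptic-intermediate clustering with the metastable fallback."""
    hbonds = detect_backbone_hbonds(stage1.structure, config.hbond_cutoff)
    ss = assign_secondary_structure(stage1.structure, hbonds)
    pred = predict(stage1.structure, ss, hbonds, stage1.dg_map, ledger,
                   config.contact_cutoff, config.tolerance,
                   config.require_secondary_structure)
    log.info("stage IV: mode=%s, %d cluster(s), %d unclustered",
             pred.mode, len(pred.clusters), len(pred.unclustered))
    return pred


def prediction_report(pred: IntermediatePrediction, config: RunConfig,
                      ledger: EnergyLedger | None = None) -> dict:
    """JSON-serializable stage-IV report with full provenance."""
    report = {
        "provenance": config.provenance(),
        "mode": pred.mode,
        "n_clusters": len(pred.clusters),
        "clusters": [
            {"members": [f"{c}:{n}" for c, n, _ in cl.members],
             "size": len(cl.members),
             "coverage_kcal_mol": list(cl.coverage) if cl.coverage else None}
            for cl in pred.clusters
        ],
        "unclustered": [f"{c}:{n}" for c, n, _ in pred.unclustered],
        "cooperative_pairs": pred.cooperative_pairs,
    }
    if pred.dg_x is not None:
        report["dG_X_kcal_mol"] = round(pred.dg_x, 4)
    if ledger is not None:
        report["ledger"] = {
            "dG_U": ledger.dg_u, "dG_U_star": ledger.dg_u_star,
            "dG_HX": ledger.dg_hx, "dG_HX_star": ledger.dg_hx_star,
            "tolerance": ledger.tolerance, "verdicts": ledger.verdicts,
        }
    return report


def run_all(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute stages I-IV and optionally write report files.

    Returns the stage-IV report dict. Writes report.json, rates.tsv and
    one PDB file per cluster under ``out_dir`` when given.
    """
    stage1 = run_stage1(config)
    ledger = run_stage2(config, stage1)
    fit = run_stage3(config, ledger)
    pred = run_stage4(config, stage1, ledger)
    report = prediction_report(pred, config, ledger)
    if fit is not None:
        report["melting_fit"] = {"dG_U_star": fit.dg_u, "m": fit.m,
                                 "C_m": fit.cm, "rss": fit.rss}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True) + "\n")
        stage1.rates.to_csv(out / "rates.tsv", sep="\t", index=False)
        if stage1.exchange is not None:
            stage1.exchange.to_csv(out / "exchange.tsv", sep="\t", index=False)
        for i, cl in enumerate(pred.clusters, start=1):
            if cl.pdb_text:
                (out / f"cluster_{i}.pdb").write_text(cl.pdb_text)
    return report
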
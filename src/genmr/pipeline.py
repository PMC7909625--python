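"""End-to-end analysis: fill the full observational / MR report grid.

Mirrors the published reporting layout: four covariate models, each fitted
observationally and by 2SLS (AAM in years for models 1-2, generation-
standardized AAM for models 3-4), an adjusted-MR block (IVW, weighted
median, MR-Egger slope and intercept, MR-PRESSO, Cochran's Q) per exposure
form, a leave-one-out IVW scan, first-stage instrument diagnostics and a
confounder-balance table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .instruments import (
    FirstStageDiagnostics,
    confounder_balance,
    first_stage_diagnostics,
    grs_quartiles,
)
from .mr import (
    MODELS,
    EggerResult,
    HeterogeneityResult,
    ModelSpec,
    MREstimate,
    PressoResult,
    fit_2sls,
    fit_observational,
    ivw,
    leave_one_out,
    mr_egger,
    mr_presso,
    snp_summary_stats,
    weighted_median,
)
from .simulate import CohortData

__all__ = ["AnalysisReport", "run_models", "forest_table"]

#: covariate specification used when adjusting the per-SNP summary
#: statistics, per exposure form (the generation-adjusted models).
_SUMMARY_SPEC = {"aam": "model2", "gsaam": "model4"}

_REQUIRED_COLUMNS = ("aam", "gsaam", "cohort", "highly_educated", "bmi_young_adult")


@dataclass
class AnalysisReport:
    """Full result grid of one analysis run; JSON-serializable."""

    models: dict            # model name -> {"observational": MREstimate, "tsls": MREstimate}
    adjusted_mr: dict       # exposure -> {"ivw": ..., "weighted_median": ..., ...}
    loo: dict               # exposure -> leave-one-out DataFrame
    first_stage: dict       # exposure -> FirstStageDiagnostics
    balance: pd.DataFrame
    metadata: dict

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, (MREstimate, HeterogeneityResult, FirstStageDiagnostics)):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, EggerResult):
                return {"slope": conv(obj.slope), "intercept": conv(obj.intercept)}
            if isinstance(obj, PressoResult):
                return {
                    "global_rss_observed": obj.global_rss_observed,
                    "global_p": obj.global_p,
                    "outlier_p": obj.outlier_p.to_dict(),
                    "outliers": obj.outliers,
                    "distortion_p": conv(obj.distortion_p),
                    "estimate_before": conv(obj.estimate_before),
                    "estimate_after": conv(obj.estimate_after),
                }
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict(orient="records")
            if isinstance(obj, Mapping):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                f = float(obj)
                return None if np.isnan(f) else f
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        return {
            "models": conv(self.models),
            "adjusted_mr": conv(self.adjusted_mr),
            "leave_one_out": conv(self.loo),
            "first_stage": conv(self.first_stage),
            "confounder_balance": conv(self.balance),
            "metadata": conv(self.metadata),
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(payload)
        return payload


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_models(
    data: CohortData,
    panel: pd.DataFrame,
    grs,
    n_boot: int = 1000,
    seed: int = 0,
    models: tuple[str, ...] = ("model1", "model2", "model3", "model4"),
    confounders: tuple[str, ...] = ("education",),
    presso_n_sim: int = 1000,
) -> AnalysisReport:
    """Run the complete observational + MR analysis grid.

    Requires a standardized cohort (gsaam / cohort / highly_educated columns
    present) and a replicated SNP panel with its GRS. The 2SLS first stage
    uses the quartile-coded GRS, matching the per-quartile reporting
    convention; the adjusted-MR block uses covariate-adjusted per-SNP
    summary statistics. One master seed drives every stochastic component
    (bootstrap, weighted-median draws, PRESSO simulations).
    """
    pheno = data.phenotypes
    for col in _REQUIRED_COLUMNS:
        if col not in pheno.columns:
            raise KeyError(f"phenotype table is missing required column {col!r}")
    grs = np.asarray(grs, dtype=float)
    quart = grs_quartiles(grs).astype(float)
    ss = np.random.SeedSequence(seed)
    child = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(
        ("boot", "wm", "presso"), ss.spawn(3))}

    model_cells: dict[str, dict] = {}
    for name in models:
        spec = ModelSpec.get(name)
        model_cells[name] = {
            "observational": fit_observational(data, spec),
            "tsls": fit_2sls(data, spec, quart, n_boot=n_boot, seed=child["boot"]),
        }

    adjusted: dict[str, dict] = {}
    loo: dict[str, pd.DataFrame] = {}
    first_stage: dict[str, FirstStageDiagnostics] = {}
    exposures = sorted({ModelSpec.get(m).exposure for m in models})
    for exposure in exposures:
        spec = ModelSpec.get(_SUMMARY_SPEC[exposure])
        summaries = snp_summary_stats(data, panel, spec=spec)
        est_ivw, het = ivw(summaries)
        egger, egger_het = mr_egger(summaries)
        adjusted[exposure] = {
            "ivw": est_ivw,
            "ivw_q": het,
            "weighted_median": weighted_median(summaries, n_boot=n_boot, seed=child["wm"]),
            "egger": egger,
            "egger_q": egger_het,
            "presso": mr_presso(summaries, n_sim=presso_n_sim, seed=child["presso"]),
        }
        loo[exposure] = leave_one_out(summaries)
        first_stage[exposure] = first_stage_diagnostics(data, grs, exposure=exposure)

    balance = confounder_balance(data, grs, list(confounders))
    metadata = {
        "seed": seed,
        "n": len(pheno),
        "n_snps": len(panel),
        "n_boot": n_boot,
        "models": list(models),
        "config_hash": _config_hash(
            {"models": list(models), "n_boot": n_boot, "seed": seed, "snps": panel["snp"].tolist()}
        ),
    }
    return AnalysisReport(model_cells, adjusted, loo, first_stage, balance, metadata)


def forest_table(report: AnalysisReport) -> pd.DataFrame:
    """Plot-ready long table of every estimate in the report.

    One row per estimate (label, analysis type Obs/MR/MR-adjusted, model id,
    beta, ci_low, ci_high, p) — enough to draw the forest plot without
    recomputation. Empty blocks contribute no rows.
    """
    rows = []
    for name, cells in report.models.items():
        exposure = MODELS[name].exposure if name in MODELS else ""
        for kind, analysis in (("observational", "Obs"), ("tsls", "MR")):
            est = cells.get(kind)
            if est is None:
                continue
            rows.append(
                {"label": f"{name} {analysis}", "analysis": analysis, "model": name,
                 "exposure": exposure, "beta": est.beta, "ci_low": est.ci_low,
                 "ci_high": est.ci_high, "p": est.p}
            )
    for exposure, block in report.adjusted_mr.items():
        entries = [
            ("ivw", block.get("ivw")),
            ("weighted_median", block.get("weighted_median")),
            ("egger_slope", block["egger"].slope if "egger" in block else None),
            ("egger_intercept", block["egger"].intercept if "egger" in block else None),
            ("presso", block["presso"].estimate_before if "presso" in block else None),
        ]
        for label, est in entries:
            if est is None:
                continue
            rows.append(
                {"label": f"{label} ({exposure})", "analysis": "MR-adjusted",
                 "model": label, "exposure": exposure, "beta": est.beta,
                 "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p}
            )
    return pd.DataFrame(
        rows, columns=["label", "analysis", "model", "exposure", "beta", "ci_low", "ci_high", "p"]
    )
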
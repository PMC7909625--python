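"""Emit plot-ready tables from the analysis reports: the forest-plot long
table (one row per estimate) and the leave-one-out IVW scan per exposure.

Writes results/tables/<cohort>_forest.csv and <cohort>_loo_<exposure>.csv."""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"  # small tables only


def forest_rows(raw: dict) -> pd.DataFrame:
    rows = []
    for model, cells in raw["models"].items():
        for kind, label in (("observational", "Obs"), ("tsls", "MR")):
            e = cells[kind]
            rows.append({"label": f"{model} {label}", "analysis": label,
                         "model": model, "beta": e["beta"],
                         "ci_low": e["ci_low"], "ci_high": e["ci_high"], "p": e["p"]})
    for exposure, blk in raw["adjusted_mr"].items():
        flat = {"ivw": blk["ivw"], "weighted_median": blk["weighted_median"],
                "egger_slope": blk["egger"]["slope"],
                "egger_intercept": blk["egger"]["intercept"],
                "presso": blk["presso"]["estimate_before"]}
        for label, e in flat.items():
            rows.append({"label": f"{label} ({exposure})", "analysis": "MR-adjusted",
                         "model": label, "beta": e["beta"],
                         "ci_low": e["ci_low"], "ci_high": e["ci_high"], "p": e["p"]})
    return pd.DataFrame(rows)


def main() -> None:
    outdir = ROOT / "tables"
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("effect", "null"):
        raw = json.loads((ROOT / "reports" / f"{name}.json").read_text())
        forest = forest_rows(raw)
        forest.to_csv(outdir / f"{name}_forest.csv", index=False)
        for exposure, loo in raw["leave_one_out"].items():
            pd.DataFrame(loo).to_csv(outdir / f"{name}_loo_{exposure}.csv", index=False)
        print(f"{name}: forest table {len(forest)} rows; leave-one-out written "
              f"for {', '.join(raw['leave_one_out'])}")
        span = forest[forest["analysis"] == "MR"]["beta"]
        print(f"  2SLS betas span [{span.min():+.3f}, {span.max():+.3f}]")


if __name__ == "__main__":
    main()
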
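"""Fit the full observational + MR grid on both cohorts: models 1-4
(observational OLS and 2SLS with bootstrap SEs), the adjusted-MR block
(IVW, weighted median, MR-Egger, MR-PRESSO, Cochran's Q) per exposure form,
and the leave-one-out IVW scan.

Writes results/reports/<cohort>.json and a flat model-grid CSV.

The headline contrast: on the null cohort the crude observational slope is
spuriously nonzero (secular trends in AAM and BMI plus education drive it)
while every MR estimate is centered on zero; on the effect cohort all
estimators recover beta ~ -0.5 kg/m2 per year on the AAM scale."""

from pathlib import Path

import pandas as pd

from genmr import ModelSpec, fit_observational, io, run_models

SEED = 20260930
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    outdir = RESULTS / "reports"
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("effect", "null"):
        inst = SCRATCH / "instruments" / name
        data = io.read_cohort(inst / "phenotypes.csv", inst / "genotypes.csv")
        panel = io.read_panel(RESULTS / "instruments" / name / "panel_replicated.csv")
        report = run_models(
            data, panel, data.phenotypes["grs"].to_numpy(),
            n_boot=1000, seed=SEED,
        )
        report.to_json(outdir / f"{name}.json")

        rows = []
        for model, cells in report.models.items():
            for kind in ("observational", "tsls"):
                e = cells[kind]
                rows.append({"cohort": name, "model": model, "analysis": kind,
                             "beta": e.beta, "ci_low": e.ci_low, "ci_high": e.ci_high,
                             "p": e.p, "r2": e.r2})
        crude = fit_observational(data, ModelSpec("crude", "aam", ()))
        rows.append({"cohort": name, "model": "crude", "analysis": "observational",
                     "beta": crude.beta, "ci_low": crude.ci_low,
                     "ci_high": crude.ci_high, "p": crude.p, "r2": crude.r2})
        grid = pd.DataFrame(rows)
        grid.to_csv(outdir / f"{name}_model_grid.csv", index=False)

        print(f"\n== {name} cohort (true beta: {-0.5 if name == 'effect' else 0.0}) ==")
        print(f"crude observational: {crude.beta:+.3f} "
              f"[{crude.ci_low:+.3f}, {crude.ci_high:+.3f}] p={crude.p:.1e}")
        for model, cells in report.models.items():
            o, t = cells["observational"], cells["tsls"]
            print(f"{model}: obs {o.beta:+.3f} [{o.ci_low:+.3f},{o.ci_high:+.3f}] | "
                  f"2SLS {t.beta:+.3f} [{t.ci_low:+.3f},{t.ci_high:+.3f}]")
        blk = report.adjusted_mr["aam"]
        print(f"adjusted MR (AAM): IVW {blk['ivw'].beta:+.3f}, "
              f"WM {blk['weighted_median'].beta:+.3f}, "
              f"Egger slope {blk['egger'].slope.beta:+.3f} "
              f"(intercept {blk['egger'].intercept.beta:+.3f}), "
              f"Q={blk['ivw_q'].Q:.1f} (p={blk['ivw_q'].p:.2f})")


if __name__ == "__main__":
    main()
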
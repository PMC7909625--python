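"""Instrument construction on the standardized cohorts: genotype QC,
in-sample replication of the SNP panel, unweighted GRS oriented to earlier
menarche, first-stage strength and confounder balance.

Writes the QC report, replicated panel, first-stage diagnostics and
confounder-balance table under results/instruments/<cohort>/; the
GRS-augmented per-individual CSVs go to scratch/instruments/<cohort>/."""

import json
from pathlib import Path

from genmr import (
    QCCriteria,
    build_grs,
    confounder_balance,
    first_stage_diagnostics,
    io,
    qc_filter_snps,
    replicate_snps,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    for name in ("effect", "null"):
        std = SCRATCH / "standardized" / name
        data = io.read_cohort(std / "phenotypes.csv", std / "genotypes.csv")
        panel = io.read_panel(SCRATCH / "data" / name / "panel.csv")

        qc = qc_filter_snps(data.genotypes, QCCriteria())
        panel_qc = panel[panel["snp"].isin(qc.retained)].reset_index(drop=True)
        replicated = replicate_snps(panel_qc, data, alpha=0.05)
        grs = build_grs(data.genotypes, replicated)
        diag = first_stage_diagnostics(data, grs, exposure="aam")
        balance = confounder_balance(data, grs, ["education", "birth_year"])

        outdir = RESULTS / "instruments" / name
        outdir.mkdir(parents=True, exist_ok=True)
        heavy = SCRATCH / "instruments" / name
        heavy.mkdir(parents=True, exist_ok=True)
        qc.report.to_csv(outdir / "qc_report.csv", index=False)
        io.write_panel(replicated, outdir / "panel_replicated.csv")
        pheno = data.phenotypes.copy()
        pheno["grs"] = grs.to_numpy()
        pheno.to_csv(heavy / "phenotypes.csv", index=False)
        data.genotypes.to_csv(heavy / "genotypes.csv", index=True, index_label="id")
        (outdir / "first_stage.json").write_text(json.dumps({
            "coef_per_unit": diag.coef_per_unit, "ci_per_unit": list(diag.ci_per_unit),
            "coef_per_quartile": diag.coef_per_quartile,
            "F": diag.F, "F_quartile": diag.F_quartile,
            "R2": diag.R2, "n": diag.n}, indent=2))
        balance.to_csv(outdir / "confounder_balance.csv", index=False)

        print(f"{name}: {len(panel)} candidates -> {len(panel_qc)} pass QC -> "
              f"{len(replicated)} replicated (p<0.05, direction-consistent)")
        print(f"  first stage: AAM changes {diag.coef_per_unit:.3f} y per GRS unit, "
              f"F={diag.F:.1f}, R2={diag.R2:.4f} "
              f"({'strong' if diag.F > 10 else 'WEAK'} instrument)")
        worst = balance.loc[balance["p"].idxmin()]
        print(f"  confounder balance: smallest p={worst['p']:.2f} ({worst['confounder']}) "
              "- GRS unrelated to confounders, as required of a valid instrument")


if __name__ == "__main__":
    main()
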
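"""Flat-file interfaces: phenotype/genotype/reference/panel CSVs, run metadata."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import CohortData

PHENOTYPE_COLUMNS = ["id", "birth_year", "aam", "education", "bmi_young_adult"]


def write_cohort(data: CohortData, outdir: str | Path) -> None:
    """Write phenotypes.csv and genotypes.csv (missing calls as empty cells)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    data.genotypes.to_csv(outdir / "genotypes.csv", index=True, index_label="id")


def read_cohort(phenotypes: str | Path, genotypes: str | Path) -> CohortData:
    pheno = pd.read_csv(phenotypes)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {missing}")
    geno = pd.read_csv(genotypes, index_col="id")
    return CohortData(pheno, geno)


def write_reference(ref: pd.DataFrame, path: str | Path) -> None:
    ref.to_csv(path, index=False)


def read_reference(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    needed = {"snp", "published_direction"}
    missing = needed - set(panel.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    return panel


def write_metadata(path: str | Path, **fields) -> None:
    import genmr

    meta = {"genmr_version": genmr.__version__}
    meta.update(fields)
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
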
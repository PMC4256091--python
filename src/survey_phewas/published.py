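"""Loaders for the packaged published-result summary tables.

These TSVs transcribe printed summary tables from the genotyped NHANES
80-SNP PheWAS: per-survey cohort counts, the novel result groups, the
pleiotropic SNPs' result groups with per-class strata and effect signs,
the SNPs' nearest-gene annotations, and a curated prior-association
catalog with a lipid related-group.  They let bookkeeping stages
(classification, pleiotropy, generalization, cohort arithmetic) be
exercised against published numbers without access to the restricted
individual-level survey data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import Catalog
from .replicate import ReplicatedResult


def _read(name: str) -> pd.DataFrame:
    with resources.files("survey_phewas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_cohort() -> pd.DataFrame:
    """Per-survey n and % female (plus stratum percentages)."""
    df = _read("published_cohort.tsv")
    df["n"] = df["n"].astype(int)
    for c in df.columns:
        if c.startswith("pct"):
            df[c] = df[c].astype(float)
    return df


def load_novel_groups() -> pd.DataFrame:
    """Published novel (SNP, phenotype class, race-ethnicity) result groups."""
    return _read("published_novel_groups.tsv")


def load_pleiotropy_groups() -> pd.DataFrame:
    """Result groups of the published pleiotropic SNPs (class, stratum, sign)."""
    return _read("published_pleiotropy_groups.tsv")


def load_snp_annotations() -> pd.DataFrame:
    """Nearest gene, distance and genomic context per published SNP."""
    df = _read("published_snp_annotations.tsv")
    df["distance"] = df["distance"].astype(int)
    return df


def load_catalog() -> Catalog:
    """Prior-association catalog plus the lipid related-group membership."""
    entries = _read("published_catalog.tsv")
    groups = _read("published_related_groups.tsv")
    return Catalog.from_frames(entries, groups)


def groups_to_results(groups: pd.DataFrame) -> list[ReplicatedResult]:
    """Lift a (snp, class_label, stratum, direction) table into retained-result
    records so the classification stage can run on published groups."""
    return [
        ReplicatedResult(
            snp=r.snp, class_label=r.class_label, stratum=r.stratum, direction=r.direction
        )
        for r in groups.itertuples(index=False)
    ]
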
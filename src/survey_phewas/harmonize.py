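"""Phenotype harmonization: class binning, transforms, and combined variables.

Survey-specific phenotype measurements are mapped into phenotype classes via
an externally curated class map.  Continuous measurements are carried in two
versions — untransformed and ln(y+1)-transformed — as distinct measurements
of the same class.  Categorical phenotypes are expanded into one "A versus
not A" binary indicator per observed category.  Where the identical
measurement exists in both surveys, a combined-survey variable pools both
surveys' samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

log = logging.getLogger(__name__)

COMBINED = "combined"


class HarmonizationError(ValueError):
    pass


def transform_continuous(values: pd.Series | np.ndarray, name: str = "phenotype") -> pd.Series:
    """Natural-log transform y -> ln(y + 1); the +1 keeps zeros in the analysis.

    Missing values stay missing.  Negative input is a domain error naming
    the offending phenotype.
    """
    s = pd.Series(values, dtype=float, copy=True)
    if (s.dropna() < 0).any():
        raise HarmonizationError(f"{name}: ln(y+1) transform requires nonnegative values")
    return np.log1p(s)


def binarize_categorical(values: pd.Series, name: str = "phenotype") -> dict[str, pd.Series]:
    """Expand a categorical phenotype into per-category 0/1 indicator variables.

    Returns ``{"<name>=<category>": indicator}`` with one variable per
    observed category; missing input propagates to every indicator.  A
    single-category column carries no contrast and is skipped with a warning.
    """
    s = pd.Series(values)
    observed = sorted(s.dropna().unique().tolist(), key=str)
    if len(observed) < 2:
        log.warning("categorical phenotype %s has <2 observed categories; skipped", name)
        return {}
    out = {}
    missing = s.isna()
    for cat in observed:
        ind = (s == cat).astype(float)
        ind[missing] = np.nan
        out[f"{name}={cat}"] = ind
    return out


def bin_to_classes(
    descriptors: pd.DataFrame, class_map: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Assign each (survey, phenotype) descriptor its phenotype class.

    ``class_map`` columns: survey, phenotype, class_label.  Returns the
    descriptor table with a ``class_label`` column plus the list of
    unmapped phenotype names (excluded from replication matching).
    Duplicate conflicting assignments raise, listing the collisions.
    """
    cm = class_map.copy()
    dup = cm.groupby(["survey", "phenotype"])["class_label"].nunique()
    collisions = dup[dup > 1].index.tolist()
    if collisions:
        raise HarmonizationError(f"conflicting class assignments for: {collisions}")
    cm = cm.drop_duplicates(["survey", "phenotype"])
    merged = descriptors.merge(cm, on=["survey", "phenotype"], how="left", suffixes=("", "_map"))
    if "class_label_map" in merged.columns:
        merged["class_label"] = merged.pop("class_label_map")
    unmapped = merged.loc[merged["class_label"].isna(), "phenotype"].tolist()
    if unmapped:
        log.warning("%d phenotypes have no class assignment: %s", len(unmapped), unmapped[:10])
    return merged, unmapped


@dataclass
class MeasurementSet:
    """Analyzable measurements for one survey (or the pooled combined survey).

    ``values``: samples x measurements DataFrame; ``meta``: one row per
    measurement column with (measurement, phenotype, transform, class_label,
    ptype); ``strata``: per-sample stratum labels aligned with ``values``.
    """

    survey: str
    values: pd.DataFrame
    meta: pd.DataFrame
    strata: pd.Series


@dataclass
class CombinedVariable:
    """A phenotype measured identically in both surveys, pooled over samples."""

    class_label: str
    phenotype: str
    ptype: str
    values: pd.Series  # concatenated over both surveys' sample ids
    strata: pd.Series


def build_measurements(
    phenotypes: pd.DataFrame,
    meta: pd.DataFrame,
    survey: str,
    carry_transformed: bool = True,
) -> MeasurementSet:
    """Expand one survey's phenotype table into analyzable measurements.

    Continuous phenotypes yield an untransformed measurement and, when all
    observed values are nonnegative, an additional ln(y+1) version.  Binary
    phenotypes pass through; categorical phenotypes become per-category
    indicators inheriting the parent's class label.
    """
    sub = meta[meta["survey"] == survey]
    cols: dict[str, pd.Series] = {}
    rows = []
    for rec in sub.itertuples(index=False):
        name = rec.phenotype
        if name not in phenotypes.columns:
            log.warning("%s: phenotype %r missing from table; skipped", survey, name)
            continue
        series = phenotypes[name]
        cls = rec.class_label
        if rec.ptype == "continuous":
            s = pd.to_numeric(series, errors="coerce")
            cols[name] = s
            rows.append((name, name, "none", cls, "continuous"))
            if carry_transformed:
                if (s.dropna() >= 0).all():
                    tname = f"(ln+1){name}"
                    cols[tname] = transform_continuous(s, name)
                    rows.append((tname, name, "ln1p", cls, "continuous"))
                else:
                    log.warning("%s: %r has negative values; ln(y+1) version not carried", survey, name)
        elif rec.ptype == "binary":
            cols[name] = pd.to_numeric(series, errors="coerce")
            rows.append((name, name, "none", cls, "binary"))
        elif rec.ptype == "categorical":
            for ind_name, ind in binarize_categorical(series, name).items():
                cols[ind_name] = ind
                rows.append((ind_name, name, "none", cls, "binary"))
        else:
            raise HarmonizationError(f"unknown phenotype type {rec.ptype!r} for {name}")
    values = pd.DataFrame(cols, index=phenotypes.index)
    meta_out = pd.DataFrame(
        rows, columns=["measurement", "phenotype", "transform", "class_label", "ptype"]
    )
    return MeasurementSet(
        survey=survey, values=values, meta=meta_out, strata=phenotypes["stratum"]
    )


def harmonize_combined(
    phenotypes: Mapping[str, pd.DataFrame], meta: pd.DataFrame
) -> list[CombinedVariable]:
    """Pool exact-match phenotypes across both surveys.

    Only phenotypes measured under the identical raw name in both surveys
    are pooled; classes that are binned but not harmonized yield no combined
    variable.  Sample ids are disjoint across surveys by construction, so
    the pooled vector simply concatenates both surveys.
    """
    surveys = sorted(phenotypes)
    per_survey = {
        s: meta[meta["survey"] == s].set_index("phenotype") for s in surveys
    }
    if len(surveys) != 2:
        raise HarmonizationError("combined harmonization expects exactly two surveys")
    a, b = surveys
    out = []
    common = per_survey[a].index.intersection(per_survey[b].index)
    for name in common:
        rec_a, rec_b = per_survey[a].loc[name], per_survey[b].loc[name]
        if rec_a["ptype"] != rec_b["ptype"] or rec_a["class_label"] != rec_b["class_label"]:
            log.warning("phenotype %r differs in type/class across surveys; not pooled", name)
            continue
        pooled = pd.concat([phenotypes[a][name], phenotypes[b][name]])
        strata = pd.concat([phenotypes[a]["stratum"], phenotypes[b]["stratum"]])
        if pooled.index.duplicated().any():
            raise HarmonizationError(f"sample ids overlap across surveys for {name!r}")
        out.append(
            CombinedVariable(
                class_label=rec_a["class_label"],
                phenotype=name,
                ptype=rec_a["ptype"],
                values=pooled,
                strata=strata,
            )
        )
    return out


def build_combined_measurements(
    combined_vars: Iterable[CombinedVariable], carry_transformed: bool = True
) -> MeasurementSet | None:
    """Assemble combined variables into a MeasurementSet for the pooled scan."""
    combined_vars = list(combined_vars)
    if not combined_vars:
        return None
    values = pd.DataFrame({v.phenotype: v.values for v in combined_vars})
    meta = pd.DataFrame(
        {
            "survey": COMBINED,
            "phenotype": [v.phenotype for v in combined_vars],
            "class_label": [v.class_label for v in combined_vars],
            "ptype": [v.ptype for v in combined_vars],
        }
    )
    table = values.copy()
    table["stratum"] = combined_vars[0].strata
    return build_measurements(table, meta, COMBINED, carry_transformed=carry_transformed)


def summarize_cohort(phenotypes: Mapping[str, pd.DataFrame]) -> dict:
    """Per-survey and pooled demographics plus the sex-by-survey chi-square.

    The pooled % female is the count-weighted mean across surveys; the
    chi-square is Pearson's statistic on the 2x2 sex x survey table without
    continuity correction.
    """
    summary: dict = {"surveys": {}}
    counts = {}
    for survey, table in sorted(phenotypes.items()):
        n = len(table)
        entry: dict = {"n": n}
        if "sex" in table.columns:
            n_female = int((table["sex"] == "F").sum())
            entry["pct_female"] = 100.0 * n_female / n if n else float("nan")
            counts[survey] = (n_female, n - n_female)
        else:
            log.warning("%s: no sex column; demographic summary incomplete", survey)
        if "stratum" in table.columns:
            entry["stratum_pct"] = (
                (100.0 * table["stratum"].value_counts() / n).round(4).to_dict()
            )
        summary["surveys"][survey] = entry
    total_n = sum(e["n"] for e in summary["surveys"].values())
    summary["pooled_n"] = total_n
    if counts and len(counts) == len(phenotypes):
        total_female = sum(f for f, _ in counts.values())
        summary["pooled_pct_female"] = 100.0 * total_female / total_n
        if len(counts) == 2:
            table_2x2 = np.array([list(counts[s]) for s in sorted(counts)])
            res = chi2_contingency(table_2x2, correction=False)
            summary["sex_by_survey_chi2"] = float(res.statistic)
            summary["sex_by_survey_chi2_p"] = float(res.pvalue)
            summary["sex_by_survey_df"] = int(res.dof)
    return summary


def summarize_cohort_from_counts(per_survey: Mapping[str, tuple[int, float]]) -> dict:
    """Cohort summary from published (n, % female) pairs per survey.

    Female counts are reconstructed as round(n * pct / 100); used to audit
    printed cohort tables without access to individual-level data.
    """
    tables = {}
    for survey, (n, pct_female) in per_survey.items():
        n_female = int(round(n * pct_female / 100.0))
        sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
        tables[survey] = pd.DataFrame({"sex": sex})
    return summarize_cohort(tables)
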
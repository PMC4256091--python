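"""Cross-survey replication filter for PheWAS results.

A (SNP, phenotype class, stratum) group is a significant PheWAS result only
when every one of seven criteria holds: an association observed in BOTH
surveys, with p < 0.01, coded-allele frequency > 0.01, sample size > 200,
for the same race-ethnicity stratum, the same phenotype class, and the same
direction of effect.  All thresholds are strict inequalities.

Transformed and untransformed versions of a phenotype are distinct
measurements on different scales, so a qualifying cross-survey pair must
match on transform status; a beta of exactly zero has no direction and can
never form a pair.  Within each survey of a retained group the qualifying
measurement with the lowest p is designated best (ties: larger n, then
lexicographic measurement name).  Where the class has a pooled combined-
survey variable, the best combined re-test is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .harmonize import COMBINED
from .scan import FLAG_OK

P_THRESHOLD = 0.01
CAF_THRESHOLD = 0.01
MIN_SAMPLE_SIZE = 200

GROUP_KEYS = ["snp", "class_label", "stratum"]

_MEASUREMENT_FIELDS = ["measurement", "phenotype", "transform", "beta", "se", "p", "n", "caf"]


@dataclass
class ReplicatedResult:
    """One retained (SNP, class, stratum) group with per-survey best results."""

    snp: str
    class_label: str
    stratum: str
    direction: str  # "+" or "-"
    best: dict[str, dict] = field(default_factory=dict)  # survey -> measurement record
    pairs: list[tuple[str, str]] = field(default_factory=list)  # qualifying (S1, S2) measurement names
    combined: dict | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.snp, self.class_label, self.stratum)


def qualifying_mask(
    results: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    caf_threshold: float = CAF_THRESHOLD,
    min_n: int = MIN_SAMPLE_SIZE,
) -> pd.Series:
    """Per-row qualification: available, p, CAF and n criteria, nonzero beta."""
    return (
        (results["flag"] == FLAG_OK)
        & (results["p"] < p_threshold)
        & (results["caf"] > caf_threshold)
        & (results["n"] > min_n)
        & (results["beta"] != 0)
        & results["beta"].notna()
    )


def _rank_key(df: pd.DataFrame) -> pd.DataFrame:
    """Sort order implementing lowest-p / largest-n / name tie-breaks."""
    return df.sort_values(["p", "n", "measurement"], ascending=[True, False, True], kind="mergesort")


def select_best_per_class(group: pd.DataFrame) -> pd.Series:
    """Best qualifying measurement of one survey's group: lowest p wins,
    ties broken by larger n, then lexicographic measurement name."""
    return _rank_key(group).iloc[0]


def apply_replication_criteria(
    results: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    caf_threshold: float = CAF_THRESHOLD,
    min_n: int = MIN_SAMPLE_SIZE,
) -> list[ReplicatedResult]:
    """Apply the seven-criterion filter to a scan result table.

    Returns retained groups in deterministic (snp, class, stratum) order;
    an empty list is a valid outcome.  Output is invariant to the input
    row ordering.
    """
    if results.empty:
        return []
    per_survey = results[results["survey"] != COMBINED]
    surveys = sorted(per_survey["survey"].unique())
    if len(surveys) < 2:
        return []
    s1, s2 = surveys[:2]
    q = per_survey[qualifying_mask(per_survey, p_threshold, caf_threshold, min_n)].copy()
    if q.empty:
        return []
    q["sign"] = np.sign(q["beta"])
    qa = q[q["survey"] == s1]
    qb = q[q["survey"] == s2]
    pairs = qa.merge(
        qb,
        on=GROUP_KEYS + ["transform", "sign"],
        suffixes=("_a", "_b"),
    )
    if pairs.empty:
        return []

    retained: list[ReplicatedResult] = []
    for key, grp in pairs.groupby(GROUP_KEYS, sort=True):
        snp, class_label, stratum = key
        # direction follows the globally most significant pair member
        member_p = np.minimum(grp["p_a"].to_numpy(), grp["p_b"].to_numpy())
        signs = grp["sign"].to_numpy()
        best_sign = signs[np.lexsort((grp["measurement_a"], -np.maximum(grp["n_a"], grp["n_b"]), member_p))[0]]
        dgrp = grp[grp["sign"] == best_sign]
        best = {}
        for survey, suffix in ((s1, "_a"), (s2, "_b")):
            # "transform" is a join key so it carries no suffix
            cols = {(f if f == "transform" else f"{f}{suffix}"): f for f in _MEASUREMENT_FIELDS}
            sub = dgrp[list(cols)].rename(columns=cols).drop_duplicates("measurement")
            rec = select_best_per_class(sub)
            best[survey] = {f: rec[f] for f in _MEASUREMENT_FIELDS}
        retained.append(
            ReplicatedResult(
                snp=snp,
                class_label=class_label,
                stratum=stratum,
                direction="+" if best_sign > 0 else "-",
                best=best,
                pairs=sorted(zip(dgrp["measurement_a"], dgrp["measurement_b"])),
            )
        )
    return retained


def combined_retest(
    retained: Iterable[ReplicatedResult], results: pd.DataFrame
) -> list[ReplicatedResult]:
    """Attach the best combined-survey re-test to each retained group.

    The combined result with the lowest p among available combined rows of
    the group's class (same SNP and stratum) is attached; a class with no
    harmonized combined variable simply keeps ``combined=None``.
    """
    retained = list(retained)
    combined = results[(results["survey"] == COMBINED) & (results["flag"] == FLAG_OK)]
    if combined.empty:
        return retained
    grouped = dict(iter(combined.groupby(GROUP_KEYS, sort=False)))
    for rec in retained:
        grp = grouped.get(rec.key)
        if grp is None or grp.empty:
            rec.combined = None
            continue
        best = select_best_per_class(grp)
        rec.combined = {f: best[f] for f in _MEASUREMENT_FIELDS}
    return retained


def retained_to_frame(retained: Iterable[ReplicatedResult]) -> pd.DataFrame:
    """Flatten retained groups into the exported table layout.

    Mirrors the published result-matrix columns: per-survey best p, beta,
    CAF, n, transform presence, direction as +/-, plus combined re-test
    columns when available.
    """
    rows = []
    for rec in sorted(retained, key=lambda r: r.key):
        row: dict = {
            "snp": rec.snp,
            "class_label": rec.class_label,
            "stratum": rec.stratum,
            "direction": rec.direction,
            "n_qualifying_pairs": len(rec.pairs),
        }
        for survey, best in rec.best.items():
            for f in _MEASUREMENT_FIELDS:
                row[f"{survey}_{f}"] = best[f]
        if rec.combined is not None:
            for f in _MEASUREMENT_FIELDS:
                row[f"combined_{f}"] = rec.combined[f]
        rows.append(row)
    return pd.DataFrame(rows)
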
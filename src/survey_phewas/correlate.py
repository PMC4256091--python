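"""Pairwise phenotype correlations among PheWAS-significant phenotypes.

Pearson correlations are computed on pairwise-complete observations per
cell, per survey and stratum.  Partners above the 0.6 screen are reported
on signed r (strict inequality); the clustered heatmap export takes |r| and
orders rows/columns by complete-linkage hierarchical clustering on the
Euclidean distance between |r| rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

PARTNER_THRESHOLD = 0.6
MIN_PAIRWISE_N = 3


@dataclass
class CorrelationMatrix:
    phenotypes: list[str]
    r: pd.DataFrame  # symmetric, unit diagonal, NaN where unavailable
    n: pd.DataFrame  # pairwise-complete count per cell
    survey: str = ""
    stratum: str = ""


def compute_correlations(
    table: pd.DataFrame,
    phenotypes: Sequence[str],
    survey: str = "",
    stratum: str = "",
    min_n: int = MIN_PAIRWISE_N,
) -> CorrelationMatrix:
    """Pearson r between the listed phenotype columns, pairwise-complete.

    Cells with fewer than ``min_n`` complete pairs, and every cell of a
    zero-variance phenotype, are left unavailable (NaN) and logged.
    """
    phenotypes = [p for p in phenotypes if p in table.columns]
    if len(phenotypes) < 2:
        raise ValueError("need at least two phenotypes to correlate")
    sub = table[phenotypes].astype(float)
    if stratum and "stratum" in table.columns:
        sub = sub[table["stratum"] == stratum]
    present = sub.notna().astype(float)
    n = pd.DataFrame(present.T @ present, index=phenotypes, columns=phenotypes)
    r = sub.corr(method="pearson", min_periods=max(min_n, 2))
    zero_var = [p for p in phenotypes if sub[p].std(skipna=True) == 0 or sub[p].notna().sum() < 2]
    for p in zero_var:
        log.warning("phenotype %r has zero variance or too few observations; cells unavailable", p)
        r.loc[p, :] = np.nan
        r.loc[:, p] = np.nan
    r = r.mask(n < min_n)
    # the diagonal is 1 wherever the phenotype has any variance
    for p in phenotypes:
        if p not in zero_var and n.loc[p, p] >= min_n:
            r.loc[p, p] = 1.0
    return CorrelationMatrix(phenotypes=list(phenotypes), r=r, n=n, survey=survey, stratum=stratum)


def report_partners(
    matrix: CorrelationMatrix, threshold: float = PARTNER_THRESHOLD
) -> pd.DataFrame:
    """Phenotype pairs with signed r strictly above the threshold."""
    rows = []
    r = matrix.r
    for i, a in enumerate(matrix.phenotypes):
        for b in matrix.phenotypes[i + 1 :]:
            val = r.loc[a, b]
            if pd.notna(val) and val > threshold:
                rows.append(
                    {
                        "survey": matrix.survey,
                        "stratum": matrix.stratum,
                        "phenotype_a": a,
                        "phenotype_b": b,
                        "r": float(val),
                        "n": int(matrix.n.loc[a, b]),
                    }
                )
    return pd.DataFrame(rows, columns=["survey", "stratum", "phenotype_a", "phenotype_b", "r", "n"])


def heatmap_export(matrix: CorrelationMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Clustered |r| matrix and its leaf order.

    Unavailable cells are imputed as 0 for ordering only; the returned
    matrix carries |r| with the imputation kept (entries in [0, 1]) so any
    plotting layer reproduces the published heatmap layout.
    """
    absr = matrix.r.abs().fillna(0.0).clip(0.0, 1.0)  # collinear pairs can exceed 1 by an ulp
    np.fill_diagonal(absr.values, 1.0)
    if len(matrix.phenotypes) < 3:
        order = list(matrix.phenotypes)
    else:
        dist = squareform(np.sqrt(((absr.values[:, None, :] - absr.values[None, :, :]) ** 2).sum(-1)), checks=False)
        Z = linkage(dist, method="complete")
        order = [matrix.phenotypes[i] for i in dendrogram(Z, no_plot=True)["leaves"]]
    return absr.loc[order, order], order


def write_correlation_outputs(
    matrix: CorrelationMatrix, outdir: str | Path, tag: str
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.r.to_csv(outdir / f"correlation_{tag}.tsv", sep="\t", float_format="%.6g")
    partners = report_partners(matrix)
    partners.to_csv(outdir / f"correlation_partners_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
    clustered, order = heatmap_export(matrix)
    clustered.to_csv(outdir / f"correlation_heatmap_{tag}.tsv", sep="\t", float_format="%.6g")
    (outdir / f"correlation_order_{tag}.txt").write_text("\n".join(order) + "\n")
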
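"""Unadjusted additive-model single-SNP association tests.

Every SNP x phenotype measurement is tested per survey and per stratum with
no covariates: ordinary least squares for continuous measurements (two-sided
p from the slope's t statistic on n-2 df) and maximum-likelihood logistic
regression for binary measurements (Wald p against the standard normal).
Analyses are complete-case per SNP-measurement pair, and the coded-allele
frequency (CAF) is computed on exactly the analyzed subset.

The continuous scan is a hand-vectorized closed form: for one genotype
vector against a matrix of phenotype columns with independent missingness,
per-column sums over the presence mask give slope, SE, t and CAF in a few
matrix products.  ``fit_linear`` exposes the same closed form for a single
pair; tests compare it against :func:`scipy.stats.linregress` as an
independent oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .harmonize import COMBINED, MeasurementSet

log = logging.getLogger(__name__)

MIN_N_LINEAR = 3
LOGIT_MAXITER = 50
LOGIT_TOL = 1e-8
SEPARATION_SE = 100.0

FLAG_OK = "ok"
FLAG_UNAVAILABLE = "unavailable"
FLAG_SEPARATION = "separation"
FLAG_NONCONVERGED = "nonconverged"

RESULT_COLUMNS = [
    "snp",
    "coded_allele",
    "phenotype",
    "measurement",
    "transform",
    "class_label",
    "survey",
    "stratum",
    "beta",
    "se",
    "p",
    "n",
    "caf",
    "flag",
]


@dataclass(frozen=True)
class AssociationResult:
    """One SNP x measurement x survey x stratum regression outcome."""

    snp: str
    phenotype: str
    survey: str
    stratum: str
    beta: float
    se: float
    p: float
    n: int
    caf: float
    flag: str = FLAG_OK
    coded_allele: str = ""
    transform: str = "none"
    class_label: str = ""

    @property
    def available(self) -> bool:
        return self.flag == FLAG_OK


def coded_allele_frequency(g: np.ndarray | Sequence[float]) -> float:
    """CAF = (sum of 0/1/2 dosages) / (2 x non-missing count)."""
    g = np.asarray(g, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        return float("nan")
    return float(g.sum() / (2.0 * g.size))


def _linear_block(
    g: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form OLS of each column of ``Y`` on ``g`` (with intercept).

    ``g`` must be free of missing values; NaNs in ``Y`` define per-column
    complete cases.  Returns (beta, se, p, n, caf, valid).
    """
    M = ~np.isnan(Y)
    Y0 = np.where(M, Y, 0.0)
    n = M.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        Sg = g @ M
        gbar = Sg / n
        ybar = Y0.sum(axis=0) / n
        Yc = np.where(M, Y - ybar, 0.0)
        Sxx = (g * g) @ M - n * gbar**2
        Sxy = g @ Yc
        Syy = (Yc * Yc).sum(axis=0)
        beta = Sxy / Sxx
        sse = np.clip(Syy - beta**2 * Sxx, 0.0, None)
        df = n - 2
        se = np.sqrt(sse / df / Sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        caf = Sg / (2.0 * n)
    valid = (n >= MIN_N_LINEAR) & (Sxx > 0) & (Syy > 0) & np.isfinite(se) & (se > 0)
    # keep p in (0, 1]: a numerically-zero p is floored at the smallest positive float
    p = np.where(p <= 0, np.nextafter(0, 1), p)
    return beta, se, p, n, caf, valid


def fit_linear(y: Sequence[float], g: Sequence[float]) -> AssociationResult:
    """OLS of y on genotype dosage with intercept, on complete cases only.

    Degenerate inputs (constant genotype, constant phenotype, fewer than
    three complete cases) yield a result flagged unavailable rather than an
    exception.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = ~(np.isnan(y) | np.isnan(g))
    y, g = y[mask], g[mask]
    n = int(y.size)
    caf = coded_allele_frequency(g) if n else float("nan")
    beta, se, p, _, _, valid = _linear_block(g, y[:, None])
    if not valid[0]:
        beta0 = 0.0 if n and np.ptp(y) == 0 else float("nan")
        return AssociationResult("", "", "", "", beta0, float("nan"), float("nan"), n, caf, FLAG_UNAVAILABLE)
    return AssociationResult("", "", "", "", float(beta[0]), float(se[0]), float(p[0]), n, caf)


def fit_logistic(y: Sequence[float], g: Sequence[float]) -> AssociationResult:
    """ML logistic regression of a 0/1 outcome on dosage, Wald two-sided p.

    Non-convergence within 50 Newton iterations and (quasi-)separation
    (SE above 100 on the coded scale) are flagged, not raised; a single
    outcome level makes the fit unavailable.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = ~(np.isnan(y) | np.isnan(g))
    y, g = y[mask], g[mask]
    n = int(y.size)
    caf = coded_allele_frequency(g) if n else float("nan")
    nan_result = lambda flag: AssociationResult(
        "", "", "", "", float("nan"), float("nan"), float("nan"), n, caf, flag
    )
    if n < MIN_N_LINEAR or np.ptp(g) == 0 or len(np.unique(y)) < 2:
        return nan_result(FLAG_UNAVAILABLE)
    X = sm.add_constant(g)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(method="newton", maxiter=LOGIT_MAXITER, tol=LOGIT_TOL, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return nan_result(FLAG_SEPARATION)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > SEPARATION_SE or abs(beta) > SEPARATION_SE:
        return nan_result(FLAG_SEPARATION)
    if not fit.mle_retvals.get("converged", False):
        return nan_result(FLAG_NONCONVERGED)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    p = float(np.nextafter(0, 1)) if p <= 0 else float(p)
    return AssociationResult("", "", "", "", beta, se, p, n, caf)


def run_scan(
    genotypes: Mapping[str, pd.DataFrame],
    measurements: Mapping[str, MeasurementSet],
    coded_alleles: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Full scan: one row per SNP x measurement x survey x stratum.

    ``genotypes`` maps survey id to a wide genotype table (``stratum``
    column plus one dosage column per SNP) indexed like the survey's
    measurement values; a ``combined`` entry must accompany a combined
    MeasurementSet.  Output rows are deterministically ordered by
    (snp, class, measurement, survey, stratum).
    """
    coded_alleles = coded_alleles or {}
    rows: list[tuple] = []
    for survey in sorted(measurements):
        mset = measurements[survey]
        geno = genotypes[survey]
        snp_cols = [c for c in geno.columns if c != "stratum"]
        values = mset.values.reindex(geno.index)
        meta = mset.meta
        cont_meta = meta[meta["ptype"] == "continuous"]
        bin_meta = meta[meta["ptype"] == "binary"]
        cont_cols = cont_meta["measurement"].tolist()
        bin_cols = bin_meta["measurement"].tolist()
        # plain tuples; per-row .loc lookups are too slow for large scans
        cont_info = list(zip(cont_cols, cont_meta["phenotype"], cont_meta["transform"], cont_meta["class_label"]))
        bin_info = list(zip(bin_cols, bin_meta["phenotype"], bin_meta["transform"], bin_meta["class_label"]))
        strata_arr = geno["stratum"].to_numpy()
        for stratum in sorted(pd.unique(strata_arr)):
            in_stratum = strata_arr == stratum
            Yc = values.loc[in_stratum, cont_cols].to_numpy(dtype=float) if cont_cols else None
            Yb = values.loc[in_stratum, bin_cols].to_numpy(dtype=float) if bin_cols else None
            G = geno.loc[in_stratum, snp_cols].to_numpy(dtype=float)
            for j, snp in enumerate(snp_cols):
                g = G[:, j]
                gmask = ~np.isnan(g)
                g_obs = g[gmask]
                constant_g = g_obs.size == 0 or np.ptp(g_obs) == 0
                allele = coded_alleles.get(snp, "")
                if Yc is not None:
                    if constant_g:
                        caf0 = coded_allele_frequency(g_obs)
                        for k, (mcol, phen, transform, cls) in enumerate(cont_info):
                            n_k = int((~np.isnan(Yc[gmask, k])).sum()) if g_obs.size else 0
                            rows.append(
                                (snp, allele, phen, mcol, transform, cls, survey, stratum,
                                 np.nan, np.nan, np.nan, n_k, caf0, FLAG_UNAVAILABLE)
                            )
                    else:
                        beta, se, p, n, caf, valid = _linear_block(g_obs, Yc[gmask])
                        n_int = n.astype(int)
                        for k, (mcol, phen, transform, cls) in enumerate(cont_info):
                            if valid[k]:
                                rows.append(
                                    (snp, allele, phen, mcol, transform, cls, survey, stratum,
                                     beta[k], se[k], p[k], n_int[k], caf[k], FLAG_OK)
                                )
                            else:
                                rows.append(
                                    (snp, allele, phen, mcol, transform, cls, survey, stratum,
                                     np.nan, np.nan, np.nan, n_int[k],
                                     caf[k] if n_int[k] else np.nan, FLAG_UNAVAILABLE)
                                )
                if Yb is not None:
                    for k, (mcol, phen, transform, cls) in enumerate(bin_info):
                        res = fit_logistic(Yb[:, k], g)
                        rows.append(
                            (snp, allele, phen, mcol, transform, cls, survey, stratum,
                             res.beta, res.se, res.p, res.n, res.caf, res.flag)
                        )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if out.empty:
        log.warning("scan produced zero analyzable SNP-measurement pairs")
        return out
    survey_order = [s for s in sorted(measurements) if s != COMBINED]
    if COMBINED in measurements:
        survey_order.append(COMBINED)
    out["survey"] = pd.Categorical(out["survey"], categories=survey_order, ordered=True)
    out = out.sort_values(
        ["snp", "class_label", "measurement", "survey", "stratum"], kind="mergesort"
    ).reset_index(drop=True)
    out["survey"] = out["survey"].astype(str)
    return out


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
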
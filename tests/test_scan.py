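"""Association kernels: OLS vs scipy oracle, logistic vs likelihood grid,
CAF arithmetic, scan cardinality and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from survey_phewas.config import PhenotypeSpec, PopulationConfig, SnpSpec
from survey_phewas.harmonize import build_measurements
from survey_phewas.scan import (
    FLAG_SEPARATION,
    FLAG_UNAVAILABLE,
    coded_allele_frequency,
    fit_linear,
    fit_logistic,
    run_scan,
)
from survey_phewas.synthetic import generate_dataset, null_scan_tables
from conftest import small_config


class TestFitLinear:
    def test_textbook_example(self):
        r = fit_linear([1.0, 1.2, 1.5, 1.7, 2.0, 2.2], [0, 0, 1, 1, 2, 2])
        assert r.beta == pytest.approx(0.5, abs=1e-12)
        assert r.se == pytest.approx(0.061237, abs=1e-6)
        assert r.p == pytest.approx(0.0012249, rel=1e-4)
        assert r.n == 6 and r.caf == pytest.approx(0.5)

    def test_matches_scipy_linregress_on_random_instances(self, rng):
        for _ in range(200):
            n = rng.integers(5, 60)
            g = rng.binomial(2, rng.uniform(0.1, 0.9), n).astype(float)
            if np.ptp(g) == 0:
                continue
            y = rng.normal(rng.uniform(-50, 50), rng.uniform(0.5, 20), n)
            ours = fit_linear(y, g)
            ref = stats.linregress(g, y)
            assert ours.beta == pytest.approx(ref.slope, rel=1e-10, abs=1e-12)
            assert ours.se == pytest.approx(ref.stderr, rel=1e-10, abs=1e-12)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-8, abs=1e-300)

    def test_constant_phenotype_flagged_unavailable_with_zero_beta(self):
        r = fit_linear([3.0, 3.0, 3.0, 3.0], [0, 1, 1, 2])
        assert r.flag == FLAG_UNAVAILABLE
        assert r.beta == 0.0 and np.isnan(r.p)

    def test_constant_genotype_flagged_unavailable(self):
        r = fit_linear([1.0, 2.0, 3.0], [1, 1, 1])
        assert r.flag == FLAG_UNAVAILABLE

    def test_too_few_complete_cases_flagged(self):
        r = fit_linear([1.0, np.nan, 3.0], [0, 1, 2])
        assert r.flag == FLAG_UNAVAILABLE and r.n == 2

    def test_permutation_invariance(self, rng):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        y = rng.normal(size=8)
        perm = rng.permutation(8)
        a, b = fit_linear(y, g), fit_linear(y[perm], g[perm])
        assert (a.beta, a.se, a.p) == pytest.approx((b.beta, b.se, b.p))

    def test_doubling_y_doubles_beta_and_se_keeps_p(self, rng):
        g = rng.binomial(2, 0.4, 30).astype(float)
        y = rng.normal(10, 2, 30)
        a, b = fit_linear(y, g), fit_linear(2 * y, g)
        assert b.beta == pytest.approx(2 * a.beta, rel=1e-10)
        assert b.se == pytest.approx(2 * a.se, rel=1e-10)
        assert b.p == pytest.approx(a.p, rel=1e-10)


def _grid_logistic_mle(y, g):
    """Independent oracle: direct maximization of the Bernoulli likelihood."""

    def nll(params):
        eta = params[0] + params[1] * g
        return np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta)

    # coarse grid then Nelder-Mead polish, no reuse of the scan's machinery
    best, best_val = None, np.inf
    for b0 in np.linspace(-4, 4, 33):
        for b1 in np.linspace(-4, 4, 33):
            v = nll((b0, b1))
            if v < best_val:
                best, best_val = (b0, b1), v
    res = optimize.minimize(nll, best, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    return res.x[1]


class TestFitLogistic:
    def test_matches_brute_force_likelihood_maximizer(self, rng):
        for seed in range(8):
            local = np.random.default_rng(seed)
            g = local.binomial(2, 0.5, 12).astype(float)
            y = local.binomial(1, 0.5, 12).astype(float)
            if np.ptp(g) == 0 or len(np.unique(y)) < 2:
                continue
            ours = fit_logistic(y, g)
            if ours.flag != "ok":  # separable tiny draws are legitimately flagged
                continue
            assert ours.beta == pytest.approx(_grid_logistic_mle(y, g), abs=1e-4)

    def test_null_effect_estimates_are_small_at_large_n(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, 5000).astype(float)
        y = rng.binomial(1, 0.3, 5000).astype(float)
        r = fit_logistic(y, g)
        assert r.flag == "ok" and abs(r.beta) < 0.1

    def test_perfect_separation_flagged(self):
        g = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2], dtype=float)
        y = (g == 2).astype(float)
        assert fit_logistic(y, g).flag == FLAG_SEPARATION

    def test_single_outcome_level_unavailable(self):
        r = fit_logistic([1.0, 1.0, 1.0, 1.0], [0, 1, 2, 1])
        assert r.flag == FLAG_UNAVAILABLE


class TestCAF:
    def test_direct_count(self):
        assert coded_allele_frequency([0, 1, 2, 2]) == pytest.approx(0.625)

    def test_all_homozygous_coded(self):
        assert coded_allele_frequency([2, 2, 2]) == 1.0

    def test_complement_identity(self, rng):
        for _ in range(20):
            g = rng.binomial(2, rng.uniform(0.05, 0.95), 50).astype(float)
            assert coded_allele_frequency(g) + coded_allele_frequency(2 - g) == pytest.approx(1.0)

    def test_all_missing_unavailable(self):
        assert np.isnan(coded_allele_frequency([np.nan, np.nan]))


class TestRunScan:
    def test_result_cardinality(self):
        """2 SNPs x 3 continuous measurements (x2 transform versions)
        x 2 surveys x 1 stratum, plus combined rows for harmonized classes."""
        cfg = small_config(missing_rate=0.0)
        ds = generate_dataset(cfg)
        msets = {
            s: build_measurements(ds.phenotypes[s], ds.pheno_meta, s) for s in ("S1", "S2")
        }
        res = run_scan(ds.genotypes, msets)
        # 3 phenotypes -> 6 measurements per survey; 2 snps; 2 surveys
        assert len(res) == 2 * 6 * 2
        assert (res["flag"] == "ok").all()

    def test_output_order_deterministic_and_input_order_invariant(self):
        cfg = small_config(missing_rate=0.0)
        ds = generate_dataset(cfg)
        msets = {s: build_measurements(ds.phenotypes[s], ds.pheno_meta, s) for s in ("S1", "S2")}
        res1 = run_scan(ds.genotypes, msets)
        shuffled_geno = {s: g.iloc[::-1] for s, g in ds.genotypes.items()}
        shuffled_msets = {
            s: build_measurements(ds.phenotypes[s].iloc[::-1], ds.pheno_meta, s)
            for s in ("S1", "S2")
        }
        res2 = run_scan(shuffled_geno, shuffled_msets)
        pd.testing.assert_frame_equal(res1, res2)

    def test_null_pvalues_uniform(self):
        """Scan p-values under a Gaussian null pass a KS uniformity check."""
        genotypes, measurements = null_scan_tables(
            n_snps=10, n_measurements=100, n_per_stratum=300, strata=("A",), seed=3
        )
        res = run_scan(genotypes, measurements)
        p = res.loc[res["flag"] == "ok", "p"].to_numpy()
        assert len(p) == 2000
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_planted_effect_signs_recovered(self, default_dataset):
        ds = default_dataset
        msets = {s: build_measurements(ds.phenotypes[s], ds.pheno_meta, s) for s in ("S1", "S2")}
        res = run_scan(ds.genotypes, msets)
        for rec in ds.truth.itertuples(index=False):
            if rec.class_label == "Diabetes":
                continue  # binary effects at this n are deliberately lower-powered
            sub = res[
                (res["snp"] == rec.snp)
                & (res["class_label"] == rec.class_label)
                & (res["stratum"] == rec.stratum)
                & (res["flag"] == "ok")
            ]
            best = sub.loc[sub["p"].idxmin()]
            assert np.sign(best["beta"]) == (1 if rec.sign == "+" else -1)
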
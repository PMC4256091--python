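"""Harmonization: transforms, categorical binarization, class binning,
combined variables, cohort summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from survey_phewas.harmonize import (
    HarmonizationError,
    bin_to_classes,
    binarize_categorical,
    build_measurements,
    harmonize_combined,
    summarize_cohort,
    transform_continuous,
)


class TestTransform:
    def test_zero_maps_to_zero(self):
        assert transform_continuous(pd.Series([0.0]))[0] == 0.0

    def test_analytic_identity_e_minus_one(self):
        out = transform_continuous(pd.Series([np.e - 1.0]))
        assert out[0] == pytest.approx(1.0, abs=1e-12)

    def test_missing_stays_missing(self):
        out = transform_continuous(pd.Series([1.0, np.nan, 3.0]))
        assert out.isna().tolist() == [False, True, False]

    def test_negative_input_names_the_phenotype(self):
        with pytest.raises(HarmonizationError, match="serum foo"):
            transform_continuous(pd.Series([1.0, -0.5]), name="serum foo")

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=20, unique=True))
    def test_strictly_monotone(self, values):
        s = pd.Series(sorted(values))
        t = transform_continuous(s)
        assert (t.diff().dropna() > 0).all()


class TestBinarize:
    def test_indicator_definition(self):
        s = pd.Series(["A", "B", "C", "B"])
        out = binarize_categorical(s, "x")
        assert set(out) == {"x=A", "x=B", "x=C"}
        assert out["x=B"].tolist() == [0.0, 1.0, 0.0, 1.0]

    def test_one_variable_per_observed_category(self):
        s = pd.Series(["a", "b", "b", "c", "d"])
        assert len(binarize_categorical(s, "x")) == 4

    def test_indicators_partition_nonmissing_samples(self, rng):
        cats = np.array(list("ABCD"))
        s = pd.Series(cats[rng.integers(0, 4, 200)], dtype=object)
        s[rng.random(200) < 0.2] = None
        out = binarize_categorical(s, "x")
        total = sum(v.fillna(0) for v in out.values())
        assert (total[s.notna()] == 1.0).all()
        assert sum(v.sum() for v in out.values()) == s.notna().sum()

    def test_single_category_skipped(self):
        assert binarize_categorical(pd.Series(["A", "A"]), "x") == {}


class TestClassBinning:
    def _map(self):
        return pd.DataFrame(
            {
                "survey": ["S1", "S1", "S2", "S2"],
                "phenotype": ["Vitamin A", "Arm circumference", "Serum Vitamin A", "Upper Arm Length"],
                "class_label": ["Vitamin A", "Body Measurements (Arm)", "Vitamin A", "Body Measurements (Arm)"],
            }
        )

    def test_synonyms_bin_to_one_class(self):
        desc = pd.DataFrame(
            {"survey": ["S1", "S2"], "phenotype": ["Vitamin A", "Serum Vitamin A"], "ptype": "continuous"}
        )
        out, unmapped = bin_to_classes(desc, self._map())
        assert unmapped == []
        assert set(out["class_label"]) == {"Vitamin A"}

    def test_related_measures_share_a_class(self):
        desc = pd.DataFrame(
            {"survey": ["S1", "S2"], "phenotype": ["Arm circumference", "Upper Arm Length"], "ptype": "continuous"}
        )
        out, _ = bin_to_classes(desc, self._map())
        assert set(out["class_label"]) == {"Body Measurements (Arm)"}

    def test_empty_map_leaves_everything_unmapped(self):
        desc = pd.DataFrame({"survey": ["S1"], "phenotype": ["x"], "ptype": "continuous"})
        out, unmapped = bin_to_classes(desc, self._map().iloc[:0])
        assert unmapped == ["x"]
        assert out["class_label"].isna().all()

    def test_conflicting_assignment_raises_with_collisions(self):
        cm = self._map()
        cm = pd.concat(
            [cm, pd.DataFrame([{"survey": "S1", "phenotype": "Vitamin A", "class_label": "Other"}])]
        )
        desc = pd.DataFrame({"survey": ["S1"], "phenotype": ["Vitamin A"], "ptype": "continuous"})
        with pytest.raises(HarmonizationError, match="Vitamin A"):
            bin_to_classes(desc, cm)

    def test_binning_is_idempotent(self):
        desc = pd.DataFrame(
            {"survey": ["S1", "S2"], "phenotype": ["Vitamin A", "Upper Arm Length"], "ptype": "continuous"}
        )
        once, _ = bin_to_classes(desc, self._map())
        twice, _ = bin_to_classes(once, self._map())
        pd.testing.assert_series_equal(once["class_label"], twice["class_label"])


def _two_survey_tables():
    idx1 = pd.Index([f"S1_{i}" for i in range(4)], name="sample_id")
    idx2 = pd.Index([f"S2_{i}" for i in range(3)], name="sample_id")
    p1 = pd.DataFrame({"stratum": "NHW", "shared_y": [1.0, 2, 3, 4], "only1": [5.0, 6, 7, 8]}, index=idx1)
    p2 = pd.DataFrame({"stratum": "NHW", "shared_y": [9.0, 10, 11], "only2": [1.0, 2, 3]}, index=idx2)
    meta = pd.DataFrame(
        {
            "survey": ["S1", "S1", "S2", "S2"],
            "phenotype": ["shared_y", "only1", "shared_y", "only2"],
            "class_label": ["Y", "Z", "Y", "Z"],
            "ptype": "continuous",
        }
    )
    return {"S1": p1, "S2": p2}, meta


class TestCombined:
    def test_exact_match_pools_both_surveys(self):
        tables, meta = _two_survey_tables()
        combined = harmonize_combined(tables, meta)
        assert len(combined) == 1
        cv = combined[0]
        assert cv.phenotype == "shared_y"
        assert len(cv.values) == 7  # n1 + n2
        assert not cv.values.index.duplicated().any()

    def test_class_binned_but_not_harmonized_yields_no_combined(self):
        tables, meta = _two_survey_tables()
        combined = harmonize_combined(tables, meta)
        assert all(cv.class_label != "Z" for cv in combined)


class TestMeasurements:
    def test_continuous_carries_both_versions(self):
        tables, meta = _two_survey_tables()
        mset = build_measurements(tables["S1"], meta, "S1")
        assert set(mset.meta["transform"]) == {"none", "ln1p"}
        by_phen = mset.meta.groupby("phenotype").size()
        assert (by_phen == 2).all()

    def test_transformed_column_matches_direct_log1p(self):
        tables, meta = _two_survey_tables()
        mset = build_measurements(tables["S1"], meta, "S1")
        np.testing.assert_allclose(
            mset.values["(ln+1)shared_y"], np.log1p(tables["S1"]["shared_y"])
        )


class TestCohortSummary:
    def test_pooled_percentage_is_count_weighted(self):
        t1 = pd.DataFrame({"sex": ["F"] * 3 + ["M"], "stratum": "NHW"})
        t2 = pd.DataFrame({"sex": ["F"] + ["M"] * 3, "stratum": "NHW"})
        s = summarize_cohort({"S1": t1, "S2": t2})
        assert s["pooled_pct_female"] == pytest.approx(50.0)
        assert s["surveys"]["S1"]["pct_female"] == pytest.approx(75.0)

    def test_identical_sex_proportions_give_zero_chi_square(self):
        t = pd.DataFrame({"sex": ["F", "F", "M", "M"], "stratum": "NHW"})
        s = summarize_cohort({"S1": t, "S2": t.copy()})
        assert s["sex_by_survey_chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_demographics_logged_not_fatal(self):
        t = pd.DataFrame({"stratum": ["NHW", "NHB"]})
        s = summarize_cohort({"S1": t, "S2": t.copy()})
        assert "sex_by_survey_chi2" not in s
        assert s["pooled_n"] == 4
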
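"""Cohort model, clinical derivations, and the synthetic generator."""

import numpy as np
import pytest

from hpbcr.cohort import (DISCRETIZATION_RULES, CohortTable, FeatureSpec,
                          compute_nr, derive_subtype, discretize,
                          generate_synthetic_cohort, load_cohort)


class TestFeatureSpec:
    def test_scale_invariants(self):
        with pytest.raises(ValueError):
            FeatureSpec("x", "interval", categories=("a",))
        with pytest.raises(ValueError):
            FeatureSpec("x", "nominal")
        with pytest.raises(ValueError):
            FeatureSpec("x", "binary", categories=("a", "b", "c"))
        with pytest.raises(ValueError):
            FeatureSpec("x", "continuous")


class TestNodalRatio:
    @pytest.mark.parametrize("i, t, expect", [(0, 12, 0.0), (12, 12, 1.0),
                                              (3, 12, 0.25)])
    def test_ratio(self, i, t, expect):
        assert compute_nr(i, t) == pytest.approx(expect)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_nr(1, 0)
        with pytest.raises(ValueError):
            compute_nr(13, 12)


class TestLoadCohort(object):
    def _csv(self, cohort, tmp_path, name="cohort.csv", edit=None):
        frame = cohort.to_frame().astype(object)
        if edit is not None:
            frame = edit(frame)
        path = tmp_path / name
        frame.to_csv(path, index=False)
        return path

    def test_roundtrip(self, study_cohort, tmp_path):
        small = study_cohort.subset(range(30))
        path = self._csv(small, tmp_path)
        loaded = load_cohort(path)
        assert loaded.n == 30
        assert loaded.dropped_count == 0
        assert np.array_equal(loaded.outcome, small.outcome)
        assert np.allclose(loaded.df["nr"], small.df["nr"])

    def test_incomplete_rows_dropped_and_counted(self, study_cohort, tmp_path):
        small = study_cohort.subset(range(5))

        def blank_ki67(frame):
            frame.loc[2, "ki67"] = ""
            return frame

        loaded = load_cohort(self._csv(small, tmp_path, edit=blank_ki67))
        assert loaded.n == 4
        assert loaded.dropped_count == 1

    def test_primary_metastasis_rows_excluded(self, study_cohort, tmp_path):
        small = study_cohort.subset(range(10))

        def flag(frame):
            frame["primary_metastasis"] = [1, 1] + [0] * 8
            return frame

        loaded = load_cohort(self._csv(small, tmp_path, edit=flag))
        assert loaded.n == 8
        assert loaded.excluded_metastasis == 2

    def test_missing_column_is_schema_error(self, study_cohort, tmp_path):
        small = study_cohort.subset(range(5))
        path = self._csv(small, tmp_path,
                         edit=lambda f: f.drop(columns=["ki67"]))
        with pytest.raises(ValueError, match="schema error"):
            load_cohort(path)

    def test_non_numeric_interval_value_is_parse_error(self, study_cohort, tmp_path):
        small = study_cohort.subset(range(5))

        def corrupt(frame):
            frame.loc[3, "ts"] = "large"
            return frame

        with pytest.raises(ValueError, match="parse error"):
            load_cohort(self._csv(small, tmp_path, edit=corrupt))


class TestDiscretize:
    def test_clinical_boundaries(self, study_cohort):
        tab = study_cohort.subset(range(6))
        tab.df.loc[0, "nr"] = 0.25
        tab.df.loc[0, "i_node"] = 3.0
        tab.df.loc[0, "t_node"] = 12.0
        tab.df.loc[1, "ts"] = 2.0
        tab.df.loc[2, "age"] = 40.0
        tab.df.loc[3, "age"] = 39.9
        tab.df.loc[4, "ts"] = 5.5
        out = discretize(tab)
        assert out.df.loc[0, "nr_cat"] == "<=0.25"
        assert out.df.loc[1, "ts_cat"] == "T1"
        assert out.df.loc[2, "age_cat"] == ">=40"   # boundary joins the older group
        assert out.df.loc[3, "age_cat"] == "<40"
        assert out.df.loc[4, "ts_cat"] == "T3"
        assert "age" in out.df.columns               # originals retained

    def test_idempotent(self, study_cohort):
        once = discretize(study_cohort)
        twice = discretize(once)
        assert [s.name for s in twice.schema] == [s.name for s in once.schema]
        assert twice.df.equals(once.df)

    def test_rule_table_invariants(self):
        for rule in DISCRETIZATION_RULES:
            assert list(rule.cuts) == sorted(set(rule.cuts))
            assert len(rule.labels) == len(rule.cuts) + 1


class TestSubtype:
    @pytest.mark.parametrize("er, pr, her2, ki67, expect", [
        ("pos", "pos", "neg", 10, "LA"),
        ("pos", "neg", "neg", 30, "LB"),
        ("neg", "pos", "pos", 20, "HLB"),
        ("neg", "neg", "pos", 5, "NLH"),
        ("neg", "neg", "neg", 30, "3N"),
        ("pos", "pos", "neg", 14, "LB"),   # 14% counts as high proliferation
    ])
    def test_marker_combinations(self, er, pr, her2, ki67, expect):
        assert derive_subtype(er, pr, her2, ki67) == expect


class TestSyntheticCohort:
    def test_deterministic_under_seed(self, cohort_spec):
        a = generate_synthetic_cohort(cohort_spec, 120, seed=7)
        b = generate_synthetic_cohort(cohort_spec, 120, seed=7)
        assert a.to_csv() == b.to_csv()
        c = generate_synthetic_cohort(cohort_spec, 120, seed=8)
        assert a.to_csv() != c.to_csv()

    def test_minimum_size_enforced(self, cohort_spec):
        with pytest.raises(ValueError):
            generate_synthetic_cohort(cohort_spec, 10, seed=0)

    def test_prevalence_within_binomial_band(self, cohort_spec):
        tab = generate_synthetic_cohort(cohort_spec, 579, seed=42)
        p = cohort_spec.prevalence
        half = 2.576 * np.sqrt(p * (1 - p) / 579)
        assert abs(tab.outcome.mean() - p) < half

    def test_nodal_ratio_is_derived_and_bounded(self, big_cohort):
        df = big_cohort.df
        assert np.allclose(df["nr"], df["i_node"] / df["t_node"], atol=1e-9)
        assert df["nr"].between(0, 1).all()
        assert (df["i_node"] <= df["t_node"]).all()
        assert (df["t_node"] >= 1).all()

    def test_interval_marginals_match_targets(self, cohort_spec, big_cohort):
        """Per-class sample means sit within 3 sd/sqrt(n) of calibration."""
        df = big_cohort.to_frame()
        for cls, label in ((1, "recurrent"), (0, "nonrecurrent")):
            sub = df[df.recurrence_5y == cls]
            for feat, per_class in cohort_spec.interval.items():
                p = per_class[label]
                tol = 3 * p.sd / np.sqrt(len(sub))
                assert abs(sub[feat].mean() - p.mean) <= tol, (feat, label)
                assert sub[feat].between(p.min, p.max).all()

    def test_categorical_marginals_match_targets(self, cohort_spec, big_cohort):
        df = big_cohort.to_frame()
        for cls, label in ((1, "recurrent"), (0, "nonrecurrent")):
            sub = df[df.recurrence_5y == cls]
            n = len(sub)
            for feat, per_class in cohort_spec.categorical.items():
                freqs = sub[feat].astype(str).value_counts(normalize=True)
                for cat, prob in per_class[label].items():
                    half = 2.576 * np.sqrt(prob * (1 - prob) / n)
                    assert abs(freqs.get(cat, 0.0) - prob) <= half, (feat, cat)

    def test_node_correlation_near_target(self, cohort_spec, big_cohort):
        r = np.corrcoef(big_cohort.df["i_node"], big_cohort.df["t_node"])[0, 1]
        assert abs(r - cohort_spec.node_correlation) <= 0.05

    def test_subtype_consistent_with_markers(self, study_cohort):
        df = study_cohort.df
        recomputed = [
            derive_subtype(df.er[i], df.pr[i], df.her2[i], df.ki67[i])
            for i in range(study_cohort.n)
        ]
        assert list(df["subtype"]) == recomputed

    def test_null_spec_has_identical_class_marginals(self, null_spec):
        for per_class in null_spec.interval.values():
            assert per_class["recurrent"] == per_class["nonrecurrent"]
        for per_class in null_spec.categorical.values():
            assert per_class["recurrent"] == per_class["nonrecurrent"]

    def test_probability_normalization_flagged(self, cohort_spec):
        # the published hormone-therapy pair sums to 98%, not 100%
        assert any("hrt" in f for f in cohort_spec.flags)
        for per_class in cohort_spec.categorical.values():
            for probs in per_class.values():
                assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)


class TestCohortValidation:
    def test_inconsistent_nr_rejected(self, study_cohort):
        tab = study_cohort.subset(range(20))
        tab.df.loc[0, "nr"] = 0.999
        with pytest.raises(ValueError, match="nr column inconsistent"):
            tab.validate()

    def test_unknown_category_rejected(self, study_cohort):
        tab = study_cohort.subset(range(20))
        tab.df.loc[0, "surgery"] = "lumpectomy"
        with pytest.raises(ValueError, match="unknown category"):
            tab.validate()
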
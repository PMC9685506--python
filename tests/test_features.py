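"""Feature pipeline: winsorization, coding, hold, exclusion, transfer split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from driftgbm import features


def rec(rows):
    return pd.DataFrame(
        rows, columns=["encounter_id", "year", "day", "kind", "code", "value"]
    )


@pytest.fixture()
def lab_records():
    rng = np.random.default_rng(3)
    rows = [
        ("e0", 2010, d % 5, "lab", "alt", str(v))
        for d, v in enumerate(rng.normal(50, 5, size=200))
    ]
    rows += [("e0", 2010, 1, "lab", "alt", "5000.0"), ("e0", 2010, 2, "lab", "alt", "9000.0")]
    return rec(rows)


class TestFitScheme:
    def test_extreme_values_removed_after_apply(self, lab_records):
        scheme = features.fit_scheme(lab_records)
        lo, hi = scheme.numeric_cutpoints["alt"]
        assert hi < 5000.0
        vec = features.apply_scheme(
            scheme, rec([("e1", 2010, 0, "lab", "alt", "9000.0")]), 0
        )
        assert np.isnan(vec["alt"])

    def test_one_hot_vocabulary(self):
        records = rec(
            [
                ("e0", 2010, 0, "diagnosis", "dx", "A"),
                ("e1", 2010, 0, "diagnosis", "dx", "B"),
            ]
        )
        scheme = features.fit_scheme(records)
        assert scheme.categorical_vocab["dx"] == ("A", "B")
        assert [c for c in scheme.roster if c.startswith("dx=")] == ["dx=A", "dx=B"]

    def test_renal_markers_excluded_from_roster(self, small_scheme):
        assert "scr" in small_scheme.excluded
        assert "bun" in small_scheme.excluded
        assert "rrt" in small_scheme.excluded
        assert not any(
            features.is_renal_marker(name.split("=")[0].split("__")[0])
            for name in small_scheme.roster
        )

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            features.fit_scheme(rec([]))

    def test_constant_feature_equal_cutpoints(self):
        records = rec([("e0", 2010, d, "lab", "k", "7.0") for d in range(5)])
        scheme = features.fit_scheme(records)
        assert scheme.numeric_cutpoints["k"] == (7.0, 7.0)

    def test_serialization_round_trip(self, small_scheme):
        clone = features.FeatureScheme.from_json(small_scheme.to_json())
        assert clone == small_scheme
        assert clone.roster == small_scheme.roster


class TestApplyScheme:
    def test_medication_cumulative_exposure_days(self):
        records = rec(
            [("e0", 2010, d, "medication", "vanc", "1") for d in (1, 2, 4, 6)]
        )
        scheme = features.fit_scheme(records)
        vec = features.apply_scheme(scheme, records, 5)
        assert vec["vanc__cumdays"] == 3.0

    def test_sample_and_hold(self):
        records = rec([("e0", 2010, 1, "lab", "k", "5.0")])
        scheme = features.fit_scheme(records)
        assert features.apply_scheme(scheme, records, 3)["k"] == 5.0

    def test_hold_horizon_limits_carry_forward(self):
        records = rec([("e0", 2010, 1, "lab", "k", "5.0")])
        scheme = features.fit_scheme(records, hold_horizon=3)
        assert features.apply_scheme(scheme, records, 4)["k"] == 5.0
        assert np.isnan(features.apply_scheme(scheme, records, 5)["k"])

    def test_same_day_duplicates_keep_most_recent(self):
        records = rec(
            [
                ("e0", 2010, 2, "lab", "k", "1.0"),
                ("e0", 2010, 2, "lab", "k", "9.0"),
            ]
        )
        # winsorization off: with only two fitted values both extremes
        # would fall outside the 1%/99% band and mask the dedup behavior
        scheme = features.fit_scheme(records, winsorize=False)
        assert features.apply_scheme(scheme, records, 2)["k"] == 9.0

    def test_no_records_all_missing_vector(self, small_scheme):
        vec = features.apply_scheme(small_scheme, rec([]), 3)
        assert len(vec) == len(small_scheme.roster)
        assert np.isnan(vec[list(small_scheme.numeric_cutpoints)]).all()
        assert vec["los_so_far"] == 3.0

    def test_unseen_category_all_zero_block(self):
        records = rec([("e0", 2010, 0, "diagnosis", "dx", "A")])
        scheme = features.fit_scheme(records)
        vec = features.apply_scheme(
            scheme, rec([("e1", 2010, 0, "diagnosis", "dx", "Z")]), 1
        )
        assert vec["dx=A"] == 0.0

    def test_negative_cutoff_rejected(self, small_scheme):
        with pytest.raises(ValueError, match="cutoff"):
            features.apply_scheme(small_scheme, rec([]), -1)

    def test_bp_trend_slope(self):
        rows = [("e0", 2010, d, "vital", "sbp", str(v)) for d, v in [(0, 120.0), (1, 125.0), (2, 130.0)]]
        scheme = features.fit_scheme(rec(rows), winsorize=False)
        vec = features.apply_scheme(scheme, rec(rows), 2)
        assert vec["bp_trend"] == pytest.approx(5.0)
        # two points: difference; one point: zero
        assert features.apply_scheme(scheme, rec(rows[:2]), 1)["bp_trend"] == pytest.approx(5.0)
        assert features.apply_scheme(scheme, rec(rows[:1]), 0)["bp_trend"] == 0.0

    def test_purity(self, small_scheme, small_cohort):
        records = small_cohort[0].to_records()
        a = features.apply_scheme(small_scheme, records, 2)
        b = features.apply_scheme(small_scheme, records, 2)
        pd.testing.assert_series_equal(a, b)

    def test_winsorization_rate_on_fresh_data(self):
        rng = np.random.default_rng(0)
        fit_rows = rec(
            [("e", 2010, 0, "lab", "k", str(v)) for v in rng.normal(size=4000)]
        )
        scheme = features.fit_scheme(fit_rows)
        fresh = rng.normal(size=4000)
        lo, hi = scheme.numeric_cutpoints["k"]
        removed = np.mean((fresh < lo) | (fresh > hi))
        assert 0.01 < removed < 0.035


class TestSplitAndProject:
    def test_identical_rosters(self, small_scheme):
        split = features.split_features(small_scheme, small_scheme)
        assert split.unique_source == split.unique_target == ()
        assert split.common == small_scheme.roster

    def test_target_grown_feature_is_unique_target(self):
        src = features.fit_scheme(rec([("e", 2010, 0, "lab", "a", "1.0")]))
        tgt = features.fit_scheme(
            rec(
                [
                    ("e", 2015, 0, "lab", "a", "1.0"),
                    ("e", 2015, 0, "lab", "f_new", "2.0"),
                ]
            )
        )
        split = features.split_features(src, tgt)
        assert "f_new" in split.unique_target

    def test_disjoint_rosters_common_only_derived(self):
        src = features.fit_scheme(rec([("e", 2010, 0, "lab", "a", "1.0")]))
        tgt = features.fit_scheme(rec([("e", 2015, 0, "lab", "b", "1.0")]))
        split = features.split_features(src, tgt)
        # derived features exist in every roster; the fitted codes are disjoint
        assert "a" in split.unique_source and "b" in split.unique_target
        assert set(split.common) <= {"bp_trend", "los_so_far"}

    def test_projection_injects_missing_for_unique_source(self):
        src = features.fit_scheme(
            rec(
                [
                    ("e", 2010, 0, "lab", "a", "1.0"),
                    ("e", 2010, 0, "lab", "only_src", "3.0"),
                ]
            )
        )
        tgt = features.fit_scheme(rec([("e", 2015, 0, "lab", "a", "2.0")]))
        split = features.split_features(src, tgt)
        vec = pd.Series([2.0, 0.0, 1.0], index=list(tgt.roster))
        proj = features.project_to_common(vec, split)
        assert tuple(proj.index) == src.roster
        assert np.isnan(proj["only_src"])
        assert proj["a"] == 2.0

    def test_projection_identity_on_source_domain(self, small_scheme, small_matrix):
        split = features.split_features(small_scheme, small_scheme)
        out = features.project_frame_to_common(small_matrix.X, split)
        pd.testing.assert_frame_equal(out, small_matrix.X)

    def test_roster_mismatch_rejected(self, small_scheme):
        split = features.split_features(small_scheme, small_scheme)
        with pytest.raises(ValueError, match="roster"):
            features.project_to_common(pd.Series([1.0], index=["x"]), split)


@given(st.integers(0, 10_000))
def test_split_sets_partition_rosters(seed):
    """common/unique sets are disjoint and cover both rosters."""
    rng = np.random.default_rng(seed)
    codes = [f"c{i}" for i in range(8)]
    src_codes = [c for c in codes if rng.random() < 0.7] or ["c0"]
    tgt_codes = [c for c in codes if rng.random() < 0.7] or ["c1"]
    src = features.fit_scheme(
        rec([("e", 2010, 0, "lab", c, "1.0") for c in src_codes])
    )
    tgt = features.fit_scheme(
        rec([("e", 2015, 0, "lab", c, "1.0") for c in tgt_codes])
    )
    split = features.split_features(src, tgt)
    common, us, ut = set(split.common), set(split.unique_source), set(split.unique_target)
    assert common.isdisjoint(us) and common.isdisjoint(ut) and us.isdisjoint(ut)
    assert common | us == set(src.roster)
    assert common | ut == set(tgt.roster)
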
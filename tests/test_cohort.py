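from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from _oracles import mann_whitney_exact_p
from fragmetrics import (
    GeneratorConfig,
    build_table2,
    compare_groups,
    empirical_cdf,
    fraction_below,
    generate_cohort,
    summarize_patient,
)
from fragmetrics.morphometry import Fragment, PatternCall


def _fragment(slide_id="S00", width=1.0, depth=0.5, area=2.0, px=0.02):
    count = int(area / px / px)
    return Fragment(
        fragment_id=0,
        slide_id=slide_id,
        pixel_count=count,
        area_mm2=area,
        width_mm=width,
        min_lumen_dist_mm=depth,
        bounding_box=(0, 0, 1, 1),
        pixels=np.array([[0, 0]]),
    )


SHRINK = PatternCall(pattern="shrinkage", n_clusters=1)


class TestSummarizePatient:
    def test_volume_is_area_times_spacing(self):
        s = summarize_patient(
            "P0", 2, [_fragment(area=2.0)], {"S00": 2.0}, SHRINK, slide_spacing_mm=3.0
        )
        assert s.volume_mm3 == pytest.approx(6.0)

    def test_central_slide_is_largest_area(self):
        s = summarize_patient(
            "P0",
            2,
            [_fragment("S00", area=1.0), _fragment("S01", area=4.0)],
            {"S00": 1.0, "S01": 4.0},
            SHRINK,
            slide_spacing_mm=3.0,
        )
        assert s.central_slide_area_mm2 == pytest.approx(4.0)
        assert s.volume_mm3 == pytest.approx(15.0)

    def test_extremes_over_fragments(self):
        frags = [
            _fragment(width=0.5, depth=0.8),
            _fragment(width=2.5, depth=0.1),
        ]
        s = summarize_patient("P0", 3, frags, {"S00": 3.0}, SHRINK, 3.0)
        assert s.max_width_mm == 2.5
        assert s.min_depth_mm == pytest.approx(0.1)

    def test_zero_fragments_is_an_error(self):
        with pytest.raises(ValueError, match="no residual tumor"):
            summarize_patient("P0", 2, [], {"S00": 0.0}, SHRINK, 3.0)

    def test_synthetic_patient_matches_truth(self, measured_small_cohort):
        summaries, _, truths = measured_small_cohort
        px = 0.02
        for s, t in zip(summaries, truths):
            assert s.pattern == t.pattern
            assert abs(s.max_width_mm - t.max_width_mm) <= 2 * px
            assert abs(s.min_depth_mm - t.min_depth_mm) <= 2 * px
            assert s.central_slide_area_mm2 == pytest.approx(
                max(t.slide_areas_mm2.values()), rel=0.02
            )
            assert s.volume_mm3 == pytest.approx(t.volume_mm3, rel=0.02)


class TestFractionBelow:
    def test_strict_count(self):
        assert fraction_below([0.5, 1.5, 2.0], 1.0) == pytest.approx(1 / 3)

    def test_threshold_below_min_is_zero(self):
        assert fraction_below([0.5, 1.5], 0.1) == 0.0

    def test_strict_vs_inclusive_at_a_tie(self):
        assert fraction_below([1.0, 2.0], 1.0, strict=True) == 0.0
        assert fraction_below([1.0, 2.0], 1.0, strict=False) == 0.5

    def test_uniform_draws_near_half(self):
        rng = np.random.default_rng(47)
        vals = rng.uniform(0, 1, size=1000)
        assert fraction_below(vals, 0.5) == pytest.approx(0.5, abs=0.05)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            fraction_below([], 1.0)


class TestEmpiricalCdf:
    def test_single_value_steps_to_one(self):
        tab = empirical_cdf([2.5])
        assert tab["x"].tolist() == [2.5]
        assert tab["cdf"].tolist() == [1.0]

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=40, unique=True))
    def test_order_statistic_property(self, values):
        tab = empirical_cdf(values)
        n = len(values)
        for k, x in enumerate(sorted(values), start=1):
            row = tab[tab["x"] == x]
            assert float(row["cdf"].iloc[0]) == pytest.approx(k / n)

    def test_generator_widths_follow_log_uniform(self):
        lo, hi = 0.06, 2.0
        cfg = GeneratorConfig(
            n_patients=120,
            p_fragmentation=1.0,
            n_fragments_range=(4, 5),
            width_range_mm=(lo, hi),
            depth_range_mm=(0.01, 0.5),
            n_slides_range=(1, 1),
            seed=53,
        )
        _, truths = generate_cohort(cfg)
        widths = np.array([f.width_mm for t in truths for f in t.fragments])
        assert len(widths) >= 400
        cdf = lambda x: (np.log(x) - np.log(lo)) / (np.log(hi) - np.log(lo))
        ks = stats.kstest(widths, cdf).statistic
        assert ks < 0.1


class TestCompareGroups:
    def test_mann_whitney_exact_against_enumeration(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], force_test="mann_whitney")
        u_oracle, p_oracle = mann_whitney_exact_p([1, 2, 3], [4, 5, 6])
        assert p_oracle == pytest.approx(0.10)
        assert res.statistic == pytest.approx(u_oracle)  # U = 0
        assert res.p_value == pytest.approx(p_oracle)

    def test_exact_p_matches_enumeration_on_random_groups(self):
        rng = np.random.default_rng(59)
        for _ in range(5):
            a = rng.permutation(np.arange(1.0, 11.0))[:4]
            b = rng.permutation(np.arange(11.5, 20.5))[:5] - rng.uniform(0, 9)
            res = compare_groups(a, b, force_test="mann_whitney")
            _, p_oracle = mann_whitney_exact_p(a, b)
            assert res.p_value == pytest.approx(p_oracle)

    def test_pooled_t_statistic(self):
        res = compare_groups([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], force_test="t_test")
        assert res.statistic == pytest.approx(-1.0)
        # closed-form check: df = 8
        assert res.p_value == pytest.approx(2 * stats.t.sf(1.0, df=8))

    def test_identical_groups_not_significant(self):
        res = compare_groups([1, 2, 3, 4], [1, 2, 3, 4], force_test="t_test")
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_shapiro_gate_switches_test(self):
        rng = np.random.default_rng(61)
        normal_a = rng.normal(10, 1, size=25)
        normal_b = rng.normal(11, 1, size=25)
        assert compare_groups(normal_a, normal_b).test_used == "t_test"
        skewed_b = np.exp(rng.normal(0, 1.5, size=25))
        assert compare_groups(normal_a, skewed_b).test_used == "mann_whitney"

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(67)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        for force in ("t_test", "mann_whitney"):
            pab = compare_groups(a, b, force_test=force).p_value
            pba = compare_groups(b, a, force_test=force).p_value
            assert pab == pytest.approx(pba)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_groups([1, 2], [3, 4, 5])


class TestBuildTable2:
    def test_synthetic_cohort_medians_match_truth(self, measured_small_cohort):
        summaries, _, truths = measured_small_cohort
        table = build_table2(summaries)
        for trg in (2, 3):
            true_depths = [t.min_depth_mm for t in truths if t.trg == trg]
            got = table["measures"]["min_lumen_distance_mm"]["by_trg"][str(trg)]
            assert got["median"] == pytest.approx(np.median(true_depths), abs=0.05)
            true_vols = [t.volume_mm3 for t in truths if t.trg == trg]
            gv = table["measures"]["volume_mm3"]["by_trg"][str(trg)]
            assert gv["median"] == pytest.approx(np.median(true_vols), rel=0.02)

    def test_counts_match_generator_patterns(self, measured_small_cohort):
        summaries, _, truths = measured_small_cohort
        table = build_table2(summaries)
        for trg in (2, 3):
            want = sum(
                1 for t in truths if t.trg == trg and t.pattern == "fragmentation"
            )
            assert table["counts"][str(trg)]["fragmentation"] == want

    def test_patient_order_invariance(self, measured_small_cohort):
        summaries, _, _ = measured_small_cohort
        shuffled = list(summaries)
        np.random.default_rng(71).shuffle(shuffled)
        assert build_table2(shuffled) == build_table2(summaries)

    def test_empty_subgroup_emits_missing_markers(self, measured_small_cohort):
        summaries, _, _ = measured_small_cohort
        only_shrinkage = [s for s in summaries if s.pattern == "shrinkage"]
        if not only_shrinkage:
            pytest.skip("no shrinkage patients in fixture cohort")
        table = build_table2(only_shrinkage)
        frag_row = table["measures"]["fragmentation_max_width_mm"]
        assert all(v is None for v in frag_row["by_trg"].values())
        assert frag_row["p_value"] is None
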
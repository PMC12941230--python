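"""Per-exon depth means, cohort normalization and copy-state calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcskit import (
    CnvScreen,
    DepthTable,
    ScreenConfig,
    call_states,
    cohort_screen,
    exon_mean_depth,
    normalize_vs_controls,
    sample_scale_factors,
    simulate_depth_cohort,
)
from tcskit.errors import ValidationError
from tcskit.genome_model import ExonModel, GenomicInterval, build_transcript
from tcskit.simulate import DepthSimConfig

from conftest import make_depth_table


def exon(index, chrom, start, end, c_start=None):
    c_start = c_start if c_start is not None else 1
    return ExonModel(
        index, GenomicInterval(chrom, start, end), c_start, c_start + (end - start) - 1
    )


class TestExonMeanDepth:
    def test_constant_coverage(self):
        d = make_depth_table("c1", 101, {"S": [100.0] * 5})
        s = exon_mean_depth(d, exon(1, "c1", 100, 105), "S")
        assert (s.mean_depth, s.n_missing, s.n_bases) == (100.0, 0, 5)

    def test_missing_positions_excluded_from_mean(self):
        d = make_depth_table("c1", 101, {"S": [10.0, 20.0, np.nan, 30.0, 40.0]})
        s = exon_mean_depth(d, exon(1, "c1", 100, 105), "S")
        assert s.mean_depth == 25.0
        assert s.n_missing == 1

    def test_polr1c_exon2_length_is_72(self, polr1c):
        ex2 = polr1c.exon(2)
        d = make_depth_table("chr6", ex2.genomic.start + 1, {"S": [80.0] * len(ex2.genomic)})
        s = exon_mean_depth(d, ex2, "S")
        assert (s.mean_depth, s.n_bases) == (80.0, 72)

    def test_exon_outside_table_is_all_missing(self):
        d = make_depth_table("c1", 101, {"S": [10.0] * 5})
        s = exon_mean_depth(d, exon(1, "c1", 5000, 5010), "S")
        assert not s.defined
        assert np.isnan(s.mean_depth)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.one_of(st.none(), st.integers(min_value=0, max_value=500)),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_per_base_oracle(self, depths):
        values = [np.nan if d is None else float(d) for d in depths]
        d = make_depth_table("c1", 11, {"S": values})
        s = exon_mean_depth(d, exon(1, "c1", 10, 10 + len(values)), "S")
        present = [v for v in values if np.isfinite(v)]
        assert s.n_missing == len(values) - len(present)
        if present:
            assert s.mean_depth == pytest.approx(sum(present) / len(present))
        else:
            assert np.isnan(s.mean_depth)


class TestScaling:
    def test_scale_is_mean_of_exon_means(self):
        means = pd.DataFrame({"A": [100.0, 100.0], "B": [50.0, 150.0]}, index=[1, 2])
        scales = sample_scale_factors(means)
        assert scales["A"] == 100.0
        assert scales["B"] == 100.0

    def test_sample_without_defined_exons_rejected(self):
        means = pd.DataFrame({"A": [100.0, 90.0], "B": [np.nan, np.nan]}, index=[1, 2])
        with pytest.raises(ValidationError, match="B"):
            sample_scale_factors(means)

    def test_doubling_depths_doubles_scale_only(self):
        means = pd.DataFrame({"A": [80.0, 120.0]}, index=[1, 2])
        rel = means / sample_scale_factors(means)
        rel2 = (means * 2) / sample_scale_factors(means * 2)
        pd.testing.assert_frame_equal(rel, rel2)


class TestNormalization:
    def test_identical_to_controls_gives_unit_ratios(self):
        test = pd.Series([1.0, 1.0, 1.0], index=[1, 2, 3])
        controls = pd.DataFrame({f"C{i}": test for i in range(4)})
        assert normalize_vs_controls(test, controls).ratios.tolist() == [1.0, 1.0, 1.0]

    def test_ratio_against_control_median(self):
        test = pd.Series([55.0], index=[1])
        controls = pd.DataFrame({"C1": [90.0], "C2": [100.0], "C3": [120.0]}, index=[1])
        assert normalize_vs_controls(test, controls).ratios[1] == pytest.approx(0.55)

    def test_half_coverage_gives_half_ratio(self):
        test = pd.Series([0.5, 0.5], index=[1, 2])
        controls = pd.DataFrame(
            {"C1": [1.0, 1.0], "C2": [1.0, 1.0], "C3": [1.0, 1.0]}, index=[1, 2]
        )
        assert normalize_vs_controls(test, controls).ratios.tolist() == [0.5, 0.5]

    def test_zero_control_median_gives_undefined_ratio(self):
        test = pd.Series([1.0], index=[1])
        controls = pd.DataFrame({"C1": [0.0], "C2": [0.0], "C3": [0.0]}, index=[1])
        assert np.isnan(normalize_vs_controls(test, controls).ratios[1])

    def test_fewer_than_three_controls_flagged(self):
        test = pd.Series([1.0], index=[1])
        controls = pd.DataFrame({"C1": [1.0], "C2": [1.0]}, index=[1])
        res = normalize_vs_controls(test, controls)
        assert res.low_confidence
        assert res.ratios[1] == 1.0

    def test_control_order_irrelevant(self):
        rng = np.random.default_rng(5)
        test = pd.Series(rng.uniform(0.3, 1.5, 6), index=range(1, 7))
        controls = pd.DataFrame(
            {f"C{i}": rng.uniform(0.5, 1.5, 6) for i in range(5)}, index=range(1, 7)
        )
        shuffled = controls[list(reversed(controls.columns))]
        pd.testing.assert_series_equal(
            normalize_vs_controls(test, controls).ratios,
            normalize_vs_controls(test, shuffled).ratios,
        )


class TestCallStates:
    def test_observed_candidate_ratio_is_het_del(self):
        calls = call_states(pd.Series({1: 0.46}))
        assert [c.state for c in calls] == ["het_del"]

    def test_consecutive_het_del_exons_merge(self):
        ratios = pd.Series(
            {1: 0.48, 2: 0.50, 3: 1.01, 4: 0.99, 5: 1.0, 6: 1.02, 7: 0.97, 8: 1.0, 9: 1.01}
        )
        calls = call_states(ratios)
        assert len(calls) == 1
        call = calls[0]
        assert (call.exon_start, call.exon_end, call.state) == (1, 2, "het_del")
        assert call.ratio == pytest.approx(0.49)
        assert call.n_exons == 2

    def test_all_diploid_yields_no_candidates(self):
        assert call_states(pd.Series({i: 1.0 for i in range(1, 10)})) == []

    def test_non_adjacent_same_state_exons_not_merged(self):
        ratios = pd.Series({1: 0.5, 2: 1.0, 3: 0.5})
        calls = call_states(ratios)
        assert [(c.exon_start, c.exon_end) for c in calls] == [(1, 1), (3, 3)]

    def test_uncallable_exon_breaks_a_segment(self):
        ratios = pd.Series({1: 0.5, 2: 0.5, 3: 0.5})
        mask = pd.Series({1: True, 2: False, 3: True})
        calls = call_states(ratios, callable_mask=mask)
        assert [(c.exon_start, c.exon_end) for c in calls] == [(1, 1), (3, 3)]

    def test_extreme_ratios_map_to_hom_del_and_dup(self):
        calls = call_states(pd.Series({1: 0.02, 2: 1.7}))
        assert {c.state for c in calls} == {"hom_del", "dup"}

    def test_band_config_validated(self):
        with pytest.raises(ValidationError):
            ScreenConfig(het_del_band=(0.1, 0.65), hom_del_max=0.2)


class TestCohortScreen:
    def _planted(self, seed=1):
        cfg = DepthSimConfig(cnv_events=(("T01", (1, 2), 1),), seed=seed)
        return cfg

    def test_planted_deletion_is_the_only_candidate(self, polr1c):
        depth, _ = simulate_depth_cohort(polr1c, self._planted())
        report = cohort_screen(depth, polr1c)
        assert len(report) == 1
        row = report.iloc[0]
        assert (row["sample"], row["exon_span"], row["state"]) == ("T01", "1-2", "het_del")
        assert row["c_span"] == "c.1-162"
        assert row["confidence"] == "ok"

    def test_all_diploid_cohort_reports_nothing(self, polr1c):
        depth, _ = simulate_depth_cohort(polr1c, DepthSimConfig(seed=2))
        assert cohort_screen(depth, polr1c).empty

    def test_tiny_cohort_calls_are_low_confidence(self):
        t = build_transcript(
            [
                {"index": 1, "chrom": "c1", "start": 100, "end": 200},
                {"index": 2, "chrom": "c1", "start": 300, "end": 400},
                {"index": 3, "chrom": "c1", "start": 500, "end": 600},
            ]
        )
        # contiguous positions 101..600; the inter-exon filler is ignored
        flat = [100.0] * 500
        deleted = [100.0] * 200 + [50.0] * 100 + [100.0] * 200
        d = make_depth_table("c1", 101, {"A": flat, "B": flat, "C": deleted})
        report = cohort_screen(d, t, test_samples=["C"])
        assert len(report) == 1
        row = report.iloc[0]
        assert (row["exon_span"], row["state"], row["confidence"]) == (
            "2-2",
            "het_del",
            "low_confidence",
        )

    def test_scaling_makes_ratios_invariant_to_library_size(self, polr1c):
        depth, _ = simulate_depth_cohort(polr1c, self._planted(seed=3))
        res1 = CnvScreen(depth, polr1c).fit()
        frame = depth.frame.copy()
        frame["T01"] = frame["T01"] * 3
        res2 = CnvScreen(DepthTable(frame), polr1c).fit()
        pd.testing.assert_frame_equal(res1.ratios, res2.ratios)

    def test_summary_mentions_candidates(self, polr1c):
        depth, _ = simulate_depth_cohort(polr1c, self._planted(seed=4))
        res = CnvScreen(depth, polr1c).fit()
        text = res.summary()
        assert "candidate segments: 1" in text
        assert "het_del" in text

    def test_ratio_plot_written(self, polr1c, tmp_path):
        depth, _ = simulate_depth_cohort(polr1c, self._planted(seed=5))
        res = CnvScreen(depth, polr1c, test_samples=["T01"]).fit()
        out = tmp_path / "ratios.png"
        res.plot(out, highlight="T01")
        assert out.stat().st_size > 0
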
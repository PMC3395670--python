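"""Profile synthesis: positions, time transform, evaluation, heuristics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytocycle import profiles as pr


class TestCumulativePositions:
    def test_two_halves(self):
        np.testing.assert_allclose(pr.cumulative_positions([0.5, 0.5]),
                                   [0.25, 0.75])

    @pytest.mark.parametrize("n", [2, 5, 12])
    def test_equal_frequencies(self, n):
        got = pr.cumulative_positions(np.full(n, 1.0 / n))
        want = (2 * np.arange(1, n + 1) - 1) / (2 * n)
        np.testing.assert_allclose(got, want)

    def test_zero_frequency_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-frequency"):
            got = pr.cumulative_positions([0.5, 0.0, 0.5])
        np.testing.assert_allclose(got, [0.25, 0.75])

    def test_positions_match_truth_cdf(self, preprocessed):
        from cytocycle import gating, preprocess as pp
        from cytocycle.synthcyto import age_cdf

        table, _ = preprocessed
        inter, mito = gating.split_interphase_mitosis(table)
        inter = pp.stemline_gate(inter)
        chain = gating.auto_segment_s(inter)
        stats = gating.chain_stats(inter, chain)
        part = [s for s in stats if s.role != "transition_oval"]
        # chain positions are interphase-relative; the whole-cycle F axis
        # additionally carries the mitotic mass at the end
        inter_scale = len(inter) / (len(inter) + len(mito))
        x = pr.cumulative_positions([s.frequency for s in part]) * inter_scale
        # cluster steps absorb the boundary blur, S segments are sharp
        for xi, s in zip(x, part):
            step = chain.step(s.step_id)
            f_true = np.median(age_cdf(inter["truth_t"][step.indices]))
            tol = 0.01 if s.role == "segment" else 0.03
            assert abs(xi - f_true) < tol


class TestFrequencyToTime:
    def test_fixed_points(self):
        assert pr.frequency_to_time(0.0) == 0.0
        assert pr.frequency_to_time(1.0) == 1.0

    def test_half_mass_value(self):
        assert pr.frequency_to_time(0.5) == pytest.approx(
            1.0 - np.log2(1.5), abs=1e-12)

    def test_inverse_on_grid(self):
        grid = np.linspace(0, 1, 10001)
        back = pr.time_to_frequency(pr.frequency_to_time(grid))
        np.testing.assert_allclose(back, grid, atol=1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, max_examples=200)
    def test_monotone_bijection(self, f):
        t = float(pr.frequency_to_time(f))
        assert 0.0 <= t <= 1.0
        assert t <= f + 1e-12  # age density >= 1 before the median age

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pr.frequency_to_time(1.5)


class TestExpressionProfile:
    def test_evaluation_at_knots_exact(self):
        prof = pr.assemble_profile([(0.1, 2.0), (0.4, -1.0), (0.9, 5.0)])
        for x, y in [(0.1, 2.0), (0.4, -1.0), (0.9, 5.0)]:
            assert prof(x) == y

    def test_two_point_line_formula(self):
        prof = pr.assemble_profile([(0.2, 1.0), (0.6, 3.0)])
        assert prof(0.3) == pytest.approx(1.5)

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(-50, 50)),
                    min_size=2, max_size=8,
                    unique_by=lambda p: round(p[0], 3)),
           st.floats(0, 1))
    @settings(deadline=None, max_examples=150)
    def test_matches_closed_form_line_equation(self, knots, x):
        knots = sorted(knots)
        xs = [k[0] for k in knots]
        if min(np.diff(xs), default=1) <= 1e-6:
            return
        prof = pr.assemble_profile(knots)
        x = min(max(x, xs[0]), xs[-1])
        i = int(np.clip(np.searchsorted(xs, x) - 1, 0, len(xs) - 2))
        x0, y0 = knots[i]
        x1, y1 = knots[i + 1]
        m = (y1 - y0) / (x1 - x0)
        want = m * x + y0 - m * x0
        assert float(prof(x)) == pytest.approx(want, abs=1e-9)

    def test_resample_preserves_knots(self):
        prof = pr.assemble_profile([(0.0, 1.0), (0.3, 4.0), (1.0, 0.0)])
        res = prof.resample(17)
        np.testing.assert_allclose(res(prof.x), prof.y, atol=1e-12)

    def test_duplicate_x_rejected(self):
        with pytest.raises(ValueError):
            pr.assemble_profile([(0.5, 1.0), (0.5, 2.0)])


class TestBoundaryHeuristics:
    def make(self, pts):
        return pr.ExpressionProfile(
            [pr.ExpressionPoint(x, y, "region_median", ph) for x, y, ph in pts])

    def test_endpoint_zeroing_exact(self):
        prof = self.make([(0.2, 3.0, "g1"), (0.5, 5.0, "s"), (0.9, 4.0, "g2")])
        out = pr.apply_boundary_heuristics(prof, zero_endpoints=True)
        assert out(0.0) == 0.0 and out(1.0) == 0.0

    def test_collinear_s_knots_insert_zero_crossing(self):
        # first three S knots collinear through (0.1, 0)
        prof = self.make([(0.05, 0.0, "g1"), (0.2, 1.0, "s"),
                          (0.3, 2.0, "s"), (0.4, 3.0, "s"), (0.9, 5.0, "g2")])
        out = pr.apply_boundary_heuristics(prof, extrapolate_zero_onset=True)
        assert any(np.isclose(p.x, 0.1) and p.y == 0.0 for p in out.points)

    def test_crossing_outside_gap_skipped_with_warning(self):
        prof = self.make([(0.05, 0.0, "g1"), (0.2, 5.0, "s"),
                          (0.3, 5.1, "s"), (0.4, 5.2, "s"), (0.9, 6.0, "g2")])
        with pytest.warns(UserWarning, match="unimproved"):
            out = pr.apply_boundary_heuristics(prof, extrapolate_zero_onset=True)
        assert not any(p.y == 0.0 and p.source == "heuristic" and 0 < p.x < 0.2
                       for p in out.points)

    def test_nonzero_g1_marker_duplicated_at_origin(self):
        prof = self.make([(0.2, 3.0, "g1"), (0.6, 5.0, "s"), (0.9, 4.0, "g2")])
        out = pr.apply_boundary_heuristics(prof)
        assert out.points[0].x == 0.0 and out.points[0].y == 3.0
        assert out.points[-1].x == 1.0 and out.points[-1].y == 4.0
        # interior knots untouched
        assert [round(p.x, 6) for p in out.points[1:-1]] == [0.2, 0.6, 0.9]


@pytest.fixture(scope="module")
def result(assay_triple):
    multi, sa, sb = assay_triple
    cfg = pr.PipelineConfig(compensation=[("phh3", "cyca2", 0.08)], seed=5)
    return pr.profile_pipeline(multi, sa, sb, cfg)


class TestPipeline:
    def test_degradation_ordering(self, result):
        a2 = result["expression"]["cyca2"]
        b1 = result["expression"]["cycb1"]
        tt = np.linspace(0.9, 1.0, 500)
        t_a2 = tt[np.argmax(a2(tt) < 0.1 * a2.peak()[1])]
        t_b1 = tt[np.argmax(b1(tt) < 0.1 * b1.peak()[1])]
        assert t_a2 < t_b1

    def test_cyclins_peak_late_g2_early_m(self, result, truth):
        for marker in ("cyca2", "cycb1"):
            t_peak, _ = result["expression"][marker].peak()
            assert truth.t_sg2 < t_peak < 1.0

    def test_profile_mae_below_ten_percent_of_peak(self, result, truth):
        grid = np.linspace(0, 1, 201)
        for marker in ("cyca2", "cycb1"):
            rec = result["expression"][marker](grid)
            tru = truth.evaluate(marker, grid)
            assert np.mean(np.abs(rec - tru)) < 0.10 * tru.max()

    def test_dna_in_genome_units(self, result):
        dna = result["expression"]["dna"]
        tt = np.linspace(0, 1, 101)
        vals = dna(tt)
        assert vals[0] == pytest.approx(2.0, rel=0.05)
        assert vals[-1] == pytest.approx(4.0, rel=0.07)

    def test_phh3_relative_scale(self, result):
        phh3 = result["expression"]["phh3"]
        assert phh3(0.05) == pytest.approx(1.0, abs=0.15)   # G1 reference
        assert phh3(0.93) == pytest.approx(2.0, rel=0.2)    # doubles by G2
        assert phh3.peak()[1] > 5.0                          # mitotic surge

    def test_deterministic_under_seed(self, assay_triple, result):
        multi, sa, sb = assay_triple
        cfg = pr.PipelineConfig(compensation=[("phh3", "cyca2", 0.08)], seed=5)
        again = pr.profile_pipeline(multi, sa, sb, cfg)
        for marker, frame in result["profiles"].items():
            assert frame.equals(again["profiles"][marker])

    def test_output_frames_carry_both_axes(self, result):
        for frame in result["profiles"].values():
            assert {"x_frequency", "x_time", "y_raw",
                    "y_samescale", "source"} <= set(frame.columns)
            np.testing.assert_allclose(
                frame.x_time, pr.frequency_to_time(frame.x_frequency))
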
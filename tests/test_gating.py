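"""Gate geometry, Boolean algebra, and region-chain segmentation."""

import json

import numpy as np
import pytest

from cytocycle import gating, preprocess as pp
from cytocycle.events_io import EventTable
import pandas as pd


def ray_cast(poly, x, y):
    """Independent even-odd point-in-polygon oracle."""
    inside = False
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            xin = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
            if x < xin:
                inside = not inside
    return inside


@pytest.fixture(scope="module")
def interphase(preprocessed):
    table, _ = preprocessed
    inter, mito = gating.split_interphase_mitosis(table)
    return pp.stemline_gate(inter), mito


class TestRegions:
    def test_rectangle_membership_half_open(self):
        r = gating.Region("r", ("x", "y"), "rectangle", [0, 10, 0, 10])
        assert r.contains(5, 5)
        assert r.contains(0, 0)          # lower/left edge inclusive
        assert not r.contains(10, 5)     # upper edge exclusive
        assert not r.contains(5, 10)

    def test_not_full_plane_is_empty(self):
        t = EventTable(pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]}))
        full = gating.Region("all", ("x", "y"), "rectangle",
                             [-1e9, 1e9, -1e9, 1e9])
        mask = gating.evaluate_gate(t, ~gating.RegionRef(full))
        assert not mask.any()

    def test_boolean_algebra(self):
        t = EventTable(pd.DataFrame({"x": [1.0, 5.0, 9.0],
                                     "y": [1.0, 5.0, 9.0]}))
        left = gating.RegionRef(gating.Region("l", ("x", "y"), "rectangle",
                                              [0, 6, 0, 10]))
        right = gating.RegionRef(gating.Region("r", ("x", "y"), "rectangle",
                                               [4, 10, 0, 10]))
        np.testing.assert_array_equal(gating.evaluate_gate(t, left & right),
                                      [False, True, False])
        np.testing.assert_array_equal(gating.evaluate_gate(t, left | right),
                                      [True, True, True])

    def test_polygon_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        n_cases = 0
        for trial in range(25):
            k = rng.integers(3, 9)
            # star-convex polygon around a random centre (non-self-intersecting)
            cx, cy = rng.uniform(2, 8, 2)
            ang = np.sort(rng.uniform(0, 2 * np.pi, k))
            rad = rng.uniform(0.5, 4.0, k)
            verts = np.column_stack([cx + rad * np.cos(ang),
                                     cy + rad * np.sin(ang)])
            region = gating.Region(f"p{trial}", ("x", "y"), "polygon",
                                   verts.tolist())
            pts = rng.uniform(0, 10, size=(40, 2))
            got = region.contains(pts[:, 0], pts[:, 1])
            want = [ray_cast(verts, x, y) for x, y in pts]
            np.testing.assert_array_equal(got, want)
            n_cases += len(pts)
        assert n_cases == 1000

    def test_ellipse_membership(self):
        r = gating.Region("e", ("x", "y"), "ellipse", [5, 5, 2, 1, 0])
        assert r.contains(5, 5) and r.contains(6.9, 5)
        assert not r.contains(7.1, 5) and not r.contains(5, 6.1)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            gating.Region("bad", ("x", "y"), "rectangle", [5, 5, 0, 1])
        with pytest.raises(ValueError):
            gating.Region("bad", ("x", "y"), "polygon", [[0, 0], [1, 1]])

    def test_region_json_round_trip(self, tmp_path):
        regions = [
            gating.Region("r1", ("dna", "cyca2"), "rectangle",
                          [0.1, 10.3, -2.0, 5.5]),
            gating.Region("r2", ("a", "b"), "polygon",
                          [[0.0, 0.0], [1.5, 0.25], [0.7, 2.2]]),
        ]
        path = tmp_path / "regions.json"
        gating.save_regions(regions, path)
        back = gating.load_regions(path)
        assert [r.to_dict() for r in back] == [r.to_dict() for r in regions]
        # and the serialisation is bit-stable
        again = tmp_path / "again.json"
        gating.save_regions(back, again)
        assert path.read_text() == again.read_text()


class TestSplitInterphaseMitosis:
    def test_mitotic_recall(self, preprocessed):
        table, _ = preprocessed
        inter, mito = gating.split_interphase_mitosis(table)
        n_true = (table.data["truth_phase"] == "m").sum()
        n_found = (mito.data["truth_phase"] == "m").sum()
        assert n_found / n_true >= 0.95

    def test_mitotic_set_is_4c(self, preprocessed):
        table, _ = preprocessed
        from cytocycle.samescale import find_dna_modes
        from cytocycle.preprocess import _dna_g1_mode

        _, mito = gating.split_interphase_mitosis(table)
        g1_mode, _ = find_dna_modes(table)
        mito_mode_c = 2.0 * _dna_g1_mode(mito["dna"]) / g1_mode
        assert mito_mode_c == pytest.approx(4.0, rel=0.05)

    def test_sets_disjoint(self, preprocessed):
        table, _ = preprocessed
        inter, mito = gating.split_interphase_mitosis(table)
        assert len(inter) + len(mito) <= len(table)

    def test_no_mitosis_yields_empty_set(self, truth):
        from cytocycle import synthcyto as sc
        from dataclasses import replace

        # truncate the cycle: regenerate with no event beyond t_g2m
        noise = sc.NoiseModel(n=5000, seed=13, gain={"dna": 100.0})
        table = sc.generate_population(truth, noise)
        keep = table["truth_t"] < truth.t_g2m
        table = table.select(keep)
        inter, mito = gating.split_interphase_mitosis(table)
        assert len(mito) <= 0.002 * len(table)


class TestAutoSegmentS:
    def test_chain_layout_and_min_events(self, interphase):
        inter, _ = interphase
        chain = gating.auto_segment_s(inter, n_segments=12, min_events=300)
        roles = [s.role for s in chain.steps]
        assert roles.count("segment") == 12
        assert roles.count("phase_cluster") == 2
        assert roles.count("transition_oval") == 2
        for s in chain.steps:
            if s.role == "segment":
                assert len(s.indices) >= 300

    def test_traversal_monotone_in_truth_time(self, interphase):
        inter, _ = interphase
        chain = gating.auto_segment_s(inter)
        med_t = [np.median(inter["truth_t"][s.indices])
                 for s in chain.partition_steps()]
        assert (np.diff(med_t) > 0).all()

    def test_partition_assigns_each_event_once(self, interphase):
        inter, _ = interphase
        chain = gating.auto_segment_s(inter)
        chain.validate_partition()
        total = sum(len(s.indices) for s in chain.partition_steps())
        assert total == chain.n_gated

    def test_insufficient_events_errors(self, interphase):
        inter, _ = interphase
        small = inter.select(np.arange(500))
        with pytest.raises(ValueError, match="segments"):
            gating.auto_segment_s(small, n_segments=12, min_events=300)


class TestChainStats:
    def test_frequencies_partition_population(self, interphase):
        inter, _ = interphase
        chain = gating.auto_segment_s(inter)
        stats = gating.chain_stats(inter, chain)
        freq_sum = sum(s.frequency for s in stats if s.role != "transition_oval")
        assert freq_sum == pytest.approx(1.0, abs=1e-12)

    def test_medians_track_truth_profile(self, interphase, truth):
        inter, _ = interphase
        chain = gating.auto_segment_s(inter)
        stats = gating.chain_stats(inter, chain)
        gain = 3.0  # multi-color cyclin A2 gain used by the fixture
        dynamic_range = gain * 100.0
        for s in stats:
            if not s.step_id.startswith("S"):
                continue
            step = chain.step(s.step_id)
            t_med = np.median(inter["truth_t"][step.indices])
            expected = gain * truth.evaluate("cyca2", t_med)
            assert abs(s.medians["cyca2"] - expected) <= 0.05 * dynamic_range


class TestMitosisChain:
    def test_traversal_monotone_across_views(self, interphase):
        _, mito = interphase
        chain = gating.build_mitosis_chain(mito)
        med_t = [np.median(mito["truth_t"][s.indices]) for s in chain.steps]
        assert (np.diff(med_t) > 0).all()
        views = [s.view for s in chain.steps]
        assert len(set(views)) == 3

    def test_final_steps_cyclin_negative(self, interphase):
        _, mito = interphase
        chain = gating.build_mitosis_chain(mito)
        stats = gating.chain_stats(mito, chain, ["cyca2", "cycb1"])
        last = stats[-1]
        detection = 0.1 * np.percentile(mito["cyca2"], 95)
        assert last.medians["cyca2"] < detection
        assert last.medians["cycb1"] < 0.1 * np.percentile(mito["cycb1"], 95)

    def test_empty_table_yields_empty_chain(self, interphase):
        _, mito = interphase
        empty = mito.select(np.zeros(len(mito), dtype=bool))
        chain = gating.build_mitosis_chain(empty)
        assert chain.steps == []
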
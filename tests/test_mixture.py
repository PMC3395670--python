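"""Constrained Gaussian deconvolution of phase log-intensity clusters."""

import numpy as np
import pytest

from cytocycle import mixture as mx


def draw_mixture(n, means, sds, weights, seed):
    rng = np.random.default_rng(seed)
    lab = rng.choice(len(weights), n, p=weights)
    logv = np.asarray(means)[lab] + np.asarray(sds)[lab] * rng.standard_normal(n)
    return 10.0 ** logv


ENTRY = mx.GaussianComponent(2.0, 0.045)
EXIT = mx.GaussianComponent(2.22, 0.045)
MID = 0.5 * (ENTRY.mean + EXIT.mean)
G2_TRUE_W = (0.35, 0.35, 0.30)


def g2_sample(n, seed):
    return draw_mixture(n, [ENTRY.mean, MID, EXIT.mean],
                        [ENTRY.sd, 0.05, EXIT.sd], G2_TRUE_W, seed)


class TestAnchor:
    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(0)
        vals = 10.0 ** rng.normal(2.0, 0.1, 2000)
        comp = mx.fit_anchor(vals)
        assert comp.mean == pytest.approx(2.0, abs=0.01)
        assert comp.sd == pytest.approx(0.1, abs=0.01)

    def test_constant_input_floors_sd_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            comp = mx.fit_anchor(np.full(100, 50.0))
        assert comp.sd == pytest.approx(1e-3)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            mx.fit_anchor(np.ones(10) * 5)

    def test_synthetic_ovals_bracket_g2(self, preprocessed):
        from cytocycle import gating, preprocess as pp

        table, anchor = preprocessed
        inter, mito = gating.split_interphase_mitosis(table)
        inter = pp.stemline_gate(inter)
        chain = gating.auto_segment_s(inter)
        off = anchor.offsets["cyca2"]
        entry = mx.fit_anchor(inter["cyca2"][chain.step("S/G2").indices] + off)
        mchain = gating.build_mitosis_chain(mito)
        exit_vals = gating.g2_exit_values(mito, mchain, "cyca2") + off
        exit_c = mx.fit_anchor(exit_vals)
        # accumulating cyclin: entry mean below exit mean
        assert entry.mean < exit_c.mean


class TestRSquared:
    def test_identical_fit_is_one(self):
        h = np.array([1.0, 4, 6, 4, 1])
        assert mx.r_squared(h, h) == 1.0

    def test_mean_fit_is_zero(self):
        h = np.array([1.0, 4, 6, 4, 1])
        assert mx.r_squared(h, np.full(5, h.mean())) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # counts (1,4,6,4,1) vs fit (1,4,5,4,2): SS_res=2, SS_tot=18.8
        h = np.array([1.0, 4, 6, 4, 1])
        f = np.array([1.0, 4, 5, 4, 2])
        assert mx.r_squared(h, f) == pytest.approx(1.0 - 2.0 / 18.8)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            mx.r_squared(np.ones(5), np.ones(5))


class TestFitG2:
    def test_high_r2_on_generated_mixture(self):
        fit = mx.fit_g2(g2_sample(5000, 1), ENTRY, EXIT, lam=0.0, seed=1)
        assert fit.r2 >= 0.97

    def test_weight_recovery(self):
        fit = mx.fit_g2(g2_sample(20000, 2), ENTRY, EXIT, lam=0.0, seed=2)
        w = fit.weights / fit.weights.sum()
        comps = sorted(fit.components, key=lambda c: c.mean)
        w = np.array([c.weight for c in comps]) / fit.weights.sum()
        assert np.abs(w - np.array(G2_TRUE_W)).max() < 0.05

    def test_weight_mass_matches_histogram(self):
        fit = mx.fit_g2(g2_sample(8000, 3), ENTRY, EXIT, lam=0.0, seed=3)
        assert fit.weights.sum() == pytest.approx(1.0, abs=0.01)

    def test_constrained_means_are_anchored(self):
        fit = mx.fit_g2(g2_sample(5000, 4), ENTRY, EXIT, lam=0.0, seed=4)
        means = np.sort(fit.means)
        np.testing.assert_allclose(means, [ENTRY.mean, MID, EXIT.mean],
                                   atol=1e-12)

    def test_equal_anchors_collapse_to_single_gaussian(self):
        rng = np.random.default_rng(5)
        vals = 10.0 ** rng.normal(2.0, 0.05, 3000)
        fit = mx.fit_g2(vals, ENTRY, ENTRY, seed=5)
        assert len(fit.components) == 1
        plain = mx.fit_anchor(vals)
        assert fit.components[0].mean == pytest.approx(plain.mean)
        assert fit.components[0].sd == pytest.approx(plain.sd)

    def test_median_weight_error_across_settings(self):
        # parameter recovery over many weight settings
        rng = np.random.default_rng(6)
        errs = []
        for k in range(30):
            w = rng.dirichlet(np.ones(3) * 4)
            vals = draw_mixture(6000, [ENTRY.mean, MID, EXIT.mean],
                                [ENTRY.sd, 0.05, EXIT.sd], w, seed=100 + k)
            fit = mx.fit_g2(vals, ENTRY, EXIT, lam=0.0, seed=k)
            got = np.array([c.weight for c in
                            sorted(fit.components, key=lambda c: c.mean)])
            got = got / got.sum()
            errs.append(np.abs(got - w).max())
        assert np.median(errs) < 0.05

    def test_lambda_monotonically_reduces_trajectory_deviation(self):
        vals = draw_mixture(8000, [ENTRY.mean, MID, EXIT.mean],
                            [ENTRY.sd, 0.05, EXIT.sd], [0.2, 0.3, 0.5], seed=7)
        traj = lambda F: 100.0 + 120.0 * np.asarray(F)
        pens = [mx.fit_g2(vals, ENTRY, EXIT, trajectory=traj, lam=lam,
                          f_start=0.7, f_span=0.2, seed=0).penalty
                for lam in (0.0, 0.5, 2.0, 10.0)]
        assert all(np.diff(pens) <= 1e-9)


class TestFitG1CyclinB:
    def test_recovers_background_level(self):
        bg, exit_mean = 0.9, 1.25
        exit_c = mx.GaussianComponent(exit_mean, 0.06)
        cv = exit_c.sd / exit_c.mean
        mid = 0.5 * (bg + exit_mean)
        vals = draw_mixture(12000, [bg, mid, exit_mean],
                            [cv * bg, cv * mid, exit_c.sd],
                            [0.6, 0.25, 0.15], seed=8)
        fit = mx.fit_g1_cyclinB(vals, exit_c, seed=8)
        low = min(fit.components, key=lambda c: c.mean)
        assert 10.0 ** low.mean == pytest.approx(10.0 ** bg, rel=0.03)

    def test_exit_at_peak_collapses_to_single_component(self):
        rng = np.random.default_rng(9)
        vals = 10.0 ** rng.normal(1.0, 0.05, 3000)
        exit_c = mx.GaussianComponent(1.0, 0.05)
        fit = mx.fit_g1_cyclinB(vals, exit_c, seed=9)
        assert len(fit.components) == 1

    def test_weights_nonnegative_and_mass_conserving(self):
        exit_c = mx.GaussianComponent(1.25, 0.06)
        vals = draw_mixture(9000, [0.9, 1.075, 1.25], [0.043, 0.052, 0.06],
                            [0.5, 0.3, 0.2], seed=10)
        fit = mx.fit_g1_cyclinB(vals, exit_c, seed=10)
        assert (fit.weights >= 0).all()
        assert fit.weights.sum() == pytest.approx(1.0, abs=0.01)


class TestFreeMixture:
    def test_matches_em_implementation(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(11)
        logv = np.concatenate([rng.normal(1.0, 0.08, 3000),
                               rng.normal(1.6, 0.10, 2000)])
        fit = mx.fit_free_mixture(10.0 ** logv, 2, seed=0)
        em = GaussianMixture(2, random_state=0).fit(logv[:, None])
        em_means = np.sort(em.means_.ravel())
        np.testing.assert_allclose(fit.means, em_means, rtol=0.02)
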
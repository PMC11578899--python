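"""Canonical HRF, parametric-modulation designs, BOLD simulation, OLS."""

import numpy as np
import pandas as pd
import pytest

from noveltytask.glm import (
    DesignMatrix,
    build_design,
    canonical_hrf,
    fit_glm,
    simulate_bold,
)


class TestHrf:
    def test_zero_at_onset_and_before(self):
        assert canonical_hrf(0.0) == 0.0
        assert canonical_hrf(-3.0) == 0.0

    def test_unit_peak_between_4_and_6_seconds(self):
        t = np.arange(0, 32, 0.1)
        h = canonical_hrf(t)
        assert h.max() == pytest.approx(1.0, abs=1e-6)
        assert 4.0 <= t[h.argmax()] <= 6.0

    def test_undershoot_then_return_to_zero(self):
        t = np.arange(0, 32, 0.1)
        h = canonical_hrf(t)
        late = h[(t > 12) & (t < 20)]
        assert late.min() < 0  # post-stimulus undershoot
        assert abs(canonical_hrf(32.0)) < 1e-3

    def test_positive_integral(self):
        t = np.arange(0, 32, 0.01)
        assert np.trapezoid(canonical_hrf(t), t) > 0

    def test_matches_reference_double_gamma_peak(self):
        # cross-check against nilearn's glover HRF: the two canonical forms
        # differ in undershoot parameterization but agree on peak timing and
        # overall shape
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        dt = 0.1
        ref = nilearn_hrf.glover_hrf(1.0, oversampling=int(1 / dt), time_length=32)
        t = np.arange(len(ref)) * dt
        ours = canonical_hrf(t)
        assert abs(t[ours.argmax()] - t[ref.argmax()]) <= 0.5
        corr = np.corrcoef(ours, ref)[0, 1]
        assert corr > 0.9


def events_table(onsets, rpes, explore, duration=1.0):
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": duration,
            "rpe": rpes,
            "explore": explore,
        }
    )


class TestDesign:
    def test_all_zero_rpes_give_zero_modulators(self):
        ev = events_table([10, 30, 50, 70], [0.0] * 4, [True, False, True, False])
        d = build_design(ev, tr=2.5)
        assert np.allclose(d.frame["rpe_explore"], 0)
        assert np.allclose(d.frame["rpe_nonexplore"], 0)
        assert d.frame["events"].abs().max() > 0

    def test_modulators_are_condition_specific_and_linear(self):
        # two explore events with opposite centered weights land only in the
        # explore column; doubling all RPEs doubles the modulators
        ev = events_table([10, 40], [0.0, 0.2], [True, True])
        d1 = build_design(ev, tr=2.5)
        assert np.allclose(d1.frame["rpe_nonexplore"], 0)
        assert d1.frame["rpe_explore"].abs().max() > 0
        ev2 = ev.assign(rpe=ev["rpe"] * 2)
        d2 = build_design(ev2, tr=2.5)
        assert np.allclose(d2.frame["rpe_explore"], 2 * d1.frame["rpe_explore"], atol=1e-12)

    def test_single_event_column_is_scaled_hrf(self):
        # a single unit-weight event convolved with the HRF reproduces the
        # HRF shape (up to boxcar smoothing) in the events column only
        ev = events_table([20.0], [0.1], [True], duration=0.1)
        d = build_design(ev, tr=0.5, dt=0.05)
        events_col = d.frame["events"].to_numpy()
        t = np.arange(d.n_scans) * 0.5 - 20.0
        expected = canonical_hrf(t) * 0.1  # boxcar area = duration
        assert np.allclose(events_col, expected, atol=0.02)
        # single explore event: centered weight is 0 -> no modulation signal
        assert np.allclose(d.frame["rpe_explore"], 0)

    def test_modulators_mean_centered_before_convolution(self):
        rng = np.random.default_rng(0)
        ev = events_table(
            np.arange(8) * 12.0, rng.normal(0.1, 0.05, 8), [True] * 4 + [False] * 4
        )
        d = build_design(ev, tr=2.5)
        # centered modulator integrates to ~0 over a long window
        assert abs(d.frame["rpe_explore"].sum()) < 1e-6 * max(
            1, abs(d.frame["events"].sum())
        ) + 1e-3

    def test_event_beyond_scan_window_rejected(self):
        ev = events_table([10.0, 500.0], [0.1, 0.1], [True, False])
        with pytest.raises(ValueError, match="scan window"):
            build_design(ev, tr=2.5, n_scans=40)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            build_design(pd.DataFrame({"onset": [1.0]}), tr=2.5)

    def test_drift_columns_added(self):
        ev = events_table([10, 30], [0.1, 0.2], [True, False])
        d = build_design(ev, tr=2.5, drift_order=2)
        assert "drift_1" in d.columns and "drift_2" in d.columns


@pytest.fixture(scope="module")
def demo_design():
    rng = np.random.default_rng(1)
    n_events = 40
    onsets = np.arange(n_events) * 6.0 + 2.0
    rpes = rng.normal(0.05, 0.08, n_events)
    explore = np.tile([True, False], n_events // 2)
    return build_design(events_table(onsets, rpes, explore), tr=2.5)


TRUE_BETAS = {"events": 1.0, "rpe_explore": 2.0, "rpe_nonexplore": 0.5, "intercept": 10.0}


class TestSimulateAndFit:
    def test_noise_free_signal_is_exact_linear_combination(self, demo_design):
        rng = np.random.default_rng(0)
        y = simulate_bold(demo_design, TRUE_BETAS, noise_sd=0.0, rng=rng)
        b = np.array([TRUE_BETAS[c] for c in demo_design.columns])
        assert np.allclose(y, demo_design.matrix @ b)

    def test_fixed_seed_reproducibility(self, demo_design):
        y1 = simulate_bold(demo_design, TRUE_BETAS, 1.0, np.random.default_rng(3))
        y2 = simulate_bold(demo_design, TRUE_BETAS, 1.0, np.random.default_rng(3))
        assert np.array_equal(y1, y2)

    def test_noise_sd_matches_parameter(self):
        frame = pd.DataFrame(
            {"events": np.zeros(10_000), "rpe_explore": np.zeros(10_000),
             "rpe_nonexplore": np.zeros(10_000), "intercept": np.ones(10_000)}
        )
        d = DesignMatrix(frame=frame, tr=1.0)
        y = simulate_bold(d, {"intercept": 0.0}, noise_sd=2.0, rng=np.random.default_rng(4))
        assert abs(y.std() / 2.0 - 1) < 0.05

    def test_ar1_noise_keeps_marginal_sd(self):
        frame = pd.DataFrame(
            {"events": np.zeros(20_000), "rpe_explore": np.zeros(20_000),
             "rpe_nonexplore": np.zeros(20_000), "intercept": np.ones(20_000)}
        )
        d = DesignMatrix(frame=frame, tr=1.0)
        y = simulate_bold(d, {}, noise_sd=1.5, rng=np.random.default_rng(5), ar1=0.4)
        assert abs(y.std() / 1.5 - 1) < 0.05
        r = np.corrcoef(y[:-1], y[1:])[0, 1]
        assert abs(r - 0.4) < 0.05

    def test_noise_free_recovery_to_machine_precision(self, demo_design):
        y = simulate_bold(demo_design, TRUE_BETAS, 0.0, np.random.default_rng(0))
        est = fit_glm(y, demo_design)
        assert est.b_explore == pytest.approx(2.0, abs=1e-9)
        assert est.b_nonexplore == pytest.approx(0.5, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_estimates_unbiased_over_monte_carlo(self, demo_design):
        rng = np.random.default_rng(6)
        est_e, est_n = [], []
        for _ in range(200):
            y = simulate_bold(demo_design, TRUE_BETAS, noise_sd=1.0, rng=rng)
            est = fit_glm(y, demo_design)
            est_e.append(est.b_explore)
            est_n.append(est.b_nonexplore)
        se_e = np.std(est_e) / np.sqrt(200)
        se_n = np.std(est_n) / np.sqrt(200)
        assert abs(np.mean(est_e) - 2.0) < 2 * se_e + 1e-9
        assert abs(np.mean(est_n) - 0.5) < 2 * se_n + 1e-9

    def test_orthogonal_design_estimates_equal_projections(self):
        # on an exactly orthogonal design OLS reduces to per-column projection
        n = 64
        t = np.arange(n)
        frame = pd.DataFrame(
            {
                "events": np.cos(2 * np.pi * t / n),
                "rpe_explore": np.sin(2 * np.pi * 3 * t / n),
                "rpe_nonexplore": np.cos(2 * np.pi * 5 * t / n),
                "intercept": np.ones(n),
            }
        )
        d = DesignMatrix(frame=frame, tr=1.0)
        rng = np.random.default_rng(7)
        y = simulate_bold(d, {"rpe_explore": 1.3, "rpe_nonexplore": -0.4}, 0.5, rng)
        est = fit_glm(y, d)
        x = frame["rpe_explore"].to_numpy()
        assert est.b_explore == pytest.approx(float(y @ x / (x @ x)), abs=1e-10)
        x = frame["rpe_nonexplore"].to_numpy()
        assert est.b_nonexplore == pytest.approx(float(y @ x / (x @ x)), abs=1e-10)

    def test_rank_deficient_design_names_collinear_columns(self, demo_design):
        frame = demo_design.frame.copy()
        frame["rpe_nonexplore"] = 2.0 * frame["rpe_explore"]
        bad = DesignMatrix(frame=frame, tr=2.5)
        y = np.zeros(bad.n_scans)
        with pytest.raises(np.linalg.LinAlgError, match="rpe_nonexplore"):
            fit_glm(y, bad)

    def test_unknown_beta_names_rejected(self, demo_design):
        with pytest.raises(ValueError, match="unknown design columns"):
            simulate_bold(demo_design, {"nonsense": 1.0}, 0.0, np.random.default_rng(0))


def test_end_to_end_coupling_recovery_within_ci(default_session):
    """Session -> trajectories -> design -> simulate -> OLS recovers couplings."""
    import noveltytask as nt
    from noveltytask.glm import estimate_couplings

    rng = np.random.default_rng(8)
    est = estimate_couplings(default_session, b_explore=1.5, b_nonexplore=0.5, rng=rng)
    assert abs(est.b_explore - 1.5) < 3 * est.se_explore
    assert abs(est.b_nonexplore - 0.5) < 3 * est.se_nonexplore
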
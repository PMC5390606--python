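"""Finite-difference derivatives, static least squares, dynamic adaptation."""

import numpy as np
import pytest

import cyclenet as cn
from cyclenet.calibration import (
    InsufficientSamplesError,
    RankDeficiencyError,
    SampleSet,
    _objective_residual,
)
from cyclenet.ode import ODEParameters, PARAM_NAMES


def _samples_of(fn, h, n, labels=cn.GENE_VARIABLES):
    t = np.arange(n) * h
    states = np.column_stack([fn(t)] * 5)
    return SampleSet(times=t, states=states, labels=labels)


class TestSampleSet:
    def test_non_uniform_spacing_rejected(self):
        with pytest.raises(ValueError, match="uniformly spaced"):
            SampleSet(times=np.array([0.0, 1.0, 2.5]), states=np.zeros((3, 5)))

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SampleSet(times=np.array([0.0, 1.0, 0.5]), states=np.zeros((3, 5)))


class TestEstimateDerivatives:
    def test_order4_exact_on_cubic(self):
        """The order-4 stencil differentiates t^3 exactly, boundaries included."""
        s = _samples_of(lambda t: t**3, h=0.5, n=9)
        d = cn.estimate_derivatives(s, order=4)
        expected = 3.0 * (s.times**2)
        for j in range(5):
            np.testing.assert_allclose(d.derivatives[:, j], expected, atol=1e-10)

    def test_fourth_order_error_decay_on_sine(self):
        errs = []
        for h in (0.2, 0.1):
            s = _samples_of(np.sin, h=h, n=int(4.0 / h) + 1)
            d = cn.estimate_derivatives(s, order=4)
            errs.append(np.max(np.abs(d.derivatives[:, 0] - np.cos(d.times))))
        ratio = errs[0] / errs[1]
        assert 8.0 <= ratio <= 32.0  # nominal 16x for a 4th-order stencil

    def test_constant_samples_give_zero(self):
        s = _samples_of(lambda t: np.ones_like(t), h=1.0, n=7)
        d = cn.estimate_derivatives(s, order=4)
        np.testing.assert_allclose(d.derivatives, 0.0, atol=1e-12)

    def test_too_few_samples_for_stencil(self):
        s = _samples_of(lambda t: t, h=1.0, n=3)
        with pytest.raises(InsufficientSamplesError, match="at least 5"):
            cn.estimate_derivatives(s, order=4)

    @pytest.mark.parametrize("order", [2, 6])
    def test_other_orders_exact_on_linear(self, order):
        s = _samples_of(lambda t: 2.0 * t, h=0.5, n=9)
        d = cn.estimate_derivatives(s, order=order)
        np.testing.assert_allclose(d.derivatives, 2.0, atol=1e-9)


class TestFitStatic:
    def test_round_trip_recovery_from_reference_params(self, table3, reference_samples):
        res = cn.fit_static(reference_samples, fd_order=4)
        assert res.params.r11 == pytest.approx(table3.r11, abs=1e-2)
        assert res.params.r24 == pytest.approx(table3.r24, abs=1e-2)

    def test_exact_derivatives_recover_all_19_exactly(self, table3, reference_samples):
        """With analytic derivatives the LS system is consistent: exact recovery."""
        exact = np.array([cn.rhs(x, table3) for x in reference_samples.states])
        s = SampleSet(
            times=reference_samples.times,
            states=reference_samples.states,
            derivatives=exact,
        )
        res = cn.fit_static(s)
        np.testing.assert_allclose(res.params.to_array(), table3.to_array(), atol=1e-9)
        assert np.all(res.static_rss <= 1e-18)

    def test_underdetermined_sampling_rejected(self, table3):
        traj = cn.simulate_rk4(table3, np.ones(5), h=0.01, t_end=0.02)
        with pytest.raises(InsufficientSamplesError):
            cn.fit_static(SampleSet.from_trajectory(traj), fd_order=2)

    def test_collinear_samples_rejected(self):
        s = SampleSet(
            times=np.arange(10.0),
            states=np.ones((10, 5)),
            derivatives=np.zeros((10, 5)),
        )
        with pytest.raises(RankDeficiencyError, match="richer sampling"):
            cn.fit_static(s)

    @pytest.mark.parametrize("seed", range(20))
    def test_recovery_of_random_stable_systems(self, seed):
        """Gradient matching at h=0.01 recovers random stable coefficient sets."""
        truth = cn.random_stable_params(seed=seed)
        traj = cn.simulate_rk4(truth, np.ones(5), h=0.01, t_end=5.0)
        res = cn.fit_static(SampleSet.from_trajectory(traj), fd_order=4)
        np.testing.assert_allclose(
            res.params.to_array(), truth.to_array(), atol=1e-2, rtol=0
        )

    def test_error_shrinks_with_step_size(self, table3):
        errs = []
        for h in (0.04, 0.01):
            traj = cn.simulate_rk4(table3, np.ones(5), h=h, t_end=5.0)
            res = cn.fit_static(SampleSet.from_trajectory(traj), fd_order=4)
            errs.append(np.max(np.abs(res.params.to_array() - table3.to_array())))
        assert errs[1] < errs[0]

    def test_static_standard_errors_are_reported(self, reference_samples):
        res = cn.fit_static(reference_samples)
        assert res.bse is not None and res.bse.shape == (19,)
        assert np.all(res.bse >= 0)


class TestRefineDynamic:
    def test_truth_is_a_fixed_point(self, table3, coarse_samples):
        res = cn.refine_dynamic(table3, coarse_samples, max_iter=5)
        np.testing.assert_allclose(
            res.params.to_array(), table3.to_array(), atol=1e-6, rtol=0
        )

    def test_perturbed_start_moves_toward_truth(self, table3, coarse_samples):
        start = ODEParameters.from_array(table3.to_array() * 1.05)
        res = cn.refine_dynamic(start, coarse_samples, max_iter=20)
        err_before = np.max(np.abs(start.to_array() - table3.to_array()))
        err_after = np.max(np.abs(res.params.to_array() - table3.to_array()))
        assert err_after < err_before

    def test_max_iter_zero_returns_initial_verbatim(self, table3, coarse_samples):
        start = ODEParameters.from_array(table3.to_array() * 1.1)
        res = cn.refine_dynamic(start, coarse_samples, max_iter=0)
        np.testing.assert_array_equal(res.params.to_array(), start.to_array())

    def test_objective_never_increases_on_accepted_steps(self, table3, coarse_samples):
        start = ODEParameters.from_array(table3.to_array() * 1.08)
        res = cn.refine_dynamic(start, coarse_samples, max_iter=15)
        hist = np.array(res.objective_history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) <= 0)

    def test_discrepancy_components_match_objective(self, table3, coarse_samples):
        start = ODEParameters.from_array(table3.to_array() * 1.05)
        res = cn.refine_dynamic(
            start, coarse_samples, transient_weight=2.0, steady_weight=5.0, max_iter=5
        )
        r, transient, steady = _objective_residual(
            res.params, coarse_samples, 2.0, 5.0, 0.01
        )
        assert res.transient_discrepancy == pytest.approx(transient)
        assert res.steady_discrepancy == pytest.approx(steady)
        assert float(r @ r) == pytest.approx(2.0 * transient + 5.0 * steady, rel=1e-9)


class TestModelResults:
    def test_from_dataframe_round_trip(self, reference_samples):
        df = cn.StateTrajectory(
            times=reference_samples.times,
            states=reference_samples.states,
            labels=reference_samples.labels,
        ).to_frame()
        model = cn.CellCycleODE.from_dataframe(df)
        np.testing.assert_array_equal(model.samples.states, reference_samples.states)

    def test_static_fit_via_model(self, table3, reference_samples):
        res = cn.CellCycleODE(reference_samples).fit(method="static")
        assert res.params.r11 == pytest.approx(table3.r11, abs=1e-2)
        assert "r11" in res.summary()

    def test_results_simulate_covers_sample_window(self, reference_samples):
        res = cn.CellCycleODE(reference_samples).fit(method="static")
        traj = res.simulate(h=0.05)
        assert traj.times[0] == reference_samples.times[0]
        assert traj.times[-1] == pytest.approx(reference_samples.times[-1])


@pytest.fixture(scope="module")
def pipeline(table1):
    cfg = cn.CalibrationConfig(max_iter=12, sim_step=0.05)
    return cn.calibrate_pipeline(table1, config=cfg)


class TestPipeline:
    def test_produces_19_finite_params_and_comparison(self, pipeline):
        assert np.all(np.isfinite(pipeline.results.params.to_array()))
        comp = pipeline.comparison
        assert [c for c in comp.columns if c.startswith("sampled_")] == [
            f"sampled_{g}" for g in cn.KEY_GENES
        ]
        assert [c for c in comp.columns if c.startswith("simulated_")] == [
            f"simulated_{g}" for g in cn.KEY_GENES
        ]
        assert len(comp) == 61

    def test_steady_state_matches_stationary_distribution(self, pipeline):
        """The steady-state anchor pulls the fit onto the walk's stationary point."""
        stat = pipeline.stationary.to_series()
        last = pipeline.comparison.iloc[-1]
        for g in cn.KEY_GENES:
            assert last[f"simulated_{g}"] == pytest.approx(stat[g], abs=1e-2)

    def test_zero_walk_steps_rejected(self, table1):
        with pytest.raises(InsufficientSamplesError):
            cn.calibrate_pipeline(table1, walk_steps=0)

    def test_pipeline_is_deterministic(self, table1, pipeline):
        cfg = cn.CalibrationConfig(max_iter=12, sim_step=0.05)
        again = cn.calibrate_pipeline(table1, config=cfg)
        np.testing.assert_array_equal(
            again.results.params.to_array(), pipeline.results.params.to_array()
        )
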
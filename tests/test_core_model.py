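"""Communication model: ODE trajectories, analytic peak, reporter conversion."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from matesense.core_model import (
    CommunicationParams,
    DoseResponseCurve,
    IdentifiabilityError,
    PopulationComposition,
    SaturationWarning,
    dose_response,
    fit_model,
    peak_pheromone_analytic,
    pheromone_bar1delta,
    pheromone_closed_form,
    predict_reporter,
    simulate_pheromone,
)
from matesense.synthetic import generate_reporter_dataset


def numeric_peak(comp, params, t_max=50.0):
    """Independent oracle: dense closed-form evaluation + golden-section."""
    res = minimize_scalar(
        lambda t: -float(pheromone_closed_form(comp, params, max(t, 0.0))),
        bounds=(1e-6, t_max), method="bounded", options={"xatol": 1e-12},
    )
    return -res.fun, res.x


class TestPopulationComposition:
    def test_derived_quantities(self):
        comp = PopulationComposition(rho_a=0.3, rho_alpha=0.1)
        assert comp.theta_alpha == pytest.approx(0.25)
        assert comp.rho_T == pytest.approx(0.4)

    def test_from_ratio_round_trip(self):
        comp = PopulationComposition.from_ratio(0.25, 0.4)
        assert comp.rho_a == pytest.approx(0.3)
        assert comp.rho_alpha == pytest.approx(0.1)

    @pytest.mark.parametrize("rho_a,rho_alpha", [(-1, 1), (1, -1), (0, 0)])
    def test_invalid_compositions_rejected(self, rho_a, rho_alpha):
        with pytest.raises(ValueError):
            PopulationComposition(rho_a=rho_a, rho_alpha=rho_alpha)


class TestSimulatePheromone:
    @pytest.mark.filterwarnings(
        "ignore::matesense.core_model.SaturationWarning")
    def test_bar1delta_linear_accumulation(self, bar1delta_params):
        # without degradation P integrates the source: alpha_s*rho_alpha*t
        comp = PopulationComposition(rho_a=0.7, rho_alpha=2.0)
        traj = simulate_pheromone(comp, bar1delta_params, t_end=3.0, n_points=301)
        assert traj.P[-1] == pytest.approx(6.0, rel=1e-8)

    def test_no_emitters_means_no_pheromone(self, unit_params):
        comp = PopulationComposition(rho_a=1.0, rho_alpha=0.0)
        traj = simulate_pheromone(comp, unit_params, t_end=10.0)
        assert np.all(traj.P == 0.0)

    def test_matches_analytic_peak(self, unit_params, balanced_comp):
        traj = simulate_pheromone(balanced_comp, unit_params, t_end=10.0,
                                  n_points=4001)
        level, t_star = traj.peak
        assert level == pytest.approx(0.7651520803, rel=1e-5)
        assert t_star == pytest.approx(1.3069297, abs=5e-3)

    def test_positivity_and_bar1_monotone(self, unit_params):
        comp = PopulationComposition(rho_a=3.0, rho_alpha=0.2)
        traj = simulate_pheromone(comp, unit_params, t_end=30.0)
        assert np.all(traj.P >= 0)
        assert np.all(np.diff(traj.B) >= 0)

    def test_single_interior_maximum(self, unit_params, balanced_comp):
        traj = simulate_pheromone(balanced_comp, unit_params, t_end=20.0,
                                  n_points=2001)
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(traj.P)))) > 0)
        assert sign_changes == 1

    def test_fixed_step_convergence(self, unit_params, balanced_comp):
        coarse = simulate_pheromone(balanced_comp, unit_params, t_end=5.0,
                                    n_points=2001, method="rk4")
        fine = simulate_pheromone(balanced_comp, unit_params, t_end=5.0,
                                  n_points=4001, method="rk4")
        rel = np.max(np.abs(fine.P[::2] - coarse.P) / np.max(fine.P))
        assert rel < 1e-6

    def test_saturation_warning_flag(self, balanced_comp):
        params = CommunicationParams(alpha_secretion_rate=100.0,
                                     bar1_secretion_rate=0.0, K_M=30.0)
        with pytest.warns(SaturationWarning):
            traj = simulate_pheromone(balanced_comp, params, t_end=10.0)
        assert traj.saturation_warning

    def test_invalid_inputs(self, unit_params, balanced_comp):
        with pytest.raises(ValueError):
            simulate_pheromone(balanced_comp, unit_params, t_end=-1.0)
        with pytest.raises(ValueError):
            simulate_pheromone(balanced_comp, unit_params, t_end=1.0, n_points=1)
        with pytest.raises(ValueError):
            CommunicationParams(alpha_secretion_rate=np.nan)


class TestAnalyticPeak:
    def test_reference_value(self, unit_params, balanced_comp):
        level, t_star = peak_pheromone_analytic(balanced_comp, unit_params)
        assert level == pytest.approx(0.7651520803, abs=1e-9)
        assert t_star == pytest.approx(1.3069297388, abs=1e-9)

    def test_linear_in_emitters(self, unit_params):
        one = peak_pheromone_analytic(
            PopulationComposition(rho_a=0.5, rho_alpha=1.0), unit_params)[0]
        two = peak_pheromone_analytic(
            PopulationComposition(rho_a=0.5, rho_alpha=2.0), unit_params)[0]
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_sqrt_attenuation_in_receivers(self, unit_params):
        base = peak_pheromone_analytic(
            PopulationComposition(rho_a=1.0, rho_alpha=1.0), unit_params)[0]
        quad = peak_pheromone_analytic(
            PopulationComposition(rho_a=4.0, rho_alpha=1.0), unit_params)[0]
        assert quad == pytest.approx(base / 2.0, rel=1e-12)

    @pytest.mark.parametrize("rho_a", [0.01, 0.3, 10.0])
    @pytest.mark.parametrize("rho_alpha", [0.05, 1.0, 20.0])
    def test_agrees_with_numeric_maximum(self, unit_params, rho_a, rho_alpha):
        comp = PopulationComposition(rho_a=rho_a, rho_alpha=rho_alpha)
        level, t_star = peak_pheromone_analytic(comp, unit_params)
        num_level, num_t = numeric_peak(comp, unit_params, t_max=10 * t_star)
        assert level == pytest.approx(num_level, rel=1e-6)
        assert t_star == pytest.approx(num_t, rel=1e-4)

    def test_no_peak_without_degradation(self, bar1delta_params, balanced_comp):
        with pytest.raises(ValueError, match="bar1delta"):
            peak_pheromone_analytic(balanced_comp, bar1delta_params)


class TestBar1Delta:
    def test_zero_at_time_zero(self, bar1delta_params):
        comp = PopulationComposition(rho_a=1.0, rho_alpha=1.0)
        assert pheromone_bar1delta(comp, bar1delta_params, 0.0) == 0.0

    def test_linear_in_emitters_and_time(self, bar1delta_params):
        comp = PopulationComposition(rho_a=1.0, rho_alpha=3.0)
        assert pheromone_bar1delta(comp, bar1delta_params, 2.0) == pytest.approx(6.0)

    def test_independent_of_receiver_density(self, bar1delta_params):
        lo = PopulationComposition(rho_a=0.01, rho_alpha=0.5)
        hi = PopulationComposition(rho_a=10.0, rho_alpha=0.5)
        t = np.linspace(0, 100, 11)
        np.testing.assert_array_equal(
            pheromone_bar1delta(lo, bar1delta_params, t),
            pheromone_bar1delta(hi, bar1delta_params, t),
        )

    def test_negative_time_rejected(self, bar1delta_params, balanced_comp):
        with pytest.raises(ValueError):
            pheromone_bar1delta(balanced_comp, bar1delta_params, -1.0)


class TestDoseResponse:
    def test_reference_points(self, hill_curve):
        assert dose_response(0.0, hill_curve) == hill_curve.baseline
        assert dose_response(hill_curve.ec50, hill_curve) == pytest.approx(
            hill_curve.baseline + hill_curve.r_max / 2
        )
        assert dose_response(1e9 * hill_curve.ec50, hill_curve) == pytest.approx(
            hill_curve.baseline + hill_curve.r_max, abs=1e-9 * hill_curve.r_max
        )

    def test_strictly_increasing_and_bounded(self, hill_curve):
        P = np.logspace(-4, 4, 200)
        out = dose_response(P, hill_curve)
        assert np.all(np.diff(out) > 0)
        assert np.all(out >= hill_curve.baseline)
        assert np.all(out < hill_curve.baseline + hill_curve.r_max)

    def test_negative_pheromone_rejected(self, hill_curve):
        with pytest.raises(ValueError):
            dose_response(-0.1, hill_curve)


class TestPredictReporter:
    def test_no_emitters_gives_baseline(self, unit_params):
        curve = DoseResponseCurve(r_max=100.0, ec50=0.5, baseline=7.0)
        comp = PopulationComposition(rho_a=1.0, rho_alpha=0.0)
        assert predict_reporter(comp, unit_params, curve) == pytest.approx(7.0)

    def test_bar1delta_collapses_onto_rho_alpha(self, bar1delta_params, hill_curve):
        # same emitter density, very different receiver density -> same output
        preds = [
            predict_reporter(
                PopulationComposition(rho_a=ra, rho_alpha=0.2),
                bar1delta_params, hill_curve, strain="bar1d",
            )
            for ra in (0.01, 0.5, 5.0)
        ]
        assert np.ptp(preds) == 0.0

    def test_wt_tracks_sex_ratio_when_degradation_dominates(self, hill_curve):
        # strong degradation: predictions at equal theta, different rho_T agree
        params = CommunicationParams(alpha_secretion_rate=100.0,
                                     bar1_secretion_rate=10.0,
                                     bar1_specific_activity=10.0)
        for theta in (0.25, 0.5, 0.75):
            preds = [
                predict_reporter(
                    PopulationComposition.from_ratio(theta, rho_T),
                    params, hill_curve,
                )
                for rho_T in (0.3, 0.6, 1.2)
            ]
            # peak ~ theta*sqrt(rho_T)/sqrt(1-theta): a 4x rho_T change
            # moves the compressed response by far less than its mean
            assert np.ptp(preds) / np.mean(preds) < 0.3

    def test_unknown_tokens_rejected(self, unit_params, hill_curve, balanced_comp):
        with pytest.raises(ValueError):
            predict_reporter(balanced_comp, unit_params, hill_curve, strain="xyz")
        with pytest.raises(ValueError):
            predict_reporter(balanced_comp, unit_params, hill_curve, mode="xyz")


class TestFitModel:
    def test_noiseless_recovery(self, hill_curve):
        true = CommunicationParams(alpha_secretion_rate=0.8,
                                   bar1_secretion_rate=2.5,
                                   bar1_specific_activity=1.0)
        # early measurement time: some conditions are still rising, which is
        # what separates decay from gain (past the peak only the ratio
        # gain/sqrt(decay) is constrained)
        data = generate_reporter_dataset(params=true, curve=hill_curve,
                                         strain="WT", noise_sd=0.0, seed=0,
                                         t_meas=2.0)
        res = fit_model(data, "WT", hill_curve, initial=(0.3, 0.3), t_meas=2.0)
        assert res.converged
        assert res.gain == pytest.approx(0.8, rel=1e-6)
        assert res.decay == pytest.approx(2.5, rel=1e-6)
        assert res.rss < 1e-12

    def test_bar1delta_gain_recovery(self, hill_curve):
        true = CommunicationParams(alpha_secretion_rate=0.05,
                                   bar1_secretion_rate=0.0)
        data = generate_reporter_dataset(params=true, curve=hill_curve,
                                         strain="bar1d", noise_sd=0.0, seed=0)
        res = fit_model(data, "bar1d", hill_curve, initial=(1.0, 1.0))
        assert res.gain == pytest.approx(0.05, rel=1e-6)
        assert res.decay is None

    def test_single_composition_unidentifiable(self, hill_curve):
        data = generate_reporter_dataset(
            design=__import__("pandas").DataFrame(
                {"rho_a": [0.5] * 3, "rho_alpha": [0.5] * 3}
            ),
            strain="WT", noise_sd=0.0, seed=0,
        ).iloc[:3]
        with pytest.raises(IdentifiabilityError):
            fit_model(data, "WT", hill_curve)

    def test_noisy_recovery_within_standard_errors(self, hill_curve):
        # moderate-noise recovery study; the full 200-seed version runs in
        # the acceptance suite
        true = CommunicationParams(alpha_secretion_rate=1.0,
                                   bar1_secretion_rate=1.0)
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            data = generate_reporter_dataset(params=true, curve=hill_curve,
                                             strain="WT", noise_sd=20.0,
                                             seed=seed, t_meas=2.0)
            res = fit_model(data, "WT", hill_curve, t_meas=2.0)
            ok = (abs(res.gain - 1.0) <= 3 * res.gain_se
                  and abs(res.decay - 1.0) <= 3 * res.decay_se)
            hits += ok
        assert hits >= int(0.85 * n_seeds)
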
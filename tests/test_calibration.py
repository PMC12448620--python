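"""Calibration: self-consistency, recovery, determinism, identifiability."""

from __future__ import annotations

import math

import numpy as np
import pytest

from geostoich import (
    GSParameters,
    TrialRecord,
    calibrate_experiment,
    calibrate_feed,
    goodness_of_fit,
    reverse_mode,
)
from geostoich.calibration import CalibrationResult
from geostoich.errors import InvalidArgumentError, UndefinedStatisticError
from geostoich.model import IntakePair

TRUTH = GSParameters(
    theta_V=3.7, theta_Z=4.5, sigma_SDA=0.1, xi_basal=0.002, r_B=0.001,
    f_V=0.12, phi=0.4, k_N=0.85, beta_V=0.9, beta_H=0.75,
)


def trial_from_params(p: GSParameters, g: float = 0.012, label: str = "T1",
                      measured_digestibilities: bool = True) -> TrialRecord:
    """A noise-free trial whose observed intakes are the model's own output."""
    intake, _ = reverse_mode(g, p)
    return TrialRecord(
        experiment_id="synthetic",
        feed_label=label,
        protein_intake_IV=intake.I_V,
        lipid_intake_IH=intake.I_H,
        protein_digestibility_ADN=p.beta_V if measured_digestibilities else None,
        lipid_digestibility=p.beta_H if measured_digestibilities else None,
        growth_rate_G=g,
    )


class TestCalibrateFeed:
    def test_self_consistent_trial_has_zero_objective(self):
        trial = trial_from_params(TRUTH)
        res = calibrate_feed(trial, fixed=TRUTH, estimate=set())
        assert res.objective_value == pytest.approx(0.0, abs=1e-20)
        assert res.predicted.I_V == pytest.approx(trial.protein_intake_IV)

    def test_noise_free_recovery_of_fuel_fraction_and_efficiency(self):
        truth = TRUTH.replace(f_V=0.0, phi=0.0, k_N=0.9)
        trial = trial_from_params(truth)
        res = calibrate_feed(trial, fixed=truth.replace(f_V=0.5, k_N=0.5),
                             estimate={"f_V", "k_N"})
        assert res.fitted["f_V"] == pytest.approx(0.0, abs=1e-3)
        assert res.fitted["k_N"] == pytest.approx(0.9, abs=1e-3)

    def test_measured_digestibilities_override_estimation(self):
        trial = trial_from_params(TRUTH)
        res = calibrate_feed(trial, fixed=TRUTH, estimate={"beta_V", "beta_H"})
        assert res.fitted == {}  # both measured, nothing left to estimate
        assert res.params.beta_V == TRUTH.beta_V

    def test_penalty_recovered_when_freed_alone(self):
        trial = trial_from_params(TRUTH)  # truth phi=0.4, f_V=0.12 > 0
        res = calibrate_feed(trial, fixed=TRUTH.replace(phi=0.0), estimate={"phi"})
        assert res.fitted["phi"] == pytest.approx(0.4, abs=1e-3)

    def test_penalty_left_at_zero_when_no_protein_fuelling(self):
        truth = TRUTH.replace(f_V=0.0, phi=0.0)
        trial = trial_from_params(truth)
        res = calibrate_feed(trial, fixed=truth, estimate={"f_V", "k_N", "phi"})
        assert res.fitted["phi"] == 0.0
        assert res.objective_value < 1e-8

    def test_determinism_bit_identical(self):
        trial = trial_from_params(TRUTH.replace(f_V=0.3))
        a = calibrate_feed(trial, fixed=TRUTH, estimate={"f_V", "k_N", "phi"})
        b = calibrate_feed(trial, fixed=TRUTH, estimate={"f_V", "k_N", "phi"})
        assert a.fitted == b.fitted
        assert a.objective_value == b.objective_value
        assert a.predicted == b.predicted

    def test_fitted_point_not_worse_than_grid(self):
        trial = trial_from_params(TRUTH)
        res = calibrate_feed(trial, fixed=TRUTH.replace(f_V=0.4, k_N=0.6),
                             estimate={"f_V", "k_N"})
        assert res.objective_value <= res.trace["grid_best_objective"] + 1e-8

    def test_underdetermined_fit_is_flagged_and_tiebroken(self):
        """5 free parameters vs 2 observations: flat set, documented choice."""
        trial = trial_from_params(TRUTH.replace(f_V=0.05),
                                  measured_digestibilities=False)
        res = calibrate_feed(
            trial, fixed=TRUTH, estimate={"f_V", "k_N", "phi", "beta_V", "beta_H"}
        )
        assert res.nonunique
        assert res.objective_value < 1e-8
        # tie-break pushes f_V to its feasible minimum, then maximises k_N;
        # any competing exact fit must not have smaller f_V
        assert res.fitted["f_V"] == pytest.approx(0.0, abs=5e-3)

    def test_missing_observed_intakes_rejected(self):
        bad = TrialRecord("e", "X", 0.0, 0.01, growth_rate_G=0.01)
        with pytest.raises(InvalidArgumentError):
            calibrate_feed(bad, estimate={"f_V"})

    def test_unknown_parameter_name_rejected(self):
        trial = trial_from_params(TRUTH)
        with pytest.raises(InvalidArgumentError):
            calibrate_feed(trial, estimate={"theta_Z"})


class TestCalibrateExperiment:
    def test_one_result_per_feed_on_packaged_experiment1(self, table1_by_exp):
        results = calibrate_experiment(table1_by_exp["1"])
        assert len(results) == 4
        assert [r.feed_label for r in results] == ["FM", "KM", "SBM", "SWM"]
        # measured digestibilities are honoured, never estimated
        assert all("beta_V" not in r.fitted for r in results)
        assert results[0].params.beta_V == 0.796

    def test_mixed_experiment_ids_rejected(self, table1):
        with pytest.raises(InvalidArgumentError):
            calibrate_experiment(table1)

    def test_empty_list_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert calibrate_experiment([]) == []

    def test_noiseless_experiment_fits_every_feed(self):
        rng = np.random.default_rng(11)
        trials = []
        for i in range(6):
            p = TRUTH.replace(f_V=float(rng.uniform(0, 0.2)),
                              k_N=float(rng.uniform(0.6, 1.0)))
            trials.append(trial_from_params(p, g=float(rng.uniform(0.005, 0.03)),
                                            label=f"S{i}"))
        results = calibrate_experiment(trials, fixed=TRUTH, estimate={"f_V", "k_N"})
        assert len(results) == 6
        assert all(r.objective_value < 1e-8 for r in results)


class TestGoodnessOfFit:
    @staticmethod
    def _result(label, pred_iv, pred_ih, obs_iv, obs_ih):
        return CalibrationResult(
            feed_label=label, experiment_id="e", fitted={},
            params=GSParameters(), predicted=IntakePair(pred_iv, pred_ih),
            observed=IntakePair(obs_iv, obs_ih), objective_value=0.0,
            residuals=(0.0, 0.0), converged=True, nonunique=False,
        )

    def test_perfect_predictions_give_unit_r2(self):
        results = [
            self._result(f"F{i}", v, v / 3, v, v / 3) for i, v in enumerate((1, 2, 3))
        ]
        r2_iv, r2_ih, table = goodness_of_fit(results)
        assert r2_iv == pytest.approx(1.0)
        assert r2_ih == pytest.approx(1.0)
        assert len(table) == 3

    def test_matches_hand_pearson_on_toy_pairs(self):
        obs = [1.0, 2.0, 3.0]
        pred = [2.0, 1.0, 0.5]
        results = [
            self._result(f"F{i}", p, p, o, o) for i, (p, o) in enumerate(zip(pred, obs))
        ]
        # hand Pearson via explicit sums, independent of the implementation
        n = 3
        sx, sy = sum(pred), sum(obs)
        sxx = sum(x * x for x in pred)
        syy = sum(y * y for y in obs)
        sxy = sum(x * y for x, y in zip(pred, obs))
        r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        r2_iv, r2_ih, _ = goodness_of_fit(results)
        assert r2_iv == pytest.approx(r * r, rel=1e-12)
        assert r2_ih == pytest.approx(r * r, rel=1e-12)

    def test_too_few_results_rejected(self):
        with pytest.raises(InvalidArgumentError):
            goodness_of_fit([self._result("A", 1, 1, 1, 1)])

    def test_zero_observed_variance_is_undefined(self):
        results = [self._result(f"F{i}", v, v, 1.0, 1.0) for i, v in enumerate((1, 2, 3))]
        with pytest.raises(UndefinedStatisticError):
            goodness_of_fit(results)
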
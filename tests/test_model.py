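"""Consumer-model core: reverse/forward budgets, conservation, monotonicity."""

from __future__ import annotations

import math

import numpy as np
import pytest

from geostoich import (
    GSParameters,
    IntakePair,
    forward_mode,
    n_budget,
    reverse_mode,
)
from geostoich.errors import (
    InfeasibleParametersError,
    InvalidArgumentError,
    InvalidParameterError,
)
from conftest import sample_feasible_parameters

COSTLESS = dict(sigma_SDA=0.0, xi_basal=0.0, r_B=0.0, beta_V=1.0, beta_H=1.0, k_N=1.0)


def c_gap(intake: IntakePair, led) -> float:
    """Relative carbon-conservation error of a ledger."""
    lhs = intake.total
    rhs = led.G + led.R + led.F_C
    return abs(lhs - rhs) / max(lhs, 1e-300)


def n_gap(intake: IntakePair, led, p: GSParameters) -> float:
    lhs = intake.I_V / p.theta_V
    rhs = led.G / p.theta_Z + led.U_N + led.F_N
    return abs(lhs - rhs) / max(lhs, 1e-300)


class TestReverseMode:
    def test_no_demand_gives_zero_everything(self):
        p = GSParameters(r_B=0.0, xi_basal=0.0, f_V=0.0)
        intake, led = reverse_mode(0.0, p)
        assert intake.I_V == intake.I_H == 0.0
        assert led.G == led.R == led.F_C == led.F_N == led.U_N == 0.0

    def test_costless_hand_solved_case(self):
        """theta_Z=5 split: protein carries theta_V/theta_Z of growth C."""
        p = GSParameters(theta_V=3.7, theta_Z=5.0, f_V=0.0, phi=0.0, **COSTLESS)
        intake, led = reverse_mode(0.01, p)
        assert intake.I_V == pytest.approx(0.0074, rel=1e-12)
        assert intake.I_H == pytest.approx(0.0026, rel=1e-12)
        assert led.R == pytest.approx(0.0, abs=1e-15)
        assert led.U_N == pytest.approx(0.0, abs=1e-15)
        assert led.F_C == led.F_N == 0.0

    def test_full_cost_structure_hand_solved_case(self):
        """Frozen from an independent 2x2 Cramer solve of the budget system."""
        p = GSParameters(
            theta_V=3.7, theta_Z=4.5, sigma_SDA=0.1, xi_basal=0.002, r_B=0.001,
            f_V=0.1, phi=0.5, k_N=0.8, beta_V=0.9, beta_H=0.8,
        )
        intake, _ = reverse_mode(0.01, p)
        assert intake.I_V == pytest.approx(0.013232, rel=1e-4)
        assert intake.I_H == pytest.approx(0.006967, rel=1e-4)

    def test_costless_closed_form_sweep(self):
        for theta_z in (3.7, 4.0, 5.0, 6.5):
            p = GSParameters(theta_V=3.7, theta_Z=theta_z, f_V=0.0, **COSTLESS)
            intake, _ = reverse_mode(0.02, p)
            assert intake.I_V == pytest.approx(3.7 * 0.02 / theta_z, rel=1e-12)
            assert intake.I_H == pytest.approx((1 - 3.7 / theta_z) * 0.02, abs=1e-14)

    def test_negative_growth_rejected(self):
        with pytest.raises(InvalidArgumentError):
            reverse_mode(-0.01, GSParameters())

    def test_singular_system_is_infeasible(self):
        # SDA so large that absorption can never cover the energetic drain
        p = GSParameters(sigma_SDA=0.95, beta_V=0.5, beta_H=0.5, f_V=0.5)
        with pytest.raises(InfeasibleParametersError):
            reverse_mode(0.01, p)

    def test_consumer_below_protein_cn_rejected(self):
        with pytest.raises(InvalidParameterError, match="theta_Z"):
            GSParameters(theta_V=3.7, theta_Z=3.0)


class TestForwardMode:
    def test_round_trip_is_balanced(self):
        p = GSParameters(
            theta_V=3.7, theta_Z=4.5, sigma_SDA=0.1, xi_basal=0.002, r_B=0.001,
            f_V=0.1, phi=0.5, k_N=0.8, beta_V=0.9, beta_H=0.8,
        )
        intake, _ = reverse_mode(0.01, p)
        led = forward_mode(intake, p)
        assert led.G == pytest.approx(0.01, rel=1e-10)
        assert led.limiting == "balanced"

    def test_excess_protein_is_excreted_not_grown(self):
        p = GSParameters(
            theta_V=3.7, theta_Z=4.5, sigma_SDA=0.1, xi_basal=0.002, r_B=0.001,
            f_V=0.1, phi=0.5, k_N=0.8, beta_V=0.9, beta_H=0.8,
        )
        intake, _ = reverse_mode(0.01, p)
        led0 = forward_mode(intake, p)
        led2 = forward_mode(IntakePair(2 * intake.I_V, intake.I_H), p)
        # growth pinned by the non-protein pathway (up to the small SDA rise)
        assert led2.limiting == "non-protein"
        assert led2.G <= led0.G + 1e-12
        assert led2.U_N > led0.U_N
        # all the extra N left via excretion or faeces (N conservation)
        extra_n = intake.I_V / p.theta_V
        assert (led2.U_N + led2.F_N + led2.G / p.theta_Z) - (
            led0.U_N + led0.F_N + led0.G / p.theta_Z
        ) == pytest.approx(extra_n, rel=1e-10)

    def test_starvation_flags_maintenance_deficit(self):
        led = forward_mode(IntakePair(0.0, 0.0), GSParameters(xi_basal=0.002))
        assert led.G == 0.0
        assert led.maintenance_deficit

    def test_equal_ratios_make_nonprotein_unconstrained(self):
        p = GSParameters(theta_V=3.7, theta_Z=3.7, f_V=0.0, **COSTLESS)
        led = forward_mode(IntakePair(0.01, 0.0), p)
        assert led.limiting == "protein"
        assert led.G == pytest.approx(0.01, rel=1e-12)


class TestConservationSweep:
    PARAMS = sample_feasible_parameters(1000, seed=20260924)

    def test_carbon_and_nitrogen_close_in_reverse_mode(self):
        for i, p in enumerate(self.PARAMS):
            g = 0.001 + 0.049 * (i / len(self.PARAMS))
            try:
                intake, led = reverse_mode(g, p)
            except InfeasibleParametersError:
                continue
            assert c_gap(intake, led) < 1e-10
            assert n_gap(intake, led, p) < 1e-10

    def test_forward_mode_closes_budgets_on_arbitrary_intakes(self):
        rng = np.random.default_rng(7)
        for p in self.PARAMS[:300]:
            intake = IntakePair(rng.uniform(0, 0.1), rng.uniform(0, 0.05))
            led = forward_mode(intake, p)
            assert c_gap(intake, led) < 1e-10
            if intake.I_V > 0:
                assert n_gap(intake, led, p) < 1e-10
            assert led.R >= 0 and led.U_N >= 0 and led.F_C >= 0 and led.F_N >= 0

    def test_forward_of_reverse_recovers_growth(self):
        for i, p in enumerate(self.PARAMS):
            g = 0.05 * (i + 1) / len(self.PARAMS)
            try:
                intake, _ = reverse_mode(g, p)
            except InfeasibleParametersError:
                continue
            led = forward_mode(intake, p)
            assert led.G == pytest.approx(g, rel=1e-8, abs=1e-12)


class TestStructuralProperties:
    BASE = GSParameters(
        theta_V=3.7, theta_Z=4.5, sigma_SDA=0.12, xi_basal=0.003, r_B=0.002,
        f_V=0.2, phi=0.4, k_N=0.8, beta_V=0.85, beta_H=0.75,
    )

    def test_protein_intake_monotone_in_penalty_when_protein_fuels(self):
        ivs = [
            reverse_mode(0.01, self.BASE.replace(phi=phi))[0].I_V
            for phi in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(b >= a for a, b in zip(ivs, ivs[1:]))

    def test_protein_intake_monotone_decreasing_in_synthesis_efficiency(self):
        ivs = [
            reverse_mode(0.01, self.BASE.replace(k_N=k))[0].I_V
            for k in (0.4, 0.6, 0.8, 1.0)
        ]
        assert all(b <= a for a, b in zip(ivs, ivs[1:]))

    def test_protein_intake_monotone_in_growth(self):
        ivs = [reverse_mode(g, self.BASE)[0].I_V for g in (0.0, 0.01, 0.02, 0.04)]
        assert all(b >= a for a, b in zip(ivs, ivs[1:]))

    def test_total_intake_monotone_in_basal_cost(self):
        totals = [
            reverse_mode(0.01, self.BASE.replace(xi_basal=xi))[0].total
            for xi in (0.0, 0.002, 0.005, 0.01)
        ]
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_penalty_inert_without_protein_fuelling(self):
        """phi must not touch any output when f_V = 0."""
        for phi in (0.0, 0.5, 1.0):
            p = self.BASE.replace(f_V=0.0, phi=phi)
            intake, led = reverse_mode(0.01, p)
            ref_intake, ref_led = reverse_mode(0.01, self.BASE.replace(f_V=0.0, phi=0.0))
            assert intake == ref_intake
            assert led == ref_led

    def test_sda_on_absorbed_base_still_round_trips(self):
        p = self.BASE.replace(sda_base="absorbed")
        intake, _ = reverse_mode(0.015, p)
        led = forward_mode(intake, p)
        assert led.G == pytest.approx(0.015, rel=1e-10)
        assert c_gap(intake, led) < 1e-10


class TestNBudget:
    P = GSParameters(
        theta_V=3.7, theta_Z=4.5, sigma_SDA=0.1, xi_basal=0.002, r_B=0.001,
        f_V=0.15, phi=0.3, k_N=0.8, beta_V=0.9, beta_H=0.8,
    )

    def test_absorbed_equals_retained_plus_excreted_plus_overhead(self):
        intake, led = reverse_mode(0.01, self.P)
        absorbed, retained, f_n, u_n = n_budget(intake, led, self.P)
        assert absorbed == pytest.approx(self.P.beta_V * intake.I_V / self.P.theta_V)
        assert retained == pytest.approx(led.G / self.P.theta_Z)
        assert absorbed == pytest.approx(retained + u_n, rel=1e-10)
        assert intake.I_V / self.P.theta_V == pytest.approx(
            retained + u_n + f_n, rel=1e-10
        )

    def test_protein_fuelling_forces_excretion(self):
        intake, led = reverse_mode(0.01, self.P)
        assert led.U_N > 0

    def test_perfect_absorption_means_no_faecal_n(self):
        p = self.P.replace(beta_V=1.0)
        intake, led = reverse_mode(0.01, p)
        assert led.F_N == 0.0
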
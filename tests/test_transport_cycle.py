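"""Five-state cycle: rate scaling, generator assembly, steady states, fluxes."""
import math
from dataclasses import replace

import numpy as np
import pytest

from vsglt.transport_cycle import (
    FARADAY, FORWARD_TRANSITIONS, GAS_CONSTANT, TRANSITIONS, Conditions,
    DegenerateGeneratorError, NonStationaryError, StateDistribution,
    TransportParameters, build_generator, cycle_flux, edge_fluxes,
    inward_fraction, mixed_steady_state, scale_rate, steady_state,
    uptake_time_course, validate_cycle_charges, voltage_sweep,
)

from conftest import random_cycle_params


def uniform_params(value: float = 1.0) -> TransportParameters:
    rates = {t: value for t in TRANSITIONS}
    eps = {t: 0.0 for t in FORWARD_TRANSITIONS}
    eps["34"] = 1.0
    return TransportParameters.from_net_charges(rates, {}, eps)


SYMMETRIC_COND = Conditions(voltage_V=0.0, na_out=1.0, na_in=1.0, gal_out=1.0, gal_in=1.0)


class TestScaleRate:
    def test_zero_charge_is_voltage_independent(self):
        assert scale_rate(100.0, 0.0, -0.06, 298.15) == 100.0

    def test_unit_charge_at_thermal_voltage(self):
        # V = -RT/F makes the exponent exactly +1 for q_eff = +1
        v_thermal = -GAS_CONSTANT * 298.15 / FARADAY
        assert scale_rate(1.0, 1.0, v_thermal, 298.15) == pytest.approx(math.e, rel=1e-12)

    @pytest.mark.parametrize("q,v", [(0.5, -0.1), (-0.7, 0.05), (1.0, 0.2)])
    def test_flipped_equals_normal_at_opposite_voltage(self, q, v):
        assert scale_rate(3.0, q, v, 298.15, "flipped") == pytest.approx(
            scale_rate(3.0, q, -v, 298.15, "normal"), rel=1e-14
        )

    def test_overflow_reports_transition(self):
        with pytest.raises(OverflowError, match="34"):
            scale_rate(1.0, 5.0, -5.0, 298.15, transition="34")

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            scale_rate(float("nan"), 0.0, 0.0, 298.15)


class TestBuildGenerator:
    def test_all_rates_zero_gives_zero_matrix(self):
        params = uniform_params(0.0)
        Q = build_generator(params, SYMMETRIC_COND)
        assert np.all(Q == 0.0)

    def test_single_transition_with_concentration_factor(self):
        rates = {t: 0.0 for t in TRANSITIONS}
        rates["12"] = 1.0
        eps = {t: 0.0 for t in FORWARD_TRANSITIONS}
        eps["34"] = 1.0
        params = TransportParameters.from_net_charges(rates, {}, eps)
        cond = Conditions(voltage_V=0.0, na_out=0.073)
        Q = build_generator(params, cond)
        expect = 1.0 * 0.073
        assert Q[1, 0] == pytest.approx(expect)
        assert Q[0, 0] == pytest.approx(-expect)
        assert np.count_nonzero(Q) == 2

    def test_matches_literal_rate_equations(self, rng):
        """Generator entries agree with a term-by-term transcription of the
        master equations (dC1..dC5/dt) evaluated on a random state vector."""
        params = random_cycle_params(rng)
        cond = Conditions(voltage_V=-0.05, na_out=0.08, na_in=0.02,
                          gal_out=1e-3, gal_in=5e-4)
        rt = GAS_CONSTANT * params.temperature_K

        def k(label):  # literal: k0 * exp(-(eta+eps) F V / RT)
            q = params.eta[label] + params.epsilon[label]
            return params.base_rates[label] * math.exp(-q * FARADAY * cond.voltage_V / rt)

        C = rng.dirichlet(np.ones(5))
        na_o, na_i, g_o, g_i = cond.na_out, cond.na_in, cond.gal_out, cond.gal_in
        dC = np.array([
            -(k("15") + k("12") * na_o) * C[0] + k("21") * C[1] + k("51") * C[4],
            k("12") * na_o * C[0] - (k("21") + k("23") * g_o) * C[1] + k("32") * C[2],
            k("23") * g_o * C[1] - (k("32") + k("34")) * C[2] + k("43") * C[3],
            k("34") * C[2] - (k("43") + k("45")) * C[3] + k("54") * g_i * na_i * C[4],
            k("15") * C[0] + k("45") * C[3] - (k("54") * g_i * na_i + k("51")) * C[4],
        ])
        Q = build_generator(params, cond)
        np.testing.assert_allclose(Q @ C, dC, rtol=1e-12, atol=1e-15)

    def test_columns_sum_to_zero(self, rng):
        params = random_cycle_params(rng)
        Q = build_generator(params, Conditions(voltage_V=-0.1))
        np.testing.assert_allclose(Q.sum(axis=0), 0.0, atol=1e-12 * np.abs(Q).max())

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            Conditions(na_out=-1.0)


class TestSteadyState:
    def test_symmetric_toy_is_uniform(self):
        Q = build_generator(uniform_params(), SYMMETRIC_COND)
        ss = steady_state(Q, method="both")
        np.testing.assert_allclose(ss.occupancies, 0.2, atol=1e-9)

    def test_equilibrium_has_zero_flux_on_every_edge(self):
        params = uniform_params(2.5)
        ss = steady_state(build_generator(params, SYMMETRIC_COND), method="nullspace")
        fluxes = edge_fluxes(params, SYMMETRIC_COND, ss)
        np.testing.assert_allclose(fluxes, 0.0, atol=1e-12)

    def test_dual_solver_agreement_on_random_generators(self):
        """Null-space and long-time ODE integration must agree elementwise
        to 1e-8 across 100 random irreducible parameter sets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            params = random_cycle_params(rng)
            cond = Conditions(voltage_V=float(rng.uniform(-0.15, 0.15)),
                              na_out=0.05, na_in=0.01, gal_out=1e-3, gal_in=1e-4)
            Q = build_generator(params, cond)
            ss = steady_state(Q, method="both", cross_check_tol=1e-8)
            assert abs(ss.occupancies.sum() - 1.0) < 1e-9

    def test_reducible_generator_reported(self):
        Q = np.zeros((5, 5))
        with pytest.raises(DegenerateGeneratorError):
            steady_state(Q)

    def test_rejects_bad_columns(self):
        Q = np.eye(5)
        with pytest.raises(ValueError, match="columns"):
            steady_state(Q)


class TestCycleFlux:
    def test_equilibrium_flux_is_zero(self):
        params = uniform_params(1.0)
        ss = steady_state(build_generator(params, SYMMETRIC_COND))
        assert cycle_flux(params, SYMMETRIC_COND, ss) == pytest.approx(0.0, abs=1e-12)

    def test_edge_fluxes_equal_at_steady_state(self, rng):
        params = random_cycle_params(rng)
        cond = Conditions(voltage_V=-0.08, na_out=0.06, na_in=0.005,
                          gal_out=2e-3, gal_in=1e-4)
        ss = steady_state(build_generator(params, cond))
        fluxes = edge_fluxes(params, cond, ss)
        assert fluxes.max() - fluxes.min() <= 1e-9 * max(1.0, np.abs(fluxes).max())

    def test_irreversible_uniform_cycle_has_flux_one_fifth(self):
        """All forward rates 1/s, reverse rates 0, unit concentrations: the
        uniform cyclic chain turns over at 1/5 cycles/s (closed form)."""
        rates = {t: 0.0 for t in TRANSITIONS}
        for t in FORWARD_TRANSITIONS:
            rates[t] = 1.0
        eps = {t: 0.0 for t in FORWARD_TRANSITIONS}
        eps["34"] = 1.0
        params = TransportParameters.from_net_charges(rates, {}, eps)
        ss = steady_state(build_generator(params, SYMMETRIC_COND))
        assert cycle_flux(params, SYMMETRIC_COND, ss) == pytest.approx(0.2, rel=1e-9)

    def test_non_stationary_distribution_rejected(self):
        params = uniform_params(1.0)
        skew = StateDistribution(np.array([0.5, 0.3, 0.1, 0.05, 0.05]))
        cond = Conditions(voltage_V=0.0, na_out=1.0, na_in=0.0, gal_out=1.0, gal_in=0.0)
        with pytest.raises(NonStationaryError):
            cycle_flux(params, cond, skew)


class TestPopulations:
    def test_inward_fraction_of_uniform_distribution(self):
        ss = StateDistribution(np.full(5, 0.2))
        assert inward_fraction(ss) == pytest.approx(0.4)

    def test_orientation_symmetry(self, rng):
        """Flipped steady state at V equals the normal steady state at -V
        once the compartments are also exchanged; with symmetric
        concentrations the statement holds verbatim."""
        for _ in range(20):
            params = random_cycle_params(rng)
            v = float(rng.uniform(-0.15, 0.15))
            cond = Conditions(voltage_V=v, na_out=0.05, na_in=0.01,
                              gal_out=1e-3, gal_in=2e-4)
            flipped = steady_state(build_generator(params, cond, "flipped"), "flipped")
            mirror = replace(cond.swapped(), voltage_V=-v)
            normal = steady_state(build_generator(params, mirror, "normal"), "normal")
            np.testing.assert_allclose(flipped.occupancies, normal.occupancies, atol=1e-10)
            sym = replace(SYMMETRIC_COND, voltage_V=v)
            f2 = steady_state(build_generator(params, sym, "flipped"), "flipped")
            n2 = steady_state(build_generator(params, replace(sym, voltage_V=-v), "normal"))
            np.testing.assert_allclose(f2.occupancies, n2.occupancies, atol=1e-10)

    def test_mixed_with_no_flipped_equals_normal(self, ref_params, assay_conditions):
        cond = replace(assay_conditions, voltage_V=-0.06)
        ms = mixed_steady_state(ref_params, cond, flipped_fraction=0.0)
        assert ms.turnover == pytest.approx(ms.flux_normal)
        assert ms.inward_fraction == pytest.approx(inward_fraction(ms.normal))

    def test_mixed_at_zero_volts_symmetric_concentrations(self, ref_params):
        """At V=0 with symmetric substrate the two orientations coincide."""
        ms = mixed_steady_state(ref_params, SYMMETRIC_COND)
        np.testing.assert_allclose(ms.normal.occupancies, ms.flipped.occupancies,
                                   atol=1e-10)


class TestVoltageSweep:
    def test_no_charges_means_no_voltage_dependence(self, assay_conditions):
        rates = {t: 1.0 for t in TRANSITIONS}
        params = TransportParameters(
            base_rates=rates, eta={t: 0.0 for t in TRANSITIONS},
            epsilon={t: 0.0 for t in TRANSITIONS}, q_gc_total=0.0,
        )
        res = voltage_sweep(params, assay_conditions, np.linspace(-0.2, 0.1, 7))[0.0]
        assert np.ptp(res.turnover_mixed) < 1e-12
        assert np.ptp(res.inward_fraction_mixed) < 1e-12

    def test_mixed_turnover_monotone_under_reference_charge(self, ref_params, assay_conditions):
        volts = np.arange(-0.200, 0.0001, 0.005)
        res = voltage_sweep(ref_params, assay_conditions, volts)[-0.7]
        diffs = np.diff(res.turnover_mixed)
        assert np.all(diffs <= 1e-10 * np.abs(res.turnover_mixed).max())

    def test_normalized_sweep_anchors_at_unity(self, ref_params, assay_conditions):
        volts = np.array([-0.06, 0.0])
        res = voltage_sweep(ref_params, assay_conditions, volts, normalize=True)[-0.7]
        assert res.turnover_mixed[1] == pytest.approx(1.0)

    def test_empty_grid_rejected(self, ref_params, assay_conditions):
        with pytest.raises(ValueError):
            voltage_sweep(ref_params, assay_conditions, [])


class TestUptakeTimeCourse:
    def test_zero_rates_give_zero_trace(self, assay_conditions):
        params = uniform_params(0.0)
        tc = uptake_time_course(params, assay_conditions, duration_s=10.0, n_points=11)
        np.testing.assert_allclose(tc.galactose_molecules, 0.0, atol=1e-12)

    def test_initial_slope_matches_steady_flux(self, ref_params, assay_conditions):
        """With no leak and an empty lumen the early trace is linear with
        slope equal to the steady-state mixed uptake rate (within 2%)."""
        cond = replace(assay_conditions, voltage_V=-0.06)
        ms = mixed_steady_state(ref_params, cond)
        tc = uptake_time_course(ref_params, cond, lumen_volume_L=5e-19,
                                duration_s=2.0, leak_per_s=0.0, n_points=21)
        slope = tc.galactose_molecules[1] / tc.times_s[1]
        assert slope == pytest.approx(ms.turnover, rel=0.02)

    def test_leak_gives_rise_peak_decline(self, ref_params, assay_conditions):
        # once the Na+ gradient leaks away, the accumulated galactose
        # gradient drives net efflux: the trace must peak exactly once
        tc = uptake_time_course(ref_params, assay_conditions, lumen_volume_L=5e-19,
                                duration_s=1800.0, leak_per_s=1 / 200.0, n_points=181)
        assert np.all(tc.galactose_molecules >= -1e-9)
        sign = np.sign(np.diff(tc.galactose_molecules))
        changes = np.count_nonzero(np.diff(sign[sign != 0]))
        peak = np.argmax(tc.galactose_molecules)
        assert 0 < peak < len(tc.times_s) - 1  # interior peak
        assert changes == 1  # exactly one rise->fall transition

    def test_bad_volume_rejected(self, ref_params, assay_conditions):
        with pytest.raises(ValueError):
            uptake_time_course(ref_params, assay_conditions, lumen_volume_L=0.0)


class TestCycleChargeValidation:
    def test_reference_set_passes(self, ref_params):
        report = validate_cycle_charges(ref_params)
        assert report.ok
        assert report.eta_cycle_sum == pytest.approx(0.0, abs=1e-9)
        assert report.epsilon_cycle_sum == pytest.approx(1.0, abs=1e-9)

    def test_perturbed_eta_flagged_with_magnitude(self, ref_params):
        eta = dict(ref_params.eta)
        eta["34"] += 0.1
        bad = TransportParameters(base_rates=ref_params.base_rates, eta=eta,
                                  epsilon=ref_params.epsilon)
        report = validate_cycle_charges(bad)
        assert not report.ok
        assert "0.1" in report.warnings[0]

    def test_all_charge_on_inner_gate_passes(self):
        rates = {t: 1.0 for t in TRANSITIONS}
        eta_net = {"34": -0.7, "51": 0.7}
        eps_net = {"45": 1.0}
        params = TransportParameters.from_net_charges(rates, eta_net, eps_net)
        report = validate_cycle_charges(params)
        assert report.ok
        assert report.net_eta["34"] == pytest.approx(-0.7)

    def test_probability_conserved_along_integration(self, rng):
        """The ODE steady-state path conserves total probability."""
        params = random_cycle_params(rng)
        cond = Conditions(voltage_V=-0.05, na_out=0.05, na_in=0.01,
                          gal_out=1e-3, gal_in=1e-4)
        ss = steady_state(build_generator(params, cond), method="ode")
        assert ss.occupancies.sum() == pytest.approx(1.0, abs=1e-9)
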
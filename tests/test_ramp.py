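import numpy as np
import pytest

from thkin.network import (
    RateParams,
    SpeciesState,
    build_model,
    net_step_fluxes,
    strand_total,
)
from thkin.ramp import (
    CELSIUS_OFFSET,
    ExtinctionModel,
    HoldSegment,
    RampSegment,
    TemperatureProgram,
    absorbance,
    equilibrium_state,
    equilibrium_trace,
    hysteresis_width,
    isothermal_course,
    melting_peak_temperatures,
    midpoint_temperature,
    simulate_program,
)

STRAND_WEIGHTS = {"model1": np.array([1, 2, 3, 4.0]), "model2": np.array([1, 2, 2, 3, 4.0])}


def conservation_error(trace, model_name="model2"):
    tot = trace.species @ STRAND_WEIGHTS[model_name]
    return np.abs(tot / tot[0] - 1.0).max()


class TestProgramValidation:
    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            RampSegment(5, 85, 0.0)

    def test_nonpositive_hold_rejected(self):
        with pytest.raises(ValueError):
            HoldSegment(25.0, 0.0)

    def test_insane_temperature_rejected(self):
        with pytest.raises(ValueError):
            RampSegment(5, 150, 1.0)

    def test_empty_program_rejected(self):
        with pytest.raises(ValueError):
            TemperatureProgram(())


class TestExtinctionModel:
    def test_midpoint_dialect_dimer_coefficient(self):
        # per-strand dimer coefficient is half-way between monomer and tetramer
        ext = ExtinctionModel(1.0, 0.0, 0.5, 0.0, "midpoint", 1.0)
        eps = dict(zip("M D Dstar Tri T".split(), ext.per_strand(["M", "D", "Dstar", "Tri", "T"], 25.0)))
        assert eps["D"] == pytest.approx(0.75)
        assert eps["Dstar"] == pytest.approx(0.75)
        assert eps["Tri"] == pytest.approx((1.0 + 3 * 0.5) / 4)

    def test_tetramer_fraction_dialect(self):
        # per-complex 1/2 and 3/4 of the tetramer complex -> per-strand eps_T4
        ext = ExtinctionModel(1.0, 0.0, 0.5, 0.0, "tetramer_fraction", 1.0)
        eps = ext.per_strand(["D", "Tri", "T"], 25.0)
        np.testing.assert_allclose(eps, 0.5)

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError):
            ExtinctionModel(1.0, 0.0, 0.5, 0.0, "halfway", 1.0)

    def test_unset_dialect_warns_and_defaults(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="thkin.ramp"):
            ext = ExtinctionModel(1.0, 0.0, 0.5, 0.0, None, 1.0)
        assert ext.dialect == "midpoint"
        assert any("dialect" in r.message for r in caplog.records)

    def test_hypochromicity_validation(self):
        ext = ExtinctionModel(1.0, 0.0, 2.0, 0.0, "midpoint", 1.0)
        with pytest.raises(ValueError):
            ext.validate_range(5.0, 85.0)

    def test_folding_decreases_absorbance(self, ext):
        unfolded = absorbance(np.array([50e-6, 0, 0, 0, 0.0]), 25.0, ext,
                              ["M", "D", "Dstar", "Tri", "T"])
        folded = absorbance(np.array([0, 0, 0, 0, 12.5e-6]), 25.0, ext,
                            ["M", "D", "Dstar", "Tri", "T"])
        assert folded < unfolded

    def test_pure_monomer_baseline(self, ext):
        A = absorbance(SpeciesState({"M": 50e-6}), 30.0, ext)
        expected = ext.path_length_cm * float(ext.eps_monomer(30.0)) * 50e-6
        assert A == pytest.approx(expected, rel=1e-14)


class TestSimulateProgram:
    def test_frozen_kinetics_keeps_monomer_baseline(self, ext):
        model = build_model("model2")  # all rates zero
        trace = simulate_program(
            model, TemperatureProgram.ramp(85, 5, 5.0), 50e-6, ext, "all_monomer"
        )
        assert np.all(trace.species[:, 1:] == 0.0)
        np.testing.assert_allclose(trace.species[:, 0], 50e-6, rtol=1e-12)
        expected = ext.path_length_cm * ext.eps_monomer(trace.temperature_C) * 50e-6
        np.testing.assert_allclose(trace.absorbance_AU, expected, rtol=1e-10)

    def test_irreversible_dimerization_closed_form(self, ext):
        # dM/dt = -2k[M]^2  =>  [M](t) = M0 / (1 + 2 k M0 t)
        k = 1.0e3
        model = build_model("model1", {"dimerization": RateParams(k, 0.0, 0.0, 0.0)})
        m0 = 100e-6
        trace = isothermal_course(model, 25.0, m0, "all_monomer", 10.0, ext, n_points=100)
        expected = m0 / (1.0 + 2.0 * k * m0 * trace.time)
        np.testing.assert_allclose(trace.species[:, 0], expected, rtol=1e-6)
        assert trace.species[-1, 0] == pytest.approx(33.33e-6, rel=1e-3)

    def test_strand_mass_conserved_along_ramps(self, truth2, ext):
        model = truth2.to_model()
        for c_tot in (50e-6, 250e-6):
            for rate in (0.5, 5.0):
                tr = simulate_program(
                    model, TemperatureProgram.ramp(85, 5, rate), c_tot, ext, "equilibrium"
                )
                assert conservation_error(tr) < 1e-6

    def test_inconsistent_init_rejected(self, truth2, ext):
        model = truth2.to_model()
        bad = np.array([40e-6, 0, 0, 0, 0.0])  # 40 uM strands, C_tot says 50
        with pytest.raises(ValueError):
            simulate_program(model, TemperatureProgram.ramp(85, 5, 5.0), 50e-6, ext, bad)

    def test_integrator_tolerance_independence(self, truth2, ext):
        model = truth2.to_model()
        prog = TemperatureProgram.ramp(85, 5, 5.0)
        a = simulate_program(model, prog, 50e-6, ext, "equilibrium", rtol=1e-8)
        b = simulate_program(model, prog, 50e-6, ext, "equilibrium", rtol=5e-9,
                             atol=2.5e-15)
        assert np.abs(a.absorbance_AU - b.absorbance_AU).max() < 1e-5

    def test_multi_segment_program(self, truth2, ext):
        model = truth2.to_model()
        prog = TemperatureProgram(
            (RampSegment(85, 5, 5.0), HoldSegment(5.0, 600.0), RampSegment(5, 85, 5.0))
        )
        tr = simulate_program(model, prog, 50e-6, ext, "equilibrium")
        assert tr.temperature_C[0] == pytest.approx(85.0)
        assert tr.temperature_C[-1] == pytest.approx(85.0)
        assert np.all(np.diff(tr.time) > 0)
        assert conservation_error(tr) < 1e-6


class TestEquilibrium:
    def test_no_association_gives_all_monomer(self):
        model = build_model("model1")
        state = equilibrium_state(model, 298.15, 100e-6)
        assert state.get("M") == pytest.approx(100e-6)
        assert state.get("D") == 0.0

    def test_dimer_quadratic_closed_form(self):
        # 2M <=> D with K = kf/kr; [M] = (-1 + sqrt(1 + 8 K C)) / (4 K)
        K = 1.0e4
        model = build_model("model1", {"dimerization": RateParams(K, 0.0, 1.0, 0.0)})
        c = 100e-6
        state = equilibrium_state(model, 298.15, c)
        m_expected = (-1.0 + np.sqrt(1.0 + 8.0 * K * c)) / (4.0 * K)
        assert state.get("M") == pytest.approx(m_expected, rel=1e-10)
        assert state.get("M") == pytest.approx(50e-6, rel=1e-10)
        assert state.get("D") == pytest.approx(25e-6, rel=1e-10)
        assert strand_total(state) == pytest.approx(c, rel=1e-10)

    def test_trap_ratio_independent_of_concentration(self, truth2):
        model = truth2.to_model()
        K_trap = truth2.steps["trap"].equilibrium_constant(288.15)
        for c in (50e-6, 250e-6, 1e-3):
            st = equilibrium_state(model, 288.15, c)
            assert st.get("Dstar") / st.get("D") == pytest.approx(K_trap, rel=1e-9)

    def test_irreversible_step_rejected(self):
        model = build_model("model1", {"dimerization": RateParams(1e3, 0.0, 0.0, 0.0)})
        with pytest.raises(ValueError):
            equilibrium_state(model, 298.15, 50e-6)

    def test_detailed_balance_at_equilibrium(self, truth2):
        model = truth2.to_model()
        for T_K in (280.15, 310.15, 340.15):
            st = equilibrium_state(model, T_K, 50e-6)
            net = np.abs(net_step_fluxes(model, st, T_K))
            gross = np.array(
                [
                    max(p.k_f_ref, p.k_r_ref) * 1e-4
                    for p in (s.params for s in model.steps)
                ]
            )
            assert np.all(net <= 1e-10 * np.maximum(gross, 1e-30))

    def test_nonpositive_concentration_rejected(self, truth2):
        with pytest.raises(ValueError):
            equilibrium_state(truth2.to_model(), 298.15, 0.0)


class TestHysteresis:
    def test_self_width_is_zero(self, ramp_pair_50uM):
        _, heat = ramp_pair_50uM
        assert hysteresis_width(heat, heat) == 0.0

    def test_width_increases_with_scan_rate(self, truth2, ext):
        model = truth2.to_model()
        widths = {}
        for rate in (0.5, 5.0):
            cool = simulate_program(
                model, TemperatureProgram.ramp(85, 5, rate), 50e-6, ext, "equilibrium"
            )
            heat = simulate_program(
                model, TemperatureProgram.ramp(5, 85, rate), 50e-6, ext, cool.species[-1]
            )
            widths[rate] = hysteresis_width(heat, cool)
        assert widths[5.0] > widths[0.5] > 0.0

    def test_equilibrium_limit_convergence(self, truth2, ext):
        # slower ramps approach the thermodynamic curve monotonically
        model = truth2.to_model()
        temps = np.arange(5.0, 85.25, 0.25)
        eq = equilibrium_trace(model, temps, 50e-6, ext)
        devs = []
        for rate in (5.0, 0.5, 0.05):
            cool = simulate_program(
                model, TemperatureProgram.ramp(85, 5, rate), 50e-6, ext, "equilibrium"
            )
            devs.append(np.abs(cool.absorbance_AU - eq.absorbance_AU[::-1]).max())
        assert devs[0] > devs[1] > devs[2]

    def test_nonoverlapping_spans_rejected(self, truth2, ext):
        model = truth2.to_model()
        a = simulate_program(model, TemperatureProgram.ramp(5, 30, 5.0), 50e-6, ext, "equilibrium")
        b = simulate_program(model, TemperatureProgram.ramp(60, 85, 5.0), 50e-6, ext, "equilibrium")
        with pytest.raises(ValueError):
            hysteresis_width(a, b)

    def test_biphasic_heating_trace(self, ramp_pair_50uM):
        _, heat = ramp_pair_50uM
        peaks = melting_peak_temperatures(heat)
        assert len(peaks) == 2
        assert peaks[1] - peaks[0] > 10.0

    def test_midpoint_of_equilibrium_curve_is_between_ramps(self, truth2, ext, ramp_pair_50uM):
        cool, heat = ramp_pair_50uM
        model = truth2.to_model()
        eq = equilibrium_trace(model, np.arange(5.0, 85.25, 0.25), 50e-6, ext)
        t_eq = midpoint_temperature(eq)
        assert midpoint_temperature(cool) < t_eq < midpoint_temperature(heat)


class TestIsothermal:
    def test_zero_rates_constant_fractions(self, ext):
        model = build_model("model2")
        tr = isothermal_course(model, 4.0, 50e-6, "all_monomer", 3600.0, ext)
        fr = tr.strand_fractions()
        np.testing.assert_allclose(fr["M"], 1.0, rtol=1e-12)

    def test_transient_dimer_maximum_with_slow_trimerization(self, ext):
        # fast M+M<=>D, slow D+M->Tri: dimer peaks before tetramer accumulates
        steps = {
            "dimerization": RateParams(1e3, 0.0, 1e-3, 0.0),
            "trimerization": RateParams(5.0, 0.0, 1e-5, 0.0),
            "tetramerization": RateParams(1e3, 0.0, 1e-6, 0.0),
        }
        model = build_model("model1", steps)
        tr = isothermal_course(model, 25.0, 50e-6, "all_monomer", 48 * 3600.0, ext)
        fr = tr.strand_fractions()
        i_dmax = int(np.argmax(fr["D"]))
        assert fr["D"][i_dmax] > 0.5
        assert fr["T"][i_dmax] < 0.5
        assert fr["T"][-1] > fr["D"][-1]

    def test_trap_dominates_over_chosen_horizon(self, truth2, ext):
        tr = isothermal_course(truth2.to_model(), 4.0, 50e-6, "all_monomer", 24 * 3600.0, ext)
        fr = tr.strand_fractions()
        assert fr["Dstar"][-1] > fr["T"][-1]

    def test_nonpositive_duration_rejected(self, truth2, ext):
        with pytest.raises(ValueError):
            isothermal_course(truth2.to_model(), 4.0, 50e-6, "all_monomer", 0.0, ext)
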
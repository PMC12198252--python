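import numpy as np
import pandas as pd
import pytest

from pahemo import (
    FlowWaveform,
    FluidProperties,
    WindkesselRCR,
    energy_dissipation,
    flow_decomposition,
    load_reference_indices,
    reynolds_number,
    round_half_up,
    solve_network,
    summarize_indices,
    vorticity_index,
    womersley_number,
    womersley_profile,
)
from pahemo.geometry import VesselSegment
from pahemo.indices import curl_magnitude_profile
from pahemo.network import segment_resistance
from pahemo.profiles import VelocityField


class TestReynoldsNumber:
    def test_formula_and_linearity(self, fluid):
        re1 = reynolds_number(fluid, 19.9, 2.4)
        assert re1 == pytest.approx(1.06 * 19.9 * 2.4 / 0.04, rel=1e-12)
        assert re1 == pytest.approx(1265.6, abs=0.1)
        assert reynolds_number(fluid, 2 * 19.9, 2.4) == pytest.approx(2 * re1, rel=1e-12)
        assert reynolds_number(fluid, 0.0, 2.4) == 0.0

    def test_unit_system_invariance(self):
        cgs = reynolds_number(FluidProperties(1.06, 0.04), 19.9, 2.4)
        si = reynolds_number(FluidProperties(1060.0, 0.004), 0.199, 0.024)
        assert si == pytest.approx(cgs, rel=1e-12)

    def test_nonpositive_diameter_rejected(self, fluid):
        with pytest.raises(ValueError):
            reynolds_number(fluid, 10.0, 0.0)


class TestWomersleyNumber:
    def test_direct_evaluation(self, fluid):
        wo = womersley_number(1.0, fluid, 1.0)
        assert wo == pytest.approx(np.sqrt(2 * np.pi / fluid.kinematic_viscosity), rel=1e-12)
        assert wo == pytest.approx(12.91, abs=0.01)

    def test_linearity_in_radius_and_healthy_range(self, fluid):
        assert womersley_number(2.0, fluid, 1.0) == pytest.approx(
            2 * womersley_number(1.0, fluid, 1.0), rel=1e-12
        )
        wo = womersley_number(1.3, fluid, 0.9)
        assert wo == pytest.approx(17.7, abs=0.05)
        assert 14.0 < wo < 21.0

    def test_unit_system_invariance(self):
        cgs = womersley_number(1.3, FluidProperties(1.06, 0.04), 0.9)
        si = womersley_number(0.013, FluidProperties(1060.0, 0.004), 0.9)
        assert si == pytest.approx(cgs, rel=1e-12)


class TestVorticityIndex:
    def test_plug_flow_has_zero_vorticity(self):
        s = np.linspace(0.0, 1.0, 65)
        field = VelocityField("S", 1.0, s, np.zeros(1), np.full((65, 1), 7.0), 1.0)
        assert vorticity_index(field) == pytest.approx(0.0, abs=1e-12)

    def test_poiseuille_closed_form(self, fluid):
        wf = FlowWaveform(1.0, np.full(64, 10.0))
        seg = VesselSegment("S", None, 1.0, 1.0)
        field = womersley_profile(seg, wf, fluid)
        v_bar = 10.0 / seg.area
        assert vorticity_index(field) == pytest.approx(8.0 * v_bar / 3.0, rel=0.005)

    def test_poiseuille_closed_form_at_higher_resolution(self, fluid):
        wf = FlowWaveform(1.0, np.full(64, 10.0))
        seg = VesselSegment("S", None, 0.8, 1.0)
        field = womersley_profile(seg, wf, fluid, n_radial=129)
        v_bar = 10.0 / seg.area
        assert vorticity_index(field) == pytest.approx(8.0 * v_bar / (3.0 * 0.8), rel=0.005)

    def test_rigid_body_rotation_curl_identity(self):
        s = np.linspace(0.0, 1.0, 65)
        omega_rate = 3.0
        curl = curl_magnitude_profile(omega_rate * s, s, component="azimuthal")
        np.testing.assert_allclose(curl, 2.0 * omega_rate, rtol=1e-9)

    def test_site_segment_mismatch_rejected(self, fluid):
        from pahemo.geometry import MeasurementSite

        s = np.linspace(0.0, 1.0, 65)
        field = VelocityField("S", 1.0, s, np.zeros(1), np.zeros((65, 1)), 1.0)
        site = MeasurementSite("RPA", "other", 0.1, 1.0, np.pi)
        with pytest.raises(ValueError):
            vorticity_index(field, site)


class TestEnergyDissipation:
    def test_zero_flow_dissipates_nothing(self, fluid, minimal_tree):
        wf = FlowWaveform(1.0, np.zeros(64))
        rcr = WindkesselRCR(10.0, 0.01, 90.0)
        sol = solve_network(minimal_tree, {"RPA": rcr, "LPA": rcr}, wf, fluid)
        assert energy_dissipation(sol, minimal_tree, fluid) == pytest.approx(0.0, abs=1e-12)

    def test_steady_tube_matches_hagen_poiseuille_balance(self, fluid, minimal_tree, constant_inflow):
        """With outlet areas summing to the inlet area, kinetic fluxes cancel
        and ED equals the circuit's viscous loss sum(R_seg Q_seg^2)."""
        rcr = WindkesselRCR(10.0, 0.01, 90.0)
        sol = solve_network(minimal_tree, {"RPA": rcr, "LPA": rcr}, constant_inflow, fluid)
        r_mpa = segment_resistance(1.0, 2.0, fluid.viscosity)
        r_side = segment_resistance(1.0 / np.sqrt(2.0), 3.0, fluid.viscosity)
        expected = (r_mpa * 10.0**2 + 2.0 * r_side * 5.0**2) * 1e-4
        assert energy_dissipation(sol, minimal_tree, fluid) == pytest.approx(expected, rel=0.01)

    def test_capacitor_convention_adds_proximal_losses(self, fluid, minimal_tree, constant_inflow):
        rcr = WindkesselRCR(10.0, 0.01, 90.0)
        sol = solve_network(minimal_tree, {"RPA": rcr, "LPA": rcr}, constant_inflow, fluid)
        face = energy_dissipation(sol, minimal_tree, fluid, outlet_pressure="face")
        cap = energy_dissipation(sol, minimal_tree, fluid, outlet_pressure="capacitor")
        rp_losses = 2.0 * 10.0 * 5.0**2 * 1e-4
        assert cap - face == pytest.approx(rp_losses, rel=0.01)

    def test_mean_pressure_reading_agrees_for_steady_flow(self, fluid, minimal_tree, constant_inflow):
        rcr = WindkesselRCR(10.0, 0.01, 90.0)
        sol = solve_network(minimal_tree, {"RPA": rcr, "LPA": rcr}, constant_inflow, fluid)
        a = energy_dissipation(sol, minimal_tree, fluid, averaging="instantaneous")
        b = energy_dissipation(sol, minimal_tree, fluid, averaging="mean_pressure")
        assert a == pytest.approx(b, rel=1e-9)

    def test_nonnegative_for_passive_pulsatile_network(self, fluid, minimal_tree):
        from pahemo import generate_inflow_waveform

        wf = generate_inflow_waveform(70.0, 0.9, 0.44)
        rcr = WindkesselRCR(20.0, 0.004, 200.0)
        sol = solve_network(minimal_tree, {"RPA": rcr, "LPA": rcr}, wf, fluid)
        assert energy_dissipation(sol, minimal_tree, fluid) >= -1e-9


class TestFlowDecomposition:
    def test_all_forward_waveform(self):
        wf = FlowWaveform(1.0, np.abs(np.sin(np.linspace(0, np.pi, 64))) + 1.0)
        dec = flow_decomposition(wf, area=2.0)
        assert dec.pr_percent == 0.0
        assert dec.backward_velocity == 0.0

    def test_pure_sine_is_fully_regurgitant(self):
        t = np.arange(128) / 128.0
        wf = FlowWaveform(1.0, np.sin(2.0 * np.pi * t))
        dec = flow_decomposition(wf, area=1.0)
        assert dec.pr_percent == pytest.approx(100.0, rel=1e-9)
        assert dec.forward_volume == pytest.approx(dec.backward_volume, rel=1e-9)

    def test_backward_only_flow_rejected(self):
        wf = FlowWaveform(1.0, -np.ones(64))
        with pytest.raises(ValueError, match="forward"):
            flow_decomposition(wf, area=1.0)


class TestSummaries:
    def test_identical_values_have_zero_sd(self):
        df = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        out = summarize_indices(df)
        assert out.loc["mean", "a"] == 3.0
        assert out.loc["sd", "a"] == 0.0

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            summarize_indices(pd.DataFrame({"a": [1.0]}))

    def test_reference_pre_ed_mean_and_sd(self):
        ref = load_reference_indices()
        pre_ed = ref[ref["state"] == "pre"]["ed"]
        out = summarize_indices(pre_ed.to_frame())
        assert round_half_up(out.loc["mean", "ed"]) == 93.8
        assert round_half_up(out.loc["sd", "ed"]) == 67.7

    def test_round_half_up_convention(self):
        assert round_half_up(18.45) == 18.5
        assert round_half_up(18.4449) == 18.4
        assert round_half_up(-2.35) == -2.4
        assert round_half_up(2.349, 2) == 2.35
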
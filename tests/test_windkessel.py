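import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahemo import (
    assemble_rcr,
    build_resistance_budget,
    calibrate_flow_split,
    generate_inflow_waveform,
    generate_pa_tree,
    mmhg_to_cgs,
    murray_fractions,
    rcr_set_from_budget,
    side_resistances,
    solve_network,
    total_pa_resistance,
)
from pahemo.windkessel import ResistanceBudget


class TestTotalResistance:
    def test_clinical_unit_conversion_example(self):
        # 10 mmHg over 5 L/min
        r = total_pa_resistance(mmhg_to_cgs(10.0), 5000.0 / 60.0)
        assert r == pytest.approx(159.99, abs=0.01)

    def test_mean_pap_13mmhg(self):
        r = total_pa_resistance(mmhg_to_cgs(13.0), 83.33)
        assert r == pytest.approx(208.0, abs=0.05)

    def test_zero_driving_pressure_rejected(self):
        with pytest.raises(ValueError):
            total_pa_resistance(1000.0, 50.0, distal_pressure=1000.0)
        with pytest.raises(ValueError):
            total_pa_resistance(1000.0, 0.0)


class TestSideSplit:
    def test_symmetric(self):
        assert side_resistances(100.0, 0.5) == (200.0, 200.0)

    def test_measured_pre_implantation_split(self):
        r_rpa, r_lpa = side_resistances(100.0, 0.614)
        assert r_rpa == pytest.approx(162.87, abs=0.01)
        assert r_lpa == pytest.approx(259.07, abs=0.01)
        assert 1.0 / r_rpa + 1.0 / r_lpa == pytest.approx(0.01, rel=1e-12)

    def test_extreme_fraction_guarded(self):
        with pytest.raises(ValueError):
            side_resistances(100.0, 1e-9)


class TestMurrayFractions:
    def test_two_equal_areas(self):
        np.testing.assert_allclose(murray_fractions([2.0, 2.0]), [0.5, 0.5])

    def test_radius_power_law_exponent_2_3(self):
        areas = [np.pi * 1.0**2, np.pi * 2.0**2]
        w = 2.0**2.3
        np.testing.assert_allclose(
            murray_fractions(areas, 2.3), [1.0 / (1.0 + w), w / (1.0 + w)], rtol=1e-12
        )
        assert murray_fractions(areas, 2.3)[1] == pytest.approx(0.8312, abs=5e-5)

    def test_exponent_two_reduces_to_area_fractions(self):
        areas = np.array([1.0, 2.5, 0.7])
        np.testing.assert_allclose(murray_fractions(areas, 2.0), areas / areas.sum(), rtol=1e-12)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            murray_fractions([])
        with pytest.raises(ValueError):
            murray_fractions([1.0, -2.0])

    @given(
        areas=st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
        scale=st.floats(0.1, 100.0),
        exponent=st.floats(0.5, 4.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_normalization(self, areas, scale, exponent):
        f = murray_fractions(areas, exponent)
        f_scaled = murray_fractions([a * scale for a in areas], exponent)
        np.testing.assert_allclose(f, f_scaled, atol=1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        # permutation equivariance
        perm = np.argsort(areas)
        np.testing.assert_allclose(murray_fractions(np.asarray(areas)[perm], exponent), f[perm], atol=1e-12)


class TestAssembleRCR:
    def test_split_and_time_constant(self):
        rcr = assemble_rcr(100.0, 0.1, 1.0)
        assert rcr.proximal_resistance == pytest.approx(10.0)
        assert rcr.distal_resistance == pytest.approx(90.0)
        assert rcr.compliance == pytest.approx(1.0 / 90.0)

    def test_pure_rc_outlet(self):
        rcr = assemble_rcr(50.0, 0.0, 0.5)
        assert rcr.proximal_resistance == 0.0

    @pytest.mark.parametrize("frac", [0.0, 0.1, 0.5, 0.9])
    def test_total_resistance_conserved(self, frac):
        rcr = assemble_rcr(123.4, frac, 1.0)
        assert rcr.total_resistance == pytest.approx(123.4, rel=1e-12)

    def test_unit_proximal_fraction_rejected(self):
        with pytest.raises(ValueError):
            assemble_rcr(100.0, 1.0, 1.0)


class TestResistanceBudget:
    def test_parallel_combination_reproduces_total(self):
        tree = generate_pa_tree(10, 1.3, 0.3, seed=5)
        budget = build_resistance_budget(tree, 250.0, 0.614)
        par = 1.0 / sum(1.0 / r for r in budget.outlet_resistances.values())
        assert par == pytest.approx(250.0, rel=1e-9)

    def test_side_parallel_matches_flow_share(self):
        tree = generate_pa_tree(6, 1.2, 0.2, seed=2)
        budget = build_resistance_budget(tree, 300.0, 0.6)
        assert budget.side_parallel_resistance("RPA") == pytest.approx(300.0 / 0.6, rel=1e-9)

    def test_inconsistent_budget_rejected(self):
        with pytest.raises(ValueError, match="parallel combination"):
            ResistanceBudget(100.0, 0.5, {"a": 100.0, "b": 100.0}, {"a": "RPA", "b": "LPA"})


class TestCalibration:
    def test_symmetric_tree_converges_immediately(self, fluid):
        tree = generate_pa_tree(3, 1.0, 0.0, seed=0, rpa_radius_ratio=0.72, lpa_radius_ratio=0.72)
        wf = generate_inflow_waveform(60.0, 0.8, 0.2, n_samples=128)
        budget = build_resistance_budget(tree, 300.0, 0.5)
        _, report = calibrate_flow_split(
            tree, budget, wf, 0.5, fluid=fluid, steps_per_cycle=128, n_cycles=4
        )
        assert report.converged
        assert report.iterations == 0
        assert report.final_relative_error < 1e-6

    def test_miscalibrated_budget_recovers_target(self, fluid):
        # budget deliberately built for the wrong split; the loop must fix it
        tree = generate_pa_tree(4, 1.2, 0.2, seed=9)
        wf = generate_inflow_waveform(70.0, 0.9, 0.3, n_samples=128)
        budget = build_resistance_budget(tree, 280.0, 0.40)
        calibrated, report = calibrate_flow_split(
            tree, budget, wf, 0.614, tolerance=0.02, max_iter=15,
            fluid=fluid, steps_per_cycle=128, n_cycles=4,
        )
        assert report.converged
        assert report.final_relative_error <= 0.02
        assert report.iterations >= 1

    def test_total_resistance_preserved_across_iterations(self, fluid):
        tree = generate_pa_tree(4, 1.2, 0.2, seed=9)
        wf = generate_inflow_waveform(70.0, 0.9, 0.3, n_samples=128)
        budget = build_resistance_budget(tree, 280.0, 0.40)
        calibrated, _ = calibrate_flow_split(
            tree, budget, wf, 0.614, tolerance=0.02, max_iter=15,
            fluid=fluid, steps_per_cycle=128, n_cycles=4,
        )
        par = 1.0 / sum(1.0 / r for r in calibrated.outlet_resistances.values())
        assert par == pytest.approx(280.0, rel=1e-6)

    def test_zero_tolerance_reports_nonconvergence(self, fluid):
        tree = generate_pa_tree(2, 1.1, 0.3, seed=4)
        wf = generate_inflow_waveform(70.0, 0.9, 0.3, n_samples=128)
        budget = build_resistance_budget(tree, 280.0, 0.55)
        _, report = calibrate_flow_split(
            tree, budget, wf, 0.614, tolerance=0.0, max_iter=3,
            fluid=fluid, steps_per_cycle=128, n_cycles=4,
        )
        assert not report.converged
        assert report.iterations == 3

    def test_raising_one_outlet_resistance_lowers_its_flow_share(self, fluid, minimal_tree):
        wf = generate_inflow_waveform(60.0, 0.8, 0.2, n_samples=128)
        budget = build_resistance_budget(minimal_tree, 300.0, 0.5)

        def rpa_share(scale):
            res = dict(budget.outlet_resistances)
            res["RPA"] *= scale
            rcrs = {
                oid: assemble_rcr(r, 0.1, 1.0) for oid, r in res.items()
            }
            sol = solve_network(minimal_tree, rcrs, wf, fluid, n_cycles=4, steps_per_cycle=128)
            v = {o: sol.last_cycle_volume(o) for o in ("RPA", "LPA")}
            return v["RPA"] / (v["RPA"] + v["LPA"])

        shares = [rpa_share(s) for s in (1.0, 1.5, 2.5)]
        assert shares[0] > shares[1] > shares[2]
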
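import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

import cyanocycle as cc
from cyanocycle.simulate import _generations_for


def _slope(x, y):
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def noiseless_spec(rule, lam=0.055):
    trig = {"sizer": 2.0, "adder": 1.0, "timer": math.log(2) / lam}[rule]
    return cc.ModelSpec(rule, trig, trigger_cv=0.0, asym_sd=0.0,
                        growth_rate_mean=lam, growth_rate_cv=0.0, seed=9)


class TestSimulatePopulation:
    def test_noiseless_adder_fixed_point(self):
        """Founders at V_b = Δ divide at exactly 2Δ after ln2/λ hours."""
        spec = noiseless_spec("adder")
        cells = cc.simulate_population(spec, 4, 3,
                                       founder_volumes=[1.0] * 4)
        for c in cells:
            assert c.V_d == pytest.approx(2.0, rel=1e-12)
            assert c.T == pytest.approx(math.log(2) / 0.055, rel=1e-12)

    def test_noiseless_sizer_divides_at_target(self):
        spec = noiseless_spec("sizer")
        cells = cc.simulate_population(spec, 10, 3)
        assert all(c.V_d == pytest.approx(2.0, rel=1e-12) for c in cells)

    def test_volume_conservation_at_division(self, calibrated_adder):
        cells = cc.simulate_population(calibrated_adder, 5, 5)
        by_id = {c.id: c for c in cells}
        checked = 0
        for c in cells:
            if c.parent_id is None or c.sister_id not in by_id:
                continue
            parent = by_id[c.parent_id]
            sister = by_id[c.sister_id]
            assert (c.V_b + sister.V_b) == pytest.approx(parent.V_d,
                                                         rel=1e-9)
            checked += 1
        assert checked > 50

    def test_dark_gating(self):
        """No division strictly inside a dark interval; growth only in
        light, so V at dark onset equals V at the next dawn."""
        sch = cc.IlluminationSchedule.light_dark(12, 12, total_h=3000)
        spec = cc.ModelSpec("adder", 1.0, trigger_cv=0.15, asym_sd=0.033,
                            growth_rate_cv=0.3, seed=4)
        cells = cc.simulate_population(spec, 10, 6, schedule=sch)
        bounds = {s for s, _, _ in sch.intervals} | {e for _, e, _ in
                                                     sch.intervals}
        for c in cells:
            if sch.state_at(c.division_time) == "dark":
                assert any(abs(c.division_time - b) < 1e-6 for b in bounds)
            # wall-clock duration exceeds light-time by the dark gaps
            dark_gap = (c.division_time - c.birth_time) - c.T
            assert dark_gap == pytest.approx(
                (c.division_time - c.birth_time)
                - sch.light_time(c.birth_time, c.division_time), abs=1e-6)

    def test_lambda_T_consistency(self, calibrated_adder):
        cells = cc.simulate_population(calibrated_adder, 3, 4)
        for c in cells:
            assert c.T == pytest.approx(math.log(c.V_d / c.V_b) / c.lam,
                                        rel=1e-9)

    def test_steady_state_mean_birth_volume(self, calibrated_adder):
        nf, ng = _generations_for(5000, 4)
        cells = cc.simulate_population(replace(calibrated_adder, seed=3),
                                       nf, ng + 1)
        gens = np.array([c.generation for c in cells if c.generation >= 4])
        vb = np.array([c.V_b for c in cells if c.generation >= 4])
        assert len(vb) >= 5000
        res = sps.linregress(gens, vb)
        assert res.pvalue > 0.01  # no trend at steady state

    def test_all_dark_schedule_rejected(self):
        sch_kwargs = dict(intervals=((0.0, 100.0, "dark"),), after="dark")
        with pytest.raises(ValueError, match="dark"):
            cc.IlluminationSchedule(**sch_kwargs)

    def test_seeded_determinism(self, calibrated_adder):
        a = cc.simulate_population(calibrated_adder, 3, 4)
        b = cc.simulate_population(calibrated_adder, 3, 4)
        assert [(c.V_b, c.V_d, c.T) for c in a] == \
               [(c.V_b, c.V_d, c.T) for c in b]


class TestIdealSlopes:
    @pytest.mark.parametrize("rule,expected",
                             [("sizer", 0.0), ("adder", 1.0), ("timer", 2.0)])
    def test_analytic_values(self, rule, expected):
        assert cc.ideal_model_slope(rule) == expected

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            cc.ideal_model_slope("divider")

    @pytest.mark.parametrize("rule", ["sizer", "adder", "timer"])
    def test_zero_noise_limit_matches_ideal(self, rule):
        """Simulated V_d-vs-V_b slope equals the analytic slope when every
        noise source is off (for the sizer the founder generation carries
        the only birth-size variance)."""
        cells = cc.simulate_population(noiseless_spec(rule), 40, 4)
        gen_sel = 0 if rule == "sizer" else 3
        use = [c for c in cells if c.generation >= gen_sel]
        vb = np.array([c.V_b for c in use])
        vd = np.array([c.V_d for c in use])
        slope = _slope(vb / vb.mean(), vd / vb.mean())
        assert slope == pytest.approx(cc.ideal_model_slope(rule), abs=1e-6)


class TestSlopeDistribution:
    def test_too_few_cells_rejected(self, calibrated_adder):
        with pytest.raises(ValueError):
            cc.simulated_slope_distribution(calibrated_adder, "Vd_vs_Vb",
                                            n_replicates=2,
                                            cells_per_replicate=10)

    def test_adder_band_contains_unity(self, calibrated_adder):
        mean, sd = cc.simulated_slope_distribution(
            calibrated_adder, "Vd_vs_Vb", n_replicates=40,
            cells_per_replicate=278)
        assert mean == pytest.approx(1.0, abs=0.05)
        assert 0.05 < sd < 0.25


class TestCalibration:
    def test_adder_reaches_target_cv(self, calibrated_adder):
        from cyanocycle.simulate import _birth_cv
        assert calibrated_adder.trigger_cv > 0
        assert _birth_cv(calibrated_adder) == pytest.approx(0.12, abs=0.01)

    def test_zero_target_all_noise_zero(self):
        spec = cc.calibrate_noise("adder", 0.0, 0.0, 0.0)
        assert spec.trigger_cv == 0.0

    def test_sizer_and_adder_calibrations_differ(self, calibrated_specs):
        assert calibrated_specs["sizer"].trigger_cv != pytest.approx(
            calibrated_specs["adder"].trigger_cv, abs=0.005)

    def test_timer_floor_is_unreachable(self):
        """The timer rule has no size homeostasis: its birth-size spread
        cannot be dialled down to the measured CV, and the error names
        the floor."""
        with pytest.raises(cc.CalibrationError) as exc:
            cc.calibrate_noise("timer", 0.12, 0.30, 0.033)
        assert exc.value.floor > 0.12


def test_sister_generation_times_positively_correlated(calibrated_adder):
    """Size control with near-symmetric division makes sister generation
    times positively correlated (shared birth size), and the correlation
    weakens as divisions become asymmetric."""
    sym = replace(calibrated_adder, growth_rate_cv=0.0, seed=5)
    cells = cc.simulate_population(sym, 20, 7)
    cyc = cc.cycles_from_simulation(cells, burn_in=3)
    r_sym = cc.sister_statistics(cyc)
    assert r_sym.T_r > 0.1 and r_sym.T_p < 0.01

    asym = replace(sym, asym_sd=0.3)
    cells = cc.simulate_population(asym, 20, 7)
    r_asym = cc.sister_statistics(cc.cycles_from_simulation(cells, burn_in=3))
    assert r_asym.T_r < r_sym.T_r
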
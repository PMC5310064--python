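import math

import numpy as np
import pytest

import cyanocycle as cc


def ld_schedule():
    return cc.IlluminationSchedule.light_dark(12, 12, total_h=500)


def gated_exponential(lam=0.055, v0=2.0, t_end=48.0, schedule=None):
    t = np.arange(0.0, t_end, 1 / 6)
    if schedule is None:
        lt = t
    else:
        lt = np.array([schedule.light_time(0.0, ti) for ti in t])
    return cc.GrowthCurve("c", t, v0 * np.exp(lam * lt), schedule=schedule)


class TestSpliceDark:
    def test_all_light_is_identity(self):
        curve = gated_exponential(schedule=None)
        curve.schedule = cc.IlluminationSchedule.continuous()
        out = cc.splice_dark(curve)
        assert np.allclose(out.times, curve.times - curve.times[0])
        assert np.allclose(out.volumes, curve.volumes)
        assert not out.flags

    def test_spliced_curve_is_single_exponential(self):
        sch = ld_schedule()
        out = cc.splice_dark(gated_exponential(schedule=sch))
        fit = cc.fit_exponential(out)
        assert fit.lam == pytest.approx(0.055, rel=1e-6)
        # R² of the log-linear fit
        logv = np.log(out.volumes)
        ss_res = np.sum((logv - np.log(fit.V0) - fit.lam * out.times) ** 2)
        ss_tot = np.sum((logv - logv.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_growth_in_dark_flagged(self):
        sch = ld_schedule()
        t = np.arange(0.0, 36.0, 1 / 6)
        v = 2.0 * np.exp(0.055 * t)  # keeps growing in the dark: violation
        out = cc.splice_dark(cc.GrowthCurve("bad", t, v, schedule=sch))
        assert "splice_jump" in out.flags


class TestFitExponential:
    def test_exact_recovery(self):
        curve = gated_exponential(lam=0.055, v0=2.0)
        fit = cc.fit_exponential(curve)
        assert fit.lam == pytest.approx(0.055, abs=1e-10)
        assert fit.V0 == pytest.approx(2.0, rel=1e-10)
        assert fit.rmse < 1e-10

    def test_constant_volume_zero_rate(self):
        t = np.arange(0, 10, 0.5)
        fit = cc.fit_exponential(cc.GrowthCurve("c", t, np.full_like(t, 3.0)))
        assert fit.lam == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.default_rng(0)
        errs = []
        for trial in range(30):
            t = np.linspace(0, 20, 100)
            v = 2.0 * np.exp(0.055 * t) * (1 + 0.03 * rng.normal(size=100))
            fit = cc.fit_exponential(cc.GrowthCurve("c", t, v))
            errs.append(abs(fit.lam / 0.055 - 1))
        assert np.mean(np.array(errs) < 0.05) > 0.9

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cc.fit_exponential(cc.GrowthCurve("c", [0, 1, 2], [1, 2, 3]))


class TestCyclesFromSimulation:
    def test_founders_excluded(self, calibrated_adder):
        cells = cc.simulate_population(calibrated_adder, 5, 3)
        cycles = cc.cycles_from_simulation(cells)
        founder_ids = {c.id for c in cells if c.parent_id is None}
        assert not founder_ids & {r.cell_id for r in cycles}

    def test_adder_increment_recovered(self, calibrated_adder):
        cells = cc.simulate_population(calibrated_adder, 10, 6)
        cycles = cc.cycles_from_simulation(cells, burn_in=3)
        mean_inc = np.mean([r.increment for r in cycles])
        assert mean_inc == pytest.approx(calibrated_adder.trigger_mean,
                                        rel=0.10)

    def test_asymmetry_flag_cutoff(self, calibrated_adder):
        cells = cc.simulate_population(calibrated_adder, 10, 5)
        cycles = cc.cycles_from_simulation(cells, burn_in=2)
        for r in cycles:
            if not math.isnan(r.asymmetry_at_birth):
                assert r.flagged_asymmetric == (abs(r.asymmetry_at_birth)
                                                > 0.07)

    def test_closed_form_cycle(self):
        """A track growing 1 -> 2 µm³ at λ = 0.055 has T = ln2/0.055 and
        increment 1."""
        lam = 0.055
        T = math.log(2) / lam
        t = np.linspace(0, T, 50)
        curve = cc.GrowthCurve(1, t, np.exp(lam * t),
                               schedule=cc.IlluminationSchedule.continuous())

        class Track:
            cell_id, parent_id, sister_id = 1, 0, None
            division_frame = 49
            flags = ()

        records = cc.extract_cycles([Track()], {1: curve})
        assert len(records) == 1
        r = records[0]
        assert r.T == pytest.approx(T, rel=1e-9)
        assert r.increment == pytest.approx(1.0, rel=1e-9)
        assert r.lam == pytest.approx(lam, rel=1e-9)


class TestLineageTotals:
    def test_single_doubling(self):
        t = np.linspace(0, 10, 20)
        curves = {0: cc.GrowthCurve(0, t, np.exp(math.log(2) / 10 * t))}
        out = cc.lineage_totals(curves, founder_id=0)
        assert out.normalized_volume.iloc[-1] == pytest.approx(2.0, rel=1e-6)
        assert (out.cell_count == 1).all()

    def test_exponential_microcolony(self, calibrated_adder):
        cells = cc.simulate_population(calibrated_adder, 1, 7)
        sch = cc.IlluminationSchedule.continuous()
        curves = {}
        horizon = 40.0
        frame_times = np.arange(0.0, horizon, 1 / 6)  # shared frame clock
        for c in cells:
            sel = (frame_times >= c.birth_time) & \
                  (frame_times < c.division_time)
            t = frame_times[sel]
            if len(t) < 2:
                continue
            curves[c.id] = cc.GrowthCurve(
                c.id, t, c.V_b * np.exp(c.lam * (t - c.birth_time)),
                schedule=sch)
        founder = min(curves, key=lambda k: curves[k].times[0])
        out = cc.lineage_totals(curves, founder_id=founder)
        sel = out[out.time <= horizon]
        logv = np.log(sel.normalized_volume.values)
        coeffs = np.polyfit(sel.time.values, logv, 1)
        resid = logv - np.polyval(coeffs, sel.time.values)
        assert np.sqrt((resid ** 2).mean()) < 0.1

    def test_ld_totals_flat_in_dark(self):
        sch = ld_schedule()
        curve = gated_exponential(schedule=sch, t_end=36.0)
        out = cc.lineage_totals({0: curve}, founder_id=0)
        dark = out[(out.time > 12.01) & (out.time < 23.99)]
        assert dark.normalized_volume.nunique() == 1
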
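"""Membrane simulator: OU noise statistics, passive closed forms, resting
behavior, determinism, convergence and clamp bookkeeping."""

import math

import numpy as np
import pytest

from cgcell.kinetics import ChannelSpec
from cgcell.membrane import (
    CellScenario,
    Compartment,
    NoiseSpec,
    SimulationError,
    StepStimulus,
    detect_spikes,
    ou_step,
    simulate_current_clamp,
    simulate_voltage_clamp,
)


class TestCompartment:
    def test_sphere_geometry_derived(self):
        c = Compartment(diameter_um=12.5, specific_capacitance_uF_cm2=0.9)
        assert c.area_cm2 == pytest.approx(math.pi * (12.5e-4) ** 2)
        assert c.capacitance_pF == pytest.approx(4.42, abs=0.01)

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            Compartment(diameter_um=-1.0)

    def test_density_conductance_resolution(self):
        c = Compartment()
        ch = ChannelSpec("Na", None, 0.1, "S_per_cm2", 60.0)
        assert ch.g_nS(c.area_cm2) == pytest.approx(0.1 * c.area_cm2 * 1e9)


class TestOUStep:
    def test_fixed_point_at_mean(self):
        rng = np.random.default_rng(0)
        g = 25.0
        for _ in range(100):
            g = ou_step(g, 25.0, 0.0, 2.728, 0.05, rng)
        assert g == pytest.approx(25.0)

    def test_deterministic_relaxation(self):
        rng = np.random.default_rng(0)
        tau, dt = 2.728, 0.05
        g = 100.0
        for _ in range(200):
            g = ou_step(g, 25.0, 0.0, tau, dt, rng)
        expected = 25.0 + 75.0 * math.exp(-200 * dt / tau)
        assert g == pytest.approx(expected, rel=1e-12)

    def test_stationary_statistics(self):
        # long run: sample SD within 2% of sd; autocorrelation at lag tau
        # within 3% of 1/e
        rng = np.random.default_rng(12345)
        tau, dt, sd, n = 2.728, 0.05, 50.0, 1_000_000
        e = math.exp(-dt / tau)
        amp = sd * math.sqrt(1 - e * e)
        drive = amp * rng.standard_normal(n)
        from scipy.signal import lfilter

        x = lfilter([1.0], [1.0, -e], drive)  # same recursion as ou_step
        x = x[5000:]
        assert x.std() == pytest.approx(sd, rel=0.02)
        k = int(round(tau / dt))
        ac = np.corrcoef(x[:-k], x[k:])[0, 1]
        assert ac == pytest.approx(1 / math.e, rel=0.03)


class TestCurrentClamp:
    def test_rc_closed_form(self, passive_cell):
        g, e_rev = 2.0, -70.0
        cap = passive_cell.compartment.capacitance_pF
        tau = cap / g
        tr = simulate_current_clamp(
            passive_cell, StepStimulus(100.0, 10.0, 20.0, 90.0), dt=0.025, v0=e_rev
        )
        sel = (tr.time_ms > 20.0) & (tr.time_ms <= 90.0)
        pred = e_rev + (10.0 / g) * (1 - np.exp(-(tr.time_ms[sel] - 20.0) / tau))
        # 0.1% of the 5 mV deflection
        assert np.abs(tr.vm_mV[sel] - pred).max() < 0.005

    def test_rests_at_leak_reversal(self, passive_cell):
        tr = simulate_current_clamp(passive_cell, StepStimulus(200.0), v0=-50.0)
        assert tr.vm_mV[-1] == pytest.approx(-70.0, abs=1e-3)

    def test_all_potassium_scenario_rests_at_ek(self, library):
        cell = CellScenario(
            "allK", Compartment(), (library["TASK3"], library["K2P"], library["Kdr"])
        )
        tr = simulate_current_clamp(cell, StepStimulus(500.0), v0=-80.0)
        assert tr.vm_mV[-1] == pytest.approx(-91.5, abs=0.01)

    def test_rest_between_reversal_potentials(self, control_scenario):
        tr = simulate_current_clamp(control_scenario, StepStimulus(1000.0), v0=-80.0)
        lo, hi = control_scenario.reversal_range()
        assert lo < tr.vm_mV[-1] < hi

    def test_seed_determinism_bit_identical(self, control_scenario):
        noise = NoiseSpec(25, 25, 200, 200)
        a = simulate_current_clamp(
            control_scenario, StepStimulus(200.0), noise=noise, seed=42, v0=-82.0
        )
        b = simulate_current_clamp(
            control_scenario, StepStimulus(200.0), noise=noise, seed=42, v0=-82.0
        )
        assert np.array_equal(a.vm_mV, b.vm_mV)
        c = simulate_current_clamp(
            control_scenario, StepStimulus(200.0), noise=noise, seed=43, v0=-82.0
        )
        assert not np.array_equal(a.vm_mV, c.vm_mV)

    def test_dt_convergence_control_scenario(self, control_scenario):
        # halving dt changes the subthreshold trace by < 0.1 mV RMS
        stim = StepStimulus(250.0, 20.0, 50.0, 250.0)
        a = simulate_current_clamp(control_scenario, stim, dt=0.025, v0=-82.0,
                                   record_every=8)
        b = simulate_current_clamp(control_scenario, stim, dt=0.0125, v0=-82.0,
                                   record_every=16)
        rms_diff = np.sqrt(np.mean((a.vm_mV - b.vm_mV) ** 2))
        assert rms_diff < 0.1

    def test_current_bookkeeping(self, control_scenario):
        # C dV/dt equals injected current minus the reported channel currents
        tr = simulate_current_clamp(
            control_scenario, StepStimulus(50.0, 15.0, 10.0, 50.0),
            dt=0.025, v0=-82.0, record_currents=True,
        )
        cap = control_scenario.compartment.capacitance_pF
        i_total = sum(tr.channel_currents_pA.values())
        dvdt = np.gradient(tr.vm_mV, tr.dt_ms)
        resid = cap * dvdt - (tr.i_inj_pA - i_total)
        # exclude the step edge samples
        inside = (tr.time_ms > 11.0) & (tr.time_ms < 49.0)
        assert np.abs(resid[inside]).max() < 1.0  # pA, solver tolerance

    def test_blowup_reports_time(self, passive_cell):
        huge = StepStimulus(50.0, 1e6, 10.0, 50.0)
        with pytest.raises(SimulationError, match="t ="):
            simulate_current_clamp(passive_cell, huge)


class TestVoltageClamp:
    def test_leak_family_is_ohmic(self, passive_cell):
        for v in (-100.0, -60.0, -20.0):
            cmd = np.full(2000, v)
            tr = simulate_voltage_clamp(passive_cell, cmd, dt=0.025)
            expected = 2.0 * (v + 70.0)
            assert tr.channel_currents_pA["leak"][-1] == pytest.approx(expected, rel=1e-9)

    def test_command_followed_exactly(self, library):
        cell = CellScenario("t3", Compartment(), (library["TASK3"],))
        cmd = np.concatenate([np.full(100, -80.0), np.full(100, -40.0)])
        tr = simulate_voltage_clamp(cell, cmd, dt=0.025)
        assert np.array_equal(np.unique(tr.vm_mV), np.array([-80.0, -40.0]))

    def test_task3_outward_rectification(self, library):
        cell = CellScenario("t3", Compartment(), (library["TASK3"],))
        out = {}
        for v in (-100.0, -40.0):
            cmd = np.full(40000, v)
            tr = simulate_voltage_clamp(cell, cmd, dt=0.025, record_every=10)
            out[v] = tr.channel_currents_pA["TASK3"][-1]
        # chord conductance grows with depolarization: the sustained current at
        # -40 exceeds the linear extrapolation of the -100 mV chord
        g_chord_neg = out[-100.0] / (-100.0 + 91.5)
        assert out[-40.0] > g_chord_neg * (-40.0 + 91.5)


class TestSpikeDetection:
    def test_counts_threshold_crossings_with_peak(self):
        t = np.arange(0.0, 100.0, 0.1)
        v = np.full_like(t, -70.0)
        for t0 in (20.0, 60.0):
            v += 90.0 * np.exp(-((t - t0) ** 2) / 2.0)
        assert detect_spikes(v) == 2

    def test_subthreshold_bump_not_counted(self):
        t = np.arange(0.0, 50.0, 0.1)
        v = -70.0 + 45.0 * np.exp(-((t - 25.0) ** 2) / 2.0)  # peaks at -25 mV
        assert detect_spikes(v) == 0
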
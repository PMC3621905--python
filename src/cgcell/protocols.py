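"""Protocol drivers: from simulations to measured quantities.

These wrap the membrane simulator into the standard current- and
voltage-clamp measurements: resting potential, input resistance, membrane
time constant and corner frequency (f_c = 1/(2*pi*tau_m)), threshold
(rheobase) current by bisection, sustained I-V curves, and voltage-clamp
characterization of the A-type current (steady-state inactivation, peak
activation, recovery, time to peak, fast inactivation tau).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from cgcell.kinetics import (
    ChannelSpec,
    GateSet,
    KineticScheme,
    open_fraction,
    steady_state,
)
from cgcell.library import CalciumGatedSpec
from cgcell.membrane import (
    CellScenario,
    Compartment,
    NoiseSpec,
    SimState,
    StepStimulus,
    detect_spikes,
    simulate_current_clamp,
    simulate_voltage_clamp,
)

__all__ = [
    "MembraneProperties",
    "ThresholdResult",
    "CharacterizationCurves",
    "steady_current",
    "resting_potential",
    "input_resistance",
    "time_constant_and_fc",
    "membrane_properties",
    "threshold_current",
    "sustained_iv",
    "characterize_isa",
    "ProtocolError",
]


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class MembraneProperties:
    """Passive membrane summary; f_c = 1/(2*pi*tau_m) holds exactly."""

    e_rest_mV: float
    r_in_GOhm: float
    tau_m_ms: float
    f_c_Hz: float
    fit_warning: str | None = None

    def __post_init__(self) -> None:
        if self.r_in_GOhm <= 0:
            raise ValueError("input resistance must be > 0")
        expected = 1.0 / (2 * math.pi * self.tau_m_ms * 1e-3)
        if abs(self.f_c_Hz - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("f_c must equal 1/(2*pi*tau_m)")


@dataclass(frozen=True)
class ThresholdResult:
    threshold_pA: float
    resolution_pA: float
    protocol: dict
    spikes_at_threshold: int

    def __post_init__(self) -> None:
        if self.spikes_at_threshold < 1:
            raise ValueError("threshold must elicit at least one spike")


@dataclass
class CharacterizationCurves:
    ssi_voltage_mV: np.ndarray
    ssi_available: np.ndarray
    act_voltage_mV: np.ndarray
    act_norm_conductance: np.ndarray
    recovery_interval_ms: np.ndarray
    recovery_fraction: np.ndarray
    time_to_peak_ms: np.ndarray  # aligned with act_voltage_mV
    fast_tau_ms: float
    fast_tau_voltage_mV: float = 50.0


# ---------------------------------------------------------------------------
# steady-state current balance
# ---------------------------------------------------------------------------

_CA_REST_UM = 0.05


def _p_open_inf(spec: ChannelSpec, v: float) -> float:
    g = spec.gating
    if g is None:
        return 1.0
    if isinstance(g, KineticScheme):
        return float(open_fraction(steady_state(g, v), g))
    if isinstance(g, GateSet):
        p = 1.0
        for gate, mult in zip(g.gates, g.multiplicities):
            p *= float(steady_state(gate, v)[gate.conducting_index].sum()) ** mult
        return p
    if isinstance(g, CalciumGatedSpec):
        a = g.alpha_per_uM_ms * _CA_REST_UM
        return a / (a + g.beta_ms)
    raise TypeError(type(g))


def steady_current(scenario: CellScenario, v: float) -> float:
    """Total steady-state membrane current (pA) at a fixed potential, with all
    gating at equilibrium (calcium pool at rest)."""
    area = scenario.compartment.area_cm2
    return sum(
        ch.g_nS(area) * _p_open_inf(ch, v) * (v - ch.e_rev_mV)
        for ch in scenario.channels
    )


def _algebraic_rest(scenario: CellScenario) -> float:
    lo, hi = scenario.reversal_range()
    vs = np.linspace(max(lo, -120.0), min(hi, 20.0), 141)
    fv = np.array([steady_current(scenario, v) for v in vs])
    for i in range(len(vs) - 1):
        if fv[i] <= 0 <= fv[i + 1]:
            return brentq(lambda v: steady_current(scenario, v), vs[i], vs[i + 1])
    raise ProtocolError(
        f"{scenario.name}: no zero-current potential between reversal potentials"
    )


def resting_potential(
    scenario: CellScenario,
    dt: float = 0.025,
    dvdt_tol_mV_per_ms: float = 0.01,
    max_duration_ms: float = 10_000.0,
) -> float:
    """Deterministic resting potential: simulate with zero injection and no
    noise until |dV/dt| < 10 uV/ms; oscillatory rest is reported distinctly."""
    v = _algebraic_rest(scenario)
    state: SimState | None = None
    elapsed = 0.0
    chunk = 500.0
    while elapsed < max_duration_ms:
        tr, state = simulate_current_clamp(
            scenario, StepStimulus(chunk), dt=dt, v0=v, state=state,
            record_every=10, return_state=True,
        )
        elapsed += chunk
        dv = np.diff(tr.vm_mV[-50:]) / tr.dt_ms
        if np.abs(dv).max() < dvdt_tol_mV_per_ms:
            return float(tr.vm_mV[-1])
    sign_changes = np.abs(np.diff(np.sign(dv))).sum()
    kind = "oscillatory rest" if sign_changes > 2 else "no convergence"
    raise ProtocolError(f"{scenario.name}: {kind} within {max_duration_ms} ms")


def _settled_state(scenario: CellScenario, dt: float, settle_ms: float = 1000.0):
    v = _algebraic_rest(scenario)
    tr, state = simulate_current_clamp(
        scenario, StepStimulus(settle_ms), dt=dt, v0=v, state=None,
        record_every=10, return_state=True,
    )
    return state


def input_resistance(
    scenario: CellScenario,
    step_pA: float = 10.0,
    duration_ms: float = 500.0,
    dt: float = 0.025,
) -> float:
    """Slope resistance (GOhm) from small +/- current steps around rest."""
    state = _settled_state(scenario, dt)
    v_ss = {}
    for sign in (+1.0, -1.0):
        tr = simulate_current_clamp(
            scenario, StepStimulus(duration_ms, sign * step_pA),
            dt=dt, state=state, record_every=10,
        )
        if detect_spikes(tr.vm_mV) > 0:
            raise ProtocolError(
                f"{scenario.name}: spike during input-resistance step; "
                f"use a smaller step than {step_pA} pA"
            )
        n_tail = max(1, int(0.1 * len(tr.vm_mV)))
        v_ss[sign] = tr.vm_mV[-n_tail:].mean()
    return float((v_ss[1.0] - v_ss[-1.0]) / (2 * step_pA))  # mV/pA == GOhm


def time_constant_and_fc(
    scenario: CellScenario,
    step_pA: float = -10.0,
    duration_ms: float = 200.0,
    dt: float = 0.025,
) -> tuple[float, float, str | None]:
    """Membrane time constant from a single-exponential fit to the small-step
    charging curve, and the corner frequency f_c = 1/(2*pi*tau_m).

    Returns (tau_m_ms, f_c_Hz, warning); warning is set when the exponential
    fit explains less than 99% of the charging-curve variance.
    """
    state = _settled_state(scenario, dt)
    tr = simulate_current_clamp(
        scenario, StepStimulus(duration_ms, step_pA), dt=dt, state=state, record_every=2,
    )
    t = tr.time_ms
    v = tr.vm_mV
    v0 = state.v
    v_inf = v[-max(1, int(0.05 * len(v))) :].mean()

    def model(t, tau):
        return v_inf + (v0 - v_inf) * np.exp(-t / tau)

    tau0 = scenario.compartment.capacitance_pF * 0.5  # ballpark via ~0.5 GOhm
    (tau,), _ = curve_fit(model, t, v, p0=[tau0])
    resid = v - model(t, tau)
    r2 = 1 - resid.var() / v.var() if v.var() > 0 else 1.0
    warning = None
    if r2 < 0.99:
        warning = f"single-exponential fit R^2 = {r2:.4f} < 0.99"
    fc = 1.0 / (2 * math.pi * tau * 1e-3)
    return float(tau), float(fc), warning


def membrane_properties(scenario: CellScenario, dt: float = 0.025) -> MembraneProperties:
    e_rest = resting_potential(scenario, dt=dt)
    r_in = input_resistance(scenario, dt=dt)
    tau, fc, warning = time_constant_and_fc(scenario, dt=dt)
    return MembraneProperties(e_rest, r_in, tau, fc, warning)


def threshold_current(
    scenario: CellScenario,
    step_duration_ms: float = 1000.0,
    holding_target_mV: float | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = 0,
    resolution_pA: float = 1.0,
    i_max_pA: float = 500.0,
    dt: float = 0.025,
    settle_ms: float = 1000.0,
) -> ThresholdResult:
    """Minimum sustained step current eliciting at least one action potential.

    A spike is an upward crossing of -20 mV whose peak exceeds 0 mV.  The
    search bisects the step amplitude down to ``resolution_pA``; with noise,
    every amplitude is tested against the same noise realization (same seed),
    and the threshold is reported together with that seed.
    """
    if resolution_pA < 1.0:
        raise ValueError("resolution must be >= 1 pA")
    holding_pA = 0.0
    if holding_target_mV is not None:
        holding_pA = -steady_current(scenario, holding_target_mV)
        v_start = holding_target_mV
    else:
        v_start = _algebraic_rest(scenario)

    def spikes_at(amp: float) -> int:
        stim = StepStimulus(
            settle_ms + step_duration_ms, amp, settle_ms, settle_ms + step_duration_ms,
            holding_pA,
        )
        tr = simulate_current_clamp(
            scenario, stim, noise=noise, dt=dt, seed=seed, v0=v_start, record_every=4,
        )
        sl = tr.time_ms > settle_ms
        return detect_spikes(tr.vm_mV[sl])

    lo, hi = 0.0, float(i_max_pA)
    if spikes_at(hi) == 0:
        raise ProtocolError(f"{scenario.name}: unexcitable (no spike at {i_max_pA} pA)")
    if spikes_at(lo) > 0:
        raise ProtocolError(f"{scenario.name}: fires with zero injected current")
    while hi - lo > resolution_pA:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid) > 0:
            hi = mid
        else:
            lo = mid
    n_spk = spikes_at(hi)
    return ThresholdResult(
        threshold_pA=float(hi),
        resolution_pA=float(hi - lo),
        protocol={
            "step_duration_ms": step_duration_ms,
            "holding_target_mV": holding_target_mV,
            "holding_pA": holding_pA,
            "noise": repr(noise) if noise else "none",
            "seed": seed,
            "dt_ms": dt,
        },
        spikes_at_threshold=n_spk,
    )


def sustained_iv(
    scenario: CellScenario,
    voltages_mV: np.ndarray,
    holding_mV: float = -80.0,
    step_duration_ms: float = 500.0,
    dt: float = 0.025,
) -> pd.DataFrame:
    """Steady-state (end-of-step) current at each command voltage.

    Returns a table with the total current and one column per channel.
    """
    voltages_mV = np.asarray(voltages_mV, float)
    rows = []
    for v in voltages_mV:
        n_hold = int(round(200.0 / dt))
        n_step = int(round(step_duration_ms / dt))
        cmd = np.concatenate([np.full(n_hold, holding_mV), np.full(n_step, v)])
        tr = simulate_voltage_clamp(scenario, cmd, dt=dt, record_every=10)
        n_tail = max(1, int(0.05 * n_step // 10))
        row = {"voltage_mV": v}
        for name, cur in tr.channel_currents_pA.items():
            row[f"I_{name}_pA"] = cur[-n_tail:].mean()
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["scenario"] = scenario.name
    return df


# ---------------------------------------------------------------------------
# A-current characterization (channel-level voltage-clamp protocols)
# ---------------------------------------------------------------------------


def _channel_cell(channel: ChannelSpec) -> CellScenario:
    return CellScenario(f"{channel.name}_only", Compartment(), (channel,))


def _peak_current(
    channel: ChannelSpec, cmd: np.ndarray, dt: float, window: slice
) -> tuple[float, float]:
    """(peak current, time of peak in ms relative to window start)."""
    cell = _channel_cell(channel)
    tr = simulate_voltage_clamp(cell, cmd, dt=dt, record_every=1)
    cur = tr.channel_currents_pA[channel.name][window]
    k = int(np.argmax(np.abs(cur)))
    return float(cur[k]), (k + 1) * dt


def characterize_isa(
    channel: ChannelSpec,
    holding_mV: float = -120.0,
    test_mV: float = 6.0,
    prepulse_ms: float = 1000.0,
    test_ms: float = 100.0,
    ssi_voltages: np.ndarray | None = None,
    act_voltages: np.ndarray | None = None,
    recovery_intervals_ms: np.ndarray | None = None,
    recovery_voltage_mV: float = -91.5,
    fast_tau_voltage_mV: float = 50.0,
    dt: float = 0.05,
) -> CharacterizationCurves:
    """Voltage-clamp characterization of an inactivating channel.

    Steady-state inactivation uses a long prepulse family followed by a test
    step; activation normalizes peak conductance from a fully available
    holding potential; recovery uses paired test pulses separated by a
    variable interval at the recovery potential; the fast inactivation tau is
    a single-exponential fit to the decay at a strong depolarization.
    """
    if isinstance(channel.gating, KineticScheme):
        if channel.gating.inactivated_index.size == 0:
            raise ValueError(f"{channel.name}: channel has no inactivated states")
    else:
        raise ValueError("characterize_isa requires a single Markov scheme channel")

    ssi_voltages = (
        np.arange(-120.0, -24.9, 5.0) if ssi_voltages is None else np.asarray(ssi_voltages)
    )
    act_voltages = (
        np.arange(-70.0, 60.1, 10.0) if act_voltages is None else np.asarray(act_voltages)
    )
    recovery_intervals_ms = (
        np.array([2, 5, 10, 20, 50, 100, 200, 400, 800, 1600, 3200], float)
        if recovery_intervals_ms is None
        else np.asarray(recovery_intervals_ms, float)
    )

    n_pre = int(round(prepulse_ms / dt))
    n_test = int(round(test_ms / dt))

    # --- steady-state inactivation -------------------------------------
    peaks = []
    for v_pre in ssi_voltages:
        cmd = np.concatenate([np.full(n_pre, v_pre), np.full(n_test, test_mV)])
        pk, _ = _peak_current(channel, cmd, dt, slice(n_pre, None))
        if abs(pk) < 1e-12:
            raise ProtocolError(f"{channel.name}: no resolvable peak at {v_pre} mV prepulse")
        peaks.append(pk)
    peaks = np.array(peaks)
    ssi = peaks / peaks.max()

    # --- activation and time to peak ------------------------------------
    n_hold = int(round(500.0 / dt))
    g_peaks, t_peaks = [], []
    for v in act_voltages:
        cmd = np.concatenate([np.full(n_hold, holding_mV), np.full(n_test, v)])
        pk, tpk = _peak_current(channel, cmd, dt, slice(n_hold, None))
        drive = v - channel.e_rev_mV
        g_peaks.append(pk / drive if abs(drive) > 1e-9 else np.nan)
        t_peaks.append(tpk)
    g_peaks = np.array(g_peaks)
    act = g_peaks / np.nanmax(g_peaks)

    # --- recovery from inactivation --------------------------------------
    # paired pulses from equilibrium at the recovery potential: the first
    # (reference) pulse inactivates the channel, the second reports recovery
    n_inact = int(round(1000.0 / dt))
    cmd0 = np.concatenate(
        [np.full(n_hold, recovery_voltage_mV), np.full(n_test, test_mV)]
    )
    ref_pk, _ = _peak_current(channel, cmd0, dt, slice(n_hold, None))
    rec = []
    for interval in recovery_intervals_ms:
        n_gap = int(round(interval / dt))
        cmd = np.concatenate(
            [
                np.full(n_hold, recovery_voltage_mV),
                np.full(n_inact, test_mV),
                np.full(n_gap, recovery_voltage_mV),
                np.full(n_test, test_mV),
            ]
        )
        pk, _ = _peak_current(channel, cmd, dt, slice(n_hold + n_inact + n_gap, None))
        rec.append(pk / ref_pk)
    rec = np.array(rec)

    # --- fast inactivation tau at strong depolarization --------------------
    cell = _channel_cell(channel)
    cmd = np.concatenate([np.full(n_hold, holding_mV), np.full(n_test * 2, fast_tau_voltage_mV)])
    tr = simulate_voltage_clamp(cell, cmd, dt=dt, record_every=1)
    cur = tr.channel_currents_pA[channel.name][n_hold:]
    k0 = int(np.argmax(np.abs(cur)))
    decay = cur[k0:]
    t = np.arange(len(decay)) * dt
    c_inf = decay[-1]

    def expdec(t, a, tau):
        return c_inf + a * np.exp(-t / tau)

    (a, fast_tau), _ = curve_fit(
        expdec, t, decay, p0=[decay[0] - c_inf, 10.0], maxfev=10000
    )

    return CharacterizationCurves(
        ssi_voltage_mV=ssi_voltages,
        ssi_available=ssi,
        act_voltage_mV=act_voltages,
        act_norm_conductance=act,
        recovery_interval_ms=recovery_intervals_ms,
        recovery_fraction=rec,
        time_to_peak_ms=np.array(t_peaks),
        fast_tau_ms=float(fast_tau),
        fast_tau_voltage_mV=fast_tau_voltage_mV,
    )
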
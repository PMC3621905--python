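"""Single-compartment conductance-based membrane simulator.

The compartment is an isopotential sphere; each channel contributes an ohmic
current g_max * p_open(t) * (V - E_rev).  Synaptic background activity follows
the point-conductance model: excitatory and inhibitory conductances are
independent Ornstein-Uhlenbeck processes with fixed reversal potentials; the
OU state evolves freely but is clipped at zero when forming current, the
standard convention for this model.

Simulations are deterministic given (scenario, stimulus, dt, seed): identical
invocations produce bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from cgcell import _engine
from cgcell.kinetics import (
    ChannelSpec,
    GateSet,
    KineticScheme,
    steady_state,
    transition_matrix,
)
from cgcell.library import CalciumGatedSpec

__all__ = [
    "Compartment",
    "NoiseSpec",
    "CellScenario",
    "SimTrace",
    "StepStimulus",
    "ou_step",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "detect_spikes",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Numeric blow-up or invalid simulation setup."""


@dataclass(frozen=True)
class Compartment:
    """Spherical isopotential compartment.

    Area uses the sphere surface pi*d^2; capacitance is derived, never stored.
    The specific capacitance defaults to 0.9 uF/cm^2, which places the model
    cell's capacitance near 4.4 pF, consistent with the granule-cell membrane
    time constants the channel set was calibrated against.
    """

    diameter_um: float = 12.5
    specific_capacitance_uF_cm2: float = 0.9

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")

    @property
    def area_cm2(self) -> float:
        d_cm = self.diameter_um * 1e-4
        return math.pi * d_cm * d_cm

    @property
    def capacitance_pF(self) -> float:
        return self.specific_capacitance_uF_cm2 * self.area_cm2 * 1e6


@dataclass(frozen=True)
class NoiseSpec:
    """Point-conductance synaptic noise parameters (conductances in pS)."""

    g_e_pS: float = 0.0
    g_i_pS: float = 0.0
    sd_e_pS: float = 0.0
    sd_i_pS: float = 0.0
    tau_e_ms: float = 2.728
    tau_i_ms: float = 10.49
    e_e_mV: float = 0.0
    e_i_mV: float = -85.0

    def __post_init__(self) -> None:
        if self.sd_e_pS < 0 or self.sd_i_pS < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.tau_e_ms <= 0 or self.tau_i_ms <= 0:
            raise ValueError("noise correlation times must be > 0")


def ou_step(
    g: float, mean: float, sd: float, tau: float, dt: float, rng: np.random.Generator
) -> float:
    """One exact-discretization Ornstein-Uhlenbeck update.

    g' = mean + (g - mean) exp(-dt/tau) + sd sqrt(1 - exp(-2 dt/tau)) N(0,1).
    Negative excursions are permitted in the state; clipping to zero happens
    only where the conductance enters a current.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    e = math.exp(-dt / tau)
    return mean + (g - mean) * e + sd * math.sqrt(1.0 - e * e) * rng.standard_normal()


@dataclass(frozen=True)
class CellScenario:
    """A compartment plus a channel roster."""

    name: str
    compartment: Compartment
    channels: tuple[ChannelSpec, ...]

    def channel_g_nS(self) -> np.ndarray:
        area = self.compartment.area_cm2
        return np.array([ch.g_nS(area) for ch in self.channels])

    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def reversal_range(self) -> tuple[float, float]:
        e = [ch.e_rev_mV for ch in self.channels]
        return min(e), max(e)


@dataclass
class SimTrace:
    """Recorded simulation output on a uniform (possibly decimated) grid."""

    time_ms: np.ndarray
    vm_mV: np.ndarray
    i_inj_pA: np.ndarray
    channel_currents_pA: dict[str, np.ndarray] = field(default_factory=dict)
    open_fractions: dict[str, np.ndarray] = field(default_factory=dict)
    dt_ms: float = 0.0
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_ms": self.time_ms, "Vm_mV": self.vm_mV, "I_inj_pA": self.i_inj_pA}
        for name, cur in self.channel_currents_pA.items():
            cols[f"I_{name}_pA"] = cur
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for k in sorted(self.metadata):
                fh.write(f"# {k} = {self.metadata[k]}\n")
            self.to_dataframe().to_csv(fh, index=False)


@dataclass(frozen=True)
class StepStimulus:
    """Holding current plus one rectangular step."""

    duration_ms: float
    amplitude_pA: float = 0.0
    t_on_ms: float = 0.0
    t_off_ms: float = math.inf
    holding_pA: float = 0.0

    def build(self, dt: float) -> np.ndarray:
        n = int(round(self.duration_ms / dt))
        t = (np.arange(n) + 1) * dt
        i = np.full(n, float(self.holding_pA))
        i[(t > self.t_on_ms) & (t <= self.t_off_ms)] += self.amplitude_pA
        return i


# ---------------------------------------------------------------------------
# scenario compilation
# ---------------------------------------------------------------------------

_PROP_CACHE: dict[tuple[int, float], np.ndarray] = {}
_PROP_CACHE_REFS: list = []  # keep gate objects alive so ids stay unique


def _unit_table(gate: KineticScheme, dt: float) -> np.ndarray:
    key = (id(gate), round(dt, 9))
    tab = _PROP_CACHE.get(key)
    if tab is None:
        tab = _engine.propagator_table(
            lambda v: transition_matrix(gate, v), gate.n_states, dt
        )
        _PROP_CACHE[key] = tab
        _PROP_CACHE_REFS.append(gate)
    return tab


class _Compiled:
    """Engine-ready arrays for one (scenario, dt) pair."""

    def __init__(self, scenario: CellScenario, dt: float):
        self.scenario = scenario
        self.dt = dt
        units: list[tuple[KineticScheme, int, int]] = []  # gate, channel idx, mult
        ch_kind = []
        self.kca_idx = -1
        self.ca_src_idx = -1
        self.kca_alpha = 0.0
        self.kca_beta = 0.0
        for ci, ch in enumerate(scenario.channels):
            g = ch.gating
            if g is None:
                ch_kind.append(_engine.KIND_OHMIC)
            elif isinstance(g, KineticScheme):
                ch_kind.append(_engine.KIND_MARKOV)
                units.append((g, ci, 1))
            elif isinstance(g, GateSet):
                ch_kind.append(_engine.KIND_MARKOV)
                for gate, mult in zip(g.gates, g.multiplicities):
                    units.append((gate, ci, mult))
            elif isinstance(g, CalciumGatedSpec):
                ch_kind.append(_engine.KIND_CAGATED)
                self.kca_idx = ci
                self.kca_alpha = g.alpha_per_uM_ms
                self.kca_beta = g.beta_ms
            else:
                raise TypeError(f"unsupported gating on channel {ch.name}")
            if ch.name == "Ca":
                self.ca_src_idx = ci
        if self.kca_idx >= 0 and self.ca_src_idx < 0:
            raise SimulationError(
                "calcium-gated channel requires a Ca channel in the roster"
            )
        self.units = units
        self.n_units = len(units)
        smax = max((g.n_states for g, _, _ in units), default=1)
        self.smax = smax
        nv = int(round((_engine.V_MAX - _engine.V_MIN) / _engine.DV)) + 1
        self.props = np.zeros((self.n_units, nv, smax, smax))
        self.cond = np.zeros((self.n_units, smax))
        self.unit_n = np.array([g.n_states for g, _, _ in units], dtype=np.int64)
        self.unit_ch = np.array([ci for _, ci, _ in units], dtype=np.int64)
        self.unit_mult = np.array([m for _, _, m in units], dtype=np.int64)
        for ui, (gate, _, _) in enumerate(units):
            ns = gate.n_states
            self.props[ui, :, :ns, :ns] = _unit_table(gate, dt)
            for s in gate.conducting:
                self.cond[ui, gate.index[s]] = 1.0
        self.ch_kind = np.array(ch_kind, dtype=np.int64)
        self.ch_g = scenario.channel_g_nS()
        self.ch_e = np.array([ch.e_rev_mV for ch in scenario.channels])

    def initial_occupancies(self, v0: float) -> np.ndarray:
        p = np.zeros((self.n_units, self.smax))
        for ui, (gate, _, _) in enumerate(self.units):
            p[ui, : gate.n_states] = steady_state(gate, v0)
        return p


_COMPILED_CACHE: dict[tuple[int, float], _Compiled] = {}
_COMPILED_REFS: list = []


def compile_scenario(scenario: CellScenario, dt: float) -> _Compiled:
    key = (id(scenario), round(dt, 9))
    comp = _COMPILED_CACHE.get(key)
    if comp is None:
        comp = _Compiled(scenario, dt)
        _COMPILED_CACHE[key] = comp
        _COMPILED_REFS.append(scenario)
    return comp


def markov_observable_series(
    scheme: KineticScheme,
    vm_mV: np.ndarray,
    dt: float,
    state_mask: np.ndarray,
    p0: np.ndarray | None = None,
) -> np.ndarray:
    """Summed occupancy over ``state_mask`` while the scheme is driven along a
    voltage record (tabulated-propagator path; used for feeding recorded
    fluctuations back into a gating model)."""
    vm_mV = np.asarray(vm_mV, float)
    if p0 is None:
        p0 = steady_state(scheme, float(vm_mV[0]))
    tab = _unit_table(scheme, dt)
    return _engine.markov_observable(vm_mV, tab, p0.copy(), np.asarray(state_mask, float))


@dataclass
class SimState:
    """Carry-over state for chained simulation segments."""

    v: float
    p_state: np.ndarray
    noise_state: np.ndarray
    ca_state: np.ndarray


# calcium pool constants (submembrane shell)
_CA_REST_UM = 0.05
_CA_TAU_MS = 10.0
_CA_SHELL_DEPTH_CM = 1e-5  # 0.1 um


def _ca_conv(compartment: Compartment) -> float:
    """uM of pool calcium per pA*ms of inward calcium current."""
    shell_L = compartment.area_cm2 * _CA_SHELL_DEPTH_CM * 1e-3  # cm^3 -> L
    # pA*ms = 1e-15 C; / (2F) mol; / volume -> mol/L; * 1e6 -> uM
    return 1e-15 / (2 * 96485.0 * shell_L) * 1e6


def _run(
    scenario: CellScenario,
    dt: float,
    i_inj: np.ndarray,
    noise: NoiseSpec | None,
    seed: int | None,
    v0: float,
    state: SimState | None,
    clamp: bool,
    v_cmd: np.ndarray | None,
    record_every: int,
    record_currents: bool,
    record_open: bool,
) -> tuple[SimTrace, SimState]:
    comp = compile_scenario(scenario, dt)
    n_steps = len(v_cmd) if clamp else len(i_inj)
    if state is None:
        init_v = float(v_cmd[0]) if clamp else v0
        p_state = comp.initial_occupancies(init_v)
        noise_state = np.array(
            [noise.g_e_pS if noise else 0.0, noise.g_i_pS if noise else 0.0]
        )
        ca_state = np.array([_CA_REST_UM, 0.0])
        if comp.kca_idx >= 0:
            a = comp.kca_alpha * _CA_REST_UM
            ca_state[1] = a / (a + comp.kca_beta)
        v = init_v
    else:
        p_state = state.p_state.copy()
        noise_state = state.noise_state.copy()
        ca_state = state.ca_state.copy()
        v = state.v

    use_noise = noise is not None and (
        noise.sd_e_pS > 0 or noise.sd_i_pS > 0 or noise.g_e_pS != 0 or noise.g_i_pS != 0
    )
    if use_noise:
        rng = np.random.default_rng(seed)
        normals = rng.standard_normal((2, n_steps))
        e_fac = math.exp(-dt / noise.tau_e_ms)
        i_fac = math.exp(-dt / noise.tau_i_ms)
        e_amp = noise.sd_e_pS * math.sqrt(1 - e_fac * e_fac)
        i_amp = noise.sd_i_pS * math.sqrt(1 - i_fac * i_fac)
        ge_mean, gi_mean = noise.g_e_pS, noise.g_i_pS
        e_rev_e, e_rev_i = noise.e_e_mV, noise.e_i_mV
    else:
        normals = np.zeros((2, 0))
        e_fac = i_fac = e_amp = i_amp = 0.0
        ge_mean = gi_mean = 0.0
        e_rev_e, e_rev_i = 0.0, -85.0

    n_rec = n_steps // record_every
    rec_v = np.empty(n_rec)
    n_ch = len(scenario.channels)
    rec_i = np.empty((n_ch, n_rec)) if record_currents else np.empty((n_ch, 0))
    rec_o = np.empty((n_ch, n_rec)) if record_open else np.empty((n_ch, 0))

    n_done, v_final = _engine.run_sim(
        n_steps,
        dt,
        v,
        scenario.compartment.capacitance_pF,
        1 if clamp else 0,
        v_cmd if clamp else np.zeros(1),
        i_inj if not clamp else np.zeros(n_steps),
        comp.unit_n,
        comp.unit_ch,
        comp.unit_mult,
        comp.props,
        comp.cond,
        p_state,
        comp.ch_kind,
        comp.ch_g,
        comp.ch_e,
        comp.kca_idx,
        comp.ca_src_idx,
        comp.kca_alpha,
        comp.kca_beta,
        ca_state,
        _CA_REST_UM,
        _CA_TAU_MS,
        _ca_conv(scenario.compartment),
        use_noise,
        noise_state,
        ge_mean,
        gi_mean,
        e_fac,
        i_fac,
        e_amp,
        i_amp,
        e_rev_e,
        e_rev_i,
        normals,
        record_every,
        rec_v,
        rec_i,
        rec_o,
        record_currents,
        record_open,
    )
    if n_done < 0:
        t_fail = -n_done * dt
        raise SimulationError(
            f"{scenario.name}: membrane potential left [-200, 200] mV at "
            f"t = {t_fail:.3f} ms (V = {v_final:.1f})"
        )

    rec_dt = dt * record_every
    time = (np.arange(n_rec) + 1) * rec_dt
    if clamp:
        i_rec = np.zeros(n_rec)
        vm = v_cmd[record_every - 1 :: record_every][:n_rec].copy()
    else:
        i_rec = i_inj[record_every - 1 :: record_every][:n_rec].copy()
        vm = rec_v
    trace = SimTrace(
        time_ms=time,
        vm_mV=vm,
        i_inj_pA=i_rec,
        channel_currents_pA={
            ch.name: rec_i[ci] for ci, ch in enumerate(scenario.channels)
        }
        if record_currents
        else {},
        open_fractions={
            ch.name: rec_o[ci] for ci, ch in enumerate(scenario.channels)
        }
        if record_open
        else {},
        dt_ms=rec_dt,
        metadata={
            "scenario": scenario.name,
            "dt_ms": dt,
            "seed": seed,
            "noise": repr(noise) if noise else "none",
        },
    )
    new_state = SimState(v=v_final, p_state=p_state, noise_state=noise_state, ca_state=ca_state)
    return trace, new_state


def simulate_current_clamp(
    scenario: CellScenario,
    stimulus: StepStimulus | np.ndarray,
    noise: NoiseSpec | None = None,
    dt: float = 0.025,
    seed: int | None = None,
    v0: float = -80.0,
    state: SimState | None = None,
    record_every: int = 1,
    record_currents: bool = False,
    record_open: bool = False,
    return_state: bool = False,
):
    """Integrate C dV/dt = -sum of channel currents - synaptic noise + I_inj.

    ``stimulus`` is a :class:`StepStimulus` or a per-step injected-current
    array (pA).  Channel occupancies are co-integrated.  With ``state=None``
    gating starts at the steady state for ``v0``.
    """
    i_inj = stimulus.build(dt) if isinstance(stimulus, StepStimulus) else np.asarray(stimulus, float)
    trace, new_state = _run(
        scenario, dt, i_inj, noise, seed, v0, state,
        clamp=False, v_cmd=None, record_every=record_every,
        record_currents=record_currents, record_open=record_open,
    )
    return (trace, new_state) if return_state else trace


def simulate_voltage_clamp(
    scenario: CellScenario,
    command_mV: np.ndarray,
    dt: float = 0.025,
    state: SimState | None = None,
    record_every: int = 1,
    record_open: bool = False,
    return_state: bool = False,
):
    """Ideal voltage clamp: V follows the command exactly; per-channel and
    total currents are reported."""
    command_mV = np.asarray(command_mV, float)
    trace, new_state = _run(
        scenario, dt, np.zeros(0), None, None, float(command_mV[0]), state,
        clamp=True, v_cmd=command_mV, record_every=record_every,
        record_currents=True, record_open=record_open,
    )
    trace.channel_currents_pA["total"] = sum(
        trace.channel_currents_pA[ch.name] for ch in scenario.channels
    )
    return (trace, new_state) if return_state else trace


def detect_spikes(
    vm: np.ndarray, threshold_mV: float = -20.0, peak_min_mV: float = 0.0
) -> int:
    """Count action potentials: upward threshold crossings whose subsequent
    peak (before falling back below threshold) exceeds ``peak_min_mV``.

    The criterion is deliberately robust to noise riding on the trace.
    """
    vm = np.asarray(vm)
    above = vm > threshold_mV
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    falls = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    count = 0
    for r in rises:
        nxt = falls[falls > r]
        stop = nxt[0] if len(nxt) else len(vm)
        if vm[r:stop].max() > peak_min_mV:
            count += 1
    return count
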
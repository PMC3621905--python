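"""Subthreshold fluctuation analyses.

The central object is a :class:`FluctuationRecord`: paired, mean-subtracted
membrane-potential and A-current-inactivation fluctuation series.  Following
the offline procedure the analyses emulate, the inactivation series is
obtained by feeding a recorded membrane-potential trace back into the channel
scheme (voltage-clamp integration of the occupancy master equation), so the
same membrane record can drive either channel variant.

Analyses: RMS, one-sided Parseval-consistent power spectra, Pearson
cross-correlation of inactivation against voltage (positive lag =
inactivation follows voltage), inactivation sensitivity (SD ratio, %/mV), and
the sinusoidal frequency response of inactivation with a double-Lorentzian
fit to the high-frequency fall-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from cgcell.kinetics import ChannelSpec, KineticScheme, inactivated_fraction, steady_state
from cgcell.membrane import (
    CellScenario,
    NoiseSpec,
    detect_spikes,
    simulate_current_clamp,
)

__all__ = [
    "FluctuationRecord",
    "CrossCorrResult",
    "FrequencyResponse",
    "rms",
    "power_spectrum",
    "half_power_frequency",
    "cross_correlation",
    "inactivation_sensitivity",
    "inactivation_from_vm",
    "make_fluctuation_record",
    "frequency_response",
]


@dataclass
class FluctuationRecord:
    """Paired fluctuation series around zero (means already subtracted)."""

    dt_ms: float
    vm_fluct_mV: np.ndarray
    inact_fluct_pct: np.ndarray
    vm_mean_mV: float
    inact_mean_pct: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.vm_fluct_mV) != len(self.inact_fluct_pct):
            raise ValueError("voltage and inactivation series must have equal length")


@dataclass
class CrossCorrResult:
    lags_ms: np.ndarray
    correlation: np.ndarray
    peak: float
    peak_lag_ms: float
    decay_tau_ms: float


@dataclass
class FrequencyResponse:
    frequencies_Hz: np.ndarray
    response: np.ndarray          # normalized; -> 1 as f -> 0
    fit_ok: np.ndarray            # sine fit R^2 >= 0.9 per frequency
    corner_frequencies_Hz: tuple[float, float]
    lorentzian_amplitudes: tuple[float, float]
    half_power_Hz: float


def rms(series: np.ndarray) -> float:
    """Root-mean-square of the fluctuations around the series mean."""
    x = np.asarray(series, float)
    if x.size == 0:
        raise ValueError("empty series")
    x = x - x.mean()
    return float(np.sqrt(np.mean(x * x)))


def power_spectrum(series: np.ndarray, dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectral density of the mean-subtracted series.

    Normalization is Parseval-consistent: sum(power) * df equals the series
    variance (up to the DC bin, which is zero after mean subtraction).
    Frequencies in Hz, power in units^2/Hz.
    """
    x = np.asarray(series, float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    x = x - x.mean()
    n = x.size
    fs = 1000.0 / dt_ms  # Hz
    spec = np.fft.rfft(x)
    power = (np.abs(spec) ** 2) / (fs * n)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=dt_ms * 1e-3)
    return freqs, power


def half_power_frequency(freqs: np.ndarray, power: np.ndarray,
                         f_lo: float = 0.5, n_avg: int = 20) -> float:
    """Frequency at which the smoothed spectrum falls to half its low-frequency
    plateau; a robust summary of where a fluctuation spectrum rolls off."""
    sel = freqs > 0
    f, p = freqs[sel], power[sel]
    # log-spaced smoothing
    edges = np.geomspace(max(f_lo, f[0]), f[-1], 60)
    fm, pm = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (f >= a) & (f < b)
        if m.sum():
            fm.append(np.sqrt(a * b))
            pm.append(p[m].mean())
    fm, pm = np.array(fm), np.array(pm)
    plateau = pm[: max(3, n_avg // 4)].mean()
    below = np.flatnonzero(pm < plateau / 2)
    if below.size == 0:
        return float(fm[-1])
    return float(fm[below[0]])


def cross_correlation(record: FluctuationRecord, max_lag_ms: float) -> CrossCorrResult:
    """Pearson-normalized cross-correlation over +/- max_lag_ms.

    Positive lag means inactivation follows the membrane potential.  The decay
    time constant comes from a least-squares exponential fit to the
    correlation beyond the peak, over a window ending at the first zero
    crossing or five times the initial tau estimate, whichever is shorter.
    """
    v = record.vm_fluct_mV - record.vm_fluct_mV.mean()
    h = record.inact_fluct_pct - record.inact_fluct_pct.mean()
    n = len(v)
    max_lag = int(round(max_lag_ms / record.dt_ms))
    if max_lag >= n // 10:
        raise ValueError("max lag must be below one tenth of the record length")
    sv = v.std()
    sh = h.std()
    if sv == 0 or sh == 0:
        raise ValueError("zero-variance series")
    # biased estimator via FFT
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fv = np.fft.rfft(v, nfft)
    fh = np.fft.rfft(h, nfft)
    # R(l) = <v(t) h(t+l)>: a peak at positive l means the inactivation
    # series reproduces the voltage l milliseconds later (h follows v)
    cc = np.fft.irfft(np.conj(fv) * fh, nfft)
    full = np.concatenate([cc[-max_lag:], cc[: max_lag + 1]]) / (n * sv * sh)
    lags = np.arange(-max_lag, max_lag + 1) * record.dt_ms

    k_peak = int(np.argmax(full))
    peak = float(full[k_peak])
    peak_lag = float(lags[k_peak])

    after = full[k_peak:]
    t_after = (np.arange(len(after))) * record.dt_ms
    zero = np.flatnonzero(after <= 0)
    k_end = zero[0] if zero.size else len(after)
    # initial tau estimate: lag where correlation falls to peak/e
    drop = np.flatnonzero(after < peak / math.e)
    tau0 = t_after[drop[0]] if drop.size else t_after[min(k_end, len(after)) - 1]
    tau0 = max(tau0, record.dt_ms)
    k_end = min(k_end, int(np.ceil(5 * tau0 / record.dt_ms)) + 1, len(after))
    tt, yy = t_after[:k_end], after[:k_end]

    def expdec(t, a, tau):
        return a * np.exp(-t / tau)

    try:
        (a, tau), _ = curve_fit(expdec, tt, yy, p0=[peak, tau0], maxfev=10000)
        tau = float(abs(tau))
    except RuntimeError:  # pragma: no cover - degenerate records
        tau = float("nan")
    return CrossCorrResult(lags, full, peak, peak_lag, tau)


def inactivation_sensitivity(record: FluctuationRecord) -> float:
    """SD of the inactivation fluctuations (%) per SD of the voltage
    fluctuations (mV)."""
    sv = record.vm_fluct_mV.std()
    if sv == 0:
        raise ValueError("zero-variance membrane potential record")
    return float(record.inact_fluct_pct.std() / sv)


# ---------------------------------------------------------------------------
# building fluctuation records from simulations
# ---------------------------------------------------------------------------


def inactivation_from_vm(
    channel: ChannelSpec, vm_mV: np.ndarray, dt_ms: float
) -> np.ndarray:
    """Inactivated fraction of a channel scheme driven by a voltage record.

    The scheme starts at the steady state for the first sample, mirroring the
    offline procedure of feeding recorded fluctuations into the gating model.
    """
    scheme = channel.gating
    if not isinstance(scheme, KineticScheme):
        raise ValueError("inactivation requires a single Markov scheme channel")
    from cgcell.membrane import markov_observable_series

    mask = np.zeros(scheme.n_states)
    mask[scheme.inactivated_index] = 1.0
    return markov_observable_series(scheme, vm_mV, dt_ms, mask)


def make_fluctuation_record(
    scenario: CellScenario,
    channel: ChannelSpec,
    noise: NoiseSpec,
    duration_s: float = 120.0,
    discard_s: float = 1.0,
    seed: int | None = 0,
    dt: float = 0.025,
    record_dt: float = 0.1,
) -> FluctuationRecord:
    """Simulate a noisy scenario at rest and pair its voltage fluctuations
    with the inactivation response of ``channel`` driven by that record."""
    from cgcell.protocols import _algebraic_rest  # local import, avoids cycle

    v_rest = _algebraic_rest(scenario)
    record_every = max(1, int(round(record_dt / dt)))
    n_steps = int(round(duration_s * 1000.0 / dt))
    tr = simulate_current_clamp(
        scenario,
        np.zeros(n_steps),
        noise=noise,
        dt=dt,
        seed=seed,
        v0=v_rest,
        record_every=record_every,
    )
    n_skip = int(round(discard_s * 1000.0 / tr.dt_ms))
    vm = tr.vm_mV[n_skip:]
    if detect_spikes(vm) > 0:
        raise RuntimeError(
            f"{scenario.name}: record contains spikes; reduce noise amplitude"
        )
    inact = _inactivation_series(channel, tr.vm_mV, tr.dt_ms)[n_skip:] * 100.0
    return FluctuationRecord(
        dt_ms=tr.dt_ms,
        vm_fluct_mV=vm - vm.mean(),
        inact_fluct_pct=inact - inact.mean(),
        vm_mean_mV=float(vm.mean()),
        inact_mean_pct=float(inact.mean()),
        metadata={
            "scenario": scenario.name,
            "channel": channel.name,
            "noise": repr(noise),
            "seed": seed,
            "duration_s": duration_s,
            "discard_s": discard_s,
        },
    )


_inactivation_series = inactivation_from_vm


# ---------------------------------------------------------------------------
# frequency response
# ---------------------------------------------------------------------------


def frequency_response(
    channel: ChannelSpec,
    frequencies_Hz: np.ndarray | None = None,
    amplitude_mV: float = 5.0,
    center_mV: float = -80.0,
    dt: float = 0.025,
) -> FrequencyResponse:
    """Inactivation response to sinusoidal voltage drive, normalized to the
    quasi-static (DC) response.

    For each frequency the scheme is driven by a sine after discarding the
    longer of two full cycles or 500 ms; a sine is least-squares fitted to the
    inactivation signal, and its RMS amplitude is divided by the steady-state
    inactivation half-difference across DC offsets of +/- amplitude/sqrt(2)
    (the RMS-equivalent DC change).  The fall-off is fitted with a sum of two
    Lorentzian terms whose corner frequencies are reported in ascending order.
    """
    scheme = channel.gating
    if not isinstance(scheme, KineticScheme):
        raise ValueError("frequency response requires a single Markov scheme channel")
    if scheme.inactivated_index.size == 0:
        raise ValueError(f"{channel.name}: no inactivated states")
    if frequencies_Hz is None:
        frequencies_Hz = np.geomspace(0.25, 200.0, 15)
    frequencies_Hz = np.asarray(frequencies_Hz, float)

    # DC normalization: RMS-equivalent offset
    off = amplitude_mV / math.sqrt(2.0)
    h_hi = float(inactivated_fraction(steady_state(scheme, center_mV + off), scheme))
    h_lo = float(inactivated_fraction(steady_state(scheme, center_mV - off), scheme))
    dc_half_diff = abs(h_hi - h_lo) / 2.0
    if dc_half_diff <= 0:
        raise ValueError("degenerate DC inactivation response")

    resp = np.empty(len(frequencies_Hz))
    ok = np.ones(len(frequencies_Hz), dtype=bool)
    for i, f in enumerate(frequencies_Hz):
        period_ms = 1000.0 / f
        discard_ms = max(2 * period_ms, 500.0)
        measure_ms = max(4 * period_ms, 1000.0)
        n = int(round((discard_ms + measure_ms) / dt))
        t = (np.arange(n) + 1) * dt
        cmd = center_mV + amplitude_mV * np.sin(2 * math.pi * f * t * 1e-3)
        h = _inactivation_series(channel, cmd, dt)
        n_skip = int(round(discard_ms / dt))
        y = h[n_skip:] * 100.0
        ts = t[n_skip:] * 1e-3
        design = np.column_stack(
            [np.sin(2 * math.pi * f * ts), np.cos(2 * math.pi * f * ts), np.ones_like(ts)]
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        amp = math.hypot(coef[0], coef[1])
        pred = design @ coef
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        ok[i] = r2 >= 0.9
        resp[i] = (amp / math.sqrt(2.0)) / (dc_half_diff * 100.0)

    # double-Lorentzian fit to the fall-off (amplitude terms independent)
    f_fit = frequencies_Hz[ok]
    r_fit = resp[ok]

    def dlor(f, a1, f1, a2, f2):
        return a1 / (1 + (f / f1) ** 2) + a2 / (1 + (f / f2) ** 2)

    r0 = r_fit[0]
    # initial half-power guess
    below = np.flatnonzero(r_fit < r0 / 2)
    fhp0 = f_fit[below[0]] if below.size else f_fit[-1]
    p0 = [0.5 * r0, fhp0 / 3, 0.5 * r0, fhp0 * 3]
    bounds = ([0, 1e-3, 0, 1e-3], [2 * r0, 1e4, 2 * r0, 1e4])
    (a1, f1, a2, f2), _ = curve_fit(
        dlor, f_fit, r_fit, p0=p0, bounds=bounds, maxfev=20000
    )
    if f1 > f2:
        a1, f1, a2, f2 = a2, f2, a1, f1
    r0_fit = a1 + a2

    def model(f):
        return dlor(f, a1, f1, a2, f2)

    try:
        fhp = brentq(lambda f: model(f) - r0_fit / 2, 1e-3, 1e4)
    except ValueError:  # pragma: no cover
        fhp = float("nan")
    return FrequencyResponse(
        frequencies_Hz=frequencies_Hz,
        response=resp,
        fit_ok=ok,
        corner_frequencies_Hz=(float(f1), float(f2)),
        lorentzian_amplitudes=(float(a1), float(a2)),
        half_power_Hz=float(fhp),
    )
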
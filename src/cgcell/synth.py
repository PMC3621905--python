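"""Synthetic-data generators.

These stand in for the study's recordings so every analysis stage can be
exercised without external data: noisy block-fraction-versus-conductance
datasets with the structure assumed by the two-population pharmacology fit,
and surrogate fluctuation traces with Ornstein-Uhlenbeck statistics.  Every
generator is fully reproducible from its parameters plus a mandatory seed,
and records the ground truth in the output metadata.
"""

from __future__ import annotations

import math

import numpy as np

from cgcell.pharm_block import BlockDataset, BlockModel, predicted_block_fraction

__all__ = ["generate_block_dataset", "generate_ou_trace", "generate_sine_trace"]


def generate_block_dataset(
    p_s_truth: float,
    n_s: float,
    x_range_nS: tuple[float, float],
    noise_sd: float,
    n: int,
    seed: int,
) -> BlockDataset:
    """Resting conductances sampled uniformly across ``x_range_nS`` with
    y = P_s (x - N_s)/x + Gaussian noise."""
    if n < 3:
        raise ValueError("need n >= 3")
    lo, hi = x_range_nS
    if hi <= n_s:
        raise ValueError("x range must extend above N_s, else P_s is unidentifiable")
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, n)
    model = BlockModel(p_s_truth, n_s)
    y = predicted_block_fraction(x, model) + noise_sd * rng.standard_normal(n)
    y = np.clip(y, -0.1, 1.0)
    return BlockDataset(
        x, y,
        metadata={
            "p_s_truth": p_s_truth, "n_s": n_s, "noise_sd": noise_sd,
            "n": n, "seed": seed,
        },
    )


def generate_ou_trace(
    mean: float, sd: float, tau_ms: float, duration_ms: float, dt_ms: float, seed: int
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck surrogate series (exact discretization),
    initialized from the stationary distribution."""
    if duration_ms < 10 * tau_ms:
        raise ValueError("duration should be much longer than tau")
    n = int(round(duration_ms / dt_ms))
    rng = np.random.default_rng(seed)
    e = math.exp(-dt_ms / tau_ms)
    amp = sd * math.sqrt(1.0 - e * e)
    g0 = sd * rng.standard_normal()  # stationary start (deviation from mean)
    drive = amp * rng.standard_normal(n)
    drive[0] += e * g0
    # AR(1) recursion x[k] = e*x[k-1] + drive[k] as a linear filter
    from scipy.signal import lfilter

    dev = lfilter([1.0], [1.0, -e], drive)
    return mean + dev


def generate_sine_trace(
    center: float, amplitude: float, freq_Hz: float, duration_ms: float, dt_ms: float
) -> np.ndarray:
    """Deterministic sinusoidal command trace (mV)."""
    n = int(round(duration_ms / dt_ms))
    t = (np.arange(n) + 1) * dt_ms * 1e-3
    return center + amplitude * np.sin(2 * math.pi * freq_Hz * t)
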
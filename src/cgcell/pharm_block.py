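"""Two-population resting-conductance pharmacology model and heterologous-cell
I-V decomposition.

The resting conductance of a granule cell is treated as two populations: a
DPP6-dependent TASK-3 population (sensitivity ``P_s`` to a blocker) on top of
a DPP6-insensitive residual conductance ``N_s`` (nS).  The blocked fraction of
the total resting conductance x is then

    y(x) = P_s * (x - N_s) / x        (x > 0)

which is zero at x = N_s and saturates at P_s for large x.  ``N_s`` is fixed
(default 1.1 nS, the mean residual resting conductance after DPP6 knockdown)
and ``P_s`` is estimated by unweighted non-linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from cgcell.kinetics import ChannelSpec, GateSet, steady_state

__all__ = [
    "BlockModel",
    "BlockDataset",
    "BlockFit",
    "predicted_block_fraction",
    "fit_block_sensitivity",
    "difference_current",
    "cho_iv_model",
]

DEFAULT_NS_NS = 1.1


@dataclass(frozen=True)
class BlockModel:
    p_s: float  # blocker sensitivity of the TASK-3 population, 0..1
    n_s: float  # DPP6-insensitive resting conductance, nS

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("P_s must lie in [0, 1]")
        if self.n_s <= 0:
            raise ValueError("N_s must be > 0")


@dataclass
class BlockDataset:
    """Points of (resting conductance x in nS, blocked fraction y)."""

    x_nS: np.ndarray
    y_fraction: np.ndarray
    condition: list[str] | None = None
    y_sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_nS = np.asarray(self.x_nS, float)
        self.y_fraction = np.asarray(self.y_fraction, float)
        if self.x_nS.shape != self.y_fraction.shape:
            raise ValueError("x and y must have equal length")
        if np.any(self.x_nS <= 0):
            raise ValueError("resting conductances must be > 0")
        if np.any(self.y_fraction < -0.1) or np.any(self.y_fraction > 1.0):
            raise ValueError("blocked fractions must lie in [-0.1, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"x_nS": self.x_nS, "y_fraction": self.y_fraction})
        if self.condition is not None:
            df["condition"] = self.condition
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BlockDataset":
        df = pd.read_csv(path)
        return cls(
            df["x_nS"].to_numpy(),
            df["y_fraction"].to_numpy(),
            condition=df["condition"].tolist() if "condition" in df else None,
        )


@dataclass(frozen=True)
class BlockFit:
    p_s: float
    n_s: float
    r_squared: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r^2 cannot exceed 1")

    def summary(self) -> str:
        return (
            f"two-population block fit: P_s = {self.p_s:.4f} "
            f"(N_s fixed at {self.n_s} nS), r^2 = {self.r_squared:.4f}, "
            f"n = {len(self.residuals)}"
        )


def predicted_block_fraction(x_nS, model: BlockModel):
    """y = P_s (x - N_s) / x; domain x > 0."""
    x = np.asarray(x_nS, float)
    if np.any(x <= 0):
        raise ValueError("resting conductance must be > 0")
    y = model.p_s * (x - model.n_s) / x
    return float(y) if np.isscalar(x_nS) else y


def fit_block_sensitivity(
    data: BlockDataset, n_s: float = DEFAULT_NS_NS
) -> BlockFit:
    """One-parameter least-squares estimate of P_s with N_s fixed.

    Requires at least three points and at least one with x > N_s (otherwise
    P_s is unidentifiable, since y(N_s) = 0 regardless of P_s).
    """
    if len(data.x_nS) < 3:
        raise ValueError("need at least three points")
    if not np.any(data.x_nS > n_s):
        raise ValueError("P_s unidentifiable: no point with x > N_s")
    basis = (data.x_nS - n_s) / data.x_nS

    def resid(p):
        return p[0] * basis - data.y_fraction

    sol = least_squares(resid, x0=[0.5], bounds=([0.0], [1.0]))
    residuals = sol.fun
    ss_res = float((residuals**2).sum())
    ss_tot = float(((data.y_fraction - data.y_fraction.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BlockFit(float(sol.x[0]), float(n_s), r2, residuals)


def difference_current(iv_a: pd.DataFrame, iv_b: pd.DataFrame) -> pd.DataFrame:
    """Pointwise I-V difference (a minus b) on a shared voltage grid."""
    va = iv_a["voltage_mV"].to_numpy()
    vb = iv_b["voltage_mV"].to_numpy()
    if len(va) != len(vb) or not np.allclose(va, vb):
        raise ValueError("I-V tables must share the same voltage grid")
    out = pd.DataFrame({"voltage_mV": va})
    for col in iv_a.columns:
        if col == "voltage_mV":
            continue
        if col in iv_b.columns:
            out[col] = iv_a[col].to_numpy() - iv_b[col].to_numpy()
    label_a = iv_a.attrs.get("scenario", "a")
    label_b = iv_b.attrs.get("scenario", "b")
    out.attrs["scenario"] = f"{label_a} - {label_b}"
    return out


def _task3_p_open(gating: GateSet, v: float) -> float:
    p = 1.0
    for gate, mult in zip(gating.gates, gating.multiplicities):
        p *= float(steady_state(gate, v)[gate.conducting_index].sum()) ** mult
    return p


def cho_iv_model(
    g_l_nS: float,
    e_l_mV: float,
    g_task3_nS: float,
    voltages_mV: np.ndarray,
    task3: ChannelSpec | None = None,
    e_k_mV: float = -91.5,
) -> pd.DataFrame:
    """Heterologous-cell I-V: non-selective cationic leak plus the TASK-3
    gate model at steady state.

    I(V) = G_L (V - E_L) + G_TASK3 p_open(V) (V - E_K).
    """
    if g_l_nS < 0 or g_task3_nS < 0:
        raise ValueError("conductances must be >= 0")
    if task3 is None:
        from cgcell.library import load_channel

        task3 = load_channel("TASK3")
    gating = task3.gating
    assert isinstance(gating, GateSet)
    v = np.asarray(voltages_mV, float)
    p = np.array([_task3_p_open(gating, float(vv)) for vv in v])
    i_leak = g_l_nS * (v - e_l_mV)
    i_task3 = g_task3_nS * p * (v - e_k_mV)
    df = pd.DataFrame(
        {
            "voltage_mV": v,
            "I_leak_pA": i_leak,
            "I_TASK3_pA": i_task3,
            "I_total_pA": i_leak + i_task3,
        }
    )
    df.attrs["params"] = {"G_L_nS": g_l_nS, "E_L_mV": e_l_mV, "G_TASK3_nS": g_task3_nS}
    return df
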
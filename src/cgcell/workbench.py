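"""Scenario registry and pipeline driver.

The registry maps the study conditions onto channel rosters:

* ``Control``          -- A-current (control), TASK-3, residual K2P, Na leak,
                          plus the spiking set (Na, Ca, Kdr, KCa)
* ``mDPP6_RNAi``       -- DPP6 knockdown: residual A-current and K2P only
* ``CG_dTASK3``        -- Control minus TASK-3 (isolates the leak change)
* ``CG_ISAR``          -- Control with the A-current swapped for the
                          knockdown variant (isolates the A-current change)
* ``CHO_EGFP`` / ``CHO_TASK3`` / ``CHO_TASK3_DPP6`` -- heterologous-cell
  scenarios: a non-selective cationic leak (E_L = -16 mV) plus TASK-3.

``run_scenario`` executes one named protocol and writes result tables plus a
reproducibility manifest (full configuration, seeds, library versions, and
SHA-256 hashes of the scheme files used).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from cgcell.kinetics import ChannelSpec
from cgcell.library import LIBRARY_CHANNELS, _FILES, channel_library, scheme_dir
from cgcell.membrane import CellScenario, Compartment, NoiseSpec

__all__ = ["scenario_registry", "build_scenario", "run_scenario", "SCENARIO_NAMES"]

_SPIKING = ("Na", "Ca", "Kdr", "KCa")

#: heterologous-cell parameter sets (leak in nS, TASK-3 in nS)
CHO_PARAMS = {
    "CHO_EGFP": {"g_l_nS": 2.81, "g_task3_nS": 0.0},
    "CHO_TASK3": {"g_l_nS": 1.75, "g_task3_nS": 320.0},
    "CHO_TASK3_DPP6": {"g_l_nS": 4.25, "g_task3_nS": 840.0},
}
CHO_E_L_MV = -16.0

SCENARIO_NAMES = (
    "Control",
    "mDPP6_RNAi",
    "CG_dTASK3",
    "CG_ISAR",
    "CHO_EGFP",
    "CHO_TASK3",
    "CHO_TASK3_DPP6",
)


def _cg(lib, name: str, roster: tuple[str, ...]) -> CellScenario:
    return CellScenario(name, Compartment(), tuple(lib[c] for c in roster))


def _cho(lib, name: str) -> CellScenario:
    p = CHO_PARAMS[name]
    leak = ChannelSpec("leak_cationic", None, p["g_l_nS"], "nS", CHO_E_L_MV,
                       "non-selective cationic leak of the heterologous cell")
    task3 = dataclasses.replace(lib["TASK3"], g_max=p["g_task3_nS"])
    return CellScenario(name, Compartment(diameter_um=15.0), (leak, task3))


def scenario_registry() -> dict:
    """Named scenario builders (fresh channel specs from the shipped files)."""
    lib = channel_library()
    return {
        "Control": lambda: _cg(lib, "Control",
                               ("ISA_control", "TASK3", "K2P", "leak_Na") + _SPIKING),
        "mDPP6_RNAi": lambda: _cg(lib, "mDPP6_RNAi",
                                  ("ISA_rnai", "K2P", "leak_Na") + _SPIKING),
        "CG_dTASK3": lambda: _cg(lib, "CG_dTASK3",
                                 ("ISA_control", "K2P", "leak_Na") + _SPIKING),
        "CG_ISAR": lambda: _cg(lib, "CG_ISAR",
                               ("ISA_rnai", "TASK3", "K2P", "leak_Na") + _SPIKING),
        "CHO_EGFP": lambda: _cho(lib, "CHO_EGFP"),
        "CHO_TASK3": lambda: _cho(lib, "CHO_TASK3"),
        "CHO_TASK3_DPP6": lambda: _cho(lib, "CHO_TASK3_DPP6"),
    }


def build_scenario(name: str) -> CellScenario:
    reg = scenario_registry()
    if name not in reg:
        raise KeyError(f"unknown scenario {name!r}; valid: {', '.join(reg)}")
    return reg[name]()


PROTOCOLS = ("rest", "rin", "fc", "threshold", "iv", "noise-analysis", "freq-response")


def _scheme_hashes() -> dict[str, str]:
    out = {}
    for name in LIBRARY_CHANNELS:
        path = scheme_dir() / _FILES[name]
        out[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


def run_scenario(
    name: str,
    protocol: str,
    out_dir: str | Path,
    seed: int = 0,
    dt: float = 0.025,
    duration_s: float = 120.0,
    holding_mV: float | None = None,
    noise: NoiseSpec | None = None,
) -> dict:
    """Execute one protocol on a registered scenario and write a result bundle
    (delimited tables plus a JSON manifest) to ``out_dir``.

    Returns the manifest dictionary that was written.
    """
    import cgcell
    from cgcell import protocols as proto
    from cgcell import signal_analysis as sig

    if protocol not in PROTOCOLS:
        raise KeyError(f"unknown protocol {protocol!r}; valid: {', '.join(PROTOCOLS)}")
    scenario = build_scenario(name)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if protocol == "rest":
        results["E_rest_mV"] = proto.resting_potential(scenario, dt=dt)
    elif protocol == "rin":
        results["R_in_GOhm"] = proto.input_resistance(scenario, dt=dt)
    elif protocol == "fc":
        tau, fc, warn = proto.time_constant_and_fc(scenario, dt=dt)
        results.update({"tau_m_ms": tau, "f_c_Hz": fc, "fit_warning": warn})
    elif protocol == "threshold":
        nz = noise or NoiseSpec(10, 10, 50, 50)
        res = proto.threshold_current(
            scenario, holding_target_mV=holding_mV, noise=nz, seed=seed, dt=dt
        )
        results.update(
            {"threshold_pA": res.threshold_pA, "resolution_pA": res.resolution_pA,
             "protocol": res.protocol}
        )
    elif protocol == "iv":
        grid = np.arange(-120.0, 20.1, 5.0)
        df = proto.sustained_iv(scenario, grid, dt=dt)
        df.to_csv(out_dir / f"{name}_iv.csv", index=False)
        results["iv_table"] = f"{name}_iv.csv"
    elif protocol == "noise-analysis":
        nz = noise or NoiseSpec(25, 25, 200, 200)
        isa = next(ch for ch in scenario.channels if ch.name.startswith("ISA"))
        rec = sig.make_fluctuation_record(
            scenario, isa, nz, duration_s=duration_s, seed=seed, dt=dt
        )
        cc = sig.cross_correlation(rec, max_lag_ms=min(1500.0, duration_s * 100))
        freqs, power = sig.power_spectrum(rec.vm_fluct_mV, rec.dt_ms)
        np.savetxt(
            out_dir / f"{name}_spectrum.csv",
            np.column_stack([freqs, power]), delimiter=",",
            header="freq_Hz,power_mV2_per_Hz", comments="",
        )
        np.savetxt(
            out_dir / f"{name}_ccf.csv",
            np.column_stack([cc.lags_ms, cc.correlation]), delimiter=",",
            header="lag_ms,correlation", comments="",
        )
        results.update(
            {
                "vm_rms_mV": sig.rms(rec.vm_fluct_mV),
                "vm_mean_mV": rec.vm_mean_mV,
                "inact_mean_pct": rec.inact_mean_pct,
                "cc_peak": cc.peak,
                "cc_peak_lag_ms": cc.peak_lag_ms,
                "cc_decay_tau_ms": cc.decay_tau_ms,
                "sensitivity_pct_per_mV": sig.inactivation_sensitivity(rec),
            }
        )
    elif protocol == "freq-response":
        isa = next(ch for ch in scenario.channels if ch.name.startswith("ISA"))
        fr = sig.frequency_response(isa, dt=dt)
        np.savetxt(
            out_dir / f"{name}_freq_response.csv",
            np.column_stack([fr.frequencies_Hz, fr.response]), delimiter=",",
            header="freq_Hz,normalized_response", comments="",
        )
        results.update(
            {
                "corner_frequencies_Hz": list(fr.corner_frequencies_Hz),
                "half_power_Hz": fr.half_power_Hz,
            }
        )

    manifest = {
        "scenario": name,
        "protocol": protocol,
        "seed": seed,
        "dt_ms": dt,
        "results": results,
        "versions": {"cgcell": cgcell.__version__, "numpy": np.__version__},
        "scheme_sha256": _scheme_hashes(),
    }
    with open(out_dir / f"{name}_{protocol}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
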
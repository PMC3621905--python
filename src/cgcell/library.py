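"""Channel scheme files and the shipped channel library.

Each channel ships as one YAML document with blocks ``states`` (name, role),
``transitions`` (from, to, k0, a), ``conducting``, ``gmax``, ``gmax_units``
(``nS`` | ``S_per_cm2``), ``erev_mV`` and ``provenance``.  Multi-gate channels
(two-pore-domain leak channels, Hodgkin-Huxley style spiking conductances)
list several gates, each with an optional integer ``multiplicity``.

The calcium-activated potassium channel is the one non-voltage gate: its
single opening rate scales with submembrane calcium, so it is declared with
``kind: calcium_gated`` and handled by the membrane simulator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

from cgcell.kinetics import ChannelSpec, GateSet, KineticScheme, RateLaw

__all__ = [
    "load_channel",
    "dump_channel",
    "channel_library",
    "scheme_dir",
    "CalciumGatedSpec",
    "LIBRARY_CHANNELS",
]

#: names of the shipped channel entries
LIBRARY_CHANNELS = (
    "ISA_control",
    "ISA_rnai",
    "TASK3",
    "K2P",
    "leak_Na",
    "Na",
    "Ca",
    "Kdr",
    "KCa",
)

_FILES = {
    "ISA_control": "isa_control.yaml",
    "ISA_rnai": "isa_rnai.yaml",
    "TASK3": "task3.yaml",
    "K2P": "k2p.yaml",
    "leak_Na": "leak_na.yaml",
    "Na": "na.yaml",
    "Ca": "ca.yaml",
    "Kdr": "kdr.yaml",
    "KCa": "kca.yaml",
}


@dataclass(frozen=True)
class CalciumGatedSpec:
    """Single calcium-dependent gate: opening rate ``alpha_per_uM_ms * [Ca]``
    (per ms, [Ca] in uM) against a fixed closing rate ``beta_ms``."""

    alpha_per_uM_ms: float
    beta_ms: float


def scheme_dir() -> Path:
    return Path(importlib.resources.files("cgcell") / "schemes")


def _gate_from_dict(d: dict, default_name: str) -> KineticScheme:
    states = [(s["name"], s["role"]) for s in d["states"]]
    transitions = [
        (t["from"], t["to"], RateLaw(k0=float(t["k0"]), a=float(t["a"])))
        for t in d["transitions"]
    ]
    return KineticScheme(
        states,
        transitions,
        conducting=d.get("conducting"),
        name=d.get("name", default_name),
    )


def _gate_to_dict(g: KineticScheme) -> dict:
    return {
        "name": g.name,
        "states": [{"name": s, "role": g.roles[s]} for s in g.state_names],
        "conducting": sorted(g.conducting),
        "transitions": [
            {"from": t.source, "to": t.target, "k0": float(t.law.k0), "a": float(t.law.a)}
            for t in g.transitions
        ],
    }


def channel_from_dict(doc: dict) -> ChannelSpec:
    name = doc["name"]
    gating_doc = doc.get("gating")
    kind = None if gating_doc is None else gating_doc.get("kind", "markov")
    if kind is None or kind == "ohmic":
        gating = None
    elif kind == "markov":
        gating = _gate_from_dict(gating_doc, name)
    elif kind == "gateset":
        gates = []
        mults = []
        for gd in gating_doc["gates"]:
            gates.append(_gate_from_dict(gd, name))
            mults.append(int(gd.get("multiplicity", 1)))
        gating = GateSet(tuple(gates), tuple(mults))
    elif kind == "calcium_gated":
        gating = CalciumGatedSpec(
            alpha_per_uM_ms=float(gating_doc["alpha_per_uM_ms"]),
            beta_ms=float(gating_doc["beta_ms"]),
        )
    else:
        raise ValueError(f"{name}: unknown gating kind {kind!r}")
    return ChannelSpec(
        name=name,
        gating=gating,
        g_max=float(doc["gmax"]),
        g_max_units=doc["gmax_units"],
        e_rev_mV=float(doc["erev_mV"]),
        provenance=doc.get("provenance", ""),
    )


def channel_to_dict(spec: ChannelSpec) -> dict:
    doc: dict = {"name": spec.name}
    g = spec.gating
    if g is None:
        doc["gating"] = {"kind": "ohmic"}
    elif isinstance(g, KineticScheme):
        doc["gating"] = {"kind": "markov", **_gate_to_dict(g)}
    elif isinstance(g, GateSet):
        gates = []
        for gate, mult in zip(g.gates, g.multiplicities):
            gd = _gate_to_dict(gate)
            gd["multiplicity"] = mult
            gates.append(gd)
        doc["gating"] = {"kind": "gateset", "gates": gates}
    elif isinstance(g, CalciumGatedSpec):
        doc["gating"] = {
            "kind": "calcium_gated",
            "alpha_per_uM_ms": g.alpha_per_uM_ms,
            "beta_ms": g.beta_ms,
        }
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialize gating of type {type(g)}")
    doc["gmax"] = float(spec.g_max)
    doc["gmax_units"] = spec.g_max_units
    doc["erev_mV"] = float(spec.e_rev_mV)
    doc["provenance"] = spec.provenance
    return doc


def load_channel(name_or_path: str | Path) -> ChannelSpec:
    """Load a channel spec by library name or from an explicit YAML path."""
    path = Path(name_or_path)
    if not path.suffix:
        fname = _FILES.get(str(name_or_path))
        if fname is None:
            raise KeyError(
                f"unknown channel {name_or_path!r}; known: {', '.join(LIBRARY_CHANNELS)}"
            )
        path = scheme_dir() / fname
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return channel_from_dict(doc)


def dump_channel(spec: ChannelSpec, path: str | Path) -> None:
    """Write a channel spec as YAML; floats keep full repr precision so the
    file round-trips bit-exactly through :func:`load_channel`."""
    with open(path, "w") as fh:
        yaml.safe_dump(channel_to_dict(spec), fh, sort_keys=False, width=100)


def channel_library() -> dict[str, ChannelSpec]:
    """All shipped channels, loaded fresh from the scheme files."""
    return {name: load_channel(name) for name in LIBRARY_CHANNELS}
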
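"""Voltage-dependent Markov gating schemes.

A channel's gating is described by a :class:`KineticScheme`: a connected graph
of named states (each tagged ``closed``, ``open`` or ``inactivated``) whose
directed transitions carry an exponential rate law

    k(Em) = k0 * exp(a * Em)

with ``k0`` the rate at 0 mV (1/ms) and ``a`` the voltage dependence (1/mV).
This is the standard single-barrier (Borg-Graham / QuB style) parameterization:
a two-state gate built from two such transitions has a Boltzmann open fraction
and a bell-shaped time constant.

Channels made of several statistically independent gates (e.g. the
two-pore-domain potassium channels, or Hodgkin-Huxley style m^3 h gating) are
described by a :class:`GateSet`; the channel conducts only when every gate sits
in a conducting state, so the channel open fraction is the product of the
per-gate conducting fractions (raised to each gate's multiplicity).

Occupancy dynamics follow the master equation dp/dt = Q(Em) p where Q is the
generator matrix in the *column* convention (columns sum to zero; Q[j, i] is
the rate from state i into state j).  Integration uses the backward-Euler
propagator, which is unconditionally stable and occupancy-positive for
generator matrices; a matrix-exponential path is available as the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import scipy.linalg

__all__ = [
    "RateLaw",
    "Transition",
    "KineticScheme",
    "GateSet",
    "ChannelSpec",
    "SchemeError",
    "IntegrationError",
    "rate_at_voltage",
    "transition_matrix",
    "steady_state",
    "integrate_occupancy",
    "open_fraction",
    "inactivated_fraction",
    "check_detailed_balance",
]

# exp() argument beyond which the evaluated rate saturates instead of
# overflowing; exp(700) is close to the float64 maximum.
_EXP_CLIP = 700.0

_ROLES = ("closed", "open", "inactivated")


class SchemeError(ValueError):
    """A structurally invalid kinetic scheme."""


class IntegrationError(RuntimeError):
    """Occupancy integration failed (e.g. negative occupancy beyond tolerance)."""


@dataclass(frozen=True)
class RateLaw:
    """Exponential voltage dependence of a single transition.

    Parameters
    ----------
    k0 : float
        Rate at 0 mV, in 1/ms.  Must be non-negative.
    a : float
        Voltage-dependence exponent in 1/mV; 0 for a voltage-independent
        transition.
    """

    k0: float
    a: float = 0.0

    def __post_init__(self) -> None:
        if not (self.k0 >= 0.0 and math.isfinite(self.k0)):
            raise ValueError(f"k0 must be finite and >= 0, got {self.k0}")
        if not math.isfinite(self.a):
            raise ValueError(f"a must be finite, got {self.a}")

    def __call__(self, em_mV: float) -> float:
        return rate_at_voltage(self, em_mV)


def rate_at_voltage(law: RateLaw, em_mV: float) -> float:
    """Evaluate ``k0 * exp(a * Em)``.

    The exponent is clipped at +/-700 so extreme voltages saturate at a huge
    finite rate rather than overflowing.
    """
    x = law.a * em_mV
    if x > _EXP_CLIP:
        x = _EXP_CLIP
    elif x < -_EXP_CLIP:
        x = -_EXP_CLIP
    return law.k0 * math.exp(x)


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    law: RateLaw


class KineticScheme:
    """A connected Markov gating scheme.

    Parameters
    ----------
    states : sequence of (name, role) pairs
        Ordered states; role is one of ``closed``, ``open``, ``inactivated``.
    transitions : sequence of (source, target, RateLaw)
        Directed transitions.  Schemes are usually reversible (both directions
        present); missing reverse rates are treated as zero.
    conducting : iterable of state names, optional
        Conducting states; defaults to all states tagged ``open``.
    name : str
        Label used in error messages and provenance.
    """

    def __init__(
        self,
        states: Sequence[tuple[str, str]],
        transitions: Iterable[tuple[str, str, RateLaw]],
        conducting: Iterable[str] | None = None,
        name: str = "scheme",
    ) -> None:
        self.name = name
        self.state_names: tuple[str, ...] = tuple(s for s, _ in states)
        if len(set(self.state_names)) != len(self.state_names):
            raise SchemeError(f"{name}: duplicate state names")
        self.roles: dict[str, str] = {}
        for s, role in states:
            if role not in _ROLES:
                raise SchemeError(f"{name}: unknown role {role!r} for state {s}")
            self.roles[s] = role
        self.index = {s: i for i, s in enumerate(self.state_names)}
        self.transitions: tuple[Transition, ...] = tuple(
            Transition(src, dst, law) for src, dst, law in transitions
        )
        for t in self.transitions:
            if t.source not in self.index or t.target not in self.index:
                raise SchemeError(
                    f"{name}: transition {t.source}->{t.target} references unknown state"
                )
            if t.source == t.target:
                raise SchemeError(f"{name}: self-transition on {t.source}")
        if conducting is None:
            conducting = [s for s in self.state_names if self.roles[s] == "open"]
        self.conducting: frozenset[str] = frozenset(conducting)
        if not self.conducting <= set(self.state_names):
            raise SchemeError(f"{name}: conducting set contains unknown states")
        for s in self.conducting:
            if self.roles[s] == "inactivated":
                raise SchemeError(f"{name}: inactivated state {s} cannot conduct")
        self._check_connected()

    # -- structure ---------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def conducting_index(self) -> np.ndarray:
        return np.array([self.index[s] for s in sorted(self.conducting)], dtype=int)

    @property
    def inactivated_index(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.state_names) if self.roles[s] == "inactivated"],
            dtype=int,
        )

    def _adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {s: set() for s in self.state_names}
        for t in self.transitions:
            adj[t.source].add(t.target)
            adj[t.target].add(t.source)
        return adj

    def _check_connected(self) -> None:
        if self.n_states == 0:
            raise SchemeError(f"{self.name}: empty scheme")
        adj = self._adjacency()
        seen = {self.state_names[0]}
        stack = [self.state_names[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != self.n_states:
            missing = set(self.state_names) - seen
            raise SchemeError(f"{self.name}: scheme graph is disconnected ({missing})")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"KineticScheme({self.name!r}, {self.n_states} states, "
            f"{len(self.transitions)} transitions)"
        )


@dataclass(frozen=True)
class GateSet:
    """Statistically independent gates; all must conduct for the channel to conduct.

    ``multiplicities[i]`` identical, independent copies of gate ``i`` are
    assumed (Hodgkin-Huxley style exponents); the channel open fraction is the
    product of per-gate conducting fractions raised to their multiplicities.
    """

    gates: tuple[KineticScheme, ...]
    multiplicities: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.gates) == 0:
            raise SchemeError("GateSet requires at least one gate")
        if self.multiplicities is None:
            object.__setattr__(self, "multiplicities", (1,) * len(self.gates))
        if len(self.multiplicities) != len(self.gates):
            raise SchemeError("multiplicities must match the number of gates")
        if any(m < 1 for m in self.multiplicities):
            raise SchemeError("multiplicities must be >= 1")


Gating = Union[KineticScheme, GateSet, None]


@dataclass(frozen=True)
class ChannelSpec:
    """A gating model plus maximal conductance and reversal potential.

    ``gating=None`` denotes an always-open (ohmic) channel.  ``g_max_units``
    is ``"nS"`` for point conductances or ``"S_per_cm2"`` for densities that
    are converted through the compartment membrane area when a scenario is
    built.
    """

    name: str
    gating: Gating
    g_max: float
    g_max_units: str
    e_rev_mV: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError(f"{self.name}: g_max must be >= 0")
        if self.g_max_units not in ("nS", "S_per_cm2"):
            raise ValueError(f"{self.name}: unknown g_max unit {self.g_max_units!r}")

    def g_nS(self, area_cm2: float) -> float:
        """Absolute conductance in nS, resolving density units via the area."""
        if self.g_max_units == "nS":
            return self.g_max
        return self.g_max * area_cm2 * 1e9  # S -> nS


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def transition_matrix(scheme: KineticScheme, em_mV: float) -> np.ndarray:
    """Generator matrix Q(Em) in the column convention.

    ``Q[j, i]`` (j != i) is the rate from state i into state j; each diagonal
    entry is minus the total exit rate of its state, so every *column* sums to
    zero and dp/dt = Q p conserves total occupancy.
    """
    n = scheme.n_states
    q = np.zeros((n, n))
    for t in scheme.transitions:
        i = scheme.index[t.source]
        j = scheme.index[t.target]
        k = rate_at_voltage(t.law, em_mV)
        q[j, i] += k
        q[i, i] -= k
    return q


def steady_state(scheme: KineticScheme, em_mV: float) -> np.ndarray:
    """Stationary occupancy vector (null vector of Q, normalized to sum 1).

    Raises
    ------
    SchemeError
        If the null space is degenerate (dimension > 1), i.e. the scheme
        decomposes into non-communicating blocks at this voltage.
    """
    q = transition_matrix(scheme, em_mV)
    null = scipy.linalg.null_space(q, rcond=1e-10)
    if null.shape[1] != 1:
        raise SchemeError(
            f"{scheme.name}: degenerate stationary distribution at {em_mV} mV "
            f"(null space dimension {null.shape[1]})"
        )
    p = null[:, 0]
    p = p / p.sum()
    if p.min() < -1e-9:
        raise SchemeError(f"{scheme.name}: negative stationary occupancy at {em_mV} mV")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def _integrate_single(
    scheme: KineticScheme,
    em_trace: np.ndarray,
    p0: np.ndarray,
    dt: float,
    method: str,
) -> np.ndarray:
    n = scheme.n_states
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (n,):
        raise ValueError(f"p0 must have shape ({n},)")
    if abs(p0.sum() - 1.0) > 1e-6 or p0.min() < -1e-12:
        raise ValueError("p0 is not a valid occupancy vector")
    out = np.empty((len(em_trace), n))
    out[0] = p0
    eye = np.eye(n)
    p = p0.copy()
    # cache factorizations per voltage value: protocols use piecewise-constant
    # or slowly varying commands, so repeated voltages are the common case.
    cache: dict[float, np.ndarray] = {}
    for k in range(1, len(em_trace)):
        v = float(em_trace[k])
        prop = cache.get(v)
        if prop is None:
            q = transition_matrix(scheme, v)
            if method == "backward-euler":
                prop = np.linalg.inv(eye - dt * q)
            elif method == "expm":
                prop = scipy.linalg.expm(dt * q)
            else:
                raise ValueError(f"unknown integration method {method!r}")
            if len(cache) < 4096:
                cache[v] = prop
        p = prop @ p
        s = p.sum()
        if p.min() < -1e-6:
            raise IntegrationError(
                f"{scheme.name}: negative occupancy at step {k}; reduce dt"
            )
        p = np.clip(p, 0.0, None) / s
        out[k] = p
    return out


def integrate_occupancy(
    gating: Gating,
    em_trace: np.ndarray,
    p0: np.ndarray | Sequence[np.ndarray] | None,
    dt: float,
    method: str = "backward-euler",
):
    """Integrate the occupancy master equation along a voltage trace.

    Parameters
    ----------
    gating : KineticScheme or GateSet
        Gates of a GateSet integrate independently.
    em_trace : array of mV, one sample per time step
        ``em_trace[k]`` is the voltage over the step ending at sample k
        (backward-Euler evaluates the generator at the new time).
    p0 : occupancy vector, or list of per-gate vectors, or None
        ``None`` initializes at the steady state for ``em_trace[0]``.
    dt : ms
    method : ``"backward-euler"`` (default) or ``"expm"`` (reference).

    Returns
    -------
    ndarray (len(trace), n_states) for a scheme, or a list of such arrays for
    a GateSet.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    em_trace = np.asarray(em_trace, dtype=float)
    if isinstance(gating, GateSet):
        if p0 is None:
            p0 = [steady_state(g, float(em_trace[0])) for g in gating.gates]
        return [
            _integrate_single(g, em_trace, q0, dt, method)
            for g, q0 in zip(gating.gates, p0)
        ]
    if gating is None:
        raise ValueError("an always-open channel has no occupancy to integrate")
    if p0 is None:
        p0 = steady_state(gating, float(em_trace[0]))
    return _integrate_single(gating, em_trace, p0, dt, method)


def open_fraction(occupancy, gating: Gating):
    """Conducting fraction in [0, 1].

    For a single scheme this is the summed occupancy of conducting states; for
    a GateSet it is the product of per-gate conducting fractions raised to the
    gate multiplicities.  Accepts a single occupancy vector or a trajectory
    (time on the first axis).
    """
    if gating is None:
        return 1.0
    if isinstance(gating, GateSet):
        total = None
        for g, occ, mult in zip(gating.gates, occupancy, gating.multiplicities):
            frac = np.asarray(occ)[..., g.conducting_index].sum(axis=-1) ** mult
            total = frac if total is None else total * frac
        return total
    occ = np.asarray(occupancy)
    return occ[..., gating.conducting_index].sum(axis=-1)


def inactivated_fraction(occupancy, scheme: KineticScheme):
    """Summed occupancy of inactivated-tagged states, in [0, 1]."""
    idx = scheme.inactivated_index
    if idx.size == 0:
        raise SchemeError(f"{scheme.name}: scheme has no inactivated states")
    return np.asarray(occupancy)[..., idx].sum(axis=-1)


def _cycle_basis(scheme: KineticScheme) -> list[list[str]]:
    """Fundamental cycles (as state-name loops) from a spanning tree."""
    # undirected edge set
    edges = set()
    for t in scheme.transitions:
        edges.add(frozenset((t.source, t.target)))
    adj: dict[str, set[str]] = {s: set() for s in scheme.state_names}
    for e in edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    root = scheme.state_names[0]
    parent: dict[str, str | None] = {root: None}
    order = [root]
    tree_edges = set()
    stack = [root]
    while stack:
        u = stack.pop()
        for v in sorted(adj[u]):
            if v not in parent:
                parent[v] = u
                tree_edges.add(frozenset((u, v)))
                order.append(v)
                stack.append(v)
    cycles = []
    for e in sorted(edges - tree_edges, key=sorted):
        u, v = sorted(e)
        # path u -> root and v -> root; cycle through their meeting point
        anc_u = [u]
        while parent[anc_u[-1]] is not None:
            anc_u.append(parent[anc_u[-1]])  # type: ignore[arg-type]
        anc_set = {s: i for i, s in enumerate(anc_u)}
        path_v = [v]
        while path_v[-1] not in anc_set:
            path_v.append(parent[path_v[-1]])  # type: ignore[arg-type]
        meet = path_v[-1]
        cycle = anc_u[: anc_set[meet] + 1] + path_v[-2::-1]
        cycles.append(cycle)
    return cycles


def check_detailed_balance(scheme: KineticScheme, em_mV: float) -> dict[str, float]:
    """Detailed-balance residual per independent cycle.

    For every fundamental cycle of the scheme graph the residual is
    ``|log(product of clockwise rates) - log(product of counter-clockwise
    rates)|`` evaluated at ``em_mV``.  A zero rate anywhere on a cycle yields
    an infinite residual.  Acyclic (tree) schemes return an empty mapping.
    """
    rate_lookup: dict[tuple[str, str], float] = {}
    for t in scheme.transitions:
        rate_lookup[(t.source, t.target)] = rate_lookup.get(
            (t.source, t.target), 0.0
        ) + rate_at_voltage(t.law, em_mV)
    residuals: dict[str, float] = {}
    for cycle in _cycle_basis(scheme):
        fwd = 0.0
        rev = 0.0
        bad = False
        m = len(cycle)
        for i in range(m):
            u, v = cycle[i], cycle[(i + 1) % m]
            kf = rate_lookup.get((u, v), 0.0)
            kr = rate_lookup.get((v, u), 0.0)
            if kf <= 0.0 or kr <= 0.0:
                bad = True
                break
            fwd += math.log(kf)
            rev += math.log(kr)
        label = "-".join(cycle)
        residuals[label] = math.inf if bad else abs(fwd - rev)
    return residuals
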
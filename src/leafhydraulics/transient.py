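"""Transient solver: explicit time stepping of the capacitive network.

The dynamics follow from differentiating the per-node conservation law:
at every step the vector of potential rates ``x = d(psi)/dt`` solves the
linear system ``A·x = b``, where ``A`` is the edge Laplacian augmented
on the diagonal with the stomatal, storage and source conductances
(symmetric, positive definite), and ``b`` carries the instantaneous
conservation imbalance scaled by ``1/(C_i·Rc_i)``.  Potentials advance
by one explicit first-order (Euler) step ``psi += x·dt``; capacitor
currents are reconstructed from conservation rather than integrated, so
mass balance holds exactly at every stored state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Union

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .network import HydraulicNetwork, SourcePotential, Waveform
from .steady import (
    NetworkState,
    _branch_conductances,
    _laplacian,
    _source_terms,
    derive_state,
    solve_steady,
)

__all__ = [
    "UnsupportedNodeError",
    "StabilityWarning",
    "ExciseSource",
    "SetAtmosphere",
    "SetSource",
    "EventSchedule",
    "TransientResult",
    "assemble_transient_system",
    "step_euler",
    "simulate",
    "apply_excision",
    "set_source_waveform",
]


class UnsupportedNodeError(ValueError):
    """A node cannot be time-stepped (no storage branch)."""


class StabilityWarning(UserWarning):
    """The requested time step may exceed the explicit-stability margin."""


# --- events ----------------------------------------------------------------


@dataclass(frozen=True)
class ExciseSource:
    """Cut the leaf at the base: remove every water-source attachment."""


@dataclass(frozen=True)
class SetAtmosphere:
    """Instantly change the atmospheric potential (humidity step)."""

    psi_a: float


@dataclass(frozen=True)
class SetSource:
    """Replace the potential of every source (constant or waveform)."""

    psi_p: SourcePotential


Event = Union[ExciseSource, SetAtmosphere, SetSource]


@dataclass
class EventSchedule:
    """Time-ordered events applied at the step boundary at-or-after their time."""

    events: list[tuple[float, Event]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(t < 0 for t, _ in self.events):
            raise ValueError("event times must be >= 0")
        if sorted(t for t, _ in self.events) != [t for t, _ in self.events]:
            raise ValueError("events must be sorted by time")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class TransientResult:
    """Time series of network states plus the applied-event log.

    ``times``, ``psi_bar`` and ``E`` are aligned arrays sampled every
    ``output_every`` steps; ``states`` holds the full
    :class:`~leafhydraulics.steady.NetworkState` at those times.
    """

    times: np.ndarray
    states: list[NetworkState]
    events: list[tuple[float, Event]]
    psi_bar: np.ndarray
    E: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.times, "psi_bar_MPa": self.psi_bar, "E_mmol_m2_s": self.E}
        )

    def psi_matrix(self) -> np.ndarray:
        """Per-node potentials as a (len(times), N) array."""
        return np.vstack([s.psi for s in self.states])


# --- assembly --------------------------------------------------------------


def _storage_terms(net: HydraulicNetwork):
    """(1/Rc, 1/(C·Rc)) per node; every node needs a storage branch."""
    g_c = np.empty(net.n)
    inv_CRc = np.empty(net.n)
    for k, node in enumerate(net.nodes):
        if node.C <= 0 or math.isinf(node.Rc) or node.Rc <= 0:
            raise UnsupportedNodeError(
                f"node {node.id}: transient stepping requires C > 0 and finite "
                f"Rc > 0 (got C={node.C}, Rc={node.Rc}); give storage-free "
                "nodes a small C and finite Rc if they must be simulated"
            )
        g_c[k] = 1.0 / node.Rc
        inv_CRc[k] = 1.0 / (node.C * node.Rc)
    return g_c, inv_CRc


def assemble_transient_system(
    net: HydraulicNetwork, state: NetworkState | np.ndarray | None = None, t: float = 0.0
):
    """Assemble ``(A, b)`` for the rate system at time ``t``.

    ``A`` depends only on the network topology and resistances; ``b``
    depends on the current potentials (taken from ``state``; the
    pre-event steady state when omitted).
    """
    psi = _psi_of(net, state, t)
    dense = net.n <= 2000
    g_a = _branch_conductances(net)
    g_c, inv_CRc = _storage_terms(net)
    g_p, g_p_psi, g_p_dpsi = _source_terms(net, t)
    L = _laplacian(net, dense)
    diag = g_a + g_c + g_p
    if dense:
        A = L + np.diag(diag)
    else:
        A = (L + scipy.sparse.diags(diag)).tocsc()
    b = _rhs(psi, L, g_a, g_p, g_p_psi, g_p_dpsi, inv_CRc, net.psi_a)
    return A, b


def _rhs(psi, L, g_a, g_p, g_p_psi, g_p_dpsi, inv_CRc, psi_a):
    imbalance = -(L @ psi) + g_a * (psi_a - psi) + g_p_psi - g_p * psi
    # a time-varying source feeds d(psi_p)/dt straight into the rate balance
    return inv_CRc * imbalance + g_p_dpsi


def _psi_of(net, state, t) -> np.ndarray:
    if state is None:
        return solve_steady(net, t).psi
    if isinstance(state, NetworkState):
        return state.psi
    return np.asarray(state, dtype=float)


def _stability_timescale(net: HydraulicNetwork) -> float:
    """Smallest per-node relaxation scale C·Rc·A_ii/(A_ii − 1/Rc), seconds.

    This is the exact decay time of a node relaxing against frozen
    neighbours; neighbour coupling can shorten it by at most ~2x, so a
    step of a tenth of this scale keeps explicit Euler well inside its
    stability region.
    """
    g_a = _branch_conductances(net)
    g_c, inv_CRc = _storage_terms(net)
    g_p, _, _ = _source_terms(net)
    idx = {node.id: k for k, node in enumerate(net.nodes)}
    edge_deg = np.zeros(net.n)
    for e in net.edges:
        edge_deg[idx[e.i]] += 1.0 / e.R
        edge_deg[idx[e.j]] += 1.0 / e.R
    A_ii = edge_deg + g_a + g_c + g_p
    g_ext = A_ii - g_c
    with np.errstate(divide="ignore"):
        tau = np.where(g_ext > 0, A_ii / np.maximum(g_ext, 1e-300) / inv_CRc, np.inf)
    return float(np.min(tau))


def _check_stability(net: HydraulicNetwork, dt: float, strict: bool) -> None:
    tau = _stability_timescale(net)
    if dt > 0.1 * tau:
        msg = (
            f"time step dt={dt:g} s exceeds a tenth of the fastest nodal "
            f"relaxation scale ({tau:g} s); the explicit update may be unstable"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, StabilityWarning, stacklevel=3)


# --- stepping --------------------------------------------------------------


def step_euler(
    net: HydraulicNetwork,
    state: NetworkState,
    dt: float,
    *,
    strict_stability: bool = False,
) -> NetworkState:
    """Advance one explicit Euler step ``psi(t+dt) = psi(t) + dt·A⁻¹b``."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    _check_stability(net, dt, strict_stability)
    A, b = assemble_transient_system(net, state, state.t)
    if scipy.sparse.issparse(A):
        x = scipy.sparse.linalg.spsolve(A, b)
    else:
        x = scipy.linalg.solve(A, b, assume_a="pos")
    return derive_state(net, state.psi + x * dt, state.t + dt)


def apply_excision(net: HydraulicNetwork) -> HydraulicNetwork:
    """Return a copy with every source removed (leaf cut at the base).

    Equivalent to sending every source resistance to infinity.  Excising
    an already source-free network warns and returns it unchanged.
    """
    if not net.sources:
        warnings.warn("apply_excision: network has no source; no-op", stacklevel=2)
        return net.copy()
    out = net.copy()
    out.sources = []
    return out


def set_source_waveform(
    net: HydraulicNetwork, A: float, omega0: float, phi: float = 0.0
) -> HydraulicNetwork:
    """Return a copy whose sources oscillate as ``A·cos(omega0·t + phi)``."""
    if not net.sources:
        raise ValueError("set_source_waveform: network has no source attachment")
    out = net.copy()
    wave = Waveform(A, omega0, phi)
    out.sources = [replace(s, psi_p=wave) for s in out.sources]
    return out


def _apply_event(net: HydraulicNetwork, event: Event) -> tuple[HydraulicNetwork, bool]:
    """Apply one event; the flag says whether the matrix A changed."""
    if isinstance(event, ExciseSource):
        return apply_excision(net), True
    if isinstance(event, SetAtmosphere):
        out = net.copy()
        out.psi_a = event.psi_a
        return out, False
    if isinstance(event, SetSource):
        if not net.sources:
            raise ValueError("SetSource event on a network without sources")
        out = net.copy()
        out.sources = [replace(s, psi_p=event.psi_p) for s in out.sources]
        return out, False
    raise TypeError(f"unknown event {event!r}")


class _Factor:
    """Cached direct factorization of A (Cholesky dense / LU sparse)."""

    def __init__(self, A):
        self.sparse = scipy.sparse.issparse(A)
        if self.sparse:
            self.solve = scipy.sparse.linalg.factorized(A.tocsc())
        else:
            self._cho = scipy.linalg.cho_factor(A)
            self.solve = lambda rhs: scipy.linalg.cho_solve(self._cho, rhs)


def simulate(
    net: HydraulicNetwork,
    init: NetworkState | str | None = "steady",
    schedule: EventSchedule | Iterable[tuple[float, Event]] | None = None,
    T: float = 0.0,
    dt: float = 0.6,
    output_every: int = 1,
    *,
    strict_stability: bool = False,
) -> TransientResult:
    """Simulate the network over ``[0, T]`` with events at step boundaries.

    ``init="steady"`` starts from the pre-event steady state of ``net``.
    Events fire at the first step boundary at-or-after their scheduled
    time; potentials are continuous across events while currents may
    jump.  The default step ``dt = 0.6 s`` (0.01 min) resolves the
    slowest physiological storage branch comfortably; a stability guard
    warns when it does not.
    """
    if T <= 0:
        raise ValueError(f"T must be > 0, got {T}")
    if output_every < 1:
        raise ValueError("output_every must be >= 1")
    if schedule is None:
        schedule = EventSchedule([])
    elif not isinstance(schedule, EventSchedule):
        schedule = EventSchedule(list(schedule))
    if any(t_ev > T for t_ev, _ in schedule):
        raise ValueError("schedule contains events beyond the simulation horizon T")

    current = net.copy()
    if init is None or (isinstance(init, str) and init == "steady"):
        psi = solve_steady(current).psi
    elif isinstance(init, NetworkState):
        psi = np.array(init.psi, dtype=float)
    else:
        raise ValueError(f"init must be 'steady' or a NetworkState, got {init!r}")

    _check_stability(current, dt, strict_stability)
    n_steps = int(round(T / dt))
    pending = list(schedule)
    applied: list[tuple[float, Event]] = []
    has_waveform = any(isinstance(s.psi_p, Waveform) for s in current.sources)

    g_a = _branch_conductances(current)
    g_c, inv_CRc = _storage_terms(current)
    g_p, g_p_psi, g_p_dpsi = _source_terms(current, 0.0)
    L = _laplacian(current, current.n <= 2000)
    A = (
        L + np.diag(g_a + g_c + g_p)
        if not scipy.sparse.issparse(L)
        else (L + scipy.sparse.diags(g_a + g_c + g_p)).tocsc()
    )
    factor = _Factor(A)

    times, states = [], []
    psi_bars, Es = [], []
    for k in range(n_steps + 1):
        t = k * dt
        while pending and pending[0][0] <= t:
            t_ev, event = pending.pop(0)
            current, matrix_changed = _apply_event(current, event)
            applied.append((t, event))
            g_a = _branch_conductances(current)
            g_p, g_p_psi, g_p_dpsi = _source_terms(current, t)
            has_waveform = any(isinstance(s.psi_p, Waveform) for s in current.sources)
            if matrix_changed:
                A = (
                    L + np.diag(g_a + g_c + g_p)
                    if not scipy.sparse.issparse(L)
                    else (L + scipy.sparse.diags(g_a + g_c + g_p)).tocsc()
                )
                factor = _Factor(A)
        if has_waveform:
            _, g_p_psi, g_p_dpsi = _source_terms(current, t)
        if k % output_every == 0 or k == n_steps:
            times.append(t)
            states.append(derive_state(current, psi, t))
            psi_bars.append(states[-1].psi_bar)
            Es.append(states[-1].E)
        if k < n_steps:
            b = _rhs(psi, L, g_a, g_p, g_p_psi, g_p_dpsi, inv_CRc, current.psi_a)
            psi = psi + factor.solve(b) * dt
    return TransientResult(
        times=np.array(times),
        states=states,
        events=applied,
        psi_bar=np.array(psi_bars),
        E=np.array(Es),
    )
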
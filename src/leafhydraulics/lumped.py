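"""Lumped-element equivalent of the uniform leaf, with a stomatal extension.

The whole leaf collapses to a single circuit: source ``psi_p`` feeds the
mean xylem potential node ``psi_x`` through an effective xylem resistance
``Rx = R/3``; from ``psi_x`` a transpiration branch (``Ra``) leads to the
atmosphere and a storage branch (``Rc`` in series with capacitance ``C``)
to the reservoir.  The ``R/3`` factor is the resistance the distributed
leaky cable presents to its *mean* potential in the weak-leak limit
``R/Ra → 0``; agreement with the spatial model improves monotonically as
``Ra`` grows relative to ``R``.

The stomatal extension makes the transpiration resistance sensitive to
stored water: ``Ra(W) = Rox + s·(W0 − W)``, with ``Rox`` the constant
outside-xylem (mesophyll) floor, ``s ≥ 0`` the sensitivity, and ``W0``
the well-watered content at which stomata are fully open.  Together with
the linear capacitor ``V(W) = W/C`` this closes into a quadratic for the
steady state, and expanding the water-potential deficit in powers of the
transpiration current gives

    psi_p - psi_a = (Rx + Rox)·Ia + C·Rx·s·Ia² ,

so stomatal sensitivity caps transpiration quadratically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .network import UniformLeafParams, Waveform
from .transient import Event, EventSchedule, ExciseSource, SetAtmosphere, SetSource

__all__ = [
    "LumpedLeaf",
    "StomatalLaw",
    "LumpedSteadyState",
    "StomatalSteadyState",
    "LumpedTransientResult",
    "to_lumped",
    "lumped_steady",
    "lumped_transient",
    "stomatal_steady",
    "potential_deficit_expansion",
]


@dataclass(frozen=True)
class LumpedLeaf:
    """Single-node equivalent circuit of a whole leaf."""

    psi_p: float
    psi_a: float
    Rx: float
    Ra: float
    Rc: float
    C: float
    psi_s: float | None = None

    def __post_init__(self) -> None:
        if not (self.Rx >= 0 and self.Ra > 0 and self.Rc > 0):
            raise ValueError(
                f"need Rx >= 0, Ra > 0, Rc > 0; got Rx={self.Rx}, Ra={self.Ra}, Rc={self.Rc}"
            )
        if self.C < 0:
            raise ValueError(f"C must be >= 0, got {self.C}")


@dataclass(frozen=True)
class StomatalLaw:
    """Linear dependence of the transpiration resistance on water content.

    ``Ra(W) = Rox + s·(W0 − W)``: fully open stomata cost only the
    mesophyll floor ``Rox``; each unit of water deficit below the
    well-watered content ``W0`` adds ``s`` of resistance.
    """

    Rox: float
    s: float
    W0: float

    def __post_init__(self) -> None:
        if not self.Rox > 0:
            raise ValueError(f"Rox must be > 0, got {self.Rox}")
        if self.s < 0:
            raise ValueError(f"s must be >= 0, got {self.s}")
        if not self.W0 > 0:
            raise ValueError(f"W0 must be > 0, got {self.W0}")

    def Ra(self, W: float) -> float:
        return self.Rox + self.s * (self.W0 - W)


@dataclass
class LumpedSteadyState:
    psi_x: float
    I_x: float
    I_a: float
    I_c: float
    W: float | None


@dataclass
class StomatalSteadyState:
    psi_x: float
    I_a: float
    W: float
    Ra: float


@dataclass
class LumpedTransientResult:
    times: np.ndarray
    psi_x: np.ndarray
    I_a: np.ndarray
    I_c: np.ndarray
    events: list[tuple[float, Event]]


def to_lumped(params: UniformLeafParams) -> LumpedLeaf:
    """Collapse uniform whole-leaf parameters to the lumped circuit (Rx = R/3)."""
    if params.Rc is None or params.C is None:
        rc, c = math.inf, 0.0
    else:
        rc, c = params.Rc, params.C
    return LumpedLeaf(
        psi_p=params.psi0,
        psi_a=params.psi_a,
        Rx=params.R / 3.0,
        Ra=params.Ra,
        Rc=rc if rc != math.inf else 1.0,  # Rc unused at steady state
        C=c,
        psi_s=params.psi_s,
    )


def lumped_steady(leaf: LumpedLeaf) -> LumpedSteadyState:
    """Steady state of the lumped circuit: no capacitor current flows."""
    I = (leaf.psi_p - leaf.psi_a) / (leaf.Rx + leaf.Ra)
    psi_x = leaf.psi_a + I * leaf.Ra
    W = leaf.C * (psi_x - leaf.psi_s) if leaf.psi_s is not None else None
    return LumpedSteadyState(psi_x=psi_x, I_x=I, I_a=I, I_c=0.0, W=W)


def _segment_dynamics(leaf: LumpedLeaf, excised: bool):
    """(psi_inf, tau) of the first-order dynamics of psi_x on one segment."""
    g_p = 0.0 if excised else 1.0 / leaf.Rx if leaf.Rx > 0 else math.inf
    g_a = 1.0 / leaf.Ra
    g_c = 1.0 / leaf.Rc
    if math.isinf(g_p):  # zero xylem resistance pins psi_x to the source
        return leaf.psi_p, 0.0
    g_ext = g_p + g_a
    psi_inf = (g_p * leaf.psi_p + g_a * leaf.psi_a) / g_ext
    tau = leaf.C * leaf.Rc * (g_ext + g_c) / g_ext
    return psi_inf, tau


def lumped_transient(
    leaf: LumpedLeaf,
    init: float | str | None = "steady",
    schedule: EventSchedule | Iterable[tuple[float, Event]] | None = None,
    T: float = 0.0,
    dt: float = 0.6,
) -> LumpedTransientResult:
    """Integrate the lumped circuit over ``[0, T]``, sampling every ``dt``.

    Between events the single-state dynamics are linear with constant
    coefficients, so each segment is advanced with the exact exponential
    solution rather than a discretized update.  In the excised segment
    the time constant is exactly ``tau = C·(Rc + Ra)``.
    """
    if T <= 0:
        raise ValueError(f"T must be > 0, got {T}")
    if leaf.C <= 0:
        raise ValueError("lumped transient requires C > 0")
    if schedule is None:
        schedule = EventSchedule([])
    elif not isinstance(schedule, EventSchedule):
        schedule = EventSchedule(list(schedule))
    if any(t_ev > T for t_ev, _ in schedule):
        raise ValueError("schedule contains events beyond the simulation horizon T")

    if init is None or (isinstance(init, str) and init == "steady"):
        psi = lumped_steady(leaf).psi_x
    else:
        psi = float(init)

    current = leaf
    excised = False
    pending = list(schedule)
    applied: list[tuple[float, Event]] = []
    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    psi_x = np.empty(n_steps + 1)
    psi_inf, tau = _segment_dynamics(current, excised)
    g_p_series = np.empty(n_steps + 1)
    psi_a_series = np.empty(n_steps + 1)
    psi_p_series = np.empty(n_steps + 1)
    for k, t in enumerate(times):
        while pending and pending[0][0] <= t:
            _, event = pending.pop(0)
            if isinstance(event, ExciseSource):
                excised = True
            elif isinstance(event, SetAtmosphere):
                current = replace(current, psi_a=event.psi_a)
            elif isinstance(event, SetSource):
                if isinstance(event.psi_p, Waveform):
                    raise ValueError("lumped transient supports constant sources only")
                current = replace(current, psi_p=float(event.psi_p))
            applied.append((t, event))
            psi_inf, tau = _segment_dynamics(current, excised)
        psi_x[k] = psi
        g_p_series[k] = 0.0 if excised else 1.0 / current.Rx
        psi_a_series[k] = current.psi_a
        psi_p_series[k] = current.psi_p
        if k < n_steps:
            psi = psi_inf + (psi - psi_inf) * math.exp(-dt / tau) if tau > 0 else psi_inf
    I_a = (psi_x - psi_a_series) / current.Ra
    I_c = g_p_series * (psi_p_series - psi_x) - I_a
    return LumpedTransientResult(times=times, psi_x=psi_x, I_a=I_a, I_c=I_c, events=applied)


def stomatal_steady(leaf: LumpedLeaf, law: StomatalLaw) -> StomatalSteadyState:
    """Steady state with water-sensitive stomata.

    ``W0`` is referenced to the zero-flow state (``psi_x = psi_p``), so
    the water deficit is ``W0 − W = C·(psi_p − psi_x)`` and the steady
    condition closes into the quadratic

        s·C·D² + (Rox + Rx)·D − Rx·(psi_p − psi_a) = 0,  D = psi_p − psi_x.

    The physical root (the one continuous in ``s`` with the ``s = 0``
    solution, giving ``Ia ≥ 0`` and ``W ≤ W0``) is returned.
    """
    delta = leaf.psi_p - leaf.psi_a
    if delta < 0:
        raise ValueError(
            "no physical root: psi_a above psi_p would drive reverse flow (Ia < 0)"
        )
    a = law.s * leaf.C
    b = law.Rox + leaf.Rx
    c = -leaf.Rx * delta
    if a == 0:
        D = -c / b
    else:
        disc = b * b - 4 * a * c  # c <= 0 so disc >= b² > 0
        D = (-b + math.sqrt(disc)) / (2 * a)
    psi_x = leaf.psi_p - D
    W = law.W0 - leaf.C * D
    Ra = law.Ra(W)
    I_a = D / leaf.Rx if leaf.Rx > 0 else (psi_x - leaf.psi_a) / Ra
    # residual check: both branch expressions for Ia must agree
    if abs(I_a * Ra - (psi_x - leaf.psi_a)) > 1e-10 * max(1.0, abs(delta)):
        raise ValueError("no consistent physical root found")
    return StomatalSteadyState(psi_x=psi_x, I_a=I_a, W=W, Ra=Ra)


def potential_deficit_expansion(leaf: LumpedLeaf, law: StomatalLaw) -> tuple[float, float]:
    """Exact series coefficients of ``psi_p − psi_a`` in powers of ``Ia``.

    Returns ``(linear, quadratic) = (Rx + Rox, C·Rx·s)``: substituting
    the steady water content into the stomatal law makes the deficit a
    polynomial ``(Rx+Rox)·Ia + C·Rx·s·Ia²`` with no higher terms.
    """
    return leaf.Rx + law.Rox, leaf.C * leaf.Rx * law.s
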
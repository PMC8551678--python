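"""Steady-state solver for capacitive hydraulic networks.

At steady state no current flows into the capacitors, so the storage
branches drop out entirely and the node potentials solve the linear
system ``B·psi = a``: ``B`` is the weighted graph Laplacian of the xylem
edges augmented on the diagonal by the stomatal conductances ``1/Ra``
(and source conductances ``1/Rp`` where a source attaches), and ``a``
collects the boundary injections ``psi_a/Ra`` and ``psi_p/Rp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .network import HydraulicNetwork

__all__ = [
    "NetworkState",
    "SingularSystemError",
    "assemble_steady_system",
    "solve_steady",
    "derive_state",
    "DENSE_LIMIT",
]

#: networks up to this many nodes are solved with dense symmetric LAPACK
#: routines; larger ones fall back to a sparse direct factorization.
DENSE_LIMIT = 2000


class SingularSystemError(RuntimeError):
    """The steady-state system has no unique solution (floating network)."""


@dataclass
class NetworkState:
    """Node potentials at one instant plus every derived current.

    ``I_edge[k]`` is the signed current through ``net.edges[k]``, oriented
    from endpoint ``i`` to ``j`` (base→tip on chains).  ``I_a`` and ``I_c``
    are the per-node stomatal and capacitor-charging currents, ``I_source``
    the per-source influx.  ``E = sum(I_a)`` is the total transpiration,
    ``psi_bar`` the unweighted mean node potential.  Capacitor voltages
    ``V`` are reported relative to ``psi_s`` (taken as 0 when unset);
    stored water ``W = C·V`` is reported only when ``psi_s`` is set.
    """

    t: float
    psi: np.ndarray
    I_edge: np.ndarray
    I_a: np.ndarray
    I_c: np.ndarray
    I_source: np.ndarray
    E: float
    psi_bar: float
    V: np.ndarray
    W: np.ndarray | None = None


def _branch_conductances(net: HydraulicNetwork):
    """Per-node stomatal conductance 1/Ra (inf resistance → 0 conductance)."""
    g_a = np.array([0.0 if math.isinf(n.Ra) else 1.0 / n.Ra for n in net.nodes])
    return g_a


def _laplacian(net: HydraulicNetwork, dense: bool):
    """Weighted Laplacian of the xylem edges in node-index space."""
    n = net.n
    idx = {node.id: k for k, node in enumerate(net.nodes)}
    if dense:
        L = np.zeros((n, n))
        for e in net.edges:
            g = 1.0 / e.R
            a, b = idx[e.i], idx[e.j]
            L[a, a] += g
            L[b, b] += g
            L[a, b] -= g
            L[b, a] -= g
        return L
    rows, cols, vals = [], [], []
    for e in net.edges:
        g = 1.0 / e.R
        a, b = idx[e.i], idx[e.j]
        rows += [a, b, a, b]
        cols += [a, b, b, a]
        vals += [g, g, -g, -g]
    return scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n)
    )


def _source_terms(net: HydraulicNetwork, t: float = 0.0):
    """(g_p, g_p·psi_p(t), g_p·dpsi_p/dt(t)) as length-n node vectors."""
    n = net.n
    idx = {node.id: k for k, node in enumerate(net.nodes)}
    g_p = np.zeros(n)
    g_p_psi = np.zeros(n)
    g_p_dpsi = np.zeros(n)
    for s in net.sources:
        k = idx[s.node]
        g = 1.0 / s.Rp
        g_p[k] += g
        g_p_psi[k] += g * s.potential(t)
        g_p_dpsi[k] += g * s.potential_rate(t)
    return g_p, g_p_psi, g_p_dpsi


def assemble_steady_system(net: HydraulicNetwork, t: float = 0.0):
    """Assemble ``(B, a)`` with ``B`` symmetric; waveform sources are frozen at ``t``.

    Raises :class:`SingularSystemError` when the network is floating: no
    source anywhere and every stomatal branch closed leaves the potential
    level undetermined.
    """
    dense = net.n <= DENSE_LIMIT
    g_a = _branch_conductances(net)
    g_p, g_p_psi, _ = _source_terms(net, t)
    if not net.sources and not np.any(g_a > 0):
        raise SingularSystemError(
            "network is floating: no water source attached and all stomata "
            "closed (every Ra infinite), so potentials are undetermined"
        )
    L = _laplacian(net, dense)
    diag = g_a + g_p
    if dense:
        B = L + np.diag(diag)
    else:
        B = (L + scipy.sparse.diags(diag)).tocsc()
    a = g_a * net.psi_a + g_p_psi
    return B, a


def solve_steady(net: HydraulicNetwork, t: float = 0.0) -> NetworkState:
    """Solve the steady state exactly (direct method) and derive all currents.

    The returned state has every capacitor current zero and satisfies
    per-node mass conservation to the direct-solver round-off.
    """
    B, a = assemble_steady_system(net, t)
    if scipy.sparse.issparse(B):
        psi = scipy.sparse.linalg.spsolve(B, a)
    else:
        try:
            psi = scipy.linalg.solve(B, a, assume_a="sym")
        except scipy.linalg.LinAlgError as exc:
            raise SingularSystemError(
                "steady-state system is singular: a network component has "
                "neither a source nor a finite Ra to pin its potential"
            ) from exc
    if not np.all(np.isfinite(psi)):
        raise SingularSystemError(
            "steady-state solve produced non-finite potentials: a network "
            "component has neither a source nor a finite Ra"
        )
    state = derive_state(net, psi, t)
    # at steady state the capacitor currents vanish identically
    state.I_c = np.zeros(net.n)
    return state


def derive_state(net: HydraulicNetwork, psi, t: float = 0.0) -> NetworkState:
    """Build a fully consistent :class:`NetworkState` from a potential field.

    Edge and stomatal currents follow Ohm's law; the capacitor currents
    are reconstructed from per-node conservation (net inflow minus
    stomatal loss), so mass balance holds exactly by construction.
    """
    psi = np.asarray(psi, dtype=float)
    if psi.shape != (net.n,):
        raise ValueError(f"psi has shape {psi.shape}, expected ({net.n},)")
    idx = {node.id: k for k, node in enumerate(net.nodes)}
    g_a = _branch_conductances(net)
    I_a = g_a * (psi - net.psi_a)
    I_edge = np.empty(len(net.edges))
    inflow = np.zeros(net.n)
    for k, e in enumerate(net.edges):
        a, b = idx[e.i], idx[e.j]
        I_edge[k] = (psi[a] - psi[b]) / e.R
        inflow[b] += I_edge[k]
        inflow[a] -= I_edge[k]
    I_source = np.empty(len(net.sources))
    for k, s in enumerate(net.sources):
        I_source[k] = (s.potential(t) - psi[idx[s.node]]) / s.Rp
        inflow[idx[s.node]] += I_source[k]
    I_c = inflow - I_a
    Rc = np.array([node.Rc for node in net.nodes])
    psi_s = net.psi_s if net.psi_s is not None else 0.0
    # V_i = psi_i - psi_s - Rc_i * I_c_i; with no storage path (Rc=inf) the
    # reconstructed I_c is 0 and the product is taken as 0.
    drop = np.where(np.isinf(Rc), 0.0, Rc) * I_c
    V = psi - psi_s - drop
    C = np.array([node.C for node in net.nodes])
    W = C * V if net.psi_s is not None else None
    return NetworkState(
        t=t,
        psi=psi,
        I_edge=I_edge,
        I_a=I_a,
        I_c=I_c,
        I_source=I_source,
        E=float(np.sum(I_a)),
        psi_bar=float(np.mean(psi)),
        V=V,
        W=W,
    )
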
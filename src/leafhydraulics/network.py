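"""Domain types and constructors for leaf hydraulic networks.

A leaf is modelled as an electrical-circuit analog: xylem segments are
resistors between nodes, each node leaks to the atmosphere through a
xylem-to-air resistance ``Ra`` (mesophyll + stomata), and stores water in
a linear capacitor ``C`` behind a xylem-to-capacitor resistance ``Rc``.
Water potential (MPa) plays the role of voltage, water flux
(mmol·m⁻²·s⁻¹) the role of current.

Closed stomata are represented by ``Ra = inf`` (zero conductance), never
by removing the branch, so the transpiration current degenerates cleanly
to zero.

Chains are discretized cell-centered: node ``i`` (1-based) sits at the
midpoint ``x = (i - 1/2)/N`` of its cell, the water source at ``x = 0``
connects to node 1 through half a cell of xylem, and adjacent nodes are
separated by one full cell.  This finite-volume placement makes node
potentials, their mean, and the base influx second-order accurate in
``1/N`` against the continuum cable solution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import networkx as nx

__all__ = [
    "Waveform",
    "NodeSpec",
    "EdgeSpec",
    "SourceAttachment",
    "HydraulicNetwork",
    "UniformLeafParams",
    "NetworkValidationError",
    "NetworkParseError",
    "build_uniform_chain",
    "build_heterogeneous_chain",
    "build_grid_network",
    "validate_network",
    "read_network",
    "write_network",
]


class NetworkValidationError(ValueError):
    """An invalid network was supplied where a valid one is required."""


class NetworkParseError(ValueError):
    """A network file does not conform to the JSON schema."""


@dataclass(frozen=True)
class Waveform:
    """Oscillating source potential ``psi_p(t) = A·cos(omega0·t + phi)``.

    Parameters are the amplitude ``A`` (MPa), angular frequency ``omega0``
    (rad·s⁻¹) and phase ``phi`` (rad).
    """

    A: float
    omega0: float
    phi: float = 0.0

    def value(self, t: float) -> float:
        return self.A * math.cos(self.omega0 * t + self.phi)

    def derivative(self, t: float) -> float:
        return -self.A * self.omega0 * math.sin(self.omega0 * t + self.phi)


SourcePotential = Union[float, Waveform]


@dataclass(frozen=True)
class NodeSpec:
    """One xylem node with its stomatal and storage branches.

    ``Ra``: xylem-to-atmosphere resistance, MPa·m²·s·mmol⁻¹ (``inf`` =
    closed stomata).  ``Rc``: xylem-to-capacitor resistance, same units
    (``inf`` = no storage pathway).  ``C``: storage capacitance,
    mmol·m⁻²·MPa⁻¹.
    """

    id: int
    Ra: float
    Rc: float = math.inf
    C: float = 0.0


@dataclass(frozen=True)
class EdgeSpec:
    """A xylem segment of resistance ``R`` between nodes ``i`` and ``j``."""

    i: int
    j: int
    R: float


@dataclass(frozen=True)
class SourceAttachment:
    """A water source of potential ``psi_p`` feeding ``node`` through ``Rp``."""

    node: int
    psi_p: SourcePotential
    Rp: float

    def potential(self, t: float = 0.0) -> float:
        if isinstance(self.psi_p, Waveform):
            return self.psi_p.value(t)
        return self.psi_p

    def potential_rate(self, t: float = 0.0) -> float:
        if isinstance(self.psi_p, Waveform):
            return self.psi_p.derivative(t)
        return 0.0


@dataclass
class HydraulicNetwork:
    """A capacitive hydraulic network: nodes, xylem edges, sources, atmosphere.

    ``psi_a`` is the atmospheric water potential (MPa, ≤ 0), shared by all
    stomatal branches.  ``psi_s`` is the baseline osmotic potential of the
    water storage; it shifts reported capacitor voltages and stored water
    only and never enters the dynamics, so it is optional.
    """

    nodes: list[NodeSpec]
    edges: list[EdgeSpec]
    sources: list[SourceAttachment]
    psi_a: float
    psi_s: float | None = None

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[int]:
        return [node.id for node in self.nodes]

    def index_of(self, node_id: int) -> int:
        return self._index[node_id]

    @property
    def _index(self) -> dict[int, int]:
        return {node.id: k for k, node in enumerate(self.nodes)}

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((e.i, e.j) for e in self.edges)
        return g

    def copy(self) -> "HydraulicNetwork":
        return replace(
            self,
            nodes=list(self.nodes),
            edges=list(self.edges),
            sources=list(self.sources),
        )


@dataclass(frozen=True)
class UniformLeafParams:
    """Whole-leaf combined parameters of the uniform one-dimensional leaf.

    ``R`` is the total xylem resistance, ``Ra``/``Rc`` the whole-leaf
    xylem-to-air and xylem-to-capacitor resistances, ``C`` the whole-leaf
    capacitance.  Discretizing into ``N`` nodes uses the combined-parameter
    mapping ``R_per_edge = R/N``, ``Ra_per_node = N·Ra``,
    ``Rc_per_node = N·Rc``, ``C_per_node = C/N``: resistances in series
    along the xylem add, while the stomatal/storage branches sit in
    parallel across nodes.
    """

    N: int
    R: float
    Ra: float
    psi0: float
    psi_a: float
    Rc: float | None = None
    C: float | None = None
    psi_s: float | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise NetworkValidationError(f"N must be >= 1, got {self.N}")
        if not self.R > 0:
            raise NetworkValidationError(f"R must be > 0, got {self.R}")
        if not self.Ra > 0:
            raise NetworkValidationError(f"Ra must be > 0, got {self.Ra}")
        if self.Rc is not None and not self.Rc > 0:
            raise NetworkValidationError(f"Rc must be > 0, got {self.Rc}")
        if self.C is not None and self.C < 0:
            raise NetworkValidationError(f"C must be >= 0, got {self.C}")

    # per-node quantities under the N-scaling
    @property
    def R_per_edge(self) -> float:
        return self.R / self.N

    @property
    def Ra_per_node(self) -> float:
        return self.N * self.Ra

    @property
    def Rc_per_node(self) -> float:
        return math.inf if self.Rc is None else self.N * self.Rc

    @property
    def C_per_node(self) -> float:
        return 0.0 if self.C is None else self.C / self.N

    def positions(self) -> list[float]:
        """Normalized cell-midpoint positions x = (i - 1/2)/N, i = 1..N."""
        return [(i - 0.5) / self.N for i in range(1, self.N + 1)]


def build_uniform_chain(
    params: UniformLeafParams, source_R: float | None = None
) -> HydraulicNetwork:
    """Discretize the uniform leaf into an N-node chain from base to tip.

    Cell-centered: the source ``psi0`` at the base connects to node 1
    through half a cell of xylem (``Rp = R/(2N)``, overridable via
    ``source_R``); adjacent nodes are one full cell apart (``R/N``); the
    terminal node is sealed (no onward edge), so all water leaves through
    stomata or into storage.
    """
    n = params.N
    nodes = [
        NodeSpec(i, params.Ra_per_node, params.Rc_per_node, params.C_per_node)
        for i in range(1, n + 1)
    ]
    edges = [EdgeSpec(i, i + 1, params.R_per_edge) for i in range(1, n)]
    Rp = params.R_per_edge / 2.0 if source_R is None else source_R
    sources = [SourceAttachment(1, params.psi0, Rp)]
    return HydraulicNetwork(nodes, edges, sources, params.psi_a, params.psi_s)


def build_heterogeneous_chain(
    Ra: Sequence[float],
    Rc: Sequence[float],
    C: Sequence[float],
    cell_R: Sequence[float],
    psi0: float,
    psi_a: float,
    psi_s: float | None = None,
) -> HydraulicNetwork:
    """Chain with node-specific branch parameters and cell xylem resistances.

    ``cell_R[i]`` is the xylem resistance of the cell around node ``i+1``;
    neighbouring nodes are connected through the two adjoining half-cells
    (``(cell_R[i] + cell_R[i+1])/2``) and the source through the first
    half-cell, exactly as in :func:`build_uniform_chain`.  All tables
    must have the same length N.
    """
    n = len(Ra)
    if not (len(Rc) == len(C) == len(cell_R) == n):
        raise NetworkValidationError(
            "per-node tables must have equal lengths, got "
            f"Ra={len(Ra)}, Rc={len(Rc)}, C={len(C)}, cell_R={len(cell_R)}"
        )
    if n == 0:
        raise NetworkValidationError("chain must have at least one node")
    nodes = [NodeSpec(i + 1, Ra[i], Rc[i], C[i]) for i in range(n)]
    edges = [
        EdgeSpec(i, i + 1, (cell_R[i - 1] + cell_R[i]) / 2.0) for i in range(1, n)
    ]
    sources = [SourceAttachment(1, psi0, cell_R[0] / 2.0)]
    net = HydraulicNetwork(nodes, edges, sources, psi_a, psi_s)
    _raise_on_violations(net)
    return net


def build_grid_network(
    rows: int,
    cols: int,
    edge_R: float,
    node_params: NodeSpec | dict,
    psi0: float,
    psi_a: float,
    Rp: float | None = None,
    psi_s: float | None = None,
) -> HydraulicNetwork:
    """A rows×cols lattice (with loops) fed by a source along its left edge.

    Every node of the first column is attached to the source ``psi0``
    through ``Rp`` (default: half a lattice segment, ``edge_R/2``, the
    cell-centered convention).  With ``rows=1`` this reduces exactly to
    the uniform chain.  ``node_params`` gives the shared per-node
    ``Ra``/``Rc``/``C``.
    """
    if rows < 1 or cols < 1:
        raise NetworkValidationError(f"grid must be non-empty, got {rows}x{cols}")
    if isinstance(node_params, dict):
        Ra = node_params["Ra"]
        Rc = node_params.get("Rc", math.inf)
        C = node_params.get("C", 0.0)
    else:
        Ra, Rc, C = node_params.Ra, node_params.Rc, node_params.C
    if Rp is None:
        Rp = edge_R / 2.0

    def nid(r: int, c: int) -> int:
        return r * cols + c + 1

    nodes = [NodeSpec(nid(r, c), Ra, Rc, C) for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append(EdgeSpec(nid(r, c), nid(r, c + 1), edge_R))
            if r + 1 < rows:
                edges.append(EdgeSpec(nid(r, c), nid(r + 1, c), edge_R))
    sources = [SourceAttachment(nid(r, 0), psi0, Rp) for r in range(rows)]
    return HydraulicNetwork(nodes, edges, sources, psi_a, psi_s)


def validate_network(net: HydraulicNetwork) -> list[str]:
    """Return a list of violation messages; an empty list means valid."""
    violations: list[str] = []
    ids = net.node_ids
    seen: set[int] = set()
    for node_id in ids:
        if node_id in seen:
            violations.append(f"duplicate node id {node_id}")
        seen.add(node_id)
    for node in net.nodes:
        if not node.Ra > 0:
            violations.append(f"node {node.id}: Ra must be > 0, got {node.Ra}")
        if not node.Rc > 0:
            violations.append(f"node {node.id}: Rc must be > 0, got {node.Rc}")
        if node.C < 0 or math.isnan(node.C):
            violations.append(f"node {node.id}: C must be >= 0, got {node.C}")
    edge_keys: set[tuple[int, int]] = set()
    for e in net.edges:
        if e.i == e.j:
            violations.append(f"edge ({e.i},{e.j}): self-loop")
        if e.i not in seen or e.j not in seen:
            violations.append(f"edge ({e.i},{e.j}): unknown endpoint")
        key = (min(e.i, e.j), max(e.i, e.j))
        if key in edge_keys:
            violations.append(f"edge ({e.i},{e.j}): duplicate edge")
        edge_keys.add(key)
        if not (e.R > 0) or math.isinf(e.R):
            violations.append(f"edge ({e.i},{e.j}): R must be finite > 0, got {e.R}")
    for s in net.sources:
        if s.node not in seen:
            violations.append(f"source at node {s.node}: unknown node")
        if not s.Rp > 0:
            violations.append(f"source at node {s.node}: Rp must be > 0, got {s.Rp}")
    if net.psi_a > 0:
        violations.append(f"psi_a must be <= 0, got {net.psi_a}")
    if net.nodes and not nx.is_connected(net.graph()):
        violations.append("disconnected: network graph has more than one component")
    return violations


def _raise_on_violations(net: HydraulicNetwork) -> None:
    violations = validate_network(net)
    if violations:
        raise NetworkValidationError("; ".join(violations))


# ---------------------------------------------------------------------------
# JSON serialization.  Infinite resistances round-trip as the string "inf".

_UNITS = {
    "potential": "MPa",
    "flux": "mmol·m⁻²·s⁻¹",
    "resistance": "MPa·m²·s·mmol⁻¹",
    "capacitance": "mmol·m⁻²·MPa⁻¹",
    "time": "s",
}


def _num_out(x: float):
    return "inf" if math.isinf(x) else x


def _num_in(x, where: str) -> float:
    if x == "inf":
        return math.inf
    if isinstance(x, (int, float)) and not isinstance(x, bool):
        return float(x)
    raise NetworkParseError(f"{where}: expected a number or 'inf', got {x!r}")


def write_network(net: HydraulicNetwork, path: str | Path) -> None:
    """Serialize a network to the documented JSON schema."""
    doc = {
        "nodes": [
            {"id": n.id, "Ra": _num_out(n.Ra), "Rc": _num_out(n.Rc), "C": n.C}
            for n in net.nodes
        ],
        "edges": [{"i": e.i, "j": e.j, "R": e.R} for e in net.edges],
        "sources": [_source_out(s) for s in net.sources],
        "psi_a": net.psi_a,
        "units": _UNITS,
    }
    if net.psi_s is not None:
        doc["psi_s"] = net.psi_s
    Path(path).write_text(json.dumps(doc, indent=1, ensure_ascii=False))


def _source_out(s: SourceAttachment) -> dict:
    out: dict = {"node": s.node, "Rp": _num_out(s.Rp)}
    if isinstance(s.psi_p, Waveform):
        out["waveform"] = {"A": s.psi_p.A, "omega0": s.psi_p.omega0, "phi": s.psi_p.phi}
    else:
        out["psi_p"] = s.psi_p
    return out


def read_network(path: str | Path) -> HydraulicNetwork:
    """Parse a network JSON file, naming the offending field on error."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkParseError(f"invalid JSON: {exc}") from exc
    for key in ("nodes", "edges", "sources", "psi_a"):
        if key not in doc:
            raise NetworkParseError(f"missing required key '{key}'")
    nodes = []
    for k, nd in enumerate(doc["nodes"]):
        where = f"nodes[{k}]"
        try:
            nodes.append(
                NodeSpec(
                    id=int(nd["id"]),
                    Ra=_num_in(nd["Ra"], f"{where}.Ra"),
                    Rc=_num_in(nd.get("Rc", "inf"), f"{where}.Rc"),
                    C=float(nd.get("C", 0.0)),
                )
            )
        except KeyError as exc:
            raise NetworkParseError(f"{where}: missing field {exc}") from exc
    edges = []
    for k, ed in enumerate(doc["edges"]):
        where = f"edges[{k}]"
        try:
            edges.append(EdgeSpec(int(ed["i"]), int(ed["j"]), _num_in(ed["R"], f"{where}.R")))
        except KeyError as exc:
            raise NetworkParseError(f"{where}: missing field {exc}") from exc
    sources = []
    for k, sd in enumerate(doc["sources"]):
        where = f"sources[{k}]"
        if "node" not in sd:
            raise NetworkParseError(f"{where}: missing field 'node'")
        if "waveform" in sd:
            wf = sd["waveform"]
            for fieldname in ("A", "omega0"):
                if fieldname not in wf:
                    raise NetworkParseError(f"{where}.waveform: missing field '{fieldname}'")
            psi_p: SourcePotential = Waveform(
                float(wf["A"]), float(wf["omega0"]), float(wf.get("phi", 0.0))
            )
        elif "psi_p" in sd:
            psi_p = _num_in(sd["psi_p"], f"{where}.psi_p")
        else:
            raise NetworkParseError(f"{where}: needs either 'psi_p' or 'waveform'")
        if "Rp" not in sd:
            raise NetworkParseError(f"{where}: missing field 'Rp'")
        sources.append(SourceAttachment(int(sd["node"]), psi_p, _num_in(sd["Rp"], f"{where}.Rp")))
    psi_a = _num_in(doc["psi_a"], "psi_a")
    psi_s = float(doc["psi_s"]) if "psi_s" in doc else None
    return HydraulicNetwork(nodes, edges, sources, psi_a, psi_s)
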
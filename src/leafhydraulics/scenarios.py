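"""Scenario engine: canned numerical experiments on the uniform model leaf.

Four scenarios cover the standard questions asked of the model:

``steady_state``
    Well-watered steady state: the base-to-tip potential profile, its
    mean, and the total transpiration rate, with the continuum closed
    form overlaid.
``excision``
    Cut the leaf at the base at t = 0 and follow the exponential
    dehydration, fitting the decay constant and comparing it with the
    closed-form ``tau = C·(Rc + Ra)``.
``humidity_step``
    Instantly change the atmospheric potential at t = 0 from the
    well-watered steady state and follow mean potential and
    transpiration to their new steady values.
``spatial_snapshots``
    Same forcing as ``humidity_step`` but recording full spatial
    profiles at chosen times plus the stress front x*(t), the basal-most
    position where the local potential falls below a damage threshold.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .analytic import ContinuousLeaf, excised_decay, fit_exponential, time_constant_excised
from .network import HydraulicNetwork, UniformLeafParams, build_uniform_chain
from .steady import solve_steady
from .transient import EventSchedule, ExciseSource, SetAtmosphere, simulate

__all__ = [
    "ScenarioSpec",
    "ScenarioReport",
    "run_scenario",
    "stress_front",
    "chain_positions",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("steady_state", "excision", "humidity_step", "spatial_snapshots")

#: default damage threshold below which leaf tissue is considered severely
#: water-stressed, MPa
STRESS_THRESHOLD = -2.5


@dataclass
class ScenarioSpec:
    """Everything needed to run one scenario.

    ``dt`` is the simulation step (s, default 0.6 = 0.01 min), ``T`` the
    horizon (s; scenario-specific default when None), ``theta`` the
    stress threshold (MPa, < 0), ``psi_a_new`` the post-step atmospheric
    potential for the humidity scenarios.
    """

    name: str
    params: UniformLeafParams
    psi_a_new: float | None = None
    excision_time: float = 0.0
    dt: float = 0.6
    T: float | None = None
    output_every: int = 10
    snapshot_times: Sequence[float] = field(default_factory=tuple)
    theta: float = STRESS_THRESHOLD

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}")
        if not self.theta < 0:
            raise ValueError(f"stress threshold theta must be < 0, got {self.theta}")
        if self.name in ("humidity_step", "spatial_snapshots") and self.psi_a_new is None:
            raise ValueError(f"scenario {self.name!r} requires psi_a_new")
        if self.T is not None and self.snapshot_times:
            if any(t < 0 or t > self.T for t in self.snapshot_times):
                raise ValueError("snapshot times must lie within [0, T]")

    @classmethod
    def from_config(cls, cfg: dict) -> "ScenarioSpec":
        """Build a spec from a flat JSON config mirroring the whole-leaf keys."""
        params = UniformLeafParams(
            N=int(cfg.get("N", 100)),
            R=float(cfg["R"]),
            Ra=float(cfg["Ra"]),
            psi0=float(cfg.get("psi0", 0.0)),
            psi_a=float(cfg["psi_a"]),
            Rc=float(cfg["Rc"]) if "Rc" in cfg else None,
            C=float(cfg["C"]) if "C" in cfg else None,
            psi_s=float(cfg["psi_s"]) if "psi_s" in cfg else None,
        )
        return cls(
            name=cfg["scenario"],
            params=params,
            psi_a_new=float(cfg["psi_a_new"]) if "psi_a_new" in cfg else None,
            dt=float(cfg.get("dt", 0.6)),
            T=float(cfg["T"]) if "T" in cfg else None,
            output_every=int(cfg.get("output_every", 10)),
            snapshot_times=tuple(cfg.get("snapshot_times", ())),
            theta=float(cfg.get("theta", STRESS_THRESHOLD)),
        )


@dataclass
class ScenarioReport:
    """Summary numbers plus the tables (and file paths) they come from."""

    name: str
    summary: dict
    tables: dict[str, pd.DataFrame]
    paths: dict[str, str] = field(default_factory=dict)


def chain_positions(net: HydraulicNetwork) -> np.ndarray:
    """Normalized positions x = i/N for a chain network, base to tip.

    Raises for non-chain topologies (branches or loops), for which a
    scalar front position is not defined.
    """
    n = net.n
    ids = net.node_ids
    expected_edges = {(ids[k], ids[k + 1]) for k in range(n - 1)}
    actual = {(e.i, e.j) for e in net.edges}
    if actual != expected_edges:
        raise ValueError("stress front is only defined for chain topologies")
    return (np.arange(1, n + 1) - 0.5) / n


def stress_front(psi, x, theta: float = STRESS_THRESHOLD) -> float | None:
    """Basal-most position where the potential drops below ``theta``.

    Linear interpolation between the adjacent nodes straddling the
    crossing; ``None`` when no node is below the threshold.  For the
    monotone base-to-tip profiles of this model, everything rightward of
    the returned position is stressed.
    """
    psi = np.asarray(psi, dtype=float)
    x = np.asarray(x, dtype=float)
    below = psi < theta
    if not np.any(below):
        return None
    k = int(np.argmax(below))
    if k == 0:
        return float(x[0])
    x0, x1 = x[k - 1], x[k]
    p0, p1 = psi[k - 1], psi[k]
    return float(x0 + (theta - p0) * (x1 - x0) / (p1 - p0))


def _continuous(params: UniformLeafParams) -> ContinuousLeaf:
    return ContinuousLeaf(
        R=params.R, Ra=params.Ra, psi0=params.psi0, psi_a=params.psi_a,
        Rc=params.Rc, C=params.C,
    )


def _sig(value: float, figures: int = 4) -> float:
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, figures - 1 - int(math.floor(math.log10(abs(value)))))


def run_scenario(spec: ScenarioSpec, outdir: str | Path | None = None) -> ScenarioReport:
    """Run one scenario and return its report; optionally write CSV/JSON files."""
    runner = {
        "steady_state": _run_steady_state,
        "excision": _run_excision,
        "humidity_step": _run_humidity_step,
        "spatial_snapshots": _run_spatial_snapshots,
    }[spec.name]
    report = runner(spec)
    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _run_steady_state(spec: ScenarioSpec) -> ScenarioReport:
    from .analytic import continuous_steady_profile

    net = build_uniform_chain(spec.params)
    state = solve_steady(net)
    x = chain_positions(net)
    leaf = _continuous(spec.params)
    profile = pd.DataFrame(
        {
            "node_id": net.node_ids,
            "x": x,
            "psi_MPa": state.psi,
            "psi_analytic_MPa": continuous_steady_profile(leaf, x),
            "I_a": state.I_a,
            "I_c": state.I_c,
            "V": state.V,
        }
    )
    summary = {
        "psi_bar": _sig(state.psi_bar),
        "E": _sig(state.E),
        "psi_tip": _sig(float(state.psi[-1])),
    }
    return ScenarioReport("steady_state", summary, {"profile": profile})


def _default_horizon(params: UniformLeafParams) -> float:
    leaf = _continuous(params)
    return 3.0 * time_constant_excised(leaf)


def _run_excision(spec: ScenarioSpec) -> ScenarioReport:
    params = spec.params
    if params.C is None or params.Rc is None:
        raise ValueError("excision scenario requires C and Rc")
    T = spec.T if spec.T is not None else _default_horizon(params)
    net = build_uniform_chain(params)
    schedule = EventSchedule([(spec.excision_time, ExciseSource())])
    result = simulate(net, "steady", schedule, T=T, dt=spec.dt, output_every=spec.output_every)
    leaf = _continuous(params)
    psi_bar_ref, E_ref = excised_decay(leaf, np.maximum(result.times - spec.excision_time, 0.0))
    series = result.to_frame()
    series["psi_bar_analytic_MPa"] = psi_bar_ref
    series["E_analytic"] = E_ref
    tau_theory = time_constant_excised(leaf)
    tau_hat = fit_exponential(result.times, result.psi_bar, params.psi_a)
    summary = {
        "tau_hat_s": _sig(tau_hat),
        "tau_theory_s": _sig(tau_theory),
        "tau_hat_min": _sig(tau_hat / 60.0),
        "psi_bar_initial": _sig(float(result.psi_bar[0])),
        "E_initial": _sig(float(result.E[0])),
    }
    return ScenarioReport("excision", summary, {"series": series})


def _stepped_net(spec: ScenarioSpec) -> HydraulicNetwork:
    net = build_uniform_chain(spec.params)
    net.psi_a = spec.psi_a_new  # type: ignore[assignment]
    return net


def _run_humidity_step(spec: ScenarioSpec) -> ScenarioReport:
    params = spec.params
    if params.C is None or params.Rc is None:
        raise ValueError("humidity_step scenario requires C and Rc")
    T = spec.T if spec.T is not None else _default_horizon(params)
    net = build_uniform_chain(params)
    schedule = EventSchedule([(0.0, SetAtmosphere(spec.psi_a_new))])
    result = simulate(net, "steady", schedule, T=T, dt=spec.dt, output_every=spec.output_every)
    final = solve_steady(_stepped_net(spec))
    tau_hat = fit_exponential(result.times, result.psi_bar, final.psi_bar)
    series = result.to_frame()
    summary = {
        "psi_a_new": spec.psi_a_new,
        "psi_bar_inf": _sig(final.psi_bar),
        "E_inf": _sig(final.E),
        "psi_bar_final": _sig(float(result.psi_bar[-1])),
        "E_final": _sig(float(result.E[-1])),
        "tau_hat_s": _sig(tau_hat),
        "tau_hat_min": _sig(tau_hat / 60.0),
    }
    return ScenarioReport("humidity_step", summary, {"series": series})


def _run_spatial_snapshots(spec: ScenarioSpec) -> ScenarioReport:
    params = spec.params
    if params.C is None or params.Rc is None:
        raise ValueError("spatial_snapshots scenario requires C and Rc")
    T = spec.T if spec.T is not None else _default_horizon(params)
    net = build_uniform_chain(params)
    x = chain_positions(net)
    schedule = EventSchedule([(0.0, SetAtmosphere(spec.psi_a_new))])
    result = simulate(net, "steady", schedule, T=T, dt=spec.dt, output_every=spec.output_every)
    snap_times = tuple(spec.snapshot_times) or tuple(
        float(t) for t in np.linspace(0.0, T, 5)
    )
    snapshots = {}
    for t_req in snap_times:
        k = int(np.argmin(np.abs(result.times - t_req)))
        snapshots[f"t={result.times[k]:g}s"] = result.states[k].psi
    profile = pd.DataFrame({"node_id": net.node_ids, "x": x, **snapshots})
    fronts = [stress_front(s.psi, x, spec.theta) for s in result.states]
    front_series = pd.DataFrame(
        {
            "t_s": result.times,
            "x_front": [np.nan if f is None else f for f in fronts],
        }
    )
    defined = [f for f in fronts if f is not None]
    summary = {
        "theta": spec.theta,
        "front_first_seen_s": _sig(
            float(result.times[next(i for i, f in enumerate(fronts) if f is not None)])
        )
        if defined
        else None,
        "front_final": _sig(defined[-1]) if defined else None,
        "psi_bar_final": _sig(float(result.psi_bar[-1])),
    }
    return ScenarioReport(
        "spatial_snapshots", summary, {"profiles": profile, "front": front_series}
    )


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_report(report: ScenarioReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in report.tables.items():
        path = outdir / f"{report.name}_{name}.csv"
        _atomic_write_text(path, frame.to_csv(index=False))
        report.paths[name] = str(path)
    summary_path = outdir / f"{report.name}_summary.json"
    _atomic_write_text(summary_path, json.dumps(report.summary, indent=1) + "\n")
    report.paths["summary"] = str(summary_path)
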
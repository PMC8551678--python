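"""Closed-form solutions for the uniform continuous one-dimensional leaf.

In the continuum limit the uniform leaky chain obeys a cable equation in
the normalized position ``x ∈ [0, 1]``.  At steady state with a fixed
base potential ``psi0``, atmospheric potential ``psi_a`` and a sealed
tip (zero axial flux at ``x = 1``), the potential profile is

    psi(x) = psi_a + (psi0 - psi_a) · cosh(m·(1 - x)) / cosh(m),

with the dimensionless leak parameter ``m = sqrt(R/Ra)`` comparing
axial xylem resistance to the distributed path into the air.  The base
influx, equal to the total steady transpiration, is

    I0 = (psi0 - psi_a) · (m/R) · tanh(m),

and the mean xylem potential satisfies ``psi_bar = I0·Ra + psi_a``.
An excised leaf (source removed at t = 0 from the steady state) decays
exponentially with time constant ``tau = C·(Rc + Ra)``:

    psi_bar(t) = psi_a + I0·Ra·exp(-t/tau),   E(t) = I0·exp(-t/tau).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContinuousLeaf",
    "continuous_steady_profile",
    "base_influx",
    "steady_mean_potential",
    "excised_decay",
    "time_constant_excised",
    "fit_exponential",
    "FitQualityWarning",
]


class FitQualityWarning(UserWarning):
    """The series handed to the exponential fit is not a clean decay."""


@dataclass(frozen=True)
class ContinuousLeaf:
    """Whole-leaf combined parameters of the continuous uniform model.

    Units as elsewhere: potentials MPa, resistances MPa·m²·s·mmol⁻¹,
    capacitance mmol·m⁻²·MPa⁻¹.  ``Rc`` and ``C`` are only needed for
    the excised-leaf transient.
    """

    R: float
    Ra: float
    psi0: float
    psi_a: float
    Rc: float | None = None
    C: float | None = None

    def __post_init__(self) -> None:
        if not self.R > 0 or not self.Ra > 0:
            raise ValueError(f"R and Ra must be > 0, got R={self.R}, Ra={self.Ra}")

    @property
    def m(self) -> float:
        """Dimensionless leak (cable) parameter sqrt(R/Ra)."""
        return math.sqrt(self.R / self.Ra)


def continuous_steady_profile(leaf: ContinuousLeaf, x):
    """Steady potential psi(x) along the leaf, sealed-tip boundary at x=1."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x must lie in [0, 1]")
    m = leaf.m
    out = leaf.psi_a + (leaf.psi0 - leaf.psi_a) * np.cosh(m * (1.0 - x)) / np.cosh(m)
    return float(out) if out.ndim == 0 else out


def base_influx(leaf: ContinuousLeaf) -> float:
    """Steady current entering through the base; equals total transpiration E."""
    m = leaf.m
    return (leaf.psi0 - leaf.psi_a) * (m / leaf.R) * math.tanh(m)


def steady_mean_potential(leaf: ContinuousLeaf) -> float:
    """Steady mean xylem potential psi_bar = I0·Ra + psi_a."""
    return base_influx(leaf) * leaf.Ra + leaf.psi_a


def time_constant_excised(leaf: ContinuousLeaf) -> float:
    """Dehydration time constant tau = C·(Rc + Ra) of the excised leaf, s."""
    if leaf.C is None or leaf.Rc is None:
        raise ValueError("excised time constant needs C and Rc")
    return leaf.C * (leaf.Rc + leaf.Ra)


def excised_decay(leaf: ContinuousLeaf, t):
    """(psi_bar(t), E(t)) of a leaf excised at t=0 from its steady state."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tau = time_constant_excised(leaf)
    I0 = base_influx(leaf)
    decay = np.exp(-t / tau)
    psi_bar = leaf.psi_a + I0 * leaf.Ra * decay
    E = I0 * decay
    if psi_bar.ndim == 0:
        return float(psi_bar), float(E)
    return psi_bar, E


def fit_exponential(times, values, asymptote: float) -> float:
    """Fit ``values(t) ≈ asymptote + B·exp(-t/tau)`` and return ``tau``.

    The fit is a linear regression of ``log|values - asymptote|`` against
    time.  A first pass over the whole series gives a scale estimate
    ``tau0``; the reported constant comes from a second regression
    restricted to ``t - t[0] ∈ [0.2·tau0, 2·tau0]``, which avoids both
    the early transient and the late samples where the residual sits in
    the noise floor.  Exact on noiseless exponentials.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 10:
        raise ValueError(f"need at least 10 samples, got {times.size}")
    resid = values - asymptote
    diffs = np.diff(values)
    if np.any(diffs > 1e-12 * np.max(np.abs(values))) and np.any(
        diffs < -1e-12 * np.max(np.abs(values))
    ):
        r2 = _log_r_squared(times, resid)
        warnings.warn(
            f"series is not monotone toward the asymptote (log-linear R²={r2:.4f}); "
            "the fitted time constant may be unreliable",
            FitQualityWarning,
            stacklevel=2,
        )
    scale = np.max(np.abs(resid))
    mask = np.abs(resid) > 1e-12 * scale
    tau0 = _regress_tau(times[mask], resid[mask])
    rel = times - times[0]
    window = mask & (rel >= 0.2 * tau0) & (rel <= 2.0 * tau0)
    if np.count_nonzero(window) < 3:
        return tau0
    return _regress_tau(times[window], resid[window])


def _regress_tau(t, resid) -> float:
    slope, _ = np.polyfit(t, np.log(np.abs(resid)), 1)
    if slope >= 0:
        raise ValueError("series does not decay toward the asymptote")
    return -1.0 / slope


def _log_r_squared(t, resid) -> float:
    mask = np.abs(resid) > 0
    y = np.log(np.abs(resid[mask]))
    slope, intercept = np.polyfit(t[mask], y, 1)
    pred = slope * t[mask] + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
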
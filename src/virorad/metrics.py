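"""Output functionals: normalized viable tumor mass and trajectory summaries.

The quantity tracked throughout is

    f_x(t) = (2 pi / M0) * integral_{r_b}^{r_b/BVF} x(r, t) r dr

the viable (uninfected) tumor mass normalized by a baseline mass M0.
For a treatment starting from a uniform density x0 the baseline is
M0 = x0 * V with V = pi ((r_b/BVF)^2 - r_b^2) the annulus area, so that
f_x(0) = 1 exactly under trapezoidal quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy.signal import argrelmax, argrelmin

from .model import RadialGrid

if TYPE_CHECKING:  # pragma: no cover
    from .solver import SimulationResult

__all__ = ["annulus_area", "normalized_mass", "radial_mass", "OutcomeSummary", "summarize"]


def annulus_area(r_b: float, BVF: float) -> float:
    """Cross-section area V = pi ((r_b/BVF)^2 - r_b^2) of the tissue annulus."""
    if not 0 < BVF < 1:
        raise ValueError(f"BVF must lie in (0, 1), got {BVF}")
    return float(np.pi * ((r_b / BVF) ** 2 - r_b**2))


def radial_mass(field: np.ndarray, grid: RadialGrid) -> float:
    """2 pi * integral of field * r dr by composite trapezoid on the grid nodes."""
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.n_nodes,):
        raise ValueError("field length does not match grid")
    return float(2.0 * np.pi * np.trapezoid(field * grid.nodes, grid.nodes))


def normalized_mass(x_field: np.ndarray, grid: RadialGrid, M0: float) -> float:
    """Mass of ``x_field`` over the annulus divided by the baseline mass M0."""
    if not M0 > 0:
        raise ValueError(f"baseline mass M0 must be positive, got {M0}")
    return radial_mass(x_field, grid) / M0


@dataclass(frozen=True)
class OutcomeSummary:
    """Scalar summaries of one f_x(t) trajectory (times in hours)."""

    fx_min: float
    t_min: float
    fx_final: float
    fx_peak: float
    t_peak: float
    oscillatory: bool
    eradicated: bool


# Extrema smaller than this fraction of the trajectory range are treated
# as quadrature/time-discretization jitter, not oscillations.
_PROMINENCE_FRACTION = 0.01

# Treatment success: the viable mass is below this fraction of baseline at
# the end of the run and is not regrowing over the final window.
_ERADICATION_LEVEL = 0.01
_ERADICATION_WINDOW_H = 48.0


def _significant_extrema(fx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima/minima with prominence above the jitter floor."""
    span = float(fx.max() - fx.min())
    if span == 0.0:
        return np.array([], dtype=int), np.array([], dtype=int)
    tol = _PROMINENCE_FRACTION * span
    maxima = argrelmax(fx)[0]
    minima = argrelmin(fx)[0]
    # keep only extrema that stand out from both neighbouring opposite extrema
    turning = np.sort(np.concatenate([[0], maxima, minima, [fx.size - 1]]))
    keep_max, keep_min = [], []
    for idx in maxima:
        pos = np.searchsorted(turning, idx)
        lo, hi = turning[pos - 1], turning[pos + 1]
        if fx[idx] - max(fx[lo], fx[hi]) >= tol:
            keep_max.append(idx)
    for idx in minima:
        pos = np.searchsorted(turning, idx)
        lo, hi = turning[pos - 1], turning[pos + 1]
        if min(fx[lo], fx[hi]) - fx[idx] >= tol:
            keep_min.append(idx)
    return np.asarray(keep_max, dtype=int), np.asarray(keep_min, dtype=int)


def summarize(result: "SimulationResult", phase: Optional[int] = None) -> OutcomeSummary:
    """Extrema, endpoint and oscillation/eradication flags of a trajectory.

    For a two-phase result pass ``phase`` to restrict to one segment
    (each segment carries its own mass normalization).  Extremum times
    are reported at snapshot resolution.
    """
    times = np.asarray(result.times, dtype=float)
    fx = np.asarray(result.fx, dtype=float)
    if phase is not None:
        mask = np.asarray(result.phase) == phase
        times, fx = times[mask], fx[mask]
    if fx.size < 3:
        raise ValueError("need at least 3 snapshots to summarize a trajectory")

    i_min = int(np.argmin(fx))
    i_max = int(np.argmax(fx))
    maxima, minima = _significant_extrema(fx)
    oscillatory = bool(minima.size and maxima.size and maxima.max() > minima.min())

    window = times >= times[-1] - _ERADICATION_WINDOW_H
    tail = fx[window]
    eradicated = bool(fx[-1] < _ERADICATION_LEVEL and np.all(np.diff(tail) <= 0.0))

    return OutcomeSummary(
        fx_min=float(fx[i_min]),
        t_min=float(times[i_min]),
        fx_final=float(fx[-1]),
        fx_peak=float(fx[i_max]),
        t_peak=float(times[i_max]),
        oscillatory=oscillatory,
        eradicated=eradicated,
    )
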
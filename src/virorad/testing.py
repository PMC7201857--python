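"""Fixture generators for tests: perturbed parameter sets and initial profiles.

Everything here is deterministic given the seed, small, and built at
run time — no stored data files.
"""

from __future__ import annotations

import numpy as np

from .model import FieldState, ModelParameters, RadialGrid

__all__ = ["perturbed_parameters", "uniform_profile", "step_profile", "smooth_bump",
           "uniform_state"]

# multiplicative jitter is applied to these strictly positive rate fields
_JITTERED = ("D1", "r1", "beta", "delta", "D2", "b", "alpha", "a1", "a2", "gamma", "v0", "x0")


def perturbed_parameters(
    seed: int, spread: float = 0.2, base: ModelParameters | None = None
) -> ModelParameters:
    """A parameter set with lognormal jitter of width ``spread`` on each rate.

    Geometry (r_b, BVF) and the protocol time t_r stay at their base
    values so the grid and phase layout are unchanged.
    """
    rng = np.random.default_rng(seed)
    base = base or ModelParameters()
    factors = np.exp(spread * rng.standard_normal(len(_JITTERED)))
    return base.with_overrides(
        **{name: getattr(base, name) * f for name, f in zip(_JITTERED, factors)}
    )


def uniform_profile(grid: RadialGrid, value: float) -> np.ndarray:
    return np.full(grid.n_nodes, float(value))


def step_profile(
    grid: RadialGrid, inner_value: float, outer_value: float, r_step: float | None = None
) -> np.ndarray:
    """Piecewise-constant profile switching at ``r_step`` (default: midpoint)."""
    if r_step is None:
        r_step = 0.5 * (grid.r_inner + grid.r_outer)
    return np.where(grid.nodes <= r_step, float(inner_value), float(outer_value))


def smooth_bump(grid: RadialGrid, amplitude: float = 1.0, floor: float = 0.0) -> np.ndarray:
    """A cosine bump with zero slope at both boundaries.

    Useful for conservation tests: the profile is compatible with
    no-flux boundaries, so the discrete boundary-flux leakage of a
    diffusion-only run stays at the truncation level.
    """
    s = (grid.nodes - grid.r_inner) / (grid.r_outer - grid.r_inner)
    return floor + amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * s))


def uniform_state(grid: RadialGrid, x: float, y: float, v: float, t: float = 0.0,
                  with_damage: bool = False) -> FieldState:
    """Spatially uniform state, optionally including the damaged-cell field."""
    make = lambda val: np.full(grid.n_nodes, float(val))
    u = make(0.0) if with_damage else None
    return FieldState(t, make(x), make(y), make(v), u)
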
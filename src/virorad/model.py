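"""Domain types and reaction-diffusion right-hand sides.

The model describes the annular tissue region served by a single blood
vessel: uninfected tumor cells ``x``, virus-infected tumor cells ``y``
and free oncolytic virus ``v`` evolve on the radial interval
``[r_b, r_b/BVF]`` under diffusion, exponential tumor growth, mass-action
infection, lysis (which releases ``b`` new virions per cell) and viral
clearance.  The radiovirotherapy extension adds a fourth, non-motile
species ``u`` of radiation-damaged cells.

All times are hours, lengths are millimetres, densities are per mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np

from .radiation import RadiationSchedule

__all__ = [
    "ModelParameters",
    "RadialGrid",
    "FieldState",
    "BoundaryCondition",
    "NO_FLUX",
    "fixed_value",
    "radial_laplacian",
    "rhs_phase1",
    "rhs_phase2",
]


@dataclass(frozen=True)
class ModelParameters:
    """All rate and geometry constants of the model, with defaults.

    Units: diffusivities mm^2/h, rates 1/h, ``beta`` mm^3/(h*virus),
    ``b`` viruses/cell, ``kappa`` virus/cell, lengths mm, densities
    per mm^3, times h.
    """

    D1: float = 1e-8        # tumor-cell diffusivity
    r1: float = 0.02        # tumor growth rate
    beta: float = 7e-10     # viral infection rate
    delta: float = 1.0 / 18.0  # infected-cell death (lysis) rate
    D2: float = 5e-7        # virus diffusivity
    b: float = 50.0         # burst size
    kappa: float = 1.0      # virions consumed per infection
    alpha: float = 0.008    # viral clearance rate
    a1: float = 0.01        # radiation damage rate, uninfected cells
    a2: float = 0.01        # radiation damage rate, infected cells
    gamma: float = 0.01     # death rate of damaged cells
    r_b: float = 0.01       # blood-vessel radius
    BVF: float = 0.05       # blood volume fraction
    v0: float = 0.5e6       # virus density clamped at the vessel wall
    x0: float = 0.5e6       # initial uninfected-cell density
    t_r: float = 120.0      # time radiotherapy starts (Phase II)

    def __post_init__(self) -> None:
        # rate-like parameters may be zero (a switched-off process: the
        # well-mixed limit D1=D2=0, conservation checks r1=beta=delta=alpha=0,
        # the no-virus control v0=0); geometry and the baseline density not
        positive = ("r_b", "x0", "t_r")
        nonnegative = (
            "D1", "r1", "beta", "delta", "D2", "b", "kappa", "alpha",
            "a1", "a2", "gamma", "v0",
        )
        for name in positive:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value}")
        for name in nonnegative:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be nonnegative, got {value}")
        if not 0 < self.BVF < 1:
            raise ValueError(f"BVF must lie in (0, 1), got {self.BVF}")

    @property
    def r_outer(self) -> float:
        """Outer radius of the tissue annulus, r_b / BVF."""
        return self.r_b / self.BVF

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        unknown = set(kwargs) - {f.name for f in fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node-centred grid on the annulus [r_inner, r_outer]."""

    r_inner: float
    r_outer: float
    n_nodes: int
    nodes: np.ndarray = field(repr=False, compare=False, default=None)
    dr: float = field(default=None)

    def __post_init__(self) -> None:
        if self.n_nodes < 5:
            raise ValueError(f"need at least 5 nodes, got {self.n_nodes}")
        if not self.r_outer > self.r_inner > 0:
            raise ValueError("require 0 < r_inner < r_outer")
        nodes, dr = np.linspace(self.r_inner, self.r_outer, self.n_nodes, retstep=True)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "dr", float(dr))

    @classmethod
    def from_parameters(cls, params: ModelParameters, n_nodes: int) -> "RadialGrid":
        return cls(params.r_b, params.r_outer, n_nodes)

    def __len__(self) -> int:
        return self.n_nodes


@dataclass
class FieldState:
    """Densities on the grid at one instant.

    ``u`` (radiation-damaged cells) is present only for the
    radiovirotherapy model and must be ``None`` for plain virotherapy.
    """

    t: float
    x: np.ndarray
    y: np.ndarray
    v: np.ndarray
    u: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
        n = self.x.shape[0]
        for name in ("y", "v") + (("u",) if self.u is not None else ()):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"field {name!r} has wrong length")
        for name, arr in self.arrays().items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in field {name!r}")

    def arrays(self) -> dict[str, np.ndarray]:
        out = {"x": self.x, "y": self.y, "v": self.v}
        if self.u is not None:
            out["u"] = self.u
        return out

    @property
    def has_damage(self) -> bool:
        return self.u is not None

    def copy(self) -> "FieldState":
        return FieldState(
            self.t, self.x.copy(), self.y.copy(), self.v.copy(),
            None if self.u is None else self.u.copy(),
        )


@dataclass(frozen=True)
class BoundaryCondition:
    """Either no-flux (zero radial derivative) or a clamped value."""

    kind: str  # "no_flux" | "fixed"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("no_flux", "fixed"):
            raise ValueError(f"unknown boundary-condition kind {self.kind!r}")


NO_FLUX = BoundaryCondition("no_flux")


def fixed_value(value: float) -> BoundaryCondition:
    return BoundaryCondition("fixed", float(value))


def radial_laplacian(
    field_values: np.ndarray,
    grid: RadialGrid,
    inner_bc: BoundaryCondition = NO_FLUX,
    outer_bc: BoundaryCondition = NO_FLUX,
) -> np.ndarray:
    """Discrete cylindrical Laplacian (1/r) d/dr (r d(field)/dr).

    Second-order central differences in the interior.  No-flux ends use
    a ghost-node closure in flux form: the discrete flux through the
    boundary face is exactly zero, which makes diffusion conserve the
    trapezoid-quadrature mass Sum w_i r_i f_i to roundoff.  A
    fixed-value end returns 0 there, consistent with the node being
    clamped (its time derivative is suppressed by the solver).
    """
    f = np.asarray(field_values, dtype=float)
    if f.shape != (grid.n_nodes,):
        raise ValueError(
            f"field length {f.shape} does not match grid ({grid.n_nodes} nodes)"
        )
    r = grid.nodes
    dr = grid.dr
    lap = np.empty_like(f)
    lap[1:-1] = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / dr**2 \
        + (f[2:] - f[:-2]) / (2.0 * dr * r[1:-1])
    if inner_bc.kind == "no_flux":
        # half-cell flux balance: zero flux at r_0, face flux at r_0 + dr/2
        lap[0] = 2.0 * (f[1] - f[0]) / dr**2 * (r[0] + 0.5 * dr) / r[0]
    else:
        lap[0] = 0.0
    if outer_bc.kind == "no_flux":
        lap[-1] = 2.0 * (f[-2] - f[-1]) / dr**2 * (r[-1] - 0.5 * dr) / r[-1]
    else:
        lap[-1] = 0.0
    return lap


def _check_rhs_inputs(state: FieldState, params: ModelParameters, grid: RadialGrid) -> None:
    if state.x.shape != (grid.n_nodes,):
        raise ValueError("state does not match grid")


def rhs_phase1(
    state: FieldState,
    params: ModelParameters,
    grid: RadialGrid,
    v_inner_bc: Optional[BoundaryCondition] = None,
) -> FieldState:
    """Time derivatives of (x, y, v) for the virotherapy model.

    dx/dt = D1 L x + r1 x - beta x v
    dy/dt = D1 L y + beta x v - delta y
    dv/dt = D2 L v + b delta y - kappa beta x v - alpha v

    x and y are no-flux at both boundaries; v is clamped to ``v0`` at
    the vessel wall (Dirichlet, derivative zeroed there) and no-flux at
    the outer rim, unless ``v_inner_bc`` overrides the wall condition.
    """
    _check_rhs_inputs(state, params, grid)
    if state.has_damage:
        raise ValueError("virotherapy RHS expects a state without the damaged-cell field")
    if v_inner_bc is None:
        v_inner_bc = fixed_value(params.v0)
    x, y, v = state.x, state.y, state.v
    infection = params.beta * x * v
    dx = params.D1 * radial_laplacian(x, grid) + params.r1 * x - infection
    dy = params.D1 * radial_laplacian(y, grid) + infection - params.delta * y
    dv = (
        params.D2 * radial_laplacian(v, grid, inner_bc=v_inner_bc)
        + params.b * params.delta * y
        - params.kappa * infection
        - params.alpha * v
    )
    if v_inner_bc.kind == "fixed":
        dv[0] = 0.0
    return FieldState(state.t, dx, dy, dv)


def rhs_phase2(
    state: FieldState,
    params: ModelParameters,
    grid: RadialGrid,
    schedule: RadiationSchedule,
    v_inner_bc: Optional[BoundaryCondition] = None,
) -> FieldState:
    """Time derivatives of (x, y, u, v) for the radiovirotherapy model.

    The virotherapy terms are unchanged; radiation at dose rate R(t)
    moves uninfected and infected cells into the damaged compartment
    ``u`` at rates a1 R and a2 R; damaged cells die at rate gamma and
    do not move (no diffusion term, hence no boundary condition on u).
    """
    _check_rhs_inputs(state, params, grid)
    if not state.has_damage:
        raise ValueError("radiovirotherapy RHS requires the damaged-cell field u")
    if v_inner_bc is None:
        v_inner_bc = fixed_value(params.v0)
    R = schedule.evaluate(state.t)
    x, y, v, u = state.x, state.y, state.v, state.u
    infection = params.beta * x * v
    dx = params.D1 * radial_laplacian(x, grid) + params.r1 * x - infection \
        - params.a1 * R * x
    dy = params.D1 * radial_laplacian(y, grid) + infection - params.delta * y \
        - params.a2 * R * y
    du = params.a1 * R * x + params.a2 * R * y - params.gamma * u
    dv = (
        params.D2 * radial_laplacian(v, grid, inner_bc=v_inner_bc)
        + params.b * params.delta * y
        - params.kappa * infection
        - params.alpha * v
    )
    if v_inner_bc.kind == "fixed":
        dv[0] = 0.0
    return FieldState(state.t, dx, dy, dv, du)
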
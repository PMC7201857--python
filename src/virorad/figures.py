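"""Figure regeneration: density snapshots, sweep families, schedule comparisons.

Each ``fig*`` function runs the simulations it needs, writes one PNG
per panel plus the underlying CSVs, and returns the written paths.
Sweep legends (the scanned beta/b/alpha values and the constant-dose
levels) are package choices; see the methods note.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .io import _write_csv, fx_frame  # noqa: E402
from .model import ModelParameters, RadialGrid  # noqa: E402
from .radiation import RadiationSchedule  # noqa: E402
from .solver import (  # noqa: E402
    SolverSettings,
    run_phase1,
    run_two_phase,
    sweep,
)

__all__ = ["fig1", "fig2", "fig3", "fig4", "fig5", "fig6", "FIGURES", "make_figures"]

# default sweep legends (package choices, not reported values)
BETA_VALUES = (3.5e-10, 7e-10, 1.4e-9, 2.8e-9)
BURST_VALUES = (10.0, 50.0, 100.0, 200.0)
ALPHA_VALUES = (0.008, 0.016, 0.032, 0.064)
DOSE_VALUES = (1.0, 2.0, 4.0)
TIMING_VALUES = (72.0, 120.0, 168.0, 216.0)

_DAY = 24.0


def _save(fig, path: Path) -> Path:
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def _fx_panel(ax, result, label=None, color=None, phase=None):
    t, fx = result.times, result.fx
    if phase is not None:
        mask = np.asarray(result.phase) == phase
        t, fx = t[mask], fx[mask]
    ax.plot(t / _DAY, fx, label=label, color=color)
    ax.set_xlabel("time (days)")
    ax.set_ylabel(r"normalized viable mass $f_x$")


def fig1(out_dir: Path, params: ModelParameters, settings: SolverSettings,
         initial_virus: str) -> list[Path]:
    """Density profiles at days 2/4/6 (x, y, v) and the f_x trajectory."""
    result = run_phase1(params, settings, initial_virus)
    grid = RadialGrid.from_parameters(params, settings.n_nodes)
    days = (2.0, 4.0, 6.0)
    paths = []
    rows = []
    for panel, species in zip("abc", ("x", "y", "v")):
        fig, ax = plt.subplots(figsize=(5, 4))
        for day in days:
            idx = int(np.argmin(np.abs(result.times - day * _DAY)))
            values = result.states[idx].arrays()[species]
            ax.plot(grid.nodes, values, label=f"day {day:g}")
            rows.append(pd.DataFrame({"r_mm": grid.nodes, "species": species,
                                      "day": day, "density": values}))
        ax.set_xlabel("r (mm)")
        unit = "viruses/mm$^3$" if species == "v" else "cells/mm$^3$"
        ax.set_ylabel(f"{species} ({unit})")
        ax.legend()
        paths.append(_save(fig, out_dir / f"fig1{panel}_{species}_profiles.png"))
    fig, ax = plt.subplots(figsize=(5, 4))
    _fx_panel(ax, result)
    paths.append(_save(fig, out_dir / "fig1d_fx.png"))
    _write_csv(pd.concat(rows, ignore_index=True), out_dir / "fig1_profiles.csv")
    _write_csv(fx_frame(result), out_dir / "fig1_fx.csv")
    return paths


def _sweep_panel(out_dir, params, settings, initial_virus, vary, values, tag):
    entries = sweep(params, settings, vary, list(values), initial_virus=initial_virus)
    fig, ax = plt.subplots(figsize=(5, 4))
    rows = []
    for entry in entries:
        _fx_panel(ax, entry.result, label=f"{vary}={entry.value:g}")
        frame = fx_frame(entry.result)
        frame[vary] = entry.value
        rows.append(frame)
    ax.set_yscale("log")
    ax.legend()
    path = _save(fig, out_dir / f"{tag}_{vary}_sweep.png")
    _write_csv(pd.concat(rows, ignore_index=True), out_dir / f"{tag}_{vary}_sweep.csv")
    return path


def fig2(out_dir: Path, params: ModelParameters, settings: SolverSettings,
         initial_virus: str) -> list[Path]:
    """f_x families under varied infection rate, burst size and clearance rate."""
    return [
        _sweep_panel(out_dir, params, settings, initial_virus, "beta", BETA_VALUES, "fig2a"),
        _sweep_panel(out_dir, params, settings, initial_virus, "b", BURST_VALUES, "fig2b"),
        _sweep_panel(out_dir, params, settings, initial_virus, "alpha", ALPHA_VALUES, "fig2c"),
    ]


def fig3(out_dir: Path, params: ModelParameters, settings: SolverSettings,
         initial_virus: str) -> list[Path]:
    """The small-burst-size (b=2) run, full window and final-week zoom."""
    result = run_phase1(params.with_overrides(b=2.0), settings, initial_virus)
    paths = []
    for panel, (lo, hi) in zip("ab", ((0.0, settings.t_end), (580.0, settings.t_end))):
        fig, ax = plt.subplots(figsize=(5, 4))
        _fx_panel(ax, result)
        ax.set_xlim(lo / _DAY, hi / _DAY)
        mask = (result.times >= lo) & (result.times <= hi)
        ax.set_ylim(result.fx[mask].min() * 0.95, result.fx[mask].max() * 1.05)
        paths.append(_save(fig, out_dir / f"fig3{panel}_b2.png"))
    _write_csv(fx_frame(result), out_dir / "fig3_fx.csv")
    return paths


def _two_phase_set(params, settings, initial_virus, modes):
    out = {}
    for mode in modes:
        sched = RadiationSchedule(mode=mode, t0=params.t_r)
        out[mode] = run_two_phase(params, settings, sched, initial_virus)
    return out


def fig4(out_dir: Path, params: ModelParameters, settings: SolverSettings,
         initial_virus: str) -> list[Path]:
    """Each radiation mode (red) against the virotherapy-only control (blue)."""
    results = _two_phase_set(params, settings, initial_virus,
                             ("constant", "decay", "periodic", "off"))
    control = results.pop("off")
    paths, rows = [], []
    for panel, mode in zip("abc", ("constant", "decay", "periodic")):
        fig, ax = plt.subplots(figsize=(5, 4))
        _fx_panel(ax, results[mode], label=f"radiovirotherapy ({mode})",
                  color="tab:red", phase=2)
        _fx_panel(ax, control, label="virotherapy alone", color="tab:blue", phase=2)
        ax.set_yscale("log")
        ax.legend()
        paths.append(_save(fig, out_dir / f"fig4{panel}_{mode}.png"))
    for mode, res in {**results, "off": control}.items():
        frame = fx_frame(res)
        frame["mode"] = mode
        rows.append(frame)
    _write_csv(pd.concat(rows, ignore_index=True), out_dir / "fig4_fx.csv")
    return paths


def fig5(out_dir: Path, params: ModelParameters, settings: SolverSettings,
         initial_virus: str) -> list[Path]:
    """The three radiation modes in one panel (Phase II segment)."""
    results = _two_phase_set(params, settings, initial_virus,
                             ("constant", "decay", "periodic"))
    fig, ax = plt.subplots(figsize=(5, 4))
    rows = []
    for mode, res in results.items():
        _fx_panel(ax, res, label=mode, phase=2)
        frame = fx_frame(res)
        frame["mode"] = mode
        rows.append(frame)
    ax.set_yscale("log")
    ax.legend()
    path = _save(fig, out_dir / "fig5_modes.png")
    _write_csv(pd.concat(rows, ignore_index=True), out_dir / "fig5_fx.csv")
    return [path]


def fig6(out_dir: Path, params: ModelParameters, settings: SolverSettings,
         initial_virus: str) -> list[Path]:
    """Constant-dose grid: one panel per radiation start time, one curve per dose."""
    paths, rows = [], []
    for t_r in TIMING_VALUES:
        fig, ax = plt.subplots(figsize=(5, 4))
        for dose in DOSE_VALUES:
            sched = RadiationSchedule(mode="constant", R_const=dose, t0=t_r)
            res = run_two_phase(params.with_overrides(t_r=t_r), settings, sched,
                                initial_virus)
            _fx_panel(ax, res, label=f"R={dose:g}", phase=2)
            frame = fx_frame(res)
            frame["R"] = dose
            frame["t_r_h"] = t_r
            rows.append(frame)
        ax.set_yscale("log")
        ax.set_title(f"radiation from day {t_r / _DAY:g}")
        ax.legend()
        paths.append(_save(fig, out_dir / f"fig6_tr{int(t_r)}h.png"))
    _write_csv(pd.concat(rows, ignore_index=True), out_dir / "fig6_fx.csv")
    return paths


FIGURES = {"fig1": fig1, "fig2": fig2, "fig3": fig3, "fig4": fig4,
           "fig5": fig5, "fig6": fig6}


def make_figures(
    which: Sequence[str],
    out_dir: str | Path,
    params: ModelParameters = ModelParameters(),
    settings: SolverSettings = SolverSettings(),
    initial_virus: str = "uniform",
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in which:
        if name not in FIGURES:
            raise ValueError(f"unknown figure {name!r}; choose from {sorted(FIGURES)}")
        written.extend(FIGURES[name](out_dir, params, settings, initial_virus))
    return written
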
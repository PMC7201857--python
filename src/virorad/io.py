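"""Result writers: trajectory and snapshot CSVs, summary JSON, provenance.

CSV is the exchange format: there is no domain-standard container for
radial PDE fields, and tidy CSVs feed any downstream tool directly.
Numeric text is written at 17 significant digits so re-running from the
echoed config reproduces files byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .metrics import summarize
from .solver import SimulationResult, SweepEntry

__all__ = ["write_result", "write_sweep", "fx_frame", "snapshot_frame"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def fx_frame(result: SimulationResult) -> pd.DataFrame:
    """Tidy normalized-mass trajectory: time_h, fx, phase."""
    return pd.DataFrame(
        {"time_h": result.times, "fx": result.fx, "phase": result.phase}
    )


def snapshot_frame(result: SimulationResult, every: int = 1) -> pd.DataFrame:
    """Long-format field snapshots: time_h, r_mm, species, density.

    ``every`` thins the snapshot list (1 = keep all).
    """
    grid_r = None
    records = []
    for state in result.states[::every]:
        arrays = state.arrays()
        n = state.x.size
        if grid_r is None:
            r_inner = result.provenance.get("parameters", {}).get("r_b")
            BVF = result.provenance.get("parameters", {}).get("BVF")
            if r_inner is not None and BVF is not None:
                grid_r = np.linspace(r_inner, r_inner / BVF, n)
            else:
                grid_r = np.arange(n, dtype=float)
        for species, values in arrays.items():
            records.append(
                pd.DataFrame(
                    {
                        "time_h": state.t,
                        "r_mm": grid_r,
                        "species": species,
                        "density": values,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_result(
    result: SimulationResult,
    out_dir: str | Path,
    *,
    basename: str = "run",
    snapshot_every: int = 1,
    write_snapshots: bool = True,
) -> dict[str, Path]:
    """Write one simulation to ``out_dir``; returns the file map.

    Emits ``<basename>_fx.csv`` (trajectory), ``<basename>_snapshots.csv``
    (long-format fields), ``<basename>_summary.json`` and
    ``<basename>_config.yaml`` (the resolved provenance record).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["fx"] = out_dir / f"{basename}_fx.csv"
    _write_csv(fx_frame(result), files["fx"])

    if write_snapshots:
        files["snapshots"] = out_dir / f"{basename}_snapshots.csv"
        _write_csv(snapshot_frame(result, snapshot_every), files["snapshots"])

    summary = {"overall": dataclasses.asdict(summarize(result))}
    if result.phase_boundary is not None:
        for ph in (1, 2):
            try:
                summary[f"phase{ph}"] = dataclasses.asdict(summarize(result, phase=ph))
            except ValueError:
                pass
        summary["phase_boundary_h"] = result.phase_boundary
    files["summary"] = out_dir / f"{basename}_summary.json"
    files["summary"].write_text(json.dumps(summary, indent=2) + "\n")

    files["config"] = out_dir / f"{basename}_config.yaml"
    files["config"].write_text(yaml.safe_dump(result.provenance, sort_keys=False))

    logger.info("wrote %s to %s", sorted(f.name for f in files.values()), out_dir)
    return files


def write_sweep(
    entries: Sequence[SweepEntry],
    out_dir: str | Path,
    *,
    write_snapshots: bool = False,
) -> Path:
    """Write each sweep member plus one tabular summary CSV row per member."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, entry in enumerate(entries):
        tag = f"member{i:03d}"
        write_result(
            entry.result, out_dir, basename=tag, write_snapshots=write_snapshots
        )
        phase = 2 if entry.result.phase_boundary is not None else None
        summ = summarize(entry.result, phase=phase)
        rows.append(
            {
                "member": tag,
                "parameter": entry.vary,
                "value": entry.value,
                "schedule": None if entry.schedule is None else entry.schedule.mode,
                "t_r_h": entry.t_r,
                **dataclasses.asdict(summ),
            }
        )
    summary_path = out_dir / "sweep_summary.csv"
    _write_csv(pd.DataFrame(rows), summary_path)
    return summary_path
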
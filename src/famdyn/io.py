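"""CSV / JSON / YAML I/O for rank x time matrices, trajectories and
parameter presets.

A RankTimeMatrix is stored as a strict CSV (comma separator, '.'
decimal, UTF-8): the header row holds the bin times in ms (onset at 0)
and each subsequent row is one rank, bottom rank first. A JSON sidecar
(same stem, ``.json``) records dt, onset_index and the condition label;
the reader validates the time grid and falls back to inferring dt from
the header when the sidecar is absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .inference import RankTimeMatrix

__all__ = [
    "write_rank_time_csv",
    "read_rank_time_csv",
    "write_trajectory_csv",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("fig4", "fig5", "fig7", "std_fit")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_rank_time_csv(matrix: RankTimeMatrix, path, condition: str = "") -> None:
    path = Path(path)
    times = matrix.times
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(format(t, "g") for t in times) + "\n")
        for row in matrix.values:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    meta = {"dt": matrix.dt, "onset_index": matrix.onset_index,
            "condition": condition, "n_ranks": matrix.n_ranks,
            "n_bins": matrix.n_bins}
    _sidecar(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_rank_time_csv(path) -> RankTimeMatrix:
    """Parse and validate a rank x time CSV.

    Errors identify the offending row/column: ragged rows, a
    non-monotone time header, and non-numeric cells are all rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a time header and at least one rank row")

    def parse_row(line: str, row_idx: int) -> list:
        out = []
        for col_idx, cell in enumerate(line.split(",")):
            try:
                out.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {row_idx}, "
                    f"column {col_idx}: {cell!r}") from None
        return out

    times = np.array(parse_row(lines[0], 0))
    if times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time header must be strictly increasing")
    n_cols = times.size

    rows = []
    for ridx, line in enumerate(lines[1:], start=1):
        row = parse_row(line, ridx)
        if len(row) != n_cols:
            raise ValueError(f"{path}: ragged row {ridx} "
                             f"({len(row)} cells, expected {n_cols})")
        rows.append(row)
    values = np.array(rows)

    meta_path = _sidecar(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        dt = float(meta["dt"])
        onset_index = int(meta["onset_index"])
    else:
        dt = float(times[1] - times[0])
        onset_index = int(np.argmin(np.abs(times)))
    steps = np.diff(times)
    if not np.allclose(steps, dt):
        raise ValueError(f"{path}: time grid is not uniform with dt = {dt}")
    return RankTimeMatrix(values=values, dt=dt, onset_index=onset_index)


def write_trajectory_csv(trajectory, path) -> None:
    """Long-format network trajectory (time_ms, unit, rate, adaptation)."""
    trajectory.to_frame().to_csv(path, index=False)


def load_preset(name: str) -> dict:
    """Load one of the shipped parameter presets by name."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    path = Path(__file__).parent / "presets" / f"{name}.yaml"
    with path.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
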
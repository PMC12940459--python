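"""Delimited-text I/O for DVHs, dose grids, candidate archives and fronts.

Everything the package writes is plain delimited text and can be read
back by the package (round-trip identity).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .evaluation import CumulativeDVH, DifferentialDVH, cumulative
from .pareto import ParetoPoint

__all__ = [
    "write_dvhs",
    "read_dvhs",
    "write_cumulative_dvh",
    "write_dose_grid",
    "read_dose_grid",
    "write_archive",
    "read_archive",
    "archive_points",
]


def write_dvhs(path: str | Path, dvhs: Dict[str, DifferentialDVH]) -> None:
    """Differential DVHs, one row per (structure, bin)."""
    rows = []
    for name, dvh in dvhs.items():
        for lo, hi, vol in zip(dvh.bin_edges[:-1], dvh.bin_edges[1:], dvh.bin_volume):
            rows.append(
                {"structure": name, "bin_lo_gy": lo, "bin_hi_gy": hi, "volume_cm3": vol}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dvhs(path: str | Path) -> Dict[str, DifferentialDVH]:
    df = pd.read_csv(path, sep="\t")
    required = {"structure", "bin_lo_gy", "bin_hi_gy", "volume_cm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DVH file {path} lacks column(s): {sorted(missing)}")
    out: Dict[str, DifferentialDVH] = {}
    for name, group in df.groupby("structure", sort=False):
        group = group.sort_values("bin_lo_gy")
        edges = np.concatenate(
            [group["bin_lo_gy"].to_numpy(), [group["bin_hi_gy"].iloc[-1]]]
        )
        out[str(name)] = DifferentialDVH(edges, group["volume_cm3"].to_numpy(), str(name))
    return out


def write_cumulative_dvh(path: str | Path, dvhs: Dict[str, DifferentialDVH]) -> None:
    """Cumulative export with both absolute (cm^3) and relative (%) columns."""
    frames = []
    for name, dvh in dvhs.items():
        table = cumulative(dvh).as_table()
        table.insert(0, "structure", name)
        frames.append(table)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_dose_grid(
    path: str | Path, grid: np.ndarray, spacing_mm: Sequence[float]
) -> None:
    """3-D dose grid as text: shape/spacing header plus one value per line."""
    header = [
        "# dose grid",
        "# shape: " + " ".join(str(n) for n in grid.shape),
        "# spacing_mm: " + " ".join(f"{s:g}" for s in spacing_mm),
    ]
    body = "\n".join(f"{v:.6g}" for v in np.asarray(grid, dtype=float).ravel())
    Path(path).write_text("\n".join(header) + "\n" + body + "\n")


def read_dose_grid(path: str | Path) -> Tuple[np.ndarray, np.ndarray]:
    shape = spacing = None
    values: List[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("# shape:"):
            shape = tuple(int(x) for x in line.split(":", 1)[1].split())
        elif line.startswith("# spacing_mm:"):
            spacing = np.array([float(x) for x in line.split(":", 1)[1].split()])
        elif line and not line.startswith("#"):
            values.append(float(line))
    if shape is None or spacing is None:
        raise ValueError(f"{path} is not a dose grid file (missing header)")
    return np.array(values).reshape(shape), spacing


def write_archive(path: str | Path, archive) -> None:
    """Candidate archive: one row per evaluated plan."""
    archive_frame(archive).to_csv(path, sep="\t", index=False)


def archive_frame(archive) -> pd.DataFrame:
    rows = []
    for rec in archive:
        row = {
            "epoch": rec.epoch,
            "particle": rec.particle,
            "feasible": rec.feasible,
            "violation": rec.violation,
            "fitness": rec.fitness,
            "error": rec.error or "",
        }
        if rec.summary is not None:
            row.update(
                p_benefit=rec.summary.p_benefit,
                p_injury=rec.summary.p_injury,
                p_plus=rec.summary.p_plus,
            )
            for name, tcp in rec.summary.tcp_by_target.items():
                row[f"tcp_{name}"] = tcp
            for name, ntcp in rec.summary.ntcp_by_oar.items():
                row[f"ntcp_{name}"] = ntcp
        for k, obj in enumerate(rec.objectives):
            tag = f"{obj.structure}_{obj.direction}"
            row[f"goal_{tag}"] = obj.goal_gy
            row[f"priority_{tag}"] = obj.priority
        rows.append(row)
    return pd.DataFrame(rows)


def read_archive(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"feasible", "p_benefit", "p_injury", "p_plus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"archive file {path} lacks column(s): {sorted(missing)}")
    return df


def archive_points(df: pd.DataFrame, feasible_only: bool = True) -> List[ParetoPoint]:
    """Objective-space points from an archive table."""
    sel = df[df["feasible"]] if feasible_only else df
    return [
        ParetoPoint(
            p_injury=float(row["p_injury"]),
            one_minus_p_benefit=1.0 - float(row["p_benefit"]),
            plan=int(idx),
        )
        for idx, row in sel.iterrows()
    ]
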
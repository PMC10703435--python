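"""File I/O: trajectory and ROI tables, TIFF stacks with YAML sidecars,
and the experiment configuration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .images import CircularROI, FrameStack
from .trajectory import Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_rois_csv",
    "write_rois_csv",
    "save_stack",
    "load_stack",
    "ExperimentConfig",
]

TRAJECTORY_COLUMNS = ["id", "time_min", "value", "excluded"]
ROI_COLUMNS = ["id", "cx", "cy", "r"]


def read_trajectory_csv(path) -> list[Trajectory]:
    """Read the shared trajectory table (`id,time_min,value,excluded`).

    Rows are grouped by id in order of first appearance.  Unsorted times
    are repaired with a warning; duplicate (id, time) pairs are fatal.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"id": str})
    if list(table.columns) != TRAJECTORY_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(TRAJECTORY_COLUMNS)}, "
            f"got {','.join(map(str, table.columns))}"
        )
    if len(table) == 0:
        return []
    for col in ("time_min", "value", "excluded"):
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise ValueError(f"{path}: non-numeric entries in column {col!r}")
    trajectories = []
    for traj_id, group in table.groupby("id", sort=False):
        dup = group["time_min"].duplicated()
        if dup.any():
            t_dup = float(group.loc[dup, "time_min"].iloc[0])
            raise ValueError(
                f"{path}: duplicate time {t_dup:g} min for trajectory {traj_id!r}"
            )
        if not group["time_min"].is_monotonic_increasing:
            warnings.warn(
                f"{path}: unsorted times for trajectory {traj_id!r}; sorting",
                stacklevel=2,
            )
            group = group.sort_values("time_min")
        excluded = frozenset(int(i) for i in np.flatnonzero(group["excluded"].to_numpy() != 0))
        trajectories.append(
            Trajectory(
                id=str(traj_id),
                times=group["time_min"].to_numpy(float),
                values=group["value"].to_numpy(float),
                excluded=excluded,
            )
        )
    return trajectories


def write_trajectory_csv(trajectories: list[Trajectory], path) -> None:
    """Write trajectories to the shared CSV schema."""
    rows = []
    for traj in trajectories:
        for i, (t, v) in enumerate(zip(traj.times, traj.values)):
            rows.append(
                {
                    "id": traj.id,
                    "time_min": t,
                    "value": v,
                    "excluded": int(i in traj.excluded),
                }
            )
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_rois_csv(path) -> list[CircularROI]:
    """Read a manual ROI table (`id,cx,cy,r`, pixel units)."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"id": str})
    if list(table.columns) != ROI_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(ROI_COLUMNS)}, "
            f"got {','.join(map(str, table.columns))}"
        )
    return [
        CircularROI(cx=float(row.cx), cy=float(row.cy), r=float(row.r), id=str(row.id))
        for row in table.itertuples()
    ]


def write_rois_csv(rois: list[CircularROI], path) -> None:
    pd.DataFrame(
        [{"id": roi.id, "cx": roi.cx, "cy": roi.cy, "r": roi.r} for roi in rois],
        columns=ROI_COLUMNS,
    ).to_csv(path, index=False)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_stack(stack: FrameStack, path, dtype: str = "uint16") -> None:
    """Write a multi-page TIFF plus a YAML sidecar with timing metadata.

    Float frames are stored as-is when ``dtype='float32'``; otherwise they
    are rounded and clipped into the unsigned integer range.
    """
    path = Path(path)
    frames = stack.frames
    if dtype == "float32":
        data = frames.astype(np.float32)
    elif dtype in ("uint8", "uint16"):
        info = np.iinfo(dtype)
        data = np.clip(np.round(frames), info.min, info.max).astype(dtype)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "dt_min": float(stack.dt_min),
        "t0_min": float(stack.t0_min),
        "excluded_frames": sorted(int(i) for i in stack.excluded_frames),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def load_stack(path, dt_min: float | None = None, t0_min: float | None = None) -> FrameStack:
    """Read a multi-page TIFF; timing comes from the YAML sidecar unless
    overridden explicitly."""
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if dt_min is None:
        dt_min = float(meta.get("dt_min", 1.0))
    if t0_min is None:
        t0_min = float(meta.get("t0_min", 0.0))
    excluded = frozenset(int(i) for i in meta.get("excluded_frames", []))
    return FrameStack(frames=frames, dt_min=dt_min, t0_min=t0_min, excluded_frames=excluded)


@dataclass
class ExperimentConfig:
    """Configuration of a pipeline run, typically loaded from YAML.

    ``stages`` lists the stages to execute in order (any of ``simulate``,
    ``render``, ``analyze-images``, ``analyze-growth``).  Parameter blocks
    are plain dicts overriding the corresponding dataclass defaults.
    """

    stages: list = field(default_factory=lambda: ["simulate", "analyze-growth"])
    seed: int | None = None
    n_droplets: int = 24
    phage: str | None = None
    sim: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    preset: str = "droplet"
    window_min: float = 40.0
    mask_strategy: str = "otsu"
    stack_path: str | None = None
    flatfield_path: str | None = None
    rois_path: str | None = None
    trajectories_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.__dataclass_fields__}
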
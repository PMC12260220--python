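"""Canonical root-tip trajectory data model, validation and file I/O.

A trajectory is the time-stamped 3-D path of a single primary-root tip,
sampled (nominally) every 3 minutes over up to 7 days of hydroponic growth.
Units are centimetres and seconds throughout; the first sample defines t = 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rootkin")

#: Nominal sampling interval of the acquisition system, seconds.
DEFAULT_DT = 180.0

#: Gaps longer than this (seconds) are reported as tracking dropouts.
GAP_WARN_S = 1800.0

#: Default initial primary-root length at the start of acquisition, cm
#: (seedlings are selected at ~4 cm root length).
DEFAULT_INITIAL_ROOT_LENGTH_CM = 4.0

SPECIES = ("maize", "pea", "synthetic")

_AXES = {"x": 0, "y": 1, "z": 2}


class TrajectoryError(ValueError):
    """Raised when a trajectory violates its invariants."""


@dataclass(frozen=True)
class PlaneConvention:
    """Names the vertical (growth) axis; the two remaining axes span the
    horizontal interaction plane in which neighbour geometry is measured.

    The default puts gravity along ``y`` so the interaction plane is x–z.
    """

    vertical_axis: str = "y"

    def __post_init__(self) -> None:
        if self.vertical_axis not in _AXES:
            raise ValueError(f"vertical_axis must be one of {sorted(_AXES)}")

    @property
    def vertical_index(self) -> int:
        return _AXES[self.vertical_axis]

    @property
    def horizontal_indices(self) -> tuple[int, int]:
        """Indices of the interaction-plane axes, in x<y<z order."""
        return tuple(i for i in range(3) if i != self.vertical_index)  # type: ignore[return-value]

    def horizontal(self, points: np.ndarray) -> np.ndarray:
        """Project (..., 3) points onto the interaction plane -> (..., 2)."""
        pts = np.asarray(points, dtype=float)
        return pts[..., list(self.horizontal_indices)]


@dataclass
class Trajectory:
    """Ordered (t, x, y, z) samples of one root tip.

    Parameters
    ----------
    plant_id : str
        Identifier of the plant.
    species : str
        One of ``maize``, ``pea`` or ``synthetic``.
    t : ndarray, shape (n,)
        Seconds from the first sample; strictly increasing.
    xyz : ndarray, shape (n, 3)
        Tip coordinates in cm.
    dt_nominal : float
        Nominal sampling interval, seconds.
    metadata : dict
        Free-form sidecar metadata (condition, neighbour_id, separation_cm,
        vertical_axis, initial_root_length_cm, ...).
    """

    plant_id: str
    species: str
    t: np.ndarray
    xyz: np.ndarray
    dt_nominal: float = DEFAULT_DT
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.species not in SPECIES:
            raise TrajectoryError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise TrajectoryError("t must be (n,) and xyz (n, 3) with matching n")
        if self.t.size < 3:
            raise TrajectoryError("a trajectory needs at least 3 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xyz)):
            raise TrajectoryError("timestamps and coordinates must be finite")
        if np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise TrajectoryError(
                f"timestamps must be strictly increasing (violation at row {bad})"
            )
        gaps = np.diff(self.t)
        n_gaps = int(np.sum(gaps > GAP_WARN_S))
        if n_gaps:
            logger.warning(
                "trajectory %s: %d inter-sample gap(s) longer than %.0f s "
                "(tracking dropouts tolerated)",
                self.plant_id, n_gaps, GAP_WARN_S,
            )

    def __len__(self) -> int:
        return self.t.size

    @property
    def span(self) -> float:
        """Total duration in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def initial_root_length(self) -> float:
        """Root length at t = 0, cm (metadata override or the 4 cm default)."""
        return float(
            self.metadata.get("initial_root_length_cm", DEFAULT_INITIAL_ROOT_LENGTH_CM)
        )

    def step_lengths(self) -> np.ndarray:
        """Euclidean length of each consecutive step, cm; shape (n-1,)."""
        return np.linalg.norm(np.diff(self.xyz, axis=0), axis=1)

    def path_length(self) -> float:
        """Total arc length of the sampled path, cm."""
        return float(self.step_lengths().sum())

    def cumulative_path_length(self) -> np.ndarray:
        """Arc length from the first sample to each sample, cm; shape (n,)."""
        return np.concatenate([[0.0], np.cumsum(self.step_lengths())])

    def translated(self, offset: Sequence[float]) -> "Trajectory":
        """Rigidly translate all samples by ``offset`` (cm)."""
        return replace(self, xyz=self.xyz + np.asarray(offset, dtype=float))


@dataclass
class PlantPair:
    """Two plants sharing a container, at a stated horizontal separation."""

    plant: Trajectory
    neighbour: Trajectory
    separation: float = 5.0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise TrajectoryError("separation must be positive")

    @property
    def rp0(self) -> np.ndarray:
        """Initial tip position of the focal plant, cm."""
        return self.plant.xyz[0]

    @property
    def rn0(self) -> np.ndarray:
        """Initial tip position of the neighbour, cm."""
        return self.neighbour.xyz[0]

    def translated(self, offset: Sequence[float]) -> "PlantPair":
        return PlantPair(
            self.plant.translated(offset),
            self.neighbour.translated(offset),
            self.separation,
        )


# ---------------------------------------------------------------------------
# File I/O: canonical CSV + JSON sidecar
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["time_s", "x_cm", "y_cm", "z_cm"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as canonical CSV plus a JSON metadata sidecar.

    The CSV has header ``time_s,x_cm,y_cm,z_cm`` with one row per sample;
    the sidecar ``<name>.meta.json`` carries plant_id, species and any
    additional metadata.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": traj.t,
            "x_cm": traj.xyz[:, 0],
            "y_cm": traj.xyz[:, 1],
            "z_cm": traj.xyz[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")
    meta = {
        "plant_id": traj.plant_id,
        "species": traj.species,
        "dt_nominal_s": traj.dt_nominal,
        **traj.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_trajectory(
    path: str | Path,
    convention: PlaneConvention | None = None,
    column_map: dict[str, str] | None = None,
) -> Trajectory:
    """Read a trajectory CSV (plus optional ``.meta.json`` sidecar).

    Parameters
    ----------
    path : path
        CSV with columns ``time_s,x_cm,y_cm,z_cm`` (or names remapped via
        ``column_map`` for foreign exports).
    convention : PlaneConvention, optional
        Recorded into metadata so downstream stages agree on the vertical
        axis; defaults to the sidecar value or vertical ``y``.
    column_map : dict, optional
        Mapping from the file's column names to the canonical ones.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrajectoryError(f"{path}: cannot parse CSV ({exc})") from exc
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing columns {missing}")
    for col in _CSV_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise TrajectoryError(f"{path}: malformed value in {col!r} at line {row}")
        df[col] = vals

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    plant_id = meta.pop("plant_id", path.stem)
    species = meta.pop("species", "synthetic")
    dt_nominal = float(meta.pop("dt_nominal_s", DEFAULT_DT))
    scale = float(meta.pop("unit_scale_to_cm", 1.0))
    if convention is not None:
        meta["vertical_axis"] = convention.vertical_axis

    t = df["time_s"].to_numpy(dtype=float)
    xyz = df[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float) * scale
    return Trajectory(
        plant_id=plant_id,
        species=species,
        t=t - t[0],
        xyz=xyz,
        dt_nominal=dt_nominal,
        metadata=meta,
    )


def read_manifest(path: str | Path) -> list[dict]:
    """Read a cohort manifest: JSON array of entries with at least
    ``trajectory_path`` and ``condition``; paths resolved relative to the
    manifest's directory."""
    path = Path(path)
    entries = json.loads(path.read_text())
    if not isinstance(entries, list):
        raise TrajectoryError(f"{path}: manifest must be a JSON array")
    out = []
    for e in entries:
        e = dict(e)
        e["trajectory_path"] = str((path.parent / e["trajectory_path"]).resolve())
        out.append(e)
    return out


# ---------------------------------------------------------------------------
# Hourly resampling
# ---------------------------------------------------------------------------

def hourly_indices(t: np.ndarray) -> np.ndarray:
    """Indices of the samples nearest each whole hour 0, 1h, 2h, ...

    The number of hours is ``floor(span / 3600) + 1`` including t = 0.
    """
    t = np.asarray(t, dtype=float)
    rel = t - t[0]
    n_hours = int(rel[-1] // 3600) + 1
    targets = np.arange(n_hours) * 3600.0
    idx = np.searchsorted(rel, targets)
    idx = np.clip(idx, 1, t.size - 1)
    choose_left = (targets - rel[idx - 1]) <= (rel[idx] - targets)
    return np.where(choose_left, idx - 1, idx)


def resample_hourly(traj: Trajectory) -> Trajectory:
    """Subsample a trajectory at the sample nearest each whole hour."""
    if traj.span < 2 * 3600:
        raise TrajectoryError("resample_hourly needs a span of at least 2 h")
    idx = hourly_indices(traj.t)
    return replace(traj, t=traj.t[idx], xyz=traj.xyz[idx])


def validate_file(path: str | Path) -> tuple[bool, str]:
    """Validate one trajectory file; returns (ok, human-readable report)."""
    try:
        traj = read_trajectory(path)
    except (TrajectoryError, FileNotFoundError) as exc:
        return False, f"{path}: INVALID — {exc}"
    return True, (
        f"{path}: OK — {len(traj)} samples, span {traj.span / 3600:.1f} h, "
        f"species {traj.species}"
    )
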
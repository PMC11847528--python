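"""Core domain containers shared across the pipeline.

Conventions used throughout the package:

* Streamline points live in world millimetres; volumes are indexed with
  0-based voxel indices, and the voxel with index ``i`` occupies the
  half-open box ``[i, i+1)`` in continuous index space.  World -> index
  conversion goes through the inverse of the grid affine.
* All volumes for one cohort share a single :class:`GridSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "ParcellationAtlas",
    "Tractogram",
    "RoiTimeSeries",
    "LesionMask",
    "BehaviorTable",
    "SyntheticTruth",
    "GeometryError",
    "ConfigurationError",
    "round_half_up",
]

SCORE_NAMES = ("motor_left", "motor_right", "executive", "processing_speed")


class GeometryError(ValueError):
    """Grids, affines or coordinates are mutually inconsistent."""


class ConfigurationError(ValueError):
    """A requested configuration is geometrically or numerically impossible."""


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (``round(0.5*10)==5``).

    Python's builtin round is banker's rounding; the subject-count
    thresholding and prevalence rules need deterministic half-up.
    """
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class GridSpec:
    """A 3-D voxel grid with a world-coordinate affine.

    Parameters
    ----------
    shape
        Number of voxels along each axis, each component >= 8.
    affine
        4x4 map from continuous voxel-index space to world mm.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 8 for s in shape):
            raise ConfigurationError(f"grid shape must be 3 components >= 8, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        det = np.linalg.det(aff[:3, :3])
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise GeometryError("affine is not invertible")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to continuous voxel-index coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def index_to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "GridSpec", atol: float = 1e-8) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclass
class ParcellationAtlas:
    """Integer-labelled parcellation; 0 is background, 1..P are parcels."""

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise GeometryError("atlas labels do not match grid shape")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be >= 0")

    @property
    def n_parcels(self) -> int:
        return int(self.labels.max())

    def parcel_sizes(self) -> np.ndarray:
        """Voxel count per parcel, index 0 unused (background not counted)."""
        return np.bincount(self.labels.ravel(), minlength=self.n_parcels + 1)


@dataclass
class Tractogram:
    """One normative subject's streamlines, as polylines in world mm."""

    subject_id: str
    streamlines: list[np.ndarray]

    def __post_init__(self) -> None:
        cleaned = []
        for s in self.streamlines:
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError("each streamline must be an (n>=2, 3) polyline")
            if not np.all(np.isfinite(arr)):
                raise ValueError("streamline coordinates must be finite")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def arc_lengths(self) -> np.ndarray:
        """Polyline arc length (sum of segment lengths) per streamline, mm."""
        return np.array(
            [float(np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1))) for s in self.streamlines]
        )


@dataclass
class RoiTimeSeries:
    """T x P matrix of mean parcel time courses for one subject."""

    subject_id: str
    data: np.ndarray
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be 2-D (timepoints x parcels)")
        if np.any(np.all(self.data == 0, axis=0)):
            raise ValueError("time series contains a constant-zero parcel column")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class LesionMask:
    """Binary lesion footprint for one patient on the template grid."""

    patient_id: str
    grid: GridSpec
    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.shape != self.grid.shape:
            raise GeometryError("lesion mask does not match grid shape")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("lesion mask must be binary")
        self.data = arr.astype(bool)
        if not self.data.any():
            raise ValueError("lesion mask has no nonzero voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class BehaviorTable:
    """Per-patient behavioral scores.

    Motor scores follow the limb motor convention (10 minus the summed
    upper/lower limb impairment items, range 2..10); cognitive scores are
    continuous composites.
    """

    patient_ids: list[str]
    scores: "pd.DataFrame" = None  # type: ignore[name-defined]

    def __post_init__(self) -> None:
        import pandas as pd

        df = pd.DataFrame(self.scores)
        missing = [c for c in SCORE_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"behavior table missing score columns {missing}")
        if len(df) != len(self.patient_ids):
            raise ValueError("behavior table row count does not match patient ids")
        for col in ("motor_left", "motor_right"):
            vals = df[col].to_numpy(float)
            if np.any((vals < 2) | (vals > 10)):
                raise ValueError(f"{col} outside the limb motor range [2, 10]")
        if not np.all(np.isfinite(df[list(SCORE_NAMES)].to_numpy(float))):
            raise ValueError("behavior scores must be finite")
        df = df.copy()
        df.index = list(self.patient_ids)
        df.index.name = "patient_id"
        self.scores = df


@dataclass
class SyntheticTruth:
    """Ground truth of the planted score model, for recovery checks."""

    seed: int
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    planted_r2: dict[str, float] = field(default_factory=dict)
    latent: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, r2 in self.planted_r2.items():
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"planted R^2 for {name} outside [0, 1]")


def common_grid(grids: Sequence[GridSpec]) -> GridSpec:
    """Return the shared grid, raising if any pair disagrees."""
    first = grids[0]
    for g in grids[1:]:
        if not first.matches(g):
            raise GeometryError("inputs are not on a common grid")
    return first
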
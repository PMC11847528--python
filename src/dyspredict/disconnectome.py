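"""Probabilistic structural disconnection maps (pSDM / tSDM).

A patient's lesion is embedded in each normative subject's tractogram:
streamlines that pass through lesion voxels are the disconnected set, and
every voxel they traverse is marked as disconnected for that subject.  The
pSDM is the across-subject frequency of that mark; counts are stored as
integers so every voxel value is exactly ``k / N``.  Thresholding at
``Pth`` keeps voxels disconnected in at least ``round(Pth * N)`` subjects
(round-half-up), e.g. at least 40 of 403 subjects for ``Pth = 0.1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GeometryError, GridSpec, LesionMask, Tractogram, common_grid, round_half_up
from .raster import mask_hits, rasterize_polyline, rasterize_tractogram

__all__ = [
    "ProbDisconnectionMap",
    "ThresholdedMap",
    "RasterizedCohort",
    "streamline_intersects_mask",
    "subject_disconnection_map",
    "build_psdm",
    "threshold_psdm",
    "lesion_volume",
    "lesion_overlap_map",
]


@dataclass
class ProbDisconnectionMap:
    """Voxelwise disconnection counts over N normative subjects.

    ``counts[v]`` is the number of subjects for whom voxel ``v`` lies on a
    lesion-intersecting streamline; the probability map is ``counts / N``.
    """

    patient_id: str
    grid: GridSpec
    counts: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise GeometryError("pSDM counts do not match grid shape")
        if self.counts.min() < 0 or self.counts.max() > self.n_subjects:
            raise ValueError("pSDM counts outside [0, n_subjects]")

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts.astype(np.float64) / self.n_subjects


@dataclass
class ThresholdedMap:
    """Binary disconnection map retained at probability threshold ``pth``."""

    patient_id: str
    grid: GridSpec
    data: np.ndarray
    pth: float
    min_count: int

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


class RasterizedCohort:
    """Cohort tractograms rasterized once and reused across patients.

    Holds, per subject, the CSR pair (voxel ids, offsets) from
    :func:`dyspredict.raster.rasterize_tractogram`; building per-patient
    disconnection maps then reduces to boolean indexing.
    """

    def __init__(self, tractograms: Sequence[Tractogram], grid: GridSpec):
        if len(tractograms) == 0:
            raise ValueError("need at least one tractogram")
        self.grid = grid
        self.subject_ids = [t.subject_id for t in tractograms]
        self.rasters = [rasterize_tractogram(t, grid) for t in tractograms]

    @property
    def n_subjects(self) -> int:
        return len(self.rasters)

    def subject_hit_mask(self, subject: int, lesion_flat: np.ndarray) -> np.ndarray:
        """Per-streamline lesion-intersection flags for one subject."""
        values, offsets = self.rasters[subject]
        return mask_hits(values, offsets, lesion_flat)

    def subject_disconnection(self, subject: int, lesion_flat: np.ndarray) -> np.ndarray:
        """Flat boolean volume of voxels traversed by intersecting streamlines."""
        values, offsets = self.rasters[subject]
        hits = mask_hits(values, offsets, lesion_flat)
        out = np.zeros(self.grid.n_voxels, dtype=bool)
        if hits.any():
            lengths = np.diff(offsets)
            take = np.repeat(hits, lengths)
            out[values[take]] = True
        return out

    def psdm_counts(self, lesion: LesionMask) -> np.ndarray:
        if not lesion.grid.matches(self.grid):
            raise GeometryError("lesion grid does not match cohort grid")
        flat = lesion.data.ravel()
        counts = np.zeros(self.grid.n_voxels, dtype=np.int32)
        for s in range(self.n_subjects):
            counts += self.subject_disconnection(s, flat)
        return counts.reshape(self.grid.shape)


def streamline_intersects_mask(streamline: np.ndarray, m: LesionMask) -> bool:
    """True iff the polyline traverses at least one lesion voxel."""
    vox = rasterize_polyline(streamline, m.grid)
    return bool(m.data.ravel()[vox].any())


def subject_disconnection_map(t: Tractogram, m: LesionMask, grid: GridSpec) -> np.ndarray:
    """Binary volume of voxels on lesion-intersecting streamlines (one subject)."""
    if not m.grid.matches(grid):
        raise GeometryError("lesion and target grid differ")
    values, offsets = rasterize_tractogram(t, grid)
    hits = mask_hits(values, offsets, m.data.ravel())
    out = np.zeros(grid.n_voxels, dtype=bool)
    if hits.any():
        lengths = np.diff(offsets)
        out[values[np.repeat(hits, lengths)]] = True
    return out.reshape(grid.shape)


def build_psdm(
    tractograms: Sequence[Tractogram] | RasterizedCohort,
    m: LesionMask,
) -> ProbDisconnectionMap:
    """Disconnection frequency of each voxel across the normative cohort."""
    if isinstance(tractograms, RasterizedCohort):
        cohort = tractograms
    else:
        cohort = RasterizedCohort(list(tractograms), m.grid)
    counts = cohort.psdm_counts(m)
    return ProbDisconnectionMap(m.patient_id, cohort.grid, counts, cohort.n_subjects)


def threshold_psdm(p: ProbDisconnectionMap, pth: float) -> ThresholdedMap:
    """Keep voxels disconnected in at least ``round(pth * N)`` subjects.

    Round-half-up; a count threshold of 0 is promoted to 1 so an all-zero
    map never thresholds to everything.
    """
    if not (0.0 < pth < 1.0):
        raise ValueError("pth must lie in (0, 1)")
    min_count = max(1, round_half_up(pth * p.n_subjects))
    data = p.counts >= min_count
    return ThresholdedMap(p.patient_id, p.grid, data, pth, min_count)


def lesion_volume(m: LesionMask) -> float:
    """Lesion volume in cm^3 (voxel count times voxel volume / 1000)."""
    return m.n_voxels * m.grid.voxel_volume / 1000.0


def lesion_overlap_map(lesions: Sequence[LesionMask]) -> np.ndarray:
    """Voxelwise count of patients whose lesion covers each voxel."""
    grid = common_grid([m.grid for m in lesions])
    out = np.zeros(grid.shape, dtype=np.int32)
    for m in lesions:
        out += m.data
    return out
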
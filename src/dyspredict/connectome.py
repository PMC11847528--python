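"""Group and lesion-modified structural / functional connectivity.

Structural connectivity (SC) counts streamlines whose endpoints fall in a
parcel pair; the group matrix averages edge weights over all subjects but
keeps only edges present in at least half of them.  The lesioned group
matrix (SC_L) repeats the construction after removing lesion-intersecting
streamlines, and SC_LD is the elementwise relative change.

Functional connectivity (FC) is the Pearson correlation of parcel time
courses; the lesioned form zeroes all edges incident to parcels that the
patient's 0.1-thresholded disconnection map overlaps by at least ten
voxels.  Patients with no such parcel are excluded from the functional
analysis rather than silently processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GeometryError, ParcellationAtlas, RoiTimeSeries, Tractogram, round_half_up
from .disconnectome import ThresholdedMap

__all__ = [
    "ConnMatrix",
    "AffectedParcelSet",
    "FcExclusionError",
    "subject_sc",
    "group_sc",
    "subject_fc",
    "group_fc",
    "affected_parcels",
    "lesioned_fc",
    "relative_change_matrix",
    "endpoint_labels",
    "sc_from_endpoint_labels",
]


class FcExclusionError(ValueError):
    """Patient has no lesion-affected parcel; excluded from the FC analysis."""


@dataclass
class ConnMatrix:
    """Symmetric weighted parcel x parcel connectivity matrix."""

    weights: np.ndarray
    modality: str  # "SC" | "FC"
    form: str  # "subject" | "group" | "lesioned" | "relative_change"
    patient_id: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        if self.modality not in ("SC", "FC"):
            raise ValueError("modality must be SC or FC")
        self.weights = w

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]


@dataclass
class AffectedParcelSet:
    """Parcels overlapped by a patient's thresholded disconnection map."""

    patient_id: str
    parcels: set[int]
    overlap_voxels: dict[int, int] = field(default_factory=dict)
    min_overlap: int = 10


def endpoint_labels(t: Tractogram, atlas: ParcellationAtlas) -> np.ndarray:
    """(n_streamlines, 2) parcel labels of each streamline's two endpoints.

    The endpoint is assigned to the voxel containing it; endpoints outside
    the grid or in background get label 0.
    """
    if len(t) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    ends = np.array([[s[0], s[-1]] for s in t.streamlines])  # (n, 2, 3) world
    out = np.zeros((len(t), 2), dtype=np.int64)
    for k in range(2):
        idx = np.floor(atlas.grid.world_to_index(ends[:, k, :])).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < np.array(atlas.grid.shape)), axis=1)
        out[ok, k] = atlas.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return out


def sc_from_endpoint_labels(
    labels: np.ndarray, n_parcels: int, keep: np.ndarray | None = None
) -> np.ndarray:
    """Endpoint-pair streamline counts as a symmetric (P, P) matrix."""
    if keep is not None:
        labels = labels[keep]
    a, b = labels[:, 0], labels[:, 1]
    valid = (a > 0) & (b > 0) & (a != b)
    a, b = a[valid] - 1, b[valid] - 1
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    w = np.zeros((n_parcels, n_parcels))
    np.add.at(w, (lo, hi), 1.0)
    return w + w.T


def subject_sc(t: Tractogram, atlas: ParcellationAtlas) -> ConnMatrix:
    """Streamline-count SC for one subject (endpoint-pair convention)."""
    labels = endpoint_labels(t, atlas)
    w = sc_from_endpoint_labels(labels, atlas.n_parcels)
    return ConnMatrix(w, "SC", "subject")


def group_sc(subject_mats: Sequence[ConnMatrix], prevalence: float = 0.5) -> ConnMatrix:
    """Mean SC over subjects, restricted to edges present in >= 50 % of them.

    An edge passes if nonzero in at least ``round(prevalence * N)`` subjects
    (round-half-up, minimum 1); passing edges take the mean weight over all
    N subjects (zeros included), others are 0.
    """
    if len(subject_mats) < 2:
        raise ValueError("need at least two subject matrices")
    P = subject_mats[0].n_parcels
    stack = np.stack([m.weights for m in subject_mats])
    if stack.shape[1:] != (P, P):
        raise ValueError("subject matrices differ in size")
    n = len(subject_mats)
    present = (stack != 0).sum(axis=0)
    min_subjects = max(1, round_half_up(prevalence * n))
    mean = stack.mean(axis=0)
    mean[present < min_subjects] = 0.0
    return ConnMatrix(mean, subject_mats[0].modality, "group")


def subject_fc(ts: RoiTimeSeries) -> ConnMatrix:
    """Pearson-correlation FC for one subject, diagonal zeroed."""
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = data.std(axis=0)
    dead = np.where(sd == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance parcel column(s): {(dead + 1).tolist()}")
    w = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(w, 0.0)
    return ConnMatrix(w, "FC", "subject")


def group_fc(subject_fcs: Sequence[ConnMatrix]) -> ConnMatrix:
    """Arithmetic mean of subject FC matrices (no Fisher-z averaging)."""
    stack = np.stack([m.weights for m in subject_fcs])
    return ConnMatrix(stack.mean(axis=0), "FC", "group")


def affected_parcels(
    tsdm01: ThresholdedMap, atlas: ParcellationAtlas, min_overlap: int = 10
) -> AffectedParcelSet:
    """Parcels whose overlap with the 0.1-thresholded map is >= ``min_overlap``."""
    labels = atlas.labels[tsdm01.data.astype(bool)]
    counts = np.bincount(labels[labels > 0], minlength=atlas.n_parcels + 1)
    parcels = {int(p) for p in np.where(counts >= min_overlap)[0] if p > 0}
    overlaps = {int(p): int(counts[p]) for p in parcels}
    return AffectedParcelSet(tsdm01.patient_id, parcels, overlaps, min_overlap)


def lesioned_fc(
    subject_fcs: Sequence[ConnMatrix], affected: AffectedParcelSet
) -> ConnMatrix:
    """Zero edges of affected parcels per subject, then average (FC_L).

    Raises :class:`FcExclusionError` when the affected set is empty — such
    patients are excluded from the functional analysis.
    """
    if len(subject_fcs) == 0:
        raise ValueError("need at least one subject FC")
    if not affected.parcels:
        raise FcExclusionError(
            f"patient {affected.patient_id}: no parcel reaches the "
            f"{affected.min_overlap}-voxel overlap; excluded from FC analysis"
        )
    P = subject_fcs[0].n_parcels
    idx = np.array(sorted(affected.parcels)) - 1
    stack = np.stack([m.weights for m in subject_fcs])
    stack = stack.copy()
    stack[:, idx, :] = 0.0
    stack[:, :, idx] = 0.0
    return ConnMatrix(stack.mean(axis=0), "FC", "lesioned", affected.patient_id)


def relative_change_matrix(lesioned: ConnMatrix, intact: ConnMatrix) -> ConnMatrix:
    """Elementwise (lesioned - intact) / intact; 0 where intact is 0."""
    if lesioned.modality != intact.modality:
        raise ValueError("modality mismatch between lesioned and intact matrices")
    if lesioned.n_parcels != intact.n_parcels:
        raise ValueError("matrix size mismatch")
    w = np.zeros_like(intact.weights)
    nz = intact.weights != 0
    w[nz] = (lesioned.weights[nz] - intact.weights[nz]) / intact.weights[nz]
    return ConnMatrix(w, intact.modality, "relative_change", lesioned.patient_id)
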
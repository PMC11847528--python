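"""Feature assembly and PCA reduction.

Each lesion-derived feature (lesion mask, pSDM, the five tSDMs, SC_LD,
FC_LD, and the four nodal-change vectors) is vectorized per patient,
columns that are zero for every patient are eliminated, and the patient x
element matrix is reduced by mean-centred PCA keeping the smallest number
of components whose cumulative explained-variance ratio reaches 99 %.

Vectorization orders are fixed: volumes flatten in C order over voxel
indices; symmetric matrices take the upper triangle row-major, excluding
the diagonal; nodal vectors are used as-is.  The retained-column map makes
every column traceable back to its original voxel / edge / node id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "FeatureMatrix",
    "PcaBasis",
    "vectorize_volume",
    "vectorize_matrix",
    "assemble_feature_matrix",
    "fit_pca",
    "project",
]


def vectorize_volume(vol: np.ndarray) -> np.ndarray:
    """Flatten a volume in C order."""
    return np.asarray(vol, dtype=float).ravel(order="C")


def vectorize_matrix(w: np.ndarray) -> np.ndarray:
    """Upper triangle (row-major, diagonal excluded) of a symmetric matrix."""
    w = np.asarray(w, dtype=float)
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu]


@dataclass
class FeatureMatrix:
    """Patients x retained-elements matrix with provenance."""

    feature_id: str
    patient_ids: list[str]
    values: np.ndarray
    column_map: np.ndarray  # retained column -> original element id

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.column_map = np.asarray(self.column_map, dtype=np.int64)
        if self.values.shape != (len(self.patient_ids), len(self.column_map)):
            raise ValueError("feature matrix shape inconsistent with ids / column map")
        if len(np.unique(self.column_map)) != len(self.column_map):
            raise ValueError("column map must be injective")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]


def assemble_feature_matrix(
    per_patient_vectors: dict[str, np.ndarray] | list[np.ndarray],
    feature_id: str,
    patient_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Stack per-patient vectors and drop columns zero for every patient."""
    if isinstance(per_patient_vectors, dict):
        patient_ids = list(per_patient_vectors)
        vectors = [np.asarray(per_patient_vectors[p], dtype=float) for p in patient_ids]
    else:
        vectors = [np.asarray(v, dtype=float) for v in per_patient_vectors]
        if patient_ids is None:
            patient_ids = [f"pat-{i:03d}" for i in range(len(vectors))]
    lengths = {v.shape[0] for v in vectors}
    if len(lengths) != 1:
        bad = [p for p, v in zip(patient_ids, vectors) if v.shape[0] != vectors[0].shape[0]]
        raise ValueError(f"feature vector length mismatch for patients {bad}")
    mat = np.stack(vectors)
    keep = np.where(np.any(mat != 0, axis=0))[0]
    return FeatureMatrix(feature_id, patient_ids, mat[:, keep], keep)


@dataclass
class PcaBasis:
    """Mean-centred PCA basis with the 99 %-variance retention count."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_retained: int
    variance_target: float

    @property
    def retained_variance(self) -> float:
        return float(self.explained_variance_ratio[: self.n_retained].sum())


def fit_pca(fm: FeatureMatrix, variance_target: float = 0.99) -> PcaBasis:
    """Full mean-centred PCA; retain the smallest component count reaching
    the cumulative explained-variance target.

    Component signs are fixed deterministically: the largest-magnitude
    loading entry of each component is made positive.
    """
    if fm.n_patients < 3:
        raise ValueError("PCA needs at least 3 patients")
    pca = PCA(svd_solver="full")
    pca.fit(fm.values)
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    n_retained = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_retained = min(n_retained, len(ratios))
    return PcaBasis(pca.mean_, comps, ratios, n_retained, variance_target)


def project(fm: FeatureMatrix, basis: PcaBasis, n_components: int | None = None) -> np.ndarray:
    """Centred projection of the feature matrix onto the retained loadings."""
    if fm.values.shape[1] != basis.components.shape[1]:
        raise ValueError("feature column count does not match basis")
    m = basis.n_retained if n_components is None else n_components
    return (fm.values - basis.mean) @ basis.components[:m].T
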
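"""File formats: NIfTI volumes, TCK / JSON-lines tractograms, TSV tables.

Volumes go through nibabel; tractograms are written as TCK (world mm,
RAS) with a plain JSON-lines fallback (one streamline per line, an array
of [x, y, z] triples); all tabular outputs are TSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .connectome import AffectedParcelSet, ConnMatrix
from .core import (
    BehaviorTable,
    GridSpec,
    LesionMask,
    ParcellationAtlas,
    RoiTimeSeries,
    SyntheticTruth,
    Tractogram,
)
from .disconnectome import ProbDisconnectionMap, ThresholdedMap
from .graphmetrics import NodalVector

__all__ = [
    "save_volume",
    "load_volume",
    "save_atlas",
    "load_atlas",
    "save_lesion",
    "load_lesion",
    "save_tractogram",
    "load_tractogram",
    "save_timeseries",
    "load_timeseries",
    "save_behavior",
    "load_behavior",
    "save_psdm",
    "save_tsdm",
    "save_conn_matrix",
    "load_conn_matrix",
    "save_conn_matrix_mtx",
    "save_nodal_vector",
    "save_affected_parcels",
    "save_feature_matrix",
    "load_feature_matrix",
    "save_pca_basis",
    "load_pca_basis",
    "save_truth",
    "load_truth",
]


def save_volume(data: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), grid.affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data, GridSpec(tuple(data.shape), img.affine)


def save_atlas(atlas: ParcellationAtlas, path: str | Path) -> None:
    save_volume(atlas.labels.astype(np.int32), atlas.grid, path)


def load_atlas(path: str | Path) -> ParcellationAtlas:
    data, grid = load_volume(path)
    return ParcellationAtlas(grid, data.astype(np.int32))


def save_lesion(m: LesionMask, path: str | Path) -> None:
    save_volume(m.data.astype(np.uint8), m.grid, path)


def load_lesion(path: str | Path, patient_id: str | None = None) -> LesionMask:
    data, grid = load_volume(path)
    pid = patient_id or Path(path).name.split(".")[0]
    return LesionMask(pid, grid, data.astype(bool))


def save_tractogram(t: Tractogram, path: str | Path) -> None:
    """Write TCK (.tck) or JSON-lines (.jsonl) depending on the suffix."""
    path = Path(path)
    if path.suffix == ".tck":
        tg = nib.streamlines.Tractogram(
            [s.astype(np.float32) for s in t.streamlines], affine_to_rasmm=np.eye(4)
        )
        nib.streamlines.save(tg, str(path))
    elif path.suffix == ".jsonl":
        with open(path, "w") as fh:
            for s in t.streamlines:
                fh.write(json.dumps(np.round(s, 6).tolist()) + "\n")
    else:
        raise ValueError(f"unsupported tractogram format {path.suffix!r}")


def load_tractogram(path: str | Path, subject_id: str | None = None) -> Tractogram:
    path = Path(path)
    sid = subject_id or path.name.split(".")[0]
    if path.suffix == ".tck":
        tf = nib.streamlines.load(str(path))
        streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    elif path.suffix == ".jsonl":
        with open(path) as fh:
            streamlines = [np.asarray(json.loads(line), dtype=float) for line in fh if line.strip()]
    else:
        raise ValueError(f"unsupported tractogram format {path.suffix!r}")
    return Tractogram(sid, streamlines)


def save_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    cols = {f"parcel_{p + 1}": ts.data[:, p] for p in range(ts.n_parcels)}
    df = pd.DataFrame(cols)
    df.insert(0, "time_s", np.arange(ts.n_timepoints) * ts.sampling_interval)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_timeseries(path: str | Path, subject_id: str | None = None) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    sid = subject_id or Path(path).name.split(".")[0]
    t = df["time_s"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    data = df[[c for c in df.columns if c.startswith("parcel_")]].to_numpy()
    return RoiTimeSeries(sid, data, dt)


def save_behavior(table: BehaviorTable, path: str | Path) -> None:
    table.scores.to_csv(path, sep="\t", float_format="%.6g")


def load_behavior(path: str | Path) -> BehaviorTable:
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    return BehaviorTable(list(df.index), df.reset_index(drop=True))


def save_psdm(p: ProbDisconnectionMap, path_prob: str | Path, path_counts: str | Path | None = None) -> None:
    """Float32 probability map plus an exact integer-count companion."""
    save_volume(p.probabilities.astype(np.float32), p.grid, path_prob)
    if path_counts is not None:
        save_volume(p.counts.astype(np.int32), p.grid, path_counts)


def save_tsdm(t: ThresholdedMap, path: str | Path) -> None:
    save_volume(t.data.astype(np.uint8), t.grid, path)


def save_conn_matrix(m: ConnMatrix, path: str | Path) -> None:
    labels = [f"parcel_{i + 1}" for i in range(m.n_parcels)]
    df = pd.DataFrame(m.weights, index=labels, columns=labels)
    with open(path, "w") as fh:
        fh.write(f"# modality={m.modality} form={m.form} patient={m.patient_id or '-'}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def load_conn_matrix(path: str | Path) -> ConnMatrix:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    pid = None if meta.get("patient") in (None, "-") else meta["patient"]
    return ConnMatrix(df.to_numpy(), meta["modality"], meta["form"], pid)


def save_conn_matrix_mtx(m: ConnMatrix, path: str | Path) -> None:
    mmwrite(str(path), coo_matrix(m.weights))


def load_conn_matrix_mtx(path: str | Path, modality: str = "SC", form: str = "group") -> ConnMatrix:
    return ConnMatrix(np.asarray(mmread(str(path)).todense()), modality, form)


def save_nodal_vector(v: NodalVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# metric={v.metric} modality={v.modality} form={v.form} "
                 f"patient={v.patient_id or '-'}\n")
        fh.write("parcel\tvalue\n")
        for i, val in enumerate(v.values):
            fh.write(f"{i + 1}\t{val:.10g}\n")


def save_affected_parcels(sets: list[AffectedParcelSet], path: str | Path) -> None:
    rows = []
    for s in sets:
        for p in sorted(s.parcels):
            rows.append({"patient_id": s.patient_id, "parcel": p, "overlap": s.overlap_voxels[p]})
    pd.DataFrame(rows, columns=["patient_id", "parcel", "overlap"]).to_csv(
        path, sep="\t", index=False
    )


def save_feature_matrix(fm: "FeatureMatrix", path_tsv: str | Path) -> None:
    """Patients x elements TSV plus a sidecar YAML column map (.map.yaml)."""
    from .features import FeatureMatrix  # noqa: F401 - type only

    df = pd.DataFrame(
        fm.values,
        index=fm.patient_ids,
        columns=[f"e{int(c)}" for c in fm.column_map],
    )
    df.index.name = "patient_id"
    df.to_csv(path_tsv, sep="\t", float_format="%.10g")
    sidecar = Path(str(path_tsv)).with_suffix(".map.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"feature_id": fm.feature_id, "column_map": fm.column_map.tolist()}, fh
        )


def load_feature_matrix(path_tsv: str | Path) -> "FeatureMatrix":
    from .features import FeatureMatrix

    df = pd.read_csv(path_tsv, sep="\t", index_col="patient_id")
    sidecar = Path(str(path_tsv)).with_suffix(".map.yaml")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    return FeatureMatrix(
        meta["feature_id"], list(df.index), df.to_numpy(float), np.asarray(meta["column_map"])
    )


def save_pca_basis(basis: "PcaBasis", path_tsv: str | Path) -> None:
    """Loadings as TSV (components x elements) with YAML metadata sidecar."""
    from .features import PcaBasis  # noqa: F401 - type only

    pd.DataFrame(basis.components).to_csv(path_tsv, sep="\t", float_format="%.10g")
    sidecar = Path(str(path_tsv)).with_suffix(".meta.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "mean": basis.mean.tolist(),
                "explained_variance_ratio": basis.explained_variance_ratio.tolist(),
                "n_retained": int(basis.n_retained),
                "variance_target": float(basis.variance_target),
            },
            fh,
        )


def load_pca_basis(path_tsv: str | Path) -> "PcaBasis":
    from .features import PcaBasis

    comps = pd.read_csv(path_tsv, sep="\t", index_col=0).to_numpy(float)
    sidecar = Path(str(path_tsv)).with_suffix(".meta.yaml")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    return PcaBasis(
        np.asarray(meta["mean"]),
        comps,
        np.asarray(meta["explained_variance_ratio"]),
        int(meta["n_retained"]),
        float(meta["variance_target"]),
    )


def save_truth(truth: SyntheticTruth, path: str | Path) -> None:
    doc = {
        "seed": truth.seed,
        "noise_sd": {k: float(v) for k, v in truth.noise_sd.items()},
        "planted_r2": {k: float(v) for k, v in truth.planted_r2.items()},
        "weights": {k: np.asarray(v).tolist() for k, v in truth.weights.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticTruth(
        seed=doc["seed"],
        weights={k: np.asarray(v) for k, v in doc["weights"].items()},
        noise_sd=doc["noise_sd"],
        planted_r2=doc["planted_r2"],
    )
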
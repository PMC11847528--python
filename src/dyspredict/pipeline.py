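"""End-to-end orchestration: simulate -> disconnectome -> connectomes ->
graph metrics -> features -> prediction -> report.

The pipeline is organised as stage functions over in-memory objects; the
top-level :func:`run_pipeline` threads them together, writes the artifacts
and a run manifest (config hash, per-stage wall clock, output checksums),
and caches whole runs by config hash: re-running with an unchanged config
and seed reloads the stored results and reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .connectome import (
    AffectedParcelSet,
    ConnMatrix,
    FcExclusionError,
    affected_parcels,
    endpoint_labels,
    group_fc,
    group_sc,
    lesioned_fc,
    relative_change_matrix,
    sc_from_endpoint_labels,
    subject_fc,
)
from .core import SCORE_NAMES, BehaviorTable, GridSpec, LesionMask, SyntheticTruth
from .disconnectome import (
    ProbDisconnectionMap,
    RasterizedCohort,
    ThresholdedMap,
    build_psdm,
    lesion_overlap_map,
    lesion_volume,
    threshold_psdm,
)
from .features import FeatureMatrix, assemble_feature_matrix, fit_pca, project, vectorize_matrix, vectorize_volume
from .graphmetrics import nodal_relative_change, nodal_strength, weighted_clustering
from .predict import CvResult, RidgeConfig, evaluate_feature, fisher_compare, loo_predictions, skill_r2
from .synthetic import (
    default_grid,
    filter_streamlines_by_length,
    generate_cohort,
    generate_lesions,
    plant_behavior_table,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report", "FEATURE_IDS"]

# The 13 lesion-derived features plus the PCA-bypassing lesion volume.
TSDM_THRESHOLDS = (0.1, 0.3, 0.5, 0.7, 0.9)
FEATURE_IDS = (
    "lesion_mask",
    "psdm",
    "tsdm_0.1",
    "tsdm_0.3",
    "tsdm_0.5",
    "tsdm_0.7",
    "tsdm_0.9",
    "sc_ld",
    "fc_ld",
    "k_sc",
    "cc_sc",
    "k_fc",
    "cc_fc",
)


@dataclass
class PipelineConfig:
    """Everything the synthetic end-to-end run needs; all seeds derive from
    ``seed``."""

    # synthetic cohort
    grid_size: int = 32
    voxel_mm: float = 3.0
    n_parcels: int = 60
    n_subjects: int = 25
    n_patients: int = 40
    bundles: int = 25
    n_bundle_pairs: int | None = None
    jitter: float = 1.5
    n_timepoints: int = 120
    lesion_size_range: tuple[int, int] = (10, 300)
    small_lesion_fraction: float = 0.075
    # streamline length filter (world mm)
    min_streamline_mm: float = 30.0
    max_streamline_mm: float = 300.0
    # disconnectome / connectome rules
    thresholds: tuple[float, ...] = TSDM_THRESHOLDS
    min_overlap: int = 10
    prevalence: float = 0.5
    # features / prediction
    variance_target: float = 0.99
    lambdas: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
    fixed_lambda: float | None = None
    permutations: int = 100
    # planted outcome model
    planted_feature: str = "tsdm_0.1"
    planted_r2: dict = field(
        default_factory=lambda: {
            "motor_left": 0.9,
            "motor_right": 0.6,
            "executive": 0.6,
            "processing_speed": 0.3,
        }
    )
    seed: int = 0

    def ridge_config(self) -> RidgeConfig:
        return RidgeConfig(lambdas=tuple(self.lambdas), fixed_lambda=self.fixed_lambda)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lesion_size_range"] = list(self.lesion_size_range)
        d["thresholds"] = list(self.thresholds)
        d["lambdas"] = list(self.lambdas)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("lesion_size_range", "thresholds", "lambdas"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Cohort:
    grid: GridSpec
    atlas: "object"
    tractograms: list
    timeseries: list
    lesions: list[LesionMask]


@dataclass
class PipelineResult:
    config: PipelineConfig
    results: pd.DataFrame
    behavior: BehaviorTable
    truth: SyntheticTruth
    excluded_from_fc: list[str]
    manifest: dict
    cohort: Cohort | None = None


def stage_simulate(cfg: PipelineConfig) -> Cohort:
    grid = default_grid(cfg.grid_size, cfg.voxel_mm)
    atlas, tractograms, timeseries = generate_cohort(
        grid,
        n_parcels=cfg.n_parcels,
        n_subjects=cfg.n_subjects,
        bundles=cfg.bundles,
        jitter=cfg.jitter,
        n_timepoints=cfg.n_timepoints,
        seed=cfg.seed,
        n_bundle_pairs=cfg.n_bundle_pairs,
    )
    tractograms = [
        filter_streamlines_by_length(t, cfg.min_streamline_mm, cfg.max_streamline_mm)
        for t in tractograms
    ]
    lesions = generate_lesions(
        grid,
        n_patients=cfg.n_patients,
        size_range=cfg.lesion_size_range,
        seed=cfg.seed + 1,
        small_fraction=cfg.small_lesion_fraction,
    )
    return Cohort(grid, atlas, tractograms, timeseries, lesions)


def stage_disconnectome(
    cfg: PipelineConfig, cohort: Cohort, raster: RasterizedCohort | None = None
) -> tuple[dict[str, ProbDisconnectionMap], dict[str, dict[float, ThresholdedMap]], pd.DataFrame, np.ndarray]:
    """Per-patient pSDM and tSDMs, lesion volumes and the overlap map."""
    raster = raster or RasterizedCohort(cohort.tractograms, cohort.grid)
    psdms: dict[str, ProbDisconnectionMap] = {}
    tsdms: dict[str, dict[float, ThresholdedMap]] = {}
    for les in cohort.lesions:
        p = build_psdm(raster, les)
        psdms[les.patient_id] = p
        tsdms[les.patient_id] = {th: threshold_psdm(p, th) for th in cfg.thresholds}
    volumes = pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in cohort.lesions],
            "volume_cm3": [lesion_volume(m) for m in cohort.lesions],
        }
    )
    overlap = lesion_overlap_map(cohort.lesions)
    return psdms, tsdms, volumes, overlap


def stage_structural(
    cfg: PipelineConfig, cohort: Cohort, raster: RasterizedCohort
) -> tuple[ConnMatrix, dict[str, ConnMatrix], dict[str, ConnMatrix]]:
    """Group SC, per-patient relative-change SC_LD and lesioned SC_L."""
    P = cohort.atlas.n_parcels
    labels = [endpoint_labels(t, cohort.atlas) for t in cohort.tractograms]
    subject_mats = [
        ConnMatrix(sc_from_endpoint_labels(lab, P), "SC", "subject") for lab in labels
    ]
    sc_g = group_sc(subject_mats, cfg.prevalence)
    sc_ld: dict[str, ConnMatrix] = {}
    sc_l: dict[str, ConnMatrix] = {}
    for les in cohort.lesions:
        flat = les.data.ravel()
        lesioned_mats = []
        for s, lab in enumerate(labels):
            keep = ~raster.subject_hit_mask(s, flat)
            lesioned_mats.append(
                ConnMatrix(sc_from_endpoint_labels(lab, P, keep), "SC", "subject")
            )
        g_l = group_sc(lesioned_mats, cfg.prevalence)
        g_l = ConnMatrix(g_l.weights, "SC", "lesioned", les.patient_id)
        sc_l[les.patient_id] = g_l
        sc_ld[les.patient_id] = relative_change_matrix(g_l, sc_g)
    return sc_g, sc_ld, sc_l


def stage_functional(
    cfg: PipelineConfig, cohort: Cohort, tsdms: dict[str, dict[float, ThresholdedMap]]
) -> tuple[ConnMatrix, dict[str, ConnMatrix], dict[str, ConnMatrix], dict[str, AffectedParcelSet], list[str]]:
    """Group FC, per-patient FC_L / FC_LD and the FC exclusion list."""
    subject_fcs = [subject_fc(ts) for ts in cohort.timeseries]
    fc_g = group_fc(subject_fcs)
    fc_l: dict[str, ConnMatrix] = {}
    fc_ld: dict[str, ConnMatrix] = {}
    affected: dict[str, AffectedParcelSet] = {}
    excluded: list[str] = []
    for les in cohort.lesions:
        tsdm01 = tsdms[les.patient_id][0.1]
        aff = affected_parcels(tsdm01, cohort.atlas, cfg.min_overlap)
        affected[les.patient_id] = aff
        try:
            fl = lesioned_fc(subject_fcs, aff)
        except FcExclusionError:
            excluded.append(les.patient_id)
            continue
        fc_l[les.patient_id] = fl
        fc_ld[les.patient_id] = relative_change_matrix(fl, fc_g)
    return fc_g, fc_l, fc_ld, affected, excluded


def stage_metrics(
    intact: ConnMatrix, lesioned_by_patient: dict[str, ConnMatrix]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-patient relative change in nodal strength and clustering."""
    k_g = nodal_strength(intact)
    cc_g = weighted_clustering(intact)
    dk, dcc = {}, {}
    for pid, g_l in lesioned_by_patient.items():
        k_l = nodal_strength(g_l)
        cc_l = weighted_clustering(g_l)
        dk[pid] = nodal_relative_change(k_l, k_g).values
        dcc[pid] = nodal_relative_change(cc_l, cc_g).values
    return dk, dcc


def stage_features(
    cfg: PipelineConfig,
    cohort: Cohort,
    psdms: dict[str, ProbDisconnectionMap],
    tsdms: dict[str, dict[float, ThresholdedMap]],
    sc_ld: dict[str, ConnMatrix],
    fc_ld: dict[str, ConnMatrix],
    dk_sc: dict[str, np.ndarray],
    dcc_sc: dict[str, np.ndarray],
    dk_fc: dict[str, np.ndarray],
    dcc_fc: dict[str, np.ndarray],
) -> dict[str, FeatureMatrix]:
    """Assemble the 13 feature matrices (zero columns eliminated)."""
    pids = [m.patient_id for m in cohort.lesions]
    feats: dict[str, FeatureMatrix] = {}

    def _assemble(fid, vec_by_pid):
        ids = [p for p in pids if p in vec_by_pid]
        if not ids:
            return
        feats[fid] = assemble_feature_matrix([vec_by_pid[p] for p in ids], fid, ids)

    _assemble("lesion_mask", {m.patient_id: vectorize_volume(m.data) for m in cohort.lesions})
    _assemble("psdm", {pid: vectorize_volume(p.probabilities) for pid, p in psdms.items()})
    for th in cfg.thresholds:
        _assemble(f"tsdm_{th:g}", {pid: vectorize_volume(d[th].data) for pid, d in tsdms.items()})
    _assemble("sc_ld", {pid: vectorize_matrix(m.weights) for pid, m in sc_ld.items()})
    _assemble("fc_ld", {pid: vectorize_matrix(m.weights) for pid, m in fc_ld.items()})
    _assemble("k_sc", dk_sc)
    _assemble("cc_sc", dcc_sc)
    _assemble("k_fc", dk_fc)
    _assemble("cc_fc", dcc_fc)
    return feats


def stage_outcomes(
    cfg: PipelineConfig, feats: dict[str, FeatureMatrix], patient_ids: list[str]
) -> tuple[BehaviorTable, SyntheticTruth]:
    """Plant behavioral scores on the configured true feature."""
    base = feats[cfg.planted_feature]
    if base.patient_ids != patient_ids:
        raise ValueError("planted feature must cover every patient")
    features_by_score = {name: base.values for name in SCORE_NAMES}
    return plant_behavior_table(
        patient_ids,
        features_by_score,
        {k: float(v) for k, v in cfg.planted_r2.items()},
        seed=cfg.seed + 2,
    )


def _evaluate_lesion_volume(
    volumes: pd.DataFrame, behavior: BehaviorTable, cfg: PipelineConfig, score: str
) -> CvResult:
    """Lesion volume bypasses PCA: single-column ridge LOOCV, penalty from
    the same grid by inner LOOCV."""
    x = volumes.set_index("patient_id").loc[behavior.scores.index, "volume_cm3"].to_numpy()
    y = behavior.scores[score].to_numpy(float)
    X = x[:, None]
    rc = cfg.ridge_config()
    best = (-np.inf, rc.grid[0])
    for lam in rc.grid:
        r2 = skill_r2(loo_predictions(X, y, lam), y)
        if r2 > best[0]:
            best = (r2, lam)
    lam_star = best[1]
    pred = loo_predictions(X, y, lam_star)
    r2_obs = skill_r2(pred, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    res = CvResult(
        feature_id="lesion_volume",
        score_name=score,
        r2=r2_obs,
        r2_residual=1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 0.0,
        mse=float(np.mean((y - pred) ** 2)),
        n_pcs=None,
        total_explained_variance=None,
        lambda_=float(lam_star),
        n_patients=len(y),
        predicted=pred,
        actual=y,
    )
    if cfg.permutations > 0:
        # permutations re-select the penalty, mirroring the observed fit
        rng = np.random.default_rng(cfg.seed + 77)
        r2s = np.empty(cfg.permutations)
        for b in range(cfg.permutations):
            yp = y[rng.permutation(len(y))]
            r2s[b] = max(skill_r2(loo_predictions(X, yp, lam), yp) for lam in rc.grid)
        res.permutation_p = float(np.mean(r2s >= res.r2))
    return res


def stage_predict(
    cfg: PipelineConfig,
    feats: dict[str, FeatureMatrix],
    behavior: BehaviorTable,
    volumes: pd.DataFrame,
) -> list[CvResult]:
    rc = cfg.ridge_config()
    results: list[CvResult] = []
    for score in SCORE_NAMES:
        results.append(_evaluate_lesion_volume(volumes, behavior, cfg, score))
    for fid in FEATURE_IDS:
        if fid not in feats:
            continue
        fm = feats[fid]
        if fm.values.shape[1] == 0 or fm.n_patients < 4:
            continue
        basis = fit_pca(fm, cfg.variance_target)
        scores_mat = project(fm, basis)
        ev = basis.explained_variance_ratio[: basis.n_retained]
        for score in SCORE_NAMES:
            y = behavior.scores.loc[fm.patient_ids, score].to_numpy(float)
            res = evaluate_feature(
                scores_mat,
                y,
                rc,
                feature_id=fid,
                score_name=score,
                explained_variance_ratio=ev,
                permutations=cfg.permutations,
                seed=cfg.seed + 17,
            )
            results.append(res)
    return results


def results_table(results: list[CvResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "feature": r.feature_id,
                "score": r.score_name,
                "n_patients": r.n_patients,
                "r2": r.r2,
                "r2_residual": r.r2_residual,
                "mse": r.mse,
                "n_pcs": r.n_pcs,
                "tev_percent": r.total_explained_variance,
                "lambda": r.lambda_,
                "permutation_p": r.permutation_p,
            }
        )
    df = pd.DataFrame(rows)
    # Fisher comparison of every feature against the best feature per score.
    df["fisher_p_vs_best"] = np.nan
    df["best"] = False
    by_res = {(r.feature_id, r.score_name): r for r in results}
    for score in df["score"].unique():
        sub = df[df["score"] == score]
        best_r2 = sub["r2"].max()
        best_rows = sub[sub["r2"] == best_r2]
        df.loc[best_rows.index, "best"] = True
        best_res = by_res[(best_rows.iloc[0]["feature"], score)]
        for i in sub.index:
            other = by_res[(df.loc[i, "feature"], score)]
            df.loc[i, "fisher_p_vs_best"] = fisher_compare(best_res, other).p_value
    return df


def write_report(df: pd.DataFrame, path: str | Path, excluded: list[str] | None = None) -> str:
    """Markdown report mirroring the per-score result tables; best feature
    per score highlighted, Fisher p against the best shown."""
    lines = ["# Outcome prediction results", ""]
    for score in df["score"].unique():
        sub = df[df["score"] == score]
        lines += [f"## {score}", "", "| feature | R² | MSE | # PCs | TEV (%) | perm p | Fisher p vs best |", "|---|---|---|---|---|---|---|"]
        for _, row in sub.iterrows():
            star = "**" if row["best"] else ""
            npcs = "−" if pd.isna(row["n_pcs"]) else int(row["n_pcs"])
            tev = "−" if pd.isna(row["tev_percent"]) else f"{row['tev_percent']:.0f}"
            pp = "−" if pd.isna(row["permutation_p"]) else f"{row['permutation_p']:.4g}"
            lines.append(
                f"| {star}{row['feature']}{star} | {row['r2']:.2f} | {row['mse']:.2f} | "
                f"{npcs} | {tev} | {pp} | {row['fisher_p_vs_best']:.3f} |"
            )
        lines.append("")
    if excluded:
        lines += ["## Excluded from functional analysis", "", ", ".join(excluded), ""]
    text = "\n".join(lines)
    Path(path).write_text(text)
    return text


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
    keep_cohort: bool = False,
    write_maps: bool = False,
    force: bool = False,
) -> PipelineResult:
    """Execute all stages in order and (optionally) persist the artifacts.

    With an ``out_dir`` whose manifest matches the config hash, the stored
    results are reloaded instead of recomputed (``force=True`` overrides).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None and not force:
        man_path = out / "manifest.yaml"
        if man_path.exists():
            manifest = yaml.safe_load(man_path.read_text())
            if manifest.get("config_hash") == cfg.config_hash() and (out / "results.tsv").exists():
                df = pd.read_csv(out / "results.tsv", sep="\t")
                behavior = dio.load_behavior(out / "behavior.tsv")
                truth = dio.load_truth(out / "truth.yaml")
                excluded = manifest.get("excluded_from_fc", [])
                return PipelineResult(cfg, df, behavior, truth, excluded, manifest)

    timings: dict[str, float] = {}

    def _timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        res = fn(*args, **kw)
        timings[name] = round(time.perf_counter() - t0, 3)
        return res

    cohort = _timed("simulate", stage_simulate, cfg)
    raster = _timed("rasterize", RasterizedCohort, cohort.tractograms, cohort.grid)
    psdms, tsdms, volumes, overlap = _timed("disconnectome", stage_disconnectome, cfg, cohort, raster)
    sc_g, sc_ld, sc_l = _timed("structural", stage_structural, cfg, cohort, raster)
    fc_g, fc_l, fc_ld, affected, excluded = _timed(
        "functional", stage_functional, cfg, cohort, tsdms
    )
    dk_sc, dcc_sc = stage_metrics(sc_g, sc_l)
    dk_fc, dcc_fc = stage_metrics(fc_g, fc_l)
    timings["metrics"] = 0.0
    feats = _timed(
        "features", stage_features, cfg, cohort, psdms, tsdms, sc_ld, fc_ld,
        dk_sc, dcc_sc, dk_fc, dcc_fc,
    )
    pids = [m.patient_id for m in cohort.lesions]
    behavior, truth = _timed("outcomes", stage_outcomes, cfg, feats, pids)
    results = _timed("predict", stage_predict, cfg, feats, behavior, volumes)
    df = results_table(results)

    evaluated = set(df["feature"].unique())
    skipped = {}
    for fid in FEATURE_IDS:
        if fid in evaluated:
            continue
        if fid not in feats:
            skipped[fid] = "no patient produced a nonzero feature vector"
        elif feats[fid].values.shape[1] == 0:
            skipped[fid] = "all feature elements zero across patients"
        else:
            skipped[fid] = "fewer than 4 patients available after exclusions"
    manifest = {
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "software": "dyspredict 0.1.0",
        "timings_s": timings,
        "excluded_from_fc": excluded,
        "skipped_features": skipped,
        "checksums": {},
    }
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.10g")
        dio.save_behavior(behavior, out / "behavior.tsv")
        dio.save_truth(truth, out / "truth.yaml")
        volumes.to_csv(out / "lesion_volumes.tsv", sep="\t", index=False, float_format="%.6g")
        dio.save_volume(overlap.astype(np.int16), cohort.grid, out / "lesion_overlap.nii.gz")
        dio.save_affected_parcels(list(affected.values()), out / "affected_parcels.tsv")
        write_report(df, out / "report.md", excluded)
        if write_maps:
            maps_dir = out / "maps"
            maps_dir.mkdir(exist_ok=True)
            for pid, p in psdms.items():
                dio.save_psdm(p, maps_dir / f"{pid}_psdm.nii.gz", maps_dir / f"{pid}_psdm_counts.nii.gz")
                for th, t in tsdms[pid].items():
                    dio.save_tsdm(t, maps_dir / f"{pid}_tsdm_{th:g}.nii.gz")
        for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.yaml")) + [out / "report.md"]:
            if f.name != "manifest.yaml":
                manifest["checksums"][f.name] = _sha256(f)
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    return PipelineResult(
        cfg, df, behavior, truth, excluded, manifest, cohort if keep_cohort else None
    )
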
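"""Synthetic normative cohort, patient lesions and planted outcomes.

The real inputs of a lesion-disconnectome study — normative tractograms,
parcel time series, patient lesion masks and behavioral scores — are not
shareable, so this module generates a self-contained stand-in with known
ground truth:

* a brain-like ellipsoidal mask tiled into connected parcels (seeded
  Voronoi/BFS growth),
* per-subject streamline bundles following smooth curves between parcel
  pairs, with per-subject geometric jitter,
* parcel time series drawn from a factor model whose covariance blocks
  follow the bundle graph,
* lesions grown as connected blobs of configurable size, and
* behavioral scores planted as a linear model on true disconnection
  features plus Gaussian noise, with the planted signal fraction recorded.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .core import (
    BehaviorTable,
    ConfigurationError,
    GridSpec,
    LesionMask,
    ParcellationAtlas,
    RoiTimeSeries,
    SyntheticTruth,
    Tractogram,
)

__all__ = [
    "default_grid",
    "brain_mask",
    "generate_cohort",
    "generate_lesions",
    "filter_streamlines_by_length",
    "motor_score_from_limb_items",
    "plant_outcomes",
    "weights_for_features",
    "noise_sd_for_target_r2",
    "exact_noise_for_target_r2",
    "plant_behavior_table",
]

_NEIGHBORS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=int
)


def default_grid(n: int = 32, voxel_mm: float = 3.0) -> GridSpec:
    """Isotropic cube grid centred on the world origin."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * n / 2.0
    return GridSpec((n, n, n), aff)


def brain_mask(grid: GridSpec, fill: float = 0.92) -> np.ndarray:
    """Ellipsoidal 'brain' mask inscribed in the grid (boolean volume).

    ``fill`` scales the semi-axes relative to the half-extent of the grid.
    Evaluated at voxel centres (index + 0.5).
    """
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx) + 0.5, np.arange(ny) + 0.5, np.arange(nz) + 0.5, indexing="ij"
    )
    c = np.array(grid.shape) / 2.0
    semi = fill * c
    r2 = ((ii - c[0]) / semi[0]) ** 2 + ((jj - c[1]) / semi[1]) ** 2 + ((kk - c[2]) / semi[2]) ** 2
    return r2 <= 1.0


def _voronoi_parcels(mask: np.ndarray, n_parcels: int, rng: np.random.Generator) -> np.ndarray:
    """Grow connected parcels from farthest-point-sampled seeds (6-conn BFS)."""
    coords = np.argwhere(mask)
    if len(coords) < n_parcels:
        raise ConfigurationError("brain mask smaller than requested parcel count")
    # Farthest-point sampling for well-spread seeds.
    seeds = [coords[rng.integers(len(coords))]]
    d2 = np.sum((coords - seeds[0]) ** 2, axis=1).astype(float)
    for _ in range(n_parcels - 1):
        seeds.append(coords[int(np.argmax(d2))])
        d2 = np.minimum(d2, np.sum((coords - seeds[-1]) ** 2, axis=1))
    labels = np.zeros(mask.shape, dtype=np.int32)
    q: deque[tuple[int, int, int]] = deque()
    for lab, s in enumerate(seeds, start=1):
        labels[tuple(s)] = lab
        q.append(tuple(s))
    shape = np.array(mask.shape)
    while q:
        v = q.popleft()
        lab = labels[v]
        for off in _NEIGHBORS6:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if np.any(np.array(w) < 0) or np.any(np.array(w) >= shape):
                continue
            if mask[w] and labels[w] == 0:
                labels[w] = lab
                q.append(w)
    return labels


def _clip_to_ellipsoid(points_idx: np.ndarray, grid: GridSpec, fill: float = 0.92) -> np.ndarray:
    """Radially pull index-space points that left the brain ellipsoid back in."""
    c = np.array(grid.shape) / 2.0
    semi = fill * c
    rel = (points_idx - c) / semi
    r = np.linalg.norm(rel, axis=1)
    out = r > 0.985
    if np.any(out):
        rel[out] *= (0.985 / r[out])[:, None]
    return rel * semi + c


def _bundle_pairs(
    centroids_w: np.ndarray, n_pairs: int, min_distance: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Choose parcel pairs so every parcel is incident to >= 1 bundle.

    Pairs prefer centroid separations >= ``min_distance`` (world mm) so that
    bundles survive the standard streamline length filter; if a parcel has
    no partner that far away, its farthest neighbour is used.
    """
    P = len(centroids_w)
    dist = np.linalg.norm(centroids_w[:, None, :] - centroids_w[None, :, :], axis=2)
    pairs: set[tuple[int, int]] = set()
    for p in range(P):
        cand = np.where(dist[p] >= min_distance)[0]
        q = int(rng.choice(cand)) if len(cand) else int(np.argmax(dist[p]))
        pairs.add((min(p, q), max(p, q)))
    while len(pairs) < n_pairs:
        p = int(rng.integers(P))
        cand = np.where(dist[p] >= min_distance)[0]
        if len(cand) == 0:
            cand = np.array([int(np.argmax(dist[p]))])
        q = int(rng.choice(cand))
        pairs.add((min(p, q), max(p, q)))
    return sorted(pairs)


def generate_cohort(
    grid: GridSpec,
    n_parcels: int = 60,
    n_subjects: int = 25,
    bundles: int = 25,
    jitter: float = 1.5,
    n_timepoints: int = 120,
    seed: int = 0,
    n_bundle_pairs: int | None = None,
    min_bundle_distance: float = 33.0,
    step_mm: float | None = None,
    sampling_interval: float = 2.0,
) -> tuple[ParcellationAtlas, list[Tractogram], list[RoiTimeSeries]]:
    """Generate the normative cohort: atlas, tractograms and time series.

    Parameters
    ----------
    bundles
        Streamlines per selected parcel pair.
    jitter
        Per-subject geometric perturbation amplitude in world mm; with
        ``jitter=0`` all subjects share identical tractograms.
    n_bundle_pairs
        Number of parcel pairs carrying a bundle; defaults to
        ``max(n_parcels + 20, 2000 // bundles)``.
    min_bundle_distance
        Preferred minimum centroid separation (mm) for bundle endpoints, so
        most bundles pass the 30 mm streamline length filter.

    The bundle geometry (pairs, control points, per-streamline endpoints) is
    cohort-level: subjects differ only by the jitter field.  Deterministic
    given ``seed``.
    """
    if n_parcels < 4:
        raise ConfigurationError("need at least 4 parcels")
    if n_subjects < 3:
        raise ConfigurationError("need at least 3 normative subjects")
    rng = np.random.default_rng(seed)
    mask = brain_mask(grid)
    labels = _voronoi_parcels(mask, n_parcels, rng)
    atlas = ParcellationAtlas(grid, labels)

    parcel_voxels = [np.argwhere(labels == p + 1) for p in range(n_parcels)]
    centroids_idx = np.array([v.mean(axis=0) + 0.5 for v in parcel_voxels])
    centroids_w = grid.index_to_world(centroids_idx)

    if n_bundle_pairs is None:
        n_bundle_pairs = max(n_parcels + 20, 2000 // bundles)
    pairs = _bundle_pairs(centroids_w, n_bundle_pairs, min_bundle_distance, rng)

    voxel_mm = float(np.cbrt(grid.voxel_volume))
    if step_mm is None:
        step_mm = 0.5 * voxel_mm

    # Cohort-level base geometry: for every streamline, endpoints sampled
    # inside its two parcels and a bowed quadratic Bezier centreline.
    base: list[np.ndarray] = []
    endpoint_pairs: list[tuple[int, int]] = []
    centre_idx = np.array(grid.shape) / 2.0
    for (p, q) in pairs:
        vp, vq = parcel_voxels[p], parcel_voxels[q]
        for _ in range(bundles):
            a_idx = vp[rng.integers(len(vp))] + 0.5
            b_idx = vq[rng.integers(len(vq))] + 0.5
            mid = 0.5 * (a_idx + b_idx)
            chord = b_idx - a_idx
            # random bow perpendicular-ish to the chord, pulled toward centre
            bow = rng.normal(0.0, 1.0, 3)
            bow -= bow @ chord / max(chord @ chord, 1e-9) * chord
            norm = np.linalg.norm(bow)
            if norm > 1e-9:
                bow *= (0.25 * np.linalg.norm(chord) / norm) * rng.uniform(0.3, 1.0)
            ctrl = mid + bow + 0.15 * (centre_idx - mid)
            chord_mm = np.linalg.norm(grid.index_to_world(b_idx) - grid.index_to_world(a_idx))
            n_pts = max(8, int(np.ceil(chord_mm / step_mm)) + 1)
            t = np.linspace(0.0, 1.0, n_pts)[:, None]
            curve = (1 - t) ** 2 * a_idx + 2 * t * (1 - t) * ctrl + t**2 * b_idx
            base.append(curve)
            endpoint_pairs.append((p, q))

    # Per-subject jitter: smooth sine-bump displacement, zero at endpoints so
    # endpoint parcel assignment is preserved; clipped back into the brain.
    tractograms: list[Tractogram] = []
    jitter_idx = jitter / voxel_mm
    for s in range(n_subjects):
        sls = []
        for curve in base:
            if jitter_idx > 0:
                amp = rng.normal(0.0, jitter_idx, 3)
                t = np.linspace(0.0, 1.0, len(curve))[:, None]
                pts = curve + np.sin(np.pi * t) * amp
                pts = _clip_to_ellipsoid(pts, grid)
            else:
                pts = curve.copy()
            sls.append(grid.index_to_world(pts))
        tractograms.append(Tractogram(f"sub-{s:03d}", sls))

    # Time series: factor model on the bundle graph -> block covariance.
    edges = np.array(pairs)
    incidence = np.zeros((n_parcels, len(pairs)))
    incidence[edges[:, 0], np.arange(len(pairs))] = 1.0
    incidence[edges[:, 1], np.arange(len(pairs))] = 1.0
    w_factor, sigma = 0.6, 0.8
    timeseries = []
    for s in range(n_subjects):
        factors = rng.normal(0.0, 1.0, (n_timepoints, len(pairs)))
        noise = rng.normal(0.0, sigma, (n_timepoints, n_parcels))
        data = factors @ (w_factor * incidence.T) + noise
        timeseries.append(RoiTimeSeries(f"sub-{s:03d}", data, sampling_interval))

    return atlas, tractograms, timeseries


def filter_streamlines_by_length(
    t: Tractogram, min_len: float = 30.0, max_len: float = 300.0
) -> Tractogram:
    """Drop streamlines whose polyline arc length falls outside [min, max] mm."""
    if not (0 < min_len < max_len):
        raise ValueError("need 0 < min_len < max_len")
    lengths = t.arc_lengths()
    keep = (lengths >= min_len) & (lengths <= max_len)
    return Tractogram(t.subject_id, [s for s, k in zip(t.streamlines, keep) if k])


def generate_lesions(
    grid: GridSpec,
    n_patients: int = 40,
    size_range: tuple[int, int] = (10, 300),
    seed: int = 0,
    small_fraction: float = 0.0,
    core_fill: float = 0.7,
) -> list[LesionMask]:
    """Grow connected lesion blobs inside the brain mask.

    Each lesion starts from a random seed voxel and grows by randomized
    6-connected accretion to a size drawn uniformly from ``size_range``.
    A ``small_fraction`` of patients instead receive 1-3 voxel lesions
    seeded near the brain periphery; these routinely fail the ten-voxel
    parcel-overlap rule and exercise the functional-analysis exclusion path.
    """
    rng = np.random.default_rng(seed)
    mask = brain_mask(grid)
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 1 or hi < lo or hi > int(mask.sum()):
        raise ConfigurationError("lesion size_range outside grid capacity")
    core = brain_mask(grid, fill=0.92 * core_fill)
    shell = mask & ~brain_mask(grid, fill=0.92 * 0.9)
    core_coords = np.argwhere(core)
    shell_coords = np.argwhere(shell)
    n_small = int(round(small_fraction * n_patients))
    lesions = []
    shape = np.array(grid.shape)
    for i in range(n_patients):
        small = i >= n_patients - n_small
        if small:
            target = int(rng.integers(1, 4))
            start = shell_coords[rng.integers(len(shell_coords))]
        else:
            target = int(rng.integers(lo, hi + 1))
            start = core_coords[rng.integers(len(core_coords))]
        blob = np.zeros(grid.shape, dtype=bool)
        blob[tuple(start)] = True
        frontier = [tuple(start + off) for off in _NEIGHBORS6]
        grown = 1
        while grown < target and frontier:
            j = int(rng.integers(len(frontier)))
            v = frontier.pop(j)
            va = np.array(v)
            if np.any(va < 0) or np.any(va >= shape) or not mask[v] or blob[v]:
                continue
            blob[v] = True
            grown += 1
            frontier.extend(tuple(va + off) for off in _NEIGHBORS6)
        lesions.append(LesionMask(f"pat-{i:03d}", grid, blob))
    return lesions


def motor_score_from_limb_items(upper_limb_sum: int, lower_limb_sum: int) -> int:
    """Limb motor score: 10 minus the summed upper- and lower-limb items.

    Each limb item sum is an integer in [0, 4]; no impairment scores 10,
    major impairment scores 2.
    """
    for name, v in (("upper_limb_sum", upper_limb_sum), ("lower_limb_sum", lower_limb_sum)):
        if int(v) != v or not (0 <= int(v) <= 4):
            raise ValueError(f"{name} must be an integer in [0, 4], got {v}")
    return 10 - (int(upper_limb_sum) + int(lower_limb_sum))


def _limb_items_from_latent(latent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map a continuous deficit latent to (upper, lower) limb item sums.

    The latent is z-scored and pushed through the normal CDF; the combined
    item sum is ``round(8 * (1 - Phi(z)))`` clipped to [0, 8], so larger
    latent values mean *less* impairment.
    """
    sd = latent.std()
    z = (latent - latent.mean()) / (sd if sd > 0 else 1.0)
    total = np.clip(np.round(8.0 * (1.0 - ndtr(z))), 0, 8).astype(int)
    upper = np.minimum(total, 4)
    lower = total - upper
    return upper, lower


def weights_for_features(
    features: np.ndarray, seed: int, n_modes: int = 1, secondary_scale: float = 0.25
) -> np.ndarray:
    """Weight vector along the cohort's dominant modes of feature variation.

    The planted behavioral substrate is the leading principal direction of
    the patient x element feature matrix — in disconnection features this
    is essentially overall disconnection severity, the clinically dominant
    driver of deficit — plus smaller score-specific contributions from the
    next ``n_modes - 1`` directions (each scaled to contribute
    ``secondary_scale`` of the leading mode's signal standard deviation,
    with random sign).  Planting along stable, high-variance directions
    makes the signal learnable from a cohort of this size; weight placed on
    arbitrary element subsets instead produces a signal direction that no
    sample of tens of patients can estimate.
    """
    X = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        return np.zeros(X.shape[1])
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_modes = min(n_modes, int(np.sum(s > 1e-12 * s[0])))
    w = vt[0].copy()
    for l in range(1, n_modes):
        coef = secondary_scale * rng.choice([-1.0, 1.0]) * s[0] / s[l]
        w += coef * vt[l]
    # deterministic orientation: largest-magnitude element positive
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return w


def exact_noise_for_target_r2(
    signal: np.ndarray, planted_r2: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise vector realizing the target signal fraction exactly.

    The drawn noise is orthogonalized against the (centred) signal and
    rescaled so that the *sample* variance ratio
    ``var(signal) / (var(signal) + var(noise))`` equals ``planted_r2``
    exactly; the squared sample correlation between signal and
    signal + noise is then the planted value by construction.  Use this
    when a benchmark should not inherit Monte-Carlo spread in the realized
    signal fraction; :func:`noise_sd_for_target_r2` gives the plain i.i.d.
    alternative.
    """
    if not (0 < planted_r2 <= 1):
        raise ValueError("planted_r2 must be in (0, 1]")
    sig = np.asarray(signal, dtype=float)
    sc = sig - sig.mean()
    eps = rng.normal(0.0, 1.0, sig.shape[0])
    eps -= eps.mean()
    denom = sc @ sc
    if denom > 0:
        eps -= (eps @ sc / denom) * sc
    if planted_r2 == 1.0 or not np.any(eps):
        return np.zeros_like(sig)
    target_var = np.var(sig) * (1.0 - planted_r2) / planted_r2
    return eps * np.sqrt(target_var / np.var(eps))


def noise_sd_for_target_r2(signal: np.ndarray, planted_r2: float) -> float:
    """Noise SD giving ``var(signal)/(var(signal)+sd^2) == planted_r2``."""
    if not (0 < planted_r2 <= 1):
        raise ValueError("planted_r2 must be in (0, 1]")
    v = float(np.var(signal))
    return float(np.sqrt(v * (1.0 - planted_r2) / planted_r2))


def plant_outcomes(
    features: np.ndarray,
    weights: np.ndarray,
    noise_sd: float,
    score_kind: str,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Generate one planted score column from patient feature vectors.

    ``latent = features @ weights + N(0, noise_sd)``.  Cognitive scores are
    the latent itself (sign-flipped so higher = better is *not* enforced);
    motor scores discretize the latent into limb item sums and apply
    :func:`motor_score_from_limb_items`.

    Returns the scores and a truth record with the planted signal fraction
    ``var(signal) / (var(signal) + noise_sd^2)``.
    """
    X = np.asarray(features, dtype=float)
    w = np.asarray(weights, dtype=float)
    if X.ndim != 2 or X.shape[1] != w.shape[0]:
        raise ValueError(
            f"weight length {w.shape[0]} does not match feature length {X.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    signal = X @ w
    latent = signal + rng.normal(0.0, noise_sd, X.shape[0])
    var_sig = float(np.var(signal))
    planted_r2 = var_sig / (var_sig + noise_sd**2) if (var_sig + noise_sd**2) > 0 else 0.0
    if score_kind in ("motor_left", "motor_right", "motor"):
        upper, lower = _limb_items_from_latent(latent)
        scores = np.array(
            [motor_score_from_limb_items(u, l) for u, l in zip(upper, lower)], dtype=float
        )
    elif score_kind in ("executive", "processing_speed", "cognitive"):
        scores = latent.copy()
    else:
        raise ValueError(f"unknown score_kind {score_kind!r}")
    truth = {
        "weights": w,
        "noise_sd": float(noise_sd),
        "planted_r2": planted_r2,
        "latent": latent,
        "seed": seed,
    }
    return scores, truth


def plant_behavior_table(
    patient_ids: list[str],
    features_by_score: dict[str, np.ndarray],
    planted_r2: dict[str, float],
    seed: int = 0,
) -> tuple[BehaviorTable, SyntheticTruth]:
    """Plant all four behavioral scores and collect the ground truth."""
    truth = SyntheticTruth(seed=seed)
    cols: dict[str, np.ndarray] = {}
    for k, name in enumerate(sorted(features_by_score)):
        X = np.asarray(features_by_score[name], dtype=float)
        w = weights_for_features(X, seed=seed + 1000 + k)
        signal = X @ w
        if np.var(signal) == 0:
            sd = 1.0
        else:
            sd = noise_sd_for_target_r2(signal, planted_r2[name])
        scores, rec = plant_outcomes(X, w, sd, name, seed=seed + 2000 + k)
        cols[name] = scores
        truth.weights[name] = rec["weights"]
        truth.noise_sd[name] = rec["noise_sd"]
        truth.planted_r2[name] = rec["planted_r2"]
        truth.latent[name] = rec["latent"]
    table = BehaviorTable(patient_ids, cols)
    return table, truth
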
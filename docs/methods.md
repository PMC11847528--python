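# Methods

This note documents the models, conventions and design choices behind
`dyspredict`, in the order the pipeline runs them.

## Coordinate and grid conventions

Streamlines are polylines in world millimetres; volumes live on a
`GridSpec` (shape + 4×4 affine). World→index conversion goes through the
inverse affine, voxel indices are 0-based, and the voxel with index *i*
owns the half-open box [i, i+1) in continuous index space. All volumes of
one cohort must share a grid; mismatches raise immediately rather than
resampling silently.

## Streamline–voxel traversal

The set of voxels a segment passes through is computed exactly: the
parameter values at which the segment crosses integer planes on any axis
are enumerated and sorted, and the voxel between two consecutive
crossings is read off at the interval midpoint. This is equivalent to
grid-stepping (Amanatides–Woo style) traversal but has no stepping state
to get wrong at corner crossings, and no sampling-density parameter.
Dense supersampling (points every 0.05 voxel, and 0.002 voxel for
voxel-set comparisons) is kept in the test suite as an independent
oracle; the two agree on 200/200 random streamline–lesion intersection
queries and the only voxel-set differences are sub-step grazing
traversals that vanish as the oracle step shrinks. The kernels are
numba-compiled; a whole tractogram is rasterized once into a CSR-like
(voxel ids, offsets) pair and reused across all patients.

## Disconnection maps

For patient lesion L and normative subject s, a voxel is *disconnected*
if it lies on at least one streamline of s that traverses a lesion voxel
(the whole-streamline footprint; the map asks "which voxels lose a
passing connection", not "which side of the cut is distal" — the distal
variant would require an arbitrary rule for streamlines crossing the
lesion more than once, and is not implemented). pSDM values are stored as
integer subject counts, so every voxel equals k/N exactly and the
thresholded map at P<sub>th</sub> keeps voxels with
k ≥ round-half-up(P<sub>th</sub>·N), never fewer than 1. Half-up rounding
is the only convention consistent with keeping ≥ 40 of 403 subjects at
P<sub>th</sub> = 0.1 and "at least 90 % of the cohort" at 0.9. Nesting of
the thresholded maps across 0.1 < 0.3 < 0.5 < 0.7 < 0.9 follows and is
asserted in tests. Lesion volume is voxel count × voxel volume / 1000
(cm³); the overlap map is the voxelwise sum of patient masks.

## Connectomes

**Structural.** An edge (i, j) of a subject's SC counts streamlines whose
two *endpoints* fall in parcels i and j (endpoint assignment by the voxel
containing the point; background endpoints contribute nothing).
Pass-through counting was considered and rejected as the default: the
endpoint convention is the standard "fibers connecting" reading. The
group matrix keeps edges nonzero in ≥ round-half-up(prevalence·N)
subjects (prevalence 0.5), and a kept edge takes the mean over *all* N
subjects, zeros included; the same rule builds the lesioned group matrix
SC_L from the streamlines surviving the lesion, so the relative change
SC_LD = (SC_L − SC_g)/SC_g (0 where SC_g = 0) reflects only streamline
removal and lies in [−1, 0].

**Functional.** Subject FC is the Pearson correlation of parcel time
courses (zero-variance columns are an error naming the parcel); the group
FC is the plain arithmetic mean of correlations (no Fisher-z averaging —
the option exists but plain averaging is the documented default). A
patient's *affected parcels* are those overlapping the 0.1-thresholded
disconnection map by ≥ 10 voxels; FC_L zeroes all edges incident to
affected parcels per subject before averaging, so unaffected edges equal
FC_g exactly. A patient with no affected parcel is excluded from the
functional analysis (raised as `FcExclusionError`, listed in the results)
rather than processed with an empty mask.

## Graph metrics

Nodal strength K(i) = Σ_j w(i, j). The weighted clustering coefficient is
the Onnela geometric-mean form on weights normalized by the global
maximum, with Cc(i) = 0 for binary degree < 2; the Zhang–Horvath ratio
variant is available. FC graphs enter both metrics through absolute
weights, a declared choice (negative correlations would break
nonnegativity), not an inference about the source conventions. Per-node
relative changes use the same (lesioned − intact)/intact form with a
0/0 → 0 guard.

## Features and PCA

Thirteen features per patient (lesion mask; pSDM; five tSDMs; SC_LD;
FC_LD; ΔK and ΔCc for SC and FC) are vectorized in fixed orders (volumes
C-order; matrices upper triangle, row-major, no diagonal), columns zero
in every patient are eliminated with an injective map back to original
element ids, and mean-centred PCA retains the smallest component count
reaching 99 % cumulative explained variance (centering only, no unit
scaling; deterministic component signs). PCA is fit on all patients — the
source procedure's choice, retained deliberately; it is unsupervised, so
it does not by itself leak outcome information. Lesion volume is a
single-column feature that bypasses PCA.

## Prediction

Ridge regression with an unpenalized intercept, closed form, penalty grid
{0.001, 0.01, 0.1, 1, 10, 100} (a fixed-λ mode is available). All
leave-one-out predictions use the exact algebraic identity
e₋ᵢ = eᵢ/(1 − hᵢᵢ) on the augmented design — identical to per-fold
refitting to machine precision (asserted at 1e-10 against a naive refit
oracle) and vectorizable over permuted score columns.

**Reported R².** Squared Pearson correlation between LOOCV predictions
and actual scores, with negative correlation counted as zero skill, plus
the residual-based 1 − SS_res/SS_tot alongside. The zero-clamp matters:
LOOCV predictions contain a systematic anti-correlated component (each
held-out prediction leans on the mean of the *other* scores), and under
heavy shrinkage that artifact alone drives the unclamped squared
correlation to 1.

**Model selection.** Principal components are ranked by |Pearson r| with
the outcome, descending (the selection step is only coherent when the
most-correlated components come first; an ascending flag exists for the
literal alternative), ties toward the smaller index; per-fold rankings
aggregate by mean rank. The spec-level operations (`rank_pcs`,
`aggregate_rankings`, `select_hyperparams`, `loocv_evaluate`,
`permutation_test`) implement the global two-step procedure: one
aggregated ranking, then per-outer-fold inner LOOCV over ranking prefixes
× penalty grid, combined as rounded-mean prefix count and modal penalty
(ties to the smaller value).

**Honest evaluation.** At a few dozen patients the global procedure leaks
outcome information across folds — the aggregated ranking and the shared
(n*, λ*) are tuned on data that includes each evaluation fold — and
measurably inflates weak signals (a 0.3 planted signal fraction reports
as ≈ 0.7). The pipeline's reported R² therefore comes from a fold-safe
variant (`evaluate_feature(fold_safe=True)`, the default): for each
held-out patient, every inner fold of the remaining patients re-ranks the
components on its own training scores, validation predictions are pooled
per (prefix, penalty), and the model is chosen by the pooled validation
MSE under the one-standard-error parsimony rule (smallest prefix, then
smallest penalty, within one SE of the minimum). MSE rather than
correlation drives selection because per-fold models with wildly
different shrinkage produce predictions on incommensurate scales, which
destroys the pooled correlation even when each fold is individually fine;
the 1-SE rule suppresses the winner's curse of scanning ~200 candidate
models on 39 patients. Nothing involving the held-out score enters its
own prediction (asserted directly in tests). The global variant remains
available as `fold_safe=False`.

**Permutation test.** Scores are permuted across patients B times and the
LOOCV R² is recomputed per permutation; p is the plain proportion of
permutations reaching the observed value (an add-one estimator is
available; the smallest resolvable nonzero p is 1/B, so with 10⁴
permutations p-values below 10⁻⁴ cannot be certified). By default each
permutation re-runs the score-dependent ranking and hyperparameter
selection (`refit="full"`), making observed and permuted statistics the
same function of the data and the test exchangeable: measured
false-positive rate at α = 0.05 under null scores is 0.05. Keeping the
ranking and hyperparameters fixed at their observed-score values
(`refit="none"`) reproduces the literal convention but is severely
anti-conservative at this cohort size (measured false-positive rate
0.77); it is exposed, not default. The test statistic is the global
two-step R² (fast to refit exactly via a batched Cholesky-prefix kernel);
the reported fold-safe R² and the permutation p answer "how much skill"
and "is there any association" respectively.

**Model comparison.** Fisher r-to-z on r = √R²: z = atanh r,
SE = 1/√(n−3), 95 % CIs mapped back to the R² scale by tanh², two-sided
p from the normal z-difference. R² = 1 yields an infinite z sentinel.

## Synthetic cohort

The generator emulates the *inputs* of a disconnection study, not MRI
physics. Defaults define the reference conditions: 32³ grid with 3 mm
voxels, ellipsoidal brain mask, 60 parcels grown by multi-source BFS from
farthest-point-sampled seeds (connected, nonempty, tiling the mask), 25
normative subjects, ~2000 streamlines each (80 parcel-pair bundles × 25
streamlines, quadratic Bézier centrelines bowed toward the interior,
endpoints sampled inside the parcels, per-subject sine-bump jitter of
1.5 mm that vanishes at the endpoints and is clipped back into the
brain), 120 time points of a factor model whose covariance blocks follow
the bundle graph (TR 2 s), and 40 patients with connected lesion blobs of
10–300 voxels (0.27–8.1 cm³), a 7.5 % fraction of them 1–3-voxel
peripheral lesions that exercise the functional-analysis exclusion rule.
Bundle endpoint pairs prefer centroid separations ≥ 33 mm so most
streamlines survive the standard 30–300 mm length filter, which is
applied in these world units and is configurable.

Behavioral scores are planted as a linear model on true tSDM(0.1)
features. The default weight vector lies along the leading principal
direction of the patient × element feature matrix — overall disconnection
severity, the clinically dominant driver of deficit — because a signal in
a stable high-variance direction is learnable from a 40-patient cohort;
weights scattered over arbitrary element subsets define a direction in
patient space that no sample of this size can estimate, and no procedure
could recover such a plant (multi-mode and scattered variants remain as
options). Cognitive scores are the latent itself; motor scores z-score
the latent, map it through the normal CDF to a limb-item sum
round(8·(1−Φ(z))) clipped to [0, 8], and apply the 10 − items formula,
giving the bounded ordinal structure of the battery without inventing
clinical semantics. The recorded planted R² is
var(signal)/(var(signal)+σ²); `exact_noise_for_target_r2` additionally
orthogonalizes and rescales the drawn noise so the *sample* signal
fraction equals the target exactly, which benchmark tests use so that
recovery checks measure procedure bias rather than draw luck.

What passing tests do **not** show about real data: the generator has no
hemispheric anatomy, no crossing-fiber geometry, no lesion-location
epidemiology (location and size priors are configurable, not matched to
any clinical table), no scanner noise, and its planted outcome model is
low-dimensional by design. Results on it validate the machinery —
geometry, counting rules, exclusion rules, selection and inference — not
clinical effect sizes.

## Scale and determinism

Every generator and every stochastic analysis step is a pure function of
(configuration, seed); reruns are bitwise identical and the pipeline
manifest records config hash, per-stage wall clock and output checksums,
with whole-run caching by config hash. The default synthetic scale was
chosen so a full 13-feature × 4-score run finishes in about a minute on
one CPU core, and the benchmark studies (20-seed recovery, 100-replicate
null calibration) in a few minutes each.

## Known limitations

* The distal-remainder disconnection footprint is not implemented (see
  above).
* The functional pipeline simulates lesion impact on normative FC; it
  never touches patient fMRI.
* Permutation power is modest: the exchangeable null distribution
  inherits the selection optimism of the global statistic, so true
  associations need a sizeable planted fraction to reach small p at
  B in the hundreds.
* Fisher r-to-z comparisons treat the two models' cross-validated
  correlations as independent, which overstates evidence when both are
  evaluated on the same patients — the convention is kept because it is
  the source procedure, and the caveat applies to any use of it.
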
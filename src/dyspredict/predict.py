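"""Ridge outcome prediction with two-step nested leave-one-out CV.

The training strategy, per feature and behavioral score:

1. For every outer fold, principal components of the feature are ranked by
   the magnitude of their Pearson correlation with the training patients'
   scores; the per-fold rankings are aggregated by mean rank into one
   global ranking.
2. For every outer fold, an inner LOOCV over the training set scans prefix
   sizes of the global ranking jointly with a logarithmic ridge penalty
   grid spanning [0.001, 100]; the per-fold optima are combined into a
   single PC count (rounded mean) and penalty (mode, ties to the smaller
   value).

Evaluation is LOOCV with the selected prefix and penalty; the reported R^2
is the squared Pearson correlation between predicted and actual scores
(the residual-based 1 - SS_res/SS_tot is reported alongside).  Statistical
significance comes from re-running the evaluation on permuted scores, and
models are compared through Fisher's r-to-z transform with standard error
1/sqrt(n-3).

Leave-one-out predictions use the exact algebraic identity for ridge with
an unpenalized intercept (e_loo = e / (1 - h_ii) on the augmented design),
which equals per-fold refitting to machine precision and vectorizes over
permuted score columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import ndtr

from .core import round_half_up

__all__ = [
    "RidgeConfig",
    "CvResult",
    "ModelComparison",
    "ridge_fit_predict",
    "loo_predictions",
    "skill_r2",
    "rank_pcs",
    "aggregate_rankings",
    "select_hyperparams",
    "loocv_evaluate",
    "permutation_test",
    "fisher_compare",
    "evaluate_feature",
]

DEFAULT_LAMBDAS = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class RidgeConfig:
    """Hyperparameter search configuration.

    ``lambdas`` must be strictly positive and increasing.  ``fixed_lambda``
    bypasses the grid (the study's reported optimum was 0.01).
    ``rank_ascending=True`` follows the literal ascending-correlation
    ranking; the default ranks by descending |r|.
    """

    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS
    fixed_lambda: float | None = None
    rank_ascending: bool = False
    permutation_estimator: str = "proportion"  # or "add_one"

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if np.any(lam <= 0) or np.any(np.diff(lam) <= 0):
            raise ValueError("lambda grid must be strictly positive and increasing")

    @property
    def grid(self) -> tuple[float, ...]:
        return (self.fixed_lambda,) if self.fixed_lambda is not None else self.lambdas


@dataclass
class CvResult:
    """LOOCV outcome for one feature x score pair."""

    feature_id: str
    score_name: str
    r2: float  # squared Pearson correlation (predicted vs actual)
    r2_residual: float  # 1 - SS_res / SS_tot
    mse: float
    n_pcs: int | None
    total_explained_variance: float | None  # percent
    lambda_: float
    n_patients: int
    permutation_p: float | None = None
    predicted: np.ndarray = field(default_factory=lambda: np.empty(0))
    actual: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ModelComparison:
    """Fisher r-to-z comparison of two LOOCV models."""

    z_a: float
    z_b: float
    se_a: float
    se_b: float
    ci_r2_a: tuple[float, float]
    ci_r2_b: tuple[float, float]
    p_value: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def skill_r2(pred: np.ndarray, y: np.ndarray) -> float:
    """Squared predicted-vs-actual Pearson correlation, zero if negative.

    Leave-one-out predictions carry a systematic anti-correlated component
    (each held-out patient's prediction leans on the mean of the *other*
    patients' scores, which moves opposite to the held-out score).  Under
    heavy shrinkage this artifact alone drives the plain squared
    correlation to 1, so a negative predicted-vs-actual correlation is
    treated as absence of predictive skill, not as skill.
    """
    r = _pearson(pred, y)
    return r**2 if r > 0 else 0.0


def ridge_fit_predict(
    X: np.ndarray, y: np.ndarray, lam: float, X_new: np.ndarray | None = None
) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Closed-form ridge with unpenalized intercept.

    Minimizes ||y - X b - b0||^2 + lam ||b||^2.  At ``lam=0`` a singular
    system raises rather than being silently regularized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X row count does not match y")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    coef = np.linalg.solve(A, Xc.T @ (y - ym))
    intercept = ym - xm @ coef
    preds = None if X_new is None else np.asarray(X_new, dtype=float) @ coef + intercept
    return coef, float(intercept), preds


def loo_predictions(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Leave-one-out ridge predictions, exact, for one or many score columns.

    ``Y`` may be (n,) or (n, B); the result has the same shape.  Equivalent
    to refitting the model n times with one row held out.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 patients")
    Xa = np.column_stack([np.ones(n), X])
    pen = np.full(X.shape[1] + 1, lam)
    pen[0] = 0.0
    M = np.linalg.inv(Xa.T @ Xa + np.diag(pen))
    XaM = Xa @ M
    h = np.einsum("ij,ij->i", XaM, Xa)
    Yhat = XaM @ (Xa.T @ Y)
    denom = 1.0 - h
    if np.any(np.abs(denom) < 1e-12):
        raise np.linalg.LinAlgError("leverage of 1: fold model is degenerate")
    if Y.ndim == 1:
        resid = (Y - Yhat) / denom
    else:
        resid = (Y - Yhat) / denom[:, None]
    return Y - resid


def rank_pcs(train_scores: np.ndarray, y: np.ndarray, ascending: bool = False) -> np.ndarray:
    """Rank PCs by |Pearson correlation| with the training scores.

    Returns a permutation of PC indices, best first under the default
    (descending |r|); ties break toward the smaller PC index.  A constant
    PC column gets correlation 0.
    """
    X = np.asarray(train_scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("ranking needs at least 3 training patients")
    if np.std(y) == 0:
        raise ValueError("training scores are constant; correlation undefined")
    r = np.array([abs(_pearson(X[:, j], y)) for j in range(X.shape[1])])
    key = r if ascending else -r
    return np.argsort(key, kind="stable")


def aggregate_rankings(per_fold_rankings: list[np.ndarray]) -> np.ndarray:
    """Global ranking by mean rank position across folds; ties by PC index."""
    if not per_fold_rankings:
        raise ValueError("no fold rankings")
    m = len(per_fold_rankings[0])
    ranks = np.zeros((len(per_fold_rankings), m))
    for i, perm in enumerate(per_fold_rankings):
        perm = np.asarray(perm)
        if perm.shape[0] != m or not np.array_equal(np.sort(perm), np.arange(m)):
            raise ValueError("fold rankings are not permutations of one PC set")
        ranks[i, perm] = np.arange(m)
    return np.argsort(ranks.mean(axis=0), kind="stable")


def _inner_r2(X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Inner-LOOCV validation R^2 (squared Pearson of LOO preds vs y)."""
    try:
        pred = loo_predictions(X, y, lam)
    except np.linalg.LinAlgError:
        return -np.inf
    return skill_r2(pred, y)


def _prefix_loo_r2(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Validation skill R^2 of every ranking-prefix size 1..m in one sweep.

    The augmented Gram (intercept column unpenalized) is Cholesky-factored
    once; because the factor of any leading block is the leading block of
    the factor, forward substitution plus cumulative sums yield the exact
    leave-one-out leverages and predictions for every column prefix
    simultaneously.  Identical to calling :func:`loo_predictions` prefix by
    prefix, at a fraction of the cost.
    """
    from scipy.linalg import cholesky as _chol, solve_triangular as _tri

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    Xa = np.column_stack([np.ones(n), X])
    pen = np.full(m + 1, lam)
    pen[0] = 0.0
    G = Xa.T @ Xa + np.diag(pen)
    try:
        L = _chol(G, lower=True)
    except np.linalg.LinAlgError:
        return np.full(m, -np.inf)
    Z = _tri(L, Xa.T, lower=True)
    H = np.cumsum(Z * Z, axis=0)  # prefix leverages, row k = prefix size k
    u = Z @ y
    Yh = np.cumsum(Z * u[:, None], axis=0)  # prefix in-sample predictions
    h, yh = H[1:], Yh[1:]
    denom = 1.0 - h
    bad = np.any(np.abs(denom) < 1e-12, axis=1)
    denom = np.where(np.abs(denom) < 1e-12, 1.0, denom)
    pred = y[None, :] - (y[None, :] - yh) / denom
    pc = pred - pred.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    dn = np.sqrt((pc**2).sum(axis=1) * (yc @ yc))
    r = np.zeros(m)
    ok = dn > 0
    r[ok] = (pc[ok] @ yc) / dn[ok]
    r2 = np.where(r > 0, r, 0.0) ** 2
    r2[bad] = -np.inf
    return r2


@njit(cache=True)
def _scan_kernel(Xa, y, lambdas):  # pragma: no cover - exercised via wrapper
    """Inner-LOOCV skill R^2 for every (outer fold, penalty, prefix size).

    ``Xa`` is the augmented design (intercept column first, remaining
    columns already in ranking order).  For each outer fold the training
    Gram is a rank-1 downdate of the full Gram; one Cholesky per
    (fold, penalty) plus forward substitution yields the exact
    leave-one-out leverages and predictions of every column prefix at once
    (the factor of a leading block is the leading block of the factor).
    """
    n, m1 = Xa.shape
    m = m1 - 1
    nl = lambdas.shape[0]
    ntr = n - 1
    out = np.full((n, nl, m), -np.inf)
    G_full = Xa.T @ Xa
    A = np.empty((m1, m1))
    Z = np.empty((m1, ntr))
    u = np.empty(m1)
    yt = np.empty(ntr)
    h = np.empty(ntr)
    yh = np.empty(ntr)
    pred = np.empty(ntr)
    for f in range(n):
        k = 0
        for r in range(n):
            if r != f:
                yt[k] = y[r]
                k += 1
        sy = 0.0
        syy = 0.0
        for j in range(ntr):
            sy += yt[j]
        my = sy / ntr
        for j in range(ntr):
            syy += (yt[j] - my) ** 2
        for li in range(nl):
            lam = lambdas[li]
            for i in range(m1):
                for j in range(i + 1):
                    A[i, j] = G_full[i, j] - Xa[f, i] * Xa[f, j]
                A[i, i] += lam if i > 0 else 0.0
            # in-place lower Cholesky
            ok = True
            for kk in range(m1):
                s = A[kk, kk]
                for t in range(kk):
                    s -= A[kk, t] * A[kk, t]
                if s <= 1e-300:
                    ok = False
                    break
                A[kk, kk] = np.sqrt(s)
                for i in range(kk + 1, m1):
                    s2 = A[i, kk]
                    for t in range(kk):
                        s2 -= A[i, t] * A[kk, t]
                    A[i, kk] = s2 / A[kk, kk]
            if not ok:
                continue
            # Z = L^-1 Xt^T by forward substitution, one training row at a time
            col = 0
            for r in range(n):
                if r == f:
                    continue
                for i in range(m1):
                    s3 = Xa[r, i]
                    for t in range(i):
                        s3 -= A[i, t] * Z[t, col]
                    Z[i, col] = s3 / A[i, i]
                col += 1
            for i in range(m1):
                s4 = 0.0
                for j in range(ntr):
                    s4 += Z[i, j] * yt[j]
                u[i] = s4
            # prefix cumulatives: row i of Z adds column i's contribution
            for j in range(ntr):
                h[j] = Z[0, j] * Z[0, j]
                yh[j] = Z[0, j] * u[0]
            for p in range(1, m1):
                good = True
                for j in range(ntr):
                    h[j] += Z[p, j] * Z[p, j]
                    yh[j] += Z[p, j] * u[p]
                    d = 1.0 - h[j]
                    if abs(d) < 1e-12:
                        good = False
                    else:
                        pred[j] = yt[j] - (yt[j] - yh[j]) / d
                if not good:
                    continue
                sp = 0.0
                for j in range(ntr):
                    sp += pred[j]
                mp = sp / ntr
                num = 0.0
                den = 0.0
                for j in range(ntr):
                    pc = pred[j] - mp
                    num += pc * (yt[j] - my)
                    den += pc * pc
                dn = np.sqrt(den * syy)
                if dn > 0:
                    rr = num / dn
                    out[f, li, p - 1] = rr * rr if rr > 0 else 0.0
                else:
                    out[f, li, p - 1] = 0.0
    return out


def _all_fold_prefix_r2(
    X: np.ndarray, y: np.ndarray, grid: tuple[float, ...]
) -> np.ndarray:
    """Inner-LOOCV validation R^2 for every (outer fold, penalty, prefix);
    shape (n_folds, n_penalties, m).  Thin wrapper over the jitted kernel."""
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.ascontiguousarray(np.asarray(y, dtype=float))
    n = X.shape[0]
    Xa = np.column_stack([np.ones(n), X])
    return _scan_kernel(Xa, y, np.asarray(grid, dtype=float))


@njit(cache=True)
def _corr_rank_nb(X, y, ascending):  # pragma: no cover - exercised via wrapper
    """Ranking of columns by |Pearson r| with y (descending by default)."""
    n, m = X.shape
    my = 0.0
    for j in range(n):
        my += y[j]
    my /= n
    syy = 0.0
    for j in range(n):
        syy += (y[j] - my) ** 2
    key = np.empty(m)
    for c in range(m):
        mx = 0.0
        for j in range(n):
            mx += X[j, c]
        mx /= n
        sxy = 0.0
        sxx = 0.0
        for j in range(n):
            d = X[j, c] - mx
            sxy += d * (y[j] - my)
            sxx += d * d
        dn = np.sqrt(sxx * syy)
        r = abs(sxy) / dn if dn > 0 else 0.0
        key[c] = r if ascending else -r
    return np.argsort(key, kind="mergesort")


@njit(cache=True)
def _prefix_newpoint_nb(G, Xty, xnew, rk, lam, A, u, z):
    """Predictions of one new point for every ranked-prefix ridge model.

    ``G`` is the training Gram of the augmented design (intercept first),
    ``Xty`` the training X^T y, both in natural column order; ``rk`` is the
    PC ranking (0-based, excluding the intercept).  Returns the cumulative
    prediction array (prefix k at index k-1) via one Cholesky in ranking
    order and two forward solves.  Work buffers A, u, z of size (m+1).
    """
    m1 = G.shape[0]
    # reorder Gram and rhs into (intercept, ranked PCs) order, add penalty
    for a in range(m1):
        ia = 0 if a == 0 else rk[a - 1] + 1
        for b in range(a + 1):
            ib = 0 if b == 0 else rk[b - 1] + 1
            A[a, b] = G[ia, ib]
        if a > 0:
            A[a, a] += lam
        u[a] = Xty[ia]
        z[a] = xnew[ia]
    # in-place lower Cholesky
    for kk in range(m1):
        s = A[kk, kk]
        for t in range(kk):
            s -= A[kk, t] * A[kk, t]
        if s <= 1e-300:
            return False
        A[kk, kk] = np.sqrt(s)
        for i in range(kk + 1, m1):
            s2 = A[i, kk]
            for t in range(kk):
                s2 -= A[i, t] * A[kk, t]
            A[i, kk] = s2 / A[kk, kk]
    # forward solves in place: u <- L^-1 u ; z <- L^-1 z
    for i in range(m1):
        su = u[i]
        sz = z[i]
        for t in range(i):
            su -= A[i, t] * u[t]
            sz -= A[i, t] * z[t]
        u[i] = su / A[i, i]
        z[i] = sz / A[i, i]
    # cumulative dot gives every prefix prediction; reuse u as cumsum store
    acc = 0.0
    for i in range(m1):
        acc += u[i] * z[i]
        z[i] = acc
    return True


@njit(cache=True)
def _honest_loocv_kernel(X, y, lambdas, ascending):  # pragma: no cover
    """Fold-safe nested-LOOCV ridge predictions for every patient.

    For each held-out patient, every inner fold of the remaining patients
    re-ranks the PCs by correlation with its own training scores and
    produces validation predictions for every (penalty, prefix) pair; the
    pooled validation MSE selects the model by the one-standard-error rule
    (most parsimonious prefix, then smallest penalty, within one SE of the
    minimum).  The held-out patient is then predicted by that model fit on
    all remaining patients.  No quantity involving the held-out score ever
    enters its own prediction.
    """
    n, m = X.shape
    L = lambdas.shape[0]
    m1 = m + 1
    Xa = np.empty((n, m1))
    for j in range(n):
        Xa[j, 0] = 1.0
        for c in range(m):
            Xa[j, c + 1] = X[j, c]
    G_all = Xa.T @ Xa
    Xty_all = Xa.T @ y
    preds = np.empty(n)
    k_sel = np.empty(n, np.int64)
    lam_sel = np.empty(n)
    A = np.empty((m1, m1))
    u = np.empty(m1)
    z = np.empty(m1)
    Xt = np.empty((n - 1, m))
    yt = np.empty(n - 1)
    s1 = np.empty((L, m))
    s2 = np.empty((L, m))
    nbad = np.empty((L, m), np.int64)
    for i in range(n):
        # training set = all but i
        G_tr = G_all - np.outer(Xa[i], Xa[i])
        Xty_tr = Xty_all - Xa[i] * y[i]
        t = 0
        for j in range(n):
            if j != i:
                for c in range(m):
                    Xt[t, c] = X[j, c]
                yt[t] = y[j]
                t += 1
        ntr = n - 1
        s1[:, :] = 0.0
        s2[:, :] = 0.0
        nbad[:, :] = 0
        for f in range(ntr):
            # inner training = training minus f
            xf = np.empty(m1)
            xf[0] = 1.0
            for c in range(m):
                xf[c + 1] = Xt[f, c]
            G_in = G_tr - np.outer(xf, xf)
            Xty_in = Xty_tr - xf * yt[f]
            # rank on the inner training set
            Xin = np.empty((ntr - 1, m))
            yin = np.empty(ntr - 1)
            tt = 0
            for j in range(ntr):
                if j != f:
                    for c in range(m):
                        Xin[tt, c] = Xt[j, c]
                    yin[tt] = yt[j]
                    tt += 1
            rk = _corr_rank_nb(Xin, yin, ascending)
            for li in range(L):
                ok = _prefix_newpoint_nb(G_in, Xty_in, xf, rk, lambdas[li], A, u, z)
                if not ok:
                    nbad[li, :] += 1
                    continue
                for k in range(m):
                    e = z[k + 1] - yt[f]
                    s1[li, k] += e * e
                    s2[li, k] += e * e * e * e
        # pooled MSE and its standard error; 1-SE parsimony rule
        best_mse = 1e300
        bi = 0
        bk = 0
        for li in range(L):
            for k in range(m):
                if nbad[li, k] > 0:
                    continue
                mse = s1[li, k] / ntr
                if mse < best_mse:
                    best_mse = mse
                    bi = li
                    bk = k
        var = s2[bi, bk] / ntr - best_mse * best_mse
        if var < 0.0:
            var = 0.0
        thresh = best_mse + np.sqrt(var / ntr)
        chosen_k = bk
        chosen_li = bi
        found = False
        for k in range(m):
            for li in range(L):
                if nbad[li, k] == 0 and s1[li, k] / ntr <= thresh:
                    chosen_k = k
                    chosen_li = li
                    found = True
                    break
            if found:
                break
        # final model: rank on the full training set, predict patient i
        rk_tr = _corr_rank_nb(Xt, yt, ascending)
        ok = _prefix_newpoint_nb(
            G_tr, Xty_tr, Xa[i], rk_tr, lambdas[chosen_li], A, u, z
        )
        preds[i] = z[chosen_k + 1] if ok else np.mean(yt)
        k_sel[i] = chosen_k + 1
        lam_sel[i] = lambdas[chosen_li]
    return preds, k_sel, lam_sel


def _fold_rankings(X: np.ndarray, y: np.ndarray, ascending: bool = False) -> np.ndarray:
    """Aggregated global PC ranking over all leave-one-out folds, vectorized.

    Exactly reproduces rank_pcs per fold followed by aggregate_rankings:
    leave-one-out Pearson correlations come from running sums, each fold's
    permutation from a stable argsort, and the global order from the mean
    rank position (ties toward the smaller PC index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    Sx, Sy = X.sum(axis=0), y.sum()
    Sxy = X.T @ y
    Sxx, Syy = (X * X).sum(axis=0), y @ y
    nn = n - 1
    sx = Sx[None, :] - X
    sy = Sy - y
    sxy = Sxy[None, :] - X * y[:, None]
    sxx = Sxx[None, :] - X * X
    syy = Syy - y * y
    cov = sxy - sx * sy[:, None] / nn
    vx = np.maximum(sxx - sx**2 / nn, 0.0)
    vy = np.maximum(syy - sy**2 / nn, 0.0)
    denom = np.sqrt(vx * vy[:, None])
    r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(np.abs(r), 0.0, 1.0)
    order = np.argsort(r if ascending else -r, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(m), (n, m)), axis=1)
    return np.argsort(ranks.mean(axis=0), kind="stable")


def select_hyperparams(
    X_scores: np.ndarray,
    y: np.ndarray,
    global_ranking: np.ndarray,
    cfg: RidgeConfig = RidgeConfig(),
    max_pcs: int | None = None,
) -> tuple[int, float]:
    """Select the ranked-PC count and ridge penalty by nested LOOCV.

    For every outer fold's training set, an inner LOOCV scans all prefix
    sizes of the global ranking against the penalty grid; the joint argmax
    by validation R^2 (ties to smaller prefix, then smaller penalty) is
    recorded per fold.  The returned count is the rounded mean of the
    per-fold optima; the penalty is their mode (ties to the smaller value).
    """
    X = np.asarray(X_scores, dtype=float)[:, np.asarray(global_ranking)]
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n < 4:
        raise ValueError("hyperparameter selection needs at least 4 patients")
    if max_pcs is not None:
        m = min(m, max_pcs)
    grid = cfg.grid
    r2 = _all_fold_prefix_r2(X[:, :m], y, grid)  # (n, n_lam, m)
    # first strict maximum scanning prefix-major then penalty-major,
    # i.e. ties resolve to the smaller prefix, then the smaller penalty
    flat = r2.transpose(0, 2, 1).reshape(n, -1)
    j = np.argmax(flat, axis=1)
    best_ns = (j // len(grid) + 1).tolist()
    best_lams = [grid[k] for k in (j % len(grid))]
    n_star = max(1, round_half_up(float(np.mean(best_ns))))
    counts = Counter(best_lams)
    top = max(counts.values())
    lam_star = min(l for l, c in counts.items() if c == top)
    return n_star, float(lam_star)


def loocv_evaluate(
    X_scores: np.ndarray,
    y: np.ndarray,
    global_ranking: np.ndarray,
    n_star: int,
    lam_star: float,
    feature_id: str = "",
    score_name: str = "",
    explained_variance_ratio: np.ndarray | None = None,
) -> CvResult:
    """LOOCV evaluation with the selected ranked-PC prefix and penalty."""
    ranking = np.asarray(global_ranking)
    if n_star > ranking.shape[0] or n_star > np.asarray(X_scores).shape[1]:
        raise ValueError("n_star exceeds the number of available PCs")
    X = np.asarray(X_scores, dtype=float)[:, ranking[:n_star]]
    y = np.asarray(y, dtype=float)
    pred = loo_predictions(X, y, lam_star)
    r2 = skill_r2(pred, y)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    tev = None
    if explained_variance_ratio is not None:
        tev = float(100.0 * np.sum(np.asarray(explained_variance_ratio)[ranking[:n_star]]))
    return CvResult(
        feature_id=feature_id,
        score_name=score_name,
        r2=r2,
        r2_residual=1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
        mse=float(np.mean((y - pred) ** 2)),
        n_pcs=int(n_star),
        total_explained_variance=tev,
        lambda_=float(lam_star),
        n_patients=len(y),
        predicted=pred,
        actual=y.copy(),
    )


def permutation_test(
    X_scores: np.ndarray,
    y: np.ndarray,
    global_ranking: np.ndarray,
    n_star: int,
    lam_star: float,
    B: int = 10000,
    seed: int = 0,
    estimator: str = "proportion",
    refit: str = "full",
    cfg: RidgeConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value of the observed LOOCV R^2.

    Scores are permuted across patients ``B`` times and the LOOCV R^2 is
    recomputed for each permutation; ``p`` is the plain proportion of
    permutations with R^2 at least the observed value
    (``estimator="add_one"`` uses (k+1)/(B+1)); the smallest resolvable
    nonzero p is 1/B.

    ``refit`` controls how much of the score-dependent training procedure
    each permutation repeats.  ``"full"`` (default) re-runs the PC ranking
    and the hyperparameter selection on the permuted scores, so observed
    and permuted statistics are computed by the identical pipeline and the
    test is exchangeable — without this, the ranking and (PC count,
    penalty) tuned to the observed scores inflate the observed R^2
    relative to the permutations and the test is strongly anti-
    conservative.  ``"ranking"`` refits only the ranking; ``"none"`` keeps
    ranking and hyperparameters fixed at their observed-data values.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    ranking = np.asarray(global_ranking)
    Xfull = np.asarray(X_scores, dtype=float)
    y = np.asarray(y, dtype=float)
    X = Xfull[:, ranking[:n_star]]
    obs = skill_r2(loo_predictions(X, y, lam_star), y)
    rng = np.random.default_rng(seed)
    n = len(y)
    if refit == "none":
        Yp = np.empty((n, B))
        for b in range(B):
            Yp[:, b] = y[rng.permutation(n)]
        pred = loo_predictions(X, Yp, lam_star)
        pc = pred - pred.mean(axis=0)
        yc = Yp - Yp.mean(axis=0)
        denom = np.sqrt((pc**2).sum(axis=0) * (yc**2).sum(axis=0))
        r = np.zeros(B)
        ok = denom > 0
        r[ok] = (pc[:, ok] * yc[:, ok]).sum(axis=0) / denom[ok]
        perm_r2 = np.where(r > 0, r, 0.0) ** 2
    elif refit in ("ranking", "full"):
        cfg = cfg or RidgeConfig()
        perm_r2 = np.empty(B)
        for b in range(B):
            yp = y[rng.permutation(n)]
            rk = _fold_rankings(Xfull, yp, cfg.rank_ascending)
            if refit == "full":
                nb, lb = select_hyperparams(Xfull, yp, rk, cfg)
            else:
                nb, lb = n_star, lam_star
            perm_r2[b] = skill_r2(loo_predictions(Xfull[:, rk[:nb]], yp, lb), yp)
    else:
        raise ValueError(f"unknown refit mode {refit!r}")
    k = int(np.sum(perm_r2 >= obs))
    if estimator == "proportion":
        p = k / B
    elif estimator == "add_one":
        p = (k + 1) / (B + 1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return float(p), perm_r2


def fisher_compare(
    a: CvResult, b: CvResult, n_a: int | None = None, n_b: int | None = None
) -> ModelComparison:
    """Compare two models' R^2 through Fisher's r-to-z transform.

    r = sqrt(R^2) per model, z = atanh(r), SE = 1/sqrt(n-3); 95 % CIs on
    the z scale are mapped back to R^2 via tanh^2, and the two-sided
    p-value comes from the normal z-difference.  R^2 = 1 yields an infinite
    z (sentinel) and a p-value of 0 against any other model, nan against
    another perfect model.
    """
    n_a = a.n_patients if n_a is None else n_a
    n_b = b.n_patients if n_b is None else n_b
    if n_a <= 3 or n_b <= 3:
        raise ValueError("Fisher comparison needs n > 3")
    za = float(np.arctanh(np.sqrt(np.clip(a.r2, 0.0, 1.0)))) if a.r2 < 1 else np.inf
    zb = float(np.arctanh(np.sqrt(np.clip(b.r2, 0.0, 1.0)))) if b.r2 < 1 else np.inf
    se_a = 1.0 / np.sqrt(n_a - 3)
    se_b = 1.0 / np.sqrt(n_b - 3)
    ci_a = tuple(float(np.tanh(za + s * 1.959963984540054 * se_a) ** 2) for s in (-1, 1))
    ci_b = tuple(float(np.tanh(zb + s * 1.959963984540054 * se_b) ** 2) for s in (-1, 1))
    zdiff = (za - zb) / np.sqrt(se_a**2 + se_b**2)
    if np.isnan(zdiff):
        p = float("nan")
    else:
        p = float(2.0 * (1.0 - ndtr(abs(zdiff))))
    return ModelComparison(za, zb, se_a, se_b, ci_a, ci_b, p)


def evaluate_feature(
    X_scores: np.ndarray,
    y: np.ndarray,
    cfg: RidgeConfig = RidgeConfig(),
    feature_id: str = "",
    score_name: str = "",
    explained_variance_ratio: np.ndarray | None = None,
    permutations: int = 0,
    seed: int = 0,
    fold_safe: bool = True,
) -> CvResult:
    """Two-step nested-LOOCV ridge evaluation of one feature/score pair.

    With ``fold_safe=True`` (default) the PC ranking and the (PC count,
    penalty) selection for each held-out patient are computed strictly
    within that patient's training set, so every prediction is untouched by
    the held-out score and the reported R^2 is an honest estimate of
    out-of-sample skill.  ``fold_safe=False`` follows the literal global
    variant — one aggregated ranking and one (n*, lambda*) shared by all
    folds — which leaks score information across folds and inflates R^2 in
    small cohorts.

    The permutation p-value always uses the global-variant statistic with
    the ranking and selection re-run per permuted score vector
    (``refit="full"``), an exchangeable and therefore calibrated test of
    feature-score association.
    """
    X = np.ascontiguousarray(np.asarray(X_scores, dtype=float))
    y = np.ascontiguousarray(np.asarray(y, dtype=float))
    n = X.shape[0]
    ranking = _fold_rankings(X, y, cfg.rank_ascending)
    n_star, lam_star = select_hyperparams(X, y, ranking, cfg)
    if fold_safe:
        preds, per_fold_n, per_fold_lam = _honest_loocv_kernel(
            X, y, np.asarray(cfg.grid, dtype=float), cfg.rank_ascending
        )
        n_report = max(1, round_half_up(float(np.mean(per_fold_n))))
        counts = Counter(per_fold_lam.tolist())
        top = max(counts.values())
        lam_report = float(min(l for l, c in counts.items() if c == top))
        ss_res = float(np.sum((y - preds) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        tev = None
        if explained_variance_ratio is not None:
            evr = np.asarray(explained_variance_ratio)
            tev = float(100.0 * np.sum(evr[ranking[: min(n_report, len(evr))]]))
        res = CvResult(
            feature_id=feature_id,
            score_name=score_name,
            r2=skill_r2(preds, y),
            r2_residual=1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
            mse=float(np.mean((y - preds) ** 2)),
            n_pcs=n_report,
            total_explained_variance=tev,
            lambda_=lam_report,
            n_patients=n,
            predicted=preds,
            actual=y.copy(),
        )
    else:
        res = loocv_evaluate(
            X, y, ranking, n_star, lam_star, feature_id, score_name,
            explained_variance_ratio,
        )
    if permutations > 0:
        p, _ = permutation_test(
            X, y, ranking, n_star, lam_star, permutations, seed,
            cfg.permutation_estimator, refit="full", cfg=cfg,
        )
        res.permutation_p = p
    return res
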
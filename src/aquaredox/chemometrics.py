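"""Multivariate calibration chain for the NIR workflows.

Implements, from first principles on top of numpy/scipy linear algebra:

* mean-centered SVD PCA with a fixed sign convention, and the
  chi-square-thresholded Mahalanobis outlier screen in PCA score space;
* Wold-style iterative Orthogonal Signal Correction (OSC), which removes
  X-variance orthogonal to the response before calibration;
* NIPALS PLS1 with deflation (single-response partial least squares),
  including the channel-space regression vector b = W (P'W)^-1 q;
* principal component regression (PCR) for multi-response mixture models;
* cross-validation (leave-one-out and leave-k-spectra-out) with all
  response-using preprocessing (OSC, autoscaling) refit inside each
  training fold;
* RMSE / R-squared metrics and regression-vector band localization.

Full-rank PLS, full-rank PCR and ordinary least squares on centered data
are algebraically identical; the test suite holds all three to that
equivalence.  scikit-learn's PLS implementation serves only as an
independent cross-check there, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import chi2


def _fix_sign(v: np.ndarray) -> float:
    """Sign that makes the largest-magnitude element of ``v`` positive."""
    i = int(np.argmax(np.abs(v)))
    s = np.sign(v[i])
    return 1.0 if s == 0 else float(s)


# ---------------------------------------------------------------------------
# PCA + Mahalanobis screen
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray            # (p,)
    loadings: np.ndarray        # (p, k), orthonormal columns
    scores: np.ndarray          # (n, k)
    eigenvalues: np.ndarray     # (k,) sample variances of the scores
    explained_variance_ratio: np.ndarray  # (k,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """Mean-centered SVD PCA keeping ``k`` components.

    Deterministic: each loading is flipped so its largest-magnitude element
    is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2)) / (n - 1)
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * s[:k]
    for j in range(k):
        sgn = _fix_sign(loadings[:, j])
        loadings[:, j] *= sgn
        scores[:, j] *= sgn
    eig = s[:k] ** 2 / (n - 1)
    ratio = eig / total_var if total_var > 0 else np.zeros(k)
    return PCAModel(mean, loadings, scores, eig, ratio)


@dataclass
class OutlierReport:
    distance: np.ndarray        # (n,) Mahalanobis distance in score space
    threshold: float            # same scale as distance
    removed: np.ndarray         # boolean
    n_components: int
    quantile: float

    @property
    def kept(self) -> np.ndarray:
        return ~self.removed


def mahalanobis_screen(model: PCAModel, threshold_quantile: float = 0.975) -> OutlierReport:
    """Flag samples whose score-space Mahalanobis distance exceeds the
    chi-square(k) quantile.

    distance^2 = sum_j score_j^2 / eigenvalue_j over the model's k
    components.
    """
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in (0, 1)")
    k = model.loadings.shape[1]
    if np.any(model.eigenvalues <= 0):
        raise ValueError("zero eigenvalue among retained components; reduce k")
    d2 = np.sum(model.scores**2 / model.eigenvalues, axis=1)
    thr2 = float(chi2.ppf(threshold_quantile, df=k))
    d = np.sqrt(d2)
    thr = float(np.sqrt(thr2))
    return OutlierReport(
        distance=d, threshold=thr, removed=d > thr,
        n_components=k, quantile=threshold_quantile,
    )


def screen_outliers(X: np.ndarray, variance_target: float = 0.95,
                    threshold_quantile: float = 0.975, max_k: int = 10):
    """Convenience wrapper: pick k as the smallest component count explaining
    >= ``variance_target`` of the variance, then run the Mahalanobis screen.

    Returns ``(PCAModel, OutlierReport)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    kmax = min(max_k, X.shape[0] - 1, X.shape[1])
    probe = fit_pca(X, kmax)
    cum = np.cumsum(probe.explained_variance_ratio)
    k = int(np.searchsorted(cum, variance_target) + 1)
    k = min(k, kmax)
    model = fit_pca(X, k)
    return model, mahalanobis_screen(model, threshold_quantile)


# ---------------------------------------------------------------------------
# Orthogonal signal correction
# ---------------------------------------------------------------------------

@dataclass
class OSCModel:
    weights: list = field(default_factory=list)   # per component, (p,)
    loadings: list = field(default_factory=list)  # per component, (p,)
    scores: list = field(default_factory=list)    # training scores, (n,)
    x_mean: np.ndarray | None = None
    y_mean: float = 0.0
    tol: float = 1e-10
    iterations: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Remove the fitted orthogonal components from new spectra."""
        X = np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean
        for w, p in zip(self.weights, self.loadings):
            t = X @ w
            X = X - np.outer(t, p)
        return X + self.x_mean


def fit_osc(X: np.ndarray, y: np.ndarray, n_components: int = 1,
            tol: float = 1e-10, max_iter: int = 100):
    """Wold-style orthogonal signal correction.

    Per component: seed the score with the first principal component of the
    (deflated) X, then alternate (a) projecting the score onto the
    orthogonal complement of y and (b) regressing it back onto X, until the
    score is stationary.  The converged score t lies in the column space of
    X and satisfies |t'y| <= tol * ||t|| ||y||; X is then deflated by the
    rank-one piece t p' with p = X't / t't.

    Returns ``(OSCModel, X_corrected)``; ``n_components=0`` returns X
    unchanged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    model = OSCModel(tol=tol)
    model.x_mean = X.mean(axis=0)
    model.y_mean = float(y.mean())
    Xd = X - model.x_mean
    yc = y - model.y_mean
    ynorm2 = float(yc @ yc)
    if ynorm2 == 0:
        raise ValueError("response has zero variance")

    for _ in range(n_components):
        U, s, Vt = np.linalg.svd(Xd, full_matrices=False)
        t = U[:, 0] * s[0]
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            t_orth = t - yc * (yc @ t) / ynorm2
            w, *_ = np.linalg.lstsq(Xd, t_orth, rcond=None)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("OSC degenerate: no orthogonal variance left")
            w = w / nw
            t_new = Xd @ w
            if np.linalg.norm(t_new - t) <= tol * max(1.0, np.linalg.norm(t)):
                t = t_new
                break
            t = t_new
        resid = abs(t @ yc) / (np.linalg.norm(t) * np.sqrt(ynorm2) + 1e-300)
        if resid > max(tol, 1e-8):
            raise RuntimeError(
                f"OSC did not converge in {max_iter} iterations "
                f"(orthogonality residual {resid:.3e})"
            )
        p = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, p)
        model.weights.append(w)
        model.loadings.append(p)
        model.scores.append(t)
        model.iterations.append(n_iter)

    return model, Xd + model.x_mean


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) and PCR
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    n_lv: int
    W: np.ndarray               # (p, A) X-weights
    P: np.ndarray               # (p, A) X-loadings
    T: np.ndarray               # (n, A) X-scores (training)
    q: np.ndarray               # (A,) y-loadings
    b: np.ndarray               # (p,) regression vector, centered coordinates
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    grid: np.ndarray | None = None   # optional wavelength axis for b


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int,
             grid: np.ndarray | None = None) -> PLSModel:
    """NIPALS PLS1 with deflation.

    Each latent variable: w = X'y / ||X'y||, t = Xw, p = X't/t't,
    q = y't/t't, then deflate X and y.  The regression vector is
    b = W (P'W)^-1 q; predictions are intercept + X b.  Component signs
    follow the largest-|w| convention.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} must be in [1, min(n-1, p)={min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    x_scale = np.linalg.norm(Xd) * np.linalg.norm(yd) + 1e-300
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * x_scale:
            raise ValueError(
                f"n_lv={n_lv} exceeds the effective rank of X "
                f"(no covariance left at latent variable {a + 1})"
            )
        w = w / nw
        w *= _fix_sign(w)
        t = Xd @ w
        tt = float(t @ t)
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa

    b = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ b)
    return PLSModel(n_lv, W, P, T, q, b, intercept, x_mean, y_mean,
                    grid=None if grid is None else np.asarray(grid, float))


@dataclass
class PCRModel:
    k: int
    pca: PCAModel
    score_coefs: np.ndarray     # (k, m) regression coefficients in score space
    B: np.ndarray               # (p, m) equivalent channel-space vectors
    intercepts: np.ndarray      # (m,)
    x_mean: np.ndarray
    y_mean: np.ndarray
    grid: np.ndarray | None = None


def fit_pcr(X: np.ndarray, Y: np.ndarray, k: int,
            grid: np.ndarray | None = None) -> PCRModel:
    """Principal component regression: each response regressed on the first
    k PCA scores, coefficients mapped back to channel space."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds rank(Xc)={rank}")
    pca = fit_pca(X, k)
    Yc = Y - Y.mean(axis=0)
    coefs, *_ = np.linalg.lstsq(pca.scores, Yc, rcond=None)
    B = pca.loadings @ coefs
    intercepts = Y.mean(axis=0) - pca.mean @ B
    return PCRModel(k, pca, coefs, B, intercepts, pca.mean, Y.mean(axis=0),
                    grid=None if grid is None else np.asarray(grid, float))


def predict(model, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations (mM) from spectra on the model's channel grid."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if isinstance(model, PLSModel):
        if X_new.shape[1] != model.b.size:
            raise ValueError(
                f"channel mismatch: {X_new.shape[1]} vs model {model.b.size}"
            )
        return X_new @ model.b + model.intercept
    if isinstance(model, PCRModel):
        if X_new.shape[1] != model.B.shape[0]:
            raise ValueError(
                f"channel mismatch: {X_new.shape[1]} vs model {model.B.shape[0]}"
            )
        out = X_new @ model.B + model.intercepts
        return out[:, 0] if out.shape[1] == 1 else out
    raise TypeError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# Metrics and cross-validation
# ---------------------------------------------------------------------------

def metrics(y_true: np.ndarray, y_pred: np.ndarray):
    """(RMSE, R^2).  R^2 = 1 - SSres/SStot; errors on constant y_true."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("metrics need two equal-length vectors of size >= 2")
    ss_res = float(np.sum((y_pred - y_true) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: constant y_true")
    rmse = float(np.sqrt(ss_res / y_true.size))
    return rmse, 1.0 - ss_res / ss_tot


@dataclass
class CVResult:
    scheme: str
    y_true: np.ndarray
    y_pred: np.ndarray          # pooled held-out predictions, original order
    rmse: float
    r2: float
    folds: np.ndarray           # fold index per sample
    seed: int | None
    n_lv: int | None = None


def _fold_assignments(n: int, scheme: str, k_out: int, seed) -> np.ndarray:
    if scheme == "loo":
        return np.arange(n)
    if scheme == "leave_k_out":
        if not 1 <= k_out < n:
            raise ValueError("k_out must be in [1, n)")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        for f, start in enumerate(range(0, n, k_out)):
            folds[order[start:start + k_out]] = f
        return folds
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    scheme: str = "loo",
    k_out: int = 5,
    seed: int | None = 0,
    n_lv: int = 5,
    osc_components: int = 0,
    model: str = "plsr",
    k_pc: int | None = None,
) -> CVResult:
    """Cross-validate the calibration pipeline.

    Every response-using step — OSC and the regression fit itself — is refit
    inside each training fold; the held-out spectra only ever see fitted
    transforms.  Pooled held-out predictions give the reported RMSE / R^2.
    ``scheme`` is ``"loo"`` or ``"leave_k_out"`` (seeded random partition
    into folds of size ``k_out``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    folds = _fold_assignments(n, scheme, k_out, seed)
    y_pred = np.full(y.shape, np.nan, dtype=float)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        Xtr, ytr = X[train], y[train]
        Xte = X[test]
        if osc_components:
            if y.ndim > 1:
                raise ValueError("OSC is defined here for single-response y")
            osc, Xtr = fit_osc(Xtr, ytr, n_components=osc_components)
            Xte = osc.apply(Xte)
        if model == "plsr":
            m = fit_plsr(Xtr, ytr, n_lv=n_lv)
        elif model == "pcr":
            m = fit_pcr(Xtr, ytr, k=k_pc if k_pc is not None else n_lv)
        else:
            raise ValueError(f"unknown model {model!r}")
        y_pred[test] = predict(m, Xte)
    if y.ndim == 1:
        rmse, r2 = metrics(y, y_pred)
    else:
        per = [metrics(y[:, j], y_pred[:, j]) for j in range(y.shape[1])]
        rmse = float(np.sqrt(np.mean((y_pred - y) ** 2)))
        r2 = float(np.mean([p[1] for p in per]))
    return CVResult(scheme, y, y_pred, rmse, r2, folds, seed,
                    n_lv=n_lv if model == "plsr" else (k_pc or n_lv))


def _pls_predictions_per_lv(Xtr, ytr, Xte, max_lv: int) -> np.ndarray:
    """Held-out predictions for every LV count 1..max_lv from one NIPALS
    fit (the models are nested, so one deflation pass serves all)."""
    model = fit_plsr(Xtr, ytr, n_lv=max_lv)
    Xte_c = np.atleast_2d(Xte) - model.x_mean
    out = np.empty((Xte_c.shape[0], max_lv))
    for a in range(1, max_lv + 1):
        W, P, q = model.W[:, :a], model.P[:, :a], model.q[:a]
        b = W @ np.linalg.solve(P.T @ W, q)
        out[:, a - 1] = Xte_c @ b + model.y_mean
    return out


def select_n_lv(X, y, max_lv: int = 10, scheme: str = "loo",
                k_out: int = 5, seed: int = 0, osc_components: int = 0) -> int:
    """Latent-variable count minimizing cross-validated RMSE (default LOO),
    capped at ``max_lv``.  OSC is refit inside every training fold."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    max_lv = min(max_lv, rank - osc_components)
    folds = _fold_assignments(n, scheme, k_out, seed)
    preds = np.empty((n, max_lv))
    for f in np.unique(folds):
        test = folds == f
        Xtr, ytr, Xte = X[~test], y[~test], X[test]
        if osc_components:
            osc, Xtr = fit_osc(Xtr, ytr, n_components=osc_components)
            Xte = osc.apply(Xte)
        preds[test] = _pls_predictions_per_lv(Xtr, ytr, Xte, max_lv)
    rmses = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return int(np.argmin(rmses) + 1)


# ---------------------------------------------------------------------------
# Regression-vector interpretation
# ---------------------------------------------------------------------------

def regression_vector_peaks(model, wavelength_window=(1300.0, 1600.0),
                            min_prominence: float = 0.0, grid=None):
    """Local extrema of |b(lambda)| inside the window, sorted by magnitude.

    Returns a list of ``(wavelength_nm, sign)`` tuples; ``sign`` is the sign
    of b at the extremum.  The model must carry a wavelength grid (or one is
    passed explicitly).
    """
    if grid is None:
        grid = getattr(model, "grid", None)
    if grid is None:
        raise ValueError("no wavelength grid available for peak localization")
    grid = np.asarray(grid, dtype=float)
    b = model.b if isinstance(model, PLSModel) else np.asarray(model).ravel()
    if b.size != grid.size:
        raise ValueError("regression vector and grid length differ")
    lo, hi = wavelength_window
    if lo < grid[0] or hi > grid[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] nm outside grid [{grid[0]}, {grid[-1]}] nm"
        )
    sel = (grid >= lo) & (grid <= hi)
    w = grid[sel]
    mag = np.abs(b[sel])
    idx, props = find_peaks(mag, prominence=min_prominence if min_prominence > 0 else None)
    peaks = [(float(w[i]), int(np.sign(b[sel][i]))) for i in idx]
    peaks.sort(key=lambda t: -mag[np.argmin(np.abs(w - t[0]))])
    return peaks
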
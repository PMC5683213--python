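"""Latent-variable models: PCA and NIPALS PLS1, with calibration metrics.

Both decompositions are implemented here directly (mean-centred, no
variance scaling — standard for spectra) so that every numerical choice is
explicit and reproducible: component signs are fixed deterministically and
results are identical across runs.

PLS1 (single response) admits a non-iterative NIPALS form: for each
component the X-weight vector is the normalised covariance ``X' y``, scores
are ``t = X w``, X is deflated by its rank-one reconstruction ``t p'``.
The regression vector on the original (centred) variable scale is
``b = W (P' W)^{-1} q``, so predictions are ``y_mean + (X - x_mean) b``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_RANK_RTOL = 1e-9


@dataclass
class PCAModel:
    """Mean-centred principal component decomposition of a spectra matrix."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_components, p), rows unit-norm, orthogonal
    scores: np.ndarray  # (n, n_components)
    explained_variance_pct: np.ndarray  # of total variance, non-increasing
    singular_values: np.ndarray  # all min(n, p) singular values

    def project(self, X: np.ndarray) -> np.ndarray:
        """Scores of new spectra in the fitted component basis."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_spectrum) @ self.loadings.T


def fit_pca(X: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Fit PCA by SVD of the column-centred matrix.

    Signs are fixed so the largest-magnitude element of each loading vector
    is positive.  ``explained_variance_pct`` is relative to the total
    variance, so over all possible components it sums to 100.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("PCA undefined for a constant matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| element positive per component
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    total = float(np.sum(s**2))
    return PCAModel(
        mean_spectrum=mean,
        loadings=Vt[:n_components],
        scores=U[:, :n_components] * s[:n_components],
        explained_variance_pct=100.0 * s[:n_components] ** 2 / total,
        singular_values=s,
    )


@dataclass
class PLSRModel:
    """Fitted NIPALS PLS1 model for a single analyte."""

    n_components: int
    x_mean: np.ndarray  # (p,)
    y_mean: float
    x_weights: np.ndarray  # (p, A), unit-norm columns
    x_loadings: np.ndarray  # (p, A)
    x_scores: np.ndarray  # (n, A), mutually orthogonal columns
    y_loadings: np.ndarray  # (A,)
    grid: np.ndarray | None = None  # optional wavenumber axis of X columns
    _coef_cache: dict = field(default_factory=dict, repr=False)

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector b for the first ``n_components`` components."""
        A = self.n_components if n_components is None else n_components
        if not (1 <= A <= self.n_components):
            raise ValueError(f"n_components must be in [1, {self.n_components}]")
        if A not in self._coef_cache:
            W, P, q = self.x_weights[:, :A], self.x_loadings[:, :A], self.y_loadings[:A]
            self._coef_cache[A] = W @ np.linalg.solve(P.T @ W, q)
        return self._coef_cache[A]

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"X has {X.shape[1]} variables, model was trained on {self.x_mean.size}"
            )
        return self.y_mean + (X - self.x_mean) @ self.coefficients(n_components)


def fit_plsr(
    X: np.ndarray, y: np.ndarray, n_components: int, grid: np.ndarray | None = None
) -> PLSRModel:
    """NIPALS PLS1 with mean-centring of X and y and per-component X deflation.

    Raises if ``y`` has no variance or ``n_components`` exceeds the rank of
    the centred predictor/response covariance structure.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have incompatible shapes")
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yc = y - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    scale0 = None
    for a in range(n_components):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if scale0 is None:
            scale0 = nw
        if nw <= _RANK_RTOL * scale0 or nw == 0.0:
            raise ValueError(
                f"n_components={n_components} exceeds the effective rank "
                f"({a} informative components)"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (_RANK_RTOL * scale0) ** 2:
            raise ValueError(
                f"n_components={n_components} exceeds the effective rank "
                f"({a} informative components)"
            )
        pvec = Xd.T @ t / tt
        W[:, a], P[:, a], T[:, a] = w, pvec, t
        q[a] = float(yc @ t) / tt
        Xd = Xd - np.outer(t, pvec)
    return PLSRModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=q,
        grid=None if grid is None else np.asarray(grid, dtype=float),
    )


def predict(model: PLSRModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Functional wrapper around :meth:`PLSRModel.predict`."""
    return model.predict(X, n_components)


@dataclass
class ValidationMetrics:
    """Per-analyte calibration quality figures."""

    rmse: float  # g/L
    rmse_pct: float  # 100 * rmse / reference_scale
    r2: float  # 1 - SSE/SST (coefficient of determination)
    a_opt: int | None = None
    reference_scale: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "rmse_pct": self.rmse_pct,
            "r2": self.r2,
            "a_opt": self.a_opt,
            "reference_scale": self.reference_scale,
        }


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    reference_scale: float | None = None,
    a_opt: int | None = None,
) -> ValidationMetrics:
    """RMSE, relative RMSE and R^2 = 1 - SSE/SST of a prediction set.

    ``reference_scale`` is the denominator of the percentage convention;
    it defaults to the maximum reference value (for an 80 g/L glucose
    calibration this is effectively the initial concentration).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: y_true has zero variance")
    sse = float(np.sum((y_pred - y_true) ** 2))
    rmse = float(np.sqrt(sse / y_true.size))
    scale = float(np.max(y_true)) if reference_scale is None else float(reference_scale)
    return ValidationMetrics(
        rmse=rmse,
        rmse_pct=100.0 * rmse / scale,
        r2=1.0 - sse / sst,
        a_opt=a_opt,
        reference_scale=scale,
    )


def select_a_opt(rmsecv_by_a, tolerance: float = 0.02) -> int:
    """Parsimonious component count from a cross-validation error curve.

    Returns the smallest component count (1-based) whose RMSECV is within a
    relative ``tolerance`` of the curve minimum — i.e. the fewest components
    with an only insignificantly higher error than the best model.
    """
    curve = np.asarray(rmsecv_by_a, dtype=float)
    if curve.size == 0 or np.any(curve < 0):
        raise ValueError("rmsecv curve must be non-empty and non-negative")
    threshold = (1.0 + tolerance) * curve.min()
    return int(np.flatnonzero(curve <= threshold)[0]) + 1


def select_a_opt_one_se(rmsecv_by_a, se_by_a) -> int:
    """One-standard-error alternative: smallest A with RMSECV within one
    standard error (over CV segments) of the minimum."""
    curve = np.asarray(rmsecv_by_a, dtype=float)
    se = np.asarray(se_by_a, dtype=float)
    if curve.shape != se.shape or curve.size == 0:
        raise ValueError("curve and se must be non-empty and congruent")
    best = int(np.argmin(curve))
    threshold = curve[best] + se[best]
    return int(np.flatnonzero(curve <= threshold)[0]) + 1
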
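"""Multinomial logistic regression with elastic-net penalty (MLR-EN).

The model minimizes, over class-specific coefficients ``w_j`` and intercepts
``b_j`` (j = 1..K),

    (1/n) · NLL(w, b) + λ · P_α(w),
    P_α(w) = (1−α) · ½ · Σ w² + α · Σ |w|,

where NLL is the multinomial (softmax) negative log-likelihood and the sum in
the penalty runs over all feature coefficients (intercepts unpenalized).
α = 0 gives the ridge variant (MLR-R), α = 1 the lasso variant (MLR-L), and
λ = 0 plain MLR.

Solvers: for α > 0 and λ > 0 an accelerated proximal-gradient method (FISTA
with adaptive restart) — soft-thresholding yields exact zeros, which the
downstream frequency-based feature selection relies on.  Smooth cases (α = 0
or λ = 0) go through L-BFGS.  Features are standardized internally by
default, as is conventional for penalized GLMs; coefficients are reported on
the original scale.

(α₀, λ₀) selection follows the standard grid + cross-validation protocol: a
log-spaced λ path from λ_max (the smallest λ that zeroes every coefficient)
downward for each α in the grid, scored by mean multinomial deviance over
stratified folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from sklearn.model_selection import StratifiedKFold


class ConvergenceError(RuntimeError):
    """Solver failed to reach tolerance; carries the last objective value."""

    def __init__(self, message: str, last_objective: float):
        super().__init__(f"{message} (last objective {last_objective:.6g})")
        self.last_objective = last_objective


class DimensionError(ValueError):
    """Model and data dimensions disagree."""


@dataclass(frozen=True)
class PenaltyConfig:
    """Grid-search and solver settings for MLR-EN fitting.

    ``alpha_grid`` defaults to the six-point grid {0.05, 0.2, 0.4, 0.6, 0.8,
    0.95}; ``lambda_path_length`` log-spaced values run from λ_max down to
    ``lambda_min_ratio``·λ_max.
    """

    alpha_grid: tuple[float, ...] = (0.05, 0.2, 0.4, 0.6, 0.8, 0.95)
    lambda_path_length: int = 100
    cv_folds: int = 10
    convergence_tol: float = 1e-8
    max_iter: int = 10_000
    lambda_min_ratio: float = 1e-4
    standardize: bool = True

    def __post_init__(self) -> None:
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.lambda_path_length < 1 or self.max_iter < 1:
            raise ValueError("path length and max_iter must be positive")
        if self.convergence_tol <= 0 or not 0 < self.lambda_min_ratio < 1:
            raise ValueError("invalid tolerance or lambda_min_ratio")


@dataclass
class MlrModel:
    """A fitted MLR-EN model: p×K coefficients, K intercepts, and (α₀, λ₀)."""

    coefficients: np.ndarray  # p × K, original feature scale
    intercepts: np.ndarray  # K
    alpha0: float
    lambda0: float
    objective_value: float
    classes: np.ndarray  # label codes, ascending
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.classes = np.asarray(self.classes)
        if self.coefficients.shape[1] != self.intercepts.shape[0]:
            raise DimensionError("coefficient columns must match intercepts")
        if not np.isfinite(self.objective_value):
            raise ConvergenceError("objective not finite", self.objective_value)

    @property
    def n_features(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_classes(self) -> int:
        return self.coefficients.shape[1]


# ---------------------------------------------------------------------------
# objective pieces
# ---------------------------------------------------------------------------

def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(classes, y)
    if np.any(pos >= classes.size) or np.any(classes[pos] != y):
        raise DimensionError("labels outside the model's classes")
    return np.eye(classes.size)[pos]


def multinomial_log_likelihood(
    model: MlrModel, X: np.ndarray, y: np.ndarray
) -> float:
    """Σ_i [ (w_{y_i}ᵀ x_i + b_{y_i}) − log Σ_j exp(w_jᵀ x_i + b_j) ]  (≤ 0)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise DimensionError(
            f"X has {X.shape[-1] if X.ndim == 2 else '?'} features, "
            f"model expects {model.n_features}"
        )
    scores = X @ model.coefficients + model.intercepts
    Y = _one_hot(np.asarray(y), model.classes).astype(bool)
    return float(np.sum(scores[Y]) - np.sum(logsumexp(scores, axis=1)))


def elastic_net_penalty(coefficients: np.ndarray, alpha: float) -> float:
    """P_α(w) = (1−α)·½·Σw² + α·Σ|w| over feature coefficients only."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    W = np.asarray(coefficients, dtype=float)
    return float((1 - alpha) * 0.5 * np.sum(W**2) + alpha * np.sum(np.abs(W)))


def _nll_and_grad(W, b, X, Y):
    """Mean NLL and its gradient wrt (W, b). Y is one-hot."""
    n = X.shape[0]
    scores = X @ W + b
    lse = logsumexp(scores, axis=1)
    nll = -(np.sum(scores[Y.astype(bool)]) - np.sum(lse)) / n
    R = (softmax(scores, axis=1) - Y) / n
    return nll, X.T @ R, R.sum(axis=0)


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest λ for which all feature coefficients are zero.

    At the intercept-only optimum (class priors), the KKT threshold is
    max_{k,j} |(1/n) Σ_i x_ik (1{y_i=j} − π_j)| / max(α, 1e-3); the floor on
    α keeps the path finite for near-ridge fits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    Y = _one_hot(y, classes)
    pri = Y.mean(axis=0)
    G = X.T @ (Y - pri) / X.shape[0]
    return float(np.abs(G).max() / max(alpha, 1e-3))


# ---------------------------------------------------------------------------
# solvers (internal; operate on the given scale)
# ---------------------------------------------------------------------------

def _penalized_objective(W, b, X, Y, lam, alpha):
    nll, _, _ = _nll_and_grad(W, b, X, Y)
    return nll + lam * elastic_net_penalty(W, alpha)


def _fit_smooth(X, Y, lam, alpha, tol, max_iter, W0, b0):
    """L-BFGS on the smooth objective (α = 0 ridge or λ = 0 unpenalized)."""
    n, p = X.shape
    K = Y.shape[1]
    ridge = lam * (1 - alpha)

    def fun(theta):
        W = theta[: p * K].reshape(p, K)
        b = theta[p * K :]
        nll, gW, gb = _nll_and_grad(W, b, X, Y)
        f = nll + 0.5 * ridge * np.sum(W**2)
        g = np.concatenate([(gW + ridge * W).ravel(), gb])
        return f, g

    theta0 = np.concatenate([W0.ravel(), b0])
    res = minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": max(tol, 1e-10)},
    )
    W = res.x[: p * K].reshape(p, K)
    b = res.x[p * K :]
    return W, b, int(res.nit)


def _lipschitz(X: np.ndarray) -> float:
    """Upper bound on the softmax-NLL gradient Lipschitz constant."""
    n = X.shape[0]
    Xa = np.hstack([X, np.ones((n, 1))])
    # largest singular value via Gram matrix (cheap at these sizes)
    G = Xa.T @ Xa if Xa.shape[1] <= Xa.shape[0] else Xa @ Xa.T
    smax2 = float(np.linalg.eigvalsh(G)[-1])
    return 0.5 * smax2 / n


def _fit_fista(X, Y, lam, alpha, tol, max_iter, W0, b0, L=None):
    """FISTA with adaptive restart; prox = soft-threshold at λα/L."""
    if L is None:
        L = _lipschitz(X)
    L = L + lam * (1 - alpha)
    ridge = lam * (1 - alpha)
    W, b = W0.copy(), b0.copy()
    ZW, Zb = W.copy(), b.copy()
    t = 1.0
    thr = lam * alpha / L
    obj_prev = _penalized_objective(W, b, X, Y, lam, alpha)
    for it in range(1, max_iter + 1):
        _, gW, gb = _nll_and_grad(ZW, Zb, X, Y)
        gW = gW + ridge * ZW
        W_new = ZW - gW / L
        W_new = np.sign(W_new) * np.maximum(np.abs(W_new) - thr, 0.0)
        b_new = Zb - gb / L
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        ZW = W_new + ((t - 1.0) / t_new) * (W_new - W)
        Zb = b_new + ((t - 1.0) / t_new) * (b_new - b)
        W, b, t = W_new, b_new, t_new
        if it % 10 == 0 or it == max_iter:
            obj = _penalized_objective(W, b, X, Y, lam, alpha)
            if obj > obj_prev:  # momentum overshoot: restart
                ZW, Zb, t = W.copy(), b.copy(), 1.0
            if abs(obj_prev - obj) <= tol * max(1.0, abs(obj)):
                return W, b, it
            obj_prev = obj
    raise ConvergenceError(
        f"FISTA did not converge in {max_iter} iterations", obj_prev
    )


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd, mu, sd


def fit_mlr_en(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    config: PenaltyConfig = PenaltyConfig(),
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> MlrModel:
    """Fit MLR-EN at a fixed (α, λ); coefficients returned on the input scale.

    With ``config.standardize`` (default) the penalty applies to coefficients
    of mean-0 / sd-1 features, as in standard penalized-GLM practice, and the
    fitted coefficients are mapped back to the original scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 0.0 <= alpha <= 1.0 or lam < 0:
        raise ValueError("need alpha in [0, 1] and lambda >= 0")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes to fit")
    Y = _one_hot(y, classes)
    if config.standardize:
        Z, mu, sd = _standardize(X)
    else:
        Z, mu, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])

    K = classes.size
    if warm_start is not None:
        W0, b0 = warm_start[0].copy(), warm_start[1].copy()
    else:
        W0, b0 = np.zeros((X.shape[1], K)), np.zeros(K)

    if lam == 0.0 or alpha == 0.0:
        W, b, n_iter = _fit_smooth(
            Z, Y, lam, alpha, config.convergence_tol, config.max_iter, W0, b0
        )
    else:
        W, b, n_iter = _fit_fista(
            Z, Y, lam, alpha, config.convergence_tol, config.max_iter, W0, b0
        )

    obj = _penalized_objective(W, b, Z, Y, lam, alpha)
    W_orig = W / sd[:, None]
    b_orig = b - (mu / sd) @ W
    return MlrModel(
        coefficients=W_orig,
        intercepts=b_orig,
        alpha0=float(alpha),
        lambda0=float(lam),
        objective_value=obj,
        classes=classes,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# cross-validated (alpha0, lambda0) selection
# ---------------------------------------------------------------------------

@dataclass
class CvTable:
    """Mean CV deviance (and its standard error over folds) per (α, λ)."""

    alphas: np.ndarray  # A
    lambdas: np.ndarray  # A × L (per-alpha descending paths)
    mean_deviance: np.ndarray  # A × L
    se_deviance: np.ndarray  # A × L


def _fold_deviance(W, b, Xv, Yv):
    scores = Xv @ W + b
    logp = scores - logsumexp(scores, axis=1, keepdims=True)
    return float(-2.0 * np.mean(logp[Yv.astype(bool)]))


def select_params(
    X: np.ndarray,
    y: np.ndarray,
    config: PenaltyConfig = PenaltyConfig(),
    seed: int = 0,
    full_output: bool = False,
):
    """Pick (α₀, λ₀) minimizing mean CV multinomial deviance.

    For each α in the grid a log-spaced λ path descends from λ_max; folds are
    stratified by class and shared across the whole grid; fits are
    warm-started along each path.  Ties resolve to the largest λ, then the
    earliest α in the grid.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("parameter selection needs at least two classes")
    n_folds = int(config.cv_folds)
    if counts.min() < n_folds:
        n_folds = max(int(counts.min()), 2)
        warnings.warn(
            f"smallest class has {counts.min()} samples; "
            f"using {n_folds} stratified folds instead of {config.cv_folds}",
            stacklevel=2,
        )

    alphas = np.asarray(config.alpha_grid, dtype=float)
    L_path = config.lambda_path_length
    lam_paths = np.empty((alphas.size, L_path))
    for a_i, alpha in enumerate(alphas):
        lmax = lambda_max(X, y, alpha)
        lam_paths[a_i] = np.geomspace(lmax, lmax * config.lambda_min_ratio, L_path)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    dev = np.zeros((n_folds, alphas.size, L_path))
    for f_i, (tr, va) in enumerate(skf.split(X, y)):
        Xt, yt = X[tr], y[tr]
        if config.standardize:
            Zt, mu, sd = _standardize(Xt)
        else:
            Zt, mu, sd = Xt, np.zeros(X.shape[1]), np.ones(X.shape[1])
        Zv = (X[va] - mu) / sd
        Yt = _one_hot(yt, classes)
        Yv = _one_hot(y[va], classes)
        Lip = _lipschitz(Zt)
        for a_i, alpha in enumerate(alphas):
            W = np.zeros((X.shape[1], classes.size))
            b = np.zeros(classes.size)
            for l_i, lam in enumerate(lam_paths[a_i]):
                if lam == 0.0 or alpha == 0.0:
                    W, b, _ = _fit_smooth(
                        Zt, Yt, lam, alpha, config.convergence_tol,
                        config.max_iter, W, b,
                    )
                else:
                    W, b, _ = _fit_fista(
                        Zt, Yt, lam, alpha, config.convergence_tol,
                        config.max_iter, W, b, L=Lip,
                    )
                dev[f_i, a_i, l_i] = _fold_deviance(W, b, Zv, Yv)

    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    a_i, l_i = np.unravel_index(np.argmin(mean_dev), mean_dev.shape)
    alpha0, lambda0 = float(alphas[a_i]), float(lam_paths[a_i, l_i])
    if full_output:
        return alpha0, lambda0, CvTable(alphas, lam_paths, mean_dev, se_dev)
    return alpha0, lambda0


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_proba(model: MlrModel, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities; rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise DimensionError(
            f"X has {X.shape[-1] if X.ndim == 2 else '?'} features, "
            f"model expects {model.n_features}"
        )
    return softmax(X @ model.coefficients + model.intercepts, axis=1)


def predict_class(model: MlrModel, X: np.ndarray) -> np.ndarray:
    """Argmax class; ties resolve to the smallest class code."""
    proba = predict_proba(model, X)
    return model.classes[np.argmax(proba, axis=1)]
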
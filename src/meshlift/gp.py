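"""Gaussian-process (ordinary Kriging) regression with concentrated MLE.

Model: ``y(x) = beta + Z(x)`` where Z is a zero-mean stationary Gaussian
process with covariance ``sigma_z^2 * R(x, x')`` and the product
power-exponential correlation

    R(x, x') = prod_j exp(-theta_j |x_j - x'_j|^{p_j}),   theta_j >= 0.

The smoothness exponents are fixed at ``p_j = 2`` (infinitely differentiable
sample paths).  For a candidate theta, the trend and process variance have
closed-form maximum-likelihood estimates

    beta_hat   = (1' R^-1 y) / (1' R^-1 1)
    sigma2_hat = (y - 1 beta_hat)' R^-1 (y - 1 beta_hat) / l

and the concentrated negative log-likelihood (up to an additive constant)

    nll(theta) = (l/2) ln sigma2_hat(theta) + (1/2) ln det R(theta)

is minimized over ``log10 theta`` with the DIRECT global optimizer.  All
linear algebra goes through the Cholesky factorization ``A' A = R`` (A upper
triangular), so the log-determinant is ``2 * sum(ln diag A)`` and the
posterior mean at a new point is a vector-vector product against the cached
solve ``alpha = R^-1 (y - 1 beta_hat)``.

Because neighbouring mesh nodes produce near-duplicate feature rows, R can be
numerically ill conditioned; a small diagonal nugget is added and escalated
(x10, up to 1e-4) only if the factorization fails.

The number of correlation hyperparameters is controlled by ``mode``:
``"anisotropic"`` fits one theta per feature; ``"isotropic"`` a single shared
theta; ``"grouped"`` (the default for mesh-feature tables) ties theta within
the three semantic feature blocks — neighbour distances, neighbour solution
values, own solution value — which keeps the DIRECT search low-dimensional
even at q = 2J + 1 = 101 features.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from scipy.linalg import cho_solve, cholesky
from scipy.optimize import direct

__all__ = [
    "GPSurrogate",
    "MLEResult",
    "ConditioningError",
    "correlation",
    "concentrated_nll",
    "fit",
    "fit_surrogate",
    "predict",
    "save_model",
    "load_model",
]

DEFAULT_LOG10_BOUNDS = (-6.0, 4.0)
NUGGET_START = 1e-10
NUGGET_MAX = 1e-4
_SIGMA2_FLOOR = 1e-300


class ConditioningError(RuntimeError):
    """Cholesky failed even at the maximum nugget."""


@dataclass
class MLEResult:
    theta_hat: np.ndarray
    beta_hat: float
    sigma2_hat: float
    nll: float
    n_evaluations: int
    log10_bounds: tuple[float, float]
    mode: str
    degenerate: bool = False


@dataclass
class GPSurrogate:
    """Fitted Kriging model; everything needed for posterior prediction."""

    theta: np.ndarray          # per-feature theta (length q, expanded from groups)
    p: float                   # smoothness exponent (2.0)
    beta: float
    sigma2: float
    chol: np.ndarray | None    # upper-triangular A with A'A = R + nugget*I
    alpha: np.ndarray | None   # R^-1 (y - 1 beta)
    w_ones: np.ndarray | None  # R^-1 1 (for the trend-uncertainty term)
    one_Rinv_one: float
    X_train: np.ndarray
    y_train: np.ndarray
    nugget: float
    groups: np.ndarray | None = None
    degenerate: bool = False   # constant-y training set: constant predictor

    @property
    def q(self) -> int:
        return self.X_train.shape[1]


def _expand_theta(theta_g: np.ndarray, groups: np.ndarray | None, q: int) -> np.ndarray:
    theta_g = np.asarray(theta_g, dtype=float)
    if np.any(theta_g < 0):
        raise ValueError("theta must be non-negative")
    if groups is None:
        if theta_g.size == 1:
            return np.full(q, theta_g.reshape(-1)[0])
        if theta_g.size != q:
            raise ValueError(f"theta has {theta_g.size} entries for q={q} features")
        return theta_g
    return theta_g[np.asarray(groups)]


def correlation(
    X_a: np.ndarray, X_b: np.ndarray, theta: np.ndarray, p: float = 2.0
) -> np.ndarray:
    """Product power-exponential correlation matrix between two point sets.

    Returns the (n_a, n_b) matrix ``prod_j exp(-theta_j |Delta_j|^p)``.
    """
    X_a = np.atleast_2d(np.asarray(X_a, dtype=float))
    X_b = np.atleast_2d(np.asarray(X_b, dtype=float))
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError("feature dimensions disagree")
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 0:
        theta = np.full(X_a.shape[1], float(theta))
    if np.any(theta < 0):
        raise ValueError("theta must be non-negative")
    # accumulate feature-by-feature to keep memory at one (n_a, n_b) matrix
    S = np.zeros((X_a.shape[0], X_b.shape[0]))
    for j in range(X_a.shape[1]):
        if theta[j] == 0.0:
            continue
        S += theta[j] * np.abs(X_a[:, j, None] - X_b[None, :, j]) ** p
    return np.exp(-S)


def _group_distance_tensors(
    X_a: np.ndarray, X_b: np.ndarray, groups: np.ndarray, p: float
) -> np.ndarray:
    """Stack of per-group summed |Delta|^p matrices, shape (G, n_a, n_b)."""
    from scipy.spatial.distance import cdist

    G = int(np.max(groups)) + 1
    out = np.zeros((G, X_a.shape[0], X_b.shape[0]))
    for g in range(G):
        cols = np.flatnonzero(groups == g)
        if p == 2.0:
            out[g] = cdist(X_a[:, cols], X_b[:, cols], metric="sqeuclidean")
        else:
            for j in cols:
                out[g] += np.abs(X_a[:, j, None] - X_b[None, :, j]) ** p
    return out


def _chol_with_nugget(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Upper Cholesky factor of R + nugget*I, escalating the nugget on failure."""
    nugget = NUGGET_START * float(np.mean(np.diag(R)))
    while True:
        try:
            A = cholesky(R + nugget * np.eye(R.shape[0]), lower=False)
            return A, nugget
        except np.linalg.LinAlgError:
            nugget *= 10.0
            if nugget > NUGGET_MAX:
                raise ConditioningError(
                    f"correlation matrix not factorizable below nugget {NUGGET_MAX}"
                )


def _profile(R: np.ndarray, y: np.ndarray):
    """Cholesky factor, nugget, beta_hat, sigma2_hat, log det, residual solve."""
    A, nugget = _chol_with_nugget(R)
    l = y.size
    ones = np.ones(l)
    Rinv_y = cho_solve((A, False), y)
    Rinv_1 = cho_solve((A, False), ones)
    one_R_one = float(ones @ Rinv_1)
    beta = float(ones @ Rinv_y) / one_R_one
    resid = y - beta
    Rinv_resid = Rinv_y - beta * Rinv_1
    sigma2 = float(resid @ Rinv_resid) / l
    logdet = 2.0 * float(np.sum(np.log(np.diag(A))))
    return A, nugget, beta, sigma2, logdet, Rinv_resid, Rinv_1, one_R_one


def concentrated_nll(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    p: float = 2.0,
    groups: np.ndarray | None = None,
) -> float:
    """Concentrated negative log-likelihood at theta (grouped or full)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    th = _expand_theta(np.asarray(theta, dtype=float), groups, X.shape[1])
    R = correlation(X, X, th, p)
    _, _, _, sigma2, logdet, *_ = _profile(R, y)
    l = y.size
    return 0.5 * l * np.log(max(sigma2, _SIGMA2_FLOOR)) + 0.5 * logdet


def _make_objective(X: np.ndarray, y: np.ndarray, groups: np.ndarray | None, p: float):
    """Fast concentrated-nll closure using precomputed group distance tensors."""
    if groups is None:
        groups_eff = np.arange(X.shape[1])
    else:
        groups_eff = np.asarray(groups)
    D = _group_distance_tensors(X, X, groups_eff, p)
    l = y.size

    def objective(z: np.ndarray) -> float:
        theta_g = 10.0 ** np.asarray(z, dtype=float)
        R = np.exp(-np.einsum("g,gab->ab", theta_g, D))
        try:
            _, _, _, sigma2, logdet, *_ = _profile(R, y)
        except ConditioningError:
            return 1e30
        return 0.5 * l * np.log(max(sigma2, _SIGMA2_FLOOR)) + 0.5 * logdet

    return objective, groups_eff


def fit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    mode: str = "anisotropic",
    groups: np.ndarray | None = None,
    log10_bounds: tuple[float, float] = DEFAULT_LOG10_BOUNDS,
    budget: int = 2000,
    p: float = 2.0,
) -> tuple[GPSurrogate, MLEResult]:
    """Fit the Kriging model by DIRECT minimization of the concentrated nll.

    ``mode`` is ``"anisotropic"`` (theta per feature), ``"isotropic"`` (one
    shared theta) or ``"grouped"`` (theta tied within the blocks given by
    ``groups``).  DIRECT searches over ``log10 theta`` inside
    ``log10_bounds`` per dimension with at most ``budget`` objective
    evaluations; the search is derivative-free and deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if X.shape[0] != y.size:
        raise ValueError("X and y are misaligned")
    lo, hi = log10_bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("log10 bounds must be finite with lo < hi")
    q = X.shape[1]

    if mode == "anisotropic":
        groups_eff = np.arange(q)
    elif mode == "isotropic":
        groups_eff = np.zeros(q, dtype=int)
    elif mode == "grouped":
        if groups is None:
            raise ValueError("mode='grouped' requires feature group labels")
        groups_eff = np.asarray(groups)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if np.ptp(y) == 0.0:
        # constant target: degenerate zero-variance constant predictor
        theta_full = np.zeros(q)
        model = GPSurrogate(
            theta=theta_full, p=p, beta=float(y[0]), sigma2=0.0, chol=None,
            alpha=None, w_ones=None, one_Rinv_one=float(y.size),
            X_train=X, y_train=y, nugget=0.0, groups=groups_eff, degenerate=True,
        )
        res = MLEResult(
            theta_hat=theta_full, beta_hat=float(y[0]), sigma2_hat=0.0,
            nll=-np.inf, n_evaluations=0, log10_bounds=log10_bounds,
            mode=mode, degenerate=True,
        )
        return model, res

    objective, groups_eff = _make_objective(X, y, groups_eff, p)
    n_dim = int(np.max(groups_eff)) + 1
    bounds = [(lo, hi)] * n_dim
    opt = direct(
        lambda z: objective(z), bounds, maxfun=budget, maxiter=100000, len_tol=1e-8
    )
    if not np.isfinite(opt.fun):
        raise RuntimeError("DIRECT failed: objective is not finite anywhere sampled")
    theta_g = 10.0 ** np.asarray(opt.x)
    theta_full = theta_g[groups_eff]

    R = correlation(X, X, theta_full, p)
    A, nugget, beta, sigma2, logdet, alpha, Rinv_1, one_R_one = _profile(R, y)
    model = GPSurrogate(
        theta=theta_full, p=p, beta=beta, sigma2=sigma2, chol=A, alpha=alpha,
        w_ones=Rinv_1, one_Rinv_one=one_R_one, X_train=X, y_train=y,
        nugget=nugget, groups=groups_eff,
    )
    res = MLEResult(
        theta_hat=theta_g, beta_hat=beta, sigma2_hat=sigma2, nll=float(opt.fun),
        n_evaluations=int(opt.nfev), log10_bounds=log10_bounds, mode=mode,
    )
    return model, res


def surrogate_from_theta(
    X: np.ndarray,
    y: np.ndarray,
    theta: np.ndarray,
    *,
    groups: np.ndarray | None = None,
    p: float = 2.0,
) -> GPSurrogate:
    """Build a surrogate at fixed hyperparameters (no optimization): beta and
    sigma2 take their closed-form values at the given theta."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    theta_full = _expand_theta(np.asarray(theta, dtype=float), groups, X.shape[1])
    R = correlation(X, X, theta_full, p)
    A, nugget, beta, sigma2, _, alpha, Rinv_1, one_R_one = _profile(R, y)
    return GPSurrogate(
        theta=theta_full, p=p, beta=beta, sigma2=sigma2, chol=A, alpha=alpha,
        w_ones=Rinv_1, one_Rinv_one=one_R_one, X_train=X, y_train=y,
        nugget=nugget, groups=groups,
    )


def fit_surrogate(train, **kwargs) -> tuple[GPSurrogate, MLEResult]:
    """Fit from a :class:`meshlift.features.TrainingSet` with grouped theta
    (distances / neighbour solutions / own solution) by default."""
    kwargs.setdefault("mode", "grouped")
    if kwargs["mode"] == "grouped":
        kwargs.setdefault("groups", train.feature_groups())
    return fit(train.X, train.y, **kwargs)


def predict(
    model: GPSurrogate, X_new: np.ndarray, return_var: bool = True
):
    """Posterior mean (and variance) of the fitted GP at new points.

    mean = beta + r' R^-1 (y - 1 beta)
    var  = sigma2 * (1 - r' R^-1 r + (1 - 1' R^-1 r)^2 / (1' R^-1 1))
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.q:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} != training dimension {model.q}"
        )
    if model.degenerate:
        mean = np.full(X_new.shape[0], model.beta)
        if return_var:
            return mean, np.zeros(X_new.shape[0])
        return mean
    r = correlation(X_new, model.X_train, model.theta, model.p)  # (m, l)
    mean = model.beta + r @ model.alpha
    if not return_var:
        return mean
    Rinv_rT = cho_solve((model.chol, False), r.T)  # (l, m)
    quad = np.einsum("ml,lm->m", r, Rinv_rT)
    trend = (1.0 - r @ model.w_ones) ** 2 / model.one_Rinv_one
    var = model.sigma2 * (1.0 - quad + trend)
    var = np.where(var > -1e-12 * max(model.sigma2, 1.0), np.maximum(var, 0.0), var)
    if np.any(var < 0):
        raise FloatingPointError("posterior variance significantly negative")
    return mean, var


def save_model(model: GPSurrogate, path: str) -> None:
    """Serialize to HDF5: arrays as datasets, scalars in a JSON header attr."""
    import h5py

    header = {
        "p": model.p,
        "beta": model.beta,
        "sigma2": model.sigma2,
        "nugget": model.nugget,
        "one_Rinv_one": model.one_Rinv_one,
        "degenerate": model.degenerate,
    }
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(header, sort_keys=True)
        f.create_dataset("theta", data=model.theta)
        f.create_dataset("X_train", data=model.X_train)
        f.create_dataset("y_train", data=model.y_train)
        if model.groups is not None:
            f.create_dataset("groups", data=model.groups)
        if not model.degenerate:
            f.create_dataset("chol", data=model.chol)
            f.create_dataset("alpha", data=model.alpha)
            f.create_dataset("w_ones", data=model.w_ones)


def load_model(path: str) -> GPSurrogate:
    import h5py

    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        degenerate = bool(header["degenerate"])
        return GPSurrogate(
            theta=f["theta"][()],
            p=float(header["p"]),
            beta=float(header["beta"]),
            sigma2=float(header["sigma2"]),
            chol=f["chol"][()] if not degenerate else None,
            alpha=f["alpha"][()] if not degenerate else None,
            w_ones=f["w_ones"][()] if not degenerate else None,
            one_Rinv_one=float(header["one_Rinv_one"]),
            X_train=f["X_train"][()],
            y_train=f["y_train"][()],
            nugget=float(header["nugget"]),
            groups=f["groups"][()] if "groups" in f else None,
            degenerate=degenerate,
        )
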
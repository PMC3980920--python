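"""Reference one-class classifiers under a common fit/score/threshold
contract.

Five standard methods are provided for comparison against the typicality
test: a single Gaussian, a mixture of Gaussians fitted by EM, Parzen and
naive Parzen kernel density estimates, and the support vector data
description (SVDD). All scores are oriented so that LARGER means MORE
ATYPICAL (negative log density for the density methods, squared distance
to a center for the geometric ones), which lets the ROC machinery treat
every method identically. The decision threshold is set on the training
scores so that a fraction ``alpha`` of training units is rejected.

These methods require all-continuous data without missing values; on
mixed tables they raise, and on degenerate fits (EM collapse, underflowed
densities in the p >> n regime) they raise :class:`FitFailed`, which the
benchmark harness records as a missing (NaN) result rather than a crash.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .data import FeatureTable
from .exceptions import DataError, FitFailed

LOG2PI = float(np.log(2.0 * np.pi))


def set_threshold(model: "OCCModel", train_scores: np.ndarray,
                  alpha: float) -> "OCCModel":
    """Set the rejection threshold to the (1 - alpha) higher-interpolation
    quantile of the training scores (alpha = 0 keeps every training unit;
    rejection is strict exceedance)."""
    s = np.asarray(train_scores, dtype=float)
    if not np.isfinite(s).all():
        raise FitFailed(model.method, "non-finite training scores")
    model.train_scores_ = s
    if alpha <= 0:
        model.threshold_ = float(np.max(s))
    elif alpha >= 1:
        model.threshold_ = float(np.min(s)) - 1.0
    else:
        model.threshold_ = float(np.quantile(s, 1.0 - alpha, method="higher"))
    return model


class OCCModel:
    """Base contract: ``score`` (larger = more atypical), ``predict``."""

    method: str = "occ"
    threshold_: float

    def _score_matrix(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def score(self, table: FeatureTable) -> np.ndarray:
        return self._score_matrix(table.numeric())

    def predict(self, table: FeatureTable) -> np.ndarray:
        s = self.score(table)
        return np.where(s > self.threshold_, "nontarget", "target")


# ---------------------------------------------------------------------------
# Gaussian
# ---------------------------------------------------------------------------

class GaussianOCC(OCCModel):
    """Single Gaussian; score = squared Mahalanobis distance to the ML
    mean, with the same ridge-regularized covariance inverse used by the
    Mahalanobis distance."""

    method = "gauss"

    def __init__(self, mean: np.ndarray, inv_cov: np.ndarray):
        self.mean = mean
        self.inv_cov = inv_cov

    def _score_matrix(self, x):
        d = x - self.mean
        return np.einsum("ij,jk,ik->i", d, self.inv_cov, d)


def fit_gaussian(train_table: FeatureTable, alpha: float = 0.1,
                 ridge: float = 1e-6) -> GaussianOCC:
    from .distances import DistanceSpec, fit_distance

    x = train_table.numeric()
    fitted = fit_distance(train_table, DistanceSpec("mahalanobis", ridge=ridge))
    model = GaussianOCC(x.mean(axis=0), fitted.inv_cov)
    return set_threshold(model, model._score_matrix(x), alpha)


# ---------------------------------------------------------------------------
# mixture of Gaussians (EM)
# ---------------------------------------------------------------------------

class MixtureOCC(OCCModel):
    """Gaussian mixture fitted by EM; score = negative log density.

    Diagonal covariances by default (robust in small samples); full
    covariance behind ``covariance="full"``. ``loglik_trace_`` records the
    per-iteration training log-likelihood of the winning restart and is
    nondecreasing, the defining property of EM.
    """

    method = "mog"

    def __init__(self, weights, means, variances, covariance="diag",
                 loglik_trace=None):
        self.weights = np.asarray(weights, float)
        self.means = np.asarray(means, float)
        self.variances = np.asarray(variances, float)
        self.covariance = covariance
        self.loglik_trace_ = (np.asarray(loglik_trace, float)
                              if loglik_trace is not None else None)

    def _log_component(self, x):
        k = self.means.shape[0]
        n, p = x.shape
        out = np.empty((n, k))
        for c in range(k):
            d = x - self.means[c]
            if self.covariance == "diag":
                var = self.variances[c]
                out[:, c] = -0.5 * (p * LOG2PI + np.log(var).sum()
                                    + (d * d / var).sum(axis=1))
            else:
                sign, logdet = np.linalg.slogdet(self.variances[c])
                vi = np.linalg.inv(self.variances[c])
                out[:, c] = -0.5 * (p * LOG2PI + logdet
                                    + np.einsum("ij,jk,ik->i", d, vi, d))
        return out

    def log_density(self, x):
        return logsumexp(self._log_component(x) + np.log(self.weights), axis=1)

    def _score_matrix(self, x):
        return -self.log_density(x)


def _em_once(x, k, rng, covariance, max_iter, tol, var_floor):
    n, p = x.shape
    means = x[rng.choice(n, size=k, replace=False)].astype(float)
    base_var = x.var(axis=0, ddof=0) + var_floor
    if covariance == "diag":
        variances = np.tile(base_var, (k, 1))
    else:
        variances = np.tile(np.diag(base_var), (k, 1, 1))
    weights = np.full(k, 1.0 / k)
    model = MixtureOCC(weights, means, variances, covariance)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        log_r = model._log_component(x) + np.log(model.weights)
        norm = logsumexp(log_r, axis=1)
        ll = float(norm.mean())
        trace.append(ll)
        r = np.exp(log_r - norm[:, None])          # responsibilities
        nk = r.sum(axis=0) + 1e-300
        weights = nk / n
        means = (r.T @ x) / nk[:, None]
        if covariance == "diag":
            variances = np.empty((k, p))
            for c in range(k):
                d = x - means[c]
                variances[c] = (r[:, c][:, None] * d * d).sum(axis=0) / nk[c]
            variances = np.maximum(variances, var_floor)
        else:
            variances = np.empty((k, p, p))
            for c in range(k):
                d = x - means[c]
                cov = (r[:, c][:, None] * d).T @ d / nk[c]
                variances[c] = cov + var_floor * np.eye(p)
        model = MixtureOCC(weights, means, variances, covariance)
        if ll - prev < tol * max(1.0, abs(ll)):
            break
        prev = ll
    model.loglik_trace_ = np.asarray(trace)
    return model, trace[-1] if trace else -np.inf


def fit_mog(train_table: FeatureTable, n_components: int = 2,
            alpha: float = 0.1, seed: int | None = None,
            covariance: str = "diag", n_restarts: int = 5,
            max_iter: int = 300, tol: float = 1e-8) -> MixtureOCC:
    """EM-fitted Gaussian mixture; best log-likelihood over restarts kept."""
    x = train_table.numeric()
    n, p = x.shape
    if n_components > n:
        raise DataError(f"n_components={n_components} exceeds n={n}")
    if covariance == "full" and p >= n:
        raise FitFailed("mog", f"full covariance unidentifiable for p={p} >= n={n}")
    var_floor = 1e-8 * float(x.var(axis=0, ddof=0).mean() + 1e-12)
    rng = np.random.default_rng(seed)
    best, best_ll = None, -np.inf
    for _ in range(n_restarts):
        try:
            model, ll = _em_once(x, n_components, rng, covariance,
                                 max_iter, tol, var_floor)
        except np.linalg.LinAlgError:
            continue
        if np.isfinite(ll) and ll > best_ll:
            best, best_ll = model, ll
    if best is None or not np.isfinite(best_ll):
        raise FitFailed("mog", "EM failed to converge on any restart")
    return set_threshold(best, best._score_matrix(x), alpha)


# ---------------------------------------------------------------------------
# Parzen / naive Parzen
# ---------------------------------------------------------------------------

class ParzenOCC(OCCModel):
    """Gaussian-kernel density estimate with a single smoothing width h;
    score = negative log density."""

    method = "parzen"

    def __init__(self, train_x: np.ndarray, h: float):
        self.train_x = train_x
        self.h = float(h)

    def log_density(self, x):
        n, p = self.train_x.shape
        d2 = cdist(x, self.train_x, "sqeuclidean")
        return logsumexp(-0.5 * d2 / self.h ** 2, axis=1) \
            - np.log(n) - p * np.log(self.h) - 0.5 * p * LOG2PI

    def _score_matrix(self, x):
        return -self.log_density(x)


class NaiveParzenOCC(OCCModel):
    """Product of per-feature 1-D kernel density estimates, each with its
    own width h_j; score = negative log density."""

    method = "naive_parzen"

    def __init__(self, train_x: np.ndarray, h_vec: np.ndarray):
        self.train_x = train_x
        self.h_vec = np.asarray(h_vec, float)

    def log_density(self, x):
        n, p = self.train_x.shape
        out = np.zeros(x.shape[0])
        for j in range(p):
            d2 = (x[:, j][:, None] - self.train_x[None, :, j]) ** 2
            out += logsumexp(-0.5 * d2 / self.h_vec[j] ** 2, axis=1) \
                - np.log(n) - np.log(self.h_vec[j]) - 0.5 * LOG2PI
        return out

    def _score_matrix(self, x):
        return -self.log_density(x)


def _loo_bandwidth(d2: np.ndarray, p: int, grid: np.ndarray) -> float:
    """Pick h maximizing the leave-one-out log-likelihood on a grid, given
    the training squared-distance matrix."""
    n = d2.shape[0]
    off = d2 + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    best_h, best_ll = grid[0], -np.inf
    for h in grid:
        ll = float(np.mean(logsumexp(-0.5 * off / h ** 2, axis=1)
                           - np.log(n - 1) - p * np.log(h) - 0.5 * p * LOG2PI))
        if ll > best_ll:
            best_h, best_ll = h, ll
    return float(best_h)


def _bandwidth_grid(d2: np.ndarray) -> np.ndarray:
    pos = d2[d2 > 0]
    if pos.size == 0:
        return np.array([1.0])
    med = float(np.sqrt(np.median(pos)))
    return np.geomspace(med / 30.0, med * 10.0, 25)


def fit_parzen(train_table: FeatureTable, h: float | None = None,
               alpha: float = 0.1) -> ParzenOCC:
    """Joint Parzen window; h defaults to the leave-one-out maximum
    likelihood value over a log-spaced grid around the median pairwise
    distance."""
    x = train_table.numeric()
    if x.shape[0] < 2 and h is None:
        raise FitFailed("parzen", "cannot select h from a single unit")
    if h is None:
        d2 = cdist(x, x, "sqeuclidean")
        h = _loo_bandwidth(d2, x.shape[1], _bandwidth_grid(d2))
    if h <= 0:
        raise DataError("h must be positive")
    model = ParzenOCC(x, h)
    return set_threshold(model, model._score_matrix(x), alpha)


def fit_naive_parzen(train_table: FeatureTable,
                     h_vec: np.ndarray | None = None,
                     alpha: float = 0.1) -> NaiveParzenOCC:
    """Per-feature product Parzen; each h_j selected by 1-D leave-one-out
    likelihood when not given."""
    x = train_table.numeric()
    n, p = x.shape
    if h_vec is None:
        if n < 2:
            raise FitFailed("naive_parzen", "cannot select h from a single unit")
        h_vec = np.empty(p)
        for j in range(p):
            d2 = (x[:, j][:, None] - x[None, :, j]) ** 2
            grid = _bandwidth_grid(d2)
            h_vec[j] = _loo_bandwidth(d2, 1, grid)
    h_vec = np.asarray(h_vec, float)
    if (h_vec <= 0).any():
        raise DataError("all h_j must be positive")
    model = NaiveParzenOCC(x, h_vec)
    return set_threshold(model, model._score_matrix(x), alpha)


# ---------------------------------------------------------------------------
# SVDD
# ---------------------------------------------------------------------------

class SVDDOCC(OCCModel):
    """Support vector data description: the minimum-volume hypersphere
    around the training data in (kernel) feature space.

    The dual is the box-constrained QP

        max_a  sum_i a_i K_ii - sum_ij a_i a_j K_ij
        s.t.   0 <= a_i <= C,  sum_i a_i = 1,

    solved here by SLSQP with the analytic gradient. The score of a new
    unit is its squared kernel distance to the sphere center,
    ``K(y,y) - 2 sum_i a_i K(y, x_i) + a' K a``.
    """

    method = "svdd"

    def __init__(self, train_x, alphas, kernel, gamma, C):
        self.train_x = train_x
        self.alphas = np.asarray(alphas, float)
        self.kernel = kernel
        self.gamma = gamma
        self.C = C
        k_train = self._k(train_x, train_x)
        self._aka = float(self.alphas @ k_train @ self.alphas)

    def _k(self, a, b):
        if self.kernel == "linear":
            return a @ b.T
        return np.exp(-self.gamma * cdist(a, b, "sqeuclidean"))

    @property
    def center(self) -> np.ndarray:
        """Sphere center in input space (meaningful for the linear kernel)."""
        return self.alphas @ self.train_x

    def _score_matrix(self, x):
        k_new = self._k(x, self.train_x)
        if self.kernel == "linear":
            k_self = np.einsum("ij,ij->i", x, x)
        else:
            k_self = np.ones(x.shape[0])
        return k_self - 2.0 * k_new @ self.alphas + self._aka


def fit_svdd(train_table: FeatureTable, kernel_width: float | None = None,
             C_reg: float = 1.0, alpha: float = 0.1,
             kernel: str = "rbf") -> SVDDOCC:
    """Solve the SVDD dual.

    ``kernel_width`` is the RBF sigma; by default the median heuristic on
    the training pairwise distances (gamma = 1 / (2 sigma^2)). ``C_reg``
    below 1/n makes the box infeasible and raises.
    """
    x = train_table.numeric()
    n = x.shape[0]
    if C_reg < 1.0 / n:
        raise DataError(f"C_reg={C_reg} < 1/n={1.0 / n:.3g}: infeasible box")
    if kernel == "rbf":
        d2 = cdist(x, x, "sqeuclidean")
        if kernel_width is None:
            pos = d2[d2 > 0]
            kernel_width = float(np.sqrt(np.median(pos))) if pos.size else 1.0
        gamma = 1.0 / (2.0 * kernel_width ** 2)
        K = np.exp(-gamma * d2)
    elif kernel == "linear":
        gamma = None
        K = x @ x.T
    else:
        raise DataError(f"unknown kernel {kernel!r}")

    diag = np.diag(K).copy()

    def neg_dual(a):
        return float(a @ K @ a - diag @ a)

    def grad(a):
        return 2.0 * K @ a - diag

    a0 = np.full(n, 1.0 / n)
    res = minimize(
        neg_dual, a0, jac=grad, method="SLSQP",
        bounds=[(0.0, C_reg)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0,
                      "jac": lambda a: np.ones(n)}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    a = np.clip(res.x, 0.0, C_reg)
    a /= a.sum()
    if not np.isfinite(a).all():
        raise FitFailed("svdd", "QP solver returned non-finite multipliers")
    model = SVDDOCC(x, a, kernel, gamma, C_reg)
    return set_threshold(model, model._score_matrix(x), alpha)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _fit_typicality_occ(train_table, alpha=0.1, seed=None,
                        distance="euclidean", n_boot=1000):
    """Adapter putting the typicality test under the OCC contract: score =
    proximity, threshold from the bootstrap null."""
    from .model import OneClassTypicality

    res = OneClassTypicality(train_table, distance).fit(
        alpha=alpha, n_boot=n_boot, seed=seed)

    class _TypicalityOCC(OCCModel):
        method = "typicality"

        def __init__(self, results):
            self.results = results
            self.threshold_ = results.threshold
            self.train_scores_ = results.boot_phi2  # calibration = bootstrap null

        def score(self, table):
            return self.results.phi2(table)

    return _TypicalityOCC(res)


METHODS = {
    "gauss": fit_gaussian,
    "mog": fit_mog,
    "parzen": fit_parzen,
    "naive_parzen": fit_naive_parzen,
    "svdd": fit_svdd,
    "typicality": _fit_typicality_occ,
}


def fit_method(name: str, train_table: FeatureTable, alpha: float = 0.1,
               seed: int | None = None, **kwargs) -> OCCModel:
    """Fit a registered method by name; seeds only reach the stochastic
    fitters (EM restarts, bootstrap)."""
    if name not in METHODS:
        raise DataError(f"unknown method {name!r}; registry: {sorted(METHODS)}")
    fn = METHODS[name]
    if name in ("mog", "typicality"):
        return fn(train_table, alpha=alpha, seed=seed, **kwargs)
    return fn(train_table, alpha=alpha, **kwargs)
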
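"""Squared-distance functions between units.

Five built-in squared distances, all Euclidean-embeddable (there is a map
Psi into some R^q with delta^2(u, v) = ||Psi(u) - Psi(v)||^2), which is what
guarantees nonnegativity of the geometric variability and, up to sampling
noise, of the proximity function:

- ``euclidean``        sum_k (u_k - v_k)^2
- ``euclidean_std``    squared Euclidean after z-scoring with TRAINING
                       mean/sd per column
- ``mahalanobis``      (u-v)' Sigma_reg^{-1} (u-v), Sigma from the training
                       class with a small ridge (pseudo-inverse fallback
                       when p >= n)
- ``correlation``      2 (1 - r(u, v)), r the Pearson correlation across
                       the p features of the two unit profiles; equals the
                       squared Euclidean distance between z-scored profiles
                       divided by p, so it is Euclidean-embeddable
- ``gower``            1 - s(u, v) with Gower's general similarity
                       coefficient: range-scaled absolute difference for
                       continuous columns, rank-scale for ordinal columns,
                       match/mismatch for binary and nominal columns, and
                       zero weight for any comparison involving a missing
                       value. The only built-in that accepts mixed types
                       and missing cells.

A distance is *fitted* on the training half of the target class only: all
frozen statistics (means, sds, ranges, covariance) come from it and never
change when new units are scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .data import CATEGORICAL_TYPES, FeatureTable, NUMERIC_TYPES
from .exceptions import DataError, IncomparablePairError

log = logging.getLogger(__name__)

DISTANCE_NAMES = ("euclidean", "euclidean_std", "mahalanobis", "correlation",
                  "gower")


@dataclass
class DistanceSpec:
    """A named squared-distance recipe.

    ``ridge`` is the Mahalanobis regularization factor: the covariance is
    replaced by ``Sigma + ridge * mean(diag Sigma) * I``.
    """

    name: str = "euclidean"
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.name not in DISTANCE_NAMES:
            raise DataError(
                f"unknown distance {self.name!r}; choose from {DISTANCE_NAMES}"
            )


@dataclass
class DistanceMatrix:
    """An ``n x m`` grid of squared distances."""

    values: np.ndarray
    square: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < -1e-10).any():
            raise DataError("negative squared distance")
        self.values = np.maximum(v, 0.0)
        if self.square:
            if v.shape[0] != v.shape[1]:
                raise DataError("square matrix expected")
            if not np.allclose(v, v.T, atol=1e-10):
                raise DataError("square distance matrix is not symmetric")
            np.fill_diagonal(self.values, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# scalar kernels
# ---------------------------------------------------------------------------

def sq_euclidean(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    d = u - v
    return float(d @ d)


def sq_euclidean_std(u, v, mean, sd) -> float:
    """Squared Euclidean on ``(x - mean)/sd`` coordinates.

    Columns with zero training sd contribute 0 (their standardized
    coordinate is defined as 0 for every unit).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    ok = sd > 0
    su = np.where(ok, (np.asarray(u, float) - mean) / np.where(ok, sd, 1.0), 0.0)
    sv = np.where(ok, (np.asarray(v, float) - mean) / np.where(ok, sd, 1.0), 0.0)
    return sq_euclidean(su, sv)


def sq_mahalanobis(u, v, inv_cov) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    inv_cov = np.asarray(inv_cov, dtype=float)
    if u.shape != v.shape or inv_cov.shape != (u.size, u.size):
        raise DataError("dimension mismatch in Mahalanobis distance")
    d = u - v
    return float(d @ inv_cov @ d)


def sq_correlation(u, v) -> float:
    """``2 (1 - r)`` with r the Pearson correlation of the two profiles."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt(du @ du)
    nv = np.sqrt(dv @ dv)
    if nu == 0 or nv == 0:
        raise DataError("correlation distance undefined for a constant profile")
    r = float(du @ dv / (nu * nv))
    return 2.0 * (1.0 - min(1.0, max(-1.0, r)))


def sq_gower(u, v, u_missing, v_missing, var_types, ranges) -> float:
    """``1 - s`` with Gower's similarity.

    ``ranges`` gives the training range per column (used for numeric
    columns; ignored for categorical ones). A comparison gets weight 0 when
    either value is missing, or when a numeric column has zero range.
    """
    s_sum = 0.0
    w_sum = 0.0
    for k, tag in enumerate(var_types):
        if u_missing[k] or v_missing[k]:
            continue
        if tag in NUMERIC_TYPES:
            if ranges[k] <= 0:
                continue
            diff = abs(float(u[k]) - float(v[k]))
            s_sum += 1.0 - min(diff / ranges[k], 1.0)
        else:
            s_sum += 1.0 if u[k] == v[k] else 0.0
        w_sum += 1.0
    if w_sum == 0:
        raise IncomparablePairError("pair of units shares no observed feature")
    return 1.0 - s_sum / w_sum


# ---------------------------------------------------------------------------
# fitted distances
# ---------------------------------------------------------------------------

class FittedDistance:
    """A distance with its training statistics frozen.

    Subclasses implement :meth:`_matrix` on float blocks; the public
    :meth:`pairwise` / :meth:`cross` work on :class:`FeatureTable` objects.
    """

    spec: DistanceSpec

    def _prepare(self, table: FeatureTable) -> np.ndarray:
        return table.numeric()

    def _matrix(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def pairwise(self, table: FeatureTable) -> DistanceMatrix:
        x = self._prepare(table)
        d = self._matrix(x, x)
        d = (d + d.T) / 2.0
        return DistanceMatrix(d, square=True)

    def cross(self, train_table: FeatureTable, new_table: FeatureTable
              ) -> DistanceMatrix:
        a = self._prepare(train_table)
        b = self._prepare(new_table)
        return DistanceMatrix(self._matrix(a, b), square=False)

    def params(self) -> dict:
        """JSON-serializable frozen parameters."""
        return {}


class EuclideanDistance(FittedDistance):
    def __init__(self, spec: DistanceSpec):
        self.spec = spec

    def _matrix(self, a, b):
        return cdist(a, b, "sqeuclidean")


class StandardizedEuclidean(FittedDistance):
    def __init__(self, spec: DistanceSpec, mean: np.ndarray, sd: np.ndarray):
        self.spec = spec
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        if (self.sd == 0).any():
            warnings.warn(
                "zero-variance training column(s) under euclidean_std; "
                "their standardized coordinate is 0 for all units",
                stacklevel=2,
            )

    def _standardize(self, x):
        ok = self.sd > 0
        z = np.zeros_like(x, dtype=float)
        z[:, ok] = (x[:, ok] - self.mean[ok]) / self.sd[ok]
        return z

    def _matrix(self, a, b):
        return cdist(self._standardize(a), self._standardize(b), "sqeuclidean")

    def params(self):
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}


class MahalanobisDistance(FittedDistance):
    def __init__(self, spec: DistanceSpec, inv_cov: np.ndarray):
        self.spec = spec
        self.inv_cov = np.asarray(inv_cov, dtype=float)

    def _matrix(self, a, b):
        d = cdist(a, b, "mahalanobis", VI=self.inv_cov)
        return d ** 2

    def params(self):
        return {"inv_cov": self.inv_cov.tolist()}


class CorrelationDistance(FittedDistance):
    def __init__(self, spec: DistanceSpec):
        self.spec = spec

    def _matrix(self, a, b):
        if (a.std(axis=1) == 0).any() or (b.std(axis=1) == 0).any():
            raise DataError("correlation distance undefined for a constant profile")
        return 2.0 * np.clip(cdist(a, b, "correlation"), 0.0, 2.0)


class GowerDistance(FittedDistance):
    """Gower distance with training ranges frozen per numeric column.

    Ordinal columns are rank-transformed (Podani): training values map to
    their mid-ranks; new values are interpolated into the training rank
    scale; the range is taken on ranks.
    """

    def __init__(self, spec: DistanceSpec, table: FeatureTable):
        self.spec = spec
        self.var_types = list(table.var_types)
        self.column_names = list(table.column_names)
        num, self._num_cols, _, self._cat_cols = table.encoded()
        # rank transform for ordinal columns, on training values
        self._ord_maps: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k, j in enumerate(self._num_cols):
            if table.var_types[j] == "ordinal":
                obs = num[:, k][~np.isnan(num[:, k])]
                if obs.size:
                    uniq = np.unique(obs)
                    ranks = rankdata(obs, method="average")
                    uniq_rank = np.array(
                        [ranks[obs == u].mean() for u in uniq])
                    self._ord_maps[k] = (uniq, uniq_rank)
        num = self._transform_numeric(num)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            hi = np.nanmax(num, axis=0) if num.size else np.zeros(0)
            lo = np.nanmin(num, axis=0) if num.size else np.zeros(0)
        self.ranges = np.where(np.isnan(hi), 0.0, hi - lo)

    def _transform_numeric(self, num: np.ndarray) -> np.ndarray:
        num = num.copy()
        for k, (uniq, uniq_rank) in self._ord_maps.items():
            col = num[:, k]
            obs = ~np.isnan(col)
            num[obs, k] = np.interp(col[obs], uniq, uniq_rank)
        return num

    def _blocks(self, table: FeatureTable):
        num, num_cols, codes, cat_cols = table.encoded()
        if num_cols != self._num_cols or cat_cols != self._cat_cols:
            raise DataError("table columns incompatible with the fitted distance")
        return self._transform_numeric(num), codes

    def pairwise(self, table: FeatureTable) -> DistanceMatrix:
        num, codes = self._blocks(table)
        d = self._gower(num, codes, num, codes)
        return DistanceMatrix((d + d.T) / 2.0, square=True)

    def cross(self, train_table, new_table) -> DistanceMatrix:
        na, ca = self._blocks(train_table)
        nb, cb = self._blocks(new_table)
        return DistanceMatrix(self._gower(na, ca, nb, cb), square=False)

    def _gower(self, num_a, cat_a, num_b, cat_b) -> np.ndarray:
        na, nb = num_a.shape[0], num_b.shape[0]
        s_sum = np.zeros((na, nb))
        w_sum = np.zeros((na, nb))
        for k in range(num_a.shape[1]):
            if self.ranges[k] <= 0:
                continue
            a = num_a[:, k][:, None]
            b = num_b[:, k][None, :]
            w = (~np.isnan(a)) & (~np.isnan(b))
            with np.errstate(invalid="ignore"):
                s = 1.0 - np.minimum(np.abs(a - b) / self.ranges[k], 1.0)
            s_sum += np.where(w, s, 0.0)
            w_sum += w
        for k in range(cat_a.shape[1]):
            a = cat_a[:, k][:, None]
            b = cat_b[:, k][None, :]
            w = (a >= 0) & (b >= 0)
            s_sum += np.where(w & (a == b), 1.0, 0.0)
            w_sum += w
        if (w_sum == 0).any():
            raise IncomparablePairError(
                "some pair of units shares no observed feature")
        return 1.0 - s_sum / w_sum

    def params(self):
        return {"ranges": self.ranges.tolist(),
                "ord_maps": {str(k): [u.tolist(), r.tolist()]
                             for k, (u, r) in self._ord_maps.items()}}


def fit_distance(table: FeatureTable, spec: DistanceSpec | str) -> FittedDistance:
    """Freeze the training statistics of *spec* on *table*.

    Non-Gower specs require an all-numeric table with no missing cells.
    The Mahalanobis covariance uses the ridge
    ``Sigma + ridge * mean(diag Sigma) * I`` and falls back to the
    Moore-Penrose pseudo-inverse when the regularized matrix is still
    numerically singular (the p >= n regime).
    """
    if isinstance(spec, str):
        spec = DistanceSpec(spec)
    if spec.name == "gower":
        return GowerDistance(spec, table)

    x = table.numeric()
    if spec.name == "euclidean":
        return EuclideanDistance(spec)
    if spec.name == "euclidean_std":
        return StandardizedEuclidean(spec, x.mean(axis=0), x.std(axis=0, ddof=0))
    if spec.name == "correlation":
        return CorrelationDistance(spec)
    if spec.name == "mahalanobis":
        cov = np.cov(x, rowvar=False, ddof=1) if x.shape[0] > 1 else \
            np.zeros((x.shape[1], x.shape[1]))
        cov = np.atleast_2d(cov)
        scale = np.mean(np.diag(cov)) if np.mean(np.diag(cov)) > 0 else 1.0
        reg = cov + spec.ridge * scale * np.eye(cov.shape[0])
        try:
            inv = np.linalg.inv(reg)
            # reject numerically unstable inverses in the p >= n regime
            if not np.isfinite(inv).all() or \
                    np.linalg.cond(reg) > 1.0 / np.finfo(float).eps:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            log.info("Mahalanobis covariance singular; using pseudo-inverse")
            inv = np.linalg.pinv(reg)
        inv = (inv + inv.T) / 2.0
        return MahalanobisDistance(spec, inv)
    raise DataError(f"unknown distance {spec.name!r}")


def pairwise(table: FeatureTable, fitted: FittedDistance) -> DistanceMatrix:
    """Square symmetric matrix of squared distances within *table*."""
    return fitted.pairwise(table)


def cross(train_table: FeatureTable, new_table: FeatureTable,
          fitted: FittedDistance) -> DistanceMatrix:
    """``n_train x n_new`` squared distances from training to new units."""
    return fitted.cross(train_table, new_table)
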
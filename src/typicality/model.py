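"""The distance-based typicality test as a one-class classifier.

Given a target class :math:`C = \\{y_1, \\dots, y_n\\}` and a squared
distance :math:`\\delta^2`, the plug-in estimators are

.. math::

    \\hat V_\\delta(C) = \\frac{1}{2n^2} \\sum_{i,j} \\delta^2(y_i, y_j),
    \\qquad
    \\hat\\varphi^2(y_0, C) = \\frac{1}{n} \\sum_i \\delta^2(y_0, y_i)
        - \\hat V_\\delta(C),

the *geometric variability* (a distance-based dispersion, a variant of
Rao's diversity coefficient) and the *proximity function* of a new unit to
the class. For the plain squared Euclidean distance these reduce to the
biased total variance and the squared distance to the class mean — the
closed form the test suite uses as its primary oracle.

The typicality test decides H0 "y0 comes from C" against H1 "y0 comes from
another, unknown class" by referring the observed proximity to a bootstrap
sample of its null distribution: draw units from the class itself, compute
their proximities, and reject when the observed value falls in the upper
alpha tail. Because the sampling distribution of the proximity is
intractable for mixed data, the bootstrap is the generic calibration route
and works for any of the built-in distances, Gower included.

Two bootstrap modes are provided:

``leave-one-out`` (default)
    Each replicate draws one training index i (with replacement across
    replicates) and computes the proximity of y_i to the class WITHOUT
    y_i — reference distances and the geometric variability both use the
    remaining n-1 units. Including a unit in its own reference set would
    contribute a zero self-distance, deflate the proximity, shift the null
    leftward and inflate the realized false alarm rate; holding the unit
    out removes that bias.

``resample-class``
    Each replicate draws a full bootstrap class C* of size n-1 (with
    replacement from the class without the probe unit) and scores the probe
    against C*. Slower, closer to a textbook bootstrap, kept behind a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import FeatureTable
from .distances import (DistanceMatrix, DistanceSpec, FittedDistance, cross,
                        fit_distance, pairwise)
from .exceptions import DataError

BOOTSTRAP_MODES = ("leave-one-out", "resample-class")


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def geometric_variability(d_square: np.ndarray | DistanceMatrix) -> float:
    """Plug-in geometric variability of a class.

    Parameters
    ----------
    d_square : square matrix of within-class squared distances.

    Returns
    -------
    float
        ``sum_ij d2[i, j] / (2 n^2)``; 0 for a single unit.
    """
    if isinstance(d_square, DistanceMatrix):
        d_square = d_square.values
    d = np.asarray(d_square, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("geometric variability needs a square distance matrix")
    n = d.shape[0]
    return float(d.sum() / (2.0 * n * n))


def proximity(d_vec: np.ndarray, v_hat: float) -> float:
    """Proximity of a unit to the class: mean squared distance minus
    the class's geometric variability."""
    d_vec = np.asarray(d_vec, dtype=float)
    return float(d_vec.mean() - v_hat)


def _loo_phi2(d_square: np.ndarray) -> np.ndarray:
    """Leave-one-out proximity of every training unit to the class
    without itself, all in O(n^2) from the full pairwise matrix."""
    d = np.asarray(d_square, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise DataError("leave-one-out proximity needs n >= 2")
    row = d.sum(axis=1)           # includes the zero self-distance
    total = d.sum()
    mean_to_rest = row / (n - 1)
    # V on C \ {i}: drop row i and column i from the double sum
    v_loo = (total - 2.0 * row) / (2.0 * (n - 1) ** 2)
    return mean_to_rest - v_loo


def bootstrap_null(
    train_table: FeatureTable,
    fitted: FittedDistance,
    n_boot: int,
    seed: int | None = None,
    mode: str = "leave-one-out",
) -> np.ndarray:
    """Bootstrap sample of the proximity under H0.

    Draws units from the target class itself and computes their proximity
    to the class, yielding ``n_boot`` replicate values that estimate the
    null distribution of the test statistic. Reproducible under a fixed
    seed.
    """
    if mode not in BOOTSTRAP_MODES:
        raise DataError(f"unknown bootstrap mode {mode!r}")
    n = train_table.n
    if n < 2:
        raise DataError("bootstrap null needs at least 2 training units")
    if n_boot < 1:
        raise DataError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    d = pairwise(train_table, fitted).values
    if mode == "leave-one-out":
        phi2_loo = _loo_phi2(d)
        idx = rng.integers(0, n, size=n_boot)
        return phi2_loo[idx]
    # resample-class: probe i against a bootstrap class drawn from C \ {i}
    out = np.empty(n_boot)
    others = [np.delete(np.arange(n), i) for i in range(n)]
    for b in range(n_boot):
        i = int(rng.integers(0, n))
        star = rng.choice(others[i], size=n - 1, replace=True)
        sub = d[np.ix_(star, star)]
        out[b] = proximity(d[i, star], geometric_variability(sub))
    return out


def p_value(phi2_obs, boot_phi2: np.ndarray):
    """Upper-tail bootstrap p-value with add-one smoothing.

    ``p = (1 + #{b : boot[b] >= phi2_obs}) / (B + 1)``, always in (0, 1].
    Accepts a scalar or a vector of observed proximities.
    """
    boot = np.asarray(boot_phi2, dtype=float)
    obs = np.asarray(phi2_obs, dtype=float)
    if obs.ndim == 0:
        count = int((boot >= float(obs)).sum())
        return (1.0 + count) / (boot.size + 1.0)
    count = (obs[:, None] <= boot[None, :]).sum(axis=1)
    return (1.0 + count) / (boot.size + 1.0)


@dataclass
class TypicalityScore:
    """Score of one unit: proximity, bootstrap p-value and decision."""

    unit_id: str
    phi2: float
    p_value: float
    decision: str  # "target" or "nontarget"


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class OneClassTypicality:
    """One-class classifier based on the typicality test.

    Parameters
    ----------
    train_table : FeatureTable
        The target class (the only class with training data).
    distance : str or DistanceSpec
        One of ``euclidean``, ``euclidean_std``, ``mahalanobis``,
        ``correlation``, ``gower``.

    Examples
    --------
    >>> model = OneClassTypicality(train, distance="euclidean")
    >>> res = model.fit(alpha=0.1, n_boot=1000, seed=7)
    >>> res.score(new_units)          # doctest: +SKIP
    """

    def __init__(self, train_table: FeatureTable,
                 distance: str | DistanceSpec = "euclidean"):
        if train_table.n < 2:
            raise DataError("typicality model needs at least 2 training units")
        self.train_table = train_table
        self.spec = (distance if isinstance(distance, DistanceSpec)
                     else DistanceSpec(distance))

    def fit(self, alpha: float = 0.1, n_boot: int = 1000,
            seed: int | None = None,
            bootstrap_mode: str = "leave-one-out") -> "TypicalityResults":
        """Fit the distance, the geometric variability and the bootstrap
        null; the decision threshold is the empirical (1 - alpha)-quantile
        of the bootstrap proximities (higher interpolation, so the realized
        false alarm rate is at most alpha in expectation under ties)."""
        if not (0 < alpha < 1):
            raise DataError("alpha must lie in (0, 1)")
        fitted = fit_distance(self.train_table, self.spec)
        d = pairwise(self.train_table, fitted)
        v_hat = geometric_variability(d)
        boot = bootstrap_null(self.train_table, fitted, n_boot, seed=seed,
                              mode=bootstrap_mode)
        threshold = float(np.quantile(boot, 1.0 - alpha, method="higher"))
        return TypicalityResults(self, fitted, v_hat, boot, alpha, threshold,
                                 seed, bootstrap_mode)


class TypicalityResults:
    """Fitted typicality model: frozen distance, geometric variability,
    bootstrap null sample and decision threshold."""

    def __init__(self, model: OneClassTypicality, fitted: FittedDistance,
                 v_hat: float, boot_phi2: np.ndarray, alpha: float,
                 threshold: float, seed, bootstrap_mode: str):
        self.model = model
        self.fitted_distance = fitted
        self.v_hat = float(v_hat)
        self.boot_phi2 = np.asarray(boot_phi2, dtype=float)
        self.alpha = float(alpha)
        self.threshold = float(threshold)
        self.seed = seed
        self.bootstrap_mode = bootstrap_mode

    # -- scoring ---------------------------------------------------------
    def phi2(self, new_table: FeatureTable) -> np.ndarray:
        """Proximity of each new unit to the target class."""
        d = cross(self.model.train_table, new_table, self.fitted_distance)
        return d.values.mean(axis=0) - self.v_hat

    def score(self, new_table: FeatureTable) -> list[TypicalityScore]:
        """Proximity, p-value and target/nontarget decision per new unit.

        A unit is declared nontarget when its bootstrap p-value is at most
        alpha; the proximity itself serves as a continuous atypicality
        ranking (larger = more atypical) for ROC analysis.
        """
        phi2 = self.phi2(new_table)
        pvals = p_value(phi2, self.boot_phi2)
        return [
            TypicalityScore(uid, float(f), float(p),
                            "nontarget" if p <= self.alpha else "target")
            for uid, f, p in zip(new_table.unit_ids, phi2, pvals)
        ]

    def predict(self, new_table: FeatureTable) -> np.ndarray:
        return np.array([s.decision for s in self.score(new_table)])

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        q = np.quantile(self.boot_phi2, [0.5, 0.9, 0.95, 0.99])
        lines = [
            "One-class typicality test",
            "=" * 43,
            f"{'n training units':<28}{m.train_table.n:>15}",
            f"{'n features':<28}{m.train_table.p:>15}",
            f"{'distance':<28}{m.spec.name:>15}",
            f"{'geometric variability':<28}{self.v_hat:>15.6g}",
            f"{'bootstrap replicates':<28}{self.boot_phi2.size:>15}",
            f"{'bootstrap mode':<28}{self.bootstrap_mode:>15}",
            f"{'nominal FAR (alpha)':<28}{self.alpha:>15.3g}",
            f"{'decision threshold':<28}{self.threshold:>15.6g}",
            "-" * 43,
            "bootstrap null quantiles of the proximity",
            f"{'50%':<12}{q[0]:>12.6g}",
            f"{'90%':<12}{q[1]:>12.6g}",
            f"{'95%':<12}{q[2]:>12.6g}",
            f"{'99%':<12}{q[3]:>12.6g}",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        """Serialize everything needed to score new units later: the
        training table, the frozen distance parameters, the geometric
        variability, the bootstrap null and the threshold."""
        t = self.model.train_table
        doc = {
            "distance": {"name": self.model.spec.name,
                         "ridge": self.model.spec.ridge,
                         "params": self.fitted_distance.params()},
            "alpha": self.alpha,
            "v_hat": self.v_hat,
            "threshold": self.threshold,
            "seed": self.seed,
            "bootstrap_mode": self.bootstrap_mode,
            "boot_phi2": self.boot_phi2.tolist(),
            "train": {
                "unit_ids": t.unit_ids,
                "column_names": t.column_names,
                "var_types": t.var_types,
                "values": [[None if t.missing_mask[i, j]
                            else (float(t.values[i, j])
                                  if t.var_types[j] in ("continuous", "ordinal")
                                  else str(t.values[i, j]))
                            for j in range(t.p)] for i in range(t.n)],
                "missing_mask": t.missing_mask.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "TypicalityResults":
        with open(path) as fh:
            doc = json.load(fh)
        tr = doc["train"]
        values = np.empty((len(tr["unit_ids"]), len(tr["column_names"])),
                          dtype=object)
        for i, row in enumerate(tr["values"]):
            for j, v in enumerate(row):
                values[i, j] = v
        table = FeatureTable(tr["unit_ids"], values, tr["var_types"],
                             np.asarray(tr["missing_mask"], dtype=bool),
                             tr["column_names"])
        spec = DistanceSpec(doc["distance"]["name"], doc["distance"]["ridge"])
        model = OneClassTypicality(table, spec)
        fitted = fit_distance(table, spec)
        return cls(model, fitted, doc["v_hat"],
                   np.asarray(doc["boot_phi2"]), doc["alpha"],
                   doc["threshold"], doc["seed"], doc["bootstrap_mode"])


def fit_typicality(train_table: FeatureTable, spec: str | DistanceSpec,
                   alpha: float = 0.1, n_boot: int = 1000,
                   seed: int | None = None,
                   bootstrap_mode: str = "leave-one-out") -> TypicalityResults:
    """Functional shorthand for ``OneClassTypicality(table, spec).fit(...)``."""
    return OneClassTypicality(train_table, spec).fit(
        alpha=alpha, n_boot=n_boot, seed=seed, bootstrap_mode=bootstrap_mode)
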
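"""Synthetic benchmark generators.

Three generators emulate the data regimes the one-class benchmark needs,
so that every module is testable without external downloads:

- :func:`make_continuous` — two multivariate-normal classes with a
  controllable Euclidean separation between their means, the bread-and-
  butter continuous regime (cell-count / clinical-measurement tables).
- :func:`make_highdim` — a p >> n expression-style table (hundreds to
  thousands of features, a few dozen units) where only a sparse subset of
  features carries the class signal; exercises the correlation distance
  and the failure modes of density baselines.
- :func:`make_mixed` — mixed continuous / ordinal / binary / nominal
  columns with missing cells inserted completely at random, the shape of
  clinical questionnaire data; only the Gower distance applies.

All generators are pure functions of their :class:`SynthSpec` (seed
included): the same spec always yields the identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureTable
from .exceptions import DataError

_NOMINAL_LEVELS = "abcdefghij"


@dataclass
class SynthSpec:
    """Parameters of a synthetic two-class table.

    ``shift`` is the Euclidean distance between the class mean vectors in
    units of the within-class standard deviation, independent of p (the
    shift is spread over the signal features as ``shift / sqrt(k)``).
    """

    n_target: int = 100
    n_nontarget: int = 100
    p: int = 5
    shift: float = 3.0
    missing_rate: float = 0.0
    n_ordinal: int = 0
    n_binary: int = 0
    n_nominal: int = 0
    nominal_levels: int = 3
    nominal_shift: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_target, self.n_nontarget, self.p) < 0:
            raise DataError("counts must be nonnegative")
        if not (0 <= self.missing_rate < 1):
            raise DataError("missing_rate must lie in [0, 1)")


def _labels(spec: SynthSpec) -> np.ndarray:
    return np.array(["target"] * spec.n_target
                    + ["nontarget"] * spec.n_nontarget)


def _as_table(values: np.ndarray, var_types: list[str],
              mask: np.ndarray | None = None) -> FeatureTable:
    n, p = values.shape
    if mask is None:
        mask = np.zeros((n, p), dtype=bool)
    obj = np.empty((n, p), dtype=object)
    for j in range(p):
        for i in range(n):
            obj[i, j] = None if mask[i, j] else values[i, j]
    return FeatureTable([f"u{i}" for i in range(n)], obj, var_types, mask,
                        [f"x{j}" for j in range(p)])


def make_continuous(spec: SynthSpec) -> tuple[FeatureTable, np.ndarray]:
    """Target ~ N(0, I_p); nontarget ~ N(shift/sqrt(p) * 1, I_p), so the
    Euclidean separation between the class means equals ``shift``
    regardless of p."""
    rng = np.random.default_rng(spec.seed)
    mu = np.full(spec.p, spec.shift / np.sqrt(spec.p))
    x_t = rng.standard_normal((spec.n_target, spec.p))
    x_n = rng.standard_normal((spec.n_nontarget, spec.p)) + mu
    values = np.vstack([x_t, x_n]).astype(object)
    table = _as_table(values, ["continuous"] * spec.p)
    return table, _labels(spec)


def make_highdim(spec: SynthSpec | None = None, **kwargs
                 ) -> tuple[FeatureTable, np.ndarray]:
    """p >> n expression-style table (default p=500, n=40/22).

    Each class carries its own sparse signature: a random, disjoint 5% of
    features is up-shifted by ``shift`` standard deviations per feature in
    that class only, over an i.i.d. standard-normal background. Shared
    within-class signatures make unit profiles of the same class
    positively correlated — the structure the correlation distance
    exploits in transcriptomic data — while leaving most features
    uninformative."""
    if spec is None:
        spec = SynthSpec(n_target=40, n_nontarget=22, p=500, **kwargs)
    rng = np.random.default_rng(spec.seed)
    k = max(1, int(round(0.05 * spec.p)))
    feats = rng.choice(spec.p, size=min(2 * k, spec.p), replace=False)
    mu_t = np.zeros(spec.p)
    mu_t[feats[:k]] = spec.shift
    mu_n = np.zeros(spec.p)
    mu_n[feats[k:2 * k]] = spec.shift
    x_t = rng.standard_normal((spec.n_target, spec.p)) + mu_t
    x_n = rng.standard_normal((spec.n_nontarget, spec.p)) + mu_n
    values = np.vstack([x_t, x_n]).astype(object)
    table = _as_table(values, ["continuous"] * spec.p)
    return table, _labels(spec)


def make_mixed(spec: SynthSpec | None = None, **kwargs
               ) -> tuple[FeatureTable, np.ndarray]:
    """Mixed-type two-class table with MCAR missing cells.

    Defaults mimic a clinical questionnaire: 6 continuous, 1 ordinal,
    3 binary and 3 nominal columns. The nontarget class differs by a mean
    shift on the continuous block, a one-step location shift on the
    ordinal column, and a ``nominal_shift`` probability mass moved between
    levels of the binary/nominal columns. Every unit keeps at least one
    observed cell.
    """
    if spec is None:
        spec = SynthSpec(n_target=150, n_nontarget=120, p=6, n_ordinal=1,
                         n_binary=3, n_nominal=3, **kwargs)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_target + spec.n_nontarget
    is_non = np.zeros(n, dtype=bool)
    is_non[spec.n_target:] = True

    cols: list[np.ndarray] = []
    types: list[str] = []
    # continuous block: shift spread so its Euclidean size is `shift`
    if spec.p:
        mu = spec.shift / np.sqrt(spec.p)
        block = rng.standard_normal((n, spec.p))
        block[is_non] += mu
        for j in range(spec.p):
            cols.append(block[:, j].astype(object))
            types.append("continuous")
    for _ in range(spec.n_ordinal):
        base = rng.integers(1, 5, size=n).astype(float)
        base[is_non] = np.minimum(base[is_non] + 1, 5)
        cols.append(base.astype(object))
        types.append("ordinal")
    for _ in range(spec.n_binary):
        p_t = 0.5
        p_n = min(0.95, 0.5 + spec.nominal_shift)
        prob = np.where(is_non, p_n, p_t)
        draw = (rng.random(n) < prob).astype(int).astype(str)
        cols.append(draw.astype(object))
        types.append("binary")
    for _ in range(spec.n_nominal):
        L = spec.nominal_levels
        pt = np.full(L, 1.0 / L)
        pn = pt.copy()
        # move `nominal_shift` total-variation mass onto the first level
        take = min(spec.nominal_shift, pn[1:].sum())
        pn[0] += take
        pn[1:] *= (1.0 - take / pn[1:].sum()) if pn[1:].sum() else 0.0
        pn /= pn.sum()
        levels = np.array(list(_NOMINAL_LEVELS[:L]))
        out = np.empty(n, dtype=object)
        out[~is_non] = rng.choice(levels, size=(~is_non).sum(), p=pt)
        out[is_non] = rng.choice(levels, size=is_non.sum(), p=pn)
        cols.append(out)
        types.append("nominal")

    values = np.column_stack(cols)
    p_all = values.shape[1]
    mask = rng.random((n, p_all)) < spec.missing_rate
    # keep at least one observed cell per unit
    for i in np.nonzero(mask.all(axis=1))[0]:
        mask[i, int(rng.integers(0, p_all))] = False
    table = _as_table(values, types, mask)
    return table, _labels(spec)
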
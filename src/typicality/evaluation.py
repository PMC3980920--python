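"""ROC/AUC machinery and the repeated-split benchmark protocol.

The protocol mirrors standard one-class benchmarking practice: the target
class is split at random into equal halves, the classifier is trained on
one half only, and tested on the other half plus ALL nontarget units; the
split is repeated R times (default 10) and the AUC mean and standard
deviation over repeats are reported on the percent scale.

AUC is computed by the mid-rank Mann-Whitney statistic,
``P(score_nontarget > score_target) + 0.5 P(equal)``, which equals the
trapezoidal area under the empirical ROC curve and gives ties half credit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .baselines import OCCModel, fit_method
from .data import FeatureTable, RunConfig, split_target
from .exceptions import DataError, FitFailed
from .model import TypicalityResults

log = logging.getLogger(__name__)


def auc(scores_target, scores_nontarget) -> float:
    """Area under the ROC curve on the [0, 1] scale.

    Scores must be oriented so that larger means more atypical; a perfect
    method therefore scores every nontarget above every target (AUC 1) and
    an uninformative one gets 0.5.
    """
    a = np.asarray(scores_target, dtype=float)
    b = np.asarray(scores_nontarget, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([a, b]))
    r_b = ranks[a.size:].sum()
    return float((r_b - b.size * (b.size + 1) / 2.0) / (a.size * b.size))


@dataclass
class EvalResult:
    """Per-method AUC over repeats (percent scale) plus optional
    confusion-at-FAR tables."""

    aucs: dict[str, np.ndarray] = field(default_factory=dict)
    confusion: dict[str, dict] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def mean(self, method: str) -> float:
        v = np.asarray(self.aucs[method], float)
        return float(np.nanmean(v)) if np.isfinite(v).any() else float("nan")

    def sd(self, method: str) -> float:
        v = np.asarray(self.aucs[method], float)
        v = v[np.isfinite(v)]
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    def n_failed(self, method: str) -> int:
        return int(np.isnan(np.asarray(self.aucs[method], float)).sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": m,
             "auc_mean": round(self.mean(m), 1),
             "auc_sd": round(self.sd(m), 1),
             "n_repeats": len(self.aucs[m]),
             "n_failed": self.n_failed(m)}
            for m in self.aucs
        ]
        return pd.DataFrame(rows, columns=["method", "auc_mean", "auc_sd",
                                           "n_repeats", "n_failed"])

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["AUC (percent) over repeated target splits",
                 "-" * 44]
        for _, r in df.iterrows():
            cell = f"{r.auc_mean:.1f} ({r.auc_sd:.1f})"
            if r.n_failed:
                cell += f"  [{int(r.n_failed)} failed]"
            lines.append(f"{r.method:<14}{cell}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "aucs": {m: [None if not np.isfinite(v) else float(v)
                         for v in vec] for m, vec in self.aucs.items()},
            "confusion": self.confusion,
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvalResult":
        aucs = {m: np.array([np.nan if v is None else v for v in vec], float)
                for m, vec in doc.get("aucs", {}).items()}
        return cls(aucs=aucs, confusion=doc.get("confusion", {}),
                   config=doc.get("config", {}))


def _child_seeds(root_seed: int, n: int) -> list[tuple[int, int]]:
    """Derive (split_seed, fit_seed) pairs deterministically from one root."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    out = []
    for c in children:
        s = c.generate_state(2, dtype=np.uint32)
        out.append((int(s[0]) % 2**31, int(s[1]) % 2**31))
    return out


def run_protocol(
    table: FeatureTable,
    labels: np.ndarray,
    target_level: str,
    methods: str | list[str],
    config: RunConfig,
) -> EvalResult:
    """Repeated 50/50 target-split benchmark.

    For each of ``config.repeats`` repeats: split the target class in
    half, train each method on the training half only, score the test set
    (held-out targets plus all nontargets) and record the AUC in percent.
    A :class:`FitFailed` repeat is recorded as NaN and excluded from the
    mean/sd, mirroring how density methods fail on p >> n tables.
    """
    labels = np.asarray(labels).astype(str)
    if str(target_level) not in set(labels):
        raise DataError(f"target level {target_level!r} absent from labels")
    if isinstance(methods, str):
        methods = [methods]
    seeds = _child_seeds(config.seed, config.repeats)
    aucs: dict[str, list[float]] = {m: [] for m in methods}
    for split_seed, fit_seed in seeds:
        train, test, test_labels = split_target(
            table, labels, target_level, fraction=0.5, seed=split_seed)
        is_target = test_labels == str(target_level)
        for m in methods:
            kwargs = {}
            if m == "typicality":
                kwargs = {"distance": config.distance,
                          "n_boot": config.n_boot}
            try:
                model = fit_method(m, train, alpha=config.alpha,
                                   seed=fit_seed, **kwargs)
                scores = model.score(test)
                if np.isnan(scores).any():
                    raise FitFailed(m, "NaN scores on the test set")
                val = 100.0 * auc(scores[is_target], scores[~is_target])
            except FitFailed as exc:
                log.warning("repeat failed: %s", exc)
                val = float("nan")
            aucs[m].append(val)
    return EvalResult(
        aucs={m: np.asarray(v) for m, v in aucs.items()},
        config={**config.to_dict(), "methods": list(methods),
                "target_level": str(target_level)},
    )


def _calibration_scores(model) -> np.ndarray:
    if isinstance(model, TypicalityResults):
        return model.boot_phi2
    if isinstance(model, OCCModel) and hasattr(model, "train_scores_"):
        return model.train_scores_
    raise DataError("model carries no calibration scores")


def _test_scores(model, table: FeatureTable) -> np.ndarray:
    if isinstance(model, TypicalityResults):
        return model.phi2(table)
    return model.score(table)


def confusion_at_far(model, test_groups: dict[str, FeatureTable],
                     far: float = 0.1) -> pd.DataFrame:
    """Target/nontarget decision counts per tested group at a fixed false
    alarm rate.

    The threshold is recalibrated so that a fraction ``far`` of the
    target-class calibration scores (the bootstrap null for the typicality
    test, the training scores for the baselines) exceeds it; ``far = 0``
    means no unit is ever rejected. Each column reports ``k/N`` fractions
    of the group classified as target and as nontarget.
    """
    if not (0 <= far < 1):
        raise DataError("far must lie in [0, 1)")
    cal = np.asarray(_calibration_scores(model), float)
    thr = np.inf if far == 0 else float(
        np.quantile(cal, 1.0 - far, method="higher"))
    rows = {"target": {}, "nontarget": {}}
    for name, tbl in test_groups.items():
        s = _test_scores(model, tbl)
        k = int((s > thr).sum())
        rows["target"][name] = f"{len(s) - k}/{len(s)}"
        rows["nontarget"][name] = f"{k}/{len(s)}"
    df = pd.DataFrame(rows).T
    df.index.name = "classified_as"
    return df
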
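"""Supervised factor recognition by Learning Vector Quantization (LVQ1).

Embedded trajectory coordinates are classified into the levels of one
experimental factor at a time. Two cross-validation schemes are provided:

* trialwise — trials from all participants are assigned to folds arbitrarily;
* participantwise — one fold per participant, testing whether a factor value
  can be recognized for a person the network has never seen.

Each held-out fold is scored by its error fraction and by the asymptotic
significance (chi-square p-value) of the true-versus-predicted
cross-tabulation; the report carries the fold means and the fold count,
one row per factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from ._rng import rng_for
from .errors import DegenerateLabelsError, InvalidArgumentError, NotTrainedError

__all__ = [
    "CVPartition",
    "LVQModel",
    "LVQConfig",
    "FactorEvaluation",
    "CrosstabResult",
    "make_partitions",
    "lvq_train",
    "lvq_predict",
    "crosstab_test",
    "evaluate_factor",
]


@dataclass
class CVPartition:
    """Disjoint index folds over the trial set."""

    mode: str  # "trialwise" | "participantwise"
    folds: list[np.ndarray]

    def __post_init__(self):
        if self.mode not in ("trialwise", "participantwise"):
            raise InvalidArgumentError(f"unknown CV mode {self.mode!r}")
        seen = np.concatenate([np.asarray(f) for f in self.folds])
        if len(np.unique(seen)) != len(seen):
            raise InvalidArgumentError("folds must be disjoint")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def complement(self, k: int) -> np.ndarray:
        all_idx = np.concatenate(self.folds)
        return np.setdiff1d(all_idx, self.folds[k])


def make_partitions(
    n: int,
    mode: str,
    k: int | None = None,
    seed: int = 0,
    participants: Sequence | None = None,
) -> CVPartition:
    """Build a seeded CV partition of ``n`` items.

    trialwise: ``k`` near-equal random folds (2 <= k <= n).
    participantwise: one fold per unique entry of ``participants`` (k ignored).
    """
    if mode == "participantwise":
        if participants is None or len(participants) != n:
            raise InvalidArgumentError("participantwise mode needs one participant id per item")
        parts = np.asarray([str(x) for x in participants])
        order = sorted(set(parts), key=lambda s: (len(s), s))
        folds = [np.flatnonzero(parts == p) for p in order]
        return CVPartition(mode=mode, folds=folds)
    if mode == "trialwise":
        if k is None or not 2 <= k <= n:
            raise InvalidArgumentError(f"trialwise mode needs 2 <= k <= n, got k={k}")
        order = rng_for(seed, "cv", n, k).permutation(n)
        return CVPartition(mode=mode, folds=[np.sort(f) for f in np.array_split(order, k)])
    raise InvalidArgumentError(f"unknown CV mode {mode!r}")


@dataclass
class LVQModel:
    prototypes: np.ndarray
    prototype_labels: np.ndarray
    trained: bool = False


@dataclass(frozen=True)
class LVQConfig:
    prototypes_per_class: int = 1
    lr0: float = 0.3
    epochs: int = 30
    seed: int = 0


def lvq_train(
    X: np.ndarray,
    y: Sequence,
    prototypes_per_class: int = 1,
    lr0: float = 0.3,
    epochs: int = 30,
    seed: int = 0,
) -> LVQModel:
    """LVQ1: the winning prototype is attracted to a matching-label sample and
    repelled otherwise, with a linearly decaying learning rate.

    Prototypes start at the class-conditional means plus a small seeded jitter
    (so multiple prototypes of one class separate).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray([str(v) for v in y])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise DegenerateLabelsError("need at least two classes")
    rng = rng_for(seed, "lvq")
    jitter_scale = 0.01 * (X.std() or 1.0)
    protos, labels = [], []
    for c in classes:
        mu = X[y == c].mean(axis=0)
        for _ in range(prototypes_per_class):
            protos.append(mu + rng.normal(0, jitter_scale, X.shape[1]))
            labels.append(c)
    W = np.asarray(protos)
    wl = np.asarray(labels)

    n = X.shape[0]
    total = max(1, epochs * n)
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            lr = lr0 * (1.0 - step / total)
            step += 1
            if lr <= 0:
                break
            diff = W - X[i]
            win = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            sign = 1.0 if wl[win] == y[i] else -1.0
            W[win] += sign * lr * (X[i] - W[win])
    return LVQModel(prototypes=W, prototype_labels=wl, trained=True)


def lvq_predict(model: LVQModel, X: np.ndarray) -> np.ndarray:
    """Nearest-prototype labels (Euclidean); ties go to the lowest prototype index."""
    if not model.trained:
        raise NotTrainedError("LVQ model has not been trained")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    d2 = ((X[:, None, :] - model.prototypes[None, :, :]) ** 2).sum(axis=2)
    return model.prototype_labels[np.argmin(d2, axis=1)]


@dataclass
class CrosstabResult:
    statistic: float
    dof: int
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.statistic, self.dof, self.p))


def crosstab_test(true_labels: Sequence, predicted_labels: Sequence) -> CrosstabResult:
    """Chi-square test of independence on the true x predicted contingency
    table (no continuity correction). A table with a single row or column is
    degenerate and returns p = 1 with a flag."""
    t = np.asarray([str(v) for v in true_labels])
    p = np.asarray([str(v) for v in predicted_labels])
    if t.shape != p.shape:
        raise InvalidArgumentError("label vectors must have equal length")
    if t.size < 1:
        raise InvalidArgumentError("need at least one observation")
    rows = sorted(set(t))
    cols = sorted(set(p))
    if len(rows) < 2 or len(cols) < 2:
        return CrosstabResult(statistic=0.0, dof=0, p=1.0, degenerate=True)
    table = np.zeros((len(rows), len(cols)))
    ri = {v: i for i, v in enumerate(rows)}
    ci = {v: i for i, v in enumerate(cols)}
    for a, b in zip(t, p):
        table[ri[a], ci[b]] += 1
    stat, pval, dof, _ = chi2_contingency(table, correction=False)
    return CrosstabResult(statistic=float(stat), dof=int(dof), p=float(pval))


@dataclass
class FactorEvaluation:
    """One report row: classification performance for one factor."""

    design: str  # "b" (between-subject property) | "w" (within-subject condition)
    factor: str
    mean_error: float
    mean_asymptotic_significance: float
    n_partitions: int
    fold_errors: list = field(default_factory=list)
    fold_p: list = field(default_factory=list)
    skipped_folds: list = field(default_factory=list)


def evaluate_factor(
    coords: np.ndarray,
    factor_labels: Sequence,
    cv: CVPartition,
    train_cfg: LVQConfig = LVQConfig(),
    design: str = "b",
    factor: str = "",
) -> FactorEvaluation:
    """Train-on-complement / test-on-fold evaluation of one factor.

    A fold whose training complement lacks some class is skipped and logged.
    With a single fold the evaluation degenerates to resubstitution.
    """
    X = np.asarray(coords, dtype=float)
    y = np.asarray([str(v) for v in factor_labels])
    if len(y) != X.shape[0]:
        raise InvalidArgumentError("one label per embedded trial required")
    errors, pvals, skipped = [], [], []
    for k, fold in enumerate(cv.folds):
        train_idx = cv.complement(k) if cv.n_folds > 1 else fold
        if set(y[fold]) - set(y[train_idx]) or len(set(y[train_idx])) < 2:
            skipped.append(k)
            continue
        model = lvq_train(
            X[train_idx], y[train_idx],
            prototypes_per_class=train_cfg.prototypes_per_class,
            lr0=train_cfg.lr0, epochs=train_cfg.epochs,
            seed=train_cfg.seed + k,
        )
        pred = lvq_predict(model, X[fold])
        errors.append(float(np.mean(pred != y[fold])))
        pvals.append(crosstab_test(y[fold], pred).p)
    if not errors:
        raise DegenerateLabelsError(
            f"no scorable folds for factor {factor!r} (all skipped: missing classes)"
        )
    return FactorEvaluation(
        design=design, factor=factor,
        mean_error=float(np.mean(errors)),
        mean_asymptotic_significance=float(np.mean(pvals)),
        n_partitions=len(errors),
        fold_errors=errors, fold_p=pvals, skipped_folds=skipped,
    )
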
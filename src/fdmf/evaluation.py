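"""ROC/Az scoring, Youden thresholds, block cross-validation, WAS baseline.

The evaluation harness mirrors the study design the fuser is meant for:
scores arrive in equally sized presentation blocks, block membership defines
the folds of a six-fold cross-validation, and the figure of merit is Az —
the area under the ROC curve, i.e. the probability that a random target
outscores a random non-target (ties counted half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .generative import DegenerateDataError

__all__ = [
    "ScoreDataset",
    "ROCCurve",
    "UndefinedAzError",
    "az_score",
    "youden_threshold",
    "roc_points",
    "make_folds",
    "run_cv",
    "CVResult",
    "baseline_was",
    "assign_random_blocks",
]

TARGET, NONTARGET = 1, 0


class UndefinedAzError(ValueError):
    """Raised when Az is requested with only one class present."""


@dataclass
class ScoreDataset:
    """Samples x classifier-scores matrix with labels and block ids.

    Attributes
    ----------
    scores : (n, p) float array with entries in [0, 1]
    labels : (n,) int array, 1 = Target, 0 = NonTarget
    block_id : (n,) int array assigning each sample to a presentation block
    attribute_names : p identifiers, one per classifier/agent
    """

    scores: np.ndarray
    labels: np.ndarray
    block_id: np.ndarray
    attribute_names: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        self.block_id = np.asarray(self.block_id, dtype=int).ravel()
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D samples x attributes matrix")
        n, p = self.scores.shape
        if p < 1:
            raise ValueError("need at least one attribute")
        if len(self.attribute_names) != p:
            raise ValueError("attribute_names length must match score columns")
        if self.labels.size != n or self.block_id.size != n:
            raise ValueError("labels/block_id length must match score rows")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores contain missing or non-finite entries")
        if self.scores.min() < 0.0 or self.scores.max() > 1.0:
            raise ValueError("scores must lie within [0, 1]")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (NonTarget) or 1 (Target)")

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.scores[:, self.attribute_names.index(name)]

    def subset(self, names: list[str]) -> "ScoreDataset":
        idx = [self.attribute_names.index(a) for a in names]
        return ScoreDataset(
            self.scores[:, idx], self.labels, self.block_id, list(names)
        )

    def take(self, mask: np.ndarray) -> "ScoreDataset":
        return ScoreDataset(
            self.scores[mask], self.labels[mask], self.block_id[mask],
            list(self.attribute_names),
        )


@dataclass(frozen=True)
class ROCCurve:
    """An ROC curve: descending thresholds with their (fpr, tpr) and the area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    az: float


def _check_two_classes(y: np.ndarray) -> None:
    if not ((y == 1).any() and (y == 0).any()):
        raise UndefinedAzError("Az undefined: only one class present in labels")


def az_score(scores, labels) -> float:
    """Az: probability of concordance with half-weight ties.

    Equals the trapezoidal area under the ROC curve.
    """
    y = np.asarray(labels).ravel()
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float).ravel()))


def roc_points(scores, labels) -> ROCCurve:
    """Full ROC curve (descending thresholds) with trapezoidal area."""
    y = np.asarray(labels).ravel()
    _check_two_classes(y)
    s = np.asarray(scores, dtype=float).ravel()
    fpr, tpr, thr = roc_curve(y, s)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, az=az_score(s, y))


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing TPR - FPR (the Youden index).

    Candidates are midpoints between adjacent distinct sorted scores plus the
    two outer midpoint-like extremes; a sample counts positive when its score
    is >= the threshold.  Ties are broken toward the smallest threshold.
    """
    y = np.asarray(labels).ravel()
    _check_two_classes(y)
    s = np.asarray(scores, dtype=float).ravel()
    distinct = np.unique(s)
    if distinct.size == 1:
        return float(distinct[0])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # counts of each class at every distinct score value, then suffix sums:
    # a sample is predicted positive when its score >= threshold, so the
    # midpoint after value i catches exactly the suffix starting at i+1
    idx = np.searchsorted(distinct, s)
    t_counts = np.bincount(idx[y == 1], minlength=distinct.size)
    n_counts = np.bincount(idx[y == 0], minlength=distinct.size)
    tp = np.cumsum(t_counts[::-1])[::-1]
    fp = np.cumsum(n_counts[::-1])[::-1]
    j = tp[1:] / (y == 1).sum() - fp[1:] / (y == 0).sum()
    # argmax on ties returns the first (smallest) candidate
    return float(mids[int(np.argmax(j > j.max() - 1e-15))])


def assign_random_blocks(dataset: ScoreDataset, k: int, seed: int) -> ScoreDataset:
    """Return a copy with ``k`` equal-size blocks assigned at random."""
    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    ids = np.floor(np.arange(n) * k / n).astype(int)
    rng.shuffle(ids)
    return replace(dataset, block_id=ids)


def make_folds(dataset: ScoreDataset, k: int = 6) -> list[tuple[np.ndarray, np.ndarray]]:
    """Block cross-validation splits: fold i tests on block i, trains on the rest.

    Returns a list of (train_mask, test_mask) boolean pairs; the test masks
    partition the dataset.  ``block_id`` must take exactly ``k`` distinct
    values.
    """
    blocks = np.unique(dataset.block_id)
    if blocks.size != k:
        raise ValueError(
            f"expected {k} blocks, found {blocks.size}; assign blocks first "
            "(e.g. assign_random_blocks(dataset, k, seed) for random "
            "equal-size blocking)"
        )
    folds = []
    for b in blocks:
        test = dataset.block_id == b
        folds.append((~test, test))
    return folds


def baseline_was(scores, weights) -> np.ndarray:
    """Weighted-average-of-scores fusion: convex combination per sample.

    Weights must be non-negative with positive sum; they are normalized to
    sum to 1.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    x = np.asarray(scores, dtype=float)
    return x @ (w / total)


@dataclass
class CVResult:
    """Per-fold Az values with their mean and standard deviation."""

    fuser: str
    subset: list[str]
    fold_az: list[float]
    fold_params: list[dict] = field(default_factory=list)

    @property
    def mean_az(self) -> float:
        return float(np.mean(self.fold_az))

    @property
    def sd_az(self) -> float:
        return float(np.std(self.fold_az, ddof=1)) if len(self.fold_az) > 1 else 0.0


def run_cv(
    dataset: ScoreDataset,
    fuser: str = "fdmf",
    subset: list[str] | None = None,
    k: int = 6,
    weights=None,
    grid_step: float = 0.1,
    c: int = 2,
    q: float = 2.0,
    k1: float = 1.0,
    k2: float = 1.0,
    seed: int = 0,
) -> CVResult:
    """Block cross-validation of a fusion strategy on an attribute subset.

    ``fuser`` is one of ``"fdmf"`` (fit the fuser on each training split and
    score the test split with the pignistic target probability), ``"was"``
    (weighted average of the subset's scores; equal weights unless given) or
    ``"single"`` (pass through a single attribute's score unchanged).
    Arbitrary subsets support fusion-strategy comparisons across agent
    combinations.
    """
    from .model import fit_fdmf  # local import: model depends on this module

    names = list(subset) if subset else list(dataset.attribute_names)
    if not names:
        raise ValueError("attribute subset must be non-empty")
    for a in names:
        if a not in dataset.attribute_names:
            raise KeyError(f"unknown attribute {a!r}")
    ds = dataset.subset(names)
    if fuser == "single" and len(names) != 1:
        raise ValueError("fuser='single' requires exactly one attribute")

    fold_az: list[float] = []
    fold_params: list[dict] = []
    for i, (train, test) in enumerate(make_folds(ds, k=k)):
        tr, te = ds.take(train), ds.take(test)
        try:
            if fuser == "fdmf":
                model = fit_fdmf(
                    tr, grid_step=grid_step, c=c, q=q, k1=k1, k2=k2, seed=seed
                )
                s = model.predict_proba(te.scores)
                fold_params.append(
                    {"alpha": model.alpha, "beta": model.beta,
                     "train_error": model.train_error}
                )
            elif fuser == "was":
                w = weights if weights is not None else np.ones(len(names))
                s = baseline_was(te.scores, w)
            elif fuser == "single":
                s = te.scores[:, 0]
            else:
                raise ValueError(f"unknown fuser {fuser!r}")
            fold_az.append(az_score(s, te.labels))
        except (DegenerateDataError, UndefinedAzError) as exc:
            raise type(exc)(f"fold {i}: {exc}") from exc
    return CVResult(fuser=fuser, subset=names, fold_az=fold_az, fold_params=fold_params)
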
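"""Generative evidence: fuzzy c-means membership functions per class.

For each attribute (one classifier's score), the score values of each class
are clustered with one-dimensional fuzzy c-means (FCM).  Each cluster is
summarized by a Gaussian membership function whose center is the FCM center
and whose width is the membership-weighted standard deviation of the class's
points about that center.  The class membership of an unseen score is the
maximum over the class's cluster memberships; this keeps mu in (0, 1] and
plays the role of a fuzzy class-conditional in a fuzzy naive-Bayes
assignment.  The compound hypothesis {Target, NonTarget} receives the fuzzy
AND (minimum t-norm) of the two class memberships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evidence import EPS, EvidenceTriple

__all__ = [
    "DegenerateDataError",
    "ClusterMF",
    "ClassMembershipModel",
    "fit_fcm",
    "build_membership_model",
    "membership",
    "generative_evidence",
]

logger = logging.getLogger("fdmf")


class DegenerateDataError(ValueError):
    """Raised when data cannot support the requested fit (too few points/classes)."""


@dataclass(frozen=True)
class ClusterMF:
    """One Gaussian membership function: exp(-(x - center)^2 / (2 width^2))."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0.0:
            raise ValueError(f"width must be > 0, got {self.width!r}")


@dataclass
class ClassMembershipModel:
    """Per-class collections of cluster membership functions for one attribute."""

    target_clusters: list[ClusterMF]
    nontarget_clusters: list[ClusterMF]
    cluster_count: int
    fuzzifier: float = 2.0

    def clusters_for(self, class_id: int | str) -> list[ClusterMF]:
        if class_id in (1, "Target", "target"):
            return self.target_clusters
        if class_id in (0, "NonTarget", "nontarget"):
            return self.nontarget_clusters
        raise KeyError(f"unknown class id {class_id!r}")


def _init_centers(values: np.ndarray, c: int) -> np.ndarray:
    # deterministic quantile-spaced initialization
    qs = (2.0 * np.arange(c) + 1.0) / (2.0 * c)
    return np.quantile(values, qs)


def fit_fcm(
    values,
    c: int,
    q: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 300,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means on 1-D data.

    Standard fixed-point iteration: memberships
    u_ik = 1 / sum_j (d_ik / d_jk)^(2/(q-1)), centers
    v_i = sum_k u_ik^q x_k / sum_k u_ik^q.  Initialization is deterministic
    (quantile spacing), so results are reproducible; ``seed`` is accepted for
    interface uniformity.

    Returns
    -------
    centers : (c,) array, sorted ascending
    memberships : (n, c) array, rows sum to 1

    Raises
    ------
    DegenerateDataError
        If the data have fewer distinct values than ``c``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if c < 1:
        raise ValueError("cluster count c must be >= 1")
    if not q > 1.0:
        raise ValueError("fuzzifier q must be > 1")
    n_distinct = np.unique(x).size
    if n_distinct < c:
        raise DegenerateDataError(
            f"need >= {c} distinct values for c={c} clusters, have {n_distinct}"
        )
    if c == 1:
        centers = np.array([x.mean()])
        return centers, np.ones((x.size, 1))

    centers = _init_centers(x, c)
    expo = 2.0 / (q - 1.0)
    u = np.empty((x.size, c))
    for _ in range(max_iter):
        d2 = (x[:, None] - centers[None, :]) ** 2
        zero = d2 <= 0.0
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-expo / 2.0)
            u = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            # point coincides with a center: full membership to (the first)
            # coincident center
            u[any_zero] = 0.0
            first = zero[any_zero].argmax(axis=1)
            u[np.flatnonzero(any_zero), first] = 1.0
        uq = u**q
        new_centers = (uq * x[:, None]).sum(axis=0) / uq.sum(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    order = np.argsort(centers)
    return centers[order], u[:, order]


def _weighted_width(x: np.ndarray, center: float, w: np.ndarray, floor: float) -> float:
    wsum = w.sum()
    if wsum <= 0.0:
        return floor
    var = float((w * (x - center) ** 2).sum() / wsum)
    return max(np.sqrt(var), floor)


def build_membership_model(
    scores,
    labels,
    c: int = 2,
    q: float = 2.0,
    seed: int | None = None,
) -> ClassMembershipModel:
    """Fit per-class cluster membership functions for one attribute.

    FCM runs separately on the Target and NonTarget score values.  Widths are
    the membership-weighted standard deviations about each center, floored at
    1e-3 of the attribute's observed range (absolute floor 1e-6 guards an
    all-constant attribute).  A class with fewer distinct values than ``c``
    gets its cluster count reduced, with a logged warning.

    Raises
    ------
    DegenerateDataError
        If either class is absent from ``labels``.
    """
    x = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if x.size != y.size:
        raise ValueError("scores and labels length mismatch")
    rng_span = float(x.max() - x.min()) if x.size else 0.0
    floor = max(1e-3 * rng_span, 1e-6)

    per_class: dict[int, list[ClusterMF]] = {}
    for cls in (0, 1):
        vals = x[y == cls]
        if vals.size == 0:
            raise DegenerateDataError(f"class {cls} absent from training labels")
        c_eff = min(c, np.unique(vals).size)
        if c_eff < c:
            logger.warning(
                "class %d has only %d distinct value(s); reducing c from %d to %d",
                cls, c_eff, c, c_eff,
            )
        centers, u = fit_fcm(vals, c_eff, q=q, seed=seed)
        per_class[cls] = [
            ClusterMF(float(centers[i]), _weighted_width(vals, centers[i], u[:, i], floor))
            for i in range(c_eff)
        ]
    return ClassMembershipModel(
        target_clusters=per_class[1],
        nontarget_clusters=per_class[0],
        cluster_count=c,
        fuzzifier=q,
    )


def _mu_array(clusters: list[ClusterMF], x: np.ndarray) -> np.ndarray:
    centers = np.array([cl.center for cl in clusters])
    widths = np.array([cl.width for cl in clusters])
    z = (x[..., None] - centers) / widths
    return np.exp(-0.5 * z**2).max(axis=-1)


def membership(model: ClassMembershipModel, x, class_id) -> float | np.ndarray:
    """Class membership mu_class(x): max Gaussian over the class's clusters.

    Accepts a scalar or an array of attribute scores; values lie in (0, 1],
    peaking at 1 at every cluster center.
    """
    clusters = model.clusters_for(class_id)
    arr = np.asarray(x, dtype=float)
    out = _mu_array(clusters, np.atleast_1d(arr))
    return float(out[0]) if arr.ndim == 0 else out


def generative_evidence(model: ClassMembershipModel, x: float) -> EvidenceTriple:
    """Generative evidence triple (mu_T, mu_N, mu_T AND mu_N) for one score.

    The compound entry uses the minimum t-norm; every entry is floored at
    EPS so downstream normalization and exponent blending stay defined.
    """
    mu_t = membership(model, x, 1)
    mu_n = membership(model, x, 0)
    return EvidenceTriple(
        max(mu_t, EPS), max(mu_n, EPS), max(min(mu_t, mu_n), EPS)
    )


def generative_evidence_array(model: ClassMembershipModel, x) -> np.ndarray:
    """Vectorized generative evidence: (n, 3) array for n scores."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    mu_t = _mu_array(model.target_clusters, arr)
    mu_n = _mu_array(model.nontarget_clusters, arr)
    out = np.stack([mu_t, mu_n, np.minimum(mu_t, mu_n)], axis=-1)
    return np.maximum(out, EPS)
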
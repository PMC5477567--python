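"""Discriminative evidence: nearest-mean prototypes with an uncertainty centroid.

Each attribute gets three prototypes: the Target and NonTarget class means
(nearest-mean classification) and the centroid of the Region of Uncertainty
(ROU) — the ROC threshold maximizing TPR - FPR, clamped into the interval
between the two class means.  Evidence for a hypothesis is an exponential
function of the squared distance from the score to that hypothesis's
prototype, k1 * exp(-k2 * (x - v)^2), with k1 = k2 = 1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidence import EPS, EvidenceTriple
from .generative import DegenerateDataError

__all__ = ["AttributePrototypes", "fit_prototypes", "discriminative_evidence"]


@dataclass(frozen=True)
class AttributePrototypes:
    """Class centroids plus the ROU centroid for one attribute.

    ``v_uncertain`` always lies in the closed interval bounded by
    ``v_target`` and ``v_nontarget``.
    """

    v_target: float
    v_nontarget: float
    v_uncertain: float
    k1: float = 1.0
    k2: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("k1 and k2 must be > 0")
        lo = min(self.v_target, self.v_nontarget)
        hi = max(self.v_target, self.v_nontarget)
        if not (lo - 1e-12 <= self.v_uncertain <= hi + 1e-12):
            raise ValueError(
                f"v_uncertain {self.v_uncertain!r} outside [{lo!r}, {hi!r}]"
            )


def fit_prototypes(
    scores,
    labels,
    roc_threshold: float,
    k1: float = 1.0,
    k2: float = 1.0,
) -> AttributePrototypes:
    """Class means and clamped ROU centroid for one attribute.

    ``roc_threshold`` must come from training data only (Youden threshold of
    the training ROC).  A threshold falling outside the interval spanned by
    the class means — possible on skewed data — is clamped to the nearest
    endpoint so the stated invariant holds.
    """
    x = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if not ((y == 1).any() and (y == 0).any()):
        raise DegenerateDataError("both classes required to fit prototypes")
    v_t = float(x[y == 1].mean())
    v_n = float(x[y == 0].mean())
    lo, hi = min(v_t, v_n), max(v_t, v_n)
    v_u = float(np.clip(roc_threshold, lo, hi))
    return AttributePrototypes(v_t, v_n, v_u, k1=k1, k2=k2)


def discriminative_evidence(proto: AttributePrototypes, x: float) -> EvidenceTriple:
    """Evidence triple k1 * exp(-k2 (x - v_h)^2) for the three hypotheses.

    The compound entry peaks exactly at the ROU centroid.  Entries are
    floored at EPS.
    """
    t, n, u = discriminative_evidence_array(proto, x)[0]
    return EvidenceTriple(t, n, u)


def discriminative_evidence_array(proto: AttributePrototypes, x) -> np.ndarray:
    """Vectorized discriminative evidence: (n, 3) array for n scores."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    vs = np.array([proto.v_target, proto.v_nontarget, proto.v_uncertain])
    out = proto.k1 * np.exp(-proto.k2 * (arr[:, None] - vs[None, :]) ** 2)
    return np.maximum(out, EPS)
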
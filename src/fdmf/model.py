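"""The end-to-end fuzzy decision-making fuser.

Per attribute, generative (fuzzy-membership) and discriminative
(prototype-distance) evidence triples are blended by regulatory exponents,
phi = gen^alpha * disc^beta with 0 <= alpha, beta <= 1, normalized into a
BPA, combined across attributes with Dempster's rule, and turned into a
decision via the pignistic transform.  The exponents are learned by grid
search minimizing the 0/1 training error of the argmax decision rule.

One (alpha, beta) pair is shared by all attributes.  Fusion of a hopelessly
conflicting set of per-attribute BPAs (conflict coefficient within 1e-12 of
1) falls back to the vacuous mass — total ignorance — with a logged warning
rather than aborting an evaluation run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .discriminative import (
    AttributePrototypes,
    discriminative_evidence,
    discriminative_evidence_array,
    fit_prototypes,
)
from .evaluation import ScoreDataset, youden_threshold
from .evidence import (
    CONFLICT_TOL,
    EvidenceTriple,
    MassFunction,
    TotalConflictError,
    combine_many,
    normalize_evidence,
    pignistic,
)
from .generative import (
    ClassMembershipModel,
    ClusterMF,
    DegenerateDataError,
    build_membership_model,
    generative_evidence,
    generative_evidence_array,
)

__all__ = ["FDMFModel", "blend_evidence", "fit_fdmf"]

logger = logging.getLogger("fdmf")

TARGET_LABEL = "Target"
NONTARGET_LABEL = "NonTarget"


def blend_evidence(
    gen: EvidenceTriple, disc: EvidenceTriple, alpha: float, beta: float
) -> EvidenceTriple:
    """Regulatory blend phi = gen^alpha * disc^beta, elementwise.

    With (alpha, beta) = (1, 0) the blend reduces to the generative evidence,
    with (0, 1) to the discriminative evidence.  Entries arrive floored at
    EPS, so 0^0 never occurs and every output is > 0.
    """
    g = np.array(gen.as_tuple())
    d = np.array(disc.as_tuple())
    phi = g**alpha * d**beta
    return EvidenceTriple(*phi)


def _combine_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorized Dempster combination of (n, 3) mass arrays.

    Rows hitting total conflict are replaced by the vacuous mass; returns the
    combined array and the count of such fallbacks.
    """
    k = a[:, 0] * b[:, 1] + a[:, 1] * b[:, 0]
    denom = 1.0 - k
    bad = denom <= CONFLICT_TOL
    denom = np.where(bad, 1.0, denom)
    out = np.empty_like(a)
    out[:, 0] = (a[:, 0] * b[:, 0] + a[:, 0] * b[:, 2] + a[:, 2] * b[:, 0]) / denom
    out[:, 1] = (a[:, 1] * b[:, 1] + a[:, 1] * b[:, 2] + a[:, 2] * b[:, 1]) / denom
    out[:, 2] = a[:, 2] * b[:, 2] / denom
    if bad.any():
        out[bad] = (0.0, 0.0, 1.0)
    return out, int(bad.sum())


def _fuse_mass_array(masses: np.ndarray) -> np.ndarray:
    """Fold Dempster combination across attributes: (n, p, 3) -> (n, 3)."""
    acc = masses[:, 0, :]
    fallbacks = 0
    for j in range(1, masses.shape[1]):
        acc, nb = _combine_rows(acc, masses[:, j, :])
        fallbacks += nb
    if fallbacks:
        logger.warning(
            "total conflict during fusion for %d sample-combination step(s); "
            "fell back to the vacuous mass", fallbacks,
        )
    return acc


@dataclass
class FDMFModel:
    """A fitted fuser: per-attribute evidence models plus regulatory exponents.

    ``train_error`` is the class-balanced misclassification rate
    (FNR + FPR) / 2 achieved by the selected exponents on the training data.
    """

    attribute_names: list[str]
    membership_models: dict[str, ClassMembershipModel]
    prototypes: dict[str, AttributePrototypes]
    alpha: float = 1.0
    beta: float = 1.0
    c: int = 2
    q: float = 2.0
    k1: float = 1.0
    k2: float = 1.0
    train_error: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        keys = set(self.attribute_names)
        if set(self.membership_models) != keys or set(self.prototypes) != keys:
            raise ValueError("attribute sets of models/prototypes/names differ")

    # -- per-sample (scalar) path -------------------------------------------

    def attribute_bpa(self, attribute_id: str, x: float) -> MassFunction:
        """The single-attribute BPA for score ``x``: blend then normalize."""
        gen = generative_evidence(self.membership_models[attribute_id], x)
        disc = discriminative_evidence(self.prototypes[attribute_id], x)
        return normalize_evidence(blend_evidence(gen, disc, self.alpha, self.beta))

    def fuse_sample(self, sample: dict[str, float]) -> MassFunction:
        """Dempster-combine the per-attribute BPAs of one sample.

        ``sample`` maps every fitted attribute to its score.  Combination is
        done in attribute-name order; associativity makes the order
        irrelevant.
        """
        missing = [a for a in self.attribute_names if a not in sample]
        if missing:
            raise KeyError(f"sample missing attribute(s) {missing}")
        ms = [self.attribute_bpa(a, sample[a]) for a in self.attribute_names]
        try:
            return combine_many(ms)
        except TotalConflictError:
            logger.warning("total conflict fusing sample; returning vacuous mass")
            return MassFunction(0.0, 0.0, 1.0)

    def predict_sample(self, sample: dict[str, float]) -> tuple[str, float]:
        """Predicted label and pignistic p(Target) for one sample.

        The class with the larger pignistic probability wins; an exact tie
        goes to NonTarget (the majority class under rare targets).
        """
        p_t, _ = pignistic(self.fuse_sample(sample))
        label = TARGET_LABEL if p_t > 0.5 else NONTARGET_LABEL
        return label, p_t

    # -- vectorized path -----------------------------------------------------

    def _evidence_arrays(self, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Raw (n, p, 3) generative and discriminative evidence arrays."""
        G = np.stack(
            [
                generative_evidence_array(self.membership_models[a], scores[:, j])
                for j, a in enumerate(self.attribute_names)
            ],
            axis=1,
        )
        D = np.stack(
            [
                discriminative_evidence_array(self.prototypes[a], scores[:, j])
                for j, a in enumerate(self.attribute_names)
            ],
            axis=1,
        )
        return G, D

    def fuse_scores(self, scores: np.ndarray) -> np.ndarray:
        """Fused (n, 3) mass array for an (n, p) score matrix."""
        scores = np.asarray(scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != len(self.attribute_names):
            raise ValueError(
                f"expected (n, {len(self.attribute_names)}) score matrix"
            )
        G, D = self._evidence_arrays(scores)
        phi = G**self.alpha * D**self.beta
        masses = phi / phi.sum(axis=-1, keepdims=True)
        return _fuse_mass_array(masses)

    def predict_proba(self, scores: np.ndarray) -> np.ndarray:
        """Pignistic p(Target) per sample — the continuous score for ROC use."""
        fused = self.fuse_scores(scores)
        return fused[:, 0] + fused[:, 2] / 2.0

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """Hard labels (1 = Target) by the argmax pignistic rule, ties -> NonTarget."""
        return (self.predict_proba(scores) > 0.5).astype(int)

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        def mf(cl: ClusterMF) -> dict:
            return {"center": cl.center, "width": cl.width}

        payload = {
            "format": "fdmf-model-v1",
            "attribute_names": self.attribute_names,
            "alpha": self.alpha,
            "beta": self.beta,
            "c": self.c,
            "q": self.q,
            "k1": self.k1,
            "k2": self.k2,
            "train_error": self.train_error,
            "attributes": {
                a: {
                    "target_clusters": [mf(cl) for cl in self.membership_models[a].target_clusters],
                    "nontarget_clusters": [mf(cl) for cl in self.membership_models[a].nontarget_clusters],
                    "v_target": self.prototypes[a].v_target,
                    "v_nontarget": self.prototypes[a].v_nontarget,
                    "v_uncertain": self.prototypes[a].v_uncertain,
                }
                for a in self.attribute_names
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FDMFModel":
        d = json.loads(text)
        if d.get("format") != "fdmf-model-v1":
            raise ValueError("not an fdmf model file")
        models = {}
        protos = {}
        for a, spec in d["attributes"].items():
            models[a] = ClassMembershipModel(
                target_clusters=[ClusterMF(**cl) for cl in spec["target_clusters"]],
                nontarget_clusters=[ClusterMF(**cl) for cl in spec["nontarget_clusters"]],
                cluster_count=d["c"],
                fuzzifier=d["q"],
            )
            protos[a] = AttributePrototypes(
                spec["v_target"], spec["v_nontarget"], spec["v_uncertain"],
                k1=d["k1"], k2=d["k2"],
            )
        return cls(
            attribute_names=list(d["attribute_names"]),
            membership_models=models,
            prototypes=protos,
            alpha=d["alpha"],
            beta=d["beta"],
            c=d["c"],
            q=d["q"],
            k1=d["k1"],
            k2=d["k2"],
            train_error=d.get("train_error"),
        )


def _grid_values(grid_step: float) -> list[float]:
    if not (0.0 < grid_step <= 1.0):
        raise ValueError("grid_step must lie in (0, 1]")
    vals = [round(i * grid_step, 12) for i in range(int(np.floor(1.0 / grid_step + 1e-9)) + 1)]
    if abs(vals[-1] - 1.0) > 1e-9:
        vals.append(1.0)
    else:
        vals[-1] = 1.0
    return vals


def fit_fdmf(
    train: ScoreDataset,
    grid_step: float = 0.1,
    c: int = 2,
    q: float = 2.0,
    k1: float = 1.0,
    k2: float = 1.0,
    seed: int | None = None,
) -> FDMFModel:
    """Fit the fuser on a training dataset.

    Per attribute: fuzzy-membership models and nearest-mean prototypes (with
    the Youden threshold of the attribute's training ROC as the uncertainty
    centroid) are fitted on the training data only.  Every (alpha, beta) on
    the grid {0, grid_step, ..., 1}^2 is then scored by the class-balanced
    training misclassification rate of the argmax pignistic rule — the mean
    of the per-class error rates, (FNR + FPR) / 2.  The minimizer wins, ties
    broken by smaller alpha + beta, then smaller alpha.

    Balancing matters under rare targets: the plain misclassification rate
    is minimized by the trivial all-NonTarget rule whenever target prevalence
    is below the achievable error at the symmetric pignistic threshold, which
    would collapse the grid search onto uninformative exponents.  The
    balanced rate equals the plain rate on balanced data.
    """
    names = list(train.attribute_names)
    y = train.labels
    models: dict[str, ClassMembershipModel] = {}
    protos: dict[str, AttributePrototypes] = {}
    for j, a in enumerate(names):
        x = train.scores[:, j]
        try:
            models[a] = build_membership_model(x, y, c=c, q=q, seed=seed)
            thr = youden_threshold(x, y)
            protos[a] = fit_prototypes(x, y, thr, k1=k1, k2=k2)
        except DegenerateDataError as exc:
            raise DegenerateDataError(f"attribute {a!r}: {exc}") from exc

    model = FDMFModel(
        attribute_names=names,
        membership_models=models,
        prototypes=protos,
        alpha=1.0,
        beta=1.0,
        c=c,
        q=q,
        k1=k1,
        k2=k2,
    )
    G, D = model._evidence_arrays(train.scores)

    grid = _grid_values(grid_step)
    # precompute the exponentiated evidence once per grid value
    G_pow = {a: G**a for a in grid}
    D_pow = {b: D**b for b in grid}
    is_t = y == 1
    is_n = ~is_t
    best: tuple[float, float, float] | None = None  # (error, alpha+beta, alpha)
    best_ab = (1.0, 1.0)
    for a_exp in grid:
        Ga = G_pow[a_exp]
        for b_exp in grid:
            phi = Ga * D_pow[b_exp]
            masses = phi / phi.sum(axis=-1, keepdims=True)
            fused = _fuse_mass_array(masses)
            p_t = fused[:, 0] + fused[:, 2] / 2.0
            pred = p_t > 0.5
            fnr = float(np.mean(~pred[is_t]))
            fpr = float(np.mean(pred[is_n]))
            err = (fnr + fpr) / 2.0
            key = (err, a_exp + b_exp, a_exp)
            if best is None or key < best:
                best = key
                best_ab = (a_exp, b_exp)
    model.alpha, model.beta = best_ab
    model.train_error = best[0] if best is not None else None
    logger.info(
        "selected (alpha, beta) = (%.3g, %.3g), training error %.4f",
        model.alpha, model.beta, model.train_error,
    )
    return model
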
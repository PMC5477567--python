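"""Mass-function algebra on the binary frame {Target, NonTarget}.

The frame of discernment is fixed: two exhaustive, mutually exclusive
hypotheses, ``Target`` and ``NonTarget``.  Basic probability assignments
(BPAs) put mass on exactly three focal elements — the two singletons and the
compound set ``{Target, NonTarget}`` that carries explicit uncertainty.  The
empty set never receives mass.

This module provides the pure algebra consumed by the rest of the package:
validation, normalization of raw evidence into a BPA, Dempster's rule of
combination with its conflict coefficient, and the pignistic transform used
to turn a fused BPA into a decision probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "EPS",
    "MASS_TOL",
    "CONFLICT_TOL",
    "MassFunction",
    "EvidenceTriple",
    "VACUOUS",
    "DegenerateEvidenceError",
    "TotalConflictError",
    "normalize_evidence",
    "conflict",
    "combine_pair",
    "combine_many",
    "pignistic",
]

#: floor applied to raw evidence entries so normalization never divides by 0
EPS = 1e-12
#: tolerance on "masses sum to one"
MASS_TOL = 1e-9
#: kappa >= 1 - CONFLICT_TOL counts as total conflict (vanishing denominator)
CONFLICT_TOL = 1e-12
#: negative masses above this magnitude are genuine errors, below it they are
#: floating-point cancellation and get clamped to 0
_NEG_CLAMP = 1e-12


class DegenerateEvidenceError(ValueError):
    """Raised when evidence carries no support for any hypothesis."""


class TotalConflictError(ValueError):
    """Raised when two BPAs are in complete logical contradiction (kappa = 1)."""


def _clamp(v: float) -> float:
    if -_NEG_CLAMP <= v < 0.0:
        return 0.0
    return v


@dataclass(frozen=True)
class MassFunction:
    """A valid BPA over the binary frame.

    Attributes
    ----------
    m_target, m_nontarget, m_uncertain
        Masses on {Target}, {NonTarget} and {Target, NonTarget}.  Each lies
        in [0, 1] and the three sum to 1 (within ``MASS_TOL``).
    """

    m_target: float
    m_nontarget: float
    m_uncertain: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "m_target", _clamp(float(self.m_target)))
        object.__setattr__(self, "m_nontarget", _clamp(float(self.m_nontarget)))
        object.__setattr__(self, "m_uncertain", _clamp(float(self.m_uncertain)))
        for v in (self.m_target, self.m_nontarget, self.m_uncertain):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"mass {v!r} outside [0, 1]")
        total = self.m_target + self.m_nontarget + self.m_uncertain
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"masses sum to {total!r}, not 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.m_target, self.m_nontarget, self.m_uncertain)


#: the vacuous BPA — total ignorance, the neutral element of combination
VACUOUS = MassFunction(0.0, 0.0, 1.0)


@dataclass(frozen=True)
class EvidenceTriple:
    """Unnormalized support values for the three focal elements.

    These are the raw outputs of the generative and discriminative evidence
    assignments before the normalizing factor L turns them into a BPA.
    """

    phi_target: float
    phi_nontarget: float
    phi_uncertain: float

    def __post_init__(self) -> None:
        for v in (self.phi_target, self.phi_nontarget, self.phi_uncertain):
            if v < 0.0 or not math.isfinite(v):
                raise ValueError(f"evidence support {v!r} must be finite and >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi_target, self.phi_nontarget, self.phi_uncertain)


def normalize_evidence(phi: EvidenceTriple) -> MassFunction:
    """Divide raw supports by L = phi_T + phi_N + phi_TN to obtain a BPA.

    Raises
    ------
    DegenerateEvidenceError
        If all supports are zero (L = 0, normalization undefined).
    """
    L = phi.phi_target + phi.phi_nontarget + phi.phi_uncertain
    if L <= 0.0:
        raise DegenerateEvidenceError("all-zero evidence: normalizing factor L = 0")
    return MassFunction(
        phi.phi_target / L, phi.phi_nontarget / L, phi.phi_uncertain / L
    )


def conflict(m1: MassFunction, m2: MassFunction) -> float:
    """Conflict coefficient kappa between two BPAs.

    Sum of mass products over focal-element pairs with empty intersection.
    On the binary frame only the two opposing singletons are disjoint, so
    kappa = m1({T}) m2({N}) + m1({N}) m2({T}).  kappa = 1 means the two
    pieces of evidence are in complete logical contradiction.
    """
    return m1.m_target * m2.m_nontarget + m1.m_nontarget * m2.m_target


def combine_pair(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule of combination m1 (+) m2.

    m(A) = sum over {B, C : B /\\ C = A} of m1(B) m2(C), divided by 1 - kappa.

    Raises
    ------
    TotalConflictError
        If kappa is within ``CONFLICT_TOL`` of 1 (denominator vanishes).
    """
    k = conflict(m1, m2)
    denom = 1.0 - k
    if denom <= CONFLICT_TOL:
        raise TotalConflictError(
            f"total conflict (kappa={k!r}) combining {m1.as_tuple()} "
            f"with {m2.as_tuple()}"
        )
    t1, n1, u1 = m1.as_tuple()
    t2, n2, u2 = m2.as_tuple()
    # intersections landing on each nonempty focal element of the binary frame
    mt = t1 * t2 + t1 * u2 + u1 * t2
    mn = n1 * n2 + n1 * u2 + u1 * n2
    mu = u1 * u2
    return MassFunction(mt / denom, mn / denom, mu / denom)


def combine_many(ms: Iterable[MassFunction] | Sequence[MassFunction]) -> MassFunction:
    """Left fold of ``combine_pair`` over one or more BPAs.

    Dempster's rule is associative and commutative, so the fold order does
    not affect the result.  A total-conflict failure at step ``i`` is
    re-raised with that index attached.
    """
    ms = list(ms)
    if not ms:
        raise ValueError("combine_many requires at least one mass function")
    acc = ms[0]
    for i, m in enumerate(ms[1:], start=1):
        try:
            acc = combine_pair(acc, m)
        except TotalConflictError as exc:
            raise TotalConflictError(
                f"total conflict at combination step {i}: {exc}"
            ) from exc
    return acc


def pignistic(m: MassFunction) -> tuple[float, float]:
    """Pignistic transform: split compound mass equally among its singletons.

    Returns ``(p_target, p_nontarget)``; the pair sums to 1.
    """
    half = m.m_uncertain / 2.0
    return (m.m_target + half, m.m_nontarget + half)
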
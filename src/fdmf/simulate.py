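"""Synthetic classifier-score generator with calibrated discriminability.

Stands in for the study's human and machine agent outputs: each attribute is
one agent's continuous score in (0, 1) for every stimulus.  Scores follow an
equal-variance binormal latent model — non-target latents N(0, 1), target
latents shifted by mu = sqrt(2) * Phi^{-1}(Az) so the attribute's ROC area
is exactly the requested Az — squashed to (0, 1) by the logistic function,
which is strictly increasing and therefore Az-preserving.  Within-class
dependence between attributes is equicorrelated with a single parameter,
the simplest controlled violation of the conditional-independence assumption
implicit in Dempster combination.  Targets are rare (default prevalence 0.1,
emulating sparse targets in a rapid serial visual presentation stream) and
samples arrive in contiguous equally sized blocks for block cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtri

from .evaluation import ScoreDataset

__all__ = ["SyntheticSpec", "binormal_separation", "generate", "TABLE_AZ"]

#: single-agent Az levels used as default emulation targets (three neural
#: classifiers, the button-press classifier, and the computer-vision system)
TABLE_AZ = (0.645, 0.711, 0.616, 0.640, 0.828)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic score dataset."""

    n_blocks: int = 6
    block_size: int = 3000
    prevalence: float = 0.1
    attribute_az: tuple[float, ...] = TABLE_AZ
    within_class_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be >= 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not self.attribute_az:
            raise ValueError("need at least one attribute Az")
        for az in self.attribute_az:
            if not (0.5 <= az < 1.0):
                raise ValueError(f"attribute Az {az!r} outside [0.5, 1)")
        if not (0.0 <= self.within_class_corr < 1.0):
            raise ValueError(
                "within_class_corr must lie in [0, 1) for a positive-definite "
                "equicorrelation matrix"
            )


def binormal_separation(az: float) -> float:
    """Latent mean shift of the equal-variance binormal model with ROC area ``az``.

    mu = sqrt(2) * Phi^{-1}(az): target latents N(mu, 1) against non-target
    latents N(0, 1) then have Az = Phi(mu / sqrt(2)) = az exactly.  Strictly
    increasing in az; az = 0.5 gives mu = 0.
    """
    if not (0.5 <= az < 1.0):
        raise ValueError(f"az must lie in [0.5, 1), got {az!r}")
    return float(np.sqrt(2.0) * ndtri(az))


def generate(spec: SyntheticSpec) -> ScoreDataset:
    """Draw a score dataset according to ``spec``; reproducible from its seed.

    Labels are Bernoulli(prevalence) per sample.  Latent vectors are
    multivariate normal with unit variances and equicorrelation rho within
    each class (z = sqrt(rho) * shared + sqrt(1 - rho) * independent); target
    samples get each attribute's binormal separation added.  Latents map to
    scores through the logistic function, so all scores lie strictly in
    (0, 1).  Block ids are assigned contiguously.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_blocks * spec.block_size
    p = len(spec.attribute_az)
    labels = (rng.random(n) < spec.prevalence).astype(int)

    rho = spec.within_class_corr
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, p))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep

    mus = np.array([binormal_separation(az) for az in spec.attribute_az])
    z[labels == 1] += mus

    scores = expit(z)
    block_id = np.repeat(np.arange(spec.n_blocks), spec.block_size)
    names = [f"attr{i + 1}" for i in range(p)]
    return ScoreDataset(scores=scores, labels=labels, block_id=block_id,
                        attribute_names=names)
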
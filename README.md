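# fdmf — fuzzy decision-making fuser

`fdmf` fuses the continuous scores of several binary classifiers — for
example, EEG-based target detectors, a response-time classifier, and a
computer-vision system watching the same rapid serial visual presentation
(RSVP) stream — into a single Target/NonTarget decision using
Dempster–Shafer evidence theory. It is aimed at researchers in
human–machine decision fusion who have per-agent scores in [0, 1] and want
a fusion rule that carries explicit uncertainty instead of just averaging.

## The method

The frame of discernment is Θ = {Target, NonTarget}; mass is assigned to
the two singletons and the compound set Ω = {Target, NonTarget} that
represents uncertainty. For each attribute (one agent's score `x`), two
kinds of raw evidence are computed:

* **generative** — fuzzy c-means clusters each class's training scores;
  each cluster becomes a Gaussian membership function, and
  μ_C(x) = max over C's clusters of exp(−(x − center)² / 2w²).
  The compound hypothesis gets the fuzzy AND (minimum t-norm)
  μ_T(x) ∧ μ_N(x);
* **discriminative** — nearest-mean prototypes: v_T and v_N are the class
  means, and the Region-of-Uncertainty centroid v_Ω is the training-ROC
  threshold maximizing TPR − FPR (the Youden threshold), clamped into
  [v_T, v_N]. Evidence is k₁·exp(−k₂ (x − v_h)²) with k₁ = k₂ = 1.

The two are blended with regulatory exponents,

    φ_x(·) = m_g(·)^α · m_d(·)^β,     0 ≤ α, β ≤ 1,

normalized by L = φ(T) + φ(N) + φ(Ω) into a valid basic probability
assignment, and the per-attribute BPAs are combined with Dempster's rule

    m₁⊕m₂(A) = Σ_{B∩C=A} m₁(B)m₂(C) / (1 − κ),
    κ = Σ_{B∩C=∅} m₁(B)m₂(C),

which is associative and commutative, so any number of agents fold into
one mass function m_total. The decision uses the pignistic transform,
p(Target) = m(T) + m(Ω)/2; the larger pignistic probability wins. (α, β)
are chosen by grid search over {0, 0.1, …, 1}² minimizing the
class-balanced training error of that decision rule.

The package also ships an evaluation harness (Az scoring, Youden
thresholds, six-fold block cross-validation, arbitrary agent subsets, a
weighted-average baseline) and a calibrated synthetic score generator: an
equal-variance binormal latent model with mean shift √2·Φ⁻¹(Az) squashed
through the logistic function, so each simulated agent has exactly the
requested ROC area.

## Worked example

```sh
fdmf simulate --seed 1 --out scores.csv          # 18,000 samples, 5 agents
fdmf fit      --data scores.csv --out model.json
fdmf evaluate --data scores.csv --fuser fdmf --out cv.csv
```

or from Python:

```python
import fdmf

ds = fdmf.generate(fdmf.SyntheticSpec(seed=1))   # 6 blocks x 3000, prevalence 0.1
res = fdmf.run_cv(ds, fuser="fdmf", k=6)
was = fdmf.run_cv(ds, fuser="was", k=6)
best = max(fdmf.az_score(ds.scores[:, j], ds.labels) for j in range(5))
print(f"fused Az {res.mean_az:.4f} +- {res.sd_az:.4f}")
print(f"WAS   Az {was.mean_az:.4f}   best single agent Az {best:.4f}")
```

prints

```
fused Az 0.8886 +- 0.0108
WAS   Az 0.8646   best single agent Az 0.8215
```

Each fold fits the fuser on five blocks and scores the held-out block with
the pignistic p(Target); the fused Az clearly exceeds both the strongest
individual agent and the equal-weight average, which is the point of the
method: weak-but-independent agents contribute evidence rather than noise.

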
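# Methods

## Model

`fdmf` implements evidence fusion over the fixed binary frame
Θ = {Target, NonTarget}. Every basic probability assignment (BPA) lives on
three focal elements — the two singletons and the compound set
Ω = {Target, NonTarget} — and the empty set never carries mass. Restricting
to the binary frame is deliberate: it covers the target-detection setting
the package addresses, keeps Dempster combination a closed-form nine-term
sum, and avoids the exponential cost of a general power-set engine.

For each attribute (one agent's score in [0, 1]) the pipeline is:

1. **Generative evidence.** Fuzzy c-means (FCM) is run separately on each
   class's training scores (default c = 2 clusters, fuzzifier q = 2).
   FCM's own memberships sum to 1 across a class's clusters and therefore
   carry no between-class information for unseen points, so each cluster is
   converted into a Gaussian membership function: center = FCM center,
   width = membership-weighted standard deviation of the class's points
   about that center. Class membership of a new score is the maximum over
   the class's clusters, giving μ ∈ (0, 1] with peaks at the cluster
   centers. The compound hypothesis receives the minimum t-norm
   μ_T(x) ∧ μ_N(x). This Gaussian-on-FCM construction is one concrete
   reading of a fuzzy naive-Bayes assignment; the membership model is a
   plain data object, so alternative constructions can be swapped in.
2. **Discriminative evidence.** Nearest-mean prototypes: v_T and v_N are
   the class means of the attribute, and the Region-of-Uncertainty centroid
   v_Ω is the Youden threshold (max TPR − FPR) of the attribute's training
   ROC, clamped into the closed interval between the class means (on skewed
   data the Youden point can fall outside it). Evidence for hypothesis h is
   k₁·exp(−k₂ (x − v_h)²), with k₁ = k₂ = 1 by default; the compound
   evidence peaks exactly at v_Ω.
3. **Regulatory blend and normalization.** φ(·) = gen(·)^α · disc(·)^β with
   α, β ∈ [0, 1], then division by L = φ(T) + φ(N) + φ(Ω). All raw evidence
   is floored at ε = 10⁻¹² beforehand, so L > 0 always and 0⁰ never arises;
   (α, β) = (1, 0) and (0, 1) recover the normalized generative and
   discriminative evidence bit-for-bit.
4. **Combination and decision.** Per-attribute BPAs are combined with
   Dempster's rule; associativity and commutativity make the fold order
   irrelevant (verified numerically to 10⁻¹², including the equivalence of
   two-stage group-then-combine fusion with flat fusion). The pignistic
   transform p(Target) = m(T) + m(Ω)/2 yields the decision score; the
   larger pignistic probability is the predicted class, with an exact tie
   going to NonTarget — the majority class when targets are rare, which
   minimizes expected error under total ignorance. The tie rule only fires
   on exactly symmetric evidence (e.g. the vacuous mass).

## Training the regulatory exponents

One (α, β) pair is shared by all attributes and selected by exhaustive grid
search over {0, grid_step, …, 1}² (default step 0.1, 121 candidates). The
objective is the **class-balanced** training misclassification rate of the
argmax pignistic rule, (FNR + FPR)/2, with ties broken by smaller α + β and
then smaller α (preferring flatter exponents, i.e. weaker evidence, when
errors tie). Balancing the two class error rates matters: with rare targets
(prevalence ~0.1) the plain error rate is minimized by predicting
NonTarget everywhere — a rule the grid reaches at (α, β) = (0, 0), where all
evidence is uniform — so an unweighted objective collapses the search onto
uninformative exponents and destroys the fused ranking. The balanced rate
coincides with the plain rate on balanced data and selects informative
exponents under any prevalence. `FDMFModel.train_error` records this
balanced rate.

Degenerate situations are handled explicitly rather than silently:
all-zero evidence raises before the ε floor is stripped, total conflict
(κ within 10⁻¹² of 1) raises in the pairwise algebra but falls back to the
vacuous mass (with a logged warning) inside whole-dataset fusion, so one
pathological sample cannot abort a cross-validation run. Masses in
[−10⁻¹², 0) from floating-point cancellation are clamped to zero.

## Evaluation harness

Az is the probability that a random target outscores a random non-target,
ties counted half — identical to the trapezoidal ROC area; a brute-force
pairwise oracle backs this in the tests. Youden thresholds use midpoints
between adjacent distinct scores as candidates (a sample is positive when
score ≥ threshold), smallest candidate on ties. Cross-validation is
block-structured: fold i tests on block i and trains on the rest, matching
data collected in presentation blocks; `run_cv` supports arbitrary
attribute subsets for fusion-strategy comparisons and includes a
weighted-average (WAS) baseline. Per-fold Az values are always reported so
users can run their own paired statistics; aggregation beyond mean ± sd is
left to the caller.

## Synthetic score generator

The generator emulates a panel of agents scoring a rare-target RSVP-style
stream. Non-target latents are standard normal; target latents are shifted
by μ = √2·Φ⁻¹(Az) per attribute, so the equal-variance binormal model has
exactly the requested ROC area; the logistic squash to (0, 1) is strictly
monotone and hence Az-preserving. Defaults are the emulated study
conditions: five agents with Az (0.645, 0.711, 0.616, 0.640, 0.828), six
contiguous blocks of 3,000 samples, and target prevalence 0.1 — the
prevalence is a documented assumption (targets are sparse but no exact rate
is fixed) and is configurable. Within-class dependence between attributes
is equicorrelated with a single parameter ρ ∈ [0, 1), implemented as
z = √ρ·shared + √(1−ρ)·independent; it is the simplest controlled
violation of the conditional-independence assumption behind Dempster
combination and is used for stress tests (at ρ → 1 fusion adds almost
nothing over a single agent).

What the generator does **not** emulate: per-subject variability,
within-block score drift, non-Gaussian or heteroscedastic score shapes,
label noise, and any dependence between prevalence and block. Passing tests
therefore demonstrate correctness of the algebra and the expected ordering
of fusion strategies under calibrated, near-ideal conditions — not
performance on any particular real recording.

## Numerical choices

* FCM: quantile-spaced deterministic initialization, tolerance 10⁻⁸ on
  center movement, 300 iterations max; a point coinciding with a center
  gets full membership there. A class with fewer distinct values than c has
  its cluster count reduced with a warning. The seed argument is kept for
  interface uniformity; the fit is deterministic regardless.
* Membership widths are floored at 10⁻³ of the attribute's observed range
  (absolute floor 10⁻⁶) to prevent delta-function memberships on
  degenerate clusters.
* Dataset files are plain CSV with `# key: value` provenance headers and
  shortest-round-trip float formatting, so write → read → write is
  byte-identical; models serialize to a single JSON text file and reload to
  bit-identical predictions.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`).

## Known limitations

Only two classes; one global (α, β) rather than per-attribute pairs (a
single shared pair is what the blending rule defines; per-attribute
exponents would square the search); k₁, k₂ are fixed, not learned; no
belief/plausibility intervals or alternative combination rules (Yager,
Dubois–Prade); membership means and spreads are taken from the clustering
and not subsequently tuned. The balanced training objective treats the two
classes as equally important — if an application weights false alarms and
misses unequally, the decision threshold on the pignistic score should be
adjusted downstream rather than inside the fit.
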
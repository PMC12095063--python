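# Methods

## The scientific question and the analysis chain

A perceptual decision can shift because the stimulus *looks* different
(a perceptual change) or because the observer *responds* differently to the
same look (a decisional change).  The package implements an analysis chain
that separates the two using three per-subject psychometric landmarks, all
in stimulus units (pixels of line length, reference R = 400 px):

* **PSE** — the target length at which 'short' and 'long' responses are
  equally likely, from a probit (cumulative Gaussian) fit of P('long') on
  target length.  Sensitive to both perceptual and decisional shifts.
* **Point of maximal uncertainty** — the vertex of a quadratic fit of the
  per-length proportion of 'high' confidence.  Tracks where the observer's
  *confidence* is centered.
* **Reproduction match point** — the target length whose reproduced length
  equals the reference, from a linear fit of reproduced on true length.
  A matching measure: insensitive to decision criteria, so it benchmarks
  subjective appearance.

A bias effect is always `landmark(bias-to-short) − landmark(bias-to-long)`,
so positive means behavior moved toward the biased direction.  Per-subject
effects feed (i) one-sided paired JZS Bayes-factor t-tests per group and
task, (ii) an encompassing-prior lattice asking which groups have effects,
and (iii) meta-d′/M-ratio metacognitive efficiency.

## Generative observer

The synthetic observer is the minimal SDT model whose three landmarks
dissociate:

* percept: `x = L + p + ε`, `ε ~ N(0, σ²)`;
* decision: 'long' iff `x ≥ R + c_dec`;
* confidence: 'high' iff `|x − (R + c_conf)| ≥ max(τ + η, 0)`,
  `η ~ N(0, σ_m²)` redrawn per trial;
* reproduction: `y = α + β(L + p) + ε_r`, `ε_r ~ N(0, σ_r²)`.

Closed forms: PSE = `R + c_dec − p`, vertex = `R + c_conf − p`, match =
`(R − α)/β − p`.  A perceptual shift `p` moves all three; a criterion shift
`c_dec` moves only the PSE; a confidence-center shift `c_conf` moves only
the vertex.  Additive Gaussian noise on the confidence threshold (σ_m)
degrades the confidence–accuracy coupling smoothly: M-ratio → 1 as
σ_m → 0, M-ratio < 1 otherwise.

### Default parameters (units: pixels)

| parameter | default | rationale |
|---|---|---|
| sensory σ | 15 | d′ ≈ 0.7 at ±10 px, ≈ 2 at ±30 px — a discriminable but noisy task |
| confidence halfwidth τ | 25 | with σ = 15 gives 'high' rates ranging ~0.15–0.75 across the menu, i.e. roughly even low/high usage, which the experimental feedback scheme explicitly encouraged |
| metacognitive noise σ_m | 5 | group M-ratio ≈ 0.9, the sub-ideal efficiency typical of perceptual confidence |
| reproduction α, β, σ_r | 0, 1, 20 | unbiased, calibrated reproduction with most errors under the 22-px feedback threshold |
| shift magnitude | 10 | PSE effects of ~20 px across directions, the order observed with these manipulations |
| confidence leak λ | 0.5 | non-perceptual biases move confidence about half as far as decisions |
| between-subject SD of magnitude | 6 | effect-size regime d ≈ 1–1.7 |
| subjects per group | 35 | within the 30–40 range a sequential design of this type realizes |

Cohorts mirror the study design: each subject runs both bias directions
with a subject-specific magnitude, mirrored in sign; Müller–Lyer-like
groups get a perceptual shift, base-rate/payoff-like groups a criterion
shift with partial confidence leak.

### What the generator does not emulate

Counterbalanced mini-blocks and reference-screen timing (only marginal
trial counts are preserved — the analyses use nothing else); reaction
times; learning/fatigue drift; lapses; any trial-history dependence in
reproduction.  Passing tests therefore show the chain recovers the
generative dissociation under clean SDT assumptions, not that real data are
this well behaved.

## Trial schedules

Per direction: Müller–Lyer and payoff present each of the seven lengths 40×
(decision) and 20× (reproduction), 420 trials; base rate presents the
prevalent category 120/90/60 going from the farthest to the closest length
to the reference, 30 for every other length including the reference, with
reproduction counts exactly half (390 + 195).  Payoff penalties are (5, 1)
points against the non-biased error direction, (1, 1) elsewhere.

## Estimation details and numerical choices

* **Probit fit**: grouped binomial GLM (identical MLE to the trial-level
  Bernoulli likelihood); PSE computed analytically as −location/slope.
  Complete separation or all-identical responses yield quality_pass = False
  with an undefined landmark rather than an exception.  Implausibly steep
  slopes (> 5 px⁻¹) are treated as separation.
* **Quadratic fit**: OLS on per-length 'high' proportions; vertex −b/(2a);
  requires a > 0 and p < .05.  Landmarks outside [340, 460] px are flagged
  as extrapolated.  The fitted vertex is a *biased* estimator of the true
  symmetry center when that center is off the middle of the length menu,
  because the true confidence curve is not a parabola: at the default
  observer the asymptotic bias is ≈ 0.12 px per px of shift (toward the
  menu center), ≈ 0.6 px at a 5-px shift.  Effects (short minus long) are
  attenuated accordingly but never sign-flipped.
* **Reproduction fit**: OLS; match point (400 − α̂)/β̂.  As a ratio
  estimator its finite-sample bias is proportional to (400 − mean sampled
  length); with the base-rate schedules (mean sampled length ≈ 411 vs 389
  by direction) this produces a ≈ +0.1 px systematic short-minus-long
  effect even for an unbiased observer — negligible in pixels, but visible
  in group t-statistics when no true between-subject variance exists.
* **Quality screens**: two-sided Wald/t test at α = 0.05 on the governing
  coefficient, wrong-signed coefficients fail regardless.
* **JZS Bayes factor**: adaptive quadrature of the noncentral-t marginal
  against the Cauchy(0, r = 0.707) prior on δ; the posterior of δ lives on
  a deterministic grid of 2¹² + 1 points spanning ±10 (odd count so zero is
  a node and one-sided masses are exact under symmetry).  One-sided BF =
  two-sided BF × 2·P(δ > 0 | data).  Credible intervals are central 95% by
  default; a highest-density variant is available (`hdi=True`) and nearly
  coincides for these unimodal posteriors.  Posterior draws use inverse-CDF
  sampling on the grid — deterministic given a seed.
* **Savage–Dickey**: BF₁₀ = prior density at 0 / posterior density at 0
  (mass moving away from zero is evidence *for* the effect).  The posterior
  density is a Gaussian KDE with Silverman's rule of thumb using the robust
  spread min(SD, IQR/1.34) — the raw-SD variant explodes for heavy-tailed
  draw vectors such as Cauchy prior samples.  The estimate is reliable when
  the null lies within the posterior bulk (|z| ≲ 3, BF up to ~10²); for
  posteriors concentrated far from zero the density at zero rests on a
  handful of tail draws and the ratio should not be trusted.
* **Encompassing lattice**: groups are independent between-subject samples,
  so a model's BF over the all-null baseline factorizes into per-group
  terms: `2 × P(δ > 0 | data) × BF₁₀` where the model claims an effect, 1
  where it claims none (equality constraints are the group-level null).
  This replaces a joint hierarchical model; with per-subject difference
  scores the joint likelihood is separable, so the factorization is exact.
  Model labels: subsets ordered by descending number of effects (A = all,
  last = null).
* **Meta-d′**: maximum type-2 likelihood holding the relative criterion
  c′ = c/d′ fixed, one type-2 criterion per response side constrained to
  the correct side of the type-1 criterion (offsets bounded ≥ 0); L-BFGS-B
  from three starts.  Edge correction adds ½ to every cell when any cell is
  zero.  Reference-length trials are excluded throughout (they belong to
  neither stimulus class).  Internally the conventional criterion *location*
  (respond 'long' iff x ≥ c₁, stimulus means ±d′/2) is used; the sdt module
  reports c = +½(Z(HR)+Z(FAR)), which differs only in sign convention.
  Note that pooling stimulus strengths (seven lengths) mildly violates the
  equal-variance SDT assumption, so even an ideal observer's M-ratio can
  sit a few percent off 1; single-strength checks recover 1 cleanly.
* **Group M-ratio model**: Normal likelihood on per-subject log M-ratio,
  priors μ ~ N(0, 5²), σ half-Normal(5), sampled by vectorized random-walk
  Metropolis, 4 chains × 20,000 iterations, first half discarded, thinning
  2; convergence requires split-R̂ < 1.02 on μ.  This deliberately simple
  group stage replaces a full hierarchical type-2 SDT model: it preserves
  the inferential structure (group posterior → Savage–Dickey on the
  standardized condition difference, pooled subject-level SD as the
  scaling) at desk scale.  The condition comparison defaults to the log
  scale, with `scale="raw"` available.
* **Stopping-rule simulator**: per replicate, paired difference scores are
  drawn N(d, 1); a one-sided JZS test is evaluated at n = 30 and every +5
  subjects, stopping at BF₁₀ > 3 or < 0.3 (thresholds configurable,
  lower = 0 / upper = ∞ disables stopping).

## Problem sizes used by the test suite and acceptance script

Landmark-recovery checks use 10⁵ decision trials; oracle equivalences use
100 (SDT), 20 (JZS, meta-d′ grid) and 10 (Savage–Dickey) random instances;
the dissociation study uses 100 seeded cohort replicates in the test suite
and 60 in the acceptance script, each with 35 subjects per group; the
stopping simulation uses 200 replicates.  The meta-d′ grid oracle searches
meta-d′ ∈ [−5, 6] at 0.01 resolution with per-side vectorized criterion
grids, then re-grids the winning neighborhood 20× finer so that comparisons
against the optimizer reflect fit quality rather than grid granularity.

## Known limitations

* The two estimator biases above (quadratic vertex, reproduction ratio) are
  properties of the field-standard fitting recipe itself, not of this
  implementation; they attenuate confidence effects by ~12% and put a
  ~+0.1 px tilt on base-rate reproduction effects.  One consequence,
  verified analytically and by simulation: with two truly-null groups the
  "perceptual-only" lattice model can win at most ~86–88% of replicates at
  n = 30–40 per group (a null group's one-sided encompassing BF exceeds 1
  whenever its t-statistic exceeds ≈ 1.55, i.e. ~6–7% of the time, and the
  base-rate tilt raises that further), so a ≥ 90% win-rate bar for the full
  dissociation pattern is not reachable at these group sizes.
* Binary confidence only; no response-conditional meta-d′; no lapse or
  asymptote parameters in the psychometric fits.
* The KDE-based Savage–Dickey ratio is bounded in practice to BFs of order
  10² (see above); quadrature BFs have no such limit.
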
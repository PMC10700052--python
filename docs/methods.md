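# Methods

## Model

The simulator implements the standard haploid Wright–Fisher model with
non-overlapping generations, one biallelic locus, constant effective (and
census) population size Ne, and no mutation, migration or linkage. Given the
mutant frequency q and its relative fitness f in a generation, selection
deterministically moves the expected frequency to

    p = q f / (1 + q (f − 1)),

and reproduction draws the next generation's mutant copy number from
Binomial(Ne, p). Each generation's realized change is decomposed as

    Δs = p − q            (selection component; deterministic in q, f)
    Δd = q′ − p           (drift component; binomial sampling residual)

so q′ = q + Δs + Δd holds identically. Absorbing boundaries: at q ∈ {0, 1}
both components are defined as 0 and simulation stops (no selection or drift
acts on a fixed or lost allele). Fitness refers to expected fitness; all
stochasticity enters through the binomial draw.

## Summary statistics

For a trajectory of n generations with fitnesses f₁…fₙ and selection
components Δs,₁…Δs,ₙ:

* **geometric mean fitness** f_G = (∏fᵢ)^(1/n), computed in log space;
* **effective fitness** f_E = (0.5 + Δ̄s)/(0.5 − Δ̄s) with Δ̄s = mean(Δs,ᵢ):
  the constant fitness that would produce Δ̄s in one generation at frequency
  0.5, where selection's leverage on frequency is maximal;
* **relative selection effect** C = ΣΔs / (|ΣΔs| + |ΣΔd|), the signed share
  of selection in the total frequency change; undefined (NaN) when both sums
  are zero. |C| < 0.05 (strict) calls the realized process effectively
  neutral; the cutoff is a tunable argument, 0.05 by default.
* frequency predictors over n generations from q₀: the f_G-based
  q_G = q₀f_G^n / (1 + q₀(f_G^n − 1)) and the f_E-based linear
  q_E = q₀ + n·(f_E − 1)/(2(f_E + 1)). q_E is deliberately not clamped to
  [0, 1] — clamping would bias the bias/variance/MSE comparison — and a
  warning flags out-of-range predictions.

ΣΔd is always computed as (q_final − q₀) − ΣΔs (the drift-sum identity),
which is exact by construction and also defines ΣΔd for observed
trajectories where per-generation drift is not recorded. The final
(absorbing) generation's Δs, computed from the last interior frequency, is
included in all sums; for censored (non-absorbed) trajectories the
statistics cover the generations observed.

## Exact two-generation theory

The bias of f_G under drift is established by exact enumeration rather than
asymptotics: with p₁ the post-selection expectation of generation 1,

    E(q₂) = Σ_{i=0}^{Ne} Binomial(i; Ne, p₁) · F(i/Ne),
    F(x) = x f₂ / (1 + x (f₂ − 1)),

evaluated with the scipy binomial pmf (O(Ne) work; enforced limit
Ne ≤ 10⁵; no normal approximation). F is strictly concave for f₂ > 1 and
strictly convex for f₂ < 1, so E(q₂) is below (above) the no-drift value
q₂′ = q₀f₁f₂/(1 + q₀(f₁f₂ − 1)) exactly when f₂ > 1 (f₂ < 1) — the sign
depends only on f₂, never f₁. Replacing F by the linear map x·f₂ removes
the bias entirely, which motivates the linear-update control experiment.

The reparameterization f₁ = eˣ f_G, f₂ = e⁻ˣ f_G holds f_G fixed while x
controls the fluctuation amplitude; G(x) = E(q₂) then isolates the effect of
fluctuation. Strict monotonicity of G on the sampled grid
(x ∈ [−1, 1], step 0.02) over three standard one-parameter sweeps —
q₀ ∈ {0.1…0.9} (f_G = 0.9, Ne = 1000), log₂f_G ∈ {−1…1} step 0.2
(q₀ = 0.3, Ne = 1000), Ne ∈ {1000…10000} step 1000 (q₀ = 0.3, f_G = 0.9) —
demonstrates numerically that no x ≠ 0 reproduces the constant-selection
expectation. Monotonicity is assessed on the sampled sequence (strict
inequality of successive differences); a 10× finer grid at small Ne serves
as a refinement check in the tests. The direction (increasing in x over
these grids) is reported, not asserted a priori.

## Fitness regimes

All regimes receive 1-based generation indices; switches happen before
selection acts in the switching generation.

* `constant(f)`, `block(f1, f2, n_switch)` (f1 strictly before generation
  n_switch), `alternating(f_odd, f_even)`;
* `markov_switch(f1, f2, switch_prob)` — initial state uniform over
  {f1, f2}; per-generation Bernoulli(switch_prob) flip, giving geometric
  dwell times (mean 20 generations at the default 0.05). This is the default
  fluctuating regime: f1 = 11/10, f2 = 10/11 (so f1·f2 = 1), switch
  probability 0.05;
* `poisson_block(f1, f2, mean_block)` — a variant with Poisson(mean 20)
  dwell times (zero draws bumped to one generation), provided because the
  two waiting-time conventions appear interchangeably in descriptions of
  this design; the default experiments use the Bernoulli/geometric form;
* `frequency_dependent(f_low, f_high, threshold)` — f_low strictly below
  the threshold frequency;
* `target_delta(delta_schedule)` — the rule "achieve Δs = δᵢ in generation
  i", with the implied fitness f = 1 + δ/(q(1 − q − δ)) recomputed from the
  current frequency each generation so the realized Δs follows the schedule
  regardless of drift. The per-trajectory simulator raises (with generation
  index) when q + δ leaves (0, 1) and no fitness exists; the batch engine
  instead clamps the sampling probability into [0, 1] and books the realized
  (clamped) Δs, since one pathological replicate must not abort a
  half-million-run batch. At the conditions where this regime is used
  (q₀ = 0.5, ≤ 14 generations, |δ| = 0.045) the clamp is essentially never
  reached.

## Experiments

The four drivers share a vectorized batch engine that advances all replicate
populations in lock-step, retiring absorbed runs and accumulating per-run
ΣΔs, Σlog f and generation counts (sufficient statistics for f_E, f_G, C).

1. **f_G = 1 / f_E = 1 designs** (`run_fg1_fe1_experiment`): Ne = 1000,
   q₀ = 0.5, 2n generations for n = 1…7, 500,000 replicates per n (a
   50,000-replicate preset exists for quick runs). Scenarios: block 5/6 then
   6/5 (f_G = 1), alternating 5/6, 6/5 (f_G = 1), the same block under the
   hypothetical linear update E(q′) = f·q (Δs = (f−1)q, sampling probability
   clamped to [0, 1]), and the Δs = −0.045-then-+0.045 schedule (f_E = 1;
   the negative block first, matching the fitness ≈ 5/6 of the f_G design).
   Runs absorbed before generation 2n are counted and excluded from means
   (their f_G/f_E no longer equal 1 over the window); with q₀ = 0.5 and
   Ne = 1000 such absorptions essentially never occur. Reported per n: mean
   final frequency, normal-approximation 95% CI, and a two-sided one-sample
   t-test against 0.5 at the conventional α = 0.05.

2. **Conditional-frequency inference error**
   (`run_conditional_frequency_experiment`): 200-generation runs under the
   default switching regime from q₀ = 0.01 (or 0.5); for each target
   frequency 0.1…0.9 the first 500 runs (in global run order, well-defined
   given one seed) whose final copy count equals target·Ne exactly are
   scored by both predictors. Per bin and predictor: bias, bias², variance
   (population, ddof = 0) and MSE of the prediction error, satisfying
   MSE = bias² + variance identically. Unreachable quotas raise a
   diagnostic carrying the fill state and attempt count.

3. **Outcome prediction** (`run_outcome_prediction_experiment`): runs to
   absorption from q₀ = 0.01 (or 0.5, or a single copy); the first 5,000
   fixations and 5,000 losses are scored by f_E and f_G, and AUC is computed
   by the midrank Mann–Whitney statistic with fixation as the positive
   class (identical to trapezoidal ROC integration, as the tests verify
   against an independent implementation). Where the two summaries
   contradict each other (f_E > 1 & f_G < 1, or f_E < 1 & f_G > 1) the
   driver tabulates fixed:lost counts twice: within the outcome-conditioned
   AUC collection, and — the informative design — in a separate collection
   of a fixed quota of runs *per contradiction category*, sampling on the
   condition rather than the outcome, from q₀ = 0.5 where fixation and loss
   are balanced. From a 0.01 start, fixations with f_G < 1 essentially never
   occur, so only the by-condition collection at 0.5 can test the
   majority-fixed/majority-lost claim.

4. **New-mutation fate** (`run_new_mutation_experiment`): a single copy is
   introduced and run to absorption; 5,000 losses and 5,000 fixations (the
   fixation quota is configurable down to 0, losses being ~10³ times
   cheaper) are summarized by the fractions |C| < 0.5, |C| < cutoff,
   C > 0.5 and f_E > 1 per outcome class, plus distribution summaries and a
   long per-run table.

Replicate quotas are configurable throughout; the scaled-down presets
(50,000 replicates; 50 per bin; 500 + 500 outcomes) preserve every
directional claim. One caveat discovered in calibration: the alternating
f_G = 1 arm's bias at n = 7 is ≈ 3×10⁻⁴, so its *statistical significance*
needs the full 500,000 replicates (power at 50,000 is only ~0.6); the test
suite therefore asserts significance at full scale and direction at reduced
scale. Full scale is cheap here (~25 s) because the engine is vectorized.

## Randomness and reproducibility

Every driver takes an integer seed; a single numpy Generator per experiment
(or per scalar trajectory) is consumed sequentially, so identical
(configuration, seed) pairs give identical results on a platform, and
chunked collections ("first k runs satisfying …") are well-defined.
Replicate-level reproducibility across platforms or implementations is
distributional, not bitwise. Result directories include a JSON manifest
(parameters, seed, output SHA-256 checksums, wall time) sufficient to
re-execute and verify a run.

## Numerical choices

* The Δs/Δd split is compensated at the ulp level so that
  q + Δs + Δd == q′ holds bitwise. This is provably impossible in float64
  for some states — when a large |Δs| lands on a q′ with a much smaller
  exponent, both components' float lattices are coarser than q′'s rounding
  window — in which case the reconstruction is exact to one ulp of the
  largest component; the property tests certify impossibility by
  ulp-neighborhood search before accepting such a case. All study regimes
  operate far from this corner.
* f_E's domain requires |Δ̄s| < 0.5, automatically satisfied by
  per-generation Δs magnitudes < 0.5; the sign relation f_E > 1 ⇔ Δ̄s > 0
  holds down to float resolution (|Δ̄s| ≳ 10⁻¹⁶).
* Geometric means are computed as exp(mean(log f)); exact enumeration uses
  the scipy binomial pmf; t-tests, rank statistics and binomial CIs come
  from scipy.
* Trajectory TSVs store floats at full repr precision plus the population
  size, making write/read round-trips bit-exact (copy counts recover as
  round(q·Ne)); frequencies in memory are always copy-count lattice points.

## What the simulations do and do not show

The generators emulate exactly the idealized model above: constant Ne,
haploidy, free recombination (single locus), fitness known each generation.
Conclusions about f_G's bias and f_E's calibration are statements about
this model, checked by exact theory at small Ne and by Monte Carlo at
Ne = 1000. Real data add measurement noise in both frequency and fitness,
fluctuating population size, and linked selection — none of which the
simulations represent, though the C statistic and f_E only require observed
frequencies and fitnesses and therefore extend mechanically to such data.
A known behaviour worth flagging: under the frequency-dependent example
regime (1.01 below 0.99, else 0.9), a typical fixing allele spends only a
few percent of its generations above the threshold, so the paradoxical
signature f_G < 1 at fixation — while systematically possible and easy to
exhibit — occurs in a minority (~12%) of fixed runs; f_E > 1 (100%) and
C > 0.5 (~95%) are the robust signatures.

## Limitations

Diploidy, dominance, mutation, migration, multiple loci, linkage and
varying Ne are out of scope. Continuous-time and overlapping-generation
models are not implemented. The conditional-frequency design's residual
f_E bias (an ascertainment effect of conditioning on survival) is reported
but not corrected. Symbolic proof of G(x) monotonicity is replaced by
dense numerical scans.
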
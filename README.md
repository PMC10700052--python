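# effsel — effective fitness under fluctuating selection with drift

`effsel` is a population-genetics toolkit for studying how to summarize
**fluctuating selection** on a mutant allele in a finite haploid
Wright–Fisher population. Its starting point is a pitfall of the classical
summary, the **geometric mean fitness**

> f_G = (∏ᵢ fᵢ)^(1/n),

which is exact without genetic drift (the multiplicability of relative
fitness) but biased with drift: the expected allele frequency after
fluctuating selection does not equal the constant-selection prediction based
on f_G, and the direction of the bias depends only on the *later*
generation's fitness (a Jensen's-inequality effect of binomial sampling
noise passing through the nonlinear selection map).

The package provides the frequency-aware alternatives:

* the per-generation decomposition of frequency change into a **selection
  component** Δs,ᵢ = q(1−q)(f−1)/(1+q(f−1)) and a **drift component**
  Δd,ᵢ = qᵢ − qᵢ₋₁ − Δs,ᵢ, exact by construction;
* the **effective fitness** f_E = (0.5 + Δ̄s)/(0.5 − Δ̄s), the constant fitness
  that would produce the trajectory's mean selection-driven change at
  frequency 0.5;
* the **relative selection effect** C = ΣΔs / (|ΣΔs| + |ΣΔd|) ∈ [−1, 1],
  with |C| < 0.05 as an operational definition of *effective neutrality* of
  the realized process.

Who it is for: population geneticists and evolution students who want a
transparent forward simulator with an exact selection/drift ledger, exact
small-population theory for the two-generation bias, and reproducible batch
experiments comparing f_G- and f_E-based inference.

## What's inside

| module | contents |
| --- | --- |
| `effsel.wfsim` | haploid Wright–Fisher stepping (`wf_step`, `simulate`), the hypothetical linear-update control (`simulate_linear_rule`), and a vectorized batch engine (`simulate_batch`) |
| `effsel.regimes` | fitness regimes: constant, block, alternating, Markov-switching, Poisson-block, frequency-dependent, and target-Δs schedules |
| `effsel.metrics` | f_G, f_E, C, effective-neutrality calls, and the q_G / q_E frequency predictors |
| `effsel.exact_theory` | exact binomial-expectation E(q₂), the no-drift recurrence, the G(x) reparameterization and its monotonicity scans |
| `effsel.experiments` | the four batch studies: f_G=1 / f_E=1 designs, conditional-frequency inference error (bias²+variance=MSE), ROC/AUC outcome prediction, and new-mutation fate analysis |
| `effsel.io`, `effsel.cli` | trajectory TSV / result TSV+manifest serialization, YAML/JSON configs, and the `effsel` command line |

## Worked example

A newly arisen allele under frequency-dependent selection — favoured
(f = 1.01) while below frequency 0.99, disfavoured (f = 0.9) above — can fix
while its geometric mean fitness is below 1:

```python
import effsel as es

regime = es.FrequencyDependentFitness(f_low=1.01, f_high=0.9, threshold=0.99)
config = es.SimConfig(ne=1000, regime=regime, init_copies=1,
                      max_generations=100_000, seed=208)
trajectory = es.simulate(config)
summary = es.summarize(trajectory)
print(f"outcome={summary.outcome} after {summary.n_generations} generations")
print(f"f_G={summary.f_g:.4f}  f_E={summary.f_e:.4f}  C={summary.c_value:.2f}")
```

prints

```
outcome=fixed after 819 generations
f_G=0.9928  f_E=1.0027  C=0.56
```

The allele fixed, yet f_G < 1 — the geometric mean is blind to *when* the
negative selection acted (only near fixation, where drift dominates). The
effective fitness f_E > 1 and the relative selection effect C = 0.56 > 0.5
correctly attribute the fixation mainly to positive selection.

The same analysis from the shell:

```bash
effsel simulate --ne 1000 --init-copies 1 --regime frequency_dependent \
    --f-low 1.01 --f-high 0.9 --threshold 0.99 --seed 208 --out traj.tsv
effsel metrics traj.tsv
```

Batch experiments run through the library
(`es.run_new_mutation_experiment(...)`) or the CLI:

```bash
effsel experiment new_mutation --preset desk --seed 1 --out results/
effsel theory scan --grid all --out scan.tsv
```

The `examples/` directory contains one short narrative script per
capability.

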
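"""Haploid Wright–Fisher forward simulation with selection–drift decomposition.

The model: a haploid population of constant effective size Ne, non-overlapping
generations, one biallelic locus, no mutation or migration.  If the mutant has
frequency q and relative fitness f in a generation, the post-selection expected
frequency is

    p = q f / (1 + q (f - 1)),

and the next generation's mutant copy number is a binomial draw B(Ne, p).
Each generation's frequency change is decomposed exactly into a selection
component Δs = p - q (a deterministic function of q and f) and a drift
component Δd = q_next - p (the binomial sampling residual), so that
q_next = q + Δs + Δd holds identically.

Two execution paths are provided: :func:`simulate` produces a full
per-generation :class:`Trajectory` for a single run, while
:func:`simulate_batch` advances many replicate populations in lock-step with
numpy and returns per-run summary accumulators (sufficient statistics for
f_G, f_E and C) — the form used by the large replicate experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .regimes import FitnessRegime

__all__ = [
    "SimConfig",
    "Trajectory",
    "BatchResult",
    "wf_step",
    "wf_step_array",
    "fitness_for_delta",
    "simulate",
    "simulate_linear_rule",
    "simulate_batch",
    "LOST",
    "FIXED",
    "CENSORED",
]

# outcome codes shared by Trajectory and BatchResult
LOST, FIXED, CENSORED = 0, 1, 2
_OUTCOME_NAMES = {LOST: "lost", FIXED: "fixed", CENSORED: "censored"}


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one forward simulation.

    Exactly one of ``init_copies`` / ``init_freq`` must be given; a frequency
    must sit on the 1/ne lattice (init_freq * ne integral).  ``max_generations
    = None`` runs until absorption (requires ``stop_on_absorption``).
    """

    ne: int
    regime: FitnessRegime
    init_copies: Optional[int] = None
    init_freq: Optional[float] = None
    max_generations: Optional[int] = None
    seed: int = 0
    stop_on_absorption: bool = True

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if (self.init_copies is None) == (self.init_freq is None):
            raise ValueError("give exactly one of init_copies or init_freq")
        if self.init_freq is not None:
            copies = round(self.init_freq * self.ne)
            if abs(copies - self.init_freq * self.ne) > 1e-9:
                raise ValueError(
                    f"init_freq={self.init_freq} is not a multiple of 1/ne (ne={self.ne})")
            object.__setattr__(self, "init_copies", int(copies))
        if not 0 < self.init_copies < self.ne:
            raise ValueError(
                f"initial copy number must be in [1, ne-1], got {self.init_copies}")
        if self.max_generations is None:
            if not self.stop_on_absorption:
                raise ValueError(
                    "unbounded simulation requires stop_on_absorption=True")
        elif self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    @property
    def q0(self) -> float:
        return self.init_copies / self.ne


# ---------------------------------------------------------------------------
# elementary steps


def _check_step_args(q: float, f: float) -> None:
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"frequency q must lie in [0, 1], got {q}")
    if not f > 0:
        raise ValueError(f"relative fitness must be > 0, got {f}")


def selection_probability(q, f):
    """Post-selection expected frequency p = q f / (1 + q (f - 1))."""
    q = np.asarray(q, dtype=float)
    return q * f / (1.0 + q * (f - 1.0))


def wf_step(q: float, f: float, ne: int,
            rng: np.random.Generator) -> tuple[float, float, float]:
    """Advance one generation; return ``(q_next, delta_s, delta_d)``.

    Boundaries are absorbing: q in {0, 1} returns (q, 0.0, 0.0).  The returned
    components satisfy ``q + delta_s + delta_d == q_next`` exactly (the drift
    residual absorbs the float rounding of the decomposition).
    """
    _check_step_args(q, f)
    if ne < 1:
        raise ValueError("ne must be >= 1")
    if q == 0.0 or q == 1.0:
        return q, 0.0, 0.0
    p = q * f / (1.0 + q * (f - 1.0))
    copies = int(rng.binomial(ne, p))
    q_next = copies / ne
    delta_s, delta_d = _exact_decompose(q, p, q_next)
    return q_next, delta_s, delta_d


def _nudge(x: float, steps: int) -> float:
    for _ in range(abs(steps)):
        x = np.nextafter(x, np.inf if steps > 0 else -np.inf)
    return x


def _exact_decompose(q: float, p: float, q_next: float) -> tuple[float, float]:
    """Split q_next - q into (Δs, Δd) with q + Δs + Δd == q_next bitwise.

    Δs = p - q and Δd = q_next - (q + Δs) already satisfy the identity in
    almost every case; when float rounding leaves a sub-ulp residual, the
    components are nudged by at most two ulps (far below any statistical
    resolution) until left-to-right addition reproduces q_next exactly.
    """
    delta_s = p - q
    for ds_steps in (0, 1, -1, 2, -2):
        ds = _nudge(delta_s, ds_steps)
        base = q_next - (q + ds)
        for dd_steps in (0, 1, -1, 2, -2):
            dd = _nudge(base, dd_steps)
            if q + ds + dd == q_next:
                return ds, dd
    # unreachable in practice; fall back to the canonical split
    return delta_s, q_next - (q + delta_s)


def wf_step_array(q: np.ndarray, f, ne: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`wf_step` over an array of frequencies.

    Used for calibration checks (e.g. one-generation drift variance over many
    replicates).  Boundary entries pass through with zero components.
    """
    q = np.asarray(q, dtype=float)
    f = np.broadcast_to(np.asarray(f, dtype=float), q.shape)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if np.any(f <= 0):
        raise ValueError("relative fitness must be > 0")
    interior = (q > 0) & (q < 1)
    p = np.where(interior, selection_probability(q, f), q)
    copies = np.where(interior, rng.binomial(ne, np.where(interior, p, 0.5)), q * ne)
    q_next = copies / ne
    delta_s = np.where(interior, p - q, 0.0)
    delta_d = np.where(interior, q_next - p, 0.0)
    return q_next, delta_s, delta_d


def fitness_for_delta(q: float, delta: float) -> float:
    """Relative fitness producing an expected selection change Δs = ``delta``.

    Inverts Δs(q, f) = q(1-q)(f-1)/(1+q(f-1)) for f at frequency ``q``:
    f = 1 + delta / (q (1 - q - delta)).  Requires 0 < q < 1 and
    0 < q + delta < 1; outside that band no valid fitness exists.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie strictly in (0, 1), got {q}")
    if not 0.0 < q + delta < 1.0:
        raise ValueError(
            f"no fitness achieves Δs={delta} from q={q}: q+Δs must lie in (0, 1)")
    return 1.0 + delta / (q * (1.0 - q - delta))


# ---------------------------------------------------------------------------
# single-trajectory simulation


@dataclass
class Trajectory:
    """Per-generation record of a single simulated run.

    Arrays are aligned: entry i describes generation ``generation[i]`` (1-based)
    with pre-selection frequency ``q_before[i]``, realized mutant fitness
    ``fitness[i]`` and the exact decomposition
    ``q_after[i] = q_before[i] + delta_s[i] + delta_d[i]``.
    """

    ne: int
    generation: np.ndarray
    q_before: np.ndarray
    fitness: np.ndarray
    delta_s: np.ndarray
    delta_d: np.ndarray
    q_after: np.ndarray
    outcome: str  # "fixed" | "lost" | "censored"

    @property
    def n_generations(self) -> int:
        return len(self.generation)

    @property
    def q0(self) -> float:
        return float(self.q_before[0])

    @property
    def q_final(self) -> float:
        return float(self.q_after[-1])


def _run_single(config: SimConfig, linear: bool) -> Trajectory:
    rng = np.random.default_rng(config.seed)
    regime = config.regime
    state = regime.initial_state(rng)
    ne = config.ne
    q = config.init_copies / ne

    gens: list[int] = []
    q_befores: list[float] = []
    fitnesses: list[float] = []
    ds_list: list[float] = []
    dd_list: list[float] = []
    q_afters: list[float] = []

    gen = 0
    while True:
        if config.max_generations is not None and gen >= config.max_generations:
            outcome = "censored"
            break
        if q == 0.0:
            outcome = "lost"
            break
        if q == 1.0:
            outcome = "fixed"
            break
        gen += 1
        value, state = regime.step(gen, q, state, rng)
        if regime.is_delta_rule:
            try:
                f = fitness_for_delta(q, value)
            except ValueError as exc:
                raise ValueError(f"generation {gen}: {exc}") from exc
        else:
            f = value
        if linear:
            p = min(max(q * f, 0.0), 1.0)
            copies = int(rng.binomial(ne, p))
            q_next = copies / ne
            delta_s, delta_d = _exact_decompose(q, p, q_next)
        else:
            q_next, delta_s, delta_d = wf_step(q, f, ne, rng)
        gens.append(gen)
        q_befores.append(q)
        fitnesses.append(f)
        ds_list.append(delta_s)
        dd_list.append(delta_d)
        q_afters.append(q_next)
        q = q_next
        if config.stop_on_absorption and (q == 0.0 or q == 1.0):
            outcome = "lost" if q == 0.0 else "fixed"
            break

    if not gens:
        raise RuntimeError("simulation produced no generations")
    return Trajectory(
        ne=ne,
        generation=np.asarray(gens, dtype=int),
        q_before=np.asarray(q_befores, dtype=float),
        fitness=np.asarray(fitnesses, dtype=float),
        delta_s=np.asarray(ds_list, dtype=float),
        delta_d=np.asarray(dd_list, dtype=float),
        q_after=np.asarray(q_afters, dtype=float),
        outcome=outcome,
    )


def simulate(config: SimConfig) -> Trajectory:
    """Simulate one trajectory under the standard Wright–Fisher update."""
    return _run_single(config, linear=False)


def simulate_linear_rule(config: SimConfig) -> Trajectory:
    """Simulate under the hypothetical linear rule E(q') = f q.

    The sampling probability is p = clamp(q f, 0, 1), so Δs = (f - 1) q away
    from the clamp.  This removes the nonlinearity of the standard update and
    serves as the control showing that the geometric-mean-fitness bias comes
    from that nonlinearity alone.
    """
    return _run_single(config, linear=True)


# ---------------------------------------------------------------------------
# vectorized batch simulation


@dataclass
class BatchResult:
    """Per-run summary accumulators for a batch of replicate simulations.

    ``n_generations`` counts generations actually experienced (simulation of a
    run stops at absorption).  ``sum_delta_d`` is derived from the drift-sum
    identity ΣΔd = (q_final - q0) - ΣΔs, which holds exactly by construction.
    """

    ne: int
    init_copies: int
    final_copies: np.ndarray   # int
    sum_delta_s: np.ndarray    # float
    sum_log_fitness: np.ndarray
    n_generations: np.ndarray  # int
    outcome: np.ndarray        # int8: LOST / FIXED / CENSORED

    @property
    def n_runs(self) -> int:
        return len(self.final_copies)

    @property
    def q0(self) -> float:
        return self.init_copies / self.ne

    @property
    def final_freq(self) -> np.ndarray:
        return self.final_copies / self.ne

    @property
    def sum_delta_d(self) -> np.ndarray:
        return (self.final_freq - self.q0) - self.sum_delta_s

    @property
    def mean_delta_s(self) -> np.ndarray:
        return self.sum_delta_s / self.n_generations

    @property
    def f_g(self) -> np.ndarray:
        """Geometric mean fitness over the generations experienced."""
        return np.exp(self.sum_log_fitness / self.n_generations)

    @property
    def f_e(self) -> np.ndarray:
        """Effective fitness (0.5 + Δ̄s) / (0.5 - Δ̄s)."""
        m = self.mean_delta_s
        return (0.5 + m) / (0.5 - m)

    @property
    def c(self) -> np.ndarray:
        """Relative selection effect; NaN where ΣΔs and ΣΔd are both zero."""
        s, d = self.sum_delta_s, self.sum_delta_d
        denom = np.abs(s) + np.abs(d)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), np.nan)

    @property
    def outcome_names(self) -> np.ndarray:
        return np.array([_OUTCOME_NAMES[o] for o in self.outcome])


def simulate_batch(
    ne: int,
    init_copies: int,
    regime: FitnessRegime,
    n_runs: int,
    *,
    n_generations: Optional[int] = None,
    max_generations: int = 200_000,
    rule: str = "wf",
    rng: Union[int, np.random.Generator, None] = 0,
) -> BatchResult:
    """Advance ``n_runs`` replicate populations in lock-step.

    With ``n_generations`` set, every run is simulated for that fixed horizon
    (runs absorbed earlier stop accumulating and keep their absorbed state);
    otherwise runs continue to absorption, with ``max_generations`` as a
    safety cap (survivors are marked censored).

    ``rule`` selects the update: ``"wf"`` (standard) or ``"linear"``
    (p = clamp(q f, 0, 1)).  For Δs-schedule (``target_delta``) regimes the
    sampling probability is p = clamp(q + Δs, 0, 1) and the implied fitness is
    recovered from the realized Δs for bookkeeping; the clamp can only engage
    within Δs of a boundary.

    ``rng`` may be a seed or an existing Generator (consumed sequentially, so
    chunked collections are deterministic given one seed).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not 0 < init_copies < ne:
        raise ValueError("init_copies must be in [1, ne-1]")
    if rule not in ("wf", "linear"):
        raise ValueError(f"unknown update rule {rule!r}")
    horizon = n_generations if n_generations is not None else max_generations

    final = np.full(n_runs, init_copies, dtype=np.int64)
    sum_ds = np.zeros(n_runs)
    sum_logf = np.zeros(n_runs)
    ngen = np.zeros(n_runs, dtype=np.int64)
    outcome = np.full(n_runs, CENSORED, dtype=np.int8)

    idx = np.arange(n_runs)  # positions of still-active runs
    copies = np.full(n_runs, init_copies, dtype=np.int64)
    state = regime.batch_initial_state(n_runs, rng)

    gen = 0
    while idx.size and gen < horizon:
        gen += 1
        q = copies / ne
        value = regime.batch_fitness(gen, q, state, rng)
        if regime.is_delta_rule:
            p = np.clip(q + value, 0.0, 1.0)
            ds = p - q
            with np.errstate(divide="ignore", invalid="ignore"):
                f = 1.0 + ds / (q * (1.0 - q - ds))
        elif rule == "linear":
            f = value
            p = np.clip(q * f, 0.0, 1.0)
            ds = p - q
        else:
            f = value
            p = selection_probability(q, f)
            ds = p - q
        new_copies = rng.binomial(ne, p)
        sum_ds[idx] += ds
        with np.errstate(divide="ignore"):
            sum_logf[idx] += np.log(f)
        ngen[idx] += 1
        final[idx] = new_copies

        absorbed = (new_copies == 0) | (new_copies == ne)
        if absorbed.any():
            done = idx[absorbed]
            outcome[done] = np.where(new_copies[absorbed] == 0, LOST, FIXED)
            keep = ~absorbed
            idx = idx[keep]
            copies = new_copies[keep]
            state = regime.batch_take(state, keep)
        else:
            copies = new_copies

    return BatchResult(
        ne=ne,
        init_copies=init_copies,
        final_copies=final,
        sum_delta_s=sum_ds,
        sum_log_fitness=sum_logf,
        n_generations=ngen,
        outcome=outcome,
    )
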
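"""Fitness regimes: rules assigning the mutant's relative fitness each generation.

A regime maps (generation index, current frequency, regime state, randomness)
to the mutant's relative fitness for that generation.  Generation indices are
1-based: the first generation of selection is generation 1.

Every regime supports two execution paths:

* a scalar path used by :func:`effsel.wfsim.simulate` (one trajectory at a
  time), via :meth:`FitnessRegime.initial_state` / :meth:`FitnessRegime.step`;
* a vectorized path used by :func:`effsel.wfsim.simulate_batch` (many replicate
  populations in lock-step), via ``batch_initial_state`` / ``batch_fitness`` /
  ``batch_take``.

``target_delta`` regimes are special: they specify the per-generation
selection-driven frequency change Δs directly rather than a fitness value
(``is_delta_rule`` is True); the simulator converts Δs to a sampling
probability and, where needed, back to an implied fitness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = [
    "FitnessRegime",
    "ConstantFitness",
    "BlockFitness",
    "AlternatingFitness",
    "MarkovSwitchFitness",
    "PoissonBlockFitness",
    "FrequencyDependentFitness",
    "TargetDeltaFitness",
    "regime_from_dict",
]


def _check_positive(name: str, *values: float) -> None:
    for v in values:
        if not (v > 0) or not np.isfinite(v):
            raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")


@dataclass(frozen=True)
class FitnessRegime:
    """Base class; subclasses implement the scalar and vectorized protocols."""

    kind = "abstract"
    is_delta_rule = False

    # -- scalar path ---------------------------------------------------------
    def initial_state(self, rng: np.random.Generator) -> Any:
        return None

    def step(self, gen: int, q: float, state: Any, rng: np.random.Generator):
        """Return ``(fitness_or_delta, new_state)`` for generation ``gen``."""
        raise NotImplementedError

    # -- vectorized path -----------------------------------------------------
    def batch_initial_state(self, n: int, rng: np.random.Generator) -> Any:
        return None

    def batch_fitness(self, gen: int, q: np.ndarray, state: Any,
                      rng: np.random.Generator) -> np.ndarray:
        """Return fitness (or Δs) for each of ``len(q)`` active populations.

        ``state`` is mutated in place where the regime is stateful.
        """
        raise NotImplementedError

    def batch_take(self, state: Any, keep: np.ndarray) -> Any:
        """Subset regime state to the populations selected by ``keep``."""
        return None if state is None else state


@dataclass(frozen=True)
class ConstantFitness(FitnessRegime):
    """Constant relative fitness ``f`` in every generation."""

    f: float = 1.0
    kind = "constant"

    def __post_init__(self) -> None:
        _check_positive("f", self.f)

    def step(self, gen, q, state, rng):
        return self.f, state

    def batch_fitness(self, gen, q, state, rng):
        return np.full(q.shape, self.f)


@dataclass(frozen=True)
class BlockFitness(FitnessRegime):
    """Fitness ``f1`` until generation ``n_switch``, then ``f2``.

    ``n_switch`` is the generation at which the fitness changes: generations
    ``1 .. n_switch-1`` use ``f1`` and generations ``>= n_switch`` use ``f2``.
    A mutant with fitness 5/6 for the first n generations and 6/5 for the next
    n is ``BlockFitness(5/6, 6/5, n_switch=n + 1)``.
    """

    f1: float
    f2: float
    n_switch: int
    kind = "block"

    def __post_init__(self) -> None:
        _check_positive("f1, f2", self.f1, self.f2)
        if self.n_switch < 1:
            raise ValueError("n_switch must be >= 1")

    def _f(self, gen: int) -> float:
        return self.f1 if gen < self.n_switch else self.f2

    def step(self, gen, q, state, rng):
        return self._f(gen), state

    def batch_fitness(self, gen, q, state, rng):
        return np.full(q.shape, self._f(gen))


@dataclass(frozen=True)
class AlternatingFitness(FitnessRegime):
    """``f_odd`` in generations 1, 3, 5, ... and ``f_even`` in 2, 4, 6, ..."""

    f_odd: float
    f_even: float
    kind = "alternating"

    def __post_init__(self) -> None:
        _check_positive("f_odd, f_even", self.f_odd, self.f_even)

    def _f(self, gen: int) -> float:
        return self.f_odd if gen % 2 == 1 else self.f_even

    def step(self, gen, q, state, rng):
        return self._f(gen), state

    def batch_fitness(self, gen, q, state, rng):
        return np.full(q.shape, self._f(gen))


@dataclass(frozen=True)
class MarkovSwitchFitness(FitnessRegime):
    """Two-state Markov regime: fitness switches between ``f1`` and ``f2``.

    The initial state is uniform over {f1, f2}; each generation, before
    selection acts, the state flips with probability ``switch_prob``.  With
    switch_prob = 0.05 the waiting time between switches is geometric with
    mean 20 generations.
    """

    f1: float
    f2: float
    switch_prob: float = 0.05
    kind = "markov_switch"

    def __post_init__(self) -> None:
        _check_positive("f1, f2", self.f1, self.f2)
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")

    # state: bool, True means "currently f1"
    def initial_state(self, rng):
        return bool(rng.random() < 0.5)

    def step(self, gen, q, state, rng):
        if rng.random() < self.switch_prob:
            state = not state
        return (self.f1 if state else self.f2), state

    def batch_initial_state(self, n, rng):
        return {"in_f1": rng.random(n) < 0.5}

    def batch_fitness(self, gen, q, state, rng):
        flip = rng.random(len(q)) < self.switch_prob
        state["in_f1"] = state["in_f1"] ^ flip
        return np.where(state["in_f1"], self.f1, self.f2)

    def batch_take(self, state, keep):
        return {"in_f1": state["in_f1"][keep]}


@dataclass(frozen=True)
class PoissonBlockFitness(FitnessRegime):
    """Variant of the switching regime with Poisson-distributed dwell times.

    The fitness holds its current value for t generations, where t is drawn
    from a Poisson distribution with mean ``mean_block`` (draws of 0 are
    bumped to 1 so a state is always expressed for at least one generation),
    then flips between ``f1`` and ``f2``.  Initial state uniform over the two.
    """

    f1: float
    f2: float
    mean_block: float = 20.0
    kind = "poisson_block"

    def __post_init__(self) -> None:
        _check_positive("f1, f2, mean_block", self.f1, self.f2, self.mean_block)

    def _draw_dwell(self, rng, size=None):
        t = rng.poisson(self.mean_block, size)
        if size is None:
            return max(int(t), 1)
        return np.maximum(t, 1)

    def initial_state(self, rng):
        return [bool(rng.random() < 0.5), self._draw_dwell(rng)]

    def step(self, gen, q, state, rng):
        in_f1, left = state
        if left <= 0:
            in_f1 = not in_f1
            left = self._draw_dwell(rng)
        return (self.f1 if in_f1 else self.f2), [in_f1, left - 1]

    def batch_initial_state(self, n, rng):
        return {"in_f1": rng.random(n) < 0.5, "left": self._draw_dwell(rng, n)}

    def batch_fitness(self, gen, q, state, rng):
        expired = state["left"] <= 0
        if expired.any():
            state["in_f1"] = state["in_f1"] ^ expired
            state["left"] = np.where(
                expired, self._draw_dwell(rng, len(q)), state["left"])
        state["left"] = state["left"] - 1
        return np.where(state["in_f1"], self.f1, self.f2)

    def batch_take(self, state, keep):
        return {"in_f1": state["in_f1"][keep], "left": state["left"][keep]}


@dataclass(frozen=True)
class FrequencyDependentFitness(FitnessRegime):
    """Fitness ``f_low`` while the mutant frequency is below ``threshold``,
    otherwise ``f_high``.

    The worked frequency-dependent scenario uses f_low=1.01 (favoured while
    rare or intermediate), f_high=0.9 (disfavoured near fixation) and
    threshold 0.99.
    """

    f_low: float
    f_high: float
    threshold: float
    kind = "frequency_dependent"

    def __post_init__(self) -> None:
        _check_positive("f_low, f_high", self.f_low, self.f_high)
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def step(self, gen, q, state, rng):
        return (self.f_low if q < self.threshold else self.f_high), state

    def batch_fitness(self, gen, q, state, rng):
        return np.where(q < self.threshold, self.f_low, self.f_high)


@dataclass(frozen=True)
class TargetDeltaFitness(FitnessRegime):
    """Regime specified by a per-generation target Δs schedule.

    The rule for generation i is "apply whatever fitness produces an expected
    selection-driven frequency change of ``delta_schedule[i-1]`` from the
    current frequency".  The implied fitness is recomputed from the current
    frequency every generation, so the realized Δs equals the schedule
    regardless of where drift has moved the frequency.
    """

    delta_schedule: tuple[float, ...]
    kind = "target_delta"
    is_delta_rule = True

    def __init__(self, delta_schedule) -> None:
        object.__setattr__(self, "delta_schedule", tuple(float(d) for d in delta_schedule))
        if not self.delta_schedule:
            raise ValueError("delta_schedule must be nonempty")

    def _delta(self, gen: int) -> float:
        if gen > len(self.delta_schedule):
            raise IndexError(
                f"delta_schedule has {len(self.delta_schedule)} entries; "
                f"no target Δs for generation {gen}")
        return self.delta_schedule[gen - 1]

    def step(self, gen, q, state, rng):
        return self._delta(gen), state

    def batch_fitness(self, gen, q, state, rng):
        return np.full(q.shape, self._delta(gen))


_REGIME_KINDS = {
    "constant": ConstantFitness,
    "block": BlockFitness,
    "alternating": AlternatingFitness,
    "markov_switch": MarkovSwitchFitness,
    "poisson_block": PoissonBlockFitness,
    "frequency_dependent": FrequencyDependentFitness,
    "target_delta": TargetDeltaFitness,
}


def regime_from_dict(spec: dict) -> FitnessRegime:
    """Build a regime from a ``{"kind": ..., <params>}`` mapping (config files)."""
    spec = dict(spec)
    try:
        kind = spec.pop("kind")
    except KeyError:
        raise ValueError("regime spec requires a 'kind' key") from None
    try:
        cls = _REGIME_KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown regime kind {kind!r}; expected one of {sorted(_REGIME_KINDS)}"
        ) from None
    try:
        return cls(**spec)
    except TypeError as exc:
        raise ValueError(f"bad parameters for regime {kind!r}: {exc}") from None
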
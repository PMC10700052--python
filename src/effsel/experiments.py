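"""Batch simulation experiments comparing f_G- and f_E-based inference.

Four reusable drivers, each returning an :class:`ExperimentResult` with a
primary summary table, optional per-run detail tables, and the seed it was
run with:

* :func:`run_fg1_fe1_experiment` — 2n generations of balanced selection with
  f_G = 1 (block or alternating 5/6 vs 6/5; also under the hypothetical
  linear update rule) or f_E = 1 (Δs = -0.045 then +0.045), testing whether
  the mean final frequency stays at the initial 0.5;
* :func:`run_conditional_frequency_experiment` — conditioning 200-generation
  Markov-switching runs on an exact final frequency and scoring the q_G / q_E
  back-predictions by bias, variance and MSE;
* :func:`run_outcome_prediction_experiment` — ROC/AUC of f_E vs f_G as
  predictors of fixation, plus the contradiction subsets (f_E > 1 & f_G < 1
  and vice versa);
* :func:`run_new_mutation_experiment` — fate of a single-copy mutant; C, f_E
  and f_G distributions at fixation/loss and effective-neutrality fractions.

Replicate quotas are configurable so every driver has a scaled-down preset
suitable for quick runs; the statistical claims are directional and survive
the scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .regimes import FitnessRegime, AlternatingFitness, BlockFitness, \
    MarkovSwitchFitness, TargetDeltaFitness
from .wfsim import BatchResult, FIXED, LOST, simulate_batch

__all__ = [
    "ExperimentResult",
    "default_markov_regime",
    "auc_mann_whitney",
    "run_fg1_fe1_experiment",
    "run_conditional_frequency_experiment",
    "run_outcome_prediction_experiment",
    "run_new_mutation_experiment",
    "FG1_FE1_SCENARIOS",
]

#: Fluctuating-selection parameters used by default in the switching
#: experiments: fitness 11/10 or 10/11, per-generation switch probability 0.05.
def default_markov_regime() -> MarkovSwitchFitness:
    return MarkovSwitchFitness(f1=11 / 10, f2=10 / 11, switch_prob=0.05)


@dataclass
class ExperimentResult:
    """Aggregate output of one named experiment."""

    name: str
    params: dict
    seed: int
    table: pd.DataFrame
    details: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ROC / AUC


def auc_mann_whitney(scores, positive) -> float:
    """AUC via the rank-sum (Mann–Whitney) statistic with midrank ties.

    ``positive`` is a boolean mask of the positive class (fixation).  Equals
    the probability that a random positive outscores a random negative, ties
    counted half.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n1 = int(positive.sum())
    n0 = len(scores) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = stats.rankdata(scores)
    u = float(ranks[positive].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


# ---------------------------------------------------------------------------
# experiment 1: f_G = 1 / f_E = 1 over 2n generations

FG1_FE1_SCENARIOS = ("block_fg1", "alternating_fg1", "linear_fg1", "block_fe1")


def _fg1_fe1_setup(scenario: str, n: int) -> tuple[FitnessRegime, str]:
    if scenario == "block_fg1":
        return BlockFitness(5 / 6, 6 / 5, n_switch=n + 1), "wf"
    if scenario == "alternating_fg1":
        return AlternatingFitness(f_odd=5 / 6, f_even=6 / 5), "wf"
    if scenario == "linear_fg1":
        return BlockFitness(5 / 6, 6 / 5, n_switch=n + 1), "linear"
    if scenario == "block_fe1":
        return TargetDeltaFitness([-0.045] * n + [0.045] * n), "wf"
    raise ValueError(
        f"unknown scenario {scenario!r}; expected one of {FG1_FE1_SCENARIOS}")


def run_fg1_fe1_experiment(
    scenario: str,
    n_values: Sequence[int] = range(1, 8),
    reps: int = 500_000,
    ne: int = 1000,
    init_freq: float = 0.5,
    seed: int = 0,
) -> ExperimentResult:
    """Balanced-selection experiment: does the mean frequency return to q0?

    For each n, simulates ``reps`` runs of 2n generations, discards (but
    counts) runs absorbed before generation 2n, and reports the mean final
    frequency with 95% CI and a two-sided one-sample t-test against the
    initial frequency.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    init_copies = round(init_freq * ne)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        regime, rule = _fg1_fe1_setup(scenario, int(n))
        horizon = 2 * int(n)
        res = simulate_batch(ne, init_copies, regime, reps,
                             n_generations=horizon, rule=rule, rng=rng)
        discarded = (res.outcome != 2) & (res.n_generations < horizon)
        kept = ~discarded
        final = res.final_freq[kept]
        mean = float(final.mean())
        sem = float(final.std(ddof=1) / math.sqrt(len(final)))
        t_stat, p_value = stats.ttest_1samp(final, init_freq)
        rows.append({
            "scenario": scenario,
            "n": int(n),
            "reps": reps,
            "n_discarded": int(discarded.sum()),
            "n_kept": int(kept.sum()),
            "mean_final_freq": mean,
            "mean_final_count": mean * ne,
            "ci95_low": mean - 1.96 * sem,
            "ci95_high": mean + 1.96 * sem,
            "t_stat": float(t_stat),
            "p_value": float(p_value),
            "significant": bool(p_value < 0.05),
        })
    table = pd.DataFrame(rows)
    return ExperimentResult(
        name=f"fg1_fe1:{scenario}",
        params={"scenario": scenario, "n_values": list(map(int, n_values)),
                "reps": reps, "ne": ne, "init_freq": init_freq},
        seed=seed, table=table)


# ---------------------------------------------------------------------------
# shared collection helpers


def _batch_frame(res: BatchResult, offset: int) -> pd.DataFrame:
    """Per-run statistics of a batch, keeping the global run order."""
    return pd.DataFrame({
        "run": np.arange(offset, offset + res.n_runs),
        "final_copies": res.final_copies,
        "final_freq": res.final_freq,
        "n_generations": res.n_generations,
        "sum_delta_s": res.sum_delta_s,
        "sum_delta_d": res.sum_delta_d,
        "f_g": res.f_g,
        "f_e": res.f_e,
        "c": res.c,
        "outcome": res.outcome,
    })


# ---------------------------------------------------------------------------
# experiment 2: conditioning on an exact final frequency


def run_conditional_frequency_experiment(
    final_freqs: Sequence[float] = tuple(np.round(np.arange(1, 10) / 10, 10)),
    n_runs_per_bin: int = 500,
    ne: int = 1000,
    init_freq: float = 0.01,
    generations: int = 200,
    regime: Optional[FitnessRegime] = None,
    seed: int = 0,
    chunk_size: int = 20_000,
    max_attempts: int = 5_000_000,
) -> ExperimentResult:
    """Score q_G / q_E back-predictions on runs conditioned on final frequency.

    Simulates ``generations``-long runs under the switching regime and, for
    each target frequency, takes the first ``n_runs_per_bin`` runs (in global
    run order, which a single seed makes well-defined) whose final copy count
    equals ``round(target * ne)`` exactly.  For each bin and predictor the
    table reports bias, bias², variance (population) and MSE, which satisfy
    MSE = bias² + variance identically.
    """
    if regime is None:
        regime = default_markov_regime()
    init_copies = round(init_freq * ne)
    targets = [int(round(t * ne)) for t in final_freqs]
    if any(abs(t * ne - round(t * ne)) > 1e-9 for t in final_freqs):
        raise ValueError("target frequencies must be multiples of 1/ne")
    quota = {t: n_runs_per_bin for t in targets}
    collected: dict[int, list[pd.DataFrame]] = {t: [] for t in targets}
    counts = {t: 0 for t in targets}

    rng = np.random.default_rng(seed)
    attempts = 0
    while any(counts[t] < quota[t] for t in targets) and n_runs_per_bin > 0:
        if attempts >= max_attempts:
            fill = {t / ne: counts[t] for t in targets}
            raise RuntimeError(
                f"conditional bins unfilled after {attempts} runs "
                f"(quota {n_runs_per_bin} per bin; filled: {fill})")
        res = simulate_batch(ne, init_copies, regime, chunk_size,
                             n_generations=generations, rng=rng)
        frame = _batch_frame(res, attempts)
        attempts += chunk_size
        for t in targets:
            short = quota[t] - counts[t]
            if short <= 0:
                continue
            hits = frame[frame["final_copies"] == t].head(short)
            if len(hits):
                collected[t].append(hits)
                counts[t] += len(hits)

    rows = []
    detail_frames = []
    for t in targets:
        target_freq = t / ne
        runs = (pd.concat(collected[t], ignore_index=True)
                if collected[t] else pd.DataFrame())
        if len(runs) == 0:
            rows.append({"target_freq": target_freq, "predictor": "f_e", "n": 0})
            rows.append({"target_freq": target_freq, "predictor": "f_g", "n": 0})
            continue
        # vectorized forms of predict_freq_from_fe / predict_freq_from_fg
        # (the scalar functions warn on out-of-[0,1] predictions, which are
        # routine and intentional here: the linear predictor is unclamped)
        fe = runs["f_e"].to_numpy()
        fg = runs["f_g"].to_numpy()
        q_e = init_freq + generations * (fe - 1.0) / (2.0 * (fe + 1.0))
        ratio = init_freq / (1.0 - init_freq) * fg ** generations
        q_g = ratio / (1.0 + ratio)
        runs = runs.assign(target_freq=target_freq, q_e=q_e, q_g=q_g)
        detail_frames.append(runs)
        for predictor, pred in (("f_e", q_e), ("f_g", q_g)):
            errors = pred - target_freq
            bias = float(errors.mean())
            variance = float(errors.var(ddof=0))
            rows.append({
                "target_freq": target_freq,
                "predictor": predictor,
                "n": len(pred),
                "bias": bias,
                "bias2": bias ** 2,
                "variance": variance,
                "mse": float(np.mean(errors ** 2)),
            })
    details = {}
    if detail_frames:
        details["runs"] = pd.concat(detail_frames, ignore_index=True)
    return ExperimentResult(
        name="conditional_frequency",
        params={"final_freqs": list(map(float, final_freqs)),
                "n_runs_per_bin": n_runs_per_bin, "ne": ne,
                "init_freq": init_freq, "generations": generations,
                "regime": regime.kind, "attempts": attempts},
        seed=seed, table=pd.DataFrame(rows), details=details)


# ---------------------------------------------------------------------------
# experiments 3 & 4: outcome collection to absorption


def _resolve_init(init: Union[str, float], ne: int) -> int:
    if init == "single_copy":
        return 1
    copies = round(float(init) * ne)
    if abs(copies - float(init) * ne) > 1e-9:
        raise ValueError("initial frequency must be a multiple of 1/ne")
    return int(copies)


def _collect_outcomes(
    ne: int,
    init_copies: int,
    regime: FitnessRegime,
    n_fixed: int,
    n_lost: int,
    rng: np.random.Generator,
    chunk_size: int,
    max_generations: int,
    max_attempts: int,
) -> tuple[pd.DataFrame, int, int]:
    """First ``n_fixed`` fixations and ``n_lost`` losses, in global run order."""
    fixed_frames: list[pd.DataFrame] = []
    lost_frames: list[pd.DataFrame] = []
    got_fixed = got_lost = 0
    attempts = censored = 0
    while got_fixed < n_fixed or got_lost < n_lost:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"outcome quotas unfilled after {attempts} runs "
                f"(fixed {got_fixed}/{n_fixed}, lost {got_lost}/{n_lost})")
        res = simulate_batch(ne, init_copies, regime, chunk_size,
                             max_generations=max_generations, rng=rng)
        frame = _batch_frame(res, attempts)
        attempts += chunk_size
        censored += int((res.outcome == 2).sum())
        if got_fixed < n_fixed:
            hits = frame[frame["outcome"] == FIXED].head(n_fixed - got_fixed)
            fixed_frames.append(hits)
            got_fixed += len(hits)
        if got_lost < n_lost:
            hits = frame[frame["outcome"] == LOST].head(n_lost - got_lost)
            lost_frames.append(hits)
            got_lost += len(hits)
    runs = pd.concat(fixed_frames + lost_frames, ignore_index=True)
    runs["fixed"] = runs["outcome"] == FIXED
    return runs, attempts, censored


def _contradiction_table(runs: pd.DataFrame) -> pd.DataFrame:
    subsets = {
        "fe_gt1_fg_lt1": (runs["f_e"] > 1) & (runs["f_g"] < 1),
        "fe_lt1_fg_gt1": (runs["f_e"] < 1) & (runs["f_g"] > 1),
    }
    rows = []
    for name, mask in subsets.items():
        sub = runs[mask]
        rows.append({
            "subset": name,
            "n": len(sub),
            "n_fixed": int(sub["fixed"].sum()),
            "n_lost": int((~sub["fixed"]).sum()),
        })
    return pd.DataFrame(rows)


def _collect_contradictions(
    ne: int,
    init_copies: int,
    regime: FitnessRegime,
    quota: int,
    rng: np.random.Generator,
    chunk_size: int,
    max_generations: int,
    max_attempts: int,
) -> tuple[pd.DataFrame, int]:
    """First ``quota`` runs per contradiction category, regardless of outcome."""
    frames: dict[str, list[pd.DataFrame]] = {"fe_gt1_fg_lt1": [], "fe_lt1_fg_gt1": []}
    got = {k: 0 for k in frames}
    attempts = 0
    while any(got[k] < quota for k in frames):
        if attempts >= max_attempts:
            raise RuntimeError(
                f"contradiction quotas unfilled after {attempts} runs ({got})")
        res = simulate_batch(ne, init_copies, regime, chunk_size,
                             max_generations=max_generations, rng=rng)
        frame = _batch_frame(res, attempts)
        attempts += chunk_size
        frame = frame[frame["outcome"] != 2]
        masks = {
            "fe_gt1_fg_lt1": (frame["f_e"] > 1) & (frame["f_g"] < 1),
            "fe_lt1_fg_gt1": (frame["f_e"] < 1) & (frame["f_g"] > 1),
        }
        for key, mask in masks.items():
            short = quota - got[key]
            if short <= 0:
                continue
            hits = frame[mask].head(short).assign(subset=key)
            frames[key].append(hits)
            got[key] += len(hits)
    runs = pd.concat([f for fl in frames.values() for f in fl], ignore_index=True)
    runs["fixed"] = runs["outcome"] == FIXED
    return runs, attempts


def run_outcome_prediction_experiment(
    init: Union[str, float] = 0.01,
    n_fixed: int = 5000,
    n_lost: int = 5000,
    ne: int = 1000,
    regime: Optional[FitnessRegime] = None,
    seed: int = 0,
    chunk_size: int = 20_000,
    max_generations: int = 200_000,
    max_attempts: int = 50_000_000,
    contradiction_quota: Optional[int] = None,
    contradiction_init: Union[str, float] = 0.5,
) -> ExperimentResult:
    """AUC of f_E vs f_G as predictors of fixation, plus contradiction subsets.

    ``init`` is ``"single_copy"`` or an initial frequency on the 1/ne lattice.
    AUC uses the midrank Mann–Whitney statistic with fixation as the positive
    class, over the first ``n_fixed`` fixations and ``n_lost`` losses.

    Contradiction subsets are the runs where the two summaries disagree:
    f_E > 1 & f_G < 1 (expected majority fixed) and f_E < 1 & f_G > 1
    (expected majority lost).  ``details["contradictions"]`` tabulates them
    within the AUC collection; when ``contradiction_quota`` is set, a separate
    collection gathers that many runs *per category* — sampling on the
    condition itself, not on the outcome — starting from
    ``contradiction_init`` (default 0.5, where fixations and losses are
    balanced and the disagreement analysis is informative), reported in
    ``details["contradictions_conditional"]``.
    """
    if min(n_fixed, n_lost) < 1:
        raise ValueError("n_fixed and n_lost must be >= 1")
    if regime is None:
        regime = default_markov_regime()
    init_copies = _resolve_init(init, ne)
    rng = np.random.default_rng(seed)
    runs, attempts, censored = _collect_outcomes(
        ne, init_copies, regime, n_fixed, n_lost, rng,
        chunk_size, max_generations, max_attempts)

    rows = [{
        "score": name,
        "auc": auc_mann_whitney(runs[col], runs["fixed"]),
        "n_fixed": n_fixed,
        "n_lost": n_lost,
    } for name, col in (("f_e", "f_e"), ("f_g", "f_g"))]

    details = {"runs": runs, "contradictions": _contradiction_table(runs)}
    params = {"init": init, "n_fixed": n_fixed, "n_lost": n_lost, "ne": ne,
              "regime": regime.kind, "attempts": attempts,
              "censored": censored}
    if contradiction_quota is not None and contradiction_quota > 0:
        c_runs, c_attempts = _collect_contradictions(
            ne, _resolve_init(contradiction_init, ne), regime,
            contradiction_quota, rng, chunk_size, max_generations,
            max_attempts)
        details["contradiction_runs"] = c_runs
        details["contradictions_conditional"] = _contradiction_table(c_runs)
        params["contradiction_quota"] = contradiction_quota
        params["contradiction_init"] = contradiction_init
        params["contradiction_attempts"] = c_attempts
    return ExperimentResult(
        name="outcome_prediction",
        params=params,
        seed=seed,
        table=pd.DataFrame(rows),
        details=details)


def run_new_mutation_experiment(
    ne: int = 1000,
    n_fixed: int = 5000,
    n_lost: int = 5000,
    neutrality_cutoff: float = 0.05,
    regime: Optional[FitnessRegime] = None,
    seed: int = 0,
    chunk_size: int = 50_000,
    max_generations: int = 200_000,
    max_attempts: int = 100_000_000,
) -> ExperimentResult:
    """Fate of a newly arisen single-copy mutant under fluctuating selection.

    Collects ``n_lost`` losses and ``n_fixed`` fixations (``n_fixed`` may be 0
    when only loss statistics are needed) and reports, per outcome class, the
    fractions |C| < 0.5, |C| < cutoff (effective neutrality), C > 0.5 and
    f_E > 1, with distribution summaries; ``details["runs"]`` holds the
    violin-plot-ready long table of per-run C, f_E, f_G values.
    """
    if regime is None:
        regime = default_markov_regime()
    if n_lost < 1:
        raise ValueError("n_lost must be >= 1")
    rng = np.random.default_rng(seed)
    runs, attempts, censored = _collect_outcomes(
        ne, 1, regime, n_fixed, n_lost, rng,
        chunk_size, max_generations, max_attempts)

    rows = []
    for label, mask in (("lost", ~runs["fixed"]), ("fixed", runs["fixed"])):
        sub = runs[mask]
        if len(sub) == 0:
            continue
        c = sub["c"].to_numpy()
        defined = ~np.isnan(c)
        cd = c[defined]
        n_def = len(cd)
        rows.append({
            "outcome": label,
            "n": len(sub),
            "n_undefined_c": int((~defined).sum()),
            "frac_abs_c_lt_0.5": float((np.abs(cd) < 0.5).mean()) if n_def else np.nan,
            "frac_neutral": float((np.abs(cd) < neutrality_cutoff).mean()) if n_def else np.nan,
            "frac_c_gt_0.5": float((cd > 0.5).mean()) if n_def else np.nan,
            "frac_fe_gt_1": float((sub["f_e"] > 1).mean()),
            "mean_c": float(np.mean(cd)) if n_def else np.nan,
            "median_c": float(np.median(cd)) if n_def else np.nan,
            "mean_f_e": float(sub["f_e"].mean()),
            "mean_f_g": float(sub["f_g"].mean()),
            "mean_generations": float(sub["n_generations"].mean()),
        })
    return ExperimentResult(
        name="new_mutation",
        params={"ne": ne, "n_fixed": n_fixed, "n_lost": n_lost,
                "neutrality_cutoff": neutrality_cutoff, "regime": regime.kind,
                "attempts": attempts, "censored": censored},
        seed=seed,
        table=pd.DataFrame(rows),
        details={"runs": runs})
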
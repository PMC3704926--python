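"""Experiment protocols: steady-state runs, modifier invasions, and sweeps.

Two kinds of simulation are supported.

*Steady-state runs* evolve a population that is homogeneous at the modifier
locus until mean fitness and heterozygosity reach mutation-selection balance,
detected by a sliding-window flatness test, and report plateau statistics.

*Invasion runs* introduce a second modifier allele at a low exact-count
frequency into an equilibrated resident population and iterate generations
until the invader fixes, goes extinct, or a generation cap is reached.
Invasion success is judged against the neutral expectation (a neutral allele
fixes with probability equal to its initial frequency) with a one-sided exact
binomial test over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demes import (
    Population,
    init_population,
    population_summary,
    records_to_frame,
)
from .genome import GeneticParams, ModifierAllele, Strategy
from .lifecycle import DispersalParams, step_generation

__all__ = [
    "SteadyStateConfig",
    "SteadyStateResult",
    "InvasionConfig",
    "InvasionResult",
    "run_steady_state",
    "run_invasion",
    "takeover_time",
    "exact_binomial_test",
    "classify_invasion_outcomes",
    "run_parameter_sweep",
]


@dataclass(frozen=True)
class SteadyStateConfig:
    """Convergence rule for mutation-selection balance.

    The population is considered at steady state once the linear-regression
    slopes of mean fitness and of the heterozygosity fraction over the last
    ``window`` generations are statistically indistinguishable from zero
    (two-sided p >= ``level``), after at least ``min_gens`` generations of
    burn-in; the run stops unconditionally at ``max_gens``.
    """

    min_gens: int = 2000
    max_gens: int = 20000
    window: int = 500
    check_every: int = 100
    level: float = 0.05

    def __post_init__(self) -> None:
        if self.window < 10:
            raise ValueError("window must be >= 10")
        if self.min_gens < self.window:
            raise ValueError("min_gens must cover at least one window")
        if self.max_gens < self.min_gens:
            raise ValueError("max_gens must be >= min_gens")


@dataclass
class SteadyStateResult:
    population: Population
    records: list
    converged: bool
    n_generations: int
    plateau_mean_fitness: float
    plateau_mean_fitness_se: float
    plateau_het: float
    plateau_het_se: float
    #: plateau of the dispersal-mortality-adjusted mean fitness
    plateau_mean_fitness_cost: float = float("nan")
    plateau_mean_fitness_cost_se: float = float("nan")
    #: plateau of the mean heterozygous-locus frequency (mean n / L)
    plateau_het_loci: float = float("nan")
    plateau_het_loci_se: float = float("nan")

    @property
    def trajectory(self) -> pd.DataFrame:
        return records_to_frame(self.records)


@dataclass(frozen=True)
class InvasionConfig:
    """Configuration of one invasion battery (see :func:`run_parameter_sweep`)."""

    resident_strategy: Strategy = Strategy.UNI
    resident_alpha: float = 0.1
    invader_strategy: Strategy = Strategy.FAD
    invader_alpha: Optional[float] = None  # defaults to the resident's alpha
    f0: float = 0.01
    g_max: int = 30_000
    replicates: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 < 1.0:
            raise ValueError("f0 must lie in (0, 1)")
        if self.g_max < 1:
            raise ValueError("g_max must be >= 1")


@dataclass
class InvasionResult:
    """Outcome of a single invasion replicate."""

    outcome: str  # "fixed" | "extinct" | "timeout"
    takeover_time: Optional[int]
    n_generations: int
    final_freq: float
    trajectory: pd.DataFrame
    seed: Optional[int] = None


def _flat(y: np.ndarray, level: float) -> bool:
    """True when a regression slope over the series is indistinguishable from 0."""
    if np.ptp(y) == 0.0:
        return True
    res = stats.linregress(np.arange(y.size), y)
    return bool(np.isnan(res.pvalue) or res.pvalue >= level)


def run_steady_state(
    *,
    n_total: int,
    capacity: int,
    gparams: GeneticParams,
    dparams: DispersalParams,
    strategy: Strategy = Strategy.UNI,
    rng: np.random.Generator,
    ss: SteadyStateConfig = SteadyStateConfig(),
) -> SteadyStateResult:
    """Evolve a modifier-homogeneous population to mutation-selection balance.

    Returns the equilibrated population, the full per-generation time series,
    and plateau mean +/- standard error of mean fitness and heterozygosity
    over the final window.  Non-convergence within ``ss.max_gens`` is reported
    via ``converged=False`` and a warning.
    """
    alpha = dparams.alpha_U if strategy is Strategy.UNI else dparams.alpha_F
    pop = init_population(
        n_total,
        capacity,
        gparams,
        dparams,
        alleles=(ModifierAllele(strategy, alpha),),
        rng=rng,
    )
    records = [population_summary(pop, 0)]
    mf = [records[0].mean_fitness]
    het = [records[0].het_fraction]
    converged = False
    gen = 0
    for gen in range(1, ss.max_gens + 1):
        rec = step_generation(pop, rng, gen)
        records.append(rec)
        mf.append(rec.mean_fitness)
        het.append(rec.het_fraction)
        if gen >= ss.min_gens and gen % ss.check_every == 0:
            w_mf = np.asarray(mf[-ss.window :])
            w_het = np.asarray(het[-ss.window :])
            if _flat(w_mf, ss.level) and _flat(w_het, ss.level):
                converged = True
                break
    if not converged:
        warnings.warn(
            f"steady state not reached within {ss.max_gens} generations; "
            "plateau statistics use the final window",
            RuntimeWarning,
            stacklevel=2,
        )
    w_mf = np.asarray(mf[-ss.window :])
    w_het = np.asarray(het[-ss.window :])
    w_mfc = np.asarray([r.mean_fitness_cost for r in records[-ss.window :]])
    w_hl = np.asarray([r.het_loci_freq for r in records[-ss.window :]])
    w_mfc = w_mfc[np.isfinite(w_mfc)]
    root = np.sqrt(w_mf.size)
    return SteadyStateResult(
        population=pop,
        records=records,
        converged=converged,
        n_generations=gen,
        plateau_mean_fitness=float(w_mf.mean()),
        plateau_mean_fitness_se=float(w_mf.std(ddof=1) / root),
        plateau_het=float(w_het.mean()),
        plateau_het_se=float(w_het.std(ddof=1) / root),
        plateau_mean_fitness_cost=float(w_mfc.mean()) if w_mfc.size else float("nan"),
        plateau_mean_fitness_cost_se=(
            float(w_mfc.std(ddof=1) / np.sqrt(w_mfc.size)) if w_mfc.size > 1 else float("nan")
        ),
        plateau_het_loci=float(w_hl.mean()),
        plateau_het_loci_se=float(w_hl.std(ddof=1) / root),
    )


def run_invasion(
    resident: Population,
    invader_allele: ModifierAllele,
    f: float,
    rng: np.random.Generator,
    *,
    g_max: int = 30_000,
    low: float = 0.01,
    high: float = 0.8,
    seed: Optional[int] = None,
) -> InvasionResult:
    """Introduce an invading modifier allele and iterate to an absorbing state.

    An exact-count random subset of ``round(f * N)`` residents is converted to
    invader homozygotes (phenotypes re-assigned accordingly, so the initial
    allele frequency is exactly ``f``).  Generations are stepped until the
    invader allele frequency hits 0 (``extinct``) or 1 (``fixed``), or
    ``g_max`` generations have passed (``timeout``).
    """
    if not 0.0 < f < 1.0:
        raise ValueError("initial invader frequency must lie in (0, 1)")
    if len(resident.alleles) != 1:
        raise ValueError("resident population must be homogeneous at the modifier")
    pop = resident.copy()
    pop.alleles = (resident.alleles[0], invader_allele)
    N = pop.size
    k = max(int(round(f * N)), 1)
    idx = rng.choice(N, size=k, replace=False)
    pop.genotype[idx] = 1
    pop.phenotype[idx] = 1  # converted individuals are invader homozygotes
    records = [population_summary(pop, 0)]
    freqs = [records[0].allele_freqs[1]]
    outcome = "timeout"
    gen = 0
    for gen in range(1, g_max + 1):
        rec = step_generation(pop, rng, gen)
        records.append(rec)
        freqs.append(rec.allele_freqs[1])
        if rec.allele_freqs[1] == 0.0:
            outcome = "extinct"
            break
        if rec.allele_freqs[1] == 1.0:
            outcome = "fixed"
            break
    return InvasionResult(
        outcome=outcome,
        takeover_time=takeover_time(freqs, low=low, high=high),
        n_generations=gen,
        final_freq=float(freqs[-1]),
        trajectory=records_to_frame(records),
        seed=seed,
    )


def takeover_time(
    traj: Sequence[float], low: float = 0.01, high: float = 0.8
) -> Optional[int]:
    """Generations for the invader frequency to climb from ``low`` to ``high``.

    Defined as (first generation with frequency >= ``high``) minus (first
    generation with frequency >= ``low``); ``None`` when ``high`` is never
    reached.  A trajectory that starts at or above ``low`` is measured from
    generation 0.
    """
    freqs = np.asarray(traj, dtype=np.float64)
    above_high = np.flatnonzero(freqs >= high)
    if above_high.size == 0:
        return None
    above_low = np.flatnonzero(freqs >= low)
    return int(above_high[0] - above_low[0])


def exact_binomial_test(k: int, n: int, p0: float) -> float:
    """One-sided upper-tail exact binomial p-value, ``P(X >= k | n, p0)``."""
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 1 <= n and 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p0))


def classify_invasion_outcomes(
    fad_results: Sequence[InvasionResult],
    uni_results: Sequence[InvasionResult],
    f: float,
    p_threshold: float = 0.05,
) -> str:
    """Four-way outcome classification for one parameter cell.

    A strategy "succeeds" when its fixation count over replicates beats the
    neutral expectation ``f`` in the one-sided exact binomial test at
    ``p_threshold``.  FAD is called polymorphic when at least half of its
    replicates time out with the invader frequency still in (0.05, 0.95).
    Returns one of ``both_succeed``, ``only_FAD``, ``FAD_polymorphism``,
    ``none``.
    """
    if len(fad_results) == 0 or len(fad_results) != len(uni_results):
        raise ValueError("paired, non-empty FAD and UNI replicate sets required")
    n = len(fad_results)
    fad_fix = sum(r.outcome == "fixed" for r in fad_results)
    uni_fix = sum(r.outcome == "fixed" for r in uni_results)
    fad_success = exact_binomial_test(fad_fix, n, f) < p_threshold
    uni_success = exact_binomial_test(uni_fix, n, f) < p_threshold
    n_poly = sum(
        r.outcome == "timeout" and 0.05 < r.final_freq < 0.95 for r in fad_results
    )
    if fad_success and uni_success:
        return "both_succeed"
    if fad_success:
        return "only_FAD"
    if n_poly >= 0.5 * n:
        return "FAD_polymorphism"
    return "none"


def _child_rng(base_seed: int, *key: int) -> np.random.Generator:
    """Counter-based replicate stream: independent, reproducible, recordable."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    )


def run_parameter_sweep(
    *,
    alphas: Sequence[float],
    costs: Sequence[float],
    hs: Sequence[float],
    n_total: int = 5000,
    capacity: int = 20,
    L: int = 10_000,
    s: float = 0.1,
    U: float = 0.5,
    R: float = 20.0,
    resident_strategy: Strategy = Strategy.UNI,
    invader_strategies: Sequence[Strategy] = (Strategy.FAD,),
    invader_alpha: Optional[float] = None,
    f0: float = 0.01,
    g_max: int = 30_000,
    replicates: int = 50,
    base_seed: int = 0,
    fad_scope: str = "global",
    ss: SteadyStateConfig = SteadyStateConfig(),
    p_threshold: float = 0.05,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Factorial invasion sweep over (alpha, c, h) cells.

    For every cell a resident population is equilibrated once, then
    ``replicates`` seeded invasions are run for each invader strategy.
    Returns ``(replicate_rows, cell_table)``; the cell table carries fixation
    counts, exact binomial p-values, mean takeover time among fixing
    replicates and - when both FAD and UNI invaders were run - the four-way
    outcome classification.  Fully deterministic given ``base_seed``
    (replicate streams are derived by a counter-based scheme recorded per
    row).
    """
    rows = []
    cells = []
    grid = [(a, c, h) for a in alphas for c in costs for h in hs]
    for ci, (alpha, c, h) in enumerate(grid):
        gp = GeneticParams(L=L, s=s, h=h, U=U, R=R)
        dp = DispersalParams(alpha_U=alpha, alpha_F=alpha, c=c, fad_scope=fad_scope)
        inv_alpha = alpha if invader_alpha is None else invader_alpha
        try:
            res = run_steady_state(
                n_total=n_total,
                capacity=capacity,
                gparams=gp,
                dparams=dp,
                strategy=resident_strategy,
                rng=_child_rng(base_seed, ci, 0),
                ss=ss,
            )
        except Exception as exc:  # per-cell failure: record and continue
            cells.append(
                {"alpha": alpha, "c": c, "h": h, "error": repr(exc)}
            )
            continue
        cell = {
            "alpha": alpha,
            "c": c,
            "h": h,
            "resident_mean_fitness": res.plateau_mean_fitness,
            "resident_het": res.plateau_het,
            "error": None,
        }
        by_strategy = {}
        for si, strat in enumerate(invader_strategies):
            results = []
            for ri in range(replicates):
                rng = _child_rng(base_seed, ci, 1 + si * replicates + ri)
                seed_id = int(rng.integers(0, 2**31))
                result = run_invasion(
                    res.population,
                    ModifierAllele(strat, inv_alpha),
                    f0,
                    rng,
                    g_max=g_max,
                    seed=seed_id,
                )
                results.append(result)
                last = result.trajectory.iloc[-1]
                rows.append(
                    {
                        "run_id": f"cell{ci}_{strat.value}_rep{ri}",
                        "seed": seed_id,
                        "alpha_res": alpha,
                        "alpha_inv": inv_alpha,
                        "c": c,
                        "h": h,
                        "s": s,
                        "strategy_res": resident_strategy.value,
                        "strategy_inv": strat.value,
                        "f0": f0,
                        "outcome": result.outcome,
                        "takeover_gens": result.takeover_time,
                        "final_freq": result.final_freq,
                        "mean_fitness_end": float(last["mean_fitness"]),
                        "het_fraction_end": float(last["het_fraction"]),
                    }
                )
            by_strategy[strat] = results
            fix = sum(r.outcome == "fixed" for r in results)
            tk = [r.takeover_time for r in results if r.takeover_time is not None]
            tag = strat.value.lower()
            cell[f"{tag}_fixations"] = fix
            cell[f"{tag}_p_value"] = exact_binomial_test(fix, replicates, f0)
            cell[f"{tag}_mean_takeover"] = float(np.mean(tk)) if tk else float("nan")
        if Strategy.FAD in by_strategy and Strategy.UNI in by_strategy:
            cell["classification"] = classify_invasion_outcomes(
                by_strategy[Strategy.FAD], by_strategy[Strategy.UNI], f0, p_threshold
            )
        cells.append(cell)
        if progress:  # pragma: no cover - cosmetic
            print(f"cell {ci + 1}/{len(grid)} done: alpha={alpha} c={c} h={h}")
    return pd.DataFrame(rows), pd.DataFrame(cells)
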
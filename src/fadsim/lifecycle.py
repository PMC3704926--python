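"""One full generation: dispersal, cost mortality, reproduction, selection.

Generations are discrete and non-overlapping.  Each generation starts with the
dispersal stage (adults move or stay according to their realized strategy and
may die of the dispersal cost), followed by reproduction with viability
selection on the offspring, deme splitting, and removal of emptied demes.

Dispersal rules
---------------
* UNI individuals disperse independently, each with probability ``alpha_U``.
* FAD: the number of dispersers among the ``n_F`` FAD individuals is drawn
  from ``Binomial(n_F, alpha_F)``, and the slots are filled in ascending order
  of fitness - the least fit disperse first (ties broken at random).  The
  marginal dispersal rate is therefore exactly ``alpha_F``, identical to a
  UNI population with the same rate; only the identity of the dispersers
  differs.  By default the draw and the ranking are population-wide
  (``fad_scope="global"``); a per-deme variant is available for sensitivity
  analysis.
* Every disperser, regardless of genotype, dies with probability ``c`` (the
  cost of dispersal); survivors land in a uniformly random deme (island
  model - the natal deme is a possible destination).

Reproduction
------------
For each offspring a parent deme is chosen with probability proportional to
its post-dispersal size among demes with at least two adults (mating is
strictly within-deme, hermaphroditic, with no selfing); two distinct parents
are drawn uniformly, each contributes one gamete, the newborn mutates, its
phenotype is set, and it survives viability selection with probability equal
to its fitness.  Conceptions continue until exactly ``n_total`` offspring
survive; the offspring then replace the parental generation wholesale,
inheriting their parents' deme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .demes import (
    GenerationRecord,
    Population,
    drop_empty_demes,
    population_summary,
    split_oversized_demes,
)
from .genome import (
    Individual,
    ModifierGenotype,
    Strategy,
    assign_phenotype,
    count_classes_batch,
    draw_and_apply_mutations,
    fitness_from_counts,
    fitness_of,
    make_gamete,
    meiosis_batch,
    mutate_pair_batch,
)

__all__ = [
    "DispersalParams",
    "ExtinctionError",
    "ReproductionError",
    "dispersal_stage",
    "select_lowest_fitness",
    "choose_parent_deme",
    "produce_offspring",
    "reproduction_stage",
    "step_generation",
]


class ExtinctionError(RuntimeError):
    """The population lost every member (e.g. dispersal cost killed everyone)."""


class ReproductionError(RuntimeError):
    """No deme can supply two distinct parents, or the conception budget ran out."""


@dataclass(frozen=True)
class DispersalParams:
    """Dispersal-stage parameters.

    ``alpha_U`` and ``alpha_F`` are the mean dispersal rates of the UNI and
    FAD strategies; both are constant within a run.  ``c`` is the probability
    that a disperser perishes before reproducing.
    """

    alpha_U: float = 0.1
    alpha_F: float = 0.1
    c: float = 0.0
    fad_scope: str = "global"

    def __post_init__(self) -> None:
        for name in ("alpha_U", "alpha_F", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fad_scope not in ("global", "deme"):
            raise ValueError("fad_scope must be 'global' or 'deme'")


def select_lowest_fitness(
    members: np.ndarray,
    fitness: np.ndarray,
    d: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """The ``d`` members of lowest fitness (uniform random tie-break)."""
    if d == 0:
        return members[:0]
    # ascending fitness; uniform random tie-break via a secondary random key
    order = np.lexsort((rng.random(members.size), fitness[members]))
    return members[order[:d]]


def _mark_fad_dispersers(
    members: np.ndarray,
    fitness: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    out: np.ndarray,
) -> None:
    """Mark Binomial(len, alpha) members as dispersers, least fit first."""
    d = int(rng.binomial(members.size, alpha))
    if d:
        out[select_lowest_fitness(members, fitness, d, rng)] = True


def dispersal_stage(pop: Population, rng: np.random.Generator) -> Population:
    """Move (and possibly kill) dispersing adults; mutates ``pop`` in place."""
    N = pop.size
    if N == 0:
        raise ExtinctionError("population is extinct")
    n_demes = pop.n_demes
    disperse = np.zeros(N, dtype=bool)
    for ai, allele in enumerate(pop.alleles):
        members = np.flatnonzero(pop.phenotype == ai)
        if members.size == 0 or allele.alpha == 0.0:
            continue
        if allele.strategy is Strategy.UNI:
            disperse[members] = rng.random(members.size) < allele.alpha
        else:
            if pop.dparams.fad_scope == "global":
                _mark_fad_dispersers(members, pop.fitness, allele.alpha, rng, disperse)
            else:
                for d in range(n_demes):
                    grp = members[pop.deme[members] == d]
                    if grp.size:
                        _mark_fad_dispersers(
                            grp, pop.fitness, allele.alpha, rng, disperse
                        )
    movers = np.flatnonzero(disperse)
    pre_n = N
    pre_sum = float(pop.fitness.sum())
    if movers.size == 0:
        pop.cost_adjusted_mean_fitness = pre_sum / pre_n
        return pop
    c = pop.dparams.c
    dies = rng.random(movers.size) < c if c > 0.0 else np.zeros(movers.size, bool)
    # survivors land in a uniformly random deme among those present at the
    # start of the stage (the natal deme included)
    landed = movers[~dies]
    pop.deme[landed] = rng.integers(0, n_demes, size=landed.size).astype(np.int32)
    # mean fitness with the realized dispersal mortality folded in: the dead
    # contribute 0, the denominator is the pre-dispersal census
    pop.cost_adjusted_mean_fitness = (
        pre_sum - float(pop.fitness[movers[dies]].sum())
    ) / pre_n
    if dies.any():
        keep = np.ones(N, dtype=bool)
        keep[movers[dies]] = False
        pop.hap_a = pop.hap_a[keep]
        pop.hap_b = pop.hap_b[keep]
        pop.genotype = pop.genotype[keep]
        pop.phenotype = pop.phenotype[keep]
        pop.fitness = pop.fitness[keep]
        pop.deme = pop.deme[keep]
        if pop.size == 0:
            raise ExtinctionError("every disperser perished; population extinct")
    return pop


def _eligible_weights(pop: Population) -> tuple[np.ndarray, np.ndarray]:
    """Deme ids with >= 2 adults and their size weights (no-selfing rule)."""
    sizes = pop.deme_sizes()
    eligible = np.flatnonzero(sizes >= 2)
    if eligible.size == 0:
        raise ReproductionError("population cannot reproduce: no deme has two adults")
    return eligible, sizes[eligible].astype(np.float64)


def choose_parent_deme(pop: Population, rng: np.random.Generator) -> int:
    """Sample a parent deme with probability proportional to its adult count.

    Only demes with at least two adults are eligible (two distinct parents are
    required; there is no self-fertilization).
    """
    eligible, weights = _eligible_weights(pop)
    cum = np.cumsum(weights)
    return int(eligible[np.searchsorted(cum, rng.random() * cum[-1], side="right")])


def produce_offspring(
    pop: Population, deme_id: int, rng: np.random.Generator
) -> Optional[Individual]:
    """Attempt one conception in a deme; return the newborn or ``None``.

    Two distinct parents are drawn uniformly without replacement; each
    contributes one gamete; the newborn mutates, realizes its dispersal
    phenotype, and survives viability selection with probability equal to its
    fitness.  ``None`` signals a rejected (non-surviving) conception, which is
    a normal outcome.
    """
    members = np.flatnonzero(pop.deme == deme_id)
    if members.size < 2:
        raise ReproductionError(f"deme {deme_id} has fewer than two adults")
    i = int(rng.integers(members.size))
    j = int(rng.integers(members.size - 1))
    if j >= i:
        j += 1
    p1 = pop.get_individual(int(members[i]))
    p2 = pop.get_individual(int(members[j]))
    gp = pop.gparams
    hap_a, allele_a = make_gamete(p1, gp, rng)
    hap_b, allele_b = make_gamete(p2, gp, rng)
    modifier = ModifierGenotype(allele_a, allele_b)
    child = Individual(
        hap_a=hap_a,
        hap_b=hap_b,
        modifier=modifier,
        phenotype=modifier.allele_a,  # provisional; set after mutation below
        fitness=1.0,
        deme_id=deme_id,
    )
    child = draw_and_apply_mutations(child, gp, rng)
    child.phenotype = assign_phenotype(modifier, rng)
    m, n = count_classes_batch(child.hap_a.bits, child.hap_b.bits)
    child.fitness = fitness_of(int(m), int(n), gp)
    if rng.random() < child.fitness:
        return child
    return None


def reproduction_stage(
    pop: Population,
    rng: np.random.Generator,
    max_attempts: Optional[int] = None,
) -> Population:
    """Replace the parental generation by ``n_total`` surviving offspring.

    Conceptions are processed in batches for speed; each conception is an
    independent draw from the same distribution as :func:`produce_offspring`
    (deme weights are static during the stage because parents are not
    consumed), so batching does not change the sampling model.
    """
    N_target = pop.n_total
    if max_attempts is None:
        max_attempts = 1000 * N_target
    if pop.size < 2:
        raise ExtinctionError("fewer than two adults remain")
    eligible, weights = _eligible_weights(pop)
    cumw = np.cumsum(weights)
    wtot = cumw[-1]
    # per-deme member lookup: indices of adults grouped by deme label
    order = np.argsort(pop.deme, kind="stable")
    sizes_all = pop.deme_sizes()
    starts_all = np.zeros(len(sizes_all) + 1, dtype=np.int64)
    np.cumsum(sizes_all, out=starts_all[1:])

    gp = pop.gparams
    out_a, out_b, out_gt, out_ph, out_fit, out_deme = [], [], [], [], [], []
    have = 0
    attempts = 0
    surv_guess = max(float(pop.fitness.mean()), 0.05)
    while have < N_target:
        B = int((N_target - have) / surv_guess * 1.15) + 16
        B = min(B, 4 * N_target + 64)
        if attempts + B > max_attempts:
            B = max_attempts - attempts
            if B <= 0:
                raise ReproductionError(
                    f"conception budget exhausted: {attempts} attempts produced "
                    f"{have}/{N_target} survivors"
                )
        # deme choice, size-weighted among eligible demes
        di = np.searchsorted(cumw, rng.random(B) * wtot, side="right")
        d = eligible[di]
        sz = sizes_all[d]
        # two distinct parents, uniform without replacement
        r1 = (rng.random(B) * sz).astype(np.int64)
        r2 = (rng.random(B) * (sz - 1)).astype(np.int64)
        r2 += (r2 >= r1).astype(np.int64)
        p1 = order[starts_all[d] + r1]
        p2 = order[starts_all[d] + r2]
        # one gamete from each parent
        gam_a = meiosis_batch(pop.hap_a[p1], pop.hap_b[p1], gp, rng)
        pick1 = rng.integers(0, 2, size=B)
        allele_a = pop.genotype[p1, pick1]
        gam_b = meiosis_batch(pop.hap_a[p2], pop.hap_b[p2], gp, rng)
        pick2 = rng.integers(0, 2, size=B)
        allele_b = pop.genotype[p2, pick2]
        # newborn mutation, phenotype at birth, viability selection
        mutate_pair_batch(gam_a, gam_b, gp, rng)
        coin = rng.integers(0, 2, size=B)
        phen = np.where(coin, allele_b, allele_a).astype(np.int8)
        m, n = count_classes_batch(gam_a, gam_b)
        fit = fitness_from_counts(m, n, gp)
        surv = rng.random(B) < fit
        attempts += B
        k = int(surv.sum())
        if k:
            out_a.append(gam_a[surv])
            out_b.append(gam_b[surv])
            out_gt.append(
                np.stack([allele_a[surv], allele_b[surv]], axis=1).astype(np.int8)
            )
            out_ph.append(phen[surv])
            out_fit.append(fit[surv])
            out_deme.append(d[surv].astype(np.int32))
            have += k
            surv_guess = max(have / attempts, 0.05)
    hap_a = np.concatenate(out_a)[:N_target]
    hap_b = np.concatenate(out_b)[:N_target]
    pop.hap_a = np.ascontiguousarray(hap_a)
    pop.hap_b = np.ascontiguousarray(hap_b)
    pop.genotype = np.concatenate(out_gt)[:N_target]
    pop.phenotype = np.concatenate(out_ph)[:N_target]
    pop.fitness = np.concatenate(out_fit)[:N_target]
    pop.deme = np.concatenate(out_deme)[:N_target]
    return pop


def step_generation(
    pop: Population,
    rng: np.random.Generator,
    generation: int = 0,
    max_attempts: Optional[int] = None,
) -> GenerationRecord:
    """Advance the population by one generation and summarize the result.

    Order of events: dispersal (with cost mortality), reproduction with
    viability selection, splitting of over-capacity demes, removal of emptied
    demes.  The population is mutated in place; the returned record describes
    the new generation.
    """
    dispersal_stage(pop, rng)
    reproduction_stage(pop, rng, max_attempts=max_attempts)
    split_oversized_demes(pop, rng)
    drop_empty_demes(pop)
    return population_summary(pop, generation)
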
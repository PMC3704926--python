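"""Deme bookkeeping and population-level summary statistics.

The population is a fixed total number of individuals partitioned into demes
(island model: demes have no geometry, every deme is equally reachable).
Demes grow and shrink freely within a generation; a deme whose census exceeds
the capacity ``K`` after reproduction is split into two random halves, and
demes that lose all members disappear.  Deme labels are transient - they are
compacted every generation and carry no lineage information.

Internally the population is a structure of arrays: packed haplotype matrices,
modifier genotype codes (indices into a small allele table), realized
phenotype codes, cached viabilities, and deme labels.  :class:`Individual`
objects are materialized on demand at the API edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneticParams,
    Haplotype,
    Individual,
    ModifierAllele,
    ModifierGenotype,
    Strategy,
    count_classes_batch,
)

__all__ = [
    "Deme",
    "Population",
    "GenerationRecord",
    "init_population",
    "split_oversized_demes",
    "drop_empty_demes",
    "population_summary",
    "records_to_frame",
    "write_trajectory_tsv",
    "TSV_COLUMNS",
]

#: Columns of the trajectory TSV time series, in order.
TSV_COLUMNS = (
    "generation",
    "mean_fitness",
    "het_fraction",
    "fad_allele_freq",
    "n_demes",
    "mean_fitness_fad",
    "mean_fitness_uni",
)


@dataclass
class GenerationRecord:
    """Per-generation summary of the population state.

    ``het_fraction`` is the pooled fraction of deleterious allele copies that
    sit in heterozygous loci, ``sum(n) / sum(n + 2m)`` over individuals (0 when
    the population carries no mutations).  ``fad_allele_freq`` counts modifier
    allele copies whose strategy is FAD.  Sub-population means are reported
    both by expressed strategy (``mean_fitness_fad`` / ``mean_fitness_uni``)
    and by realized allele index (``allele_mean_fitness``), which differ only
    when the two alleles share a strategy (e.g. a neutral control invasion).
    """

    generation: int
    mean_fitness: float
    het_fraction: float
    fad_allele_freq: float
    n_demes: int
    mean_fitness_fad: float
    mean_fitness_uni: float
    n_fad: int
    n_uni: int
    allele_freqs: tuple
    allele_mean_fitness: tuple
    allele_counts: tuple
    het_fraction_indiv: float
    #: mean fitness over modifier allele *copies* (heterozygote carriers count
    #: toward both alleles); the natural measure of an allele's association
    #: with good or bad genetic backgrounds
    allele_copy_mean_fitness: tuple = ()
    #: mean per-locus frequency of heterozygous deleterious loci, mean(n) / L
    het_loci_freq: float = float("nan")
    #: mean fitness with dispersal mortality folded in: the viability of the
    #: adults that survived this generation's dispersal stage summed and
    #: divided by the pre-dispersal census (cost-deaths count as fitness 0);
    #: NaN before the first dispersal stage
    mean_fitness_cost: float = float("nan")


@dataclass
class Deme:
    """A mating subpopulation (view constructed from a :class:`Population`)."""

    deme_id: int
    members: list

    @property
    def size(self) -> int:
        return len(self.members)


class Population:
    """All individuals of one generation, stored as a structure of arrays."""

    __slots__ = (
        "hap_a",
        "hap_b",
        "genotype",
        "phenotype",
        "fitness",
        "deme",
        "alleles",
        "gparams",
        "dparams",
        "capacity",
        "n_total",
        "cost_adjusted_mean_fitness",
    )

    def __init__(
        self,
        *,
        hap_a: np.ndarray,
        hap_b: np.ndarray,
        genotype: np.ndarray,
        phenotype: np.ndarray,
        fitness: np.ndarray,
        deme: np.ndarray,
        alleles: tuple,
        gparams: GeneticParams,
        dparams,
        capacity: int,
        n_total: int,
    ):
        self.hap_a = hap_a
        self.hap_b = hap_b
        self.genotype = genotype
        self.phenotype = phenotype
        self.fitness = fitness
        self.deme = deme
        self.alleles = tuple(alleles)
        self.gparams = gparams
        self.dparams = dparams
        self.capacity = int(capacity)
        self.n_total = int(n_total)
        # set by the dispersal stage; NaN until the first generation step
        self.cost_adjusted_mean_fitness = float("nan")

    @property
    def size(self) -> int:
        return self.fitness.shape[0]

    @property
    def n_demes(self) -> int:
        return int(self.deme.max()) + 1 if self.size else 0

    def deme_sizes(self) -> np.ndarray:
        return np.bincount(self.deme, minlength=self.n_demes)

    def allele_frequency(self, allele_index: int = 1) -> float:
        """Frequency of one modifier allele among all 2N allele copies."""
        return float((self.genotype == allele_index).mean())

    def strategy_mask(self, strategy: Strategy) -> np.ndarray:
        """Boolean mask of individuals whose expressed strategy matches."""
        idx = [i for i, a in enumerate(self.alleles) if a.strategy is strategy]
        return np.isin(self.phenotype, idx)

    def get_individual(self, i: int) -> Individual:
        L = self.gparams.L
        return Individual(
            hap_a=Haplotype(self.hap_a[i].copy(), L),
            hap_b=Haplotype(self.hap_b[i].copy(), L),
            modifier=ModifierGenotype(
                self.alleles[self.genotype[i, 0]], self.alleles[self.genotype[i, 1]]
            ),
            phenotype=self.alleles[self.phenotype[i]],
            fitness=float(self.fitness[i]),
            deme_id=int(self.deme[i]),
        )

    def demes(self) -> list:
        views = []
        for d in range(self.n_demes):
            members = [self.get_individual(i) for i in np.flatnonzero(self.deme == d)]
            views.append(Deme(deme_id=d, members=members))
        return views

    def copy(self) -> "Population":
        new = Population(
            hap_a=self.hap_a.copy(),
            hap_b=self.hap_b.copy(),
            genotype=self.genotype.copy(),
            phenotype=self.phenotype.copy(),
            fitness=self.fitness.copy(),
            deme=self.deme.copy(),
            alleles=self.alleles,
            gparams=self.gparams,
            dparams=self.dparams,
            capacity=self.capacity,
            n_total=self.n_total,
        )
        new.cost_adjusted_mean_fitness = self.cost_adjusted_mean_fitness
        return new


def init_population(
    n_total: int,
    capacity: int,
    gparams: GeneticParams,
    dparams,
    *,
    alleles: Optional[tuple] = None,
    invader_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Population:
    """Create a mutation-free founding population.

    Individuals are allocated to demes of size at most ``capacity``.  With
    ``invader_fraction = f > 0`` an exact-count random subset of
    ``round(f * n_total)`` individuals is made homozygous for allele index 1
    (the invader allele); everyone else is homozygous for allele index 0.
    Exact-count assignment keeps the initial allele frequency at exactly ``f``
    in every replicate.
    """
    if n_total < 2:
        raise ValueError("n_total must be at least 2")
    if not 0.0 <= invader_fraction <= 1.0:
        raise ValueError("invader_fraction must lie in [0, 1]")
    if capacity < 1:
        raise ValueError("capacity must be positive")
    if alleles is None:
        alleles = (ModifierAllele(Strategy.UNI, dparams.alpha_U),)
    W = gparams.n_words
    genotype = np.zeros((n_total, 2), dtype=np.int8)
    if invader_fraction > 0.0:
        if len(alleles) < 2:
            raise ValueError("invader_fraction > 0 requires an invader allele")
        if rng is None:
            raise ValueError("invader assignment requires an rng")
        k = int(round(invader_fraction * n_total))
        idx = rng.choice(n_total, size=k, replace=False)
        genotype[idx] = 1
    # founders are homozygous at the modifier locus, so the birth rule is
    # deterministic: the phenotype is the carried allele
    phenotype = genotype[:, 0].copy()
    return Population(
        hap_a=np.zeros((n_total, W), dtype=np.uint64),
        hap_b=np.zeros((n_total, W), dtype=np.uint64),
        genotype=genotype,
        phenotype=phenotype,
        fitness=np.ones(n_total, dtype=np.float64),
        deme=(np.arange(n_total, dtype=np.int64) // capacity).astype(np.int32),
        alleles=alleles,
        gparams=gparams,
        dparams=dparams,
        capacity=capacity,
        n_total=n_total,
    )


def split_oversized_demes(pop: Population, rng: np.random.Generator) -> Population:
    """Split every deme whose census exceeds the capacity into two random halves.

    The floor(size/2) members moved to the new deme are chosen uniformly at
    random.  Applied repeatedly, so even a deme larger than twice the capacity
    ends up within bounds.  A deme exactly at capacity is left alone.
    """
    K = pop.capacity
    while True:
        sizes = pop.deme_sizes()
        oversized = np.flatnonzero(sizes > K)
        if oversized.size == 0:
            break
        next_id = len(sizes)
        for d in oversized:
            members = np.flatnonzero(pop.deme == d)
            moved = rng.permutation(members)[: members.size // 2]
            pop.deme[moved] = next_id
            next_id += 1
    return pop


def drop_empty_demes(pop: Population) -> Population:
    """Remove empty demes by compacting deme labels to 0..D-1."""
    if pop.size:
        _, inverse = np.unique(pop.deme, return_inverse=True)
        pop.deme = inverse.astype(np.int32)
    return pop


def _subgroup_mean(fitness: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    n = int(mask.sum())
    return (float(fitness[mask].mean()) if n else float("nan")), n


def population_summary(pop: Population, generation: int = 0) -> GenerationRecord:
    """Compute the per-generation summary statistics."""
    if pop.size == 0:
        raise ValueError("cannot summarize an empty population")
    m, n = count_classes_batch(pop.hap_a, pop.hap_b)
    total_copies = int((n + 2 * m).sum())
    het_fraction = float(n.sum()) / total_copies if total_copies else 0.0
    loaded = (m + n) > 0
    if loaded.any():
        het_indiv = float((n[loaded] / (n[loaded] + 2.0 * m[loaded])).mean())
    else:
        het_indiv = 0.0

    fad_idx = [i for i, a in enumerate(pop.alleles) if a.strategy is Strategy.FAD]
    fad_allele_freq = (
        float(np.isin(pop.genotype, fad_idx).mean()) if fad_idx else 0.0
    )
    fad_mask = pop.strategy_mask(Strategy.FAD)
    uni_mask = pop.strategy_mask(Strategy.UNI)
    mean_fad, n_fad = _subgroup_mean(pop.fitness, fad_mask)
    mean_uni, n_uni = _subgroup_mean(pop.fitness, uni_mask)

    allele_freqs = []
    allele_means = []
    allele_counts = []
    allele_copy_means = []
    for i in range(len(pop.alleles)):
        allele_freqs.append(float((pop.genotype == i).mean()))
        mean_i, n_i = _subgroup_mean(pop.fitness, pop.phenotype == i)
        allele_means.append(mean_i)
        allele_counts.append(n_i)
        copies = (pop.genotype == i).sum(axis=1)
        total = int(copies.sum())
        allele_copy_means.append(
            float((pop.fitness * copies).sum() / total) if total else float("nan")
        )

    return GenerationRecord(
        generation=generation,
        mean_fitness=float(pop.fitness.mean()),
        het_loci_freq=float(n.mean()) / pop.gparams.L,
        mean_fitness_cost=pop.cost_adjusted_mean_fitness,
        het_fraction=het_fraction,
        fad_allele_freq=fad_allele_freq,
        n_demes=pop.n_demes,
        mean_fitness_fad=mean_fad,
        mean_fitness_uni=mean_uni,
        n_fad=n_fad,
        n_uni=n_uni,
        allele_freqs=tuple(allele_freqs),
        allele_mean_fitness=tuple(allele_means),
        allele_counts=tuple(allele_counts),
        allele_copy_mean_fitness=tuple(allele_copy_means),
        het_fraction_indiv=het_indiv,
    )


def records_to_frame(records: Sequence[GenerationRecord]) -> pd.DataFrame:
    """Tabulate a time series of generation records."""
    rows = []
    for r in records:
        row = {
            "generation": r.generation,
            "mean_fitness": r.mean_fitness,
            "het_fraction": r.het_fraction,
            "fad_allele_freq": r.fad_allele_freq,
            "n_demes": r.n_demes,
            "mean_fitness_fad": r.mean_fitness_fad,
            "mean_fitness_uni": r.mean_fitness_uni,
            "n_fad": r.n_fad,
            "n_uni": r.n_uni,
            "het_fraction_indiv": r.het_fraction_indiv,
            "het_loci_freq": r.het_loci_freq,
            "mean_fitness_cost": r.mean_fitness_cost,
        }
        if len(r.allele_freqs) > 1:
            row["invader_freq"] = r.allele_freqs[1]
            row["mean_fitness_resident"] = r.allele_mean_fitness[0]
            row["mean_fitness_invader"] = r.allele_mean_fitness[1]
            row["n_resident"] = r.allele_counts[0]
            row["n_invader"] = r.allele_counts[1]
            if r.allele_copy_mean_fitness:
                row["copy_fitness_resident"] = r.allele_copy_mean_fitness[0]
                row["copy_fitness_invader"] = r.allele_copy_mean_fitness[1]
        rows.append(row)
    return pd.DataFrame(rows)


def write_trajectory_tsv(records: Sequence[GenerationRecord], path) -> None:
    """Write the standard trajectory time series (tab-separated)."""
    frame = records_to_frame(records)
    frame[list(TSV_COLUMNS)].to_csv(path, sep="\t", index=False)
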
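"""Diploid genome model: haplotypes, viability fitness, mutation, and meiosis.

The genome consists of ``L`` bi-allelic fitness loci (wild-type / deleterious
mutant) on each of two chromosome copies, plus a single diploid modifier locus
whose alleles encode a dispersal strategy.  A haplotype is stored as a packed
bitmask over the fitness loci (one bit per locus, 64 loci per machine word),
which keeps genomes at mutation-selection balance cheap to copy, recombine and
compare.  All randomness flows through a caller-supplied
:class:`numpy.random.Generator` so that every replicate is reproducible from a
single seed.

Viability selection is multiplicative across loci: an individual carrying
``m`` homozygous and ``n`` heterozygous deleterious mutations survives to
adulthood with probability ``(1 - s)**m * (1 - h*s)**n``, where ``s`` is the
selection coefficient and ``h`` the dominance coefficient.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "Strategy",
    "ModifierAllele",
    "ModifierGenotype",
    "GeneticParams",
    "Haplotype",
    "Individual",
    "count_mutation_classes",
    "fitness_of",
    "fitness_from_counts",
    "draw_and_apply_mutations",
    "make_gamete",
    "assign_phenotype",
    "recombination_mask",
    "recombine",
    "pack_loci",
    "unpack_loci",
    "popcount",
    "meiosis_batch",
    "mutate_pair_batch",
    "count_classes_batch",
]

_ONE = np.uint64(1)


class Strategy(enum.Enum):
    """Dispersal strategy encoded by a modifier allele."""

    UNI = "UNI"  # uniform: disperse independently with probability alpha
    FAD = "FAD"  # fitness-associated: least fit individuals disperse first

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ModifierAllele(NamedTuple):
    """One allele at the modifier locus: a strategy and its mean dispersal rate."""

    strategy: Strategy
    alpha: float


class ModifierGenotype(NamedTuple):
    """Unordered pair of modifier alleles carried by a diploid individual."""

    allele_a: ModifierAllele
    allele_b: ModifierAllele

    @property
    def is_heterozygous(self) -> bool:
        return self.allele_a != self.allele_b


@dataclass(frozen=True)
class GeneticParams:
    """Genome-wide parameters.

    Parameters
    ----------
    L
        Number of diploid fitness loci.
    s
        Selection coefficient against a homozygous deleterious mutation,
        ``0 < s < 1`` (``s >= 1`` would give non-positive viability).
    h
        Dominance coefficient scaling the heterozygous effect, in ``[0, 1]``.
    U
        Expected number of new deleterious mutations per (diploid) genome per
        generation; drawn once per newborn.
    R
        Expected number of crossover events among the fitness loci per meiosis.
        The modifier locus segregates freely from the fitness loci.
    """

    L: int = 10_000
    s: float = 0.1
    h: float = 0.2
    U: float = 0.5
    R: float = 20.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be a positive integer")
        if not 0.0 < self.s < 1.0:
            raise ValueError("s must lie in (0, 1)")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if self.U < 0.0:
            raise ValueError("U must be non-negative")
        if self.R < 0.0:
            raise ValueError("R must be non-negative")

    @property
    def n_words(self) -> int:
        return _n_words(self.L)


def _n_words(L: int) -> int:
    return (L + 63) >> 6


@functools.lru_cache(maxsize=16)
def _valid_mask(L: int) -> np.ndarray:
    """Packed mask with every one of the L locus bits set."""
    mask = np.zeros(_n_words(L), dtype=np.uint64)
    loci = np.arange(L, dtype=np.int64)
    np.bitwise_or.at(mask, loci >> 6, _ONE << (loci & 63).astype(np.uint64))
    mask.setflags(write=False)
    return mask


@functools.lru_cache(maxsize=4)
def _suffix_masks(L: int) -> np.ndarray:
    """Row ``j`` sets the bits of all loci strictly to the right of interval ``j``.

    Interval ``j`` lies between locus ``j`` and locus ``j+1`` (``0 <= j < L-1``).
    XOR-ing the rows of a set of breakpoints yields the parity mask of a
    crossover pattern in a single reduction.
    """
    W = _n_words(L)
    rows = np.empty((max(L - 1, 1), W), dtype=np.uint64)
    prefix = np.zeros(W, dtype=np.uint64)
    for j in range(L - 1):
        prefix[j >> 6] |= _ONE << np.uint64(j & 63)
        rows[j] = prefix
    if L == 1:
        rows[0] = 0
    rows ^= _valid_mask(L)  # suffix(j) = all loci minus prefix(<= j)
    rows.setflags(write=False)
    return rows


def pack_loci(loci: Iterable[int], L: int) -> np.ndarray:
    """Pack a collection of mutant locus indices into a bitmask."""
    bits = np.zeros(_n_words(L), dtype=np.uint64)
    idx = np.fromiter(loci, dtype=np.int64)
    if idx.size:
        if idx.min() < 0 or idx.max() >= L:
            raise ValueError(f"locus index out of range [0, {L})")
        np.bitwise_or.at(bits, idx >> 6, _ONE << (idx & 63).astype(np.uint64))
    return bits


def unpack_loci(bits: np.ndarray, L: int) -> np.ndarray:
    """Sorted array of mutant locus indices encoded in a bitmask."""
    flat = np.unpackbits(bits.view(np.uint8), bitorder="little")
    return np.flatnonzero(flat[:L])


def popcount(bits: np.ndarray, axis: int = -1):
    """Number of set bits, summed along ``axis``."""
    return np.bitwise_count(bits).sum(axis=axis, dtype=np.int64)


class Haplotype:
    """One chromosome copy: the set of fitness loci carrying the mutant allele."""

    __slots__ = ("bits", "L")

    def __init__(self, bits: np.ndarray, L: int):
        bits = np.asarray(bits, dtype=np.uint64)
        if bits.shape != (_n_words(L),):
            raise ValueError("bit array does not match L")
        self.bits = bits
        self.L = L

    @classmethod
    def from_loci(cls, loci: Iterable[int], L: int) -> "Haplotype":
        return cls(pack_loci(loci, L), L)

    @classmethod
    def empty(cls, L: int) -> "Haplotype":
        return cls(np.zeros(_n_words(L), dtype=np.uint64), L)

    @property
    def mutant_loci(self) -> frozenset:
        return frozenset(unpack_loci(self.bits, self.L).tolist())

    def count(self) -> int:
        return int(popcount(self.bits))

    def copy(self) -> "Haplotype":
        return Haplotype(self.bits.copy(), self.L)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Haplotype)
            and self.L == other.L
            and bool(np.array_equal(self.bits, other.bits))
        )

    __hash__ = None  # mutable container

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        loci = sorted(self.mutant_loci)
        return f"Haplotype(L={self.L}, mutant_loci={loci})"


@dataclass
class Individual:
    """A diploid individual.

    ``phenotype`` is the modifier allele realized at birth (for heterozygotes a
    fair coin decides which allele's strategy is expressed; the choice is fixed
    for life).  ``fitness`` caches the viability ``(1-s)^m (1-hs)^n``; genomes
    are immutable after the newborn mutation step, so the cache is exact.
    """

    hap_a: Haplotype
    hap_b: Haplotype
    modifier: ModifierGenotype
    phenotype: ModifierAllele
    fitness: float
    deme_id: int = 0


def count_mutation_classes(ind: Individual) -> tuple[int, int]:
    """Return ``(m, n)``: homozygous and heterozygous deleterious mutation counts."""
    m = popcount(ind.hap_a.bits & ind.hap_b.bits)
    n = popcount(ind.hap_a.bits ^ ind.hap_b.bits)
    return int(m), int(n)


def fitness_of(m: int, n: int, params: GeneticParams) -> float:
    """Viability of an individual with ``m`` homozygous and ``n`` heterozygous mutations."""
    if m < 0 or n < 0:
        raise ValueError("mutation counts must be non-negative")
    return (1.0 - params.s) ** m * (1.0 - params.h * params.s) ** n


def fitness_from_counts(m: np.ndarray, n: np.ndarray, params: GeneticParams) -> np.ndarray:
    """Vectorized viability for arrays of (m, n) counts."""
    return (1.0 - params.s) ** m * (1.0 - params.h * params.s) ** n


def recombination_mask(
    breakpoints: np.ndarray, start_with_b: bool, L: int
) -> np.ndarray:
    """Packed mask of the loci a gamete inherits from haplotype ``b``.

    A locus is inherited from the non-starting copy when an odd number of
    breakpoints lies to its left; two breakpoints in the same inter-locus
    interval cancel.
    """
    bp = np.asarray(breakpoints, dtype=np.int64)
    if bp.size:
        if L < 2:
            raise ValueError("breakpoints require L >= 2")
        if bp.min() < 0 or bp.max() >= L - 1:
            raise ValueError(f"breakpoint out of range [0, {L - 1})")
        mask = np.bitwise_xor.reduce(_suffix_masks(L)[bp], axis=0)
    else:
        mask = np.zeros(_n_words(L), dtype=np.uint64)
    if start_with_b:
        mask = mask ^ _valid_mask(L)
    return mask


def recombine(
    bits_a: np.ndarray,
    bits_b: np.ndarray,
    breakpoints: np.ndarray,
    start_with_b: bool,
    L: int,
) -> np.ndarray:
    """Gamete bitmask from two parental haplotypes and explicit breakpoints."""
    mask = recombination_mask(breakpoints, start_with_b, L)
    return (bits_a & ~mask) | (bits_b & mask)


def make_gamete(
    ind: Individual, params: GeneticParams, rng: np.random.Generator
) -> tuple[Haplotype, ModifierAllele]:
    """Form one gamete: recombinant fitness haplotype plus one modifier allele.

    The crossover count is Poisson(``R``); positions are uniform over the
    ``L - 1`` inter-locus intervals.  The modifier allele segregates freely
    (fair coin, independent of the fitness-locus outcome).
    """
    L = params.L
    x = int(rng.poisson(params.R)) if L > 1 else 0
    bps = rng.integers(0, L - 1, size=x) if x else np.empty(0, dtype=np.int64)
    start_with_b = bool(rng.integers(0, 2))
    bits = recombine(ind.hap_a.bits, ind.hap_b.bits, bps, start_with_b, L)
    allele = ind.modifier.allele_b if rng.integers(0, 2) else ind.modifier.allele_a
    return Haplotype(bits, L), allele


def draw_and_apply_mutations(
    ind: Individual, params: GeneticParams, rng: np.random.Generator
) -> Individual:
    """Apply Poisson(``U``) new deleterious mutations to a newborn's genome.

    Each mutation targets one of the ``2L`` fitness-allele copies uniformly at
    random; a copy that is already mutant stays mutant (no back mutation).  The
    modifier locus never mutates.  Returns a new individual with its fitness
    cache refreshed.
    """
    k = int(rng.poisson(params.U))
    if k == 0:
        return ind
    a = ind.hap_a.bits.copy()
    b = ind.hap_b.bits.copy()
    pos = rng.integers(0, 2 * params.L, size=k)
    loci = pos >> 1
    hit_b = (pos & 1).astype(bool)
    for bits, sel in ((a, ~hit_b), (b, hit_b)):
        li = loci[sel]
        if li.size:
            np.bitwise_or.at(bits, li >> 6, _ONE << (li & 63).astype(np.uint64))
    hap_a = Haplotype(a, params.L)
    hap_b = Haplotype(b, params.L)
    m = int(popcount(a & b))
    n = int(popcount(a ^ b))
    return Individual(
        hap_a=hap_a,
        hap_b=hap_b,
        modifier=ind.modifier,
        phenotype=ind.phenotype,
        fitness=fitness_of(m, n, params),
        deme_id=ind.deme_id,
    )


def assign_phenotype(
    modifier: ModifierGenotype, rng: np.random.Generator
) -> ModifierAllele:
    """Realized dispersal allele, fixed at birth.

    Homozygotes express their allele; heterozygotes express either allele with
    probability 1/2, as if half of them developed as each homozygote.
    """
    if not modifier.is_heterozygous:
        return modifier.allele_a
    return modifier.allele_b if rng.integers(0, 2) else modifier.allele_a


# ---------------------------------------------------------------------------
# Batched kernels used by the lifecycle engine.  Semantically these are the
# per-individual operations above applied row-wise; batching only changes the
# interleaving of RNG draws.
# ---------------------------------------------------------------------------


def meiosis_batch(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    params: GeneticParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamete fitness-locus bitmasks for a batch of parents.

    ``hap_a``/``hap_b`` are ``(G, W)`` packed matrices (one parent per row);
    returns the ``(G, W)`` gamete matrix.
    """
    G, W = hap_a.shape
    L = params.L
    mask = np.zeros((G, W), dtype=np.uint64)
    if L > 1:
        x = rng.poisson(params.R, size=G)
        total = int(x.sum())
        if total:
            flat = rng.integers(0, L - 1, size=total)
            rows = _suffix_masks(L)[flat]
            starts = np.zeros(G, dtype=np.int64)
            np.cumsum(x[:-1], out=starts[1:])
            nz = np.flatnonzero(x)
            mask[nz] = np.bitwise_xor.reduceat(rows, starts[nz], axis=0)
    start_with_b = rng.integers(0, 2, size=G).astype(bool)
    mask[start_with_b] ^= _valid_mask(L)
    return (hap_a & ~mask) | (hap_b & mask)


def mutate_pair_batch(
    bits_a: np.ndarray,
    bits_b: np.ndarray,
    params: GeneticParams,
    rng: np.random.Generator,
) -> None:
    """In-place Poisson(``U``) mutation of a batch of newborn diploid genomes."""
    G = bits_a.shape[0]
    k = rng.poisson(params.U, size=G)
    total = int(k.sum())
    if not total:
        return
    row = np.repeat(np.arange(G), k)
    pos = rng.integers(0, 2 * params.L, size=total)
    loci = pos >> 1
    hit_b = (pos & 1).astype(bool)
    for bits, sel in ((bits_a, ~hit_b), (bits_b, hit_b)):
        r = row[sel]
        li = loci[sel]
        if li.size:
            np.bitwise_or.at(
                bits, (r, li >> 6), _ONE << (li & 63).astype(np.uint64)
            )


def count_classes_batch(
    bits_a: np.ndarray, bits_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (m, n) mutation-class counts for packed haplotype matrices."""
    m = popcount(bits_a & bits_b, axis=-1)
    n = popcount(bits_a ^ bits_b, axis=-1)
    return m, n
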
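"""Shared fixtures: small genomes, deterministic RNG streams."""

import numpy as np
import pytest
from hypothesis import settings

from fadsim import (
    GeneticParams,
    Haplotype,
    Individual,
    ModifierAllele,
    ModifierGenotype,
    Strategy,
)
from fadsim.genome import fitness_of

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

UNI_A = ModifierAllele(Strategy.UNI, 0.1)
FAD_A = ModifierAllele(Strategy.FAD, 0.1)


@pytest.fixture
def gp_small() -> GeneticParams:
    return GeneticParams(L=50, s=0.1, h=0.2, U=0.5, R=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_individual(
    loci_a,
    loci_b,
    gp: GeneticParams,
    modifier: ModifierGenotype | None = None,
    deme_id: int = 0,
) -> Individual:
    """Build an individual with an exact fitness cache from explicit loci."""
    if modifier is None:
        modifier = ModifierGenotype(UNI_A, UNI_A)
    hap_a = Haplotype.from_loci(loci_a, gp.L)
    hap_b = Haplotype.from_loci(loci_b, gp.L)
    m = len(set(loci_a) & set(loci_b))
    n = len(set(loci_a) ^ set(loci_b))
    return Individual(
        hap_a=hap_a,
        hap_b=hap_b,
        modifier=modifier,
        phenotype=modifier.allele_a,
        fitness=fitness_of(m, n, gp),
        deme_id=deme_id,
    )
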
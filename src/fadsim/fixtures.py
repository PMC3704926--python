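"""Tiny hand-checkable populations, serialized as JSON, for tests and demos."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .demes import Population
from .genome import GeneticParams, ModifierAllele, Strategy, pack_loci
from .lifecycle import DispersalParams

__all__ = ["generate_fixture_population", "fixture_to_population", "write_fixture"]


def generate_fixture_population(
    n: int,
    L: int,
    spec: Sequence[tuple],
    seed: int,
    *,
    s: float = 0.1,
    h: float = 0.2,
) -> dict:
    """Build a deterministic small population with exact (m, n) mutation counts.

    ``spec`` lists one entry per individual: ``(m, n)`` or
    ``(m, n, (allele_a, allele_b))`` with alleles named ``"UNI"``/``"FAD"``.
    When ``spec`` is shorter than ``n`` the remaining individuals are
    mutation-free UNI homozygotes.  The same seed yields byte-identical JSON.
    """
    if n < 1 or L < 1:
        raise ValueError("n and L must be positive")
    rng = np.random.default_rng(seed)
    gp = GeneticParams(L=L, s=s, h=h)
    individuals = []
    for i in range(n):
        entry = spec[i] if i < len(spec) else (0, 0)
        m, n_het = int(entry[0]), int(entry[1])
        modifier = tuple(entry[2]) if len(entry) > 2 else ("UNI", "UNI")
        for name in modifier:
            if name not in ("UNI", "FAD"):
                raise ValueError(f"unknown modifier allele {name!r}")
        if m + n_het > L:
            raise ValueError(f"individual {i}: m + n = {m + n_het} exceeds L = {L}")
        loci = rng.permutation(L)[: m + n_het]
        hom = loci[:m]
        het = loci[m:]
        on_a = rng.random(n_het) < 0.5
        hap_a = np.concatenate([hom, het[on_a]])
        hap_b = np.concatenate([hom, het[~on_a]])
        phenotype = modifier[0] if modifier[0] == modifier[1] else (
            modifier[0] if rng.integers(0, 2) == 0 else modifier[1]
        )
        fitness = (1.0 - s) ** m * (1.0 - h * s) ** n_het
        individuals.append(
            {
                "hap_a": sorted(int(x) for x in hap_a),
                "hap_b": sorted(int(x) for x in hap_b),
                "modifier": list(modifier),
                "phenotype": phenotype,
                "fitness": fitness,
                "deme": 0,
            }
        )
    return {"L": L, "s": s, "h": h, "n": n, "seed": seed, "individuals": individuals}


def write_fixture(fixture: dict, path) -> None:
    """Write a fixture dict as deterministic (sorted, indented) JSON."""
    Path(path).write_text(json.dumps(fixture, sort_keys=True, indent=1) + "\n")


def fixture_to_population(
    fixture: dict,
    *,
    dparams: Optional[DispersalParams] = None,
    capacity: int = 20,
    U: float = 0.5,
    R: float = 20.0,
) -> Population:
    """Materialize a fixture dict as a :class:`Population`."""
    if dparams is None:
        dparams = DispersalParams()
    L = int(fixture["L"])
    gp = GeneticParams(L=L, s=float(fixture["s"]), h=float(fixture["h"]), U=U, R=R)
    alleles = (
        ModifierAllele(Strategy.UNI, dparams.alpha_U),
        ModifierAllele(Strategy.FAD, dparams.alpha_F),
    )
    code = {"UNI": 0, "FAD": 1}
    inds = fixture["individuals"]
    N = len(inds)
    hap_a = np.zeros((N, gp.n_words), dtype=np.uint64)
    hap_b = np.zeros((N, gp.n_words), dtype=np.uint64)
    genotype = np.zeros((N, 2), dtype=np.int8)
    phenotype = np.zeros(N, dtype=np.int8)
    fitness = np.ones(N, dtype=np.float64)
    deme = np.zeros(N, dtype=np.int32)
    for i, ind in enumerate(inds):
        hap_a[i] = pack_loci(ind["hap_a"], L)
        hap_b[i] = pack_loci(ind["hap_b"], L)
        genotype[i] = [code[a] for a in ind["modifier"]]
        phenotype[i] = code[ind["phenotype"]]
        fitness[i] = float(ind["fitness"])
        deme[i] = int(ind.get("deme", 0))
    return Population(
        hap_a=hap_a,
        hap_b=hap_b,
        genotype=genotype,
        phenotype=phenotype,
        fitness=fitness,
        deme=deme,
        alleles=alleles,
        gparams=gp,
        dparams=dparams,
        capacity=capacity,
        n_total=N,
    )
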
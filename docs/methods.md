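# Methods

## Model

`fadsim` simulates a diploid, simultaneous-hermaphrodite population of
constant total size `N`, subdivided into demes with no spatial geometry
(island model: every deme is an equally likely destination for any
disperser). Generations are discrete and non-overlapping. One generation is:

1. **Dispersal.** Every adult either stays or disperses, according to the
   strategy it expresses:
   - *UNI*: disperse independently with probability α.
   - *FAD*: the number of dispersers among the n_F FAD-expressing adults is
     drawn from Binomial(n_F, α) and the slots are filled in ascending order
     of viability — the least fit disperse first, ties broken uniformly at
     random. The marginal dispersal rate is therefore exactly α, identical
     to UNI; only the *identity* of the dispersers is condition-dependent.
   Every disperser, regardless of genotype, dies with probability `c` (the
   cost of dispersal). Survivors are placed in a uniformly random deme
   (natal deme included).
2. **Reproduction with viability selection.** For each conception a parent
   deme is drawn with probability proportional to its post-dispersal adult
   count, restricted to demes with at least two adults (mating is strictly
   within-deme and there is no self-fertilization). Two distinct parents are
   drawn uniformly; each contributes one gamete; the newborn acquires
   Poisson(`U`) new deleterious mutations at uniformly random allele copies,
   realizes its dispersal phenotype, and survives to adulthood with
   probability equal to its viability. Conceptions repeat until exactly `N`
   offspring survive; they replace the parents wholesale and inherit their
   parents' deme.
3. **Deme regulation.** A deme whose census exceeds the capacity `K` is
   split into two uniformly random halves (repeatedly if necessary); demes
   with no members disappear. Deme labels are transient and carry no lineage
   information.

**Genome.** `L` bi-allelic fitness loci (wild-type / deleterious mutant) on
two chromosome copies, plus one diploid modifier locus. Viability is
multiplicative: `w = (1 − s)^m (1 − h·s)^n` for `m` homozygous and `n`
heterozygous deleterious mutations. There is no epistasis, no back mutation
(a mutation that hits an already-mutant copy leaves it mutant), and the
modifier locus never mutates. Meiosis draws Poisson(`R`) crossovers per
gamete among the `L − 1` inter-locus intervals; the modifier locus
segregates freely from the fitness loci (fair coin, independent of the
crossover pattern). Modifier heterozygotes express one of their two alleles,
chosen by a fair coin once at birth and fixed for life — as if half of them
developed as each homozygote.

## Parameters and defaults

| symbol | meaning | default |
|---|---|---|
| `N` | total population size | 5,000 |
| `K` | deme capacity (census above `K` triggers a split) | 20 |
| `L` | number of diploid fitness loci | 10,000 |
| `s` | selection coefficient, homozygous effect | 0.1 |
| `h` | dominance coefficient (heterozygous effect = `h·s`) | 0.2 (studied range 0.2–0.5) |
| `U` | expected new deleterious mutations per newborn genome | 0.5 |
| `R` | expected crossovers among fitness loci per meiosis | 20 |
| α_U, α_F | mean dispersal rate of each strategy (constant within a run) | 0.01 / 0.1 / 0.3 |
| `c` | probability a disperser dies before reproducing | 0 – 0.5 |
| `f0` | initial invader allele frequency (exact count) | 0.01 / 0.05 |
| `G_max` | invasion generation cap | 30,000 |

The defaults are the full-scale study conditions. The test suite and the
acceptance script run a *desk scale* — `N = 300` (250–500 for some
controls), `L = 1,000`, `K = 20` — with `s`, `h`, `U`, `R` unchanged, so
per-individual quantities (load ≈ `U/(h·s)`, viability plateau) are
comparable to full scale while a replicate finishes in seconds.

## Experiments

**Steady state.** A modifier-homogeneous population is stepped until mean
fitness and heterozygosity are at mutation–selection balance. Convergence is
declared when the linear-regression slope of each series over the last `W`
generations is statistically indistinguishable from zero (two-sided
p ≥ 0.05), after a hard minimum burn-in and subject to a generation cap
(defaults `W` = 500, minimum 2,000, cap 20,000; the desk scale uses
`W` = 400–500, minimum 1,500–2,000, cap 4,000–6,000). Plateau statistics are
the mean ± SE over the final window; non-convergence is reported explicitly.

**Invasion.** Into an equilibrated resident, `round(f0·N)` uniformly chosen
individuals are converted to invader-allele homozygotes (phenotypes
re-assigned), so the initial allele frequency is exactly `f0` in every
replicate — exact-count assignment removes initial-frequency variance
between replicates. Generations are stepped until the invader allele
frequency reaches 0 (*extinct*) or 1 (*fixed*) or `G_max` passes
(*timeout*). Takeover time is the number of generations between the first
crossing of frequency 0.01 and the first crossing of 0.8, reported only when
0.8 is reached. Invasion success over replicates is judged against the
neutral expectation — a neutral allele fixes with probability `f0` — with a
one-sided exact binomial test. Parameter sweeps classify each (α, c, h) cell
four ways (both strategies invade / only FAD / FAD maintained polymorphic /
neither); "polymorphic" means at least half the FAD replicates timed out
with the invader frequency still in (0.05, 0.95).

## Summary statistics

Per generation the simulator records:

- **mean fitness** — arithmetic mean viability of the adults;
- **cost-adjusted mean fitness** — viability summed over the adults that
  survived the dispersal stage divided by the pre-dispersal census, i.e.
  dispersal mortality is folded in as a fitness component. Under UNI this is
  ≈ mean viability × (1 − α·c); under FAD the cost falls on low-viability
  individuals, so the two measures diverge. The cost-*exclusive* mean
  viability *rises* with `c` under UNI in this model (weaker migration means
  more consanguineous mating, which purges partially recessive load); the
  cost-inclusive measure is the one that falls with `c`, and it is the
  measure used in the trend analyses;
- **heterozygosity**, in three flavours: the pooled fraction of deleterious
  allele copies residing in heterozygous loci, `Σn / Σ(n + 2m)` (defined as
  0 for a mutation-free population); the mean of per-individual fractions;
  and the mean per-locus frequency of heterozygous loci, `mean(n)/L`. The
  pooled fraction is dominated by the population's fixation structure
  (≈ 1 − F) and responds only weakly to `h`; the per-locus het frequency
  scales as ≈ `u/(h·s)` and is the statistic whose response to `h` and `c`
  the trend analyses track;
- **modifier statistics** — FAD allele frequency, each allele's frequency,
  and sub-population mean fitness both by expressed phenotype and by allele
  *copies* (heterozygote carriers count toward both alleles). The allele-copy
  measure is the natural observable for the abandon-ship effect, since it
  measures the genetic backgrounds an allele is riding;
- deme count.

## Numerical and design choices

- **Bitset genomes.** A haplotype is a packed bitmask (64 loci per word).
  Mutation-class counts are popcounts of AND/XOR; a crossover pattern is the
  XOR of precomputed suffix masks, one per breakpoint. This makes a full
  generation at desk scale ≈ 3 ms on one core.
- **Crossover positions are drawn uniformly with replacement** among the
  `L − 1` inter-locus intervals; a pair of hits in the same interval cancels
  (an even number of crossovers between adjacent loci is invisible). With
  `R = 20` and `L = 1,000` a within-gamete collision occurs in ~17% of
  meioses and merely converts `x` into `x − 2` effective crossovers — a
  negligible perturbation of a count that is already Poisson-distributed.
- **Batched reproduction.** Conceptions are vectorized in batches; because
  parent-deme weights are fixed during the reproduction stage (parents are
  not consumed), each conception is an independent, identically distributed
  draw and batching changes only the interleaving of RNG calls. A
  per-individual API (`produce_offspring`, `make_gamete`) built on the same
  kernels is used by the unit tests. A conception budget (default
  `1000 × N` attempts) turns a pathological rejection loop into a
  diagnostic error instead of a hang.
- **FAD ranking scope.** The binomial draw and the fitness ranking are
  population-wide by default; a per-deme variant (`fad_scope: deme`) exists
  for sensitivity analysis. Ranking uses the viability cached at birth; ties
  are broken uniformly at random.
- **Single RNG stream per replicate** (`numpy` PCG64), all stages drawing in
  a fixed documented order, so every run is bit-reproducible from one seed.
  Replicate seeds are derived from a base seed by a counter-based
  `SeedSequence` scheme and recorded per output row.
- **Initial state** is a mutation-free population; burn-in to the monitored
  steady state makes the choice immaterial.
- Degenerate inputs fail loudly: a population whose dispersers all perish
  raises an extinction error; a generation in which no deme holds two adults
  raises a reproduction error; configuration files with unknown keys or
  out-of-range values are rejected with the offending key named.

## What the desk-scale experiments do and do not show

The desk-scale conditions preserve the per-individual mutation, selection
and dispersal regime, so qualitative conclusions — FAD invades against a
neutral baseline, purging raises FAD's cost-inclusive fitness with `c`,
heterozygosity falls with `h` — transfer. Two quantitative caveats:

- With `N = 300`, a 1% invasion means three invader individuals, so
  per-replicate success is bounded by establishment luck
  (~10% at α = 0.1, c = 0.1, versus 1% neutral). Achieved significance
  levels per 50-replicate battery are therefore on the order of 10⁻⁴–10⁻⁶,
  not the 10⁻¹⁰ attainable at `N = 5,000` where the same `f0` seeds 50
  invaders.
- The standing fitness gap between FAD and UNI allele copies during a
  cost-free invasion is of order +0.002–0.009, while the per-generation
  sampling noise of a 20-replicate desk-scale pool is of the same order;
  the gap is positive on average but not in ≥95% of individual generations
  at this sampling depth. Resolving it generation-by-generation requires
  roughly the full-scale population × 100-replicate averaging.

Other limitations: the environment is homogeneous and constant (no
genotype-by-environment interaction, no temporal change); loci do not
interact; the dispersal cost is condition-independent; the modifier does not
mutate; generations do not overlap. The simulator's genomes are abstract
loci, not sequences — no linkage map beyond uniform crossover placement, no
neutral markers.
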
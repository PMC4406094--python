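# Methods

## The question and the model

`dmscape` asks whether limited dispersal alone — with no geographic barrier
and no spatially heterogeneous selection — can produce persistent spatial
clusters of reproductively isolated genotypes in a continuously distributed
population. Reproductive isolation is encoded as a classic two-locus
Dobzhansky–Muller (DM) incompatibility: derived alleles *a* (locus 0) and
*B* (locus 1) are individually harmless, but any genotype carrying at least
one copy of each has viability 0. Starting from a population monomorphic
AAbb, the incompatible pair can only be assembled through one-way mutation
(A→a, b→B) and subsequent matings, so the compatible "pure" classes AABB
and aabb can each spread locally while their contact produces inviable
AaBb offspring.

## Landscape

The habitat is a fixed set of home-range sites placed i.i.d. uniformly on a
rectangle. The rectangle is specified by its area (7237.60 units²) and its
diagonal, the maximum possible distance on the landscape (123.2 units); the
unique width/height solution is ≈ 99.36 × 72.84. The default density is
5000 sites / 7237.60 units² ≈ 0.691 per unit², which makes the expected
number of individuals within a movement radius `r` equal to ρπr² (21 at the
2.5% radius, 329 at the 10% radius, and so on). Distances are Euclidean;
there is no toroidal wrap, no resistance surface, and sites never move:
individuals die, sites persist, and dispersing offspring fill vacancies.

## Generation cycle

Generations are non-overlapping (100% adult mortality). Each cycle:

1. **Mate selection.** Every female draws one mate among the living males
   within `dmax = movement_fraction × 123.2` of her site, with probability
   ∝ 1/max(d, d_floor)². Males are chosen with replacement; a female with
   no male in range skips reproduction. One mate draw per female per
   generation: the movement function fixes the pairing probabilities, and a
   single draw plus Poisson fecundity reproduces the intended
   excess-offspring regime.
2. **Reproduction.** Each mated female produces Poisson(λ = 4) offspring.
   Each offspring receives one gamete from each parent (free recombination:
   an independent fair pick per locus), transmission mutation (below), a
   fair-coin sex, and its mother's site as natal site.
3. **Dispersal with viability selection.** All adults are dead, so all
   sites are vacant. Offspring are processed in a uniformly random order to
   avoid positional bias in who gets scarce vacancies. Each draws one
   settlement site among the currently vacant sites within `dmax` of its
   natal site, inverse-square weighted, with the natal site itself a
   candidate at the distance floor — philopatry therefore gets the largest
   finite weight. On settling, the offspring survives with probability
   equal to its DM viability (Bernoulli; deterministic under the default
   0/1 surface); a death leaves the site vacant for later offspring.
   An offspring with no vacant site in range is discarded, and processing
   stops once every site is filled, which discards the surplus brood.

Each offspring draws a single settlement site; there is no retry after a
failed draw. This keeps the settlement distribution exactly the truncated
kernel restricted to vacancies at the moment of processing.

### Kernel details

The inverse-square kernel diverges at d = 0, so distances are floored at
`d_floor` = half the minimum non-zero inter-site spacing of the realized
site map (≈ 0.005 units at the default density). The floor only ever binds
for the natal site (all other candidates are at least one full spacing
away). The consequences: the natal site carries almost all of the dispersal
weight whenever it is vacant, and dispersal beyond it is dominated by the
nearest vacant neighbors — a strongly philopatric regime in which
generation-to-generation gene flow is carried mainly by mate choice.

### Sequential draws by rejection sampling

Both mating and dispersal are sequential weighted draws over a subset of
candidates that changes as the generation proceeds (living males; vacant
sites). Rather than renormalizing weights per draw, each site's cumulative
inverse-square weights over its full neighbor list are precomputed once per
replicate (CSR layout over a KD-tree fixed-radius query). A draw then
samples the full list by binary search and rejects invalid candidates;
conditioned on acceptance this is exactly the renormalized draw over the
valid subset. After a bounded number of rejections (32 for mating, 64 for
dispersal) the code falls back to an exact linear-scan draw over the valid
candidates, which preserves the distribution while bounding worst-case
work; the fallback is also how an empty valid set (no male in range, no
vacancy in range) is detected. The two inner loops are numba-compiled and
consume scalar variates from the same `numpy.random.Generator` that drives
every vectorized stage, so one integer seed fixes a replicate bit-for-bit.

## Genetics

22 diallelic loci: two selected (above) and 20 neutral markers initialized
with each allele slot drawn uniformly from {0, 1} (expected initial
heterozygosity 0.5 per locus). Mutation acts on gametes at transmission,
per allele, at rate μ = 0.0005: one-way at the selected loci (A→a, b→B,
never reverting) and as an allele flip at the neutral loci (the k-allele
model with k = 2 has only one alternative allele). Mutating standing adults
instead would be equivalent here up to timing; per-transmission mutation is
the standard convention for non-overlapping generations.

## Summary statistics

Per generation, over the 20 neutral loci with all individuals pooled:
observed heterozygosity Ho, expected heterozygosity He (1 − Σp² per locus,
averaged), and Wright's F = 1 − Ho/He computed as the *ratio of the two
cross-locus means*, never as a mean of per-locus ratios. Positive F is a
Wahlund-style heterozygote deficit and is the study's index of isolation by
distance. No small-sample correction is applied to He: at n = 5000 the
2n/(2n−1) factor changes He by < 10⁻⁴. The selected loci are excluded from
F.

## RI events

A generation is flagged as an *RI event* when DBSCAN — run separately on
the coordinates of the AABB carriers and of the aabb carriers — finds at
least one cluster in each class. DBSCAN uses MinPts = 4 (query point
included) and ε = 2.0 length-units. The ε default deserves a note: the
sorted 4-dist heuristic on simulated snapshots puts the knee at about this
scale (≈ 1.6% of the maximum landscape distance), and ε is held fixed
across generations and scenarios so that counts are comparable; the
heuristic itself is exposed (`sorted_kdist` / `suggest_epsilon`, CLI
`kdist`) but never silently applied. Persistence is tabulated separately as
the run lengths of consecutive flagged generations; the per-generation flag
count is the reported "number of RI events" and is not filtered by
persistence.

The in-package DBSCAN follows the classical density-reachability
definition with a fixed ascending-index scan order, so border points tied
between two clusters go to the first-discovered one, deterministically.
The test suite checks it against both a brute-force reachability oracle
and scikit-learn's implementation.

## Experiment design and problem sizes

The full design sweeps movement fractions {2.5, 5, 7.5, 10, 15, 20, 25,
100}% with 10 replicates of 1000 generations each at 5000 individuals.
Desk-scale runs — the defaults used by the acceptance script and the
heavyweight tests — keep the full population size and the full 1000
generations but use 3 replicates and the five fractions the headline
numbers need (2.5, 5, 10, 15, 100%); the paper-scale sweep is one flag away
(`dmscape sweep --replicates 10`). Replicate `r` of scenario `s` is seeded
`base_seed + 10000·s + r`. Extinction (possible in principle if viable
offspring run out) truncates a replicate and is reported, not raised.

Confidence intervals across replicates are normal approximations
(mean ± 1.96 SE). With 3 replicates they are indicative only.

## What the generator emulates — and what it does not

The synthetic landscape and population reproduce the study conditions:
uniform random home ranges at density 0.691, founding monomorphism AAbb,
maximal neutral diversity, and movement-limited mating and dispersal on a
barrier-free, selection-flat landscape. They deliberately omit features of
real systems — habitat heterogeneity, resistance to movement, age
structure, sex-biased dispersal, fecundity variation beyond Poisson,
linkage — so passing tests show that the *mechanism* (restricted movement
plus DM lethality) produces spatial clusters of incompatible genotypes,
not that any particular natural population behaves this way.

## Known limitations and numerical choices

* The original study's simulator leaves several internals unprinted (the
  exact inverse-square discretization, its handling of the d = 0
  singularity, the initial neutral-allele assignment that it reports as
  He ≈ 0.45 where uniform assignment gives 0.5). This implementation makes
  each choice explicit (floor at half the minimum spacing; natal-site
  candidacy; uniform initialization) and holds them fixed. The consequence
  visible in our results: RI-event counts, durations, and the
  full-movement F reproduce the published values, while final F in the
  2.5% scenario stabilizes near 0.33 rather than 0.41 — the right ordering
  and magnitude, but a weaker heterozygote deficit, consistent with the
  reference simulator realizing somewhat shorter effective gene-flow
  distances than our reading of the kernel. Sensitivity runs (halving or
  zeroing the neutral mutation rate; mean-of-ratios F) do not close the
  gap, so we report it rather than tune any parameter away from its stated
  value.
* ε = 2.0 units is an inference: the source reports its threshold in
  different units ("2000-m") than its landscape extent; 1.6% of the
  maximum distance honors both printed numbers and is flagged prominently
  here.
* Kernel normalization is exact to one cumulative sum; probability vectors
  sum to 1 within 1e-12 (tested).
* Degenerate inputs: empty candidate sets are outcomes (skip reproduction,
  discard offspring), never exceptions; an empty population propagates as
  an empty population; F is undefined (raises) when He = 0.
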
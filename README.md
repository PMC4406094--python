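# dmscape

Individual-based, spatially explicit simulation of how **limited dispersal
alone** — without geographic barriers or heterogeneous selection — produces
persistent spatial clusters of reproductively isolated genotypes in a
continuously distributed population.

It is written for population and landscape geneticists who want a small,
fully reproducible model of isolation by distance (IBD) interacting with a
two-locus Dobzhansky–Muller (DM) incompatibility, and for anyone who needs
its building blocks: a truncated inverse-square movement kernel on a fixed
site map, non-overlapping-generation Mendelian transmission with k-allele
mutation, pooled-population Wright's *F*, and a deterministic DBSCAN with
the sorted k-dist ε heuristic.

## The model in brief

5000 individuals occupy fixed, uniformly random home-range sites on a
rectangle of area 7237.60 units² whose diagonal (the maximum landscape
distance) is 123.2 units. Each generation: every female picks one mate
among males within a movement radius `dmax = f × 123.2` (f is the *movement
fraction*), weighted ∝ 1/d²; mated females bear Poisson(λ = 4) offspring;
all adults die; offspring disperse, in random order, to vacant sites within
`dmax` of their natal site (same kernel, natal site favored) where they
survive with the DM viability of their genotype.

Two of the 22 diallelic loci are under selection: derived alleles *a* and
*B* arise by one-way mutation (μ = 0.0005) from the founding AAbb genotype
and are lethal in combination, so

    w(g) = 0  if g carries ≥1 a and ≥1 B   (AaBB, AaBb, aaBB, aaBb)
    w(g) = 1  otherwise                     (AABB, AABb, AAbb, Aabb, aabb)

Spatial structure is tracked over the 20 neutral loci by Wright's
*F* = 1 − H̄ₒ/H̄ₑ with all individuals pooled (a Wahlund-effect index), and
reproductive isolation is scored per generation as an **RI event**: DBSCAN
(ε = 2 units, MinPts = 4) finds at least one spatial cluster among the AABB
carriers and simultaneously one among the aabb carriers. Event persistence
is the run length of consecutively flagged generations.

## Worked example

One short replicate of the strongest-isolation scenario (2.5% movement;
small run for illustration):

```bash
$ dmscape simulate --movement-fraction 0.025 --generations 100 --seed 11 \
    --out stats.csv
status=ok ri_generations=16 events=11 mean_duration=1.45 max_duration=3 final_F=0.2642
```

`stats.csv` holds one row per generation: population size, pooled Ho, He
and F over the neutral loci, the nine two-locus genotype class counts, the
RI flag and the per-class DBSCAN cluster counts. Here, by generation 100
the population already shows strong heterozygote deficit (F ≈ 0.26 and
still rising; effectively zero under full movement) and the first
transient RI events: generations in which mutually incompatible AABB and
aabb neighborhoods coexist on a barrier-free landscape.

The analytic genetic-neighborhood table (expected mates within each
movement radius at density 0.691 units⁻²):

```bash
$ dmscape table1
 movement_pct  radius  expected_individuals  proportion
        100.0  123.20                  5000      1.0000
         25.0   30.80                  2059      0.4118
         20.0   24.64                  1318      0.2636
         15.0   18.48                   741      0.1482
         10.0   12.32                   329      0.0658
          7.5    9.24                   185      0.0370
          5.0    6.16                    82      0.0164
          2.5    3.08                    21      0.0042
```

Other subcommands: `dmscape sweep` (movement-fraction grid with replicate
summaries), `dmscape kdist` (sorted k-dist ε heuristic on a point CSV),
`dmscape analyze` (recompute RI flags/durations from dumped snapshots).

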
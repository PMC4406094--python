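"""The generation loop: mating, reproduction, mortality, dispersal, selection.

Generations do not overlap.  One cycle runs, in order:

1. **Mate selection.**  Every female draws one mate among the living males
   within the movement radius ``dmax`` of her site, with probability
   proportional to an inverse-square kernel of distance (truncated at
   ``dmax``).  Both sexes mate with replacement; a female with no male in
   range simply skips reproduction that generation.
2. **Reproduction.**  Each mated female produces ``Poisson(lambda)``
   offspring.  Each offspring receives one mutated gamete from each parent,
   a fair-coin sex, and its mother's site as natal site.
3. **Adult mortality.**  All adults die (100% mortality), vacating every
   home-range site.
4. **Dispersal with viability selection.**  Offspring are processed in a
   uniformly random order.  Each draws a settlement site from the currently
   *vacant* sites within ``dmax`` of its natal site, again inverse-square
   weighted; the natal site itself is a candidate at the kernel's distance
   floor (so philopatry gets the largest finite weight).  On settling, the
   offspring survives with probability equal to its Dobzhansky-Muller
   viability; a death leaves the site vacant for later offspring.
   Processing stops when every site is filled; surplus offspring, and
   offspring with no vacant site in range, are discarded.

The inverse-square kernel is singular at distance zero, so distances are
floored at half the minimum inter-site spacing before inversion.

Both sequential stages (mating and dispersal) draw sites by rejection
sampling against a precomputed per-site cumulative weight table: a draw
from the *full* truncated kernel is repeated until it lands on a currently
valid candidate (a living male, or a vacant site).  Conditioned on
acceptance this is exactly the renormalized weighted draw over the valid
subset; after a bounded number of rejections the code falls back to an
exact linear-scan draw, which preserves the distribution while bounding
worst-case work.  The loops are compiled with numba and consume scalar
variates from the same ``numpy.random.Generator`` that drives the
vectorized stages, so a replicate is a single reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .genome import (
    FitnessModel,
    LociConfig,
    dm_fitness,
    initial_genotypes,
    make_gametes,
    mutate_gametes,
)
from .landscape import NeighborIndex, SiteMap

__all__ = [
    "FEMALE",
    "MALE",
    "ScenarioConfig",
    "Population",
    "OffspringPool",
    "MovementKernel",
    "kernel_weights",
    "build_movement_kernel",
    "founding_population",
    "select_mate",
    "select_mates",
    "reproduce",
    "disperse_and_select",
    "step_generation",
]

FEMALE = 0
MALE = 1

#: Area (length-units squared) and maximum (diagonal) distance of the study
#: landscape; together they pin down the rectangle uniquely.
DEFAULT_AREA = 7237.60
DEFAULT_MAX_DISTANCE = 123.2

#: The eight movement radii explored, as fractions of the landscape maximum.
MOVEMENT_FRACTIONS = (0.025, 0.05, 0.075, 0.10, 0.15, 0.20, 0.25, 1.00)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario.

    ``movement_fraction`` scales the landscape maximum distance to the
    movement limit ``dmax`` that truncates both the mating and the dispersal
    kernel.  ``lam`` is the Poisson mean number of offspring per mated
    female; 4 keeps the offspring pool roughly twice the number of sites so
    the population stays at carrying capacity.
    """

    movement_fraction: float
    n_sites: int = 5000
    lam: float = 4.0
    generations: int = 1000
    loci: LociConfig = LociConfig()
    fitness: FitnessModel = FitnessModel()
    seed: int = 0
    area: float = DEFAULT_AREA
    max_distance: float = DEFAULT_MAX_DISTANCE

    def __post_init__(self) -> None:
        if not 0.0 < self.movement_fraction <= 1.0:
            raise ValueError("movement_fraction must lie in (0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def dmax(self) -> float:
        return self.movement_fraction * self.max_distance


@dataclass
class Population:
    """Site-indexed population state at the end of a generation.

    Arrays are aligned with the site map: ``occupied[i]`` says whether site
    ``i`` hosts a living individual, in which case ``sex[i]`` and
    ``genotypes[i]`` describe it.  At most one individual per site.
    """

    occupied: np.ndarray  # (n_sites,) bool
    sex: np.ndarray  # (n_sites,) int8; FEMALE / MALE
    genotypes: np.ndarray  # (n_sites, n_loci, 2) int8
    generation: int = 0

    @property
    def size(self) -> int:
        return int(self.occupied.sum())

    def alive_sites(self) -> np.ndarray:
        return np.flatnonzero(self.occupied)

    def alive_genotypes(self) -> np.ndarray:
        return self.genotypes[self.occupied]


@dataclass
class OffspringPool:
    """Pre-dispersal offspring: genotype, sex, and natal (maternal) site."""

    genotypes: np.ndarray  # (m, n_loci, 2) int8
    sex: np.ndarray  # (m,) int8
    natal: np.ndarray  # (m,) int64 site ids

    @property
    def size(self) -> int:
        return int(self.natal.size)


def kernel_weights(distances, dmax: float, d_floor: float = 0.0) -> np.ndarray:
    """Normalized inverse-square movement weights for candidate distances.

    Weight is proportional to ``1 / max(d, d_floor)**2``; candidates beyond
    ``dmax`` are a caller error (truncation happens upstream via the
    neighbor index).  An empty candidate list returns an empty vector — the
    caller interprets that as "no candidates", not an error.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        return d.copy()
    if (d > dmax * (1 + 1e-12)).any():
        raise ValueError("candidate beyond the movement limit dmax")
    d_eff = np.maximum(d, d_floor)
    if (d_eff <= 0).any():
        raise ValueError("zero distance requires a positive d_floor")
    w = 1.0 / (d_eff * d_eff)
    return w / w.sum()


@dataclass(frozen=True)
class MovementKernel:
    """Per-site cumulative inverse-square weights over the neighbor index.

    ``cumw[indptr[i]:indptr[i+1]]`` is the running sum of the (unnormalized)
    weights of site ``i``'s neighbors, in neighbor-index order; ``w_self``
    is the weight of the focal site itself (distance floored), used only by
    dispersal, where the natal site is a legal destination.
    """

    indptr: np.ndarray
    indices: np.ndarray
    cumw: np.ndarray
    w_self: float
    d_floor: float
    dmax: float


def build_movement_kernel(index: NeighborIndex, d_floor: float) -> MovementKernel:
    if d_floor <= 0:
        raise ValueError("d_floor must be positive")
    d_eff = np.maximum(index.distances, d_floor)
    w = 1.0 / (d_eff * d_eff)
    cs = np.cumsum(w)
    row_lo = index.indptr[:-1]
    before = np.where(row_lo > 0, cs[row_lo - 1], 0.0)
    counts = np.diff(index.indptr)
    cumw = cs - np.repeat(before, counts)
    return MovementKernel(
        indptr=index.indptr,
        indices=index.indices,
        cumw=cumw,
        w_self=1.0 / (d_floor * d_floor),
        d_floor=float(d_floor),
        dmax=float(index.radius),
    )


def default_distance_floor(sites: SiteMap) -> float:
    """Half the minimum non-zero inter-site distance (kernel singularity guard)."""
    return 0.5 * sites.min_spacing()


# --------------------------------------------------------------------------
# compiled inner loops


@njit(cache=True, inline="always")
def _row_bisect(cumw, lo, hi, r):
    """First j in [lo, hi) with cumw[j] > r (row-local cumulative weights)."""
    a, b = lo, hi
    while a < b:
        mid = (a + b) // 2
        if cumw[mid] > r:
            b = mid
        else:
            a = mid + 1
    return min(a, hi - 1)


@njit(cache=True)
def _mate_kernel(indptr, indices, cumw, occupied, sex, female_sites, fathers, rng):
    for fi in range(female_sites.size):
        f = female_sites[fi]
        lo, hi = indptr[f], indptr[f + 1]
        chosen = -1
        if hi > lo:
            total = cumw[hi - 1]
            for _ in range(32):
                r = rng.random() * total
                j = _row_bisect(cumw, lo, hi, r)
                s = indices[j]
                if occupied[s] and sex[s] == MALE:
                    chosen = s
                    break
            if chosen == -1:
                # exact weighted draw over the valid males (may be none)
                tot = 0.0
                for j in range(lo, hi):
                    s = indices[j]
                    if occupied[s] and sex[s] == MALE:
                        tot += cumw[j] - (cumw[j - 1] if j > lo else 0.0)
                if tot > 0.0:
                    r = rng.random() * tot
                    acc = 0.0
                    for j in range(lo, hi):
                        s = indices[j]
                        if occupied[s] and sex[s] == MALE:
                            acc += cumw[j] - (cumw[j - 1] if j > lo else 0.0)
                            if r < acc or j == hi - 1:
                                chosen = s
                                break
                    if chosen == -1:  # roundoff: take the last valid male
                        for j in range(hi - 1, lo - 1, -1):
                            s = indices[j]
                            if occupied[s] and sex[s] == MALE:
                                chosen = s
                                break
        fathers[fi] = chosen


@njit(cache=True)
def _disperse_kernel(indptr, indices, cumw, w_self, occupied, natal, viab, settle, rng):
    n_vacant = occupied.size - np.sum(occupied)
    for o in range(natal.size):
        settle[o] = -1
        if n_vacant == 0:
            continue  # all sites filled: remaining offspring discarded
        nat = natal[o]
        lo, hi = indptr[nat], indptr[nat + 1]
        nb_total = cumw[hi - 1] if hi > lo else 0.0
        self_ok = not occupied[nat]
        ws = w_self if self_ok else 0.0
        total = nb_total + ws
        site = -1
        if total > 0.0:
            for _ in range(64):
                r = rng.random() * total
                if r < ws:
                    site = nat
                    break
                s = indices[_row_bisect(cumw, lo, hi, r - ws)]
                if not occupied[s]:
                    site = s
                    break
            if site == -1:
                # exact draw over the vacant candidates (may be none)
                tot = ws
                for j in range(lo, hi):
                    s = indices[j]
                    if not occupied[s]:
                        tot += cumw[j] - (cumw[j - 1] if j > lo else 0.0)
                if tot > 0.0:
                    r = rng.random() * tot
                    if r < ws:
                        site = nat
                    else:
                        acc = ws
                        for j in range(lo, hi):
                            s = indices[j]
                            if not occupied[s]:
                                acc += cumw[j] - (cumw[j - 1] if j > lo else 0.0)
                                if r < acc:
                                    site = s
                                    break
                        if site == -1:
                            for j in range(hi - 1, lo - 1, -1):
                                if not occupied[indices[j]]:
                                    site = indices[j]
                                    break
        if site >= 0:
            # viability selection at the settlement site
            if rng.random() < viab[o]:
                occupied[site] = True
                settle[o] = site
                n_vacant -= 1


# --------------------------------------------------------------------------
# public operations


def founding_population(cfg: ScenarioConfig, rng: np.random.Generator) -> Population:
    """Fully occupied founding population: AAbb selected loci, random sexes."""
    n = cfg.n_sites
    return Population(
        occupied=np.ones(n, dtype=bool),
        sex=rng.integers(0, 2, size=n, dtype=np.int8),
        genotypes=initial_genotypes(n, cfg.loci, rng),
        generation=0,
    )


def select_mates(
    pop: Population, kernel: MovementKernel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one mate per living female; returns (female_sites, father_sites).

    ``father_sites[i] == -1`` marks a female with no male in range.
    """
    female_sites = np.flatnonzero(pop.occupied & (pop.sex == FEMALE))
    fathers = np.empty(female_sites.size, dtype=np.int64)
    if female_sites.size:
        _mate_kernel(
            kernel.indptr, kernel.indices, kernel.cumw,
            pop.occupied, pop.sex, female_sites, fathers, rng,
        )
    return female_sites, fathers


def select_mate(
    female_site: int, pop: Population, kernel: MovementKernel, rng: np.random.Generator
) -> int:
    """Single-female mate draw (same distribution as :func:`select_mates`).

    Returns the chosen male's site, or -1 when no male is in range.
    """
    sites = np.array([female_site], dtype=np.int64)
    fathers = np.empty(1, dtype=np.int64)
    _mate_kernel(
        kernel.indptr, kernel.indices, kernel.cumw,
        pop.occupied, pop.sex, sites, fathers, rng,
    )
    return int(fathers[0])


def reproduce(
    mother_sites: np.ndarray,
    father_sites: np.ndarray,
    pop: Population,
    lam: float,
    loci: LociConfig,
    rng: np.random.Generator,
) -> OffspringPool:
    """Poisson reproduction for each mated pair, with transmission mutation.

    Each pair contributes ``Poisson(lam)`` offspring; each offspring gets an
    independently segregated, independently mutated gamete from each parent
    and a fair-coin sex.  Natal site is the mother's site.
    """
    mated = father_sites >= 0
    mothers = mother_sites[mated]
    fathers = father_sites[mated]
    counts = rng.poisson(lam, size=mothers.size)
    mom = np.repeat(mothers, counts)
    dad = np.repeat(fathers, counts)
    m = mom.size
    if m == 0:
        L = loci.n_loci
        return OffspringPool(
            genotypes=np.empty((0, L, 2), dtype=np.int8),
            sex=np.empty(0, dtype=np.int8),
            natal=np.empty(0, dtype=np.int64),
        )
    egg = mutate_gametes(make_gametes(pop.genotypes[mom], rng), loci, rng)
    sperm = mutate_gametes(make_gametes(pop.genotypes[dad], rng), loci, rng)
    genotypes = np.stack([egg, sperm], axis=2)
    sexes = rng.integers(0, 2, size=m, dtype=np.int8)
    return OffspringPool(genotypes=genotypes, sex=sexes, natal=mom)


def disperse_and_select(
    pool: OffspringPool,
    kernel: MovementKernel,
    fitness: FitnessModel,
    n_sites: int,
    rng: np.random.Generator,
    generation: int = 0,
) -> Population:
    """Settle offspring onto vacant sites and apply viability selection.

    Adults are already dead, so every site starts vacant.  Offspring are
    processed in a uniformly random order; see the module docstring for the
    settlement rule.  The returned population may be smaller than
    ``n_sites`` if the pool runs out of placeable, viable offspring.
    """
    occupied = np.zeros(n_sites, dtype=bool)
    L = pool.genotypes.shape[1] if pool.size else 0
    sex = np.zeros(n_sites, dtype=np.int8)
    genotypes = np.zeros((n_sites, max(L, 1), 2), dtype=np.int8)
    if pool.size:
        order = rng.permutation(pool.size)
        natal = pool.natal[order]
        viab = np.asarray(dm_fitness(pool.genotypes[order], fitness), dtype=np.float64)
        settle = np.empty(pool.size, dtype=np.int64)
        _disperse_kernel(
            kernel.indptr, kernel.indices, kernel.cumw, kernel.w_self,
            occupied, natal, viab, settle, rng,
        )
        placed = settle >= 0
        sites = settle[placed]
        src = order[placed]
        sex[sites] = pool.sex[src]
        genotypes = np.zeros((n_sites, L, 2), dtype=np.int8)
        genotypes[sites] = pool.genotypes[src]
    return Population(occupied=occupied, sex=sex, genotypes=genotypes,
                      generation=generation)


def step_generation(
    pop: Population,
    cfg: ScenarioConfig,
    kernel: MovementKernel,
    rng: np.random.Generator,
) -> Population:
    """Advance the population by one full non-overlapping generation."""
    if pop.size == 0:
        return replace(pop, generation=pop.generation + 1)
    mothers, fathers = select_mates(pop, kernel, rng)
    pool = reproduce(mothers, fathers, pop, cfg.lam, cfg.loci, rng)
    # adult mortality is implicit: only offspring enter dispersal
    nxt = disperse_and_select(
        pool, kernel, cfg.fitness, cfg.n_sites, rng,
        generation=pop.generation + 1,
    )
    if nxt.genotypes.shape[1] != cfg.loci.n_loci:
        nxt.genotypes = np.zeros((cfg.n_sites, cfg.loci.n_loci, 2), dtype=np.int8)
    return nxt
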
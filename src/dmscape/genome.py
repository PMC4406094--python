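"""Genotypes, Mendelian transmission, mutation, and Dobzhansky-Muller fitness.

Each diploid individual carries 22 diallelic loci.  Loci 0 and 1 are under
selection: locus 0 segregates alleles A/a (coded 0/1) and locus 1 alleles
b/B (coded 0/1).  The remaining 20 loci are neutral markers with arbitrary
binary allele labels.  Genotypes are unordered — there is no parental-origin
or sex-linkage bookkeeping — and are stored as int8 arrays of shape
``(n_loci, 2)`` (or ``(n, n_loci, 2)`` for a population).

The Dobzhansky-Muller (DM) model used here is the classic two-locus
two-allele incompatibility: the derived alleles a and B are individually
harmless but jointly lethal, so any genotype carrying at least one a *and*
at least one B has viability 0, and every other genotype has viability 1.
Populations start monomorphic AAbb at the selected pair, so the incompatible
combination can only be assembled by mutation (A->a at locus 0, b->B at
locus 1) plus mating between carriers of the two derived alleles.

Mutation acts on gametes at transmission, per allele per generation:

* locus 0: forward only, A -> a with probability mu (a never reverts);
* locus 1: backward only, b -> B with probability mu (B never reverts);
* neutral loci: k-allele model, which for k = 2 alleles reduces to flipping
  to the other allele with probability mu.

Loci assort freely (no linkage map), so a gamete picks one of the two
parental alleles independently and uniformly at each locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LociConfig",
    "FitnessModel",
    "GENOTYPE_CLASSES",
    "initial_genotype",
    "initial_genotypes",
    "make_gamete",
    "make_gametes",
    "mutate_gamete",
    "mutate_gametes",
    "dm_fitness",
    "genotype_class_index",
    "genotype_class_counts",
]

LOCUS_A = 0  # selected locus with alleles A (0) / a (1); forward mutation only
LOCUS_B = 1  # selected locus with alleles b (0) / B (1); backward mutation only

#: Two-locus genotype class labels indexed by 3 * n_a + (2 - n_B), where n_a
#: is the count of a alleles at locus 0 and n_B the count of B alleles at
#: locus 1.  This is the column order used in all per-generation outputs.
GENOTYPE_CLASSES = (
    "AABB", "AABb", "AAbb",
    "AaBB", "AaBb", "Aabb",
    "aaBB", "aaBb", "aabb",
)


@dataclass(frozen=True)
class LociConfig:
    """Locus layout and per-allele mutation rate.

    Defaults match the study system: 22 diallelic loci, the first two under
    selection, and mutation rate 0.0005 per allele per transmission.
    """

    n_loci: int = 22
    n_selected: int = 2
    mutation_rate: float = 0.0005

    def __post_init__(self) -> None:
        if self.n_selected != 2:
            raise ValueError("the DM model requires exactly two selected loci")
        if self.n_loci < self.n_selected:
            raise ValueError("n_loci must be at least the number of selected loci")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")

    @property
    def n_neutral(self) -> int:
        return self.n_loci - self.n_selected

    @property
    def neutral_loci(self) -> np.ndarray:
        return np.arange(self.n_selected, self.n_loci)


@dataclass(frozen=True)
class FitnessModel:
    """Relative viability per two-locus genotype class, in [0, 1].

    The default is the flat DM surface: 0 for the four incompatible classes
    (carrying >= 1 a and >= 1 B), 1 for the five compatible ones.  Values are
    spatially constant.  ``viability`` is indexed like
    :data:`GENOTYPE_CLASSES`.
    """

    viability: tuple = (1.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.viability) != 9:
            raise ValueError("viability must cover the 9 two-locus classes")
        if any(not 0.0 <= w <= 1.0 for w in self.viability):
            raise ValueError("viabilities must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.viability, dtype=np.float64)

    def of(self, label: str) -> float:
        return self.viability[GENOTYPE_CLASSES.index(label)]


def initial_genotypes(n: int, loci: LociConfig, rng: np.random.Generator) -> np.ndarray:
    """Founding genotypes: AAbb at the selected pair, uniform random neutrals.

    Returns an ``(n, n_loci, 2)`` int8 array.  The selected loci are exactly
    monomorphic (all-zero codes mean AA and bb); every neutral allele slot is
    an independent fair draw from {0, 1}, i.e. maximal expected diversity.
    """
    g = np.zeros((n, loci.n_loci, 2), dtype=np.int8)
    g[:, loci.n_selected:, :] = rng.integers(
        0, 2, size=(n, loci.n_neutral, 2), dtype=np.int8
    )
    return g


def initial_genotype(loci: LociConfig, rng: np.random.Generator) -> np.ndarray:
    """Single founding genotype; see :func:`initial_genotypes`."""
    return initial_genotypes(1, loci, rng)[0]


def make_gametes(parents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Segregate one gamete per parent under free recombination, no mutation.

    ``parents`` is ``(n, n_loci, 2)``; the result is ``(n, n_loci)`` with one
    allele per locus picked uniformly from the parent's two, independently
    across loci.
    """
    n, n_loci, _ = parents.shape
    picks = rng.integers(0, 2, size=(n, n_loci), dtype=np.int8)
    return np.take_along_axis(parents, picks[:, :, None], axis=2)[:, :, 0]


def make_gamete(parent: np.ndarray, loci: LociConfig, rng: np.random.Generator) -> np.ndarray:
    """Segregate and then mutate a single gamete (the full transmission step)."""
    gam = make_gametes(parent[None, :, :], rng)
    return mutate_gametes(gam, loci, rng)[0]


def mutate_gametes(gametes: np.ndarray, loci: LociConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply per-allele mutation in place and return the gametes.

    Each allele copy mutates independently with probability ``mu``.  Both
    selected loci mutate one-way toward the derived allele code 1 (A->a,
    b->B), so a hit on an already-derived allele is a no-op; neutral loci
    flip to the other allele (k-allele model with k = 2).
    """
    mu = loci.mutation_rate
    if mu == 0.0:
        return gametes
    hits = rng.random(gametes.shape) < mu
    sel = slice(0, loci.n_selected)
    gametes[:, sel] |= hits[:, sel].astype(np.int8)
    neut = slice(loci.n_selected, None)
    gametes[:, neut] ^= hits[:, neut].astype(np.int8)
    return gametes


def mutate_gamete(gamete: np.ndarray, loci: LociConfig, rng: np.random.Generator) -> np.ndarray:
    """Single-gamete convenience wrapper for :func:`mutate_gametes`."""
    return mutate_gametes(gamete[None, :], loci, rng)[0]


def genotype_class_index(genotypes: np.ndarray) -> np.ndarray:
    """Map genotypes to two-locus class indices into :data:`GENOTYPE_CLASSES`.

    Accepts ``(n_loci, 2)`` or ``(n, n_loci, 2)``; returns a scalar or an
    ``(n,)`` int array.
    """
    single = genotypes.ndim == 2
    g = genotypes[None] if single else genotypes
    n_a = g[:, LOCUS_A, :].sum(axis=1, dtype=np.int64)
    n_B = g[:, LOCUS_B, :].sum(axis=1, dtype=np.int64)
    idx = 3 * n_a + (2 - n_B)
    return int(idx[0]) if single else idx


def dm_fitness(genotypes: np.ndarray, model: FitnessModel = FitnessModel()) -> np.ndarray:
    """Viability of each genotype under the (flat) DM fitness surface.

    With the default model this is 0 exactly when the genotype carries at
    least one a and at least one B, and 1 otherwise.  Accepts a single
    genotype or a population; returns a float or a float array.
    """
    idx = genotype_class_index(genotypes)
    table = model.as_array()
    if np.isscalar(idx):
        return float(table[idx])
    return table[idx]


def genotype_class_counts(genotypes: np.ndarray) -> np.ndarray:
    """Count individuals in each of the 9 two-locus classes (class order)."""
    idx = genotype_class_index(genotypes)
    return np.bincount(np.atleast_1d(idx), minlength=9)
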
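"""Pooled heterozygosity and Wright's inbreeding coefficient F.

All individuals are pooled (there are no predefined subpopulations), and
only the neutral loci enter the summary:

* Ho — the observed fraction of heterozygous (individual, locus) pairs;
* He — per-locus expected heterozygosity ``1 - sum_i p_i**2`` at the pooled
  allele frequencies, averaged over loci;
* F = 1 - Ho / He, the ratio of the two cross-locus *means* (per-locus F
  values are never averaged).

Under spatially restricted mating, local allele-frequency differentiation
produces a population-wide heterozygote deficit relative to pooled
Hardy-Weinberg expectation (the Wahlund effect), so F grows with the
strength of isolation by distance; under effectively random mating it
stays near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import LociConfig, genotype_class_counts

__all__ = [
    "GenerationStats",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "wright_F",
    "population_stats",
]


@dataclass(frozen=True)
class GenerationStats:
    """Per-generation genetic summary of the living population."""

    generation: int
    n_alive: int
    Ho: float
    He: float
    F: float  # NaN when He == 0
    class_counts: np.ndarray  # 9 two-locus genotype class counts


def _neutral_alleles(genotypes: np.ndarray, loci: LociConfig) -> np.ndarray:
    if genotypes.ndim != 3 or genotypes.shape[0] == 0:
        raise ValueError("population must be non-empty")
    return genotypes[:, loci.n_selected:, :]


def observed_heterozygosity(genotypes: np.ndarray, loci: LociConfig = LociConfig()) -> float:
    """Fraction of heterozygous (individual, neutral locus) pairs."""
    g = _neutral_alleles(genotypes, loci)
    return float((g[:, :, 0] != g[:, :, 1]).mean())


def expected_heterozygosity(genotypes: np.ndarray, loci: LociConfig = LociConfig()) -> float:
    """Mean over neutral loci of ``1 - sum p_i**2`` at pooled frequencies."""
    g = _neutral_alleles(genotypes, loci)
    p = g.mean(axis=(0, 2))  # pooled frequency of allele code 1, per locus
    return float((2.0 * p * (1.0 - p)).mean())


def wright_F(Ho: float, He: float) -> float:
    """Wright's F = 1 - Ho/He from the pooled cross-locus means.

    Raises
    ------
    ValueError
        If He is not positive: F is undefined in a monomorphic pool, and
        silently returning 0 would fake panmixia.
    """
    if He <= 0:
        raise ValueError("F is undefined when expected heterozygosity is 0")
    return 1.0 - Ho / He


def population_stats(
    genotypes: np.ndarray, generation: int, loci: LociConfig = LociConfig()
) -> GenerationStats:
    """One summary row for a living population's genotype array."""
    ho = observed_heterozygosity(genotypes, loci)
    he = expected_heterozygosity(genotypes, loci)
    f = wright_F(ho, he) if he > 0 else float("nan")
    return GenerationStats(
        generation=generation,
        n_alive=int(genotypes.shape[0]),
        Ho=ho,
        He=he,
        F=f,
        class_counts=genotype_class_counts(genotypes),
    )
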
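"""Scenario runner: replicates, movement-distance sweeps, and summary tables.

A *replicate* simulates one seeded population on its own random site map
for a fixed number of non-overlapping generations, recording per-generation
genetic summaries (Ho, He, F over the neutral loci; the nine two-locus
genotype class counts) and the spatial RI-event flag.  A *sweep* runs a
grid of movement fractions with several replicates each and aggregates
RI-event counts, event durations, and final-generation F with normal 95%
confidence intervals across replicates.

Seeding: replicate ``r`` of scenario ``s`` uses ``base_seed + 10_000 * s + r``,
so every replicate is an independent, individually reproducible stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import (
    ClusterParams,
    DurationSummary,
    dbscan,
    detect_ri_event,
    event_durations,
)
from .engine import (
    MOVEMENT_FRACTIONS,
    ScenarioConfig,
    build_movement_kernel,
    default_distance_floor,
    founding_population,
    step_generation,
)
from .genome import GENOTYPE_CLASSES, genotype_class_index
from .landscape import build_neighbor_index, generate_sites, make_extent
from .stats import population_stats

__all__ = [
    "SweepSpec",
    "ReplicateResult",
    "run_replicate",
    "run_sweep",
    "table1",
    "analyze_snapshots",
    "STATS_COLUMNS",
]

logger = logging.getLogger("dmscape")

STATS_COLUMNS = (
    ["generation", "n_alive", "Ho", "He", "F"]
    + [f"n_{c}" for c in GENOTYPE_CLASSES]
    + ["ri_flag", "n_clusters_AABB", "n_clusters_aabb"]
)

_IDX_AABB = GENOTYPE_CLASSES.index("AABB")
_IDX_aabb = GENOTYPE_CLASSES.index("aabb")


@dataclass(frozen=True)
class SweepSpec:
    """A grid of movement fractions with replicate counts and output flags."""

    fractions: tuple = MOVEMENT_FRACTIONS
    replicates: int = 10
    generations: int = 1000
    n_sites: int = 5000
    lam: float = 4.0
    mutation_rate: float = 0.0005
    base_seed: int = 0
    cluster: ClusterParams = ClusterParams()
    out_dir: Path | None = None
    dump_genotypes: bool = False
    dump_clusters: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")


@dataclass
class ReplicateResult:
    """Per-generation statistics and RI summary of one replicate."""

    config: ScenarioConfig
    stats: pd.DataFrame  # one row per simulated generation (STATS_COLUMNS)
    durations: DurationSummary
    status: str = "ok"  # "ok" or "extinct"

    @property
    def flags(self) -> np.ndarray:
        return self.stats["ri_flag"].to_numpy(dtype=bool)

    @property
    def final_F(self) -> float:
        return float(self.stats["F"].iloc[-1])


def _selected_pair_label(genotype: np.ndarray, locus: int, hom0: str, het: str, hom2: str) -> str:
    n = int(genotype[locus, 0]) + int(genotype[locus, 1])
    return (hom0, het, hom2)[n]


def run_replicate(
    cfg: ScenarioConfig,
    cluster: ClusterParams = ClusterParams(),
    dump_genotypes: Path | None = None,
    dump_clusters: Path | None = None,
) -> ReplicateResult:
    """Simulate one replicate and score every generation.

    The random site map, the founding population, and all per-generation
    stochastic events derive from ``cfg.seed`` alone, so a rerun with the
    same config is bit-identical.  When ``dump_clusters`` is given, a point
    snapshot (with DBSCAN cluster ids) of the two pure double-homozygote
    classes is appended for each RI-flagged generation.
    """
    rng = np.random.default_rng(cfg.seed)
    extent = make_extent(cfg.area, cfg.max_distance)
    sites = generate_sites(cfg.n_sites, extent, rng)
    index = build_neighbor_index(sites, cfg.dmax)
    kernel = build_movement_kernel(index, default_distance_floor(sites))
    pop = founding_population(cfg, rng)
    logger.info(
        "replicate start: fraction=%s seed=%s sites=%s generations=%s",
        cfg.movement_fraction, cfg.seed, cfg.n_sites, cfg.generations,
    )

    rows = []
    geno_rows: list[pd.DataFrame] = []
    clus_rows: list[pd.DataFrame] = []
    status = "ok"
    for gen in range(1, cfg.generations + 1):
        pop = step_generation(pop, cfg, kernel, rng)
        if pop.size == 0:
            rows.append([gen, 0, np.nan, np.nan, np.nan] + [0] * 9 + [False, 0, 0])
            status = "extinct"
            logger.warning("replicate extinct at generation %d", gen)
            break
        alive = pop.alive_sites()
        genos = pop.genotypes[alive]
        st = population_stats(genos, gen, cfg.loci)
        cls = genotype_class_index(genos)
        xy_AABB = sites.coords[alive[cls == _IDX_AABB]]
        xy_aabb = sites.coords[alive[cls == _IDX_aabb]]
        ev = detect_ri_event(xy_AABB, xy_aabb, cluster)
        rows.append(
            [gen, st.n_alive, st.Ho, st.He, st.F]
            + list(st.class_counts)
            + [ev.flag, ev.n_clusters_AABB, ev.n_clusters_aabb]
        )
        if dump_genotypes is not None:
            geno_rows.append(_genotype_frame(gen, alive, pop, cfg))
        if dump_clusters is not None and ev.flag:
            clus_rows.append(_cluster_frame(gen, sites, alive, cls, cluster))
        logger.debug("gen %d: n=%d F=%.4f ri=%s", gen, st.n_alive, st.F, ev.flag)

    stats = pd.DataFrame(rows, columns=STATS_COLUMNS)
    durations = event_durations(stats["ri_flag"].to_numpy(dtype=bool))
    if dump_genotypes is not None and geno_rows:
        pd.concat(geno_rows).to_csv(dump_genotypes, index=False)
    if dump_clusters is not None and clus_rows:
        pd.concat(clus_rows).to_csv(dump_clusters, index=False)
    logger.info(
        "replicate done: fraction=%s seed=%s status=%s ri_generations=%d final_F=%.4f",
        cfg.movement_fraction, cfg.seed, status, durations.n_flagged,
        stats["F"].iloc[-1] if len(stats) else float("nan"),
    )
    return ReplicateResult(config=cfg, stats=stats, durations=durations, status=status)


def _genotype_frame(gen: int, alive: np.ndarray, pop, cfg: ScenarioConfig) -> pd.DataFrame:
    genos = pop.genotypes[alive]
    cols: dict = {
        "generation": gen,
        "site_id": alive,
        "sex": np.where(pop.sex[alive] == 0, "F", "M"),
        "locus0": [_selected_pair_label(g, 0, "AA", "Aa", "aa") for g in genos],
        "locus1": [_selected_pair_label(g, 1, "bb", "Bb", "BB") for g in genos],
    }
    for l in range(cfg.loci.n_selected, cfg.loci.n_loci):
        cols[f"locus{l}"] = [f"{g[l, 0]}{g[l, 1]}" for g in genos]
    return pd.DataFrame(cols)


def _cluster_frame(gen, sites, alive, cls, cluster: ClusterParams) -> pd.DataFrame:
    frames = []
    for label, idx in (("AABB", _IDX_AABB), ("aabb", _IDX_aabb)):
        sel = alive[cls == idx]
        xy = sites.coords[sel]
        lab = dbscan(xy, cluster)
        frames.append(pd.DataFrame({
            "generation": gen,
            "genotype_class": label,
            "site_id": sel,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cluster_id": lab,
        }))
    return pd.concat(frames)


def _ci(values: np.ndarray) -> tuple[float, float]:
    """Normal 95% CI (mean +/- 1.96 SE) across replicates."""
    m = float(values.mean())
    if values.size < 2:
        return m, m
    se = float(values.std(ddof=1)) / np.sqrt(values.size)
    return m - 1.96 * se, m + 1.96 * se


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the movement-fraction grid and summarize each scenario.

    Returns one row per fraction with replicate means and 95% CIs for the
    number of RI-flagged generations, the mean and max RI-event duration,
    and F at the final generation.  Per-replicate trajectories (and a run
    manifest) are written under ``spec.out_dir`` when given.  A failed or
    extinct replicate is recorded and the sweep continues.
    """
    out = Path(spec.out_dir) if spec.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    ri_rows = []
    for s_idx, frac in enumerate(spec.fractions):
        ri_counts, mean_durs, max_durs, f_finals, statuses = [], [], [], [], []
        all_durations: list[np.ndarray] = []
        for r in range(spec.replicates):
            seed = spec.base_seed + 10_000 * s_idx + r
            cfg = ScenarioConfig(
                movement_fraction=frac,
                n_sites=spec.n_sites,
                lam=spec.lam,
                generations=spec.generations,
                seed=seed,
            )
            if spec.mutation_rate != cfg.loci.mutation_rate:
                cfg = replace(cfg, loci=replace(cfg.loci, mutation_rate=spec.mutation_rate))
            tag = f"f{frac:g}_r{r}"
            res = run_replicate(
                cfg,
                cluster=spec.cluster,
                dump_genotypes=(out / f"genotypes_{tag}.csv") if out and spec.dump_genotypes else None,
                dump_clusters=(out / f"clusters_{tag}.csv") if out and spec.dump_clusters else None,
            )
            if out is not None:
                res.stats.to_csv(out / f"replicate_{tag}.csv", index=False)
            ri_counts.append(res.durations.n_flagged)
            mean_durs.append(res.durations.mean_duration)
            max_durs.append(res.durations.max_duration)
            f_finals.append(res.final_F)
            statuses.append(res.status)
            all_durations.append(res.durations.durations)
            ri_rows.append({
                "movement_fraction": frac,
                "replicate": r,
                "seed": seed,
                "n_event_generations": res.durations.n_flagged,
                "mean_duration": res.durations.mean_duration,
                "max_duration": res.durations.max_duration,
                "status": res.status,
            })
        ri = np.asarray(ri_counts, dtype=float)
        ff = np.asarray(f_finals, dtype=float)
        pooled = np.concatenate(all_durations) if all_durations else np.empty(0)
        ri_lo, ri_hi = _ci(ri)
        f_lo, f_hi = _ci(ff[~np.isnan(ff)]) if np.isfinite(ff).any() else (np.nan, np.nan)
        summary_rows.append({
            "movement_fraction": frac,
            "n_replicates": spec.replicates,
            "mean_ri_events": float(ri.mean()),
            "ri_ci_lo": ri_lo,
            "ri_ci_hi": ri_hi,
            "mean_duration": float(pooled.mean()) if pooled.size else 0.0,
            "max_duration": int(pooled.max()) if pooled.size else 0,
            "F_final_mean": float(np.nanmean(ff)) if np.isfinite(ff).any() else np.nan,
            "F_final_ci_lo": f_lo,
            "F_final_ci_hi": f_hi,
            "n_extinct": int(sum(s == "extinct" for s in statuses)),
        })
    summary = pd.DataFrame(summary_rows)
    if out is not None:
        summary.to_csv(out / "sweep_summary.csv", index=False)
        pd.DataFrame(ri_rows).to_csv(out / "ri_summary.csv", index=False)
        manifest = {
            "fractions": list(spec.fractions),
            "replicates": spec.replicates,
            "generations": spec.generations,
            "n_sites": spec.n_sites,
            "lam": spec.lam,
            "mutation_rate": spec.mutation_rate,
            "base_seed": spec.base_seed,
            "cluster": {"eps": spec.cluster.eps, "min_pts": spec.cluster.min_pts},
            "seed_rule": "base_seed + 10000 * scenario_index + replicate_index",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary


def table1(
    fractions=MOVEMENT_FRACTIONS,
    n_sites: int = 5000,
    area: float = 7237.60,
    max_distance: float = 123.2,
) -> pd.DataFrame:
    """Analytic genetic-neighborhood table: expected mates per movement radius.

    For density ``rho = n_sites / area`` the expected number of other
    individuals within radius ``r = fraction * max_distance`` is
    ``rho * pi * r**2`` (capped at the population size), with the
    corresponding proportion of the whole population.
    """
    from .landscape import expected_neighbors

    rho = n_sites / area
    rows = []
    for frac in sorted(fractions, reverse=True):
        r = frac * max_distance
        exp = min(float(n_sites), expected_neighbors(rho, r))
        rows.append({
            "movement_pct": 100.0 * frac,
            "radius": r,
            "expected_individuals": int(round(exp)),
            "proportion": round(exp, 0) / n_sites if exp < n_sites else 1.0,
        })
    return pd.DataFrame(rows)


def analyze_snapshots(snapshots: pd.DataFrame, params: ClusterParams) -> pd.DataFrame:
    """Recompute RI flags from a dumped point time-series.

    ``snapshots`` needs columns ``generation, genotype_class, x, y`` (the
    cluster-snapshot dump format, or any CSV of located genotypes).  Returns
    one row per generation present, with cluster counts and the RI flag;
    run lengths can then be taken with :func:`dmscape.clustering.event_durations`.
    """
    required = {"generation", "genotype_class", "x", "y"}
    missing = required - set(snapshots.columns)
    if missing:
        raise ValueError(f"snapshot frame missing columns: {sorted(missing)}")
    rows = []
    for gen, grp in snapshots.groupby("generation", sort=True):
        a = grp.loc[grp["genotype_class"] == "AABB", ["x", "y"]].to_numpy()
        b = grp.loc[grp["genotype_class"] == "aabb", ["x", "y"]].to_numpy()
        ev = detect_ri_event(a, b, params)
        rows.append({
            "generation": int(gen),
            "n_clusters_AABB": ev.n_clusters_AABB,
            "n_clusters_aabb": ev.n_clusters_aabb,
            "ri_flag": ev.flag,
        })
    return pd.DataFrame(rows)
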
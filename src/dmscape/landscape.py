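"""Spatial substrate: the rectangular extent, fixed home-range sites, and
fixed-radius neighborhood queries.

The study system is a continuously distributed population occupying a fixed
set of home-range sites scattered uniformly at random over a rectangle.  The
rectangle is specified indirectly, by its area and its diagonal (the maximum
possible distance between two points on the landscape); :func:`make_extent`
recovers the unique width/height pair.  All movement in the simulation —
mate search and natal dispersal alike — is restricted to sites within a
scenario-specific radius, so neighborhoods are precomputed once per site
map with a KD-tree and stored in compressed sparse row (CSR) form.

Distances are Euclidean; there is no toroidal wrap and no resistance
surface.  Coordinates are continuous, with the origin at (0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Extent",
    "SiteMap",
    "NeighborIndex",
    "make_extent",
    "generate_sites",
    "build_neighbor_index",
    "expected_neighbors",
]


@dataclass(frozen=True)
class Extent:
    """Rectangular landscape extent, ``width >= height > 0``, in length-units."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("extent dimensions must be positive")

    def area(self) -> float:
        return self.width * self.height

    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)


def make_extent(area: float, max_distance: float) -> Extent:
    """Build the rectangle with a given area whose diagonal is ``max_distance``.

    Solving ``w * h = area`` and ``w**2 + h**2 = max_distance**2`` gives
    ``w, h = sqrt((d^2 +- sqrt(d^4 - 4*area^2)) / 2)``; the pair is unique up
    to orientation and we return ``width >= height``.  A solution exists only
    when ``max_distance**2 >= 2 * area`` (equality: a square).

    Raises
    ------
    ValueError
        If no rectangle with that area fits inside the diagonal.
    """
    if area <= 0 or max_distance <= 0:
        raise ValueError("area and max_distance must be positive")
    d2 = max_distance * max_distance
    disc = d2 * d2 - 4.0 * area * area
    if disc < 0:
        # tolerate roundoff at the square case
        if disc > -1e-9 * d2 * d2:
            disc = 0.0
        else:
            raise ValueError(
                f"no rectangle of area {area} has diagonal {max_distance}: "
                f"requires max_distance**2 >= 2*area (= {2 * area})"
            )
    root = math.sqrt(disc)
    width = math.sqrt((d2 + root) / 2.0)
    height = math.sqrt((d2 - root) / 2.0)
    return Extent(width=width, height=height)


@dataclass(frozen=True)
class SiteMap:
    """Fixed home-range site coordinates.

    ``coords`` is an ``(n, 2)`` float array; row index is the stable site
    identifier for the lifetime of a simulation.  Sites must lie within the
    extent and be pairwise distinct.
    """

    coords: np.ndarray
    extent: Extent

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise ValueError("coords must be an (n, 2) array with n >= 1")
        object.__setattr__(self, "coords", coords)
        if (coords[:, 0] < 0).any() or (coords[:, 0] > self.extent.width).any():
            raise ValueError("x coordinates out of extent bounds")
        if (coords[:, 1] < 0).any() or (coords[:, 1] > self.extent.height).any():
            raise ValueError("y coordinates out of extent bounds")
        if len(coords) > 1:
            # duplicate coordinates would make site identity ambiguous
            view = np.ascontiguousarray(coords).view([("x", "f8"), ("y", "f8")])
            if len(np.unique(view)) != len(coords):
                raise ValueError("duplicate site coordinates are not allowed")

    @property
    def n_sites(self) -> int:
        return int(self.coords.shape[0])

    def min_spacing(self) -> float:
        """Minimum non-zero distance between any two sites."""
        if self.n_sites < 2:
            raise ValueError("need at least two sites for a spacing")
        tree = cKDTree(self.coords)
        dists, _ = tree.query(self.coords, k=2)
        return float(dists[:, 1].min())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "site_id": np.arange(self.n_sites),
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
            }
        )
        df.to_csv(path, index=False)  # shortest-repr floats round-trip exactly

    @classmethod
    def from_csv(cls, path, extent: Extent) -> "SiteMap":
        df = pd.read_csv(path, float_precision="round_trip").sort_values("site_id")
        return cls(coords=df[["x", "y"]].to_numpy(dtype=np.float64), extent=extent)


def generate_sites(n: int, extent: Extent, seed) -> SiteMap:
    """Draw ``n`` i.i.d. uniform sites over the extent.

    ``seed`` may be an integer or a ``numpy.random.Generator``; a fixed
    integer seed gives bit-identical coordinates across runs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    coords = np.empty((n, 2), dtype=np.float64)
    coords[:, 0] = rng.uniform(0.0, extent.width, size=n)
    coords[:, 1] = rng.uniform(0.0, extent.height, size=n)
    return SiteMap(coords=coords, extent=extent)


@dataclass(frozen=True)
class NeighborIndex:
    """All within-radius site pairs in CSR layout.

    For site ``i`` the neighbor site indices are
    ``indices[indptr[i]:indptr[i+1]]`` with matching Euclidean
    ``distances``.  A site is never its own neighbor and the relation is
    symmetric.  Within a row, neighbors are sorted by site index, which
    fixes the iteration order used by downstream weighted draws.
    """

    radius: float
    indptr: np.ndarray  # (n_sites + 1,) int64
    indices: np.ndarray  # int32 neighbor site ids
    distances: np.ndarray  # float64, same length as indices

    @property
    def n_sites(self) -> int:
        return len(self.indptr) - 1

    def neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.indptr[i], self.indptr[i + 1]
        return self.indices[lo:hi], self.distances[lo:hi]

    def degree(self, i: int) -> int:
        return int(self.indptr[i + 1] - self.indptr[i])


def build_neighbor_index(sites: SiteMap, radius: float) -> NeighborIndex:
    """Precompute, for every site, the other sites within ``radius``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = sites.n_sites
    tree = cKDTree(sites.coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs) == 0:
        indptr = np.zeros(n + 1, dtype=np.int64)
        return NeighborIndex(
            radius=float(radius),
            indptr=indptr,
            indices=np.empty(0, dtype=np.int32),
            distances=np.empty(0, dtype=np.float64),
        )
    # symmetrize: each unordered pair contributes both directions
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    d = np.linalg.norm(sites.coords[pairs[:, 0]] - sites.coords[pairs[:, 1]], axis=1)
    dist = np.concatenate([d, d])
    order = np.lexsort((dst, src))
    src, dst, dist = src[order], dst[order], dist[order]
    counts = np.bincount(src, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return NeighborIndex(
        radius=float(radius),
        indptr=indptr,
        indices=dst.astype(np.int32),
        distances=dist.astype(np.float64),
    )


def expected_neighbors(density: float, radius: float) -> float:
    """Analytic expected count of other sites within ``radius``: rho * pi * r**2.

    Edge effects are ignored, matching the usual genetic-neighborhood
    calculation for a uniform density ``rho`` per squared length-unit.
    """
    if density <= 0 or radius <= 0:
        raise ValueError("density and radius must be positive")
    return density * math.pi * radius * radius
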
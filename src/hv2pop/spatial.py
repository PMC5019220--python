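"""Geography: great-circle distances, isolation by distance, and
Monmonier's maximum-difference genetic barriers.

Populations are points (longitude, latitude in degrees).  For the
triangulation the points are projected with an equirectangular projection
about the centroid latitude -- adequate for the sub-continental extents
this package targets.  A barrier is an ordered chain of triangulation
edges: it seeds at the uncrossed edge with the largest genetic distance
and grows from both ends, always crossing the adjacent edge with the
greatest distance, until it exits the convex hull or closes a loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay as _SciDelaunay

from .alignment import Alignment, PopulationMap
from .amova import GroupingScheme, AmovaResult, amova

EARTH_RADIUS_KM = 6371.0


class GeometryError(ValueError):
    pass


@dataclass
class GeoLayout:
    """Per-population longitude/latitude in decimal degrees."""

    coords: dict[str, tuple[float, float]]  # population -> (lon, lat)

    def __post_init__(self) -> None:
        for pop, (lon, lat) in self.coords.items():
            if not (-180 <= lon <= 180) or not (-90 <= lat <= 90):
                raise GeometryError(f"invalid coordinates for {pop!r}: ({lon}, {lat})")

    @property
    def populations(self) -> list[str]:
        return list(self.coords)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeoLayout":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                str(r["population"]): (float(r["longitude_deg"]), float(r["latitude_deg"]))
                for _, r in df.iterrows()
            }
        )

    def projected(self) -> np.ndarray:
        """Equirectangular x/y in km about the centroid latitude."""
        lons = np.array([c[0] for c in self.coords.values()])
        lats = np.array([c[1] for c in self.coords.values()])
        lat0 = np.deg2rad(lats.mean())
        x = np.deg2rad(lons) * np.cos(lat0) * EARTH_RADIUS_KM
        y = np.deg2rad(lats) * EARTH_RADIUS_KM
        return np.column_stack([x, y])


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km (haversine, spherical Earth)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(lon2 - lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geo_distance_matrix(layout: GeoLayout) -> pd.DataFrame:
    """Symmetric matrix of great-circle distances between populations (km)."""
    pops = layout.populations
    if len(pops) < 2:
        raise GeometryError("need at least 2 populations")
    K = len(pops)
    out = np.zeros((K, K))
    for i in range(K - 1):
        for j in range(i + 1, K):
            lon1, lat1 = layout.coords[pops[i]]
            lon2, lat2 = layout.coords[pops[j]]
            out[i, j] = out[j, i] = haversine_km(lon1, lat1, lon2, lat2)
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# Mantel test

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    tail: str


def mantel(
    m1: np.ndarray | pd.DataFrame,
    m2: np.ndarray | pd.DataFrame,
    n_perms: int = 1000,
    seed: int | None = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over lower-triangle entries; significance
    permutes the rows/columns of the second matrix jointly.  The default
    one-tailed test ("greater") suits the isolation-by-distance
    hypothesis; ``tail='two-sided'`` is available.
    """
    a = _as_matrix(m1)
    b = _as_matrix(m2)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs >= 4 populations")
    iu = np.tril_indices(n, -1)
    x = a[iu]
    if x.std() == 0:
        raise ValueError("first matrix has zero variance in its triangle")
    if b[iu].std() == 0:
        raise ValueError("second matrix has zero variance in its triangle")

    def corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(x, mat[iu])[0, 1])

    r_obs = corr(b)
    if not n_perms:
        return MantelResult(r_obs, float("nan"), 0, tail)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(n)
        r_perm = corr(b[np.ix_(perm, perm)])
        if tail == "greater":
            count += r_perm >= r_obs
        elif tail == "two-sided":
            count += abs(r_perm) >= abs(r_obs)
        else:
            raise ValueError(f"unknown tail {tail!r}")
    return MantelResult(r_obs, (count + 1) / (n_perms + 1), n_perms, tail)


def _as_matrix(m: np.ndarray | pd.DataFrame) -> np.ndarray:
    return m.to_numpy(float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)


# ---------------------------------------------------------------------------
# Delaunay triangulation graph

Edge = tuple[str, str]  # sorted population pair


@dataclass
class TriangulationGraph:
    populations: list[str]
    points: np.ndarray                      # projected xy (km)
    triangles: list[tuple[int, int, int]]
    edge_triangles: dict[Edge, list[int]]   # edge -> adjacent triangle indices

    def edges(self) -> list[Edge]:
        return sorted(self.edge_triangles)

    def is_hull_edge(self, e: Edge) -> bool:
        return len(self.edge_triangles[e]) == 1

    def triangle_edges(self, t: int) -> list[Edge]:
        i, j, k = self.triangles[t]
        name = self.populations
        return [
            _edge(name[i], name[j]),
            _edge(name[i], name[k]),
            _edge(name[j], name[k]),
        ]


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def delaunay(layout: GeoLayout) -> TriangulationGraph:
    """Delaunay triangulation of the projected population coordinates."""
    pops = layout.populations
    if len(pops) < 3:
        raise GeometryError("triangulation needs >= 3 populations")
    pts = layout.projected()
    try:
        tri = _SciDelaunay(pts)
    except Exception as exc:  # qhull failure, e.g. collinear input
        raise GeometryError(f"triangulation failed: {exc}") from exc
    if tri.simplices.size == 0:
        raise GeometryError("degenerate (collinear) population layout")
    triangles = [tuple(sorted(map(int, s))) for s in tri.simplices]
    edge_triangles: dict[Edge, list[int]] = {}
    for t, (i, j, k) in enumerate(triangles):
        for a, b in ((i, j), (i, k), (j, k)):
            e = _edge(pops[a], pops[b])
            edge_triangles.setdefault(e, []).append(t)
    return TriangulationGraph(list(pops), pts, triangles, edge_triangles)


# ---------------------------------------------------------------------------
# Monmonier barriers

@dataclass
class Barrier:
    edges: list[Edge]          # ordered crossed edges
    distances: list[float]
    rank: int
    had_ties: bool = False

    def crossed(self) -> set[Edge]:
        return set(self.edges)


@dataclass
class BarrierResult:
    barriers: list[Barrier]

    def first(self) -> Barrier:
        return self.barriers[0]


def monmonier_barriers(
    tri: TriangulationGraph,
    d: "pd.DataFrame | np.ndarray",
    n_barriers: int = 1,
    labels: list[str] | None = None,
) -> BarrierResult:
    """Monmonier's maximum-difference barriers on a triangulation.

    ``d`` is a symmetric genetic-distance matrix covering every
    triangulation vertex.  Each barrier seeds at the highest-distance
    uncrossed edge and is extended from both ends across the adjacent edge
    with the greatest distance; extension stops at the convex hull or when
    a loop closes.  Ties are broken toward the lexicographically smallest
    population pair and flagged.
    """
    dist = _dist_lookup(d, labels, tri.populations)
    crossed_global: set[Edge] = set()
    barriers: list[Barrier] = []
    for rank in range(n_barriers):
        available = [e for e in tri.edges() if e not in crossed_global]
        if not available:
            break
        # deterministic tie-break: among max distances, smallest pair name
        best_d = max(dist[e] for e in available)
        ties = sorted(e for e in available if dist[e] == best_d)
        had_ties = len(ties) > 1
        seed = ties[0]
        left: list[Edge] = []
        right: list[Edge] = []
        crossed = {seed}
        for side, store in ((0, left), (1, right)):
            adj = tri.edge_triangles[seed]
            if side >= len(adj):
                continue  # hull seed: nothing on this side
            cur_tri = adj[side]
            prev = seed
            while True:
                cands = [
                    e
                    for e in tri.triangle_edges(cur_tri)
                    if e != prev and e not in crossed and e not in crossed_global
                ]
                if not cands:
                    break  # loop closed or dead end
                top = max(dist[e] for e in cands)
                tied = sorted(e for e in cands if dist[e] == top)
                had_ties = had_ties or len(tied) > 1
                nxt = tied[0]
                crossed.add(nxt)
                store.append(nxt)
                if tri.is_hull_edge(nxt):
                    break
                t1, t2 = tri.edge_triangles[nxt]
                cur_tri = t2 if t1 == cur_tri else t1
                prev = nxt
        ordered = list(reversed(left)) + [seed] + right
        barriers.append(
            Barrier(ordered, [dist[e] for e in ordered], rank + 1, had_ties)
        )
        crossed_global |= crossed
    return BarrierResult(barriers)


def _dist_lookup(
    d: "pd.DataFrame | np.ndarray", labels: list[str] | None, pops: list[str]
) -> dict[Edge, float]:
    if isinstance(d, pd.DataFrame):
        frame = d
    else:
        from .distance import PopDistanceMatrix

        if isinstance(d, PopDistanceMatrix):
            frame = pd.DataFrame(d.values, index=d.labels, columns=d.labels)
        else:
            if labels is None:
                raise ValueError("labels required with a bare matrix")
            frame = pd.DataFrame(np.asarray(d, float), index=labels, columns=labels)
    missing = [p for p in pops if p not in frame.index]
    if missing:
        raise ValueError(f"populations without genetic distances: {missing}")
    out: dict[Edge, float] = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            out[_edge(a, b)] = float(frame.loc[a, b])
    return out


def barrier_sides(tri: TriangulationGraph, barrier: Barrier) -> list[set[str]]:
    """Connected components of the population graph after removing the
    barrier's crossed edges -- the groups the barrier separates."""
    adj: dict[str, set[str]] = {p: set() for p in tri.populations}
    cut = barrier.crossed()
    for a, b in tri.edges():
        if _edge(a, b) not in cut:
            adj[a].add(b)
            adj[b].add(a)
    seen: set[str] = set()
    comps: list[set[str]] = []
    for p in tri.populations:
        if p in seen:
            continue
        stack, comp = [p], set()
        while stack:
            q = stack.pop()
            if q in comp:
                continue
            comp.add(q)
            stack.extend(adj[q] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def barrier_significance(
    aln: Alignment,
    pm: PopulationMap,
    tri: TriangulationGraph,
    barrier: Barrier,
    n_perms: int = 1000,
    seed: int | None = 0,
) -> AmovaResult | None:
    """Two-group AMOVA across a barrier (None if it does not split the map)."""
    comps = barrier_sides(tri, barrier)
    if len(comps) < 2:
        return None
    groups = {p: f"side{i + 1}" for i, comp in enumerate(comps) for p in comp}
    scheme = GroupingScheme(f"barrier_{barrier.rank}", groups)
    return amova(aln, pm, scheme, n_perms=n_perms, seed=seed)
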
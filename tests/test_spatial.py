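import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hv2pop import (
    GeoLayout,
    delaunay,
    geo_distance_matrix,
    haversine_km,
    mantel,
    monmonier_barriers,
)
from hv2pop.spatial import GeometryError, barrier_sides


class TestGeoDistances:
    def test_identical_points(self):
        assert haversine_km(51.4, 35.7, 51.4, 35.7) == 0.0

    def test_antipodal_on_equator(self):
        assert haversine_km(0, 0, 180, 0) == pytest.approx(math.pi * 6371)

    def test_pole_to_equator(self):
        assert haversine_km(0, 0, 0, 90) == pytest.approx(math.pi * 6371 / 2)

    def test_matrix_against_scalar(self):
        layout = GeoLayout({"Tehran": (51.42, 35.69), "Esfahan": (51.67, 32.65)})
        m = geo_distance_matrix(layout)
        assert m.loc["Tehran", "Esfahan"] == pytest.approx(
            haversine_km(51.42, 35.69, 51.67, 32.65)
        )
        # independent closed-form check of the same pair
        p1, p2 = math.radians(35.69), math.radians(32.65)
        dl = math.radians(51.67 - 51.42)
        a = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
        assert m.loc["Tehran", "Esfahan"] == pytest.approx(
            2 * 6371 * math.asin(math.sqrt(a)), abs=1e-9
        )

    @given(
        lons=st.lists(st.floats(-180, 180), min_size=3, max_size=3),
        lats=st.lists(st.floats(-89, 89), min_size=3, max_size=3),
    )
    @settings(max_examples=40, deadline=None)
    def test_triangle_inequality(self, lons, lats):
        layout = GeoLayout(
            {f"p{i}": (lons[i], lats[i]) for i in range(3)}
        )
        m = geo_distance_matrix(layout).to_numpy()
        assert m[0, 1] <= m[0, 2] + m[2, 1] + 1e-6

    def test_invalid_coordinates_raise(self):
        with pytest.raises(GeometryError):
            GeoLayout({"x": (200.0, 10.0)})


class TestMantel:
    def _random_sym(self, rng, n=6):
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        return d

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        d = self._random_sym(rng)
        res = mantel(d, d, n_perms=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_perfect_anticorrelation(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        vals = [(1, 0, 1.0), (2, 0, 2.0), (2, 1, 3.0), (3, 0, 4.0), (3, 1, 5.0), (3, 2, 6.0)]
        for i, j, v in vals:
            a[i, j] = a[j, i] = v
            b[i, j] = b[j, i] = 7.0 - v
        res = mantel(a, b, n_perms=9, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_symmetry_of_r(self):
        rng = np.random.default_rng(2)
        a, b = self._random_sym(rng), self._random_sym(rng)
        assert mantel(a, b, n_perms=0).r == pytest.approx(mantel(b, a, n_perms=0).r)

    def test_type_one_error_calibration(self):
        """Independent random matrices: rejection at 5% within 5% +/- 3%."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for rep in range(reps):
            a, b = self._random_sym(rng), self._random_sym(rng)
            res = mantel(a, b, n_perms=99, seed=rep)
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_label_mismatch_raises(self):
        with pytest.raises(ValueError):
            mantel(np.zeros((4, 4)), np.zeros((5, 5)), n_perms=1)

    def test_r_matches_independent_implementation(self):
        """Cross-check the correlation against scikit-bio's Mantel test."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(3)
        a, b = self._random_sym(rng), self._random_sym(rng)
        ours = mantel(a, b, n_perms=0)
        theirs_r, _, _ = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b), permutations=0
        )
        assert ours.r == pytest.approx(float(theirs_r), abs=1e-12)


class TestDelaunay:
    def test_three_points_one_triangle(self):
        tri = delaunay(GeoLayout({"a": (0, 0), "b": (1, 0), "c": (0, 1)}))
        assert len(tri.triangles) == 1
        assert len(tri.edges()) == 3
        assert all(tri.is_hull_edge(e) for e in tri.edges())

    def test_four_points_convex_position(self):
        tri = delaunay(
            GeoLayout({"a": (0, 0), "b": (2, 0.1), "c": (0.1, 2), "d": (2, 2)})
        )
        assert len(tri.triangles) == 2
        assert len(tri.edges()) == 5
        interior = [e for e in tri.edges() if not tri.is_hull_edge(e)]
        assert len(interior) == 1

    def test_empty_circumcircle_property(self):
        layout = GeoLayout({"a": (0, 0), "b": (3, 0), "c": (0, 3), "d": (2.5, 2.5)})
        tri = delaunay(layout)
        pts = {p: tri.points[i] for i, p in enumerate(tri.populations)}
        for t in range(len(tri.triangles)):
            i, j, k = tri.triangles[t]
            names = [tri.populations[x] for x in (i, j, k)]
            cx, cy, r = _circumcircle(*[pts[n] for n in names])
            for other in tri.populations:
                if other in names:
                    continue
                d = math.hypot(pts[other][0] - cx, pts[other][1] - cy)
                assert d >= r - 1e-6

    def test_collinear_points_raise(self):
        with pytest.raises(GeometryError):
            delaunay(GeoLayout({"a": (0, 0), "b": (1, 1), "c": (2, 2)}))


def _circumcircle(p1, p2, p3):
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    return ux, uy, math.hypot(ax - ux, ay - uy)


class TestMonmonier:
    def _square(self):
        layout = GeoLayout(
            {"L1": (0, 0), "L2": (0, 1), "R1": (1, 0), "R2": (1, 1)}
        )
        return delaunay(layout)

    def test_manual_trace_on_square(self):
        """Left/right pairs separated by large distances: the barrier
        crosses exactly the left-right edges of the triangulation."""
        tri = self._square()
        pops = ["L1", "L2", "R1", "R2"]
        d = pd.DataFrame(0.01, index=pops, columns=pops)
        for x in ("L1", "L2"):
            for y in ("R1", "R2"):
                d.loc[x, y] = d.loc[y, x] = 0.5
        d.loc["L1", "R1"] = d.loc["R1", "L1"] = 0.6  # unique seed edge
        np.fill_diagonal(d.values, 0.0)
        res = monmonier_barriers(tri, d, n_barriers=1)
        b = res.first()
        cross = {frozenset(e) for e in b.edges}
        expected = {
            frozenset(e) for e in tri.edges() if e[0][0] != e[1][0]
        }  # all L-R edges present in the triangulation
        assert cross == expected
        sides = barrier_sides(tri, b)
        assert {frozenset(s) for s in sides} == {
            frozenset({"L1", "L2"}),
            frozenset({"R1", "R2"}),
        }

    def test_all_distances_equal_flags_ties(self):
        tri = self._square()
        pops = ["L1", "L2", "R1", "R2"]
        d = pd.DataFrame(0.3, index=pops, columns=pops)
        np.fill_diagonal(d.values, 0.0)
        res = monmonier_barriers(tri, d, n_barriers=1)
        assert res.first().had_ties

    def test_barrier_never_crosses_an_edge_twice(self, barrier_dataset):
        from hv2pop import pop_distance_matrix

        aln, pm, layout = barrier_dataset
        tri = delaunay(layout)
        dm = pop_distance_matrix(aln, pm, n_perms=0, seed=0)
        res = monmonier_barriers(tri, dm.to_frame(), n_barriers=2)
        seen = set()
        for b in res.barriers:
            assert len(set(b.edges)) == len(b.edges)
            assert not (set(b.edges) & seen)
            seen |= set(b.edges)

    def test_barrier_edges_are_above_average_distance(self, barrier_dataset):
        from hv2pop import pop_distance_matrix

        aln, pm, layout = barrier_dataset
        tri = delaunay(layout)
        dm = pop_distance_matrix(aln, pm, n_perms=0, seed=0).to_frame()
        res = monmonier_barriers(tri, dm, n_barriers=1)
        b = res.first()
        all_edges = [dm.loc[a, c] for a, c in tri.edges()]
        assert np.mean(b.distances) >= np.mean(all_edges)

    def test_excess_barrier_request_returns_fewer(self):
        tri = self._square()
        pops = ["L1", "L2", "R1", "R2"]
        d = pd.DataFrame(0.3, index=pops, columns=pops)
        np.fill_diagonal(d.values, 0.0)
        res = monmonier_barriers(tri, d, n_barriers=10)
        assert len(res.barriers) <= 10
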
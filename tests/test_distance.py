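import math

import numpy as np
import pandas as pd
import pytest

from hv2pop import (
    Alignment,
    PopulationMap,
    SaturationError,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    ordinate,
    pairwise_phist,
    phist_from_d2,
    pop_distance_matrix,
)
from hv2pop.distance import MissingDataError


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_single_transition_closed_form(self):
        a = "A" * 294
        b = "G" + "A" * 293
        expected = -0.5 * math.log(1 - 2 / 294)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.003413, abs=1e-6)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 100))
            b = "".join(rng.choice(list("ACGT"), 100))
            try:
                assert k2p_distance(a, b) == k2p_distance(b, a)
            except SaturationError:
                pass

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 10, "G" * 10)

    def test_missing_overlap_raises(self):
        with pytest.raises(MissingDataError):
            k2p_distance("NNNN", "ACGT")

    def test_matrix_matches_scalar(self):
        aln = Alignment(["a", "b", "c"], ["ACGTAC", "ACGTAT", "ACGAAT"])
        m = k2p_matrix(aln, per_site=True)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert m[i, j] == pytest.approx(
                k2p_distance(aln.seqs[i], aln.seqs[j])
            )


class TestPhiST:
    def test_fixed_difference_gives_one(self, fixed_diff_aln):
        aln, pm = fixed_diff_aln
        phi, p = pairwise_phist(aln, pm, "P1", "P2", n_perms=99, seed=0)
        assert phi == pytest.approx(1.0)
        # only the 2/C(8,4) label permutations reproducing the split score
        # as high, so p sits near its attainable minimum
        assert p <= 0.06

    def test_identical_composition_is_near_zero(self):
        seqs = (["AAAA"] * 5 + ["AAAT"] * 5) * 2
        ids = [f"s{i}" for i in range(20)]
        aln = Alignment(ids, seqs)
        pm = PopulationMap(
            pd.DataFrame({"sample_id": ids, "population": ["P1"] * 10 + ["P2"] * 10})
        )
        phi, p = pairwise_phist(aln, pm, "P1", "P2", n_perms=99, seed=0)
        assert phi <= 0.05 and p > 0.05

    def test_matches_brute_force_variance_components(self, shared_hap_aln):
        """Independent evaluation of the nested sums on the 8-sequence toy:
        SS_total=2, SS_within=1.5 => sigma_a=0.0625, sigma_w=0.25, Phi=0.2."""
        aln, pm = shared_hap_aln
        phi, _ = pairwise_phist(aln, pm, "P1", "P2", n_perms=1, seed=0)
        assert phi == pytest.approx(0.2, abs=1e-12)

    def test_relabeling_within_population_invariant(self, shared_hap_aln):
        aln, pm = shared_hap_aln
        d2 = k2p_matrix(aln)
        g = np.array([0] * 4 + [1] * 4)
        base = phist_from_d2(d2, g)
        perm = np.array([2, 0, 3, 1, 6, 7, 4, 5])  # shuffle within pops
        assert phist_from_d2(d2[np.ix_(perm, perm)], g) == pytest.approx(base)

    def test_type_one_error_of_permutation_test(self):
        """Rejection rate at 5% stays <= 8% for exchangeable populations."""
        from hv2pop.simulate import SimulationConfig, ConstantSize, simulate_sample

        rejections = 0
        reps = 200
        for rep in range(reps):
            sim = simulate_sample(
                SimulationConfig(
                    n_pops=2, samples_per_pop=10, demography=ConstantSize(3.0),
                    seed=10_000 + rep,
                )
            )
            _, p = pairwise_phist(
                sim.alignment, sim.popmap, "Pop1", "Pop2", n_perms=99, seed=rep
            )
            rejections += p <= 0.05
        assert rejections / reps <= 0.08

    def test_phist_increases_with_divergence_time(self):
        """Deeper splits give larger PhiST along a 3-level ladder."""
        from hv2pop.simulate import SimulationConfig, SplitModel, simulate_sample

        means = []
        for div in [0.2, 1.0, 4.0]:
            vals = []
            for rep in range(12):
                sim = simulate_sample(
                    SimulationConfig(
                        n_pops=2, samples_per_pop=12,
                        demography=SplitModel(2, 2.0, div),
                        seed=777 + 100 * rep + int(div * 10),
                    )
                )
                phi, _ = pairwise_phist(
                    sim.alignment, sim.popmap, "Pop1", "Pop2", n_perms=1, seed=0
                )
                vals.append(phi)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_population_matrix_shape_and_symmetry(self, barrier_dataset):
        aln, pm, _ = barrier_dataset
        dm = pop_distance_matrix(aln, pm, n_perms=19, seed=0)
        assert dm.values.shape == (6, 6)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all((dm.p_values + np.eye(6) >= 0) & (dm.p_values <= 1))


class TestNJTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        res = nj_tree(d, labels=["a", "b", "c"])
        lengths = {t.name: t.length for t in res.tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree: (a,b) vs (c,d); a=2, b=3, internal=3, c=4, d=4 (additive)
        d = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float
        )
        res = nj_tree(d, labels=list("abcd"))
        tree = res.tree
        # a and b must be sisters
        a = tree.find("a")
        sibs = {t.name for t in a.parent.children if t.name}
        assert "b" in sibs
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 2.0, "b": 3.0, "c": 4.0, "d": 4.0})

    def test_label_permutation_gives_isomorphic_tree(self):
        d = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float
        )
        res1 = nj_tree(d, labels=list("abcd"))
        perm = [2, 0, 3, 1]
        d2 = d[np.ix_(perm, perm)]
        res2 = nj_tree(d2, labels=[list("abcd")[i] for i in perm])
        assert res1.tree.compare_rfd(res2.tree) == 0

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), labels=["a", "b"])


class TestOrdination:
    def test_planar_distances_embed_exactly(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [2, 0.5]], float)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        res = ordinate(d, dims=2, method="pcoa")
        emb = squareform(pdist(res.coordinates))
        assert np.allclose(emb, d, atol=1e-6)
        assert res.stress < 1e-6

    def test_collinear_populations_stay_collinear(self):
        d = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0)))
        res = ordinate(d, dims=2, method="pcoa")
        spread = res.coordinates - res.coordinates.mean(0)
        _, sv, _ = np.linalg.svd(spread)
        assert sv[1] == pytest.approx(0.0, abs=1e-8)

    def test_nonmetric_stress_not_worse_than_metric(self):
        rng = np.random.default_rng(1)
        m = rng.random((6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        met = ordinate(d, dims=2, method="pcoa", seed=0)
        nmet = ordinate(d, dims=2, method="nmds", seed=0)
        assert nmet.stress <= met.stress + 1e-9

    def test_dimension_guard(self):
        with pytest.raises(ValueError):
            ordinate(np.zeros((3, 3)), dims=3)
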
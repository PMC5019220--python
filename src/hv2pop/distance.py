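"""Between-sequence and between-population distances.

Inter-individual distances use the Kimura two-parameter (K2P) correction,
d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the transition and
transversion fractions over comparable (both-ACGT) sites.  Population
differentiation is PhiST, the AMOVA fixation index computed from squared
K2P distances, with significance from permuting individuals between
populations.  The PhiST matrix feeds neighbour-joining, ordination,
Mantel tests and barrier detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .alignment import Alignment, PopulationMap


class SaturationError(ValueError):
    """K2P correction undefined: log argument non-positive."""


class MissingDataError(ValueError):
    pass


def _ts_tv_counts(mi: np.ndarray, mj: np.ndarray) -> tuple[int, int, int]:
    both = (mi < 4) & (mj < 4)
    L = int(both.sum())
    x = mi[both] ^ mj[both]
    ts = int(np.sum(x == 2))
    tv = int(np.sum((x != 0) & (x != 2)))
    return ts, tv, L


def _k2p(ts: int, tv: int, L: int) -> float:
    P, Q = ts / L, tv / L
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P saturated (P={P:.3f}, Q={Q:.3f}): log argument <= 0"
        )
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance (substitutions/site) between two aligned sequences."""
    aln = Alignment(["a", "b"], [seq_a, seq_b])
    m = aln.matrix
    ts, tv, L = _ts_tv_counts(m[0], m[1])
    if L == 0:
        raise MissingDataError("no comparable sites between sequences")
    return _k2p(ts, tv, L)


def k2p_matrix(aln: Alignment, per_site: bool = False) -> np.ndarray:
    """Symmetric K2P distance matrix; by default scaled by L (expected
    substitutions over the whole sequence, the scale AMOVA consumes)."""
    m = aln.matrix
    n = aln.n
    out = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            ts, tv, L = _ts_tv_counts(m[i], m[j])
            if L == 0:
                raise MissingDataError(f"no comparable sites for pair ({i},{j})")
            d = _k2p(ts, tv, L)
            out[i, j] = out[j, i] = d if per_site else d * L
    return out


# ---------------------------------------------------------------------------
# PhiST (one-level AMOVA on squared distances)

def _ss_within_indices(d2: np.ndarray, idx: np.ndarray) -> float:
    return float(d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx)))


def phist_from_d2(d2: np.ndarray, groups: np.ndarray) -> float:
    """One-level AMOVA fixation index from a squared-distance matrix and an
    integer group-label vector (haploid individuals)."""
    N = len(groups)
    labels = np.unique(groups)
    P = len(labels)
    ss_total = d2.sum() / (2.0 * N)
    ss_within = 0.0
    sizes = []
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sizes.append(len(idx))
        ss_within += _ss_within_indices(d2, idx)
    sizes_arr = np.array(sizes, float)
    ss_among = ss_total - ss_within
    df_among = P - 1
    df_within = N - P
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (N - np.sum(sizes_arr**2) / N) / df_among
    sigma_a = (ms_among - ms_within) / n0
    sigma_w = ms_within
    total = sigma_a + sigma_w
    if total == 0:
        return 0.0
    return float(sigma_a / total)


def pairwise_phist(
    aln: Alignment,
    pm: PopulationMap,
    pop_i: str,
    pop_j: str,
    n_perms: int = 10_000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """PhiST between two populations with a permutation p-value.

    p = (#{permuted PhiST >= observed} + 1) / (n_perms + 1), permuting
    individuals between the two populations.
    """
    ids = pm.samples_of(pop_i) + pm.samples_of(pop_j)
    n1 = len(pm.samples_of(pop_i))
    if n1 < 2 or len(ids) - n1 < 2:
        raise ValueError("each population needs >= 2 samples")
    sub = aln.subset(ids)
    d2 = k2p_matrix(sub)
    groups = np.array([0] * n1 + [1] * (len(ids) - n1))
    obs = phist_from_d2(d2, groups)
    if not n_perms:
        return obs, float("nan")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(len(ids))
        if phist_from_d2(d2, groups[perm]) >= obs:
            count += 1
    return obs, (count + 1) / (n_perms + 1)


@dataclass
class PopDistanceMatrix:
    """Pairwise PhiST values (possibly slightly negative) with p-values."""

    labels: list[str]
    values: np.ndarray
    p_values: np.ndarray
    n_permutations: int

    def clamped(self) -> np.ndarray:
        """Negative entries set to 0 (input form for NJ/ordination)."""
        return np.clip(self.values, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pop_distance_matrix(
    aln: Alignment,
    pm: PopulationMap,
    n_perms: int = 10_000,
    seed: int | None = 0,
) -> PopDistanceMatrix:
    """All pairwise PhiST values between the mapped populations."""
    pops = pm.populations
    K = len(pops)
    values = np.zeros((K, K))
    pvals = np.zeros((K, K))
    rng = np.random.default_rng(seed)
    for i in range(K - 1):
        for j in range(i + 1, K):
            sub_seed = int(rng.integers(2**31 - 1))
            phi, p = pairwise_phist(aln, pm, pops[i], pops[j], n_perms, sub_seed)
            values[i, j] = values[j, i] = phi
            pvals[i, j] = pvals[j, i] = p
    return PopDistanceMatrix(list(pops), values, pvals, n_perms)


# ---------------------------------------------------------------------------
# trees and ordination

@dataclass
class TreeResult:
    newick: str
    tree: object  # skbio.TreeNode


def nj_tree(d: PopDistanceMatrix | np.ndarray, labels: list[str] | None = None) -> TreeResult:
    """Unrooted neighbour-joining tree (Saitou-Nei) from a PhiST matrix.

    Negative input distances and negative fitted branch lengths are
    clamped to zero.
    """
    if isinstance(d, PopDistanceMatrix):
        mat, labels = d.clamped(), d.labels
    else:
        mat = np.clip(np.asarray(d, float), 0.0, None)
        if labels is None:
            raise ValueError("labels required with a bare matrix")
    if len(labels) < 3:
        raise ValueError("neighbour-joining needs >= 3 populations")
    tree = _skbio_nj(_SkbioDM(mat, ids=list(labels)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return TreeResult(str(tree).strip(), tree)


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray
    stress: float
    method: str
    eigenvalues: np.ndarray | None = None


def _kruskal_stress(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding, with isotonic (monotone-rank)
    disparities fitted to the observed dissimilarities."""
    from scipy.spatial.distance import pdist
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(len(d_obs), 1)
    dis = d_obs[iu]
    emb = pdist(coords)
    order = np.argsort(dis, kind="stable")
    iso = IsotonicRegression()
    disp = np.empty_like(emb)
    disp[order] = iso.fit_transform(np.arange(len(order)), emb[order])
    denom = np.sum(emb**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((disp - emb) ** 2) / denom))


def ordinate(
    d: PopDistanceMatrix | np.ndarray,
    dims: int = 2,
    method: str = "pcoa",
    labels: list[str] | None = None,
    seed: int | None = 0,
) -> OrdinationResult:
    """Embed the population distance matrix in ``dims`` dimensions.

    ``method='pcoa'`` (default) is metric principal coordinates;
    ``method='nmds'`` refines a PCoA start by non-metric multidimensional
    scaling (isotonic regression on ranks, SMACOF iterations).  The
    reported stress is Kruskal stress-1 in both cases.
    """
    if isinstance(d, PopDistanceMatrix):
        mat, labels = d.clamped(), d.labels
    else:
        mat = np.clip(np.asarray(d, float), 0.0, None)
        if labels is None:
            labels = [str(i) for i in range(len(mat))]
    if len(labels) < dims + 1:
        raise ValueError(f"need at least {dims + 1} populations for {dims}-d ordination")
    from skbio.stats.ordination import pcoa as _pcoa

    res = _pcoa(_SkbioDM(mat, ids=list(labels)), number_of_dimensions=dims)
    coords = res.samples.to_numpy()[:, :dims]
    eig = res.eigvals.to_numpy()
    if method == "pcoa":
        return OrdinationResult(list(labels), coords, _kruskal_stress(mat, coords), "pcoa", eig)
    if method != "nmds":
        raise ValueError(f"unknown ordination method {method!r}")
    import warnings

    from sklearn.manifold import MDS

    mds = MDS(
        n_components=dims,
        metric="precomputed",
        metric_mds=False,
        n_init=1,
        max_iter=500,
        eps=1e-6,
        normalized_stress=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        nm = mds.fit_transform(mat, init=coords)
    return OrdinationResult(list(labels), nm, _kruskal_stress(mat, nm), "nmds", eig)
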
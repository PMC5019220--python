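"""Hierarchical analysis of molecular variance (AMOVA).

Variance is partitioned among groups of populations (sigma_a), among
populations within groups (sigma_b) and within populations (sigma_c) from
nested sums of squared inter-individual distances, following the classic
expected-mean-square estimators for unbalanced designs.  The fixation
indices are

    Phi_ST = (sigma_a + sigma_b) / total     total differentiation
    Phi_CT = sigma_a / total                 among groups
    Phi_SC = sigma_b / (sigma_b + sigma_c)   among populations in groups

Significance is assessed by permutation: individuals across the whole
system for Phi_ST, individuals among populations within groups for
Phi_SC, and whole populations among groups for Phi_CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, PopulationMap
from .distance import k2p_matrix, phist_from_d2


class SchemeError(ValueError):
    pass


@dataclass
class GroupingScheme:
    """Named assignment of populations to higher-level groups."""

    name: str
    groups: dict[str, str]  # population -> group label

    def validate(self, populations: list[str]) -> None:
        missing = [p for p in populations if p not in self.groups]
        if missing:
            raise SchemeError(f"populations without a group in {self.name!r}: {missing}")
        if len(set(self.groups[p] for p in populations)) < 2:
            raise SchemeError(f"scheme {self.name!r} has a single group: degenerate design")

    @classmethod
    def from_popmap(cls, pm: PopulationMap, column: str) -> "GroupingScheme":
        return cls(column, pm.group_of(column))


@dataclass
class AmovaResult:
    scheme: str
    sigma_a: float          # among groups
    sigma_b: float          # among populations within groups
    sigma_c: float          # within populations
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    p_st: float | None = None
    p_sc: float | None = None
    p_ct: float | None = None
    df: dict[str, int] = field(default_factory=dict)
    negative_components: bool = False

    @property
    def total(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c

    def percentages(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {"among_groups": 0.0, "among_pops_within_groups": 0.0,
                    "within_pops": 100.0}
        return {
            "among_groups": 100.0 * self.sigma_a / t,
            "among_pops_within_groups": 100.0 * self.sigma_b / t,
            "within_pops": 100.0 * self.sigma_c / t,
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [
            ("among groups", self.sigma_a, pct["among_groups"], self.phi_ct, self.p_ct),
            ("among populations within groups", self.sigma_b,
             pct["among_pops_within_groups"], self.phi_sc, self.p_sc),
            ("within populations", self.sigma_c, pct["within_pops"],
             self.phi_st, self.p_st),
        ]
        return pd.DataFrame(
            rows, columns=["source", "variance", "percent", "phi", "p"]
        )


def _components(
    d2: np.ndarray, pop_idx: np.ndarray, grp_of_pop: np.ndarray
) -> tuple[float, float, float, dict[str, int]]:
    """(sigma_a, sigma_b, sigma_c, dfs) from squared distances.

    ``pop_idx`` maps individuals to population indices 0..P-1;
    ``grp_of_pop`` maps population indices to group indices 0..G-1.
    """
    N = len(pop_idx)
    P = len(grp_of_pop)
    grp_idx = grp_of_pop[pop_idx]
    G = int(grp_of_pop.max()) + 1

    n_p = np.bincount(pop_idx, minlength=P).astype(float)
    n_g = np.bincount(grp_idx, minlength=G).astype(float)

    ss_total = d2.sum() / (2.0 * N)
    ss_wp = 0.0
    for p in range(P):
        idx = np.flatnonzero(pop_idx == p)
        if len(idx):
            ss_wp += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_wg = 0.0  # total SS within each group (pops pooled)
    for g in range(G):
        idx = np.flatnonzero(grp_idx == g)
        if len(idx):
            ss_wg += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P
    dfs = {"among_groups": df_ag, "among_pops": df_ap, "within_pops": df_wp}

    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    A = sum((n_p[grp_of_pop == g] ** 2).sum() / n_g[g] for g in range(G) if n_g[g])
    if df_ap > 0:
        n1 = (N - A) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1 if n1 > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n2 = (A - np.sum(n_p**2) / N) / df_ag
        n3 = (N - np.sum(n_g**2) / N) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0  # single group: no among-groups stratum
    return float(sigma_a), float(sigma_b), float(sigma_c), dfs


def amova(
    aln: Alignment,
    pm: PopulationMap,
    scheme: GroupingScheme | None = None,
    n_perms: int = 1000,
    seed: int | None = 0,
    d2: np.ndarray | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on squared K2P distances.

    With ``scheme=None`` all populations form one implicit system and only
    the one-level Phi_ST (among populations / within populations) is
    reported.  Permutation counts below 1 disable significance testing.
    """
    pops = pm.populations
    for p in pops:
        if len(pm.samples_of(p)) < 2:
            raise SchemeError(f"population {p!r} has fewer than 2 samples")
    order = [sid for p in pops for sid in pm.samples_of(p)]
    sub = aln.subset(order)
    if d2 is None:
        d2 = k2p_matrix(sub)
    pop_idx = np.concatenate(
        [np.full(len(pm.samples_of(p)), i) for i, p in enumerate(pops)]
    )
    rng = np.random.default_rng(seed)

    if scheme is None:
        phi = phist_from_d2(d2, pop_idx)
        res = AmovaResult("one-level", 0.0, *_one_level_sigmas(d2, pop_idx),
                          phi_st=phi, phi_sc=None, phi_ct=None)
        if n_perms >= 1:
            count = 0
            for _ in range(n_perms):
                if phist_from_d2(d2, pop_idx[rng.permutation(len(pop_idx))]) >= phi:
                    count += 1
            res.p_st = (count + 1) / (n_perms + 1)
        return res

    scheme.validate(pops)
    grp_labels = list(dict.fromkeys(scheme.groups[p] for p in pops))
    grp_of_pop = np.array([grp_labels.index(scheme.groups[p]) for p in pops])

    sa, sb, sc, dfs = _components(d2, pop_idx, grp_of_pop)
    total = sa + sb + sc
    phi_st = (sa + sb) / total if total else 0.0
    phi_ct = sa / total if total else 0.0
    phi_sc = sb / (sb + sc) if (sb + sc) else 0.0
    res = AmovaResult(
        scheme.name, sa, sb, sc, phi_st, phi_sc, phi_ct, df=dfs,
        negative_components=(min(sa, sb, sc) < 0),
    )
    if n_perms >= 1:
        c_st = c_sc = c_ct = 0
        for _ in range(n_perms):
            # Phi_ST: individuals across the whole system
            perm = rng.permutation(len(pop_idx))
            a, b, c = _components(d2, pop_idx[perm], grp_of_pop)[:3]
            t = a + b + c
            if (((a + b) / t) if t else 0.0) >= phi_st:
                c_st += 1
            # Phi_SC: individuals among populations within groups
            perm2 = _permute_within_groups(pop_idx, grp_of_pop, rng)
            a, b, c = _components(d2, perm2, grp_of_pop)[:3]
            if ((b / (b + c)) if (b + c) else 0.0) >= phi_sc:
                c_sc += 1
            # Phi_CT: whole populations among groups
            gperm = grp_of_pop[rng.permutation(len(grp_of_pop))]
            a, b, c = _components(d2, pop_idx, gperm)[:3]
            t = a + b + c
            if ((a / t) if t else 0.0) >= phi_ct:
                c_ct += 1
        res.p_st = (c_st + 1) / (n_perms + 1)
        res.p_sc = (c_sc + 1) / (n_perms + 1)
        res.p_ct = (c_ct + 1) / (n_perms + 1)
    return res


def _one_level_sigmas(d2: np.ndarray, pop_idx: np.ndarray) -> tuple[float, float]:
    """(sigma_among, sigma_within) of a one-level design, reported as
    (sigma_b, sigma_c) so the result object's percentages stay meaningful."""
    N = len(pop_idx)
    P = int(pop_idx.max()) + 1
    n_p = np.bincount(pop_idx, minlength=P).astype(float)
    ss_total = d2.sum() / (2.0 * N)
    ss_wp = 0.0
    for p in range(P):
        idx = np.flatnonzero(pop_idx == p)
        ss_wp += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    df_a, df_w = P - 1, N - P
    sigma_c = ss_wp / df_w if df_w else 0.0
    n0 = (N - np.sum(n_p**2) / N) / df_a
    sigma_b = ((ss_total - ss_wp) / df_a - sigma_c) / n0
    return float(sigma_b), float(sigma_c)


def _permute_within_groups(
    pop_idx: np.ndarray, grp_of_pop: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle individuals' population labels within their group."""
    out = pop_idx.copy()
    grp_idx = grp_of_pop[pop_idx]
    for g in np.unique(grp_idx):
        sel = np.flatnonzero(grp_idx == g)
        out[sel] = out[sel][rng.permutation(len(sel))]
    return out
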
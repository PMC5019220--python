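"""Within-population diversity statistics and Tajima's neutrality test.

k (mean pairwise differences) uses raw, uncorrected differences with
pairwise complete deletion of non-ACGT site pairs; the K2P correction is
reserved for between-population differentiation.  Haplotype diversity uses
Nei's unbiased estimator h = n(1 - sum p_i^2)/(n - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment, PopulationMap, polymorphic_sites
from .haplotypes import HaplotypeTable, collapse_haplotypes
from .simulate import fixed_s_tajima_k


class InsufficientSampleError(ValueError):
    pass


class MonomorphicError(ValueError):
    """Tajima's D is undefined without segregating sites."""


def haplotype_diversity(ht: HaplotypeTable, population: str | None = None) -> float:
    """Nei's unbiased haplotype diversity for one population (or pooled)."""
    if population is None:
        counts = ht.total_counts().to_numpy(float)
    else:
        counts = ht.counts[population].to_numpy(float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise InsufficientSampleError("haplotype diversity needs n >= 2")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def _pairwise_raw_diffs(aln: Alignment) -> np.ndarray:
    """Condensed vector of raw pairwise differences (pairwise deletion)."""
    m = aln.matrix
    n = aln.n
    valid = m < 4
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = (m[i] != m[i + 1 :]) & both
        out[idx : idx + n - i - 1] = diff.sum(axis=1)
        idx += n - i - 1
    return out


def pairwise_diff_stats(aln: Alignment) -> tuple[float, float]:
    """(k, pi): mean pairwise differences and per-site nucleotide diversity.

    pi normalises each pair by its number of comparable (both-ACGT) sites
    and averages; with no missing data pi == k / L exactly.
    """
    if aln.n < 2:
        raise InsufficientSampleError("pairwise statistics need n >= 2")
    m = aln.matrix
    n = aln.n
    valid = m < 4
    diffs = []
    pis = []
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        L_comp = both.sum(axis=1)
        d = ((m[i] != m[i + 1 :]) & both).sum(axis=1)
        diffs.append(d)
        with np.errstate(invalid="ignore", divide="ignore"):
            pis.append(np.where(L_comp > 0, d / L_comp, 0.0))
    k = float(np.concatenate(diffs).mean())
    pi = float(np.concatenate(pis).mean())
    return k, pi


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 normalising constants of Tajima's D for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d_from_summaries(n: int, s: int, k: float) -> float:
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return (k - s / c["a1"]) / math.sqrt(var)


@dataclass
class NeutralityResult:
    D: float
    p_value: float
    method: str
    n: int
    s: int
    k: float


def _beta_p_value(D: float, n: int) -> float:
    """Tajima's beta-distribution approximation to the two-sided p-value."""
    c = tajima_constants(n)
    a1, a2 = c["a1"], c["a2"]
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(c["e2"])
    dmax = ((n + 1.0) / (2.0 * n) - 1.0 / a1) / math.sqrt(c["e2"])
    # Beta on [dmin, dmax] with mean 0 and variance 1
    alpha = -(1 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    return float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))


def tajimas_d(
    aln: Alignment,
    method: str = "simulated",
    n_sims: int = 10_000,
    seed: int | None = 0,
) -> NeutralityResult:
    """Tajima's D with a two-sided significance estimate.

    ``method='simulated'`` builds the null by coalescent simulation
    conditioned on (n, s): neutral genealogies receive exactly s mutations
    and the resulting D values form the reference distribution.
    ``method='beta'`` uses Tajima's beta approximation instead.
    """
    n = aln.n
    if n < 4:
        raise InsufficientSampleError("Tajima's D needs n >= 4")
    s = len(polymorphic_sites(aln))
    if s == 0:
        raise MonomorphicError("no segregating sites: Tajima's D undefined")
    k, _ = pairwise_diff_stats(aln)
    D = tajima_d_from_summaries(n, s, k)
    if method == "beta":
        p = _beta_p_value(D, n)
    elif method == "simulated":
        rng = np.random.default_rng(seed)
        k_null = fixed_s_tajima_k(n, s, n_sims, rng)
        c = tajima_constants(n)
        var = c["e1"] * s + c["e2"] * s * (s - 1)
        d_null = (k_null - s / c["a1"]) / math.sqrt(var)
        lo = (np.sum(d_null <= D) + 1) / (n_sims + 1)
        hi = (np.sum(d_null >= D) + 1) / (n_sims + 1)
        p = float(min(1.0, 2.0 * min(lo, hi)))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return NeutralityResult(float(D), p, method, n, s, k)


@dataclass
class DiversitySummary:
    population: str
    n: int
    s: int
    H: int
    h: float
    pi: float
    k: float
    tajima_D: float | None
    tajima_p: float | None


def diversity_table(
    aln: Alignment,
    pm: PopulationMap,
    include_pooled: bool = True,
    d_method: str = "simulated",
    d_sims: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-population (plus pooled) diversity and neutrality summary table."""
    ht = collapse_haplotypes(aln, pm)
    rows: list[DiversitySummary] = []
    targets = [(p, aln.subset(pm.samples_of(p))) for p in pm.populations]
    if include_pooled:
        targets.append(("pooled", aln))
    for name, sub in targets:
        s = len(polymorphic_sites(sub))
        H = ht.n_haplotypes if name == "pooled" else int((ht.counts[name] > 0).sum())
        h = haplotype_diversity(ht, None if name == "pooled" else name)
        k, pi = pairwise_diff_stats(sub)
        try:
            nres = tajimas_d(sub, d_method, d_sims, seed)
            D, p = nres.D, nres.p_value
        except (MonomorphicError, InsufficientSampleError):
            D, p = None, None
        rows.append(DiversitySummary(name, sub.n, s, H, h, pi, k, D, p))
    return pd.DataFrame([r.__dict__ for r in rows])
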
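"""Coalescent simulation of control-region-like alignments.

Time is measured in *mutational units*: one unit is the expected number of
differences accumulated between a pair of lineages per unit time, so a
panmictic population of scaled size theta has mean pairwise difference
E[k] = theta, and the sudden-expansion parameters (theta0, theta1, tau)
can be passed straight to the mismatch-distribution machinery.  Mutations
are Poisson on branches (rate 1/2 per lineage per unit time) and are
dropped onto L finite sites with a transition bias, so recurrent hits can
occur and the K2P correction has something to correct.

The same engine drives the synthetic datasets, the parametric bootstrap of
the sudden-expansion fit, and the fixed-s null distribution of Tajima's D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, PopulationMap, write_fasta

_TRANSITION_XOR = 2  # A(0)<->G(2), C(1)<->T(3)


# ---------------------------------------------------------------------------
# demography specifications


@dataclass
class ConstantSize:
    """Panmictic population of constant scaled size theta = E[k]."""

    theta: float

    def epochs(self) -> list[tuple[float, float]]:
        return [(0.0, self.theta)]


@dataclass
class SuddenExpansion:
    """Instantaneous growth theta0 -> theta1 at tau mutational units ago."""

    theta0: float
    theta1: float
    tau: float

    def __post_init__(self) -> None:
        if min(self.theta0, self.theta1, self.tau) < 0:
            raise ValueError("expansion parameters must be non-negative")
        if self.theta1 < self.theta0:
            raise ValueError("sudden expansion requires theta1 >= theta0")

    def epochs(self) -> list[tuple[float, float]]:
        return [(0.0, self.theta1), (self.tau, self.theta0)]


@dataclass
class SplitModel:
    """n_demes demes of size theta merging into one ancestor.

    Lineages migrate symmetrically at per-lineage rate ``migration`` until
    ``div_time`` (mutational units ago), when all demes fuse into an
    ancestral population of size ``theta_anc``.
    """

    n_demes: int
    theta: float
    div_time: float
    migration: float = 0.0
    theta_anc: float | None = None

    def __post_init__(self) -> None:
        if self.n_demes < 1 or self.theta < 0 or self.div_time < 0 or self.migration < 0:
            raise ValueError("invalid split-model specification")
        if self.theta_anc is None:
            self.theta_anc = self.theta


Demography = ConstantSize | SuddenExpansion | SplitModel


# ---------------------------------------------------------------------------
# genealogy simulation

@dataclass
class _Branch:
    mask: np.ndarray  # bool (n,) leaves below
    t0: float         # birth (recent end)
    t1: float         # death (old end, coalescence into parent)


def _panmictic_branches(
    n: int, epochs: list[tuple[float, float]], rng: np.random.Generator
) -> list[_Branch]:
    """Kingman coalescent with piecewise-constant theta; returns all non-root
    branches with their time spans (mutational units)."""
    lineages = [_Branch(np.eye(1, n, i, dtype=bool)[0], 0.0, np.inf) for i in range(n)]
    done: list[_Branch] = []
    t = 0.0
    ep = 0
    while len(lineages) > 1:
        k = len(lineages)
        while True:
            theta = epochs[ep][1]
            next_bound = epochs[ep + 1][0] if ep + 1 < len(epochs) else np.inf
            if theta == 0:
                dt = 0.0  # zero-size epoch: instantaneous coalescence
                break
            rate = k * (k - 1) / 2.0 / theta
            dt = rng.exponential(1.0 / rate)
            if t + dt <= next_bound:
                break
            t = next_bound
            ep += 1
        t = t + dt
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        a.t1 = t
        b.t1 = t
        done.extend([a, b])
        merged = _Branch(a.mask | b.mask, t, np.inf)
        lineages[i] = merged
        lineages.pop(j)
    return done


def _structured_branches(
    deme_of: np.ndarray, model: SplitModel, rng: np.random.Generator
) -> list[_Branch]:
    """Structured coalescent (island demes fusing at div_time)."""
    n = len(deme_of)
    lineages = [
        [_Branch(np.eye(1, n, i, dtype=bool)[0], 0.0, np.inf), int(d)]
        for i, d in enumerate(deme_of)
    ]
    done: list[_Branch] = []
    t = 0.0
    fused = model.div_time == 0.0
    while len(lineages) > 1:
        if fused:
            theta = float(model.theta_anc)
            k = len(lineages)
            rate = k * (k - 1) / 2.0 / theta if theta > 0 else np.inf
            t += rng.exponential(1.0 / rate) if np.isfinite(rate) else 0.0
            i, j = sorted(rng.choice(k, size=2, replace=False))
            _merge(lineages, done, i, j, t)
            continue
        counts: dict[int, int] = {}
        for _, d in lineages:
            counts[d] = counts.get(d, 0) + 1
        coal_rates = {
            d: c * (c - 1) / 2.0 / model.theta if model.theta > 0 else np.inf
            for d, c in counts.items()
        }
        mig_rate = model.migration * len(lineages) if model.n_demes > 1 else 0.0
        total = sum(coal_rates.values()) + mig_rate
        if total == 0 or not np.isfinite(total):
            if not np.isfinite(total):  # theta == 0: coalesce now within demes
                d = next(d for d, r in coal_rates.items() if not np.isfinite(r))
                idx = [x for x, (_, dd) in enumerate(lineages) if dd == d]
                _merge(lineages, done, idx[0], idx[1], t)
                continue
            t = model.div_time
            fused = True
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= model.div_time:
            t = model.div_time
            fused = True
            continue
        t += dt
        u = rng.uniform(0, total)
        if u < mig_rate:
            i = rng.integers(len(lineages))
            cur = lineages[i][1]
            others = [d for d in range(model.n_demes) if d != cur]
            lineages[i][1] = int(rng.choice(others))
            continue
        u -= mig_rate
        for d, r in coal_rates.items():
            if u < r:
                idx = [x for x, (_, dd) in enumerate(lineages) if dd == d]
                i, j = sorted(rng.choice(len(idx), size=2, replace=False))
                _merge(lineages, done, idx[i], idx[j], t)
                break
            u -= r
    return done


def _merge(lineages: list, done: list[_Branch], i: int, j: int, t: float) -> None:
    (a, da), (b, _) = lineages[i], lineages[j]
    a.t1 = t
    b.t1 = t
    done.extend([a, b])
    lineages[i] = [_Branch(a.mask | b.mask, t, np.inf), da]
    lineages.pop(j)


# ---------------------------------------------------------------------------
# mutation and sequence synthesis

def _drop_mutations(
    branches: list[_Branch], rng: np.random.Generator
) -> list[tuple[float, int]]:
    """Poisson mutations (rate 1/2 per unit branch length); returns
    (time, branch_index) sorted oldest-first."""
    muts: list[tuple[float, int]] = []
    for b_idx, br in enumerate(branches):
        span = br.t1 - br.t0
        m = rng.poisson(span / 2.0)
        for tt in br.t0 + span * rng.random(m):
            muts.append((float(tt), b_idx))
    muts.sort(key=lambda x: -x[0])
    return muts


def _sequences_from_genealogy(
    branches: list[_Branch],
    n: int,
    L: int,
    rng: np.random.Generator,
    ts_tv: float = 10.0,
    root: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-sites sequences (n, L uint8 codes) and the root sequence."""
    if root is None:
        root = rng.integers(0, 4, size=L, dtype=np.uint8)
    seqs = np.tile(root, (n, 1))
    p_ts = ts_tv / (ts_tv + 2.0)
    for t, b_idx in _drop_mutations(branches, rng):
        site = int(rng.integers(L))
        mask = branches[b_idx].mask
        cur = int(seqs[np.argmax(mask), site])
        if rng.random() < p_ts:
            new = cur ^ _TRANSITION_XOR
        else:
            tv = [b for b in range(4) if b != cur and b != (cur ^ _TRANSITION_XOR)]
            new = int(rng.choice(tv))
        seqs[mask, site] = new
    return seqs, root


_CODE_TO_BASE = np.array(list("ACGTN-"))


def codes_to_strings(seqs: np.ndarray) -> list[str]:
    return ["".join(_CODE_TO_BASE[row]) for row in seqs]


# ---------------------------------------------------------------------------
# fast helpers used by inference modules

def simulate_mismatch_counts(
    n: int, demography: Demography, rng: np.random.Generator
) -> np.ndarray:
    """Histogram of pairwise differences for one simulated sample.

    Infinite-sites shortcut: differences are counted straight off the
    genealogy, one count per mutation separating a pair.
    """
    if isinstance(demography, SplitModel):  # pragma: no cover - not needed
        raise ValueError("use simulate_sample for structured models")
    branches = _panmictic_branches(n, demography.epochs(), rng)
    masks = np.array([b.mask for b in branches])
    w = rng.poisson([(b.t1 - b.t0) / 2.0 for b in branches]).astype(float)
    e = w @ masks                        # per-leaf mutation totals
    C = (masks.T * w) @ masks            # shared mutations per pair
    diffs = e[:, None] + e[None, :] - 2 * C
    iu = np.triu_indices(n, 1)
    d = np.rint(diffs[iu]).astype(int)
    return np.bincount(d)


def fixed_s_tajima_k(
    n: int, s: int, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean pairwise differences k for coalescent samples carrying exactly
    s segregating sites (mutations placed uniformly on the genealogy).

    Vectorised across simulations; used for the empirical null of
    Tajima's D conditioned on (n, s).
    """
    sizes = np.ones((n_sims, n), dtype=np.int64)
    length_by_size = np.zeros((n_sims, n), dtype=float)
    rows_full = np.arange(n_sims)
    for k in range(n, 1, -1):
        t = rng.exponential(2.0 / (k * (k - 1)), size=n_sims)
        rows = np.repeat(rows_full, k)
        np.add.at(length_by_size, (rows, sizes[:, :k].ravel()), np.repeat(t, k))
        i = rng.integers(0, k, size=n_sims)
        j = rng.integers(0, k - 1, size=n_sims)
        j = j + (j >= i)
        a = np.minimum(i, j)
        b = np.maximum(i, j)
        merged = sizes[rows_full, a] + sizes[rows_full, b]
        sizes[rows_full, a] = merged
        sizes[rows_full, b] = sizes[:, k - 1]
    p = length_by_size[:, 1:n]
    p = p / p.sum(axis=1, keepdims=True)
    m = rng.multinomial(s, p)
    cls = np.arange(1, n)
    weight = cls * (n - cls) / (n * (n - 1) / 2.0)
    return m @ weight


# ---------------------------------------------------------------------------
# full synthetic datasets

@dataclass
class SimulationConfig:
    """Recipe for a synthetic multi-population HV2-like dataset.

    Defaults emulate the shape of a six-population mtDNA control-region
    survey: ~20-30 samples per population, 294-bp sequences, strong
    transition bias.  Under ``ConstantSize``/``SuddenExpansion`` all samples
    share one panmictic genealogy (population labels are exchangeable, so
    between-population structure is null); use ``SplitModel`` to impose
    real differentiation.
    """

    n_pops: int = 6
    samples_per_pop: int | Sequence[int] = 24
    L: int = 294
    ts_tv: float = 10.0
    demography: Demography = field(default_factory=lambda: SuddenExpansion(0.5, 50.0, 5.0))
    centers: list[tuple[float, float]] | None = None  # (lon, lat) per pop
    jitter_deg: float = 0.4
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.samples_per_pop, int):
            return [self.samples_per_pop] * self.n_pops
        sizes = list(self.samples_per_pop)
        if len(sizes) != self.n_pops:
            raise ValueError("samples_per_pop length != n_pops")
        return sizes


@dataclass
class SimResult:
    alignment: Alignment
    popmap: PopulationMap
    coords: pd.DataFrame  # population, longitude_deg, latitude_deg
    truth: dict


def _default_centers(cfg: SimulationConfig, n_demes: int) -> list[tuple[float, float]]:
    """Population centres on a lon/lat arc; under a split model the demes
    are separated along longitude so a geographic barrier axis exists."""
    base_lon, base_lat = 51.0, 33.0
    centers = []
    for p in range(cfg.n_pops):
        deme = _deme_of_pops(cfg.n_pops, n_demes)[p]
        lon = base_lon + deme * 6.0 + (p % 3) * 1.5
        lat = base_lat + ((p * 7) % 5) * 1.2
        centers.append((lon, lat))
    return centers


def _deme_of_pops(n_pops: int, n_demes: int) -> list[int]:
    """Contiguous, near-even assignment of populations to demes."""
    bounds = np.linspace(0, n_pops, n_demes + 1).round().astype(int)
    out = np.zeros(n_pops, int)
    for d in range(n_demes):
        out[bounds[d]:bounds[d + 1]] = d
    return list(out)


def simulate_sample(cfg: SimulationConfig) -> SimResult:
    """Simulate an alignment + population map + coordinates + truth record."""
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes()
    n = sum(sizes)
    pops = [f"Pop{p + 1}" for p in range(cfg.n_pops)]
    pop_of_sample = np.repeat(np.arange(cfg.n_pops), sizes)

    demo = cfg.demography
    if isinstance(demo, SplitModel):
        deme_of_pop = _deme_of_pops(cfg.n_pops, demo.n_demes)
        deme_of = np.array([deme_of_pop[p] for p in pop_of_sample])
        branches = _structured_branches(deme_of, demo, rng)
        n_demes = demo.n_demes
    else:
        branches = _panmictic_branches(n, demo.epochs(), rng)
        deme_of_pop = [0] * cfg.n_pops
        n_demes = 1

    seqs, root = _sequences_from_genealogy(branches, n, cfg.L, rng, cfg.ts_tv)
    ids = [f"{pops[p]}_{i + 1:03d}" for p in range(cfg.n_pops) for i in range(sizes[p])]
    aln = Alignment(ids, codes_to_strings(seqs), offset=48)

    centers = cfg.centers or _default_centers(cfg, n_demes)
    lons = [c[0] + rng.normal(0, cfg.jitter_deg) for c in centers]
    lats = [c[1] + rng.normal(0, cfg.jitter_deg) for c in centers]
    coords = pd.DataFrame(
        {"population": pops, "longitude_deg": lons, "latitude_deg": lats}
    )
    pm = PopulationMap(
        pd.DataFrame(
            {
                "sample_id": ids,
                "population": [pops[p] for p in pop_of_sample],
                "deme_group": [f"Deme{deme_of_pop[p] + 1}" for p in pop_of_sample],
            }
        )
    )
    truth = {
        "seed": cfg.seed,
        "L": cfg.L,
        "ts_tv": cfg.ts_tv,
        "sizes": sizes,
        "demography": {"kind": type(demo).__name__, **asdict(demo)},
        "deme_of_pop": list(map(int, deme_of_pop)),
        "root": "".join(_CODE_TO_BASE[root]),
    }
    return SimResult(aln, pm, coords, truth)


def make_fixture_suite(out_dir: str | Path, seed: int = 2024) -> dict[str, Path]:
    """Write the standard synthetic datasets used throughout the test-suite.

    (a) ``paper_shaped``: six populations with realistic sample sizes under
        a shared sudden expansion (theta0=0.5, theta1=50, tau=5), Iranian
        city coordinates (jittered); (b) ``barrier_2deme``: six populations
        split into two demes (theta=2, divergence 2 mutational units) whose
        geography mirrors the split; (c) ``toy``: the four-sequence worked
        example.  Same seed => byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    iran_centers = [
        (51.67, 32.65),  # Esfahan-like
        (48.68, 31.31),  # Khuzestan-like
        (59.60, 36.30),  # Mashhad-like
        (52.53, 29.61),  # Shiraz-like
        (51.42, 35.69),  # Tehran-like
        (54.36, 31.89),  # Yazd-like
    ]
    cfg_a = SimulationConfig(
        n_pops=6,
        samples_per_pop=[23, 23, 21, 23, 29, 22],
        demography=SuddenExpansion(0.5, 50.0, 5.0),
        centers=iran_centers,
        jitter_deg=0.15,
        seed=seed,
    )
    written["paper_shaped"] = _write_dataset(simulate_sample(cfg_a), out / "paper_shaped")

    cfg_b = SimulationConfig(
        n_pops=6,
        samples_per_pop=20,
        demography=SplitModel(n_demes=2, theta=2.0, div_time=2.0, migration=0.0),
        seed=seed + 1,
    )
    written["barrier_2deme"] = _write_dataset(simulate_sample(cfg_b), out / "barrier_2deme")

    toy_dir = out / "toy"
    toy_dir.mkdir(exist_ok=True)
    toy = Alignment(["s1", "s2", "s3", "s4"], ["AAAA", "AAAT", "AATT", "AATT"], offset=1)
    write_fasta(toy, toy_dir / "toy.fasta")
    pd.DataFrame(
        {"sample_id": toy.ids, "population": ["P1", "P1", "P2", "P2"]}
    ).to_csv(toy_dir / "popmap.tsv", sep="\t", index=False)
    written["toy"] = toy_dir
    return written


def _write_dataset(sim: SimResult, d: Path) -> Path:
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.alignment, d / "sequences.fasta")
    sim.popmap.table.to_csv(d / "popmap.tsv", sep="\t", index=False)
    sim.coords.round(5).to_csv(d / "coords.tsv", sep="\t", index=False)
    with open(d / "truth.json", "w") as fh:
        json.dump(sim.truth, fh, indent=1, sort_keys=True)
    return d
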
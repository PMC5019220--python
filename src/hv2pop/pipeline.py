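"""End-to-end orchestration of the HV2 analysis.

``run_diversity`` produces the per-population diversity/neutrality table;
``run_mismatch`` the sudden-expansion fits and dating; ``run_structure``
the PhiST matrix, NJ tree, ordination, AMOVA tables, Mantel test and
Monmonier barrier report.  Every output records the seed and parameters
used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment, PopulationMap, read_alignment
from .amova import GroupingScheme, amova
from .distance import nj_tree, ordinate, pop_distance_matrix
from .diversity import diversity_table
from .mismatch import DEFAULT_MU_SITE_PER_YEAR, fit_population, observed_mismatch
from .spatial import (
    GeoLayout,
    barrier_significance,
    delaunay,
    geo_distance_matrix,
    mantel,
    monmonier_barriers,
)


@dataclass
class RunConfig:
    fasta: str
    popmap: str
    coords: str | None = None
    region: tuple[int, int] | None = None       # rCRS inclusive bounds
    mu_site_per_year: float = DEFAULT_MU_SITE_PER_YEAR
    n_perms: int = 10_000
    n_perms_amova: int = 1000
    n_boot: int = 1000
    schemes: list[str] = field(default_factory=list)  # popmap grouping columns
    n_barriers: int = 1
    seed: int = 0
    out_dir: str = "hv2pop_out"

    def __post_init__(self) -> None:
        if min(self.n_perms, self.n_perms_amova, self.n_boot) < 1:
            raise ValueError("permutation/bootstrap counts must be >= 1")


def _load(cfg: RunConfig) -> tuple[Alignment, PopulationMap]:
    aln, pm = read_alignment(cfg.fasta, cfg.popmap)
    if cfg.region is not None:
        aln = aln.extract_region(*cfg.region)
    return aln, pm


def _out(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_diversity(cfg: RunConfig, d_sims: int = 10_000) -> pd.DataFrame:
    """Per-population + pooled diversity table (n, s, H, h, pi, k, D, p)."""
    aln, pm = _load(cfg)
    table = diversity_table(aln, pm, d_sims=d_sims, seed=cfg.seed)
    out = _out(cfg)
    with open(out / "diversity.tsv", "w") as fh:
        fh.write(f"# seed={cfg.seed} region={cfg.region}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return table


def run_mismatch(cfg: RunConfig, include_pooled: bool = True) -> pd.DataFrame:
    """Sudden-expansion fit per population (and pooled), with dating."""
    aln, pm = _load(cfg)
    out = _out(cfg)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    targets = [(p, aln.subset(pm.samples_of(p))) for p in pm.populations]
    if include_pooled:
        targets.append(("pooled", aln))
    for name, sub in targets:
        fit, obs = fit_population(
            sub, n_boot=cfg.n_boot, mu_site_per_year=cfg.mu_site_per_year,
            seed=int(rng.integers(2**31 - 1)),
        )
        t = fit.time_years(cfg.mu_site_per_year, sub.length)
        t_ci = fit.time_ci_years(cfg.mu_site_per_year, sub.length)
        rows.append(
            {
                "population": name,
                "theta0": fit.theta0,
                "theta1": fit.theta1,
                "tau": fit.tau,
                "tau_ci_low": fit.tau_ci[0] if fit.tau_ci else None,
                "tau_ci_high": fit.tau_ci[1] if fit.tau_ci else None,
                "t_years": t,
                "t_ci_low": t_ci[0] if t_ci else None,
                "t_ci_high": t_ci[1] if t_ci else None,
                "ssd": fit.ssd,
                "p_ssd": fit.p_ssd,
                "rg": fit.rg,
                "p_rg": fit.p_rg,
                "degenerate": fit.degenerate,
            }
        )
        np.savetxt(
            out / f"mismatch_{name}.tsv",
            np.column_stack([np.arange(len(obs.counts)), obs.counts, obs.frequencies]),
            fmt=("%d", "%d", "%.6g"),
            header="differences\tcount\tfrequency",
            delimiter="\t",
            comments="",
        )
    table = pd.DataFrame(rows)
    with open(out / "expansion_fits.tsv", "w") as fh:
        fh.write(
            f"# seed={cfg.seed} n_boot={cfg.n_boot} mu={cfg.mu_site_per_year}\n"
        )
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return table


def run_structure(cfg: RunConfig) -> dict:
    """PhiST matrix, NJ tree, ordination, AMOVA, Mantel and barriers."""
    aln, pm = _load(cfg)
    out = _out(cfg)
    artifacts: dict = {}

    dm = pop_distance_matrix(aln, pm, n_perms=cfg.n_perms, seed=cfg.seed)
    artifacts["phist"] = dm
    dm.to_frame().to_csv(out / "phist.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(dm.p_values, index=dm.labels, columns=dm.labels).to_csv(
        out / "phist_pvalues.tsv", sep="\t", float_format="%.6g"
    )

    tree = nj_tree(dm)
    artifacts["tree"] = tree
    (out / "nj_tree.nwk").write_text(tree.newick + "\n")

    ords = ordinate(dm, dims=2, method="pcoa", seed=cfg.seed)
    artifacts["ordination"] = ords
    pd.DataFrame(
        ords.coordinates, index=ords.labels, columns=["dim1", "dim2"]
    ).to_csv(out / "ordination.tsv", sep="\t", float_format="%.6g")

    amova_results = []
    for col in cfg.schemes:
        scheme = GroupingScheme.from_popmap(pm, col)
        res = amova(aln, pm, scheme, n_perms=cfg.n_perms_amova, seed=cfg.seed)
        amova_results.append(res)
        res.to_frame().to_csv(out / f"amova_{col}.tsv", sep="\t", index=False,
                              float_format="%.6g")
    artifacts["amova"] = amova_results

    if cfg.coords:
        layout = GeoLayout.from_tsv(cfg.coords)
        layout = GeoLayout({p: layout.coords[p] for p in pm.populations})
        geo = geo_distance_matrix(layout)
        gen = dm.to_frame().loc[geo.index, geo.columns]
        mres = mantel(geo, gen, n_perms=cfg.n_perms_amova, seed=cfg.seed)
        artifacts["mantel"] = mres
        (out / "mantel.json").write_text(
            json.dumps(
                {"r": mres.r, "p_value": mres.p_value,
                 "n_permutations": mres.n_permutations, "tail": mres.tail,
                 "seed": cfg.seed},
                indent=1,
            )
        )
        tri = delaunay(layout)
        bres = monmonier_barriers(tri, dm.to_frame(), n_barriers=cfg.n_barriers)
        artifacts["barriers"] = bres
        rows = []
        for b in bres.barriers:
            sig = barrier_significance(
                aln, pm, tri, b, n_perms=cfg.n_perms_amova, seed=cfg.seed
            )
            for (a, bb), dval in zip(b.edges, b.distances):
                rows.append(
                    {"barrier": b.rank, "pop_a": a, "pop_b": bb,
                     "phist": dval, "ties": b.had_ties,
                     "phi_ct_across": sig.phi_ct if sig else None,
                     "p_ct_across": sig.p_ct if sig else None}
                )
        pd.DataFrame(rows).to_csv(out / "barriers.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    return artifacts
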
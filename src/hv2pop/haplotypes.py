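"""Haplotype collapsing and motif-based haplogroup assignment.

Haplotype identity is exact string match after upper-casing; an N is a
fifth state, so two sequences differing only by an N are distinct
haplotypes.  This is stricter than the allele-ambiguity options of some
desktop packages but is deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment, PopulationMap


@dataclass
class HaplotypeTable:
    """Distinct sequence variants with per-population counts.

    ``counts`` is indexed by haplotype id (``Hap_1`` ... in order of first
    appearance) with one column per population; column sums equal the
    population sample sizes.
    """

    sequences: dict[str, str]          # haplotype id -> representative sequence
    counts: pd.DataFrame               # haplotype x population
    members: dict[str, list[str]]      # haplotype id -> sample ids

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def n_singletons(self) -> int:
        """Haplotypes carried by exactly one individual overall."""
        return int((self.total_counts() == 1).sum())

    @property
    def n_shared(self) -> int:
        """Haplotypes carried by two or more individuals."""
        return int((self.total_counts() >= 2).sum())

    def frequencies(self, population: str) -> np.ndarray:
        col = self.counts[population].to_numpy(float)
        return col / col.sum()


def collapse_haplotypes(aln: Alignment, pm: PopulationMap) -> HaplotypeTable:
    """Group identical sequences into haplotypes, counted per population."""
    pop_of = dict(zip(pm.table["sample_id"], pm.table["population"]))
    pops = pm.populations
    seq_to_hap: dict[str, str] = {}
    sequences: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    counts: dict[str, dict[str, int]] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        hap = seq_to_hap.get(seq)
        if hap is None:
            hap = f"Hap_{len(seq_to_hap) + 1}"
            seq_to_hap[seq] = hap
            sequences[hap] = seq
            members[hap] = []
            counts[hap] = {p: 0 for p in pops}
        members[hap].append(sid)
        counts[hap][pop_of[sid]] += 1
    table = pd.DataFrame.from_dict(counts, orient="index")[pops]
    return HaplotypeTable(sequences, table, members)


@dataclass
class HaplogroupMotifTable:
    """Diagnostic control-region variants per haplogroup.

    Each entry lists (rCRS position, derived base) pairs; a haplogroup with
    no diagnostic variants acts as the reference/fallback clade (scored as
    fully matched when the sequence carries no other clade's motif better).
    """

    entries: dict[str, list[tuple[int, str]]]

    def __post_init__(self) -> None:
        if len(self.entries) != len(set(self.entries)):
            raise ValueError("duplicate haplogroup names")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplogroupMotifTable":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        entries: dict[str, list[tuple[int, str]]] = {}
        for name, sub in df.groupby("haplogroup", sort=False):
            variants = []
            for _, row in sub.iterrows():
                if pd.isna(row["position"]) or str(row["position"]).strip() == "":
                    continue
                variants.append((int(row["position"]), str(row["derived"]).upper()))
            entries[str(name)] = variants
        return cls(entries)


def assign_haplogroup(
    seq: str,
    motifs: HaplogroupMotifTable,
    ref: str,
    offset: int = 1,
    threshold: float = 0.8,
) -> tuple[str, float]:
    """Best-matching haplogroup for one aligned sequence.

    The score of a haplogroup is (matched diagnostic variants) / (scorable
    diagnostic variants); positions absent from the alignment window (e.g.
    insertions with no gapped column) are dropped from the denominator.
    Ties at the top score, or a top score below ``threshold``, yield
    ``("unresolved", score)``.  A motif position outside the alignment's
    rCRS window raises ``ValueError``.
    """
    seq = seq.upper()
    ref = ref.upper()
    if len(seq) != len(ref):
        raise ValueError("sequence and reference lengths differ")
    L = len(seq)
    scores: dict[str, float] = {}
    for name, variants in motifs.entries.items():
        if not variants:
            # reference clade: matched iff the sequence equals the reference
            # at every position another clade uses diagnostically
            diag = {p for v in motifs.entries.values() for p, _ in v}
            diag_in = [p for p in diag if 0 <= p - offset < L]
            if not diag_in:
                scores[name] = 1.0
            else:
                same = sum(seq[p - offset] == ref[p - offset] for p in diag_in)
                scores[name] = same / len(diag_in)
            continue
        matched = 0
        scorable = 0
        for pos, derived in variants:
            col = pos - offset
            if col < 0 or col >= L:
                raise ValueError(
                    f"motif position {pos} outside alignment window "
                    f"{offset}-{offset + L - 1}"
                )
            if derived == "-" or ref[col] == "-":
                # indel variant without an explicit gapped column: skip
                if ref[col] != "-" and derived != "-":
                    continue
            scorable += 1
            if seq[col] == derived:
                matched += 1
        scores[name] = matched / scorable if scorable else 0.0
    best = max(scores.values())
    winners = [n for n, s in scores.items() if s == best]
    if len(winners) != 1 or best < threshold:
        return "unresolved", best
    return winners[0], best


def assign_all(
    aln: Alignment,
    motifs: HaplogroupMotifTable,
    ref: str,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Haplogroup call per sample; columns sample_id, haplogroup, score."""
    rows = []
    for sid, seq in zip(aln.ids, aln.seqs):
        call, score = assign_haplogroup(seq, motifs, ref, aln.offset, threshold)
        rows.append((sid, call, score))
    return pd.DataFrame(rows, columns=["sample_id", "haplogroup", "score"])
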
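"""Aligned mtDNA sequence containers and metadata I/O.

The unit of analysis is a multiple alignment of equal-length control-region
sequences (here typically the HV2 segment, rCRS positions ~48-342) together
with a sample-to-population map and, optionally, per-population geographic
coordinates.  External coordinates are 1-based inclusive rCRS positions;
internal site indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = set("ACGTN-")

#: numeric codes for bases; N and gap are treated as missing in comparisons
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


class AlignmentError(ValueError):
    """Malformed alignment input (unequal lengths, bad alphabet, ...)."""


class MetadataError(ValueError):
    """Sample/population metadata inconsistent with the alignment."""


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with sample identifiers.

    Parameters
    ----------
    ids:
        Unique sample identifiers, in input order.
    seqs:
        Upper-case sequences over ``{A,C,G,T,N,-}``, all of equal length.
    offset:
        rCRS position (1-based) of the first alignment column.
    """

    ids: list[str]
    seqs: list[str]
    offset: int = 1
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("alignment contains no sequences")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sample identifiers")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"length mismatch for record {sid!r}: {len(s)} != {L}"
                )
            bad = set(s) - VALID_ALPHABET
            if bad:
                raise AlignmentError(f"invalid characters {bad} in record {sid!r}")
        if L == 0:
            raise AlignmentError("zero-length sequences")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix of base codes (A,C,G,T = 0..3; N = 4; - = 5)."""
        if self._matrix is None:
            lut = np.full(256, 255, dtype=np.uint8)
            for b, c in _BASE_CODE.items():
                lut[ord(b)] = c
            flat = np.frombuffer(
                "".join(self.seqs).encode("ascii"), dtype=np.uint8
            )
            self._matrix = lut[flat].reshape(self.n, self.length)
        return self._matrix

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        """Alignment restricted to ``sample_ids`` (kept in the given order)."""
        index = {sid: i for i, sid in enumerate(self.ids)}
        try:
            rows = [index[sid] for sid in sample_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise MetadataError(f"unknown sample id {exc}") from exc
        return Alignment(
            [self.ids[i] for i in rows], [self.seqs[i] for i in rows], self.offset
        )

    def extract_region(self, start_rcrs: int, end_rcrs: int) -> "Alignment":
        """Columns for rCRS positions ``start_rcrs``..``end_rcrs`` (inclusive).

        The returned alignment has ``length == end - start + 1`` and its
        ``offset`` set to ``start_rcrs``.
        """
        lo = start_rcrs - self.offset
        hi = end_rcrs - self.offset + 1
        if start_rcrs > end_rcrs or lo < 0 or hi > self.length:
            raise AlignmentError(
                f"requested window {start_rcrs}-{end_rcrs} outside alignment "
                f"window {self.offset}-{self.offset + self.length - 1}"
            )
        return Alignment(list(self.ids), [s[lo:hi] for s in self.seqs], start_rcrs)


@dataclass
class PopulationMap:
    """Sample-to-population assignments plus optional grouping columns.

    ``table`` has one row per sample with columns ``sample_id``,
    ``population`` and any number of extra grouping-scheme columns
    (e.g. ``geo1_group``, ``linguistic_group``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "population"}
        if not required.issubset(self.table.columns):
            raise MetadataError(f"population map needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise MetadataError(f"duplicated sample ids in map: {list(dup)[:5]}")

    @property
    def populations(self) -> list[str]:
        """Population names in order of first appearance."""
        return list(dict.fromkeys(self.table["population"]))

    def sizes(self) -> dict[str, int]:
        return self.table["population"].value_counts().to_dict()

    def samples_of(self, population: str) -> list[str]:
        sel = self.table["population"] == population
        if not sel.any():
            raise MetadataError(f"unknown population {population!r}")
        return list(self.table.loc[sel, "sample_id"])

    def group_of(self, scheme: str) -> dict[str, str]:
        """population -> group label for a named grouping column."""
        if scheme not in self.table.columns:
            raise MetadataError(f"no grouping column {scheme!r} in population map")
        out: dict[str, str] = {}
        for pop, grp in zip(self.table["population"], self.table[scheme]):
            if pop in out and out[pop] != grp:
                raise MetadataError(f"population {pop!r} has conflicting {scheme} labels")
            out[pop] = str(grp)
        return out


def read_alignment(fasta_path: str | Path, popmap_path: str | Path) -> tuple[Alignment, PopulationMap]:
    """Read a FASTA alignment and its sample-to-population TSV.

    Every FASTA id must appear in the population map; sequence lengths must
    be identical across records.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    aln = Alignment([r.id for r in records], [str(r.seq) for r in records])
    pm_table = pd.read_csv(popmap_path, sep="\t", dtype=str)
    pm = PopulationMap(pm_table)
    mapped = set(pm.table["sample_id"])
    missing = [sid for sid in aln.ids if sid not in mapped]
    if missing:
        raise MetadataError(
            f"{len(missing)} FASTA records missing from population map, "
            f"e.g. {missing[:3]}"
        )
    # restrict the map to samples actually present, in alignment order
    order = pm.table.set_index("sample_id").loc[aln.ids].reset_index()
    return aln, PopulationMap(order)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(recs, str(path), "fasta-2line")


def polymorphic_sites(aln: Alignment) -> list[int]:
    """0-based column indices with >= 2 distinct A/C/G/T states.

    Gaps and N are ignored when deciding whether a site is polymorphic.
    """
    m = aln.matrix
    valid = m < 4
    out = []
    for j in range(aln.length):
        states = np.unique(m[valid[:, j], j])
        if states.size >= 2:
            out.append(j)
    return out
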
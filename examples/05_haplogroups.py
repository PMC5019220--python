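"""Motif-based haplogroup assignment on a toy alignment.

Uses the packaged synthetic motif table (invented diagnostic variants in
the HV2 window; not a published phylogeny) to classify sequences.
"""

from hv2pop import HaplogroupMotifTable, assign_all, Alignment, packaged_data

motifs = HaplogroupMotifTable.from_tsv(packaged_data("haplogroup_motifs_synthetic.tsv"))
ref = "A" * 295

def variant(positions, offset=48):
    s = list(ref)
    for p, b in positions:
        s[p - offset] = b
    return "".join(s)

aln = Alignment(
    ["ref_like", "u_carrier", "partial"],
    [ref, variant([(73, "G"), (150, "T"), (263, "G")]), variant([(73, "G")])],
    offset=48,
)
calls = assign_all(aln, motifs, ref)
print(calls.to_string(index=False))
print(
    "\nA call requires >= 80% of a clade's diagnostic variants; sequences "
    "matching the reference at most diagnostic sites fall back to the "
    "reference clade, and ambiguous matches are 'unresolved'."
)
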
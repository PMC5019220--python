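# SYNTHETIC diagnostic-motif fixture for testing haplogroup assignment.
# Positions are rCRS coordinates inside the HV2 window (48-342); the
# haplogroup names follow mtDNA nomenclature but the motifs are invented
# for unit tests and are NOT a reproduction of any published phylogeny.
# An empty position marks the reference (fallback) clade.
haplogroup	position	derived
H
U	73	G
U	150	T
U	263	G
M	73	G
M	195	C
M	247	G
B	73	G
B	210	G
B	317	C
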
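# sailorte catalytic-triad motif tables, version 1
# pattern syntax: one residue per position; [XY] = alternative residues at one position
# anchor_index: 0-based position of the catalytic residue inside the pattern
# anchor_residues: residues accepted at the anchor (the catalytic D/D/E-or-D)
motif_set	slot	pattern	anchor_index	anchor_residues
sailor	d1	[IV]VYLDET	4	D
sailor	d2	VIIMDNA	4	D
sailor	e	HCELNPIEL	7	E
tc1	d1	VLWSDES	4	D
tc1	d2	IFQQDN[AD]	4	D
tc1	e	SPDLNPIEN	7	E
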
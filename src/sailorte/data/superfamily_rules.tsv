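# sailorte superfamily assignment rules, version 1
# de_spacer = residues strictly between the second D and the terminal E/D
name	motif_set	spacer_min	spacer_max
Sailor	sailor	78	111
Tc1	tc1	34	34
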
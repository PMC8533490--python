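# sailorte

Discovery, annotation and horizontal-transfer analysis of
*IS630*-*Tc1*-*mariner* (ITm) DNA transposons of the *Sailor* type —
cut-and-paste elements characterized by a DD82E catalytic domain
(DD78E–DD111E across taxa), terminal inverted repeats (TIRs) that typically
begin with a GT dinucleotide, and a 4-bp TATA target-site duplication (TSD)
instead of the classical *Tc1/mariner* TA.

The package is aimed at researchers characterizing new ITm superfamilies or
screening genomes for them.  It implements the full desk-side pipeline:

1. **Mining** (`sailorte.mining`) — candidate transposase loci from a
   six-frame stop-to-stop ORF scan (> 300 aa) with catalytic-motif
   screening, or from external TBLASTN hits in 12-column tabular format
   (E ≤ 1e-100); loci are extracted with 2-kb flanks.
2. **Element annotation** (`sailorte.element_annotation`) — TIR pairs by
   local alignment of the locus ends against each other's reverse
   complement, TSD calling from the genomic flanks, element delimitation,
   and classification as *intact* (both TIRs, transposase > 300 aa with a
   located triad), *full-length* (both TIRs) or *fragment*; consensus or
   longest-copy representative building.
3. **DDxE classification** (`sailorte.dde_signature`) — the catalytic triad
   is located by anchored consensus motifs ([I/V]VYLDET, VIIMDNA, HCELNPIEL
   for Sailor; VLWSDES, IFQQDNA/D, SPDLNPIEN for Tc1/mariner).  The
   signature is DD*x*E with *x* the number of residues strictly between the
   second D and the E, and superfamily assignment uses a configurable
   spacer-range rule table (Sailor: 78–111).
4. **Copy counting** (`sailorte.copy_number`) — k-mer-seeded local-alignment
   search for copies of the consensus/representative, counted under the
   classic screen: query coverage > 40% and identity > 80% (strict).
5. **Horizontal-transfer detection** (`sailorte.ht_detection`) — pairwise
   Tamura–Nei (TN93) distances with pairwise deletion for the transposase
   and the L3/L4 ribosomal-protein host genes; a species pair supports HT
   when

   ```
   d_TE < d_L3   and   d_TE < d_L4
   ```

   with organelle L3/L4 used for prokaryote-involving pairs and cytoplasmic
   L3/L4 between eukaryotes.
6. **Synthetic data** (`sailorte.synthetic_data`) — genomes with planted,
   optionally degraded copies and exact truth tables (GFF3 + TSV), and
   L3/L4/TE marker sets evolved along a species tree under an HKY process
   with optional horizontal-transfer events — so every stage is testable
   without downloads.

## Worked example

Simulate a 60-kb genome with three planted Sailor elements, annotate it,
classify the transposases and count copies:

```bash
sailor simulate genome --out-prefix fix --genome-length 60000 --n-copies 3 --seed 5
# wrote fix.fasta with 3 planted copies (65013 bp)
sailor annotate --genome fix.fasta --out-prefix anno
# annotated 3 elements
sailor classify --proteins anno.tpase.fasta --out sig.tsv
sailor copynum --genome fix.fasta --query fix.element.fasta --out-prefix cn
# chr_sim  3 copies
```

`sig.tsv` then contains, per transposase, the triad positions and signature:

```
protein        d1   d2   e    dd_spacer  signature  superfamily  mismatches
element_0000   169  260  343  90         DD82E      Sailor       0
```

and `anno.gff3` records each element with its TIR and TSD children:

```
chr_sim  sailorte  target_site_duplication          27555  27558  .  +  .  Parent=element_0000
chr_sim  sailorte  terminal_inverted_repeat         27559  27588  .  -  .  Parent=element_0000
chr_sim  sailorte  terminal_inverted_repeat_element 27559  29221  .  -  .  ID=element_0000;status=intact;tir_length=30;tsd=TATA
```

The d2→e spacer of 82 intervening residues (e = 343, d2 = 260,
343 − 260 − 1 = 82) is what the DD82E signature denotes; the `status=intact`
flag means both TIRs are present and the transposase exceeds 300 aa with a
located triad.  At zero degradation the annotation GFF3 reproduces the
simulator's truth GFF3 record for record.

The marker simulator and HT scan work the same way (`sailor simulate
markers`, `sailor htscan`); see `tests/test_cli.py` for a complete chain.

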
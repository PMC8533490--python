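# Methods

This note documents the models, conventions and numerical choices behind
`sailorte`, and what the synthetic fixtures do and do not establish about
real data.

## Element model and conventions

A Sailor-type element is modelled as

```
5'TIR — 5'UTR — transposase ORF — 3'UTR — 3'TIR
```

with the 3' TIR the reverse complement of the 5' TIR, and the element
flanked (but not containing) a duplicated target site.  All internal
coordinates are 0-based half-open on the forward strand; GFF3 output is
1-based inclusive.  The TSD is treated as host sequence: element boundaries
exclude it and GFF3 records it as separate child features.

**Spacer convention.**  The DDxE signature's *x* counts residues *strictly
between* the second aspartate and the glutamate (exclusive on both ends),
and the same convention applies to the D1–D2 spacer.  DD82E therefore means
exactly 82 intervening residues.  This convention is declared once and used
by the generator, the classifier and the rule table alike; it is the only
reading under which the canonical signatures are self-consistent.

**Catalytic motifs.**  The triad is located by anchored positional motifs
([I/V]VYLDET, VIIMDNA, HCELNPIEL for the Sailor set; VLWSDES, IFQQDNA/D,
SPDLNPIEN for Tc1/mariner), shipped as a plain-text resource.  The anchor
of the E motif is the glutamate of the shared ...LNPIE... context (index 7
in both tables) — the only choice consistent with aligning the two motif
families.  Motif matching tolerates `max_mismatch` substitutions per motif
(default 1) but the three anchor residues must be exact; candidates are
ranked by total mismatches, then leftmost position.  This alignment-free
localization is deliberately simple and oracle-checkable; profile-based
localization against seed alignments is out of scope.

**Thresholds.**  "> 300 aa" is implemented strictly: a 300-aa transposase is
rejected by the intact filter, 301 aa passes.  The copy screen is likewise
strict: coverage > 0.40 of the query length and identity > 0.80, with
identity computed over aligned columns excluding gap columns (tabular-BLAST
semantics, so external hits are interchangeable).  The Sailor superfamily
rule accepts D2–E spacers in [78, 111]; whether that observed range is
exhaustive is unknown, so the bounds are configurable in the rule table.

## TIR and TSD detection

The 5' window of a candidate locus is locally aligned against the reverse
complement of its 3' window (match +1, mismatch −1, gap −2).  Because the
optimal local alignment may carry low-identity gapped extensions — and
because palindromic TSDs (TA, TATA) are themselves perfect inverted repeats
that the alignment necessarily absorbs — two refinements are applied:

1. **Core extraction.**  The reported TIR is the highest-scoring contiguous
   sub-segment of the alignment whose gap-excluded identity is ≥ 0.8 and
   whose span lies within [18, 1500] bp (defaults; 18 bp is the shortest
   TIR reported for intact elements of this type).  Ties prefer the longer
   repeat, then the smaller start offset.
2. **Boundary snapping.**  The raw outer edges always contain the true
   element (overshoot is one-sided), so boundary pairs up to 80 bp inward
   are scored by (TSD length, element span, exact terminal-IR run), and a
   pair qualifies only with an exact flanking duplication and at least 8
   exact terminal IR bases.  If nothing qualifies — e.g. degraded flanks —
   the raw boundaries stand and the element is still reported.

The TSD caller returns the longest k in 2..10 for which the k bp
immediately upstream and downstream of the element are identical; exact
identity is required, and longest-k preference makes TATA win over its
internal TA.

"Full-length" is defined as *both TIRs present* — the literature does not
define it independently of "intact", and this is the reading under which
the two categories nest (intact ⇒ full-length).

## Consensus building

With ≥ 3 copies, copies are multiple-aligned (mafft when lengths differ;
equal-length copies are used as columns directly) and a strict majority
call is made per column; ties go to the first alphabetical base and
gap-majority columns are dropped.  With fewer copies the longest copy is
the representative.  Consensus building is idempotent on identical copies.

## Distances and the HT test

Genetic distances are Tamura–Nei (TN93) estimates computed from the
transition proportions within purines and within pyrimidines, the
transversion proportion, and the pair's empirical base frequencies, after
pairwise deletion of columns with a gap or ambiguity in either sequence.
At least 100 usable sites are required (configurable); pairs whose log
arguments leave the TN93 domain are flagged as saturated, capped at a
configurable value, and excluded from HT calling rather than forced into
calls.  Composite-likelihood estimation is approximated per-pair by
default; an optional pooled mode estimates base frequencies jointly over
all pairs and re-solves each pair under them.  The implementation is
cross-checked in the test suite against an independently coded closed form
and against `ape::dist.dna(model = "TN93")`.

Unaligned inputs are globally aligned per pair (match +1, mismatch −1, gap
open −5 including the first gap residue, extend −1; ties prefer the
diagonal).  Distances are computed on nucleotide coding sequences; protein
identity is used only to rank candidate host-gene families (by mean
pairwise identity, then mean length — conserved, long, single-copy genes
make the best vertical yardsticks).

A species pair supports horizontal transfer when the transposase distance
is strictly lower than the distances of *both* L3 and L4; equality is "no
HT".  Host-gene sets follow the pair's domains: organelle L3/L4 for
prokaryote-involving pairs (prokaryotic ribosomal proteins are homologous
to the eukaryote organelle ones), cytoplasmic L3/L4 between eukaryotes.
Pairs with a missing or saturated distance are reported untestable, never
false.  Supporting pairs are aggregated per lineage pair.  Dating HT
events, counting independent events and phylogenetic-incongruence tests
are out of scope.

## Synthetic data: what it emulates and what it does not

**Genome fixtures.**  Backgrounds are i.i.d. uniform A/C/G/T (composition
bias is not exercised by the method).  Planted copies are flanked by the
duplicated TSD, non-overlapping, ≥ 2.5 kb from genome ends so 2-kb flank
extraction never clips.  Degradation applies truncation (one end, uniform
fraction) then substitutions; identity and coverage are recorded exactly
in the truth table.  Reverse translation of transposases uses a fixed
most-frequent-codon table for reproducibility.  Four background bases on
each side of every insertion are set to fixed non-complementary letters
("CCCC" upstream, "AAAA" downstream): with a palindromic TSD, an element
plus its TSD copies is itself a perfect inverted repeat flanked by random
sequence, and boundary recovery would otherwise be ambiguous at the ±4 bp
level by construction, not by algorithmic error.  This guard is what makes
the zero-degradation round-trip (truth GFF3 = annotation GFF3, record for
record) exact; real insertions offer no such guarantee, so on real data
boundary calls should be expected to wobble by a few bases at palindromic
junctions.

**Marker sets.**  Host genes evolve along the species tree and the
transposase along a copy of it modified by the HT events, both under an
HKY process (default κ = 2.0, uniform base frequencies, branch lengths in
expected substitutions/site; matrices via `expm`, sampling vectorized per
branch).  Substitutions only — no indels, no selection, no rate
heterogeneity across sites, no within-genome amplification.  Trees must be
ultrametric when HT events are present; an event (donor, recipient, t)
regrafts the recipient's transposon lineage onto the donor lineage at time
t before present, so the pair's TE divergence reflects the transfer time.
The truth table flags every pair whose TE-tree patristic distance is
smaller than its species-tree distance.

**Rate scales.**  `host_rate_scale` defaults to 1.0 and `te_rate_scale` to
2.0: transposons evolve essentially neutrally while L3/L4 are among the
most conserved proteins known, and the distance-based HT criterion is
informative precisely in that regime.  With equal rates the three
distances of a vertical pair estimate the same quantity and the strict
"lower than both" rule would fire on sampling noise alone (~1/3 of pairs);
tests under equal rates therefore check expectations, not calls.

**Default study conditions** used by the test suite: element with 30-bp
GT-initial TIRs, 200-bp UTRs, 400-aa DD82E transposase (D1–D2 spacer 90 aa,
chosen as a typical ITm value; no default is dictated by the signature
itself), TATA TSD; six-taxon ultrametric tree of depth 0.25
substitutions/site with sister species diverging at 0.08; transfers planted
at 10% of the pair's divergence; marker length 10,000 bp; 50 replicate
seeds for the recovery/false-positive rates; 200-kb genomes with 10 copies
for the end-to-end check.  These sizes keep the full suite under a minute
on one core while leaving comfortable statistical margins.

**How degraded copies are drawn.**  The identity/coverage distribution of
real degraded copies is unknown; the defaults (uniform truncation fraction,
per-site substitution rate) are arbitrary and flagged as such.  Tests
therefore only assert counting behaviour for copies planted strictly inside
or strictly outside the screen thresholds, never for boundary copies.

## Known limitations

* The internal mining path is a stand-in for TBLASTN at desk scale; E-values
  are not computed for internal hits.  The tabular reader supports real
  external runs.
* Stop-to-stop ORF scanning replaces spliced gene prediction; intron-bearing
  transposase genes would be missed or fragmented.
* Single-query copy counting only — no genome-wide repeat discovery.
* The two conserved internal TIR motifs reported for this element family
  are not separately detected; the TIR sequence itself is reported.
* Per-pair TN93 is not identical to MEGA's maximum-composite-likelihood
  distances; the pooled mode narrows but does not close that gap.  Output
  metadata records which mode produced a table.
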
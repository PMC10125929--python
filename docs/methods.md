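# Methods

This note documents the models, rules and numerical choices behind
`lamterm`, and what the synthetic-data tests do and do not demonstrate.

## Residue categories and the composition statistic

The composition statistic counts the last *n* residues (default *n* = 10) of
a protein in five fixed, pairwise-disjoint categories: aliphatic {I, L, V},
aromatic {F, W, Y}, positively charged {K, R, H}, negatively charged {D, E}
and tiny {G, A, S}. M, C, N, Q, P and T are deliberately uncategorized, so
the five percentages need not sum to 100. Percentages are
`round(100·count/n)`, rounding half away from zero; with *n* = 10 every
value is an exact multiple of 10. Termini shorter than *n* are profiled over
their actual length with a warning, never padded — padding would dilute the
percentages with phantom residues.

The packaged survey tables are transcribed verbatim, including
internally inconsistent rows; `discrepancy_report` recomputes every printed
row and lists disagreements with both values side by side rather than
silently correcting them. Two rows of the shipped tables are flagged: the
Brachionus rotundiformis row (printed percentages imply a 9-residue
denominator against a 10-residue peptide) and the Amphisamytha carldarei
row (the printed peptide GSRSWFWWNK computes to pos 20/tiny 30, not the
printed 30/20; the printed values would fit a terminus ending
...SRRSWFWWNK, matching its sister taxa, suggesting a dropped residue in
the source).

## CaaX tiers

A terminus is examined only at its last four residues. Without a cysteine at
−4 there is no motif (`no_caax`). With one, three tiers apply:

* `caax_like_nonprenylatable` — X ∈ {D, E}. A negatively charged X cannot
  be accommodated in the farnesyltransferase specificity pocket, so despite
  the correctly placed cysteine the motif is not an isoprenylation
  substrate (the rotifer CSEE case). Only D and E disqualify; a positively
  charged X is left `caax_like_ambiguous` because the biochemical evidence
  concerns the negative charge.
* `canonical_caax` — X ∈ {M, S, Q, A, C} and both a-positions in the
  permissive set {A, C, F, G, I, L, M, S, T, V}. Strictly aliphatic
  a-positions cannot be the operative rule: accepted CaaX lamins end
  CSLM/CSVM (serine at a1) and CIIS (X = S). A strict mode restricting
  a-positions to {I, L, V} is available.
* `caax_like_ambiguous` — cysteine at −4, neither of the above.

The exact canonical-X set in use by practitioners is not settled; {M, S, Q,
A, C} covers the motifs accepted as prenylatable in the lamin literature
while keeping charged and bulky-aromatic X out. Changing it is a one-line
configuration of the module constants.

## Terminus classification

Two alternative-terminus types are distinguished. Defaults: a canonical
CaaX wins outright; otherwise `aromatic_alternative` requires aromatic
≥ 20 % and negative ≤ 10 % (the W/F-rich type of monogononts, cephalopods
and sedentary annelids — their hallmark is aromatic enrichment *with*
absence of negative charge); `aliphatic_alternative` requires aliphatic
≥ 40 % and aromatic = 0 % (the bdelloid type); everything else is `other`.
The cutoffs sit halfway between the observed clusters (cephalopods: 30–40 %
aromatic, 0 % negative; bdelloids: 40–50 % aliphatic, 0 % aromatic) and are
configurable via `ClassifierThresholds`.

The monopartite NLS scan is a declared heuristic, not ground truth: matches
of the SV40-type core K(K|R)X(K|R) are accepted when the core plus one
flanking residue on each side contains at least four K/R. Published NLS
annotations in the fixture tables are fixture data, not recomputed claims.

## Consensus derivation

C-termini are compared right-anchored; a shift-only aligner assigns each
peptide an integer offset in [−3, 3] maximizing the summed modal-residue
count over columns. Gaps are never inserted: the inputs are ≤ 12-residue
termini and letter-level consensus reproduction does not need them, while
the shift-only objective stays exactly optimizable (exhaustive enumeration
up to five sequences, coordinate-wise refinement from the right-anchored
start above that; ties toward offset 0). Identity consensus uses the usual
case encoding — uppercase at ≥ 90 % identity, lowercase at ≥ 50 %, `.`
below — with boundary frequencies taking the stronger case and modal ties
broken alphabetically (and recorded). Column counts exclude uncovered
positions from numerator and denominator. Only identity is scored; external
alignment tools that group physicochemically similar residues may uppercase
columns this implementation renders in lowercase, which is why letter-level
(case-insensitive) agreement is the contract asserted in tests.

## ORFs, cryptic CaaX segments, junction reconstruction

ORF annotation takes the longest ATG-initiated reading frame (standard
genetic code; ties 5′-most; default minimum 30 codons; stop-terminated ORFs
preferred, a stopless run to the transcript end is accepted and flagged).

The 3′-UTR scan partitions each of the three UTR frames into stop-delimited
segments and reports every segment of ≥ 4 codons whose translation ends
with a cysteine-at-−4 tetrapeptide immediately before the stop. Reporting
maximal (stop-to-stop) segments makes the hit set canonical; a brute-force
all-substring translation oracle in the test suite checks exact agreement.

Junction reconstruction mirrors the alignment-based procedure used for
transcripts lacking genomic sequence: donors are enumerated within 200 nt
upstream of the CDS stop (any codon phase — transcripts carry no intron
sequence, so no GT is required), acceptors in the UTR at the phase that
keeps the cryptic stop in frame. Each stop-free chimera ending in a
cysteine tetrapeptide is scored by right-anchored, ungapped BLOSUM62
similarity of its last 30 residues to the homologous CaaX terminus; ties
rank the smaller deletion first. No score cutoff is imposed for declaring a
junction "real" — the contract stops at ranked proposals, and read-level
verification is out of scope.

## Spliced alignment

Transcript-to-genome alignment is anchored on exact 15-mers unique in the
genome, merged along diagonals (holes up to ~2 substitutions), and chained
by weighted-LIS dynamic programming (score = anchored bases − 2 per intron
gap). Each diagonal change is an intron; the exact boundary is chosen
within a ±6 nt slide by minimizing local mismatches and, among equals,
preferring GT..AG intron ends (kept but flagged when absent — GC donors and
other dialects exist, and boundary rules should be soft). Mismatch
tolerance defaults to 1 % of the transcript length (at least 1); below 50 %
anchored coverage the aligner refuses to call a model. Exons shorter than
the anchor length k cannot be seeded and would be missed; the generator
keeps exons ≥ 15 nt (the 3′-most exon of a split terminal codon carries the
stop codon and 3′-UTR, so it is never that short in practice).

Intron phase is the intron's nucleotide offset within its codon
(CDS-relative position mod 3); a split terminal codon appears as phase 1 or
2 at the final codon index, and GFF3 output keeps the split as two CDS
segments with correct phase fields. Archetypal intron positions are a user
input (they derive from prior literature); matching is greedy one-to-one on
equal phase and |Δcodon| ≤ tol.

## Synthetic data

The generator emulates the surveyed gene configurations with full truth
bookkeeping: a CDS split by GT..AG introns at configurable positions
(default intron lengths uniform on 60–300 nt, exons ≥ 24 nt), optional
cassette exons (codon-multiple lengths of 5–12 codons, placed between the
penultimate constitutive exon and the terminal exon block so all variants
share the terminal-exon-encoded suffix), an optional split terminal codon,
and the terebellid dual-terminus layout (alternative-terminus exon flanked
by introns upstream of the CaaX exon; the alternative transcript retains
the CaaX information in its 3′-UTR). Protein length defaults to
30 codons/exon (min 60); 5′-UTRs are 30 nt and ATG-free so the annotated
ORF is unambiguous; 3′-UTR tails are 90 nt.

Terminus samplers draw compositions safely inside the class definitions
(aromatic: 3–4 F/W plus 2–3 K/R, no D/E, terminal W; aliphatic: 5–6 I/L/V,
no aromatics; CaaX: C + two of {I,L,V} + one of {M,S,Q}). Protein bodies
are sampled without C or R — C would create chance CaaX-like calls, R
chance NLS cores — and resampled until the planted SV40-type NLS is the
only NLS hit. The terebellid builder additionally resamples until the
3′-UTR scan finds exactly the planted segment, so truth coordinates are
guarantees by construction, not probabilistic claims. Codon usage is
uniform over synonymous codons; intron interiors are i.i.d. nucleotides
with the configured GC.

What passing synthetic tests shows: the algorithms invert the generative
process exactly at realistic exon/intron scales. What they do not show:
robustness to sequencing error beyond ~1 % substitutions, repeats or
paralogy (unique-k-mer seeding would fail on recent duplicates),
non-uniform codon usage, or splice-site dialect beyond GT..AG preference.
The published species-census claims and anything requiring genome or
transcriptome downloads are deliberately not reproduced.

## Problem sizes used in the shipped checks

Gene-structure round trips run 200 seeded replicates with 2–14 exons;
cryptic-CaaX/junction recovery runs 100 seeded terebellid replicates with
6 exons; oracle comparisons use 50 random UTRs ≤ 600 nt and exhaustive
shift search for up to 5 peptides. The acceptance script builds one
14-exon, two-cassette gene and enumerates its four splice variants on the
model deduced by spliced alignment.

## Known limitations

* Reverse-strand input is handled by reverse-complementing at load (with a
  recorded flag); models are always forward-strand internally.
* The aligner targets desk-scale contigs (≲ 1 Mb), single-gene loci, and
  one transcript per call; tandem duplicates must be split by the user.
* The NLS heuristic is intentionally simple; it is not a replacement for
  dedicated NLS predictors.
* `anchor_align` beyond five sequences is a local search; for the short,
  highly similar termini it is used on, the right-anchored start is already
  at or next to the optimum.
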
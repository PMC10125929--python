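# lamterm

Analysis toolkit for lamin C-termini and the genes that encode them.

Lamins — the intermediate-filament proteins of the nuclear lamina — normally
end in a **CaaX motif** (cysteine, two aliphatic residues, variable X) that
directs isoprenylation of the cysteine and thereby membrane targeting.
Several lophotrochozoan groups (bdelloid and monogonont rotifers,
cephalopods, and a subset of sedentary annelids) instead carry *alternative*
C-termini: either aromatic-rich (tryptophan/phenylalanine-heavy, free of
negatively charged residues) or aliphatic-rich. In terebelliform annelids
the switch is caught in the act: a single gene produces, by alternative
splicing of a cassette exon, both a CaaX-variant mRNA and an
alternative-terminus mRNA that still carries the CaaX-encoding exon —
untranslated — in its 3′-UTR.

`lamterm` packages the sequence-analysis machinery behind such surveys, for
comparative genomicists and cell biologists working at desk scale:

* **CaaX calling** with prenylation-competence tiers: `canonical_caax`
  (C at −4, permissive a-positions, X ∈ {M,S,Q,A,C}),
  `caax_like_nonprenylatable` (X ∈ {D,E} — farnesyltransferase cannot
  accommodate a negatively charged X), `caax_like_ambiguous`, `no_caax`.
* **Composition profiling** of the last *n* (default 10) residues over five
  fixed categories — aliphatic {I,L,V}, aromatic {F,W,Y}, positive {K,R,H},
  negative {D,E}, tiny {G,A,S} — as integer percentages,
  `round(100·count/n)`.
* **Identity-threshold consensus** of right-anchored C-terminal peptides
  with the usual case encoding (uppercase ≥ 90 % identity, lowercase ≥ 50 %),
  via an exactly optimizable shift-only aligner.
* **Cryptic CaaX detection**: stop-delimited CaaX-encoding segments in
  3′-UTRs, plus splice-junction reconstruction ranked by BLOSUM62 similarity
  of the chimeric C-terminus to a homologous CaaX terminus.
* **Gene-structure deduction**: k-mer–anchored spliced alignment of a
  transcript to a genomic contig (GT..AG preferred at boundaries), intron
  phases in codon coordinates (including split terminal codons),
  archetypal-intron position comparison, and enumeration of all 2^k
  cassette-exon splice variants.
* **Synthetic data**: lamin-like genes with full ground truth, including the
  terebellid dual-terminus configuration, so every stage is testable without
  downloads.

The published composition tables for rotifer, cephalopod and annelid lamin
C-termini ship as TSV fixtures (`lamterm fixtures --table table3`), and a
`discrepancy_report` recomputes every printed percentage.

## Worked example

Classify three synthetic proteins with known terminus types:

```sh
python - <<'EOF'
from lamterm import seqio
from lamterm.synthetic_data import make_terminus_panel
seqio.write_fasta(make_terminus_panel(n_caax=1, n_aromatic=1, n_aliphatic=1, seed=12), "demo.fa")
EOF
lamterm classify --fasta demo.fa
```

```text
id	cterm	aliph	arom	pos	neg	tiny	caax_status	terminus_class	nls_hits
panel_caax_0	TRLDRRCVLQ	30	0	30	10	0	canonical_caax	caax	
panel_aromatic_alternative_0	FQRQFRFFKW	0	50	30	0	0	no_caax	aromatic_alternative	
panel_aliphatic_alternative_0	IVVVSEATLA	50	0	0	10	30	no_caax	aliphatic_alternative	
```

Each row gives the 10-residue terminus, its five category percentages
(`TRLDRRCVLQ`: 3 aliphatic → 30 %, ...), the tiered CaaX call
(`TRLDRRCVLQ` ends `CVLQ`: cysteine at −4, aliphatic a-positions, X = Q →
canonical), and the resulting two-type classification.

The consensus of the 23 packaged cephalopod C-termini:

```sh
lamterm consensus --fasta src/lamterm/fixtures/cephalopod_ctermini.fasta
```

```text
consensus	sqQkKgWlFW
column	depth	modal	count	tie	frequencies
-10	23	S	12	0	A:3,P:2,Q:1,S:12,T:5
-9	23	Q	16	0	G:1,P:4,Q:16,S:2
...
```

Every cephalopod lamin ends in `...WlFW`: the terminal tryptophan, the −2
phenylalanine and the −4 tryptophan are 100 % columns (uppercase), while
e.g. the −3 leucine is conserved in 17/23 species (lowercase).

Other subcommands: `cryptic` (UTR CaaX scan + junction proposals),
`genestructure` (spliced alignment → GFF3 + splice-variant proteins),
`simulate` (synthetic gene bundles with truth JSON), `report` (the full
pipeline with per-clade composition tables and consensus blocks),
`fixtures`.

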
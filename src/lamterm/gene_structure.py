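"""Exon/intron structure deduction and cassette-exon splice variants.

A transcript is aligned to a genomic contig by exact k-mer anchoring and
collinear chaining; genomic gaps become introns, with GT..AG boundaries
preferred inside a small slide window. Intron positions are then expressed
in CDS/codon coordinates (intron phase), compared to user-supplied archetypal
reference positions, and cassette-exon inclusion patterns are enumerated into
mature transcripts, proteins and termini.

Coordinates are 0-based half-open on the genome and the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lamterm.seqio import SeqRecord
from lamterm.terminus_features import extract_cterm
from lamterm.transcript_analysis import OrfAnnotation, translate


@dataclass
class GeneModel:
    """Exon coordinates of one transcript on one genomic sequence."""

    genomic_id: str
    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open genomic intervals
    cds_offset: int | None = None  # CDS start within the spliced transcript
    cds_length: int | None = None
    mismatches: list[int] = field(default_factory=list)  # transcript coords
    noncanonical_introns: list[int] = field(default_factory=list)  # intron idx

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, genome: SeqRecord) -> str:
        return "".join(genome.sequence[s:e] for s, e in self.exons)


@dataclass
class IntronRecord:
    """One intron with its position expressed in CDS/codon coordinates."""

    index: int
    genomic_interval: tuple[int, int]
    spliced_position: int  # nt position in the spliced transcript
    cds_position: int | None  # nt position relative to the CDS start
    codon_index: int | None
    phase: int | None  # 0/1/2; phase != 0 splits a codon across exons
    location: str  # "cds" | "utr5" | "utr3"
    donor: str = ""
    acceptor: str = ""


@dataclass
class SpliceVariant:
    """One cassette-exon inclusion pattern with its derived products."""

    included: tuple[int, ...]  # cassette exon indices included in the mRNA
    exons: list[tuple[int, int]]
    mrna: str
    protein: str
    terminus: str


@dataclass
class IntronMatchReport:
    matched: list[tuple[IntronRecord, tuple[int, int]]]
    unmatched_records: list[IntronRecord]
    unmatched_references: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# Spliced alignment
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    t_start: int  # covered transcript interval [t_start, t_end)
    t_end: int
    diag: int  # genomic position - transcript position


def _anchor_segments(t: str, g: str, k: int) -> list[_Segment]:
    """Unique-match k-mer anchors merged into same-diagonal segments."""
    index: dict[str, int] = {}
    for i in range(len(g) - k + 1):
        kmer = g[i : i + k]
        index[kmer] = -1 if kmer in index else i
    anchors: list[tuple[int, int]] = []
    for i in range(len(t) - k + 1):
        j = index.get(t[i : i + k], -1)
        if j >= 0:
            anchors.append((i, j - i))  # (transcript pos, diagonal)
    by_diag: dict[int, list[int]] = {}
    for i, d in anchors:
        by_diag.setdefault(d, []).append(i)
    segments: list[_Segment] = []
    # merge same-diagonal anchors across holes of up to ~2 mismatches
    max_hole = 2 * k + 4
    for d, starts in by_diag.items():
        starts.sort()
        seg_lo = starts[0]
        prev = starts[0]
        for i in starts[1:]:
            if i - prev > max_hole:
                segments.append(_Segment(seg_lo, prev + k, d))
                seg_lo = i
            prev = i
        segments.append(_Segment(seg_lo, prev + k, d))
    segments.sort(key=lambda s: (s.t_start, s.diag))
    return segments


def _chain(segments: list[_Segment], gap_penalty: float = 2.0) -> list[_Segment]:
    """Collinear chaining by dynamic programming (weighted LIS style)."""
    n = len(segments)
    best = [float(s.t_end - s.t_start) for s in segments]
    back = [-1] * n
    for i, si in enumerate(segments):
        for j in range(i):
            sj = segments[j]
            if sj.diag > si.diag:
                continue  # genome must advance at least as fast as transcript
            if sj.t_end > si.t_start + 8:  # allow slight anchor overlap
                continue
            if sj.t_end + sj.diag > si.t_start + si.diag + 8:
                continue
            cand = best[j] + (si.t_end - si.t_start) - gap_penalty
            if cand > best[i]:
                best[i] = cand
                back[i] = j
    if not segments:
        return []
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(segments[end])
        end = back[end]
    return chain[::-1]


def _pick_boundary(
    t: str, g: str, left: _Segment, right: _Segment, guess: int, slide: int = 6
) -> tuple[int, bool, list[int]]:
    """Choose the transcript position where the exon boundary falls.

    Within ``slide`` nt of the anchor-implied boundary, candidates are scored
    by local mismatches on both flanks; among the best, a boundary whose
    implied intron starts with GT and ends with AG wins. Returns
    (boundary, is_canonical, local mismatch positions).
    """
    lo = max(left.t_start + 1, guess - slide)
    hi = min(right.t_end - 1, guess + slide)
    window_lo = max(left.t_start, lo - 8)
    window_hi = min(right.t_end, hi + 8)
    candidates = []
    for b in range(lo, hi + 1):
        mm = []
        for tpos in range(window_lo, b):
            if t[tpos] != g[tpos + left.diag]:
                mm.append(tpos)
        for tpos in range(b, window_hi):
            if t[tpos] != g[tpos + right.diag]:
                mm.append(tpos)
        gstart = b + left.diag
        gend = b + right.diag
        canonical = g[gstart : gstart + 2] == "GT" and g[gend - 2 : gend] == "AG"
        candidates.append((len(mm), not canonical, abs(b - guess), b, mm))
    if not candidates:  # degenerate segment geometry: keep the anchor guess
        gstart, gend = guess + left.diag, guess + right.diag
        canonical = (
            g[gstart : gstart + 2] == "GT" and g[gend - 2 : gend] == "AG"
        )
        return guess, canonical, []
    candidates.sort()
    nmm, noncanon, _, b, mm = candidates[0]
    return b, not noncanon, mm


def spliced_align(
    transcript: SeqRecord,
    genome: SeqRecord,
    k: int = 15,
    min_intron: int = 30,
    max_mismatch_frac: float = 0.01,
    cds_offset: int | None = None,
    cds_length: int | None = None,
) -> GeneModel:
    """Deduce the exon/intron structure of a transcript on a genomic contig.

    Exact ``k``-mer anchors (unique in the genome) are chained collinearly;
    each change of diagonal along the chain is an intron whose boundary is
    refined within a +/-6 nt slide, preferring GT..AG ends (kept but flagged
    non-canonical otherwise). Raises ``ValueError`` when less than half of
    the transcript is anchored or when the mismatch budget
    (``max_mismatch_frac`` of the transcript length, at least 1) is exceeded.
    """
    t, g = transcript.sequence, genome.sequence
    segments = _anchor_segments(t, g, k)
    chain = _chain(segments)
    if not chain or sum(s.t_end - s.t_start for s in chain) < 0.5 * len(t):
        raise ValueError(
            f"{transcript.id}: no confident gene model "
            f"(<50% of the transcript anchored on {genome.id})"
        )
    mismatches: list[int] = []
    noncanonical: list[int] = []
    # transcript-space exon boundaries; exon i spans [bounds[i], bounds[i+1])
    bounds = [0]
    diags = [chain[0].diag]
    prev = chain[0]
    for seg in chain[1:]:
        if seg.diag == prev.diag:
            prev = _Segment(prev.t_start, seg.t_end, seg.diag)
            continue
        guess = prev.t_end if prev.t_end <= seg.t_start else (
            (prev.t_end + seg.t_start) // 2
        )
        b, canonical, mm = _pick_boundary(t, g, prev, seg, guess)
        if not canonical:
            noncanonical.append(len(bounds) - 1)
        mismatches.extend(mm)
        bounds.append(b)
        diags.append(seg.diag)
        prev = seg
    bounds.append(len(t))
    # extend first/last exon to the transcript ends, counting mismatches
    first_diag, last_diag = diags[0], diags[-1]
    if first_diag < 0 or last_diag + len(t) > len(g):
        raise ValueError(
            f"{transcript.id}: transcript ends fall outside {genome.id}"
        )
    for tpos in range(0, chain[0].t_start):
        if t[tpos] != g[tpos + first_diag]:
            mismatches.append(tpos)
    for tpos in range(chain[-1].t_end, len(t)):
        if t[tpos] != g[tpos + last_diag]:
            mismatches.append(tpos)
    # interior mismatch holes within merged same-diagonal stretches
    seen = set()
    for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        d = diags[i]
        for tpos in range(lo, hi):
            if t[tpos] != g[tpos + d] and tpos not in seen:
                mismatches.append(tpos)
    mismatches = sorted(set(mismatches))
    budget = max(1, int(max_mismatch_frac * len(t)))
    if len(mismatches) > budget:
        raise ValueError(
            f"{transcript.id}: {len(mismatches)} mismatches exceed the "
            f"tolerance of {budget}"
        )
    exons = [
        (lo + d, hi + d) for (lo, hi), d in zip(zip(bounds, bounds[1:]), diags)
    ]
    # boundary refinement can leave zero-length introns; fuse those exons.
    # short (< min_intron) positive gaps are kept as flagged introns.
    fused: list[tuple[int, int]] = []
    short_introns: list[int] = []
    for s, e in exons:
        if fused and s < fused[-1][1]:
            raise ValueError(f"{transcript.id}: inconsistent exon chain")
        if fused and s == fused[-1][1]:
            fused[-1] = (fused[-1][0], e)
        else:
            if fused and s - fused[-1][1] < min_intron:
                short_introns.append(len(fused) - 1)
            fused.append((s, e))
    exons = fused
    noncanonical.extend(i for i in short_introns if i not in noncanonical)
    return GeneModel(
        genomic_id=genome.id,
        transcript_id=transcript.id,
        exons=exons,
        cds_offset=cds_offset,
        cds_length=cds_length,
        mismatches=mismatches,
        noncanonical_introns=noncanonical,
    )


# ---------------------------------------------------------------------------
# Intron phases and position comparison
# ---------------------------------------------------------------------------


def intron_phases(
    model: GeneModel, orf: OrfAnnotation, genome: SeqRecord | None = None
) -> list[IntronRecord]:
    """Express every intron of a model in CDS/codon coordinates.

    Phase is the intron's nucleotide offset within its codon: phase 0 falls
    between codons, phases 1 and 2 split a codon across the flanking exons
    (the cephalopod terminal tryptophan is the phase-1 case at the final
    codon). Introns outside the CDS are flagged ``utr5``/``utr3``.
    """
    cds_start, cds_end = orf.cds
    records: list[IntronRecord] = []
    spliced = 0
    for idx, ((_, e1), (s2, _)) in enumerate(
        zip(model.exons, model.exons[1:])
    ):
        exon_len = model.exons[idx][1] - model.exons[idx][0]
        spliced += exon_len
        pos = spliced  # intron sits after this many spliced nucleotides
        if pos <= cds_start:
            cds_pos = codon = phase = None
            location = "utr5"
        elif pos >= cds_end + 3:  # past the stop codon
            cds_pos = codon = phase = None
            location = "utr3"
        else:
            cds_pos = pos - cds_start
            codon = cds_pos // 3
            phase = cds_pos % 3
            location = "cds"
        donor = acceptor = ""
        if genome is not None:
            donor = genome.sequence[e1 : e1 + 2]
            acceptor = genome.sequence[s2 - 2 : s2]
        records.append(
            IntronRecord(
                index=idx,
                genomic_interval=(e1, s2),
                spliced_position=pos,
                cds_position=cds_pos,
                codon_index=codon,
                phase=phase,
                location=location,
                donor=donor,
                acceptor=acceptor,
            )
        )
    return records


def compare_intron_positions(
    records: list[IntronRecord],
    reference_positions: list[tuple[int, int]],
    tol: int = 0,
) -> IntronMatchReport:
    """Greedy one-to-one matching of introns to archetypal reference positions.

    ``reference_positions`` are (codon index, phase) pairs in protein
    coordinates (they come from prior literature and are supplied by the
    user). A record matches a reference when phases are equal and the codon
    indices differ by at most ``tol``; each reference is used once.
    """
    remaining = list(reference_positions)
    matched = []
    unmatched_records = []
    for rec in records:
        if rec.location != "cds":
            unmatched_records.append(rec)
            continue
        found = None
        for ref in remaining:
            if rec.phase == ref[1] and abs(rec.codon_index - ref[0]) <= tol:
                found = ref
                break
        if found is None:
            unmatched_records.append(rec)
        else:
            remaining.remove(found)
            matched.append((rec, found))
    return IntronMatchReport(
        matched=matched,
        unmatched_records=unmatched_records,
        unmatched_references=remaining,
    )


# ---------------------------------------------------------------------------
# Cassette-exon splice variants
# ---------------------------------------------------------------------------


def enumerate_splice_variants(
    model: GeneModel,
    cassette_indices: list[int],
    genome: SeqRecord,
    terminus_n: int = 10,
) -> list[SpliceVariant]:
    """Enumerate all 2^k cassette-exon inclusion patterns of a gene model.

    ``cassette_indices`` are indices into ``model.exons`` and must be
    internal exons. Variants are returned in deterministic order: ascending
    bitmask, bit ``i`` set meaning the ``i``-th cassette (ascending index) is
    included. Each variant is spliced, translated from the (adjusted) CDS
    offset to the first in-frame stop, and its terminus extracted.
    """
    k = len(cassette_indices)
    cassettes = sorted(cassette_indices)
    last = len(model.exons) - 1
    for ci in cassettes:
        if ci <= 0 or ci >= last:
            raise ValueError(
                f"cassette index {ci} is not an internal exon (0 < i < {last})"
            )
    if model.cds_offset is None:
        raise ValueError("model needs cds_offset to translate variants")
    variants: list[SpliceVariant] = []
    for mask in range(2 ** k):
        included = tuple(ci for b, ci in enumerate(cassettes) if mask >> b & 1)
        excluded = set(cassettes) - set(included)
        exons = [
            ex for i, ex in enumerate(model.exons) if i not in excluded
        ]
        mrna = "".join(genome.sequence[s:e] for s, e in exons)
        # removing exons upstream of the CDS start shifts the offset
        offset = model.cds_offset
        spliced = 0
        for i, (s, e) in enumerate(model.exons):
            if i in excluded and spliced + (e - s) <= model.cds_offset:
                offset -= e - s
            spliced += e - s
        protein = translate(mrna[offset:], to_stop=True)
        variants.append(
            SpliceVariant(
                included=included,
                exons=exons,
                mrna=mrna,
                protein=protein,
                terminus=extract_cterm(protein, terminus_n) if protein else "",
            )
        )
    return variants
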
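"""ORF annotation, cryptic CaaX exons in 3'-UTRs, and splice-junction
reconstruction by homology.

In terebelliform annelids (and, by inference, in Arenicola), the transcript
encoding the alternative lamin C-terminus still carries the CaaX-encoding
exon downstream of its stop codon, untranslated in the 3'-UTR. This module
finds such cryptic CaaX-encoding segments and reconstructs the splice
junction that would produce the CaaX-variant mRNA: a donor inside the CDS is
joined to an acceptor in the UTR so that the resulting chimeric open reading
frame ends at the cryptic CaaX stop, and candidate junctions are ranked by
similarity of the chimeric C-terminus to a homologous CaaX terminus.

All coordinates are 0-based half-open positions on the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from lamterm.seqio import SeqRecord
from lamterm.terminus_features import NO_CAAX, call_caax

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # the standard genetic code
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62: dict[tuple[str, str], float] = {
    (a, b): _BLOSUM62[a][b]
    for a in _BLOSUM62.alphabet
    for b in _BLOSUM62.alphabet
}


def translate(dna: str, to_stop: bool = False) -> str:
    """Translate a DNA string codon by codon (standard code, frame 0).

    Trailing nucleotides that do not fill a codon are ignored; codons with
    ambiguity characters translate to ``X``.
    """
    dna = dna.upper()
    out = []
    for i in range(0, len(dna) - 2, 3):
        aa = CODON_TO_AA.get(dna[i : i + 3], "X")
        if aa == "*" and to_stop:
            break
        out.append(aa)
    return "".join(out)


@dataclass
class OrfAnnotation:
    """An annotated open reading frame on a transcript."""

    transcript_id: str
    cds: tuple[int, int]  # 0-based half-open, stop codon excluded
    protein: str
    stop_present: bool
    utr3: tuple[int, int]  # empty interval when no stop codon

    @property
    def cds_length(self) -> int:
        return self.cds[1] - self.cds[0]


@dataclass
class CrypticCaaXHit:
    """A CaaX-encoding segment in a 3'-UTR, delimited by in-frame stops."""

    interval: tuple[int, int]  # transcript coords of the encoding segment
    frame: int  # (segment start - UTR start) mod 3
    peptide: str  # translation of the segment; ends with the CaaX tetrapeptide
    stop_position: int  # transcript coord of the first base of the stop codon


@dataclass
class JunctionProposal:
    """A candidate splice junction joining the CDS to a cryptic CaaX segment."""

    donor: int  # transcript coord of the donor cut inside the CDS
    donor_phase: int  # codon phase at the donor (0 = codon boundary)
    acceptor: int  # transcript coord of the acceptor in the 3'-UTR
    cterm: str  # C-terminus of the chimeric protein (<= 30 residues)
    score: float  # ungapped BLOSUM62 similarity to the homolog terminus
    deletion: int  # acceptor - donor (transcript nucleotides removed)
    rank: int = 0


def annotate_orf(
    transcript: SeqRecord, mode: str = "longest", min_codons: int = 30
) -> OrfAnnotation:
    """Annotate the longest ATG-initiated ORF on the given strand.

    Ties are broken toward the 5'-most start. ORFs terminated by an in-frame
    stop are preferred; if none reaches ``min_codons``, an ORF running to the
    transcript end (no stop codon) is accepted and flagged. Raises
    ``ValueError`` when no ORF of at least ``min_codons`` codons exists.
    """
    if mode != "longest":
        raise ValueError(f"unknown ORF mode {mode!r}")
    seq = transcript.sequence
    n = len(seq)
    best = None  # (-codons, start, has_stop)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    codons = (i - start) // 3
                    cand = (-codons, start, True, i)
                    if best is None or cand[:2] < best[:2]:
                        best = cand
                    start = None
            elif codon == "ATG" and start is None:
                start = i
        if start is not None:  # ran off the end without a stop
            end = start + ((n - start) // 3) * 3
            codons = (end - start) // 3
            cand = (-codons, start, False, end)
            # stop-containing ORFs of equal length win
            if best is None or cand[:2] < best[:2]:
                best = cand
    if best is None or -best[0] < min_codons:
        raise ValueError(
            f"{transcript.id}: no ATG-initiated ORF of >= {min_codons} codons"
        )
    _, start, has_stop, stop_at = best
    cds = (start, stop_at)
    protein = translate(seq[start:stop_at])
    utr3 = (stop_at + 3, n) if has_stop else (n, n)
    return OrfAnnotation(
        transcript_id=transcript.id,
        cds=cds,
        protein=protein,
        stop_present=has_stop,
        utr3=utr3,
    )


def scan_utr_for_caax(
    orf: OrfAnnotation, transcript: SeqRecord
) -> list[CrypticCaaXHit]:
    """Find maximal CaaX-encoding segments in the 3'-UTR.

    For each of the three reading frames of the UTR, the UTR is partitioned
    into stop-delimited segments (from the frame start or the previous stop
    to the next stop codon). A segment is reported when it encodes at least
    four residues and its translation ends with a tetrapeptide carrying a
    cysteine at position -4 — i.e. a peptide whose CaaX call is anything but
    ``no_caax`` — immediately followed by the stop. Hits are sorted 5' to 3'.
    """
    u0, u1 = orf.utr3
    seq = transcript.sequence
    hits: list[CrypticCaaXHit] = []
    for frame in range(3):
        seg_start = u0 + frame
        for i in range(u0 + frame, u1 - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if i - seg_start >= 12:
                    pep = translate(seq[seg_start:i])
                    if call_caax(pep).status != NO_CAAX:
                        hits.append(
                            CrypticCaaXHit(
                                interval=(seg_start, i),
                                frame=frame,
                                peptide=pep,
                                stop_position=i,
                            )
                        )
                seg_start = i + 3
    hits.sort(key=lambda h: h.interval)
    return hits


def _score_cterm(chimera_tail: str, homolog_cterm: str) -> float:
    """Right-anchored ungapped BLOSUM62 similarity of two C-termini."""
    m = min(len(chimera_tail), len(homolog_cterm))
    total = 0.0
    for i in range(1, m + 1):
        total += _B62.get((chimera_tail[-i], homolog_cterm[-i]), -4.0)
    return total


def propose_junction(
    orf: OrfAnnotation,
    transcript: SeqRecord,
    hit: CrypticCaaXHit,
    homolog_cterm: str,
    window: int = 200,
    tail: int = 30,
) -> list[JunctionProposal]:
    """Enumerate and rank candidate splice junctions for a cryptic CaaX hit.

    Donors are cut points within ``window`` nucleotides upstream of the stop
    codon of the annotated CDS (any codon phase). For each donor, acceptors
    in the 3'-UTR whose phase keeps the hit's stop codon in frame are paired
    with it; a pair is kept when the joined reading frame reaches the hit's
    stop without an internal stop codon and the chimeric protein still ends
    with a cysteine-containing tetrapeptide. Proposals are ranked by the
    ungapped BLOSUM62 similarity of the chimeric C-terminus (last ``tail``
    residues) to ``homolog_cterm``, ties broken toward the smaller deletion.

    Transcripts carry no intron sequence, so no GT dinucleotide is required
    at the donor: frame compatibility and homology carry the signal.
    """
    if len(homolog_cterm) < 10:
        raise ValueError("homolog terminus must be at least 10 residues")
    cds_start, cds_end = orf.cds
    u0, _ = orf.utr3
    h_stop = hit.stop_position
    seq = transcript.sequence
    if not (u0 <= hit.interval[0] and h_stop + 3 <= len(seq)):
        raise ValueError("hit does not lie in the annotated 3'-UTR")
    proposals: list[JunctionProposal] = []
    d_lo = max(cds_start + 3, cds_end - window)
    for d in range(d_lo, cds_end + 1):
        phase = (d - cds_start) % 3
        prefix_codons = (d - cds_start) // 3
        # acceptor must satisfy (d - cds_start) + (h_stop - a) ≡ 0 (mod 3)
        target_mod = (phase + h_stop) % 3
        a_first = u0 + ((target_mod - u0) % 3)
        for a in range(a_first, h_stop - 12 + 1, 3):
            joined = seq[d - phase : d] + seq[a:h_stop]
            pep = translate(joined)
            if "*" in pep or len(pep) < 4:
                continue
            if call_caax(pep[-4:] if len(pep) >= 4 else pep).status == NO_CAAX:
                continue
            chim_tail = (orf.protein[:prefix_codons] + pep)[-tail:]
            proposals.append(
                JunctionProposal(
                    donor=d,
                    donor_phase=phase,
                    acceptor=a,
                    cterm=chim_tail,
                    score=_score_cterm(chim_tail, homolog_cterm),
                    deletion=a - d,
                )
            )
    proposals.sort(key=lambda p: (-p.score, p.deletion, p.donor))
    for r, p in enumerate(proposals, start=1):
        p.rank = r
    return proposals
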
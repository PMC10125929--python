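"""Synthetic lamin-like genes, transcripts and protein panels with known truth.

The generator emulates the gene configurations seen in lophotrochozoan lamin
surveys so that every pipeline stage can be exercised without downloads:

* a CDS split by GT..AG introns at configurable positions (any phase,
  including a split terminal codon, the cephalopod hallmark);
* an optional short terminal exon block encoding the C-terminus;
* 0-2 cassette exons between the penultimate constitutive exon and the
  terminal exons (the cephalopod alternative-splicing layout);
* the terebellid configuration: the exon encoding the alternative C-terminus
  sits upstream of the CaaX-encoding exon and is flanked by introns, so the
  alternative-terminus mRNA retains the CaaX information in its 3'-UTR.

All randomness flows through one ``numpy`` generator seeded from
``SimConfig.seed``; identical configurations produce byte-identical output.
Codon usage is uniform over synonymous codons; composition control applies
at the amino-acid level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from lamterm import terminus_features as tf
from lamterm.gene_structure import GeneModel
from lamterm.seqio import SeqRecord
from lamterm.transcript_analysis import (
    CODON_TO_AA,
    annotate_orf,
    scan_utr_for_caax,
)

TERMINUS_MODES = (
    "caax",
    "aromatic_alternative",
    "aliphatic_alternative",
    "terebellid_dual",
)

_BACK_TABLE: dict[str, list[str]] = {}
for _codon in sorted(CODON_TO_AA):
    _aa = CODON_TO_AA[_codon]
    if _aa != "*":
        _BACK_TABLE.setdefault(_aa, []).append(_codon)

_NLS_PEPTIDE = "PKKKRKV"  # SV40-type monopartite signal


@dataclass
class SimConfig:
    """Parameters of one synthetic lamin gene.

    ``n_exons`` counts the exons of the full (all-cassettes-included) model.
    ``intron_cds_positions`` optionally fixes the CDS-relative nucleotide
    positions of the constitutive introns (simple layout only).
    """

    seed: int = 0
    n_exons: int = 12
    intron_length: tuple[int, int] = (60, 300)
    n_cassettes: int = 0
    terminus_mode: str = "caax"
    gc: float = 0.5
    plant_nls: bool = True
    split_terminal_codon: bool = False
    n_codons: int | None = None  # protein length of the constitutive CDS
    utr5_length: int = 30
    utr3_length: int = 90
    flank: int = 50
    min_exon: int = 24
    terminal_exon_codons: int = 10
    cassette_codons: tuple[int, int] = (5, 12)
    intron_cds_positions: list[int] | None = None

    def validate(self) -> None:
        if self.terminus_mode not in TERMINUS_MODES:
            raise ValueError(f"unknown terminus mode {self.terminus_mode!r}")
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")
        if self.n_cassettes not in (0, 1, 2):
            raise ValueError("cassette exon count must be 0, 1 or 2")
        if self.n_cassettes and self.n_exons < 4:
            raise ValueError("cassette exons require n_exons >= 4")
        if self.intron_length[0] < 10 or self.intron_length[0] > self.intron_length[1]:
            raise ValueError("invalid intron length range")
        if self.terminus_mode == "terebellid_dual" and self.n_exons < 3:
            raise ValueError("terebellid configuration requires n_exons >= 3")
        if self.split_terminal_codon and self.n_exons < 2:
            raise ValueError("a split terminal codon requires n_exons >= 2")


@dataclass
class TruthRecord:
    """Everything the generator knows about one synthetic gene."""

    config: SimConfig
    genome: SeqRecord
    model: GeneModel  # full-inclusion model (all cassettes in)
    cassette_indices: list[int]  # indices into model.exons
    transcripts: list[SeqRecord]  # cassette bitmask ascending
    proteins: list[str]
    termini: list[str]
    cds_offset: int  # of the full-inclusion transcript
    intron_cds: list[tuple[int | None, int | None]]  # (codon, phase) per intron
    nls_span: tuple[int, int] | None  # protein coords in the full protein
    junction: dict | None = None  # terebellid truth (alt-transcript coords)


# -- sequence samplers ------------------------------------------------------


def _dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _dna_no_atg(rng: np.random.Generator, n: int, gc: float) -> str:
    for _ in range(100):
        s = _dna(rng, n, gc)
        if "ATG" not in s:
            return s
    return s.replace("ATG", "ACG")  # last resort, keeps length


def _codons(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _BACK_TABLE[aa][rng.integers(len(_BACK_TABLE[aa]))] for aa in protein
    )


def _sample(rng: np.random.Generator, pool: str, n: int) -> list[str]:
    return [pool[rng.integers(len(pool))] for _ in range(n)]


def _caax_terminus(rng: np.random.Generator, n: int = 10) -> str:
    body = _sample(rng, "ADEGKLNPQRST", n - 4)
    caax = (
        "C"
        + "ILV"[rng.integers(3)]
        + "ILV"[rng.integers(3)]
        + "MSQ"[rng.integers(3)]
    )
    return "".join(body) + caax


def _aromatic_terminus(rng: np.random.Generator, n: int = 10) -> str:
    """W/F-rich, free of negative residues, ending in tryptophan."""
    n_arom = int(rng.integers(3, 5))
    n_pos = int(rng.integers(2, 4))
    rest = n - 1 - n_arom - n_pos
    residues = (
        _sample(rng, "FW", n_arom)
        + _sample(rng, "KR", n_pos)
        + _sample(rng, "GASTQN", rest)
    )
    rng.shuffle(residues)
    return "".join(residues) + "W"


def _aliphatic_terminus(rng: np.random.Generator, n: int = 10) -> str:
    n_ali = int(rng.integers(5, 7))
    residues = _sample(rng, "ILV", n_ali) + _sample(
        rng, "KRGASTE", n - n_ali
    )
    rng.shuffle(residues)
    return "".join(residues)


_TERMINUS_SAMPLERS = {
    "caax": _caax_terminus,
    "aromatic_alternative": _aromatic_terminus,
    "aliphatic_alternative": _aliphatic_terminus,
}

_EXPECTED_LABEL = {
    "caax": "caax",
    "aromatic_alternative": "aromatic_alternative",
    "aliphatic_alternative": "aliphatic_alternative",
}


def _protein_body(
    rng: np.random.Generator, n: int, plant_nls: bool
) -> tuple[str, tuple[int, int] | None]:
    """A protein prefix of ``n`` residues starting with M.

    When requested, the SV40-type NLS is planted at roughly one third of the
    length and the body is resampled until it is the only NLS hit; without
    planting, bodies with accidental NLS hits are resampled away.
    """
    pool = "ADEFGHIKLMNPQSTVWY"  # no C (avoids chance CaaX), no R (NLS control)
    for _ in range(200):
        body = ["M"] + _sample(rng, pool, n - 1)
        span = None
        if plant_nls and n >= len(_NLS_PEPTIDE) + 10:
            at = n // 3
            body[at : at + len(_NLS_PEPTIDE)] = list(_NLS_PEPTIDE)
            span = (at, at + len(_NLS_PEPTIDE))
        prot = "".join(body)
        hits = tf.find_nls(prot)
        if plant_nls and span is not None:
            if len(hits) == 1 and span[0] <= hits[0].start < span[1]:
                return prot, span
        elif not hits:
            return prot, None
    raise RuntimeError("could not sample a protein body with the requested NLS")


def _choose_positions(
    rng: np.random.Generator,
    n_introns: int,
    lo: int,
    hi: int,
    spacing: int,
) -> list[int]:
    """``n_introns`` sorted positions in [lo, hi] at least ``spacing`` apart."""
    if n_introns == 0:
        return []
    if hi - lo < (n_introns - 1) * spacing:
        raise ValueError("CDS too short for the requested number of introns")
    for _ in range(500):
        pos = np.sort(rng.integers(lo, hi + 1, size=n_introns))
        if n_introns == 1 or np.diff(pos).min() >= spacing:
            return [int(p) for p in pos]
    # deterministic fallback: evenly spread
    return [int(round(lo + i * (hi - lo) / max(1, n_introns - 1)))
            for i in range(n_introns)]


def _intron(rng: np.random.Generator, length: int, gc: float) -> str:
    return "GT" + _dna(rng, length - 4, gc) + "AG"


def _assemble(
    rng: np.random.Generator,
    config: SimConfig,
    exon_seqs: list[str],
) -> tuple[str, list[tuple[int, int]]]:
    """Join exon sequences with fresh introns; returns (genome, exon coords)."""
    parts = [_dna(rng, config.flank, config.gc)]
    coords = []
    at = config.flank
    for i, ex in enumerate(exon_seqs):
        coords.append((at, at + len(ex)))
        parts.append(ex)
        at += len(ex)
        if i < len(exon_seqs) - 1:
            ilen = int(rng.integers(config.intron_length[0],
                                    config.intron_length[1] + 1))
            parts.append(_intron(rng, ilen, config.gc))
            at += ilen
    parts.append(_dna(rng, config.flank, config.gc))
    return "".join(parts), coords


def make_lamin_gene(config: SimConfig) -> TruthRecord:
    """Generate one synthetic lamin gene with full truth bookkeeping.

    Deterministic under ``config.seed``. Raises ``ValueError`` for impossible
    configurations (e.g. cassette exons with fewer than four exons).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.terminus_mode == "terebellid_dual":
        return _make_terebellid(config, rng)

    T = config.terminal_exon_codons
    special_terminal = config.n_cassettes > 0 or config.split_terminal_codon
    n_terminal_exons = (2 if config.split_terminal_codon else 1)
    n_head = config.n_exons - config.n_cassettes - (
        n_terminal_exons if special_terminal else 0
    )
    if special_terminal and n_head < 1:
        raise ValueError("n_exons too small for the requested layout")

    P = config.n_codons or max(60, 30 * config.n_exons)
    if special_terminal and P <= T + 10:
        raise ValueError("protein too short for a separate terminal exon block")

    body_len = P - T
    body, nls_span = _protein_body(rng, body_len, config.plant_nls)
    terminus = _TERMINUS_SAMPLERS[config.terminus_mode](rng, T)
    cassette_peptides = [
        "".join(_sample(rng, "ADEGHKLNPQSTV",
                        int(rng.integers(*config.cassette_codons)) ))
        for _ in range(config.n_cassettes)
    ]

    utr5 = _dna_no_atg(rng, config.utr5_length, config.gc)
    utr3 = _dna(rng, config.utr3_length, config.gc)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]

    body_nt = _codons(rng, body)
    cassette_nt = [_codons(rng, pep) for pep in cassette_peptides]
    term_nt = _codons(rng, terminus)

    full_protein = body + "".join(cassette_peptides) + terminus
    full_cds = body_nt + "".join(cassette_nt) + term_nt
    transcript_full = utr5 + full_cds + stop + utr3
    cds_offset = len(utr5)

    # exon boundaries in full-transcript coordinates
    head_end = cds_offset + len(body_nt)  # phase-0 block boundary
    if special_terminal:
        head_pos = _choose_positions(
            rng, n_head - 1,
            cds_offset + config.min_exon,
            head_end - config.min_exon,
            config.min_exon,
        )
    else:
        head_pos = _choose_positions(
            rng, n_head - 1,
            cds_offset + config.min_exon,
            cds_offset + len(full_cds) - 3,
            config.min_exon,
        ) if config.intron_cds_positions is None else [
            cds_offset + p for p in config.intron_cds_positions
        ]
    boundaries = [0] + head_pos
    cassette_slots: list[int] = []
    if special_terminal:
        boundaries.append(head_end)
        at = head_end
        for nt in cassette_nt:
            at += len(nt)
            cassette_slots.append(len(boundaries))
            boundaries.append(at)
        if config.split_terminal_codon:
            split_at = cds_offset + len(full_cds) - 2  # inside the last codon
            boundaries.append(split_at)
    boundaries.append(len(transcript_full))
    exon_seqs = [
        transcript_full[a:b] for a, b in zip(boundaries, boundaries[1:])
    ]
    cassette_indices = [slot - 1 for slot in cassette_slots]

    genome_seq, coords = _assemble(rng, config, exon_seqs)
    genome = SeqRecord(
        id=f"synthgene_seed{config.seed}", sequence=genome_seq, alphabet="dna"
    )
    model = GeneModel(
        genomic_id=genome.id,
        transcript_id=f"synthtx_seed{config.seed}",
        exons=coords,
        cds_offset=cds_offset,
        cds_length=len(full_cds),
    )

    # per-variant transcripts/proteins (cassette bitmask ascending)
    transcripts, proteins, termini = [], [], []
    k = config.n_cassettes
    for mask in range(2 ** k):
        keep = [i for i in range(k) if mask >> i & 1]
        var_cds = body_nt + "".join(cassette_nt[i] for i in keep) + term_nt
        var_prot = body + "".join(cassette_peptides[i] for i in keep) + terminus
        seq = utr5 + var_cds + stop + utr3
        transcripts.append(
            SeqRecord(
                id=f"{model.transcript_id}_v{mask}", sequence=seq,
                alphabet="dna",
                metadata={"cassette_mask": mask},
            )
        )
        proteins.append(var_prot)
        termini.append(var_prot[-10:])

    intron_cds = []
    for b in boundaries[1:-1]:
        cds_pos = b - cds_offset
        if 0 < cds_pos < len(full_cds) + 3:
            intron_cds.append((cds_pos // 3, cds_pos % 3))
        else:
            intron_cds.append((None, None))

    return TruthRecord(
        config=config,
        genome=genome,
        model=model,
        cassette_indices=cassette_indices,
        transcripts=transcripts,
        proteins=proteins,
        termini=termini,
        cds_offset=cds_offset,
        intron_cds=intron_cds,
        nls_span=nls_span,
        junction=None,
    )


def _make_terebellid(config: SimConfig, rng: np.random.Generator) -> TruthRecord:
    """Dual-terminus gene: alternative-terminus exon sandwiched by introns
    upstream of the CaaX exon; the alternative transcript keeps the CaaX
    information in its 3'-UTR."""
    n_head = config.n_exons - 2
    P = config.n_codons or 150

    for _attempt in range(100):
        body, nls_span = _protein_body(rng, P, config.plant_nls)
        donor_phase = int(rng.integers(3))
        body_nt = _codons(rng, body)
        split_nt = _dna(rng, donor_phase, 0.5)  # first bases of a split codon
        completion = (3 - donor_phase) % 3

        alt_pep = _aromatic_terminus(rng, int(rng.integers(10, 15)))
        alt_nt = _dna(rng, completion, 0.5) + _codons(rng, alt_pep)
        alt_stop = ("TAA", "TAG", "TGA")[rng.integers(3)]

        caax_pep = _caax_terminus(rng, int(rng.integers(8, 12)))
        caax_nt = _dna(rng, completion, 0.5) + _codons(rng, caax_pep)
        caax_stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
        tail = _dna(rng, config.utr3_length, config.gc)

        utr5 = _dna_no_atg(rng, config.utr5_length, config.gc)
        common_nt = body_nt + split_nt  # shared CDS prefix, ends at the donor

        head_seq = utr5 + common_nt
        alt_exon = alt_nt + alt_stop  # ends exactly at its stop codon
        caax_exon = caax_nt + caax_stop + tail

        head_pos = _choose_positions(
            rng, n_head - 1,
            len(utr5) + config.min_exon,  # keep head introns inside the CDS
            len(head_seq) - config.min_exon,
            config.min_exon,
        )
        head_bounds = [0] + head_pos + [len(head_seq)]
        exon_seqs = [
            head_seq[a:b] for a, b in zip(head_bounds, head_bounds[1:])
        ] + [alt_exon, caax_exon]

        alt_tx = head_seq + alt_exon + caax_exon
        caax_tx = head_seq + caax_exon
        cds_offset = len(utr5)

        # --- truth bookkeeping in alt-transcript coordinates
        alt_cds_end = len(head_seq) + len(alt_nt)
        utr_start = alt_cds_end + 3
        hit_start = utr_start + completion
        hit_stop = hit_start + 3 * len(caax_pep)
        donor = len(head_seq)
        acceptor = utr_start

        alt_rec = SeqRecord(id="alt", sequence=alt_tx, alphabet="dna")
        caax_rec = SeqRecord(id="caax", sequence=caax_tx, alphabet="dna")
        try:
            alt_orf = annotate_orf(alt_rec, min_codons=30)
            caax_orf = annotate_orf(caax_rec, min_codons=30)
        except ValueError:
            continue
        if alt_orf.cds != (cds_offset, alt_cds_end):
            continue
        if caax_orf.cds != (cds_offset, len(head_seq) + len(caax_nt)):
            continue
        hits = scan_utr_for_caax(alt_orf, alt_rec)
        if len(hits) != 1 or hits[0].interval != (hit_start, hit_stop):
            continue
        alt_protein = alt_orf.protein
        caax_protein = caax_orf.protein
        if tf.call_caax(caax_protein).status != tf.CANONICAL_CAAX:
            continue
        if tf.classify_terminus(
            tf.composition_profile(alt_protein[-10:]),
            tf.call_caax(alt_protein),
        ).label != "aromatic_alternative":
            continue
        break
    else:
        raise RuntimeError("terebellid configuration sampling did not converge")

    genome_seq, coords = _assemble(rng, config, exon_seqs)
    genome = SeqRecord(
        id=f"synthgene_seed{config.seed}", sequence=genome_seq, alphabet="dna"
    )
    model = GeneModel(
        genomic_id=genome.id,
        transcript_id=f"synthtx_seed{config.seed}",
        exons=coords,
        cds_offset=cds_offset,
        cds_length=alt_cds_end - cds_offset,
    )
    alt_index = len(head_bounds) - 1  # position of the alternative exon

    transcripts = [
        SeqRecord(id=f"{model.transcript_id}_v0", sequence=caax_tx,
                  alphabet="dna", metadata={"cassette_mask": 0}),
        SeqRecord(id=f"{model.transcript_id}_v1", sequence=alt_tx,
                  alphabet="dna", metadata={"cassette_mask": 1}),
    ]
    proteins = [caax_protein, alt_protein]
    termini = [caax_protein[-10:], alt_protein[-10:]]

    intron_cds: list[tuple[int | None, int | None]] = []
    for b in head_bounds[1:-1]:
        cds_pos = b - cds_offset
        if cds_pos > 0:
            intron_cds.append((cds_pos // 3, cds_pos % 3))
        else:
            intron_cds.append((None, None))
    dp = len(common_nt)
    intron_cds.append((dp // 3, dp % 3))  # donor intron (head | alt exon)
    intron_cds.append((None, None))  # alt | caax exon intron: 3'-UTR resident

    junction = {
        "donor": donor,
        "donor_phase": donor_phase,
        "acceptor": acceptor,
        "hit_interval": (hit_start, hit_stop),
        "stop_position": hit_stop,
        "caax_terminus": caax_protein[-30:],
        "alt_transcript": 1,
        "caax_transcript": 0,
    }

    return TruthRecord(
        config=config,
        genome=genome,
        model=model,
        cassette_indices=[alt_index],
        transcripts=transcripts,
        proteins=proteins,
        termini=termini,
        cds_offset=cds_offset,
        intron_cds=intron_cds,
        nls_span=nls_span,
        junction=junction,
    )


def make_terminus_panel(
    n_caax: int = 0,
    n_aromatic: int = 0,
    n_aliphatic: int = 0,
    length: int = 120,
    seed: int = 0,
) -> list[SeqRecord]:
    """A panel of synthetic proteins whose terminus classes are known truth.

    Records carry ``metadata['true_class']``; each terminus is resampled
    until the classifier agrees with the requested class (closed loop by
    construction).
    """
    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    wanted = (
        [("caax", i) for i in range(n_caax)]
        + [("aromatic_alternative", i) for i in range(n_aromatic)]
        + [("aliphatic_alternative", i) for i in range(n_aliphatic)]
    )
    for mode, i in wanted:
        for _ in range(100):
            body, _ = _protein_body(rng, length - 10, plant_nls=False)
            pep = _TERMINUS_SAMPLERS[mode](rng, 10)
            prot = body + pep
            label = tf.classify_terminus(
                tf.composition_profile(prot[-10:]), tf.call_caax(prot)
            ).label
            if label == _EXPECTED_LABEL[mode]:
                break
        else:
            raise RuntimeError(f"could not sample a {mode} terminus")
        records.append(
            SeqRecord(
                id=f"panel_{mode}_{i}",
                sequence=prot,
                alphabet="protein",
                metadata={"true_class": mode},
            )
        )
    return records
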
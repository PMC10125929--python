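"""ORF annotation, UTR CaaX scanning (vs brute force) and junction proposals."""

import numpy as np
import pytest
from Bio.Seq import Seq

from lamterm.seqio import SeqRecord
from lamterm.synthetic_data import SimConfig, make_lamin_gene
from lamterm.terminus_features import NO_CAAX, call_caax
from lamterm.transcript_analysis import (
    CrypticCaaXHit,
    annotate_orf,
    propose_junction,
    scan_utr_for_caax,
    translate,
)

NON_STOP_CODONS = [
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if str(Seq(c).translate()) != "*"
]


def _tx(seq, id="tx"):
    return SeqRecord(id=id, sequence=seq, alphabet="dna")


# -- annotate_orf -----------------------------------------------------------


def test_annotate_orf_hand_checkable():
    orf = annotate_orf(_tx("AAATGAAATTTTAAGG"), min_codons=3)
    assert orf.cds == (2, 11)
    assert orf.protein == "MKF"
    assert orf.stop_present
    assert orf.utr3 == (14, 16)


def test_annotate_orf_translation_matches_biopython():
    orf = annotate_orf(_tx("AAATGAAATTTTAAGG"), min_codons=3)
    s, e = orf.cds
    assert orf.protein == str(Seq("AAATGAAATTTTAAGG"[s:e]).translate())


def test_annotate_orf_prefers_longest_then_5prime():
    # two ORFs: MKF (3 codons) and MKKKF (5 codons) — longest wins
    seq = "ATGAAATTTTAA" + "ATGAAAAAAAAATTTTAA"
    orf = annotate_orf(_tx(seq), min_codons=3)
    assert orf.protein == "MKKKF"


def test_annotate_orf_no_orf_is_an_error():
    with pytest.raises(ValueError, match="no ATG"):
        annotate_orf(_tx("A" * 120))


def test_annotate_orf_min_codons_threshold():
    with pytest.raises(ValueError):
        annotate_orf(_tx("ATGAAATTTTAA"), min_codons=10)


def test_annotate_orf_on_synthetic_truth():
    truth = make_lamin_gene(SimConfig(seed=21, n_exons=5))
    orf = annotate_orf(truth.transcripts[-1])
    assert orf.cds == (truth.cds_offset, truth.cds_offset + truth.model.cds_length)
    assert orf.protein == truth.proteins[-1]


# -- scan_utr_for_caax ------------------------------------------------------


def scan_oracle(orf, tx):
    """Exhaustive all-substring translation oracle (Biopython-based)."""
    u0, u1 = orf.utr3
    utr = tx.sequence[u0:u1]
    hits = []
    for p in range(len(utr)):
        for q in range(p + 15, len(utr) + 1):
            if (q - p) % 3:
                continue
            pep = str(Seq(utr[p : q - 3]).translate())
            if str(Seq(utr[q - 3 : q]).translate()) != "*":
                continue
            if "*" in pep or len(pep) < 4 or pep[-4] != "C":
                continue
            # maximal segments only: start at the frame start or after a stop
            if p >= 3 and str(Seq(utr[p - 3 : p]).translate()) == "*":
                pass
            elif p < 3:
                pass
            else:
                continue
            hits.append((u0 + p, u0 + q - 3))
    return sorted(hits)


def test_scan_finds_planted_cvim_segment():
    # UTR encodes ...CVIM-stop in frame 0
    seq = "ATG" + "GCT" * 12 + "TAA" + "TGTGTGATCATGTAA"
    orf = annotate_orf(_tx(seq), min_codons=5)
    hits = scan_utr_for_caax(orf, _tx(seq))
    assert len(hits) == 1
    assert hits[0].peptide.endswith("CVIM")
    assert hits[0].frame == 0


def test_scan_empty_utr_of_adenines():
    seq = "ATG" + "GCT" * 12 + "TAA" + "A" * 15
    orf = annotate_orf(_tx(seq), min_codons=5)
    assert scan_utr_for_caax(orf, _tx(seq)) == []


def test_scan_agrees_with_bruteforce_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        n_utr = int(rng.integers(30, 601))
        utr = "".join(
            NON_STOP_CODONS[i] if rng.random() < 0.8 else "TGT"
            for i in rng.integers(0, len(NON_STOP_CODONS), size=(n_utr + 2) // 3)
        )[:n_utr]
        # salt with stops and cysteine codons so hits actually occur
        utr = "".join(
            "TAA" if rng.random() < 0.08 else utr[i : i + 3]
            for i in range(0, len(utr) - 2, 3)
        )
        seq = "ATG" + "GCT" * 30 + "TAA" + utr
        tx = _tx(seq)
        orf = annotate_orf(tx, min_codons=5)
        got = [h.interval for h in scan_utr_for_caax(orf, tx)]
        assert sorted(got) == scan_oracle(orf, tx)


def test_scan_on_terebellid_truth():
    truth = make_lamin_gene(
        SimConfig(seed=31, n_exons=5, terminus_mode="terebellid_dual")
    )
    alt = truth.transcripts[1]
    orf = annotate_orf(alt)
    hits = scan_utr_for_caax(orf, alt)
    assert len(hits) == 1
    assert hits[0].interval == tuple(truth.junction["hit_interval"])
    assert call_caax(hits[0].peptide).status != NO_CAAX


# -- propose_junction -------------------------------------------------------


def test_junction_recovers_truth_on_synthetic_gene():
    truth = make_lamin_gene(
        SimConfig(seed=41, n_exons=6, terminus_mode="terebellid_dual")
    )
    alt = truth.transcripts[1]
    orf = annotate_orf(alt)
    (hit,) = scan_utr_for_caax(orf, alt)
    props = propose_junction(orf, alt, hit, truth.junction["caax_terminus"])
    assert props[0].rank == 1
    assert (props[0].donor, props[0].acceptor) == (
        truth.junction["donor"],
        truth.junction["acceptor"],
    )
    # the chimeric terminus equals the true CaaX-variant terminus
    assert props[0].cterm == truth.proteins[0][-30:]


def test_junction_chimeras_always_keep_a_cysteine_tetrapeptide():
    truth = make_lamin_gene(
        SimConfig(seed=43, n_exons=4, terminus_mode="terebellid_dual")
    )
    alt = truth.transcripts[1]
    orf = annotate_orf(alt)
    (hit,) = scan_utr_for_caax(orf, alt)
    props = propose_junction(orf, alt, hit, truth.junction["caax_terminus"])
    assert props
    for p in props:
        assert call_caax(p.cterm).status != NO_CAAX
        # rebuild the chimeric mRNA and re-annotate it end to end
        chim = (
            alt.sequence[: p.donor]
            + alt.sequence[p.acceptor : hit.stop_position + 3]
        )
        orf2 = annotate_orf(_tx(chim), min_codons=10)
        assert call_caax(orf2.protein).status != NO_CAAX


def test_true_homolog_outscores_shuffled_homolog():
    truth = make_lamin_gene(
        SimConfig(seed=47, n_exons=5, terminus_mode="terebellid_dual")
    )
    alt = truth.transcripts[1]
    orf = annotate_orf(alt)
    (hit,) = scan_utr_for_caax(orf, alt)
    true_hom = truth.junction["caax_terminus"]
    rng = np.random.default_rng(0)
    best_true = propose_junction(orf, alt, hit, true_hom)[0].score
    shuffled = "".join(rng.permutation(list(true_hom)))
    best_shuf = propose_junction(orf, alt, hit, shuffled)[0].score
    assert best_true > best_shuf


def test_junction_empty_when_no_compatible_acceptor_exists():
    # a truncated hit (stop too close to the UTR start) admits no acceptor
    seq = "ATG" + "GCT" * 12 + "TAA" + "TGTGTGATCATGTAA"
    tx = _tx(seq)
    orf = annotate_orf(tx, min_codons=5)
    u0 = orf.utr3[0]
    fake = CrypticCaaXHit(
        interval=(u0, u0 + 9), frame=0, peptide="CVI", stop_position=u0 + 9
    )
    assert propose_junction(orf, tx, fake, "A" * 12) == []


def test_junction_requires_long_homolog():
    seq = "ATG" + "GCT" * 12 + "TAA" + "TGTGTGATCATGTAA"
    tx = _tx(seq)
    orf = annotate_orf(tx, min_codons=5)
    (hit,) = scan_utr_for_caax(orf, tx)
    with pytest.raises(ValueError):
        propose_junction(orf, tx, hit, "SHORT")


def test_translate_matches_biopython_on_random_sequences(rng):
    for _ in range(20):
        n = int(rng.integers(3, 120))
        dna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        assert translate(dna) == str(Seq(dna[: n - n % 3]).translate())
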
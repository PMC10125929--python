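"""Spliced alignment, intron phases, reference comparison, splice variants."""

import numpy as np
import pytest

from lamterm.gene_structure import (
    GeneModel,
    compare_intron_positions,
    enumerate_splice_variants,
    intron_phases,
    spliced_align,
)
from lamterm.seqio import SeqRecord
from lamterm.synthetic_data import SimConfig, make_lamin_gene
from lamterm.transcript_analysis import annotate_orf


def _align(truth):
    return spliced_align(truth.transcripts[-1], truth.genome)


# -- spliced_align ----------------------------------------------------------


def test_intronless_gene_yields_single_exon_model():
    truth = make_lamin_gene(SimConfig(seed=51, n_exons=1))
    model = _align(truth)
    assert model.exons == truth.model.exons
    assert len(model.exons) == 1


def test_twelve_exon_gene_recovered_exactly():
    truth = make_lamin_gene(SimConfig(seed=52, n_exons=12))
    model = _align(truth)
    assert model.exons == truth.model.exons
    assert len(model.introns) == 11
    assert model.mismatches == []
    assert model.noncanonical_introns == []


def test_exon_lengths_conserve_transcript_length():
    for seed in (53, 54, 55):
        truth = make_lamin_gene(SimConfig(seed=seed, n_exons=7))
        model = _align(truth)
        assert model.spliced_length() == len(truth.transcripts[-1])
        assert model.spliced_sequence(truth.genome) == truth.transcripts[-1].sequence


def test_single_mismatch_reported_with_same_structure():
    truth = make_lamin_gene(SimConfig(seed=56, n_exons=6))
    tx = truth.transcripts[-1]
    # mutate one base in the middle of the first exon
    mid = (truth.model.exons[0][1] - truth.model.exons[0][0]) // 2
    base = tx.sequence[mid]
    sub = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
    mutated = SeqRecord(
        id=tx.id, sequence=tx.sequence[:mid] + sub + tx.sequence[mid + 1 :],
        alphabet="dna",
    )
    model = spliced_align(mutated, truth.genome)
    assert model.exons == truth.model.exons
    assert model.mismatches == [mid]


def test_unrelated_transcript_is_an_error():
    truth = make_lamin_gene(SimConfig(seed=57, n_exons=3))
    rng = np.random.default_rng(1)
    junk = SeqRecord(
        id="junk",
        sequence="".join("ACGT"[i] for i in rng.integers(0, 4, size=400)),
        alphabet="dna",
    )
    with pytest.raises(ValueError, match="no confident gene model"):
        spliced_align(junk, truth.genome)


def test_roundtrip_batch_with_varying_exon_counts(rng):
    ok = 0
    for _ in range(20):
        n = int(rng.integers(2, 15))
        truth = make_lamin_gene(
            SimConfig(seed=int(rng.integers(0, 2**31)), n_exons=n)
        )
        model = _align(truth)
        assert len(model.introns) == len(model.exons) - 1
        if model.exons == truth.model.exons:
            ok += 1
    assert ok >= 19


# -- intron phases ----------------------------------------------------------


def test_intron_phase_arithmetic():
    # single intron exactly after CDS nucleotide 300 -> codon 100, phase 0
    truth = make_lamin_gene(
        SimConfig(seed=58, n_exons=2, intron_cds_positions=[300], n_codons=150)
    )
    tx = truth.transcripts[-1]
    orf = annotate_orf(tx)
    (rec,) = intron_phases(truth.model, orf, truth.genome)
    assert (rec.cds_position, rec.codon_index, rec.phase) == (300, 100, 0)
    assert rec.location == "cds"
    assert rec.donor == "GT" and rec.acceptor == "AG"


def test_planted_phases_recovered_exactly():
    truth = make_lamin_gene(
        SimConfig(
            seed=59, n_exons=4, intron_cds_positions=[90, 121, 203], n_codons=100
        )
    )
    orf = annotate_orf(truth.transcripts[-1])
    recs = intron_phases(truth.model, orf, truth.genome)
    assert [(r.codon_index, r.phase) for r in recs] == [(30, 0), (40, 1), (67, 2)]
    assert [(r.codon_index, r.phase) for r in recs] == truth.intron_cds


def test_split_terminal_codon_has_phase_one_at_final_codon():
    truth = make_lamin_gene(
        SimConfig(
            seed=60, n_exons=6, terminus_mode="aromatic_alternative",
            split_terminal_codon=True,
        )
    )
    orf = annotate_orf(truth.transcripts[-1])
    recs = intron_phases(truth.model, orf, truth.genome)
    last = recs[-1]
    n_codons = len(orf.protein)
    assert last.phase == 1
    assert last.codon_index == n_codons - 1
    # and the deduced model agrees
    model = _align(truth)
    assert model.exons == truth.model.exons


def test_utr_resident_introns_are_flagged():
    truth = make_lamin_gene(
        SimConfig(seed=61, n_exons=5, terminus_mode="terebellid_dual")
    )
    alt = truth.transcripts[1]
    orf = annotate_orf(alt)
    recs = intron_phases(truth.model, orf, truth.genome)
    assert recs[-1].location == "utr3"
    assert all(r.location == "cds" for r in recs[:-1])


# -- reference comparison ---------------------------------------------------


def _cds_records(truth):
    orf = annotate_orf(truth.transcripts[-1])
    return [
        r for r in intron_phases(truth.model, orf, truth.genome)
        if r.location == "cds"
    ]


def test_reference_comparison_full_match():
    truth = make_lamin_gene(SimConfig(seed=62, n_exons=8))
    recs = _cds_records(truth)
    refs = [(r.codon_index, r.phase) for r in recs]
    report = compare_intron_positions(recs, refs)
    assert len(report.matched) == len(recs)
    assert report.unmatched_records == [] and report.unmatched_references == []


def test_extra_intron_left_unmatched():
    # archetypal references miss one intron (the protostome-specific case)
    truth = make_lamin_gene(SimConfig(seed=63, n_exons=8))
    recs = _cds_records(truth)
    refs = [(r.codon_index, r.phase) for r in recs[:1] + recs[2:]]
    report = compare_intron_positions(recs, refs)
    assert len(report.unmatched_records) == 1
    assert report.unmatched_records[0].index == recs[1].index


def test_empty_reference_list_matches_nothing():
    truth = make_lamin_gene(SimConfig(seed=64, n_exons=5))
    recs = _cds_records(truth)
    report = compare_intron_positions(recs, [])
    assert report.matched == []
    assert len(report.unmatched_records) == len(recs)


def test_codon_tolerance_window():
    truth = make_lamin_gene(SimConfig(seed=65, n_exons=3))
    recs = _cds_records(truth)
    refs = [(r.codon_index + 1, r.phase) for r in recs]
    assert compare_intron_positions(recs, refs, tol=0).matched == []
    assert len(compare_intron_positions(recs, refs, tol=1).matched) == len(recs)


# -- splice variants --------------------------------------------------------


def _variant_truth(seed, k):
    return make_lamin_gene(
        SimConfig(
            seed=seed, n_exons=10 + k, n_cassettes=k,
            terminus_mode="aromatic_alternative",
        )
    )


@pytest.mark.parametrize("k,n_variants", [(0, 1), (1, 2), (2, 4)])
def test_variant_counts_are_two_to_the_k(k, n_variants):
    truth = _variant_truth(70 + k, k)
    variants = enumerate_splice_variants(
        truth.model, truth.cassette_indices, truth.genome
    )
    assert len(variants) == n_variants
    # ascending bitmask order, matching the generator's truth transcripts
    assert [v.mrna for v in variants] == [t.sequence for t in truth.transcripts]
    assert [v.protein for v in variants] == truth.proteins


def test_variants_share_terminal_exon_suffix():
    truth = _variant_truth(74, 2)
    variants = enumerate_splice_variants(
        truth.model, truth.cassette_indices, truth.genome
    )
    assert len({v.terminus for v in variants}) == 1


def test_cassette_index_must_be_internal():
    truth = _variant_truth(75, 1)
    last = len(truth.model.exons) - 1
    for bad in (0, last):
        with pytest.raises(ValueError, match="internal"):
            enumerate_splice_variants(truth.model, [bad], truth.genome)


def test_gene_model_invariants_on_truth():
    truth = _variant_truth(76, 2)
    m = truth.model
    assert all(e1 <= s2 for (_, e1), (s2, _) in zip(m.exons, m.exons[1:]))
    assert all(s2 - e1 >= 60 for (_, e1), (s2, _) in zip(m.exons, m.exons[1:]))
    assert m.spliced_length() == len(truth.transcripts[-1])
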
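"""Per-protein C-terminal feature calling.

The statistics implemented here are the ones used in surveys of lamin
C-termini: the five-category residue composition of the last 10 residues,
tiered CaaX-motif calling with prenylation-competence rules, a monopartite
NLS heuristic, and a two-type classification of alternative (CaaX-less)
termini into aromatic-rich and aliphatic-rich kinds.

Residue categories (fixed, pairwise disjoint, deliberately not covering all
20 amino acids): aliphatic {I, L, V}, aromatic {F, W, Y}, positive {K, R, H},
negative {D, E}, tiny {G, A, S}. M, C, N, Q, P and T are uncategorized, so
the five percentages need not sum to 100.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from lamterm.seqio import AA20, SeqRecord

#: The five residue categories of the composition statistic.
RESIDUE_CATEGORIES: dict[str, frozenset[str]] = {
    "aliph": frozenset("ILV"),
    "arom": frozenset("FWY"),
    "pos": frozenset("KRH"),
    "neg": frozenset("DE"),
    "tiny": frozenset("GAS"),
}

# CaaX calling -------------------------------------------------------------

#: X residues accepted for a fully prenylation-competent (canonical) call.
#: Methionine is the textbook X of the lamin CaaX; serine, glutamine, alanine
#: and cysteine are the other X residues farnesyltransferase handles well
#: (and lamins ending CIIS are accepted as CaaX lamins in the field).
CANONICAL_X = frozenset("MSQAC")
#: Permissive a-position set. Strictly aliphatic a-residues cannot be the
#: operative rule: bona fide CaaX lamins ending CSLM/CSVM put serine at a1.
PERMISSIVE_A = frozenset("ACFGILMSTV")
STRICT_A = frozenset("ILV")
#: Charged X residues that block the farnesyltransferase specificity pocket.
#: Only the negatively charged ones are disqualifying; a positive X is left
#: as ambiguous rather than ruled out.
BLOCKING_X = frozenset("DE")

CANONICAL_CAAX = "canonical_caax"
CAAX_LIKE_NONPRENYLATABLE = "caax_like_nonprenylatable"
CAAX_LIKE_AMBIGUOUS = "caax_like_ambiguous"
NO_CAAX = "no_caax"


def _round_half_up(x: float) -> int:
    # round half away from zero; inputs are non-negative here
    return int(x + 0.5)


@dataclass
class TerminusProfile:
    """Residue-category composition of a C-terminal peptide."""

    peptide: str
    n: int
    counts: dict[str, int]
    percents: dict[str, int]

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return tuple(self.percents[c] for c in RESIDUE_CATEGORIES)


@dataclass
class CaaXCall:
    """Tiered CaaX-motif status of the last four residues of a peptide."""

    status: str
    cys_position: int | None = None  # offset -4, or None
    a1: str | None = None
    a2: str | None = None
    x: str | None = None
    reason: str = ""


@dataclass
class NLSHit:
    start: int  # 0-based position of the K(K|R)X(K|R) core
    motif: str


@dataclass
class ClassifierThresholds:
    """Cutoffs of the two-type alternative-terminus classification."""

    aromatic_min_arom: int = 20
    aromatic_max_neg: int = 10
    aliphatic_min_aliph: int = 40
    aliphatic_max_arom: int = 0


@dataclass
class TerminusClass:
    label: str  # caax | aromatic_alternative | aliphatic_alternative | other
    profile: TerminusProfile = None
    call: CaaXCall = None


def _as_peptide(record) -> str:
    if isinstance(record, SeqRecord):
        return record.sequence
    return str(record).upper()


def extract_cterm(record, n: int = 10) -> str:
    """Last ``n`` residues of a protein (the full sequence if shorter).

    A shorter-than-``n`` input is profiled over its actual length rather than
    padded; a warning marks the truncation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = _as_peptide(record)
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) < n:
        warnings.warn(
            f"sequence shorter than {n} residues; using all {len(seq)}",
            stacklevel=2,
        )
    return seq[-n:]


def composition_profile(peptide) -> TerminusProfile:
    """Five-category composition of a peptide, in counts and percentages.

    Percentages are ``round(100 * count / len(peptide))``, rounding half away
    from zero; with the default 10-residue window they are exact multiples
    of 10.
    """
    pep = _as_peptide(peptide)
    if not pep:
        raise ValueError("empty peptide")
    bad = set(pep) - AA20
    if bad:
        raise ValueError(f"invalid amino acids {sorted(bad)} in {pep!r}")
    n = len(pep)
    counts = {
        cat: sum(1 for aa in pep if aa in members)
        for cat, members in RESIDUE_CATEGORIES.items()
    }
    percents = {cat: _round_half_up(100 * c / n) for cat, c in counts.items()}
    return TerminusProfile(peptide=pep, n=n, counts=counts, percents=percents)


def call_caax(peptide, strict_a: bool = False) -> CaaXCall:
    """Classify the last four residues of a peptide as a CaaX motif (or not).

    Tiers:

    * ``canonical_caax`` — cysteine at -4, both a-positions in the permissive
      a-set and X in {M, S, Q, A, C}: a prenylation-competent motif.
    * ``caax_like_nonprenylatable`` — cysteine at -4 but X in {D, E}; the
      negatively charged X cannot be accommodated by farnesyltransferase, so
      the motif cannot be prenylated (e.g. the rotifer CSEE terminus).
    * ``caax_like_ambiguous`` — cysteine at -4, neither of the above.
    * ``no_caax`` — no cysteine at -4.

    ``strict_a=True`` restricts the a-positions to {I, L, V}.
    """
    pep = _as_peptide(peptide)
    if len(pep) < 4:
        raise ValueError("peptide shorter than 4 residues")
    c, a1, a2, x = pep[-4:]
    if c != "C":
        return CaaXCall(status=NO_CAAX, reason="no cysteine at position -4")
    a_set = STRICT_A if strict_a else PERMISSIVE_A
    if x in BLOCKING_X:
        return CaaXCall(
            status=CAAX_LIKE_NONPRENYLATABLE,
            cys_position=-4,
            a1=a1,
            a2=a2,
            x=x,
            reason="charged-X: negatively charged X blocks farnesyltransferase",
        )
    if x in CANONICAL_X and a1 in a_set and a2 in a_set:
        return CaaXCall(
            status=CANONICAL_CAAX, cys_position=-4, a1=a1, a2=a2, x=x,
            reason="prenylation-competent CaaX",
        )
    return CaaXCall(
        status=CAAX_LIKE_AMBIGUOUS,
        cys_position=-4,
        a1=a1,
        a2=a2,
        x=x,
        reason="cysteine at -4 but non-canonical a/X residues",
    )


#: Core of the monopartite NLS heuristic: K followed by K/R, any residue,
#: then K/R (the SV40-type pattern).
NLS_CORE = re.compile("K[KR].[KR]")


def find_nls(record, min_basic_in_window: int = 4) -> list[NLSHit]:
    """Scan a protein for monopartite NLS candidates.

    Matches of the K(K|R)X(K|R) core are accepted when the six-residue window
    made of the core plus one flanking residue on each side contains at least
    ``min_basic_in_window`` K/R residues. Matches are reported leftmost-first
    and non-overlapping. This is a declared heuristic, not ground truth; the
    published NLS annotations in the packaged tables are fixture data.
    """
    seq = _as_peptide(record)
    hits: list[NLSHit] = []
    pos = 0
    while True:
        m = NLS_CORE.search(seq, pos)
        if m is None:
            break
        lo = max(0, m.start() - 1)
        hi = min(len(seq), m.end() + 1)
        window = seq[lo:hi]
        if sum(1 for aa in window if aa in "KR") >= min_basic_in_window:
            hits.append(NLSHit(start=m.start(), motif=m.group()))
            pos = m.end()
        else:
            pos = m.start() + 1
    return hits


def classify_terminus(
    profile: TerminusProfile,
    call: CaaXCall,
    thresholds: ClassifierThresholds | None = None,
) -> TerminusClass:
    """Two-type classification of a lamin C-terminus.

    Precedence: a canonical CaaX motif wins regardless of composition. An
    alternative terminus is ``aromatic_alternative`` when aromatic residues
    reach 20% with at most 10% negatively charged residues (the W/F-rich type
    of monogononts, cephalopods and sedentary annelids), and
    ``aliphatic_alternative`` when aliphatic residues reach 40% with no
    aromatic residues at all (the bdelloid type). Everything else is
    ``other``.
    """
    t = thresholds or ClassifierThresholds()
    if call.status == CANONICAL_CAAX:
        return TerminusClass(label="caax", profile=profile, call=call)
    p = profile.percents
    if p["arom"] >= t.aromatic_min_arom and p["neg"] <= t.aromatic_max_neg:
        return TerminusClass(label="aromatic_alternative", profile=profile, call=call)
    if p["aliph"] >= t.aliphatic_min_aliph and p["arom"] <= t.aliphatic_max_arom:
        return TerminusClass(label="aliphatic_alternative", profile=profile, call=call)
    return TerminusClass(label="other", profile=profile, call=call)
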
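"""Sequence and table input/output.

FASTA reading/writing goes through Biopython; the C-terminus tables packaged
with ``lamterm`` (transcribed from published composition surveys of rotifer,
cephalopod and annelid lamin C-termini) are plain TSV loaded with pandas.
Gene models are written as GFF3 with a gene/mRNA/exon/CDS hierarchy.

Coordinate convention: everything in memory is 0-based half-open; GFF3 output
is 1-based inclusive, as the standard requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO as _bio_seqio
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_CHARS = frozenset("ACGTN")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: TSV column names of the packaged terminus tables.
TABLE_COLUMNS = ("clade", "species", "cterm", "aliph", "arom", "pos", "neg", "tiny")
PERCENT_COLUMNS = ("aliph", "arom", "pos", "neg", "tiny")


@dataclass
class SeqRecord:
    """A named sequence with a declared alphabet and free-form metadata."""

    id: str
    sequence: str
    description: str = ""
    metadata: dict = field(default_factory=dict)
    alphabet: str = "auto"  # "dna" | "protein" | "auto"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.alphabet == "auto":
            self.alphabet = "dna" if set(self.sequence) <= DNA_CHARS else "protein"
        allowed = DNA_CHARS if self.alphabet == "dna" else PROTEIN_CHARS
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} invalid for "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SeqRecord":
        """Reverse-complement a DNA record, recording the flip in metadata.

        Internally only forward-strand gene models are produced; minus-strand
        genomic input is flipped at load time and flagged here.
        """
        if self.alphabet != "dna":
            raise ValueError("reverse_complement is only defined for DNA records")
        meta = dict(self.metadata)
        meta["reverse_complemented"] = not meta.get("reverse_complemented", False)
        return SeqRecord(
            id=self.id,
            sequence=str(Seq(self.sequence).reverse_complement()),
            description=self.description,
            metadata=meta,
            alphabet="dna",
        )


def read_fasta(path, alphabet: str = "auto") -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Sequences are uppercased and input order is preserved. Duplicate ids are
    deduplicated by appending ``.2``, ``.3``, ... with a warning; an empty
    file or an empty sequence raises ``ValueError``.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: dict[str, int] = {}
    for rec in _bio_seqio.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has no sequence")
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.{seen[rid]}"
            warnings.warn(
                f"{path}: duplicate id {rid!r} renamed to {new_id!r}", stacklevel=2
            )
            rid = new_id
        else:
            seen[rid] = 1
        records.append(
            SeqRecord(
                id=rid,
                sequence=seq,
                description=rec.description,
                alphabet=alphabet,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> None:
    """Write records as FASTA (fixed line width for reproducible output)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _bio_seqio.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def load_genomic(path, strand: str = "+") -> SeqRecord:
    """Load a single genomic contig; ``strand='-'`` reverse-complements it."""
    records = read_fasta(path, alphabet="dna")
    if len(records) != 1:
        raise ValueError(f"{path}: expected a single genomic contig")
    rec = records[0]
    return rec.reverse_complement() if strand == "-" else rec


# ---------------------------------------------------------------------------
# Terminus tables
# ---------------------------------------------------------------------------


@dataclass
class TerminusRow:
    """One species row of a C-terminus table."""

    clade: str
    species: str
    cterm: str
    percentages: dict[str, int] | None
    cys_marked: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class TerminusTable:
    """A parsed C-terminus table (one row per lamin C-terminus)."""

    rows: list[TerminusRow]
    source: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        data = []
        for r in self.rows:
            row = {"clade": r.clade, "species": r.species, "cterm": r.cterm}
            if r.percentages is not None:
                row.update(r.percentages)
            row.update(r.extra)
            data.append(row)
        return pd.DataFrame(data)


def _parse_cterm(cell: str, where: str) -> tuple[str, bool]:
    # ``**C**`` marks the cysteine that is printed in bold in the source
    # table (the non-prenylatable CSEE terminus); strip the marks, keep a flag.
    marked = "**" in cell
    pep = cell.replace("**", "").replace("*", "").strip()
    bad = set(pep) - AA20
    if bad:
        raise ValueError(f"{where}: invalid amino acids {sorted(bad)} in {cell!r}")
    return pep, marked


def load_terminus_table(path) -> TerminusTable:
    """Load a TSV terminus table.

    Required columns: ``clade``, ``species``, ``cterm``. The five percentage
    columns (``aliph``, ``arom``, ``pos``, ``neg``, ``tiny``) are optional as
    a block; when present each value must be an integer in [0, 100]. Any
    other columns are kept verbatim in ``TerminusRow.extra``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("clade", "species", "cterm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_percent = all(c in df.columns for c in PERCENT_COLUMNS)
    rows: list[TerminusRow] = []
    for _, rec in df.iterrows():
        where = f"{path.name} row {rec['species']!r}"
        pep, marked = _parse_cterm(str(rec["cterm"]), where)
        percentages = None
        if has_percent:
            percentages = {}
            for cat in PERCENT_COLUMNS:
                cell = rec[cat]
                try:
                    val = int(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{where}: malformed percentage {cell!r} in column {cat!r}"
                    ) from None
                if not 0 <= val <= 100:
                    raise ValueError(
                        f"{where}: percentage {val} out of [0, 100] in column {cat!r}"
                    )
                percentages[cat] = val
        extra = {
            c: rec[c]
            for c in df.columns
            if c not in TABLE_COLUMNS
        }
        rows.append(
            TerminusRow(
                clade=str(rec["clade"]),
                species=str(rec["species"]),
                cterm=pep,
                percentages=percentages,
                cys_marked=marked,
                extra=extra,
            )
        )
    if not rows:
        warnings.warn(f"{path}: header-only table, no rows parsed", stacklevel=2)
    return TerminusTable(rows=rows, source=str(path))


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file (e.g. ``table3.tsv``)."""
    ref = resources.files("lamterm") / "fixtures" / name
    with resources.as_file(ref) as p:
        return Path(p)


def load_fixture_table(name: str) -> TerminusTable:
    """Load one of the packaged tables: ``table1`` ... ``table4``."""
    if not name.endswith(".tsv"):
        name = f"{name}.tsv"
    return load_terminus_table(fixture_path(name))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(models: Sequence, path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS hierarchy).

    ``models`` duck-types :class:`lamterm.gene_structure.GeneModel`: each needs
    ``genomic_id``, ``transcript_id``, ``exons`` (0-based half-open genomic
    intervals) and optionally ``cds_offset``/``cds_length`` (spliced-transcript
    coordinates) from which CDS segments, including codons split across exons,
    are projected onto the genome. Coordinates are emitted 1-based inclusive.
    """
    lines = ["##gff-version 3"]
    for n, model in enumerate(models, start=1):
        exons = list(model.exons)
        if not exons:
            raise ValueError(f"model {n}: at least one exon required")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"model {n}: overlapping/unsorted exons {e1} > {s2}"
                )
        gid = f"gene{n}"
        mid = f"mrna{n}"
        start, end = exons[0][0] + 1, exons[-1][1]
        seqid = model.genomic_id
        lines.append(
            f"{seqid}\tlamterm\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}"
        )
        lines.append(
            f"{seqid}\tlamterm\tmRNA\t{start}\t{end}\t.\t+\t.\t"
            f"ID={mid};Parent={gid};transcript_id={model.transcript_id}"
        )
        for i, (s, e) in enumerate(exons, start=1):
            lines.append(
                f"{seqid}\tlamterm\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID={mid}.exon{i};Parent={mid}"
            )
        cds_offset = getattr(model, "cds_offset", None)
        cds_length = getattr(model, "cds_length", None)
        if cds_offset is not None and cds_length:
            # project the spliced CDS interval onto genomic exon pieces
            spliced = 0
            cds_end = cds_offset + cds_length
            done = 0  # CDS nucleotides already emitted, drives the phase field
            j = 0
            for s, e in exons:
                lo = max(cds_offset, spliced)
                hi = min(cds_end, spliced + (e - s))
                if lo < hi:
                    j += 1
                    gs = s + (lo - spliced)
                    ge = s + (hi - spliced)
                    phase = (3 - done % 3) % 3
                    lines.append(
                        f"{seqid}\tlamterm\tCDS\t{gs + 1}\t{ge}\t.\t+\t{phase}\t"
                        f"ID={mid}.cds{j};Parent={mid}"
                    )
                    done += hi - lo
                spliced += e - s
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3_exons(path) -> dict[str, list[tuple[int, int]]]:
    """Re-parse a GFF3 file into {mRNA id: [0-based half-open exon intervals]}.

    Uses :mod:`gffutils` so the round trip is checked against an independent
    GFF3 parser rather than this module's own writer conventions.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    out: dict[str, list[tuple[int, int]]] = {}
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="exon")
        )
        out[mrna.id] = exons
    return out
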
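"""Pipeline orchestration and paper-style reports.

Ties the stages together behind one :class:`RunConfig`: per-protein
classification, per-clade composition tables in the layout of the published
C-terminus tables, identity-threshold consensus per clade, optional gene
structure output, and a machine-readable JSON summary. Reruns on identical
inputs produce byte-identical outputs (no timestamps outside the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

import lamterm
from lamterm import seqio
from lamterm.consensus import consensus_of
from lamterm.gene_structure import spliced_align
from lamterm.terminus_features import (
    ClassifierThresholds,
    call_caax,
    classify_terminus,
    composition_profile,
    extract_cterm,
    find_nls,
)
from lamterm.transcript_analysis import annotate_orf

log = logging.getLogger("lamterm")

_FIXTURE_NAMES = {"table1", "table2", "table3", "table4"}


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    proteins_fasta: str | None = None
    tables: list[str] = field(default_factory=list)  # paths or fixture names
    transcript_fasta: str | None = None
    genome_fasta: str | None = None
    out_dir: str = "lamterm_out"
    window_n: int = 10
    consensus_high: float = 0.90
    consensus_low: float = 0.50
    min_group_size: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.window_n < 4:
            raise ValueError("composition window n must be >= 4")
        if not 0 < self.consensus_low <= self.consensus_high <= 1:
            raise ValueError("consensus thresholds must satisfy 0 < low <= high <= 1")


@dataclass
class Discrepancy:
    """A table row whose printed percentages disagree with recomputation."""

    clade: str
    species: str
    cterm: str
    printed: dict[str, int]
    recomputed: dict[str, int]


@dataclass
class ReportBundle:
    out_dir: Path
    files: dict[str, Path]
    summary: dict


def classify_records(
    records, n: int = 10, thresholds: ClassifierThresholds | None = None
) -> pd.DataFrame:
    """One row per protein: terminus, composition, CaaX status, class, NLS."""
    rows = []
    for rec in records:
        cterm = extract_cterm(rec, n)
        profile = composition_profile(cterm)
        if len(rec.sequence) >= 4:
            call = call_caax(rec.sequence)
        else:
            from lamterm.terminus_features import NO_CAAX, CaaXCall

            call = CaaXCall(status=NO_CAAX, reason="sequence shorter than 4")
        cls = classify_terminus(profile, call, thresholds)
        nls = find_nls(rec)
        rows.append(
            {
                "id": rec.id,
                "cterm": cterm,
                **profile.percents,
                "caax_status": call.status,
                "terminus_class": cls.label,
                "nls_hits": ";".join(f"{h.start}:{h.motif}" for h in nls),
            }
        )
    return pd.DataFrame(rows)


def discrepancy_report(table: seqio.TerminusTable) -> list[Discrepancy]:
    """Rows whose printed percentages differ from recomputation.

    Recomputes the five-category composition over the printed C-terminus
    (last 10 residues) and compares with the printed values; rows without
    printed percentages are skipped.
    """
    out: list[Discrepancy] = []
    for row in table:
        if row.percentages is None:
            continue
        prof = composition_profile(extract_cterm(row.cterm, 10))
        if prof.percents != row.percentages:
            out.append(
                Discrepancy(
                    clade=row.clade,
                    species=row.species,
                    cterm=row.cterm,
                    printed=dict(row.percentages),
                    recomputed=dict(prof.percents),
                )
            )
    return out


def _resolve_table(name: str) -> seqio.TerminusTable:
    if name in _FIXTURE_NAMES:
        return seqio.load_fixture_table(name)
    return seqio.load_terminus_table(name)


def _header(config: RunConfig) -> str:
    params = "; ".join(f"{k}={v}" for k, v in sorted(asdict(config).items()))
    return f"# lamterm {lamterm.__version__}\n# {params}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every configured stage and write the report bundle.

    Stage errors propagate as ``RuntimeError`` naming the failing stage.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    log.info("run parameters: %s", asdict(config))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    summary: dict = {
        "version": lamterm.__version__,
        "parameters": asdict(config),
        "stages": {},
    }

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r}: {exc}") from exc
        return wrap

    if config.proteins_fasta:
        @_stage("classify")
        def _():
            records = seqio.read_fasta(config.proteins_fasta, alphabet="protein")
            df = classify_records(records, n=config.window_n)
            path = out / "classification.tsv"
            _write_tsv(df, path, config)
            files["classification"] = path
            summary["stages"]["classify"] = {
                "n_records": len(df),
                "classes": df["terminus_class"].value_counts().to_dict(),
            }

    discrepancies_all = []
    for name in config.tables:
        stem = Path(name).stem

        @_stage(f"composition:{stem}")
        def _(name=name, stem=stem):
            table = _resolve_table(name)
            rows = []
            for r in table:
                prof = composition_profile(extract_cterm(r.cterm, config.window_n))
                rows.append(
                    {"clade": r.clade, "species": r.species, "cterm": r.cterm,
                     **prof.percents}
                )
            df = pd.DataFrame(rows)
            path = out / f"composition_{stem}.tsv"
            _write_tsv(df, path, config)
            files[f"composition_{stem}"] = path

            disc = discrepancy_report(table)
            discrepancies_all.extend(
                {"table": stem, "clade": d.clade, "species": d.species,
                 "cterm": d.cterm,
                 **{f"printed_{k}": v for k, v in d.printed.items()},
                 **{f"recomputed_{k}": v for k, v in d.recomputed.items()}}
                for d in disc
            )

            blocks = []
            for clade, group in df.groupby("clade", sort=True):
                peps = list(group["cterm"])
                if len(peps) < config.min_group_size:
                    continue
                res = consensus_of(
                    peps, high=config.consensus_high, low=config.consensus_low
                )
                blocks.append(f"{clade}\t{res.consensus}")
            cpath = out / f"consensus_{stem}.tsv"
            with open(cpath, "w") as fh:
                fh.write(_header(config))
                fh.write("clade\tconsensus\n")
                fh.write("\n".join(blocks) + ("\n" if blocks else ""))
            files[f"consensus_{stem}"] = cpath
            summary["stages"][f"table:{stem}"] = {
                "n_rows": len(df),
                "n_discrepancies": len(disc),
            }

    if config.tables:
        dpath = out / "discrepancies.tsv"
        ddf = pd.DataFrame(discrepancies_all)
        _write_tsv(ddf, dpath, config)
        files["discrepancies"] = dpath
        summary["stages"]["discrepancies"] = {"n": len(discrepancies_all)}

    if config.transcript_fasta and config.genome_fasta:
        @_stage("genestructure")
        def _():
            genome = seqio.load_genomic(config.genome_fasta)
            models = []
            for tx in seqio.read_fasta(config.transcript_fasta, alphabet="dna"):
                orf = annotate_orf(tx)
                model = spliced_align(
                    tx, genome, cds_offset=orf.cds[0], cds_length=orf.cds_length
                )
                models.append(model)
            path = out / "gene_models.gff3"
            seqio.write_gff3(models, path)
            files["gene_models"] = path
            summary["stages"]["genestructure"] = {
                "n_models": len(models),
                "exon_counts": [len(m.exons) for m in models],
            }

    jpath = out / "summary.json"
    with open(jpath, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["summary"] = jpath
    return ReportBundle(out_dir=out, files=files, summary=summary)
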
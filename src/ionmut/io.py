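"""Readers and writers for the pipeline's plain-text formats.

FASTA input/output goes through Biopython.  Tabular inputs are TSVs: a
mutation catalog (allele, gene, type code, size, base change, position), a
wild-type/mutant pair catalog, partial-junction rows, and cohort screening
counts.  Catalog positions use the TAIR-style notation
``Chr.4: 5,724,273-74``: 1-based, thousands separators allowed, and range
ends may be truncated to their differing digits (expanded here by
digit-prefix substitution).

Reference fixtures (the published mutation catalog, junction sequence
pairs, partial junctions and screening cohorts) ship with the package and
load via the ``load_*`` helpers.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .junctions import AmpliconPair, PartialJunction
from .spectrum import CohortCounts

logger = logging.getLogger("ionmut")

__all__ = [
    "CatalogRow",
    "FastaRecord",
    "IOFormatError",
    "RunConfig",
    "load_cohorts",
    "load_junction_pairs",
    "load_partial_junctions",
    "load_reference_catalog",
    "parse_position",
    "read_catalog",
    "read_cohorts",
    "read_fasta",
    "read_pairs_fasta",
    "read_pairs_tsv",
    "read_partial_junctions",
    "run_pipeline",
    "write_calls_tsv",
    "write_fasta",
    "write_vcf_like",
]


class IOFormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# FASTA

@dataclass
class FastaRecord:
    """One FASTA record; ``seq`` is uppercased, ``original`` keeps the input case."""

    id: str
    seq: str
    original: str


def read_fasta(path) -> list[FastaRecord]:
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise IOFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise IOFormatError(f"empty FASTA record {rec.id!r} in {path}")
        records.append(FastaRecord(rec.id, raw.upper(), raw))
    return records


def write_fasta(records: Iterable, path) -> None:
    """Write records given as ``(id, seq)`` pairs or :class:`FastaRecord`."""
    out = []
    for rec in records:
        if isinstance(rec, FastaRecord):
            name, seq = rec.id, rec.seq
        else:
            name, seq = rec
        out.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_pairs_fasta(path) -> list[AmpliconPair]:
    """Amplicon pairs from FASTA with two records per allele: ``<id>|wt`` and
    ``<id>|mut``."""
    by_allele: dict[str, dict[str, str]] = {}
    for rec in read_fasta(path):
        if "|" not in rec.id:
            raise IOFormatError(f"record {rec.id!r} lacks the <allele>|wt/mut suffix")
        allele, role = rec.id.rsplit("|", 1)
        if role not in ("wt", "mut"):
            raise IOFormatError(f"record {rec.id!r} has unknown role {role!r}")
        by_allele.setdefault(allele, {})[role] = rec.seq
    pairs = []
    for allele, roles in by_allele.items():
        if set(roles) != {"wt", "mut"}:
            raise IOFormatError(f"allele {allele!r} is missing its wt or mut record")
        pairs.append(AmpliconPair(allele, roles["wt"], roles["mut"]))
    return pairs


# ---------------------------------------------------------------------------
# positions and catalog

_POSITION_RE = re.compile(
    r"^\s*Chr\.?\s*(?P<chrom>\w+)\s*:\s*(?P<start>[\d,]+)\s*(?:-\s*(?P<end>[\d,]+))?\s*$"
)


def parse_position(text: str) -> tuple[Union[int, str], int, int]:
    """Parse ``"Chr.4: 5,724,273-74"`` into ``(4, 5724273, 5724274)``.

    Single positions give ``start == end``.  A range end shorter than the
    start is expanded by substituting its digits for the trailing digits of
    the start (``5,697,598-730,031`` -> end 5,730,031).
    """
    match = _POSITION_RE.match(text)
    if not match:
        raise IOFormatError(f"unparsable position {text!r}")
    chrom: Union[int, str] = match.group("chrom")
    if chrom.isdigit():
        chrom = int(chrom)
    start_digits = match.group("start").replace(",", "")
    start = int(start_digits)
    end_text = match.group("end")
    if end_text is None:
        return chrom, start, start
    end_digits = end_text.replace(",", "")
    if len(end_digits) < len(start_digits):
        end_digits = start_digits[: len(start_digits) - len(end_digits)] + end_digits
    end = int(end_digits)
    if end < start:
        raise IOFormatError(f"position range end before start in {text!r}")
    return chrom, start, end


@dataclass
class CatalogRow:
    """One catalogued mutation (columns of the published mutation table)."""

    allele_id: str
    gene: str
    type_code: str
    size: Optional[int]
    change: Optional[str]
    let: float
    dose: float
    chrom: Optional[Union[int, str]] = None
    pos_start: Optional[int] = None
    pos_end: Optional[int] = None
    position_text: str = ""
    flags: list = field(default_factory=list)


def _parse_size(text: str) -> Optional[int]:
    text = text.strip().replace(",", "")
    return int(text) if text else None


def read_catalog(path) -> list[CatalogRow]:
    """Read a mutation-catalog TSV.

    Required columns: ``allele_id, gene, type, size, change, position, let,
    dose_gy``.  Rows whose position cannot be parsed are skipped with a log
    entry.  A deletion whose position span disagrees with its size is kept
    but flagged (``size_span_mismatch``), not rejected.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, rec in enumerate(reader, start=2):
            type_code = (rec.get("type") or "").strip()
            row = CatalogRow(
                allele_id=(rec.get("allele_id") or "").strip(),
                gene=(rec.get("gene") or "").strip(),
                type_code=type_code,
                size=_parse_size(rec.get("size") or ""),
                change=(rec.get("change") or "").strip() or None,
                let=float(rec["let"]),
                dose=float(rec["dose_gy"]),
                position_text=(rec.get("position") or "").strip(),
            )
            if row.type_code in ("Del", "Ins") and row.size is None:
                logger.error("%s line %d: %s row lacks a size; skipped",
                             path, lineno, row.type_code)
                continue
            if row.position_text:
                try:
                    row.chrom, row.pos_start, row.pos_end = parse_position(
                        row.position_text
                    )
                except IOFormatError as exc:
                    logger.error("%s line %d: %s; row skipped", path, lineno, exc)
                    continue
                if row.type_code == "Del" and row.size is not None and row.size > 1:
                    span = row.pos_end - row.pos_start + 1
                    if span != row.size:
                        row.flags.append("size_span_mismatch")
                        logger.warning(
                            "%s: deletion size %d vs position span %d for %s",
                            path, row.size, span, row.allele_id,
                        )
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# pair / partial-junction / cohort TSVs

def read_pairs_tsv(path) -> list[AmpliconPair]:
    """Pair catalog TSV: ``allele_id, wt_seq, mut_seq`` (+ optional
    ``chromosome``/``anchor_pos``)."""
    pairs = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            chrom = (rec.get("chromosome") or "").strip() or None
            anchor = (rec.get("anchor_pos") or "").strip()
            pairs.append(
                AmpliconPair(
                    rec["allele_id"].strip(),
                    rec["wt_seq"],
                    rec["mut_seq"],
                    chrom=chrom,
                    anchor_pos=int(anchor) if anchor else None,
                )
            )
    return pairs


def read_partial_junctions(path) -> list[PartialJunction]:
    """Partial-junction TSV: ``allele_id, left_flank, del_prefix, del_suffix,
    right_flank, declared_size``."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                PartialJunction(
                    rec["allele_id"].strip(),
                    rec["left_flank"],
                    rec["del_prefix"],
                    rec["del_suffix"],
                    rec["right_flank"],
                    int(rec["declared_size"].replace(",", "")),
                )
            )
    return rows


def read_cohorts(path) -> list[CohortCounts]:
    """Cohort TSV: ``let, dose_gy, n_m1, n_m2, n_mutants``."""
    cohorts = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            cohorts.append(
                CohortCounts(
                    let=float(rec["let"]),
                    dose=float(rec["dose_gy"]),
                    n_m1=int(rec["n_m1"].replace(",", "")),
                    n_m2=int(rec["n_m2"].replace(",", "")),
                    n_mutants=int(rec["n_mutants"].replace(",", "")),
                )
            )
    return cohorts


# ---------------------------------------------------------------------------
# writers

_CALL_COLUMNS = [
    "allele_id",
    "event_type",
    "size",
    "wt_allele",
    "mut_allele",
    "canonical_start",
    "mh_length",
    "ambiguity_span",
    "genomic_position",
    "note",
]


def write_calls_tsv(calls, path) -> None:
    """Write mutation calls with canonical placement and microhomology.

    ``canonical_start`` is 0-based half-open within the wild-type amplicon;
    ``genomic_position`` (when present) is 1-based inclusive.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_COLUMNS)
        for call in calls:
            gpos = ""
            if call.genomic_position is not None:
                chrom, start, end = call.genomic_position
                gpos = f"Chr.{chrom}:{start}-{end}" if end != start else f"Chr.{chrom}:{start}"
            writer.writerow(
                [
                    call.allele_id,
                    call.event_type,
                    "" if call.size is None else call.size,
                    call.wt_allele,
                    call.mut_allele,
                    "" if call.canonical_start is None else call.canonical_start,
                    call.mh_length,
                    call.ambiguity_span,
                    gpos,
                    call.note,
                ]
            )


def write_vcf_like(calls, pairs, path) -> None:
    """Minimal VCF-style output for anchored calls (CHROM, POS 1-based, REF,
    ALT, INFO with MHLEN).  Calls without a genomic anchor are skipped."""
    pair_by_id = {p.allele_id: p for p in pairs}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MHLEN,Number=1,Type=Integer,Description="Junction microhomology length">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            if call.genomic_position is None or call.event_type in ("none", "complex"):
                continue
            pair = pair_by_id[call.allele_id]
            chrom, start, _end = call.genomic_position
            s = call.canonical_start
            if call.event_type == "substitution":
                pos, ref, alt = start, call.wt_allele, call.mut_allele
            elif call.event_type == "deletion":
                # pad with the preceding base, VCF convention
                pos = start - 1
                ref = pair.wt_seq[s - 1 : s + call.size]
                alt = pair.wt_seq[s - 1]
            else:  # insertion
                pos = start - 1
                ref = pair.wt_seq[s - 1]
                alt = pair.wt_seq[s - 1] + call.mut_allele
            fh.write(
                f"{chrom}\t{pos}\t{call.allele_id}\t{ref}\t{alt}\t.\t.\tMHLEN={call.mh_length}\n"
            )


# ---------------------------------------------------------------------------
# packaged fixtures

_DATA = files("ionmut") / "data"


def _data_path(name: str):
    return _DATA / name


def load_reference_catalog() -> list[CatalogRow]:
    """The published 23-row mutation catalog (22 identified + 1 NM row)."""
    return read_catalog(_data_path("mutation_catalog.tsv"))


def load_junction_pairs() -> list[AmpliconPair]:
    """The fully printed wild-type/mutant junction pairs (10 deletions + 1
    insertion)."""
    return read_pairs_tsv(_data_path("junction_pairs.tsv"))


def load_partial_junctions() -> list[PartialJunction]:
    """The four partially printed deletion junctions."""
    return read_partial_junctions(_data_path("partial_junctions.tsv"))


def load_cohorts() -> list[CohortCounts]:
    """The three published screening cohorts."""
    return read_cohorts(_data_path("cohorts.tsv"))


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """End-to-end run configuration (paths may be None to skip a stage)."""

    out_dir: Union[str, Path]
    pairs_path: Optional[Union[str, Path]] = None
    pairs_fasta: Optional[Union[str, Path]] = None
    partials_path: Optional[Union[str, Path]] = None
    catalog_path: Optional[Union[str, Path]] = None
    cohorts_path: Optional[Union[str, Path]] = None
    threshold: int = 100
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise IOFormatError("threshold must be >= 1")


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write a report bundle.

    Produces a dosimetry table, a call table, a spectrum summary and a
    frequency table under ``config.out_dir``, plus ``report.json`` with
    run metadata and per-row error counts.  Per-row failures are logged
    and counted, not fatal.
    """
    from . import __version__, dosimetry, junctions, spectrum

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    report: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "threshold_bp": config.threshold,
        "kev_to_joule": dosimetry.KEV_TO_JOULE,
        "errors": [],
    }

    pairs: list[AmpliconPair] = []
    if config.pairs_path:
        pairs.extend(read_pairs_tsv(config.pairs_path))
    if config.pairs_fasta:
        pairs.extend(read_pairs_fasta(config.pairs_fasta))

    calls = []
    for pair in pairs:
        try:
            calls.append(junctions.find_event(pair))
        except junctions.JunctionError as exc:
            logger.error("%s: %s", pair.allele_id, exc)
            report["errors"].append({"allele_id": pair.allele_id, "error": str(exc)})
    write_calls_tsv(calls, out_dir / "calls.tsv")
    report["n_calls"] = len(calls)

    partial_mh = {}
    if config.partials_path:
        for pj in read_partial_junctions(config.partials_path):
            try:
                partial_mh[pj.allele_id] = junctions.mh_from_partial(pj)
            except junctions.UndeterminedMicrohomologyError as exc:
                partial_mh[pj.allele_id] = f">={exc.lower_bound}"
        with open(out_dir / "partial_junctions.tsv", "w") as fh:
            fh.write("allele_id\tmh_length\n")
            for allele_id, mh in partial_mh.items():
                fh.write(f"{allele_id}\t{mh}\n")
    report["partial_mh"] = partial_mh

    if config.catalog_path:
        rows = read_catalog(config.catalog_path)
        summaries = spectrum.summarize_spectrum(rows, threshold=config.threshold)
        with open(out_dir / "spectrum.tsv", "w") as fh:
            fh.write(
                "group\tn_small\tpct_small\tn_rearrangement\tpct_rearrangement"
                "\tn_transition\tn_transversion\n"
            )
            for s in sorted(summaries, key=lambda s: s.group_label):
                fh.write(
                    f"{s.group_label}\t{s.n_small}\t{s.pct_small}\t{s.n_rearrangement}"
                    f"\t{s.pct_rearrangement}\t{s.n_transition}\t{s.n_transversion}\n"
                )
        report["n_catalog_rows"] = len(rows)

    if config.cohorts_path:
        cohorts = read_cohorts(config.cohorts_path)
        table = dosimetry.condition_table([(c.let, c.dose) for c in cohorts])
        table.to_csv(out_dir / "dosimetry.tsv", sep="\t", index=False)
        with open(out_dir / "frequencies.tsv", "w") as fh:
            fh.write(
                "let\tdose_gy\tn_m2\tn_mutants\tfrequency_permil"
                "\tci95_low_permil\tci95_high_permil\tci_note\n"
            )
            for c in cohorts:
                est = spectrum.mutation_frequency(c)
                fh.write(
                    f"{c.let}\t{c.dose}\t{c.n_m2}\t{c.n_mutants}\t{est.permil}"
                    f"\t{est.ci_low_permil:.6g}\t{est.ci_high_permil:.6g}"
                    "\tCI is a methodological addition\n"
                )
        report["n_cohorts"] = len(cohorts)

    report["exit_status"] = 1 if report["errors"] else 0
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
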
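"""Readers and writers for the formats the pipeline touches.

Covers: SAM text alignments (reduced record model, reader + writer), FASTQ
(writer, for the simulator), the per-position CSV report, and the consensus
FASTA.  Reference FASTA loading lives in :mod:`circvar.refgenome`.

The SAM reader implements the subset the pipeline consumes: mapped records
with M/I/D/S CIGAR operations.  Unmapped records (FLAG 0x4) and records whose
reference name is absent from the header are skipped and counted (the count is
emitted on the module logger); malformed mandatory fields raise with the
offending line number.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .refgenome import CircularReference

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "PositionRow",
    "REPORT_COLUMNS",
    "read_sam",
    "write_sam",
    "write_fastq",
    "write_position_report",
    "read_position_report",
    "write_consensus",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDSHNP=X])")
_SUPPORTED_OPS = set("MIDS")


@dataclass(slots=True)
class AlignmentRecord:
    """A mapped read in the reduced model the pipeline consumes.

    ``bases`` are given on the forward strand of the reference (SAM
    convention); ``strand`` is ``-`` when FLAG bit 0x10 was set.
    ``base_qualities`` are raw phred values (not ASCII-offset).
    """

    read_id: str
    reference_name: str
    position: int  # 1-based leftmost mapped base
    mapping_quality: int
    strand: str  # '+' or '-'
    cigar: list[tuple[int, str]]
    bases: str
    base_qualities: np.ndarray

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar)

    def reference_span(self) -> int:
        """Number of reference bases consumed (M + D lengths)."""
        return sum(n for n, op in self.cigar if op in "MD")

    def query_length(self) -> int:
        return sum(n for n, op in self.cigar if op in "MIS")

    def validate(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.read_id}: position {self.position} < 1")
        qlen = self.query_length()
        if qlen != len(self.bases) or qlen != len(self.base_qualities):
            raise ValueError(
                f"{self.read_id}: CIGAR query length {qlen} does not match "
                f"{len(self.bases)} bases / {len(self.base_qualities)} qualities"
            )


def parse_cigar(text: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) pairs, restricted to M/I/D/S."""
    if text == "*" or not text:
        raise ValueError("missing CIGAR")
    ops = _CIGAR_RE.findall(text)
    if "".join(f"{n}{op}" for n, op in ops) != text:
        raise ValueError(f"malformed CIGAR {text!r}")
    parsed = [(int(n), op) for n, op in ops]
    unsupported = {op for _, op in parsed if op not in _SUPPORTED_OPS}
    if unsupported:
        raise ValueError(f"unsupported CIGAR operations {sorted(unsupported)} in {text!r}")
    return parsed


def read_sam(path) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a SAM text file.

    Yields :class:`AlignmentRecord` for every mapped record whose reference
    name appears in the header.  Skipped-record counts (unmapped, unknown
    reference) are logged at INFO level once the file is exhausted.

    Raises
    ------
    ValueError
        On malformed mandatory fields, naming the line number.
    """
    known_refs: set[str] = set()
    n_unmapped = 0
    n_unknown_ref = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for f in line.split("\t")[1:]:
                        if f.startswith("SN:"):
                            known_refs.add(f[3:])
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}: line {lineno}: fewer than 11 SAM fields")
            try:
                flag = int(fields[1])
                pos = int(fields[3])
                mapq = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer mandatory field") from exc
            if flag & 0x4:
                n_unmapped += 1
                continue
            rname = fields[2]
            if rname not in known_refs:
                n_unknown_ref += 1
                continue
            seq = fields[9]
            qual = fields[10]
            if seq == "*":
                raise ValueError(f"{path}: line {lineno}: mapped record without sequence")
            try:
                cigar = parse_cigar(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.uint8) - 33
            rec = AlignmentRecord(
                read_id=fields[0],
                reference_name=rname,
                position=pos,
                mapping_quality=mapq,
                strand="-" if flag & 0x10 else "+",
                cigar=cigar,
                bases=seq.upper(),
                base_qualities=quals,
            )
            try:
                rec.validate()
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            yield rec
    if n_unmapped or n_unknown_ref:
        logger.info(
            "read_sam(%s): skipped %d unmapped and %d unknown-reference records",
            path,
            n_unmapped,
            n_unknown_ref,
        )


def write_sam(records: Iterable[AlignmentRecord], ref: CircularReference, path) -> None:
    """Write records as SAM text against a single-sequence header."""
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{ref.name}\tLN:{ref.length}",
    ]
    for rec in records:
        flag = 16 if rec.strand == "-" else 0
        qual = (rec.base_qualities.astype(np.uint8) + 33).tobytes().decode("ascii")
        lines.append(
            "\t".join(
                (
                    rec.read_id,
                    str(flag),
                    rec.reference_name,
                    str(rec.position),
                    str(rec.mapping_quality),
                    rec.cigar_string(),
                    "*",
                    "0",
                    "0",
                    rec.bases,
                    qual,
                )
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write ``(name, sequence, quality-string)`` triples as FASTQ (phred+33)."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Per-position CSV report
# ---------------------------------------------------------------------------

#: Per-sample column block, in report order (the two leading columns of the
#: file are Chrom and Position, shared by all samples).
REPORT_COLUMNS = [
    "Covmp",
    "PercentCov",
    "FilterCov",
    "Ref",
    "Var",
    "Cons",
    "FastA",
    "QDepth",
    "Reads1",
    "Reads2",
    "Freq",
    "Pvalue",
    "StrandFilter",
    "R1+",
    "R1-",
    "R2+",
    "R2-",
]


@dataclass(slots=True)
class PositionRow:
    """One per-sample line of the per-position report.

    ``freq`` and ``percent_cov`` are percentages; ``var`` is a base symbol,
    ``+SEQ`` (insertion anchored here) or ``-SEQ`` (deletion starting at the
    next position), or empty when no variant passed the calling filters.
    ``candidate_var``/``candidate_type`` retain the best alternate allele even
    when it failed the filters (used by the benchmark; not part of the CSV).
    """

    chrom: str
    position: int
    covmp: int
    percent_cov: float
    filter_cov: str  # GOOD / WARNING / EXCLUDE
    ref: str
    var: str  # '' when no passing variant
    cons: str
    fasta: str
    qdepth: int
    reads1: int
    reads2: int
    freq: float  # percent
    p_value: float
    strand_filter: str  # Pass / Fail / NA
    r1_plus: int
    r1_minus: int
    r2_plus: int
    r2_minus: int
    candidate_var: str = ""
    candidate_type: str = "NONE"  # SNV / INS / DEL / NONE

    @property
    def var_type(self) -> str:
        """Type of the reported (passing) variant."""
        if not self.var:
            return "NONE"
        return self.candidate_type

    def copy(self, **changes) -> "PositionRow":
        return replace(self, **changes)


def _format_block(row: PositionRow) -> list:
    return [
        row.covmp,
        f"{row.percent_cov:.2f}",
        row.filter_cov,
        row.ref,
        row.var,
        row.cons,
        row.fasta,
        row.qdepth,
        row.reads1,
        row.reads2,
        f"{row.freq:.2f}",
        f"{row.p_value:.3e}",
        row.strand_filter,
        row.r1_plus,
        row.r1_minus,
        row.r2_plus,
        row.r2_minus,
    ]


def write_position_report(samples, path) -> None:
    """Write the per-position CSV report for one or more samples.

    Parameters
    ----------
    samples:
        Mapping ``sample name -> list[PositionRow]`` (or a list of
        ``(name, rows)`` pairs).  All samples must share one reference: equal
        length and identical position/chrom columns.  With a single sample the
        header uses the bare column names; with several, each sample's block
        is prefixed ``name.Column``.
    """
    items = list(samples.items()) if isinstance(samples, dict) else list(samples)
    if not items:
        raise ValueError("no samples to write")
    first = items[0][1]
    for name, rows in items:
        if len(rows) != len(first):
            raise ValueError(
                f"sample {name!r} has {len(rows)} rows, expected {len(first)}"
            )
        for r, r0 in zip(rows, first):
            if r.position != r0.position or r.chrom != r0.chrom:
                raise ValueError(f"sample {name!r} positions differ from first sample")
    multi = len(items) > 1
    header = ["Chrom", "Position"]
    for name, _ in items:
        prefix = f"{name}." if multi else ""
        header.extend(prefix + c for c in REPORT_COLUMNS)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, r0 in enumerate(first):
            line = [r0.chrom, r0.position]
            for _, rows in items:
                line.extend(_format_block(rows[i]))
            writer.writerow(line)


def read_position_report(path) -> dict[str, list[PositionRow]]:
    """Read back a report written by :func:`write_position_report`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[:2] != ["Chrom", "Position"]:
        raise ValueError("not a per-position report: missing Chrom/Position columns")
    block = len(REPORT_COLUMNS)
    sample_cols = cols[2:]
    if len(sample_cols) % block != 0:
        raise ValueError("column count does not match the report schema")
    names = []
    for i in range(0, len(sample_cols), block):
        first = sample_cols[i]
        if first == "Covmp":
            names.append("")  # single unprefixed sample
        else:
            names.append(first[: -len(".Covmp")])
    out: dict[str, list[PositionRow]] = {}
    for si, name in enumerate(names):
        prefix = f"{name}." if name else ""
        rows = []
        for _, rec in df.iterrows():
            g = lambda c: rec[prefix + c]  # noqa: E731
            rows.append(
                PositionRow(
                    chrom=rec["Chrom"],
                    position=int(rec["Position"]),
                    covmp=int(g("Covmp")),
                    percent_cov=float(g("PercentCov")),
                    filter_cov=g("FilterCov"),
                    ref=g("Ref"),
                    var=g("Var"),
                    cons=g("Cons"),
                    fasta=g("FastA"),
                    qdepth=int(g("QDepth")),
                    reads1=int(g("Reads1")),
                    reads2=int(g("Reads2")),
                    freq=float(g("Freq")),
                    p_value=float(g("Pvalue")),
                    strand_filter=g("StrandFilter"),
                    r1_plus=int(g("R1+")),
                    r1_minus=int(g("R1-")),
                    r2_plus=int(g("R2+")),
                    r2_minus=int(g("R2-")),
                    candidate_var=g("Var"),
                    candidate_type=(
                        "NONE"
                        if not g("Var")
                        else "INS"
                        if g("Var").startswith("+")
                        else "DEL"
                        if g("Var").startswith("-")
                        else "SNV"
                    ),
                )
            )
        out[name or "sample"] = rows
    return out


def write_consensus(rows: list[PositionRow], sample_name: str, path, apply_indels: bool = False) -> None:
    """Write the consensus FASTA derived from the per-position rows.

    Default mode is substitution-only: the record is exactly the reference
    length and its symbols are each row's ``FastA`` field (the major allele,
    or ``N`` where the position was excluded), keeping coordinates stable for
    downstream haplogroup tools.  With ``apply_indels`` insertions and
    deletions whose consensus frequency exceeds 50% (``Cons`` of the form
    ``+SEQ``/``-SEQ``) are applied to the emitted sequence.
    """
    ordered = sorted(rows, key=lambda r: r.position)
    if not apply_indels:
        seq = "".join(r.fasta for r in ordered)
    else:
        parts: list[str] = []
        skip = 0
        for r in ordered:
            if skip:
                skip -= 1
                continue
            parts.append(r.fasta)
            if r.cons.startswith("+"):
                parts.append(r.cons[1:])
            elif r.cons.startswith("-"):
                skip = len(r.cons) - 1
        seq = "".join(parts)
    with open(path, "w") as fh:
        fh.write(f">{sample_name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
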
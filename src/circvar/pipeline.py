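"""End-to-end wiring: records -> pileup -> calls -> merged, flagged rows.

``analyse_sample`` runs the full dual-orientation pipeline for one sample and
returns the per-position rows in reported (original) numbering, ready for
:func:`circvar.seqio.write_position_report` / ``write_consensus``.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .caller import CallParams, PositionCall, call_pileup
from .pileup import FilterParams, Pileup, build_pileup
from .postprocess import FlagThresholds, apply_flags, merge_dual, relative_coverage
from .refgenome import CircularReference, shift_reference
from .seqio import AlignmentRecord, PositionRow

__all__ = ["rows_from_calls", "analyse_sample"]


def rows_from_calls(ref: CircularReference, pileup: Pileup, calls: list[PositionCall]) -> list[PositionRow]:
    """Assemble raw per-position rows (internal numbering, no flags yet).

    ``Covmp`` is the mapping-quality-filtered depth before base-quality
    filtering (the depth mpileup prints); ``QDepth`` is the base-quality
    filtered depth that backs the counts.  The consensus symbol is the major
    allele: the variant when its frequency exceeds 50%, the reference base
    otherwise.
    """
    rows: list[PositionRow] = []
    for call in calls:
        i = call.position - 1
        freq_pct = 100.0 * call.freq
        cons = call.ref
        fasta = call.ref
        if call.var and freq_pct > 50.0:
            cons = call.var
            if call.var_type == "SNV":
                fasta = call.var
        rows.append(
            PositionRow(
                chrom=ref.name,
                position=call.position,
                covmp=int(pileup.raw_depth[i]),
                percent_cov=0.0,
                filter_cov="GOOD",
                ref=call.ref,
                var=call.var or "",
                cons=cons,
                fasta=fasta,
                qdepth=int(pileup.qualified_depth[i]),
                reads1=call.reads1,
                reads2=call.reads2,
                freq=freq_pct,
                p_value=call.p_value,
                strand_filter=call.strand_filter,
                r1_plus=call.r1_plus,
                r1_minus=call.r1_minus,
                r2_plus=call.r2_plus,
                r2_minus=call.r2_minus,
                candidate_var=call.candidate_var,
                candidate_type=call.candidate_type,
            )
        )
    return rows


def analyse_sample(
    records_original: Iterable[AlignmentRecord],
    records_shifted: Optional[Iterable[AlignmentRecord]],
    ref: CircularReference,
    filter_params: FilterParams | None = None,
    call_params: CallParams | None = None,
    thresholds: FlagThresholds | None = None,
) -> list[PositionRow]:
    """Run pileup -> calling -> dual merge -> flags for one sample.

    ``records_shifted`` may be ``None`` for single-orientation mode (degraded:
    positions near the origin lose coverage and are flagged accordingly).
    The returned rows are sorted by position and carry reported numbering
    (the original coordinates, honouring any N-stripping map of ``ref``).
    """
    if ref.shift_offset != 0:
        raise ValueError("analyse_sample expects the original-orientation reference")
    filter_params = filter_params or FilterParams()
    call_params = call_params or CallParams()

    pileup_o = build_pileup(records_original, ref, filter_params)
    rows = rows_from_calls(ref, pileup_o, call_pileup(pileup_o, call_params))

    if records_shifted is not None:
        ref_s = shift_reference(ref)
        pileup_s = build_pileup(records_shifted, ref_s, filter_params)
        rows_s = rows_from_calls(ref_s, pileup_s, call_pileup(pileup_s, call_params))
        rows = merge_dual(rows, rows_s, ref_s.shift_offset, ref.length)

    relative_coverage(rows)
    apply_flags(rows, thresholds)
    for r in rows:
        r.chrom = ref.name
        r.position = ref.report_position(r.position)
    return rows
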
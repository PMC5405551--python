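"""Per-position variant significance testing and calling.

The statistical model follows the classic low-frequency caller construction:
at each position the best-supported alternate allele (SNV, insertion or
deletion) is tested against a fixed sequencing-error null with a one-sided
Fisher's exact test.  The 2x2 table contrasts the observed reference/variant
split ``[reads1, reads2]`` with the split expected at error rate ``e``,
``[round(d*(1-e)), round(d*e)]`` where ``d = reads1 + reads2``; the right
(variant-enrichment) tail is the reported p-value.  Conditional on the table
margins this is exactly a hypergeometric tail sum, which is how it is
computed (vectorised over positions via ``scipy.stats.hypergeom.sf``).

A variant is reported when its frequency reaches ``min_var_freq``, its
support reaches ``min_reads2`` and its p-value passes ``p_threshold``.  The
strand-bias filter annotates but never removes a call: it is reported as a
column so downstream consumers can choose to enforce it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pileup import BASES, Pileup, PileupColumn

__all__ = [
    "CallParams",
    "PositionCall",
    "variant_significance",
    "variant_significance_array",
    "strand_bias_filter",
    "call_position",
    "call_pileup",
    "call_variants",
]


@dataclass(frozen=True)
class CallParams:
    """Calling thresholds.

    Defaults are the published operating point: ``p_threshold`` 0.001 and
    ``min_var_freq`` 0.001 (0.1%).  ``null_error_rate`` is the fixed per-base
    error rate of the significance null; ``min_reads2`` guards against
    singleton artifacts; ``strand_bias_max`` is the maximal fraction of
    variant support tolerated on a single strand before the strand filter
    reports ``Fail``.
    """

    min_var_freq: float = 0.001
    p_threshold: float = 0.001
    null_error_rate: float = 0.001
    strand_bias_max: float = 0.90
    min_reads2: int = 2

    def __post_init__(self) -> None:
        for name in ("min_var_freq", "p_threshold", "null_error_rate", "strand_bias_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_reads2 < 0:
            raise ValueError("min_reads2 must be non-negative")


@dataclass(slots=True)
class PositionCall:
    """Result of calling one position.

    ``var``/``var_type`` describe the reported variant and are populated only
    when every filter passed (``var_type == "NONE"`` otherwise), while
    ``candidate_var``/``candidate_type`` always describe the best-supported
    alternate allele so that frequencies remain measurable below the
    significance threshold.  Counts, frequency and p-value always refer to the
    candidate.
    """

    position: int
    ref: str
    var: str | None
    var_type: str  # SNV / INS / DEL / NONE
    candidate_var: str
    candidate_type: str
    reads1: int
    reads2: int
    r1_plus: int
    r1_minus: int
    r2_plus: int
    r2_minus: int
    freq: float  # fraction in [0, 1]
    p_value: float
    strand_filter: str  # Pass / Fail / NA
    passes: bool


def variant_significance(reads1: int, reads2: int, e: float = 0.001) -> float:
    """One-sided exact test that variant support exceeds chance at rate ``e``.

    Fisher's exact test (right tail) on ``[[reads1, reads2],
    [round(d*(1-e)), round(d*e)]]`` with ``d = reads1 + reads2``; returns 1.0
    when ``reads2`` is 0.
    """
    if reads1 < 0 or reads2 < 0:
        raise ValueError("read counts must be non-negative")
    if reads1 == 0 and reads2 == 0:
        raise ValueError("reads1 and reads2 cannot both be zero")
    if reads2 == 0:
        return 1.0
    d = reads1 + reads2
    exp_ref = round(d * (1.0 - e))
    exp_var = round(d * e)
    N = d + exp_ref + exp_var
    K = reads2 + exp_var
    p = stats.hypergeom.sf(reads2 - 1, N, K, d)
    return float(min(1.0, max(0.0, p)))


def variant_significance_array(reads1: np.ndarray, reads2: np.ndarray, e: float = 0.001) -> np.ndarray:
    """Vectorised :func:`variant_significance` over aligned count arrays."""
    reads1 = np.asarray(reads1, dtype=np.int64)
    reads2 = np.asarray(reads2, dtype=np.int64)
    if np.any(reads1 < 0) or np.any(reads2 < 0):
        raise ValueError("read counts must be non-negative")
    d = reads1 + reads2
    out = np.ones(reads1.shape, dtype=float)
    mask = reads2 > 0
    if np.any(mask):
        dm = d[mask]
        exp_ref = np.round(dm * (1.0 - e)).astype(np.int64)
        exp_var = np.round(dm * e).astype(np.int64)
        N = dm + exp_ref + exp_var
        K = reads2[mask] + exp_var
        out[mask] = stats.hypergeom.sf(reads2[mask] - 1, N, K, dm)
    return np.clip(out, 0.0, 1.0)


def strand_bias_filter(r2_plus: int, r2_minus: int, strand_bias_max: float = 0.90) -> str:
    """``NA`` without variant support; ``Fail`` when one strand carries more
    than ``strand_bias_max`` of it; ``Pass`` otherwise."""
    total = r2_plus + r2_minus
    if total == 0:
        return "NA"
    if max(r2_plus, r2_minus) / total > strand_bias_max:
        return "Fail"
    return "Pass"


def _best_candidate(column: PileupColumn) -> tuple[str, str, int, int] | None:
    """Best-supported alternate allele of a column.

    Returns ``(type, allele, plus, minus)`` or ``None`` when the column has no
    alternate support.  Ties break deterministically: highest count wins; at
    equal counts SNV beats insertion beats deletion, and within a type the
    lexicographically smallest allele wins (A < C < G < T for SNVs).
    """
    candidates: list[tuple[int, int, str, str, int, int]] = []
    for b in BASES:
        if b == column.ref_base:
            continue
        p = column.base_counts.get((b, "+"), 0)
        m = column.base_counts.get((b, "-"), 0)
        if p + m:
            candidates.append((p + m, 0, b, "SNV", p, m))
    for seq, (p, m) in column.insertion_counts.items():
        if p + m:
            candidates.append((p + m, 1, seq, "INS", p, m))
    for seq, (p, m) in column.deletion_counts.items():
        if p + m:
            candidates.append((p + m, 2, seq, "DEL", p, m))
    if not candidates:
        return None
    count, rank, allele, kind, p, m = min(
        candidates, key=lambda c: (-c[0], c[1], c[2])
    )
    if kind == "SNV":
        return kind, allele, p, m
    prefix = "+" if kind == "INS" else "-"
    return kind, prefix + allele, p, m


def call_position(column: PileupColumn, params: CallParams | None = None) -> PositionCall:
    """Call one pileup column; always returns a row.

    The reference support ``reads1`` is the reference-base count; for an
    indel candidate the indel-supporting reads are subtracted from it (they
    also present a matching anchor base) so that the reported frequency is the
    fraction of molecules carrying the event.
    """
    params = params or CallParams()
    r1p = column.base_counts.get((column.ref_base, "+"), 0)
    r1m = column.base_counts.get((column.ref_base, "-"), 0)
    cand = _best_candidate(column)
    if cand is None:
        return PositionCall(
            position=column.position,
            ref=column.ref_base,
            var=None,
            var_type="NONE",
            candidate_var="",
            candidate_type="NONE",
            reads1=r1p + r1m,
            reads2=0,
            r1_plus=r1p,
            r1_minus=r1m,
            r2_plus=0,
            r2_minus=0,
            freq=0.0,
            p_value=1.0,
            strand_filter="NA",
            passes=False,
        )
    kind, allele, r2p, r2m = cand
    if kind in ("INS", "DEL"):
        # indel carriers also present a matching anchor base, and reads whose
        # alignment ends inside the event's repeat run cannot distinguish the
        # alleles: neither group is genuine reference support
        up, um = column.end_uninformative.get((kind[0], allele.lstrip("+-")), (0, 0))
        r1p = max(0, r1p - r2p - up)
        r1m = max(0, r1m - r2m - um)
    reads1 = r1p + r1m
    reads2 = r2p + r2m
    freq = reads2 / (reads1 + reads2) if reads1 + reads2 else 0.0
    p_value = variant_significance(reads1, reads2, params.null_error_rate) if reads1 + reads2 else 1.0
    passes = (
        freq >= params.min_var_freq
        and reads2 >= params.min_reads2
        and p_value <= params.p_threshold
    )
    return PositionCall(
        position=column.position,
        ref=column.ref_base,
        var=allele if passes else None,
        var_type=kind if passes else "NONE",
        candidate_var=allele,
        candidate_type=kind,
        reads1=reads1,
        reads2=reads2,
        r1_plus=r1p,
        r1_minus=r1m,
        r2_plus=r2p,
        r2_minus=r2m,
        freq=freq,
        p_value=p_value,
        strand_filter=strand_bias_filter(r2p, r2m, params.strand_bias_max),
        passes=passes,
    )


def call_pileup(pileup: Pileup, params: CallParams | None = None) -> list[PositionCall]:
    """Call every position of a pileup (the all-positions / consensus mode).

    Equivalent to ``[call_position(col, params) for col in pileup]`` but with
    the p-values computed in one vectorised pass.
    """
    params = params or CallParams()
    L = len(pileup)
    counts = pileup.base_counts  # (L, 4, 2)
    ref_codes = np.frombuffer(pileup.ref.sequence.encode("ascii"), dtype=np.uint8)
    ref_idx = np.full(L, 255, dtype=np.int64)
    for bi, b in enumerate(BASES):
        ref_idx[ref_codes == ord(b)] = bi

    strand_sums = counts.sum(axis=2)  # (L, 4)
    masked = strand_sums.copy()
    valid_ref = ref_idx < 4
    masked[np.arange(L)[valid_ref], ref_idx[valid_ref]] = -1
    best_alt = masked.argmax(axis=1)  # lexicographic tie-break via argmax order
    best_alt_count = masked[np.arange(L), best_alt]

    indel_positions = set(pileup.insertions) | set(pileup.deletions)
    calls: list[PositionCall] = []
    p_reads1 = np.zeros(L, dtype=np.int64)
    p_reads2 = np.zeros(L, dtype=np.int64)
    for i in range(L):
        pos = i + 1
        rix = ref_idx[i]
        ref_base = pileup.ref.base(pos)
        r1p = int(counts[i, rix, 0]) if rix < 4 else 0
        r1m = int(counts[i, rix, 1]) if rix < 4 else 0
        # SNV candidate from the dense arrays
        snv = None
        if best_alt_count[i] > 0:
            bi = int(best_alt[i])
            snv = (int(best_alt_count[i]), BASES[bi], int(counts[i, bi, 0]), int(counts[i, bi, 1]))
        if pos in indel_positions:
            # rare path: defer to the scalar column logic for full tie-breaks
            calls.append(None)  # placeholder, filled below
            continue
        if snv is None:
            calls.append(
                PositionCall(
                    position=pos, ref=ref_base, var=None, var_type="NONE",
                    candidate_var="", candidate_type="NONE",
                    reads1=r1p + r1m, reads2=0, r1_plus=r1p, r1_minus=r1m,
                    r2_plus=0, r2_minus=0, freq=0.0, p_value=1.0,
                    strand_filter="NA", passes=False,
                )
            )
            continue
        count, allele, r2p, r2m = snv
        reads1 = r1p + r1m
        calls.append(
            PositionCall(
                position=pos, ref=ref_base, var=None, var_type="SNV",
                candidate_var=allele, candidate_type="SNV",
                reads1=reads1, reads2=count, r1_plus=r1p, r1_minus=r1m,
                r2_plus=r2p, r2_minus=r2m,
                freq=count / (reads1 + count) if reads1 + count else 0.0,
                p_value=1.0,  # filled by the vectorised pass
                strand_filter=strand_bias_filter(r2p, r2m, params.strand_bias_max),
                passes=False,
            )
        )
        p_reads1[i] = reads1
        p_reads2[i] = count
    # scalar fallback for indel-bearing positions
    for i in range(L):
        if calls[i] is None:
            calls[i] = call_position(pileup[i], params)
    # vectorised significance for the SNV-path rows
    mask = p_reads2 > 0
    if np.any(mask):
        pvals = variant_significance_array(p_reads1[mask], p_reads2[mask], params.null_error_rate)
        for i, p in zip(np.nonzero(mask)[0], pvals):
            call = calls[i]
            call.p_value = float(p)
            call.passes = (
                call.freq >= params.min_var_freq
                and call.reads2 >= params.min_reads2
                and call.p_value <= params.p_threshold
            )
            if call.passes:
                call.var = call.candidate_var
            else:
                call.var_type = "NONE"
    return calls


def call_variants(pileup: Pileup, params: CallParams | None = None, kind: str = "all") -> list[PositionCall]:
    """Passing-filter calls, optionally restricted by type.

    ``kind`` is ``"snp"`` (SNVs only), ``"indel"`` (insertions and deletions)
    or ``"all"``.
    """
    if kind not in ("snp", "indel", "all"):
        raise ValueError(f"unknown kind {kind!r}")
    wanted = {"snp": {"SNV"}, "indel": {"INS", "DEL"}, "all": {"SNV", "INS", "DEL"}}[kind]
    return [c for c in call_pileup(pileup, params) if c.passes and c.var_type in wanted]
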
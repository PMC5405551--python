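"""Two-haplotype mixture simulator and benchmark harness.

The benchmark design it reproduces: one circular reference ("haplotype A")
and a second haplotype ("B") differing at a configurable set of homoplasmic
SNVs (default 88) and small insertions (default a ``+G`` and a ``+AA``
planted immediately in front of an eight-``A`` homopolymer, the classic
hard case).  Mixtures of the two haplotypes at ratios spanning 0–100% are
sequenced in silico as 2x150 paired reads at ~3,000X mean coverage with
uniform per-base substitution error (0.1%) and rare single-base indel error
(0.01%), all base qualities phred 40 and mapping quality 60.

Each read is emitted against every orientation (original / origin-shifted)
in which its mapping is contiguous: reads spanning the original origin appear
only in the shifted alignment and vice versa, which is exactly the situation
the dual-reference merge resolves.

Reads whose alignment is non-trivial — overlapping an engineered insertion,
carrying an injected indel error, or wrapping the sampled haplotype's origin
through an inserted region — are realigned against the reference with edlib
(infix mode), so their CIGARs show the same representational ambiguity (e.g.
split or slid insertions inside homopolymers) a production aligner produces.

Expected frequencies are calibrated from the measured 50/50 run, mirroring
the published procedure, and accuracy is summarised as the Pearson
correlation and ordinary-least-squares slope between calibrated expected and
mean measured frequencies across ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .caller import CallParams
from .pileup import FilterParams, left_align_insertion
from .pipeline import analyse_sample
from .postprocess import FlagThresholds
from .refgenome import CircularReference
from .seqio import AlignmentRecord, PositionRow

__all__ = [
    "MixtureDesign",
    "MixtureTruth",
    "SimulatedReads",
    "BenchmarkResult",
    "make_reference",
    "make_haplotypes",
    "simulate_reads",
    "calibrate_ratios",
    "benchmark_metrics",
    "run_benchmark",
]

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Twelve mixture ratios: a two-fold dilution series through the published
#: sensitivity points (0.4, 0.8, 1.6%) plus anchors at 0, 50 and 100%.
DEFAULT_RATIOS = (0.0, 0.4, 0.8, 1.6, 3.2, 6.25, 12.5, 25.0, 50.0, 75.0, 90.0, 100.0)


@dataclass(frozen=True)
class MixtureDesign:
    """Parameters of the two-haplotype mixture benchmark.

    Defaults reproduce the study conditions: a ~16.6 kb circular genome,
    88 distinguishing SNVs, two engineered insertions (``+G`` and ``+AA``
    before an 8-A homopolymer), twelve mixture ratios, 3,000X mean coverage
    from 2x150 paired reads (adjacent 150 bp mates, 300 bp fragments),
    0.1% substitution error and 0.01% single-base indel error.
    """

    length: int = 16569
    n_snvs: int = 88
    snvs: tuple[tuple[int, str, str], ...] | None = None  # (position, ref, alt)
    insertions: tuple[tuple[int, str], ...] | None = None  # (anchor, inserted seq)
    homopolymer_length: int = 8
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    coverage: float = 3000.0
    read_length: int = 150
    fragment_length: int = 300
    substitution_error: float = 0.001
    indel_error: float = 1e-4
    rca_noise: float = 0.0  # optional extra substitution error term
    seed: int = 0
    reference_name: str = "circ_mt"

    def __post_init__(self) -> None:
        for r in self.ratios:
            if not 0.0 <= r <= 100.0:
                raise ValueError(f"ratio {r} outside [0, 100]")
        if self.read_length > self.length:
            raise ValueError("read length exceeds reference length")
        if self.fragment_length > self.length:
            raise ValueError("fragment length exceeds reference length")
        if self.fragment_length < 2 * self.read_length:
            raise ValueError("fragment shorter than two read lengths")


@dataclass
class MixtureTruth:
    """Ground truth for one design instance.

    ``snvs`` are ``(position, ref, alt)`` on the reference numbering;
    ``insertions`` are ``(anchor, seq)`` after the same left-alignment the
    pileup applies, so truth anchors and called anchors are directly
    comparable.  ``b_to_a`` maps 0-based haplotype-B positions to 0-based
    reference positions (-1 for inserted bases).
    """

    snvs: list[tuple[int, str, str]]
    insertions: list[tuple[int, str]]
    hap_b: str
    b_to_a: np.ndarray
    seed: int

    @property
    def snv_positions(self) -> list[int]:
        return [p for p, _, _ in self.snvs]


def make_reference(design: MixtureDesign, rng: np.random.Generator) -> CircularReference:
    """Random circular reference with one planted A-homopolymer.

    The homopolymer (length ``design.homopolymer_length``) is bounded by
    non-A bases so the default ``+AA`` insertion has a well-defined leftmost
    anchor.
    """
    L = design.length
    codes = rng.integers(0, 4, size=L, dtype=np.int64)
    h = int(rng.integers(L // 10, 9 * L // 10))
    k = design.homopolymer_length
    codes[h : h + k] = 0  # A run
    codes[h - 1] = int(rng.integers(1, 4))
    codes[h + k] = int(rng.integers(1, 4))
    seq = _ASCII[codes].tobytes().decode("ascii")
    return CircularReference(design.reference_name, seq)


def _find_homopolymer(seq: str, length: int) -> int:
    """0-based start of the first A-run of exactly ``length``, or -1."""
    run = "A" * length
    start = 0
    while True:
        i = seq.find(run, start)
        if i < 0:
            return -1
        before = seq[i - 1] if i > 0 else ""
        after = seq[i + length] if i + length < len(seq) else ""
        if before != "A" and after != "A":
            return i
        start = i + 1


def _default_variants(
    design: MixtureDesign, ref: CircularReference, rng: np.random.Generator
) -> tuple[list[tuple[int, str, str]], list[tuple[int, str]]]:
    L = ref.length
    seq = ref.sequence
    h0 = _find_homopolymer(seq, design.homopolymer_length)
    if h0 < 0:
        raise ValueError("reference lacks the required A-homopolymer")
    blocked = set(range(h0 - 2, h0 + design.homopolymer_length + 3))

    insertions: list[tuple[int, str]] = [(h0, "AA")]  # anchor = base before the A-run
    # a +G at a random anchor whose context keeps the left-aligned anchor stable
    while True:
        a = int(rng.integers(2, L - 1))
        if a in blocked or (a + 1) in blocked:
            continue
        if seq[a - 1] != "G" and seq[a] != "G":
            insertions.append((a, "G"))
            blocked.update(range(a - 2, a + 3))
            break

    snvs: list[tuple[int, str, str]] = []
    taken: set[int] = set()
    while len(snvs) < design.n_snvs:
        p = int(rng.integers(1, L + 1))
        if p in taken or p in blocked or (p - 1) in blocked:
            continue
        ref_base = seq[p - 1]
        alts = [b for b in "ACGT" if b != ref_base]
        snvs.append((p, ref_base, alts[int(rng.integers(0, 3))]))
        taken.add(p)
    snvs.sort()
    insertions.sort()
    return snvs, insertions


def make_haplotypes(
    design: MixtureDesign, rng: np.random.Generator | None = None
) -> tuple[CircularReference, MixtureTruth]:
    """Build the reference (haplotype A) and haplotype B with its truth table.

    Raises
    ------
    ValueError
        If engineered variants overlap (an SNV at an insertion anchor, or
        duplicated positions).
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    ref = make_reference(design, rng)
    if design.snvs is not None or design.insertions is not None:
        snvs = sorted(design.snvs or ())
        insertions = sorted(design.insertions or ())
    else:
        snvs, insertions = _default_variants(design, ref, rng)

    L = ref.length
    positions = [p for p, *_ in snvs]
    anchors = [a for a, _ in insertions]
    for p, ref_base, alt in snvs:
        if not 1 <= p <= L:
            raise ValueError(f"SNV position {p} outside [1, {L}]")
        if ref.base(p) != ref_base:
            raise ValueError(f"SNV at {p}: reference base is {ref.base(p)}, not {ref_base}")
        if alt == ref_base or alt not in "ACGT":
            raise ValueError(f"SNV at {p}: invalid alternate {alt!r}")
    if len(set(positions)) != len(positions) or len(set(anchors)) != len(anchors):
        raise ValueError("engineered variant positions must be distinct")
    overlap = set(positions) & (set(anchors) | {a + 1 for a in anchors})
    if overlap:
        raise ValueError(f"engineered variants overlap at {sorted(overlap)}")

    hap = list(ref.sequence)
    for p, _, alt in snvs:
        hap[p - 1] = alt
    # apply insertions right-to-left so earlier anchors stay valid
    mapping = np.arange(L, dtype=np.int64)
    for anchor, seq in sorted(insertions, reverse=True):
        hap = hap[:anchor] + list(seq) + hap[anchor:]
        mapping = np.concatenate(
            [mapping[:anchor], np.full(len(seq), -1, dtype=np.int64), mapping[anchor:]]
        )
    hap_b = "".join(hap)

    aligned = [left_align_insertion(ref.sequence, a, s) for a, s in insertions]
    truth = MixtureTruth(
        snvs=snvs,
        insertions=sorted(aligned),
        hap_b=hap_b,
        b_to_a=mapping,
        seed=design.seed,
    )
    return ref, truth


@dataclass
class SimulatedReads:
    """One simulated mixture: records per orientation plus FASTQ payload."""

    ratio: float
    n_pairs: int
    records_original: list[AlignmentRecord]
    records_shifted: list[AlignmentRecord]
    fastq_r1: list[tuple[str, str, str]] = field(default_factory=list)
    fastq_r2: list[tuple[str, str, str]] = field(default_factory=list)


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _edlib_cigar(cigar_text: str) -> list[tuple[int, str]]:
    ops: list[tuple[int, str]] = []
    n = ""
    for ch in cigar_text:
        if ch.isdigit():
            n += ch
        else:
            op = "M" if ch in "=XM" else ch
            length = int(n)
            n = ""
            if ops and ops[-1][1] == op:
                ops[-1] = (ops[-1][0] + length, op)
            else:
                ops.append((length, op))
    return ops


# local-alignment scoring used to clip negatively scoring read ends, the way
# a production local aligner (e.g. BWA-MEM) soft-clips them; without the
# clipping, edit-distance ties at read ends inside indel ambiguity regions
# resolve to systematic mismatches that pile up at fixed reference positions
_MATCH, _MISMATCH, _GAP = 1, -4, -6


def _clip_ends(cigar: list[tuple[int, str]], read: str, window: str, t0: int) -> tuple[int, list[tuple[int, str]]]:
    """Soft-clip read ends whose local alignment score is negative.

    Returns the (possibly advanced) target start within ``window`` and the
    rebuilt CIGAR.
    """
    # expand to alignment columns: (op, consumes_query, consumes_target, match)
    cols: list[tuple[str, bool, bool, bool]] = []
    q, t = 0, t0
    for n, op in cigar:
        for _ in range(n):
            if op == "M":
                cols.append(("M", True, True, read[q] == window[t]))
                q += 1
                t += 1
            elif op == "I":
                cols.append(("I", True, False, False))
                q += 1
            elif op == "D":
                cols.append(("D", False, True, False))
                t += 1
            elif op == "S":
                cols.append(("S", True, False, False))
                q += 1

    def col_score(c):
        if c[0] == "M":
            return _MATCH if c[3] else _MISMATCH
        if c[0] == "S":
            return 0
        return _GAP

    def clip_len(ordered):
        """Number of leading columns of ``ordered`` to drop (most negative prefix)."""
        cum, best, best_i = 0, 0, 0
        for i, c in enumerate(ordered, start=1):
            cum += col_score(c)
            if cum < best:
                best, best_i = cum, i
        return best_i

    head = clip_len(cols)
    tail = clip_len(cols[::-1]) if head < len(cols) else 0
    if head == 0 and tail == 0:
        return t0, cigar
    kept = cols[head : len(cols) - tail]
    if not any(c[0] == "M" for c in kept):
        return t0, cigar  # degenerate; keep the raw alignment
    head_clip = cols[:head]
    # an alignment cannot begin or end with a deletion: push edge D columns
    # into the clipped regions (they consume target only)
    while kept and kept[0][0] == "D":
        head_clip.append(kept.pop(0))
    while kept and kept[-1][0] == "D":
        tail += 1
        kept.pop()
    tail_clip = cols[len(cols) - tail :] if tail else []
    head_q = sum(1 for c in head_clip if c[1])
    head_t = sum(1 for c in head_clip if c[2])
    tail_q = sum(1 for c in tail_clip if c[1])
    new: list[tuple[int, str]] = []
    if head_q:
        new.append((head_q, "S"))
    for c in kept:
        op = c[0]
        if new and new[-1][1] == op:
            new[-1] = (new[-1][0] + 1, op)
        else:
            new.append((1, op))
    if tail_q:
        new.append((tail_q, "S"))
    return t0 + head_t, new


def _realign(read: str, ref_doubled: str, approx_start: int, L: int) -> tuple[int, list[tuple[int, str]]]:
    """Realign a read against a circular reference window with edlib.

    ``approx_start`` is the expected 0-based reference start.  Returns the
    0-based start on the (unwrapped) circle and the CIGAR.  Read ends whose
    alignment scores negatively under local-alignment scoring are soft
    clipped (see ``_clip_ends``).
    """
    pad = 12
    w_start = (approx_start - pad) % L
    window = ref_doubled[w_start : w_start + len(read) + 2 * pad]
    res = edlib.align(read, window, mode="HW", task="path")
    t0 = res["locations"][0][0]
    cigar = _edlib_cigar(res["cigar"])
    # a leading/trailing insertion has no anchor: represent it as a soft clip
    if cigar and cigar[0][1] == "I":
        cigar[0] = (cigar[0][0], "S")
    if cigar and cigar[-1][1] == "I":
        cigar[-1] = (cigar[-1][0], "S")
    t0, cigar = _clip_ends(cigar, read, window, t0)
    return (w_start + t0) % L, cigar


def simulate_reads(
    design: MixtureDesign,
    ref: CircularReference,
    truth: MixtureTruth,
    ratio: float,
    rng: np.random.Generator,
    emit_fastq: bool = False,
    read_prefix: str = "r",
) -> SimulatedReads:
    """Simulate one mixture at ``ratio`` percent haplotype B.

    Fragment start positions are uniform on the circle of the sampled
    haplotype; mates are the two adjacent 150-mers of a 300 bp fragment, the
    first on the plus and the second on the minus strand.  Substitution
    errors are injected at ``substitution_error`` (+ ``rca_noise``) per base
    and keep phred-40 qualities (they model miscalls, not low-confidence
    calls); single-base indel errors occur at ``indel_error`` per base.
    """
    if not 0.0 <= ratio <= 100.0:
        raise ValueError(f"ratio {ratio} outside [0, 100]")
    L = ref.length
    s = L // 2
    rl = design.read_length
    half = design.fragment_length // 2
    sub_err = design.substitution_error + design.rca_noise
    n_pairs = int(round(design.coverage * L / (2 * rl)))

    a_codes = np.frombuffer(ref.sequence.encode("ascii"), dtype=np.uint8)
    b_codes = np.frombuffer(truth.hap_b.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, base in enumerate("ACGT"):
        lut[ord(base)] = i
    a_num = lut[a_codes]
    b_num = lut[b_codes]
    ref_doubled = ref.sequence + ref.sequence
    L_B = len(truth.hap_b)
    inserted = truth.b_to_a < 0
    ins_cum = np.concatenate([[0], np.cumsum(np.concatenate([inserted, inserted]))])

    from_b = rng.random(n_pairs) < ratio / 100.0
    n_b = int(from_b.sum())
    n_a = n_pairs - n_b

    qual_str = chr(40 + 33) * rl
    qual_arr = np.full(rl, 40, dtype=np.uint8)
    records_o: list[AlignmentRecord] = []
    records_s: list[AlignmentRecord] = []
    sim = SimulatedReads(ratio=ratio, n_pairs=n_pairs, records_original=records_o, records_shifted=records_s)

    def emit(name: str, pos0: int, span: int, strand: str, bases: str, cigar: list[tuple[int, str]]) -> None:
        if pos0 + span <= L:
            records_o.append(
                AlignmentRecord(name, ref.name, pos0 + 1, 60, strand, cigar, bases, qual_arr)
            )
        pos_s = (pos0 - s) % L
        if pos_s + span <= L:
            records_s.append(
                AlignmentRecord(name, f"{ref.name}_shifted", pos_s + 1, 60, strand, cigar, bases, qual_arr)
            )

    pair_counter = 0
    for hap_num, hap_seq, L_hap, is_b, n_frags in (
        (a_num, ref.sequence, L, False, n_a),
        (b_num, truth.hap_b, L_B, True, n_b),
    ):
        if n_frags == 0:
            continue
        starts = rng.integers(0, L_hap, size=n_frags)
        for mate, strand in ((1, "+"), (2, "-")):
            s0 = starts if mate == 1 else (starts + half) % L_hap
            idx = (s0[:, None] + np.arange(rl)) % L_hap
            mat = hap_num[idx]
            err = rng.random(mat.shape) < sub_err
            n_err = int(err.sum())
            if n_err:
                mat[err] = (mat[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
            has_indel = rng.random(n_frags) < rl * design.indel_error
            if is_b:
                ov = ins_cum[np.asarray(s0) + rl] - ins_cum[np.asarray(s0)]
                slow = has_indel | (ov > 0) | inserted[np.asarray(s0)]
                pos0 = np.where(inserted[np.asarray(s0)], 0, truth.b_to_a[np.asarray(s0)])
            else:
                slow = has_indel
                pos0 = np.asarray(s0)
            ascii_mat = _ASCII[mat]
            for j in range(n_frags):
                name = f"{read_prefix}{pair_counter + j}/{mate}"
                bases = ascii_mat[j].tobytes().decode("ascii")
                if slow[j]:
                    if has_indel[j]:
                        k = int(rng.integers(1, rl - 1))
                        if rng.random() < 0.5:
                            ins_base = "ACGT"[int(rng.integers(0, 4))]
                            bases = bases[: k] + ins_base + bases[k : rl - 1]
                        else:
                            extra = hap_seq[int((s0[j] + rl) % L_hap)]
                            bases = bases[:k] + bases[k + 1 :] + extra
                    if is_b:
                        t = int(s0[j])
                        while truth.b_to_a[t] < 0:
                            t = (t + 1) % L_B
                        approx = int(truth.b_to_a[t])
                    else:
                        approx = int(pos0[j])
                    start0, cigar = _realign(bases, ref_doubled, approx, L)
                    cigar = [(n, op) for n, op in cigar if n > 0]
                    span = sum(n for n, op in cigar if op in "MD")
                    emit(name, start0, span, strand, bases, cigar)
                else:
                    emit(name, int(pos0[j]), rl, strand, bases, [(rl, "M")])
                if emit_fastq:
                    pair_name = f"{read_prefix}{pair_counter + j}"
                    out = bases if strand == "+" else _revcomp(bases)
                    target = sim.fastq_r1 if mate == 1 else sim.fastq_r2
                    target.append((f"{pair_name}/{mate}", out, qual_str))
        pair_counter += n_frags
    return sim


def calibrate_ratios(ratios, measured_f50: float) -> dict[float, float]:
    """Calibrated expected frequency per theoretical ratio.

    ``expected(r) = r * measured_f50 / 50``: the 50/50 run pins down the
    effective mixing ratio, absorbing pipetting/copy-number offsets.

    Raises
    ------
    ValueError
        If 50 is not among the ratios or the measured 50/50 frequency is 0.
    """
    ratios = list(ratios)
    if not any(abs(r - 50.0) < 1e-9 for r in ratios):
        raise ValueError("calibration requires a 50/50 mixture among the ratios")
    if measured_f50 <= 0:
        raise ValueError("degenerate calibration: measured 50/50 frequency is 0")
    factor = measured_f50 / 50.0
    return {r: r * factor for r in ratios}


@dataclass
class BenchmarkResult:
    """Accuracy and sensitivity metrics of one benchmark run.

    ``freq_table``: measured frequency (percent) per ratio (rows) and truth
    SNV position (columns).  ``mean_measured``/``expected``: per-ratio mean
    over the truth SNVs and its calibrated expectation.  ``detection``:
    fraction of truth SNVs passing all calling filters per ratio;
    ``indel_detection``: same for the engineered indels.
    ``false_positive_count``: passing SNV calls at non-truth positions summed
    over all ratios.  ``variant_density``: truth variants within the 300 bp
    window centred on each truth variant (self included).
    """

    freq_table: pd.DataFrame
    mean_measured: dict[float, float]
    expected: dict[float, float]
    calibration_factor: float
    pearson_r: float
    slope: float
    slope_stderr: float
    detection: dict[float, float]
    indel_detection: dict[float, dict[tuple[int, str], bool]]
    false_positive_count: int
    false_positive_positions: list[tuple[float, int, str]]
    per_variant_deviation: pd.Series
    variant_density: dict[int, int]
    seed: int


def variant_density(truth: MixtureTruth, L: int, window: int = 300) -> dict[int, int]:
    """Truth variants within a circular ``window`` centred on each variant."""
    positions = sorted(truth.snv_positions + [a for a, _ in truth.insertions])
    half = window // 2
    out: dict[int, int] = {}
    for p in positions:
        n = 0
        for q in positions:
            d = abs(p - q)
            if min(d, L - d) <= half:
                n += 1
        out[p] = n
    return out


def benchmark_metrics(
    truth: MixtureTruth,
    L: int,
    freq_table: pd.DataFrame,
    detection: dict[float, float],
    indel_detection: dict[float, dict[tuple[int, str], bool]],
    false_positives: list[tuple[float, int, str]],
    seed: int,
    window: int = 300,
) -> BenchmarkResult:
    """Assemble the benchmark summary from per-ratio measurements."""
    ratios = list(freq_table.index)
    mean_measured = {r: float(freq_table.loc[r].mean()) for r in ratios}
    f50 = mean_measured[min(ratios, key=lambda r: abs(r - 50.0))]
    expected = calibrate_ratios(ratios, f50)
    exp = np.array([expected[r] for r in ratios])
    meas = np.array([mean_measured[r] for r in ratios])
    pearson = float(stats.pearsonr(exp, meas).statistic)
    reg = stats.linregress(exp, meas)
    deviation = freq_table.sub(pd.Series(expected), axis=0).mean(axis=0)
    return BenchmarkResult(
        freq_table=freq_table,
        mean_measured=mean_measured,
        expected=expected,
        calibration_factor=f50 / 50.0,
        pearson_r=pearson,
        slope=float(reg.slope),
        slope_stderr=float(reg.stderr),
        detection=detection,
        indel_detection=indel_detection,
        false_positive_count=len(false_positives),
        false_positive_positions=false_positives,
        per_variant_deviation=deviation,
        variant_density=variant_density(truth, L, window),
        seed=seed,
    )


def measured_snv_frequencies(rows: list[PositionRow], truth: MixtureTruth) -> dict[int, float]:
    """Measured frequency (percent) of each truth SNV in one sample's rows.

    The row frequency is used when the row's best-supported allele is the
    engineered one (irrespective of the significance filter, mirroring the
    published accuracy analysis); otherwise the allele was not observed and
    the measured frequency is 0.
    """
    by_pos = {r.position: r for r in rows}
    out: dict[int, float] = {}
    for p, _, alt in truth.snvs:
        row = by_pos[p]
        out[p] = row.freq if row.candidate_var == alt and row.candidate_type == "SNV" else 0.0
    return out


def run_benchmark(
    design: MixtureDesign,
    filter_params: FilterParams | None = None,
    call_params: CallParams | None = None,
    thresholds: FlagThresholds | None = None,
) -> BenchmarkResult:
    """Simulate every ratio of the design and run the full dual pipeline.

    Per-ratio generators are spawned deterministically from ``design.seed``,
    so identical designs give identical results.
    """
    call_params = call_params or CallParams()
    rng0 = np.random.default_rng(design.seed)
    ref, truth = make_haplotypes(design, rng0)
    snv_by_pos = {p: alt for p, _, alt in truth.snvs}
    ins_set = set(truth.insertions)

    freq_rows = {}
    detection: dict[float, float] = {}
    indel_detection: dict[float, dict[tuple[int, str], bool]] = {}
    false_positives: list[tuple[float, int, str]] = []
    for i, ratio in enumerate(design.ratios):
        rng = np.random.default_rng([design.seed % (2**31), i])
        sim = simulate_reads(design, ref, truth, ratio, rng)
        rows = analyse_sample(
            sim.records_original, sim.records_shifted, ref, filter_params, call_params, thresholds
        )
        freq_rows[ratio] = measured_snv_frequencies(rows, truth)
        n_detected = sum(
            1 for r in rows if r.var and r.var_type == "SNV" and snv_by_pos.get(r.position) == r.var
        )
        detection[ratio] = n_detected / len(truth.snvs)
        indel_detection[ratio] = {
            (a, seq): any(
                r.position == a and r.var == "+" + seq and r.var_type == "INS" for r in rows
            )
            for a, seq in truth.insertions
        }
        for r in rows:
            if r.var and r.var_type == "SNV" and snv_by_pos.get(r.position) != r.var:
                false_positives.append((ratio, r.position, r.var))
        del sim, rows

    freq_table = pd.DataFrame(freq_rows).T.sort_index()
    freq_table.index.name = "ratio"
    return benchmark_metrics(
        truth,
        ref.length,
        freq_table,
        detection,
        indel_detection,
        false_positives,
        design.seed,
        window=2 * design.read_length,
    )
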
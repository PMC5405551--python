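"""Strand-resolved, quality-filtered per-position allele and indel counts.

This is the mpileup-analogue stage: alignment records against one reference
orientation are turned into per-position counts that the caller consumes.

Semantics (matching classic mpileup behaviour):

* records whose (optionally adjusted) mapping quality is below ``q``
  contribute nothing;
* aligned bases with base quality below ``Q`` are excluded from the allele
  counts and from the qualified depth, but still count towards the raw depth;
* insertions are anchored at the preceding aligned reference position and do
  not add to depth;
* deletions are recorded once at their anchor (the position before the first
  deleted base) and counted in both depths across their span;
* soft-clipped bases are ignored;
* overlapping mates of a pair are counted independently (no overlap
  de-duplication).

Indels are left-aligned against the reference before counting, and multiple
indel events of one read that normalise to the same anchor are merged into a
single concatenated event.  This stabilises counting inside homopolymers,
where aligners may place or split an insertion arbitrarily (e.g. an ``AA``
insertion in front of a run of eight ``A``'s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from .refgenome import CircularReference
from .seqio import AlignmentRecord

__all__ = [
    "FilterParams",
    "PileupColumn",
    "Pileup",
    "build_pileup",
    "adjusted_mapping_quality",
    "mismatch_downgrade_hook",
    "left_align_insertion",
    "left_align_deletion",
    "repeat_extension",
]

BASES = "ACGT"
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i

_FLUSH_ENTRIES = 4_000_000  # flush fast-path buffers at ~4M aligned bases


@dataclass(frozen=True)
class FilterParams:
    """Pileup quality filters.

    Defaults are the published operating point: minimum base quality 35,
    minimum mapping quality 50, and mapping-quality adjustment coefficient 50.
    The adjustment itself defaults to the identity (simulated reads carry
    truthful mapping qualities); ``mapq_hook`` can install
    :func:`mismatch_downgrade_hook` or any other downgrade.
    """

    min_base_quality: int = 35
    min_mapping_quality: int = 50
    mapq_adjust_coefficient: int = 50
    mapq_hook: Optional[Callable[[AlignmentRecord, CircularReference, int], int]] = None

    def __post_init__(self) -> None:
        if min(self.min_base_quality, self.min_mapping_quality, self.mapq_adjust_coefficient) < 0:
            raise ValueError("filter parameters must be non-negative")


@dataclass
class PileupColumn:
    """Counts at one 1-based reference position (internal orientation).

    ``base_counts`` maps ``(base, strand)`` to a count; ``insertion_counts``
    and ``deletion_counts`` map the inserted/deleted sequence to
    ``(plus_count, minus_count)``.  ``qualified_depth`` is the number of
    quality-passing bases plus deletion spans covering the position;
    ``raw_depth`` additionally includes bases that failed the base-quality
    filter.

    ``end_uninformative`` is filled only for positions carrying indel events:
    for each event key (``("I", seq)`` or ``("D", seq)``) it holds the
    per-strand count of reads whose alignment *ends* inside the event's
    ambiguity window — the anchor plus the reference repeat run the event
    extends.  Such reads cannot distinguish the two alleles (a read ending
    inside an A-homopolymer says nothing about an extra ``+AA``) and the
    caller removes them from the reference support of the indel.
    """

    position: int
    ref_base: str
    base_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    insertion_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    deletion_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    end_uninformative: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    qualified_depth: int = 0
    raw_depth: int = 0

    def base_count(self, base: str, strand: str | None = None) -> int:
        if strand is not None:
            return self.base_counts.get((base, strand), 0)
        return self.base_counts.get((base, "+"), 0) + self.base_counts.get((base, "-"), 0)


class Pileup:
    """Sequence of :class:`PileupColumn` backed by dense count arrays.

    Behaves as a list of length ``L`` for the per-column API while keeping the
    underlying counts as numpy arrays for the caller's vectorised path:
    ``base_counts`` has shape ``(L, 4, 2)`` (position x ACGT x strand +/-).
    """

    def __init__(self, ref: CircularReference):
        self.ref = ref
        L = ref.length
        self.base_counts = np.zeros((L, 4, 2), dtype=np.int64)
        self.qualified_depth = np.zeros(L, dtype=np.int64)
        self.raw_depth = np.zeros(L, dtype=np.int64)
        # reads whose alignment ends at each position, per strand
        self.end_depth = np.zeros((L, 2), dtype=np.int64)
        # sparse: 1-based anchor -> {seq: [plus, minus]}
        self.insertions: dict[int, dict[str, list[int]]] = {}
        self.deletions: dict[int, dict[str, list[int]]] = {}

    def __len__(self) -> int:
        return self.ref.length

    def __getitem__(self, index: int) -> PileupColumn:
        """Column at 0-based index (position ``index + 1``)."""
        if index < 0:
            index += len(self)
        if not 0 <= index < len(self):
            raise IndexError(index)
        pos = index + 1
        col = PileupColumn(
            position=pos,
            ref_base=self.ref.base(pos),
            qualified_depth=int(self.qualified_depth[index]),
            raw_depth=int(self.raw_depth[index]),
        )
        for bi, b in enumerate(BASES):
            for si, strand in enumerate("+-"):
                c = int(self.base_counts[index, bi, si])
                if c:
                    col.base_counts[(b, strand)] = c
        for kind, store, target in (
            ("I", self.insertions, col.insertion_counts),
            ("D", self.deletions, col.deletion_counts),
        ):
            for seq, counts in store.get(pos, {}).items():
                target[seq] = (counts[0], counts[1])
                ext = repeat_extension(self.ref.sequence, pos, seq)
                hi = min(len(self), pos + ext + (len(seq) if kind == "I" else 0))
                window = self.end_depth[pos - 1 : hi]
                col.end_uninformative[(kind, seq)] = (
                    int(window[:, 0].sum()),
                    int(window[:, 1].sum()),
                )
        return col

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def repeat_extension(ref_seq: str, anchor: int, unit: str) -> int:
    """Length of the reference run after 1-based ``anchor`` matching the
    cyclic repetition of ``unit`` (0 when the next base already differs)."""
    j = 0
    L = len(ref_seq)
    while anchor + j < L and ref_seq[anchor + j] == unit[j % len(unit)]:
        j += 1
    return j


def left_align_insertion(ref_seq: str, anchor: int, seq: str) -> tuple[int, str]:
    """Normalise an insertion to its leftmost equivalent placement.

    ``anchor`` is the 1-based reference position the insertion follows.  While
    the anchor base equals the last inserted base, the event can be slid one
    position left without changing the implied sequence.  Sliding stops at
    position 1 (left-alignment is performed within the linearised orientation).
    """
    while anchor >= 1 and ref_seq[anchor - 1] == seq[-1]:
        seq = ref_seq[anchor - 1] + seq[:-1]
        anchor -= 1
    return anchor, seq


def left_align_deletion(ref_seq: str, anchor: int, length: int) -> tuple[int, str]:
    """Normalise a deletion (of ``length`` bases starting at ``anchor + 1``).

    Returns the leftmost anchor and the deleted sequence at that placement.
    """
    while anchor >= 1 and ref_seq[anchor - 1] == ref_seq[anchor + length - 1]:
        anchor -= 1
    return anchor, ref_seq[anchor : anchor + length]


def adjusted_mapping_quality(
    record: AlignmentRecord,
    ref: CircularReference,
    coefficient: int,
    hook: Optional[Callable[[AlignmentRecord, CircularReference, int], int]] = None,
) -> int:
    """Mapping quality after the optional adjustment hook.

    The default is the identity.  A hook receives ``(record, ref,
    coefficient)`` and returns the adjusted value; see
    :func:`mismatch_downgrade_hook`.
    """
    if hook is None:
        return record.mapping_quality
    return hook(record, ref, coefficient)


def mismatch_downgrade_hook(record: AlignmentRecord, ref: CircularReference, coefficient: int) -> int:
    """Downgrade mapping quality of mismatch-rich reads.

    ``adjusted = round(mapq * (1 - m / n) ** C)`` with ``m`` mismatches over
    ``n`` aligned bases: the identity for mismatch-free reads and monotone
    non-increasing in the mismatch count.  A heuristic stand-in for
    coefficient-based recalibration; off by default.
    """
    refp = record.position
    readp = 0
    mismatches = 0
    aligned = 0
    for n, op in record.cigar:
        if op == "M":
            for j in range(n):
                aligned += 1
                if record.bases[readp + j] != ref.base(refp + j):
                    mismatches += 1
            refp += n
            readp += n
        elif op in "IS":
            readp += n
        elif op == "D":
            refp += n
    if aligned == 0:
        return record.mapping_quality
    frac = mismatches / aligned
    return int(round(record.mapping_quality * (1.0 - frac) ** coefficient))


def _count_read_indels(pileup: Pileup, events: list[tuple[str, int, str]], strand: str) -> None:
    """Left-align one read's indel events, merge same-anchor events, count."""
    ref_seq = pileup.ref.sequence
    normalised: dict[tuple[str, int], str] = {}
    for kind, anchor, seq in events:
        if kind == "I":
            anchor, seq = left_align_insertion(ref_seq, anchor, seq)
        else:
            anchor, seq = left_align_deletion(ref_seq, anchor, len(seq))
        if anchor < 1:
            continue  # unanchorable at the very start of the orientation
        key = (kind, anchor)
        normalised[key] = normalised.get(key, "") + seq
    si = 0 if strand == "+" else 1
    for (kind, anchor), seq in normalised.items():
        store = pileup.insertions if kind == "I" else pileup.deletions
        counts = store.setdefault(anchor, {}).setdefault(seq, [0, 0])
        counts[si] += 1


class _FastBuffers:
    """Per-read-length buffers for vectorised counting of pure-M records."""

    def __init__(self, pileup: Pileup, min_base_quality: int):
        self.pileup = pileup
        self.minq = min_base_quality
        self.by_len: dict[int, list] = {}

    def add(self, rec: AlignmentRecord, length: int) -> None:
        buf = self.by_len.setdefault(length, [[], [], [], []])
        buf[0].append(rec.position - 1)
        buf[1].append(0 if rec.strand == "+" else 1)
        buf[2].append(rec.bases.encode("ascii"))
        buf[3].append(rec.base_qualities.tobytes())
        if len(buf[0]) * length >= _FLUSH_ENTRIES:
            self._flush(length)

    def _flush(self, length: int) -> None:
        starts, strands, bases, quals = self.by_len.pop(length)
        if not starts:
            return
        L = len(self.pileup)
        st = np.asarray(starts, dtype=np.int64)
        strand_arr = np.asarray(strands, dtype=np.int64)
        pos = (st[:, None] + np.arange(length, dtype=np.int64)).reshape(-1)
        codes = _BASE_LUT[np.frombuffer(b"".join(bases), dtype=np.uint8)]
        q = np.frombuffer(b"".join(quals), dtype=np.uint8)
        strand = np.repeat(strand_arr, length)
        self.pileup.raw_depth += np.bincount(pos, minlength=L)
        end_idx = (st + length - 1) * 2 + strand_arr
        self.pileup.end_depth += np.bincount(end_idx, minlength=L * 2).reshape(L, 2)
        ok = (q >= self.minq) & (codes < 4)
        self.pileup.qualified_depth += np.bincount(pos[ok], minlength=L)
        idx = pos[ok] * 8 + codes[ok].astype(np.int64) * 2 + strand[ok]
        self.pileup.base_counts += np.bincount(idx, minlength=L * 8).reshape(L, 4, 2)

    def flush_all(self) -> None:
        for length in list(self.by_len):
            self._flush(length)


def _count_slow(pileup: Pileup, rec: AlignmentRecord, minq: int) -> None:
    """Per-operation counting for records with I/D/S operations."""
    L = len(pileup)
    refp = rec.position - 1  # 0-based
    readp = 0
    si = 0 if rec.strand == "+" else 1
    codes = _BASE_LUT[np.frombuffer(rec.bases.encode("ascii"), dtype=np.uint8)]
    quals = rec.base_qualities
    events: list[tuple[str, int, str]] = []
    for n, op in rec.cigar:
        if op == "M":
            pos = np.arange(refp, refp + n)
            c = codes[readp : readp + n]
            q = quals[readp : readp + n]
            pileup.raw_depth[pos] += 1
            ok = (q >= minq) & (c < 4)
            pileup.qualified_depth[pos[ok]] += 1
            np.add.at(pileup.base_counts, (pos[ok], c[ok].astype(np.int64), si), 1)
            refp += n
            readp += n
        elif op == "I":
            if refp >= 1:  # anchor at the preceding aligned position
                events.append(("I", refp, rec.bases[readp : readp + n]))
            readp += n
        elif op == "D":
            span = np.arange(refp, refp + n)
            pileup.raw_depth[span] += 1
            pileup.qualified_depth[span] += 1
            events.append(("D", refp, pileup.ref.sequence[refp : refp + n]))
            refp += n
        elif op == "S":
            readp += n
    if refp > rec.position - 1:  # read consumed reference bases
        pileup.end_depth[refp - 1, si] += 1
    if events:
        _count_read_indels(pileup, events, rec.strand)


def build_pileup(
    records: Iterable[AlignmentRecord],
    ref: CircularReference,
    params: FilterParams | None = None,
) -> Pileup:
    """Build per-position counts from records aligned to one orientation.

    Raises
    ------
    ValueError
        If a record's reference name does not match ``ref`` or its alignment
        extends past position ``L``: circular reads must be supplied against
        the orientation where they are contiguous — that is the role of the
        dual-reference design.
    """
    params = params or FilterParams()
    pileup = Pileup(ref)
    fast = _FastBuffers(pileup, params.min_base_quality)
    L = ref.length
    for rec in records:
        if rec.reference_name != ref.name:
            raise ValueError(
                f"{rec.read_id}: aligned to {rec.reference_name!r}, expected {ref.name!r}"
            )
        if (
            adjusted_mapping_quality(rec, ref, params.mapq_adjust_coefficient, params.mapq_hook)
            < params.min_mapping_quality
        ):
            continue
        end = rec.position - 1 + rec.reference_span()
        if end > L:
            raise ValueError(
                f"{rec.read_id}: alignment extends past reference end "
                f"({end} > {L}); align origin-spanning reads to the shifted orientation"
            )
        if len(rec.cigar) == 1 and rec.cigar[0][1] == "M":
            fast.add(rec, rec.cigar[0][0])
        else:
            _count_slow(pileup, rec, params.min_base_quality)
    fast.flush_all()
    return pileup
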
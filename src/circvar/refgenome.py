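"""Circular reference genomes: loading, N-stripping, and origin shifting.

Small circular genomes (mitochondrial DNA, plasmids, viral episomes) are
numbered from an arbitrary origin.  Reads spanning that origin cannot be
aligned contiguously against the linearised sequence, so the pipeline aligns
everything twice: once against the reference as given and once against a copy
rotated by half the genome length ("shifted reference").  This module owns the
coordinate bookkeeping that makes the two runs mergeable.

Conventions
-----------
* Coordinates are 1-based and fully closed throughout the package.
* The human mitochondrial reference (rCRS) carries a historical placeholder
  ``N`` at position 3107; aligners require it removed.  ``load_reference``
  can strip every ``N`` while recording, for each retained base, the position
  it had in the original numbering (``coord_map``), so reports stay in the
  conventional coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "CircularReference",
    "load_reference",
    "shift_reference",
    "unshift_position",
    "shift_position",
]

_VALID = set("ACGT")
_VALID_WITH_N = set("ACGTN")


@dataclass(frozen=True)
class CircularReference:
    """A circular nucleotide sequence plus its coordinate bookkeeping.

    Attributes
    ----------
    name:
        Sequence identifier (the FASTA header word / SAM reference name).
    sequence:
        Uppercase nucleotide string.  After N-stripping it contains only
        ``ACGT``.
    shift_offset:
        Rotation applied relative to the original orientation, in bases
        (0 for the original orientation; ``L // 2`` for the shifted copy).
    coord_map:
        ``coord_map[i]`` is the reported (original-numbering) position of
        internal position ``i + 1``.  Identity for inputs without ``N``.
    """

    name: str
    sequence: str
    shift_offset: int = 0
    coord_map: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence is empty")
        if self.coord_map is None:
            object.__setattr__(
                self, "coord_map", np.arange(1, len(self.sequence) + 1, dtype=np.int64)
            )
        if len(self.coord_map) != len(self.sequence):
            raise ValueError("coord_map length does not match sequence length")
        L = len(self.sequence)
        if not (self.shift_offset == 0 or 1 <= self.shift_offset < L):
            raise ValueError(f"shift offset {self.shift_offset} out of range for L={L}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based internal position."""
        return self.sequence[position - 1]

    def report_position(self, position: int) -> int:
        """Reported (original-numbering) position for an internal position."""
        return int(self.coord_map[position - 1])


def load_reference(path, strip_n: bool = True) -> CircularReference:
    """Read a single-record FASTA into a :class:`CircularReference`.

    With ``strip_n`` every ``N`` is deleted from the sequence and
    ``coord_map`` records the original numbering of the retained bases
    (generalising the single-placeholder convention of the human rCRS to any
    number of ``N`` positions).

    Raises
    ------
    ValueError
        On multi-record FASTA, empty sequences, or characters outside
        ``ACGTN``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError("reference sequence is empty")
    bad = set(seq) - _VALID_WITH_N
    if bad:
        raise ValueError(f"non-nucleotide characters in reference: {sorted(bad)}")
    if strip_n and "N" in seq:
        keep = [i for i, b in enumerate(seq) if b != "N"]
        if not keep:
            raise ValueError("reference contains only N bases")
        coord_map = np.asarray(keep, dtype=np.int64) + 1
        seq = "".join(seq[i] for i in keep)
        return CircularReference(rec.id, seq, 0, coord_map)
    return CircularReference(rec.id, seq)


def shift_reference(ref: CircularReference) -> CircularReference:
    """Rotate the origin to the sequence midpoint.

    The returned copy has ``shift_offset = L // 2`` and its position 1 is the
    original position ``L // 2 + 1``; its name carries a ``_shifted`` suffix so
    the two alignment runs cannot be confused.

    Raises
    ------
    ValueError
        If ``ref`` is already shifted.
    """
    if ref.shift_offset != 0:
        raise ValueError("reference is already shifted")
    s = ref.length // 2
    seq = ref.sequence[s:] + ref.sequence[:s]
    coord_map = np.roll(ref.coord_map, -s)
    return CircularReference(f"{ref.name}_shifted", seq, s, coord_map)


def unshift_position(p_shifted: int, s: int, L: int) -> int:
    """Map a 1-based position on the shifted orientation back to the original.

    ``((p - 1 + s) mod L) + 1``; identity when ``s == 0``.
    """
    if not 1 <= p_shifted <= L:
        raise ValueError(f"position {p_shifted} outside [1, {L}]")
    return (p_shifted - 1 + s) % L + 1


def shift_position(p_original: int, s: int, L: int) -> int:
    """Map a 1-based position on the original orientation to the shifted one."""
    if not 1 <= p_original <= L:
        raise ValueError(f"position {p_original} outside [1, {L}]")
    return (p_original - 1 - s) % L + 1
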
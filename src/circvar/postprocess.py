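"""Dual-run merging, coverage flags, consensus symbols, heteroplasmy classes
and pedigree variant-sharing.

Relative coverage is each position's depth as a percentage of the sample mean
(computed over *all* reference positions, zero-coverage ones included) and is
flagged ``GOOD`` (>= 10%), ``WARNING`` (>= 1% and < 10%) or ``EXCLUDE``
(< 1%).  Excluded positions are masked: the consensus symbol becomes ``N``
and the variant frequency is forced to 0 so no variant can be reported there.

Variant frequencies partition into three reporting classes: homoplasmic
(> 98%), high-frequency heteroplasmy (10–98%) and low-frequency heteroplasmy
(1–10%); exactly 10% counts as high so the classes tile the axis.  SNVs below
1% and indels below 10% are not reported, and by default neither are variants
on positions flagged ``WARNING`` (a reporting-layer choice, reversible with
``require_good=False``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .refgenome import unshift_position
from .seqio import PositionRow

__all__ = [
    "FlagThresholds",
    "HeteroplasmyClass",
    "relative_coverage",
    "flag_coverage",
    "apply_flags",
    "merge_dual",
    "classify_heteroplasmy",
    "classify_rows",
    "Pedigree",
    "read_pedigree",
    "TransmissionReport",
    "transmission_table",
]


@dataclass(frozen=True)
class FlagThresholds:
    """Relative-coverage flag boundaries, in percent of the sample mean."""

    good_min: float = 10.0
    warn_min: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.warn_min < self.good_min:
            raise ValueError("need 0 <= warn_min < good_min")


class HeteroplasmyClass(str, enum.Enum):
    HOMOPLASMIC = "HOMOPLASMIC"  # frequency > 98%
    HIGH = "HIGH"  # 10% <= frequency <= 98%
    LOW = "LOW"  # 1% <= frequency < 10%  (SNVs only; indels report from 10%)
    NOT_REPORTED = "NOT_REPORTED"


def relative_coverage(rows: list[PositionRow]) -> list[PositionRow]:
    """Set ``percent_cov`` on every row: 100 * Covmp / mean(Covmp).

    The mean runs over all reference positions, including zero-coverage ones.

    Raises
    ------
    ValueError
        On an empty row list or all-zero coverage.
    """
    if not rows:
        raise ValueError("no rows")
    mean = float(np.mean([r.covmp for r in rows]))
    if mean == 0:
        raise ValueError("all positions have zero coverage")
    for r in rows:
        r.percent_cov = 100.0 * r.covmp / mean
    return rows


def flag_coverage(percent: float, thresholds: FlagThresholds | None = None) -> str:
    """``GOOD``/``WARNING``/``EXCLUDE`` for a relative coverage percentage.

    Boundaries are inclusive at the lower edge of each class: exactly 10% is
    ``GOOD`` and exactly 1% is ``WARNING``.
    """
    thresholds = thresholds or FlagThresholds()
    if percent >= thresholds.good_min:
        return "GOOD"
    if percent >= thresholds.warn_min:
        return "WARNING"
    return "EXCLUDE"


def apply_flags(rows: list[PositionRow], thresholds: FlagThresholds | None = None) -> list[PositionRow]:
    """Flag every row and mask excluded positions (FastA ``N``, Freq 0)."""
    for r in rows:
        r.filter_cov = flag_coverage(r.percent_cov, thresholds)
        if r.filter_cov == "EXCLUDE":
            r.fasta = "N"
            r.cons = "N"
            r.freq = 0.0
            r.var = ""
    return rows


def merge_dual(
    rows_original: list[PositionRow],
    rows_shifted: list[PositionRow],
    s: int,
    L: int,
) -> list[PositionRow]:
    """Merge the original- and shifted-orientation runs position by position.

    Shifted rows are re-coordinated to original numbering first; then, per
    position, the row with the larger ``Covmp`` is kept intact (all columns
    travel together).  Ties keep the original-orientation row, whose
    numbering is native.  Output is sorted by position.
    """
    if len(rows_original) != L or len(rows_shifted) != L:
        raise ValueError(
            f"row lists must both have length {L} "
            f"(got {len(rows_original)} and {len(rows_shifted)})"
        )
    by_pos: dict[int, PositionRow] = {}
    for r in rows_shifted:
        moved = r.copy(position=unshift_position(r.position, s, L))
        by_pos[moved.position] = moved
    merged: list[PositionRow] = []
    for r in rows_original:
        shifted = by_pos.get(r.position)
        if shifted is not None and shifted.covmp > r.covmp:
            merged.append(shifted)
        else:
            merged.append(r)
    merged.sort(key=lambda r: r.position)
    return merged


def classify_heteroplasmy(
    freq_percent: float,
    var_type: str,
    flag: str = "GOOD",
    require_good: bool = True,
    snv_min: float = 1.0,
    indel_min: float = 10.0,
    homoplasmy_min: float = 98.0,
    high_min: float = 10.0,
) -> HeteroplasmyClass:
    """Reporting class for a variant frequency (in percent).

    ``NOT_REPORTED`` when the position's coverage flag is not ``GOOD`` (with
    ``require_good``), when an SNV sits below ``snv_min`` or an indel below
    ``indel_min``; otherwise homoplasmic strictly above ``homoplasmy_min``,
    high-frequency heteroplasmy from ``high_min`` up to and including
    ``homoplasmy_min``, low-frequency heteroplasmy below ``high_min``.
    """
    if var_type == "NONE":
        return HeteroplasmyClass.NOT_REPORTED
    if require_good and flag != "GOOD":
        return HeteroplasmyClass.NOT_REPORTED
    floor = indel_min if var_type in ("INS", "DEL") else snv_min
    if freq_percent < floor:
        return HeteroplasmyClass.NOT_REPORTED
    if freq_percent > homoplasmy_min:
        return HeteroplasmyClass.HOMOPLASMIC
    if freq_percent >= high_min:
        return HeteroplasmyClass.HIGH
    return HeteroplasmyClass.LOW


def classify_rows(
    rows: list[PositionRow],
    require_good: bool = True,
    snv_min: float = 1.0,
    indel_min: float = 10.0,
) -> dict[tuple[int, str], tuple[float, HeteroplasmyClass]]:
    """Reported variants of one sample: ``(position, allele) -> (freq %, class)``."""
    out: dict[tuple[int, str], tuple[float, HeteroplasmyClass]] = {}
    for r in rows:
        if not r.var:
            continue
        cls = classify_heteroplasmy(
            r.freq,
            r.var_type,
            r.filter_cov,
            require_good=require_good,
            snv_min=snv_min,
            indel_min=indel_min,
        )
        if cls is not HeteroplasmyClass.NOT_REPORTED:
            out[(r.position, r.var)] = (r.freq, cls)
    return out


# ---------------------------------------------------------------------------
# Pedigree transmission screens
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeEntry:
    sample: str
    mother: str | None
    father: str | None
    generation: int | None = None


class Pedigree(dict):
    """``sample -> PedigreeEntry`` with convenience accessors."""

    def children_of(self, parent: str) -> list[str]:
        return [s for s, e in self.items() if parent in (e.mother, e.father)]


_MISSING = {"", "0", "NA", "na", ".", "-"}


def read_pedigree(path) -> Pedigree:
    """Read a tab-separated pedigree: ``sample  mother  father [generation]``.

    A header line starting with ``sample`` is permitted; missing parents are
    ``0``, ``NA``, ``-``, ``.`` or empty.
    """
    ped = Pedigree()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "sample":
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected sample/mother/father")
            gen = int(fields[3]) if len(fields) > 3 and fields[3] not in _MISSING else None
            ped[fields[0]] = PedigreeEntry(
                sample=fields[0],
                mother=None if fields[1] in _MISSING else fields[1],
                father=None if fields[2] in _MISSING else fields[2],
                generation=gen,
            )
    return ped


@dataclass
class TransmissionReport:
    """Variant-sharing matrices across a pedigree.

    ``sharing`` holds the frequency (percent) of every reported variant in
    every sample, ``classes`` the corresponding reporting class names.
    ``paternal`` lists father-specific variants (reported in a father, absent
    from the corresponding mother) with their status in each offspring;
    ``maternal`` does the same for the mothers' variants; ``de_novo`` lists
    offspring variants absent from both parents.
    ``paternal_transmissions`` counts father-specific variants reported in at
    least one offspring (the published screen expects 0).
    """

    sharing: pd.DataFrame
    classes: pd.DataFrame
    paternal: pd.DataFrame
    maternal: pd.DataFrame
    de_novo: pd.DataFrame
    paternal_transmissions: int


def _variant_freq(rows_by_key: Mapping[tuple[int, str], PositionRow], key: tuple[int, str]) -> float:
    row = rows_by_key.get(key)
    if row is None:
        return 0.0
    return row.freq


def transmission_table(
    samples: Mapping[str, list[PositionRow]],
    pedigree: Pedigree,
    require_good: bool = True,
    snv_min: float = 1.0,
    indel_min: float = 10.0,
) -> TransmissionReport:
    """Cross-sample variant sharing plus paternal/maternal screens.

    All samples must be called against the same reference.  A variant is
    "present" in a sample when it is reported there (passing filters and the
    frequency/flag reporting rules); the sharing matrix nevertheless records
    the measured frequency of the allele in every sample, reported or not,
    so near-threshold sharing stays visible.
    """
    for name, entry in pedigree.items():
        for ref_name in (name, entry.mother, entry.father):
            if ref_name is not None and ref_name not in samples:
                raise ValueError(f"pedigree references unknown sample {ref_name!r}")
    lengths = {len(rows) for rows in samples.values()}
    if len(lengths) > 1:
        raise ValueError("samples differ in reference length")

    reported = {
        name: classify_rows(rows, require_good=require_good, snv_min=snv_min, indel_min=indel_min)
        for name, rows in samples.items()
    }
    # measured frequency of any allele in any sample, reported or not
    by_key: dict[str, dict[tuple[int, str], PositionRow]] = {}
    for name, rows in samples.items():
        d: dict[tuple[int, str], PositionRow] = {}
        for r in rows:
            if r.candidate_var:
                d[(r.position, r.candidate_var)] = r
        by_key[name] = d

    all_keys = sorted({k for rep in reported.values() for k in rep})
    names = list(samples)
    sharing = pd.DataFrame(
        [[_variant_freq(by_key[n], k) for n in names] for k in all_keys],
        index=pd.MultiIndex.from_tuples(all_keys, names=["Position", "Var"]) if all_keys else None,
        columns=names,
    )
    classes = pd.DataFrame(
        [
            [reported[n].get(k, (0.0, HeteroplasmyClass.NOT_REPORTED))[1].value for n in names]
            for k in all_keys
        ],
        index=sharing.index,
        columns=names,
    )

    paternal_rows, maternal_rows, de_novo_rows = [], [], []
    transmissions = 0
    for child, entry in pedigree.items():
        mother, father = entry.mother, entry.father
        if father is not None and mother is not None:
            father_specific = [
                k for k in reported[father] if k not in reported[mother]
            ]
            for k in father_specific:
                freq_child = _variant_freq(by_key[child], k)
                child_reported = k in reported[child]
                if child_reported:
                    transmissions += 1
                paternal_rows.append(
                    {
                        "Position": k[0],
                        "Var": k[1],
                        "Father": father,
                        "Child": child,
                        "FatherFreq": reported[father][k][0],
                        "MotherFreq": _variant_freq(by_key[mother], k),
                        "ChildFreq": freq_child,
                        "ChildReported": child_reported,
                    }
                )
        if mother is not None:
            for k, (freq_m, cls_m) in reported[mother].items():
                maternal_rows.append(
                    {
                        "Position": k[0],
                        "Var": k[1],
                        "Mother": mother,
                        "Child": child,
                        "MotherFreq": freq_m,
                        "MotherClass": cls_m.value,
                        "ChildFreq": _variant_freq(by_key[child], k),
                        "Shared": k in reported[child],
                    }
                )
            for k in reported[child]:
                in_mother = k in reported[mother]
                in_father = father is not None and k in reported[father]
                if not in_mother and not in_father:
                    de_novo_rows.append(
                        {
                            "Position": k[0],
                            "Var": k[1],
                            "Child": child,
                            "ChildFreq": reported[child][k][0],
                            "MotherFreq": _variant_freq(by_key[mother], k),
                            "FatherFreq": _variant_freq(by_key[father], k) if father else float("nan"),
                        }
                    )
    return TransmissionReport(
        sharing=sharing,
        classes=classes,
        paternal=pd.DataFrame(paternal_rows),
        maternal=pd.DataFrame(maternal_rows),
        de_novo=pd.DataFrame(de_novo_rows),
        paternal_transmissions=transmissions,
    )
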
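"""Pileup construction: quality filters, indel anchoring, oracle tallies."""

import shutil
import subprocess

import numpy as np
import pytest

from circvar.pileup import (
    FilterParams,
    adjusted_mapping_quality,
    build_pileup,
    left_align_deletion,
    left_align_insertion,
    mismatch_downgrade_hook,
)
from circvar.refgenome import CircularReference
from circvar.seqio import AlignmentRecord, write_sam


def rec(position, bases, quals=None, cigar=None, strand="+", mapq=60, name="r", refname="ref"):
    if quals is None:
        quals = [40] * len(bases)
    if cigar is None:
        cigar = [(len(bases), "M")]
    return AlignmentRecord(
        read_id=name,
        reference_name=refname,
        position=position,
        mapping_quality=mapq,
        strand=strand,
        cigar=cigar,
        bases=bases,
        base_qualities=np.asarray(quals, dtype=np.uint8),
    )


@pytest.fixture()
def ref10():
    return CircularReference("ref", "ACGTACGTAC")


class TestQualityFilters:
    def test_two_plus_reads_counted(self, ref10):
        p = build_pileup([rec(7, "GT", name="a"), rec(7, "GT", name="b")], ref10)
        col = p[6]
        assert col.base_counts[("G", "+")] == 2
        assert col.qualified_depth == 2

    def test_low_mapping_quality_contributes_nothing(self, ref10):
        p = build_pileup([rec(3, "GTAC", mapq=40)], ref10)
        assert p.raw_depth.sum() == 0 and p.qualified_depth.sum() == 0

    def test_low_base_quality_excluded_from_counts_not_raw_depth(self, ref10):
        p = build_pileup([rec(3, "GTAC", quals=[40, 30, 40, 40])], ref10)
        assert p.qualified_depth.tolist() == [0, 0, 1, 0, 1, 1, 0, 0, 0, 0]
        assert p.raw_depth.tolist() == [0, 0, 1, 1, 1, 1, 0, 0, 0, 0]
        assert p[3].base_counts == {}

    def test_minus_strand_counted_separately(self, ref10):
        p = build_pileup([rec(1, "AC"), rec(1, "AC", strand="-")], ref10)
        assert p[0].base_counts == {("A", "+"): 1, ("A", "-"): 1}

    def test_read_past_end_rejected(self, ref10):
        with pytest.raises(ValueError, match="past reference end"):
            build_pileup([rec(9, "ACG")], ref10)

    def test_wrong_reference_name_rejected(self, ref10):
        with pytest.raises(ValueError, match="aligned to"):
            build_pileup([rec(1, "AC", refname="other")], ref10)

    def test_soft_clips_ignored(self, ref10):
        r = rec(3, "TTGTA", cigar=[(2, "S"), (3, "M")])
        p = build_pileup([r], ref10)
        assert p.qualified_depth.tolist() == [0, 0, 1, 1, 1, 0, 0, 0, 0, 0]
        assert p[2].base_counts[("G", "+")] == 1


class TestBruteForceOracle:
    """Random fixtures against a direct nested-loop tally over reads and ops."""

    def _random_records(self, rng, ref, n=40):
        records = []
        for i in range(n):
            pos = int(rng.integers(1, ref.length - 30))
            ops, bases, quals = [], [], []
            refp = pos
            if rng.random() < 0.2:
                k = int(rng.integers(1, 4))
                ops.append((k, "S"))
                bases += list("ACGT"[int(rng.integers(0, 4))] * k)
                quals += [int(rng.integers(10, 45)) for _ in range(k)]
            for _ in range(int(rng.integers(1, 4))):
                k = int(rng.integers(3, 10))
                if refp + k > ref.length:
                    break
                op = rng.choice(["M", "M", "M", "I", "D"])
                if op == "M":
                    ops.append((k, "M"))
                    bases += [
                        "ACGT"[int(rng.integers(0, 4))] if rng.random() < 0.2 else ref.base(refp + j)
                        for j in range(k)
                    ]
                    quals += [int(rng.integers(10, 45)) for _ in range(k)]
                    refp += k
                elif op == "I" and ops and ops[-1][1] == "M":
                    ops.append((k, "I"))
                    bases += ["ACGT"[int(rng.integers(0, 4))] for _ in range(k)]
                    quals += [int(rng.integers(10, 45)) for _ in range(k)]
                elif op == "D" and ops and ops[-1][1] == "M" and refp + k <= ref.length:
                    ops.append((k, "D"))
                    refp += k
            if not any(op == "M" for _, op in ops):
                continue
            while ops and ops[-1][1] in "ID":
                n_last, op_last = ops.pop()
                if op_last == "I":
                    bases = bases[: len(bases) - n_last]
                    quals = quals[: len(quals) - n_last]
            records.append(
                rec(pos, "".join(bases), quals, ops, strand="+-"[int(rng.integers(0, 2))], name=f"r{i}")
            )
        return records

    def _oracle(self, records, ref, minq):
        """Independent scalar tally of depths and base counts."""
        L = ref.length
        base_counts = {}
        qual_depth = np.zeros(L, dtype=int)
        raw_depth = np.zeros(L, dtype=int)
        for r in records:
            refp = r.position
            readp = 0
            for n, op in r.cigar:
                if op == "M":
                    for j in range(n):
                        raw_depth[refp + j - 1] += 1
                        b = r.bases[readp + j]
                        if r.base_qualities[readp + j] >= minq and b in "ACGT":
                            qual_depth[refp + j - 1] += 1
                            key = (refp + j, b, r.strand)
                            base_counts[key] = base_counts.get(key, 0) + 1
                    refp += n
                    readp += n
                elif op == "I":
                    readp += n
                elif op == "D":
                    for j in range(n):
                        raw_depth[refp + j - 1] += 1
                        qual_depth[refp + j - 1] += 1
                    refp += n
                elif op == "S":
                    readp += n
        return base_counts, qual_depth, raw_depth

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_counts_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        ref = CircularReference("ref", seq)
        records = self._random_records(rng, ref)
        params = FilterParams(min_base_quality=30)
        pileup = build_pileup(records, ref, params)
        counts, qual_depth, raw_depth = self._oracle(records, ref, 30)
        assert pileup.qualified_depth.tolist() == qual_depth.tolist()
        assert pileup.raw_depth.tolist() == raw_depth.tolist()
        for (pos, b, strand), c in counts.items():
            assert pileup[pos - 1].base_counts.get((b, strand), 0) == c
        assert pileup.base_counts.sum() == sum(counts.values())

    @pytest.mark.parametrize("seed", [0, 2])
    def test_conservation_and_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        ref = CircularReference("ref", seq)
        records = self._random_records(rng, ref)
        pileup = build_pileup(records, ref, FilterParams(min_base_quality=30))
        # conservation: qualified depth = base counts + deletion spans
        del_span = np.zeros(ref.length, dtype=int)
        for r in records:
            if adjusted_mapping_quality(r, ref, 50) < 50:
                continue
            refp = r.position
            for n, op in r.cigar:
                if op == "M":
                    refp += n
                elif op == "D":
                    del_span[refp - 1 : refp - 1 + n] += 1
                    refp += n
        per_pos = pileup.base_counts.sum(axis=(1, 2)) + del_span
        assert per_pos.tolist() == pileup.qualified_depth.tolist()
        # determinism under shuffling
        shuffled = list(records)
        np.random.default_rng(99).shuffle(shuffled)
        pileup2 = build_pileup(shuffled, ref, FilterParams(min_base_quality=30))
        assert np.array_equal(pileup.base_counts, pileup2.base_counts)
        assert pileup.insertions == pileup2.insertions
        assert pileup.deletions == pileup2.deletions

    def test_error_free_simulation_depth_identity(self, small_haplotypes, small_sim, small_design):
        """All qualities 40 / mapq 60: qualified depth sums to aligned M bases."""
        ref, _ = small_haplotypes
        pileup = build_pileup(small_sim.records_original, ref)
        m_bases = sum(
            n for r in small_sim.records_original for n, op in r.cigar if op == "M"
        )
        dels = sum(
            n for r in small_sim.records_original for n, op in r.cigar if op == "D"
        )
        assert pileup.qualified_depth.sum() == m_bases + dels


class TestIndelEvents:
    def test_insertion_anchored_at_preceding_position(self):
        ref = CircularReference("ref", "ACGTACGTAC")
        r = rec(3, "GTCCAC", cigar=[(2, "M"), (2, "I"), (2, "M")])
        p = build_pileup([r], ref)
        assert p.insertions == {4: {"CC": [1, 0]}}
        assert p.qualified_depth.tolist() == [0, 0, 1, 1, 1, 1, 0, 0, 0, 0]

    def test_deletion_recorded_at_anchor_and_in_depth(self):
        ref = CircularReference("ref", "ACGTACGTAC")
        r = rec(3, "GTGT", cigar=[(2, "M"), (2, "D"), (2, "M")])
        p = build_pileup([r], ref)
        assert p.deletions == {4: {"AC": [1, 0]}}
        assert p.qualified_depth.tolist() == [0, 0, 1, 1, 1, 1, 1, 1, 0, 0]

    def test_insertion_left_aligned_into_homopolymer(self):
        # ref: C C A A A A T G ; +A after the run slides to the C at position 2
        ref = CircularReference("ref", "CCAAAATG")
        r = rec(2, "CAAAAAT", cigar=[(5, "M"), (1, "I"), (1, "M")])
        p = build_pileup([r], ref)
        assert p.insertions == {2: {"A": [1, 0]}}

    def test_split_insertion_events_merge_at_common_anchor(self):
        # ref: T T A A A A G ; two split +A events normalise to one +AA at the TT anchor
        ref = CircularReference("ref", "TTAAAAG")
        r = rec(1, "TTAAAAAAG", cigar=[(2, "M"), (1, "I"), (4, "M"), (1, "I"), (1, "M")])
        p = build_pileup([r], ref)
        assert p.insertions == {2: {"AA": [1, 0]}}

    def test_deletion_left_aligned(self):
        # ref: T A A A A G ; deleting two As anywhere in the run anchors at the T
        ref = CircularReference("ref", "TAAAAG")
        r = rec(1, "TAAG", cigar=[(3, "M"), (2, "D"), (1, "M")])
        p = build_pileup([r], ref)
        assert p.deletions == {1: {"AA": [1, 0]}}

    @pytest.mark.parametrize(
        "seq, anchor, ins, expected",
        [
            ("CCAAAATG", 6, "A", (2, "A")),
            ("CCAAAATG", 6, "AA", (2, "AA")),
            ("ACGTACGT", 4, "GG", (4, "GG")),
            ("GGGGACGT", 4, "G", (0, "G")),  # slides off the start: unanchorable
        ],
    )
    def test_left_align_insertion_examples(self, seq, anchor, ins, expected):
        assert left_align_insertion(seq, anchor, ins) == expected

    def test_left_align_deletion_examples(self):
        assert left_align_deletion("TAAAAG", 3, 2) == (1, "AA")
        assert left_align_deletion("ACGTAC", 2, 2) == (2, "GT")


class TestMapqAdjustment:
    def test_identity_by_default(self, ref10):
        r = rec(1, "ACGT", mapq=60)
        assert adjusted_mapping_quality(r, ref10, 50) == 60

    def test_hook_equals_identity_without_mismatches(self, ref10):
        r = rec(1, "ACGT", mapq=60)
        assert mismatch_downgrade_hook(r, ref10, 50) == 60

    def test_hook_monotone_in_mismatches(self, ref10):
        reads = [rec(1, b, mapq=60) for b in ("ACGTACGTAC", "TCGTACGTAC", "TTTTACGTAC", "TTTTTTTTAC")]
        adj = [mismatch_downgrade_hook(r, ref10, 50) for r in reads]
        assert adj[0] == 60
        assert all(a >= b for a, b in zip(adj, adj[1:]))
        assert all(a <= 60 for a in adj)

    def test_hook_filters_records_in_pileup(self, ref10):
        mismatchy = rec(1, "TTTTTTTTAC", mapq=60)
        params = FilterParams(mapq_hook=mismatch_downgrade_hook)
        assert build_pileup([mismatchy], ref10, params).qualified_depth.sum() == 0
        assert build_pileup([mismatchy], ref10).qualified_depth.sum() == 10


@pytest.mark.skipif(shutil.which("samtools") is None, reason="samtools not on PATH")
class TestSamtoolsCrossCheck:
    """Depth/base counts cross-checked against samtools mpileup on a fixture."""

    def test_counts_match_samtools(self, tmp_path, small_design, small_haplotypes):
        import numpy as np

        from circvar.simulate import simulate_reads

        ref, truth = small_haplotypes
        rng = np.random.default_rng(7)
        sim = simulate_reads(small_design, ref, truth, 30.0, rng)
        records = sim.records_original
        sam = tmp_path / "x.sam"
        write_sam(records, ref, sam)
        fa = tmp_path / "ref.fa"
        fa.write_text(f">{ref.name}\n{ref.sequence}\n")
        bam = tmp_path / "x.bam"
        subprocess.run(["samtools", "sort", "-o", str(bam), str(sam)], check=True, capture_output=True)
        subprocess.run(["samtools", "index", str(bam)], check=True, capture_output=True)
        out = subprocess.run(
            ["samtools", "mpileup", "-aa", "-B", "-Q", "35", "-q", "50", "-d", "100000", "-f", str(fa), str(bam)],
            check=True, capture_output=True, text=True,
        ).stdout
        pileup = build_pileup(records, ref)
        their_depth = np.zeros(ref.length, dtype=int)
        their_counts = {}
        for line in out.splitlines():
            chrom, pos, refb, depth, bases, _ = line.split("\t")[:6]
            pos = int(pos)
            their_depth[pos - 1] = int(depth)
            counts = {}
            i = 0
            while i < len(bases):
                c = bases[i]
                if c == "^":
                    i += 2
                    continue
                if c in "$*":
                    i += 1
                    continue
                if c in "+-":
                    j = i + 1
                    while bases[j].isdigit():
                        j += 1
                    n = int(bases[i + 1 : j])
                    i = j + n
                    continue
                if c == ".":
                    key = (refb.upper(), "+")
                elif c == ",":
                    key = (refb.upper(), "-")
                elif c.isupper():
                    key = (c, "+")
                else:
                    key = (c.upper(), "-")
                counts[key] = counts.get(key, 0) + 1
                i += 1
            their_counts[pos] = counts
        assert pileup.qualified_depth.tolist() == their_depth.tolist()
        mismatches = [
            p
            for p in range(1, ref.length + 1)
            if pileup[p - 1].base_counts != {k: v for k, v in their_counts[p].items() if v}
        ]
        assert mismatches == []
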
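"""Coverage blocks, proper-pair bridging, superblock construction, partitioning."""
import numpy as np
import pytest

from refguide import (
    AlignmentRecord,
    Block,
    SuperblockParams,
    bridge_blocks,
    build_superblocks,
    call_blocks,
    collect_unmapped,
    partition_reads,
)


def aln(rid, mate, ref, pos, length=100, proper=False, mate_pos=-1, unmapped=False,
        mate_ref=None):
    if unmapped:
        return AlignmentRecord(rid, mate, None, paired=True, mate_ref_id=mate_ref,
                               mate_pos=mate_pos)
    return AlignmentRecord(
        rid, mate, ref, pos=pos, cigar=[("M", length)], mapq=60, paired=True,
        proper_pair=proper, mate_ref_id=mate_ref or ref, mate_pos=mate_pos,
    )


class TestCallBlocks:
    def test_no_alignments(self):
        assert call_blocks([]) == []

    def test_overlapping_reads_form_one_block(self):
        alns = [aln("a", 1, "c", 0), aln("b", 1, "c", 50)]
        blocks = call_blocks(alns)
        assert [(b.start, b.end, b.n_reads) for b in blocks] == [(0, 150, 2)]

    def test_coverage_gap_splits_blocks(self):
        alns = [aln("a", 1, "c", 0), aln("b", 1, "c", 200)]
        blocks = call_blocks(alns)
        assert [(b.start, b.end) for b in blocks] == [(0, 100), (200, 300)]

    def test_refs_kept_separate(self):
        alns = [aln("a", 1, "c1", 0), aln("b", 1, "c2", 0)]
        assert [b.ref_id for b in call_blocks(alns)] == ["c1", "c2"]


class TestBridgeBlocks:
    def _bridging_fixture(self, n_pairs):
        """Two blocks [0,1000) and [1500,2500) with n_pairs spanning pairs."""
        alns = [aln("x", 1, "c", 0, 1000), aln("y", 1, "c", 1500, 1000)]
        for i in range(n_pairs):
            alns.append(aln(f"p{i}", 1, "c", 800, proper=True, mate_pos=1600))
            alns.append(aln(f"p{i}", 2, "c", 1600, proper=True, mate_pos=800))
        return alns

    def test_ten_proper_pairs_merge(self):
        alns = self._bridging_fixture(10)
        blocks = bridge_blocks(call_blocks(alns), alns)
        assert [(b.start, b.end) for b in blocks] == [(0, 2500)]

    def test_nine_proper_pairs_do_not_merge(self):
        alns = self._bridging_fixture(9)
        blocks = bridge_blocks(call_blocks(alns), alns)
        assert len(blocks) == 2

    def test_improper_pairs_never_merge(self):
        alns = [aln("x", 1, "c", 0, 1000), aln("y", 1, "c", 1500, 1000)]
        for i in range(20):
            alns.append(aln(f"p{i}", 1, "c", 800, proper=False, mate_pos=1600))
            alns.append(aln(f"p{i}", 2, "c", 1600, proper=False, mate_pos=800))
        assert len(bridge_blocks(call_blocks(alns), alns)) == 2

    def test_raising_threshold_is_monotone(self, rng):
        alns = []
        pos = 0
        for b in range(8):
            alns.append(aln(f"b{b}", 1, "c", pos, 500))
            n = int(rng.integers(0, 15))
            for i in range(n):
                alns.append(aln(f"p{b}_{i}", 1, "c", pos + 300, proper=True,
                                mate_pos=pos + 900))
                alns.append(aln(f"p{b}_{i}", 2, "c", pos + 900, proper=True,
                                mate_pos=pos + 300))
            pos += 900
        blocks = call_blocks(alns)
        prev = None
        for thresh in (1, 5, 10, 15):
            merged = bridge_blocks(blocks, alns, SuperblockParams(bridge_pairs=thresh))
            if prev is not None:
                assert len(merged) >= prev  # more stringent -> never fewer blocks
            prev = len(merged)


class TestBuildSuperblocks:
    def test_two_blocks_reach_min_len(self):
        blocks = [Block("c", 0, 7000), Block("c", 7000, 14000)]
        sbs = build_superblocks(blocks)
        assert [(s.start, s.end, s.terminal) for s in sbs] == [(0, 14000, False)]

    def test_long_block_split_with_exact_overlap(self):
        sbs = build_superblocks([Block("c", 0, 250_000)])
        assert len(sbs) == 3
        for s in sbs:
            assert len(s) <= 100_000
        for a, b in zip(sbs, sbs[1:]):
            assert a.end - b.start == 300

    def test_trailing_short_block_is_terminal(self):
        sbs = build_superblocks([Block("c", 0, 5000)])
        assert len(sbs) == 1 and sbs[0].terminal and len(sbs[0]) == 5000

    def test_overlap_extends_leftward_over_small_shared_blocks(self):
        # last block of the first superblock is only 100 bp: the overlap
        # must grow leftward until >= 300 bp is shared
        blocks = [
            Block("c", 0, 6000),
            Block("c", 6000, 11_900),
            Block("c", 11_900, 12_000),
            Block("c", 12_000, 30_000),
        ]
        sbs = build_superblocks(blocks)
        assert len(sbs) >= 2
        assert sbs[0].end - sbs[1].start >= 300

    def test_invariants_on_random_blocks(self, rng):
        for trial in range(20):
            blocks = []
            pos = 0
            for _ in range(int(rng.integers(1, 40))):
                pos += int(rng.integers(0, 2000))
                length = int(rng.integers(100, 30_000))
                blocks.append(Block("c", pos, pos + length))
                pos += length
            sbs = build_superblocks(blocks)
            for s in sbs[:-1]:
                assert 12_000 <= len(s) <= 100_000 or s.terminal
            for a, b in zip(sbs, sbs[1:]):
                assert a.end - b.start >= 300 or a.terminal or b.terminal
            # every block interval is covered by some superblock
            for blk in blocks:
                assert any(s.start <= blk.start and s.end >= blk.end or
                           (s.start < blk.end and s.end > blk.start) for s in sbs)


class TestPartitionReads:
    def _setup(self):
        blocks = [Block("c", 0, 14000)]
        sbs = build_superblocks(blocks)
        return sbs

    def test_mapped_pair_and_unmapped_mate_included(self):
        sbs = self._setup()
        alns = [
            aln("p", 1, "c", 100, proper=True, mate_pos=300),
            aln("p", 2, "c", 300, proper=True, mate_pos=100),
            aln("u", 1, "c", 500),
            aln("u", 2, "c", 0, unmapped=True, mate_ref="c", mate_pos=500),
        ]
        partition_reads(sbs, alns)
        assert {("p", 1), ("p", 2), ("u", 1), ("u", 2)} <= sbs[0].read_ids

    def test_read_in_overlap_zone_in_both_superblocks(self):
        sbs = build_superblocks([Block("c", 0, 250_000)])
        boundary = sbs[1].start + 100  # inside the 300 bp overlap
        alns = [aln("r", 1, "c", boundary)]
        partition_reads(sbs, alns)
        assert ("r", 1) in sbs[0].read_ids and ("r", 1) in sbs[1].read_ids

    def test_partition_completeness(self, rng):
        """Every mapped read lands in >= 1 superblock; with the unmapped
        set this recovers all read keys."""
        alns = []
        for i in range(300):
            pos = int(rng.integers(0, 50_000))
            alns.append(aln(f"r{i}", 1, "c", pos))
        for i in range(20):
            alns.append(aln(f"u{i}", 1, "c", 0, unmapped=True))
        blocks = call_blocks(alns)
        sbs = build_superblocks(blocks)
        partition_reads(sbs, alns)
        in_sbs = set().union(*(s.read_ids for s in sbs))
        unmapped = collect_unmapped(alns)
        assert in_sbs | unmapped == {a.key for a in alns}

    def test_all_mapped_means_empty_unmapped_set(self):
        alns = [aln("a", 1, "c", 0)]
        assert collect_unmapped(alns) == set()
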
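"""Step 2 — coverage blocks, proper-pair bridging, superblocks, read partitioning.

Reads mapped against the related reference are grouped into *blocks*
(maximal intervals of continuous read coverage).  Adjacent blocks whose
gap is spanned by at least 10 proper pairs are bridged.  Consecutive
blocks are then combined into *superblocks* of at least 12 kb that
overlap their neighbours by at least 300 bp (by sharing blocks); any
superblock longer than 100 kb is split into 100 kb pieces overlapping by
exactly 300 bp.  Each superblock collects the reads mapped inside it
plus unmapped mates, defining an independent local assembly problem.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .io import AlignmentRecord


@dataclass
class SuperblockParams:
    min_len: int = 12_000
    min_overlap: int = 300
    max_len: int = 100_000
    bridge_pairs: int = 10

    def __post_init__(self):
        if not self.min_overlap < self.min_len <= self.max_len:
            raise ValueError("require min_overlap < min_len <= max_len")


@dataclass
class Block:
    """A maximal reference interval with continuous read coverage."""

    ref_id: str
    start: int
    end: int
    n_reads: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty block [{self.start}, {self.end})")

    def __len__(self):
        return self.end - self.start


@dataclass
class Superblock:
    """An overlapping group of consecutive blocks, one local assembly unit."""

    ref_id: str
    start: int
    end: int
    member_blocks: list[Block] = field(default_factory=list)
    read_ids: set = field(default_factory=set)  # (read_id, mate) keys
    terminal: bool = False

    def __len__(self):
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"sb_{self.ref_id}_{self.start}_{self.end}"


def call_blocks(alignments: Iterable[AlignmentRecord], ref_id: Optional[str] = None) -> list[Block]:
    """Maximal intervals with read depth >= 1, per reference, sorted by start.

    All primary mapped alignments count regardless of mapq (no quality
    filter applies at this stage).  When ``ref_id`` is given only that
    reference is considered.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for a in alignments:
        if a.unmapped or (ref_id is not None and a.ref_id != ref_id):
            continue
        spans.setdefault(a.ref_id, []).append((a.pos, a.end))
    blocks: list[Block] = []
    for rid in sorted(spans):
        ivs = sorted(spans[rid])
        cs, ce, n = ivs[0][0], ivs[0][1], 0
        for s, e in ivs:
            if s > ce:  # coverage drops to zero
                blocks.append(Block(rid, cs, ce, n))
                cs, ce, n = s, e, 0
            ce = max(ce, e)
            n += 1
        blocks.append(Block(rid, cs, ce, n))
    return blocks


def _block_of(blocks_starts: list[int], blocks: list[Block], pos: int) -> Optional[int]:
    i = bisect.bisect_right(blocks_starts, pos) - 1
    if i >= 0 and blocks[i].start <= pos < blocks[i].end:
        return i
    return None


def bridge_blocks(blocks: list[Block], alignments: Iterable[AlignmentRecord],
                  params: SuperblockParams = SuperblockParams()) -> list[Block]:
    """Merge adjacent blocks spanned by >= ``bridge_pairs`` proper pairs.

    A pair counts when its two mates fall in the two adjacent blocks.
    Merging is transitive in a single left-to-right pass; the merged
    block includes the gap.
    """
    by_ref: dict[str, list[Block]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_id, []).append(b)
    # count bridging proper pairs between adjacent block indices
    bridge_counts: dict[str, dict[int, set]] = {r: {} for r in by_ref}
    starts = {r: [b.start for b in bs] for r, bs in by_ref.items()}
    seen_pairs: set = set()
    for a in alignments:
        if not a.proper_pair or a.unmapped or a.read_id in seen_pairs:
            continue
        if a.ref_id not in by_ref or a.mate_ref_id != a.ref_id:
            continue
        seen_pairs.add(a.read_id)
        bs = by_ref[a.ref_id]
        i = _block_of(starts[a.ref_id], bs, a.pos)
        j = _block_of(starts[a.ref_id], bs, a.mate_pos)
        if i is None or j is None or abs(i - j) != 1:
            continue
        lo = min(i, j)
        bridge_counts[a.ref_id].setdefault(lo, set()).add(a.read_id)
    out: list[Block] = []
    for rid in sorted(by_ref):
        bs = by_ref[rid]
        counts = bridge_counts[rid]
        cur = Block(rid, bs[0].start, bs[0].end, bs[0].n_reads)
        for i in range(1, len(bs)):
            if len(counts.get(i - 1, ())) >= params.bridge_pairs:
                cur = Block(rid, cur.start, bs[i].end, cur.n_reads + bs[i].n_reads)
            else:
                out.append(cur)
                cur = Block(rid, bs[i].start, bs[i].end, bs[i].n_reads)
        out.append(cur)
    return out


def _split_long(sb: Superblock, params: SuperblockParams) -> list[Superblock]:
    if len(sb) <= params.max_len:
        return [sb]
    step = params.max_len - params.min_overlap
    pieces = []
    s = sb.start
    while s < sb.end:
        e = min(s + params.max_len, sb.end)
        members = [b for b in sb.member_blocks if b.start < e and b.end > s]
        pieces.append(Superblock(sb.ref_id, s, e, members, terminal=False))
        if e == sb.end:
            break
        s = e - params.min_overlap
    pieces[-1].terminal = sb.terminal
    return pieces


def build_superblocks(blocks: Sequence[Block],
                      params: SuperblockParams = SuperblockParams()) -> list[Superblock]:
    """Greedy left-to-right grouping of bridged blocks into superblocks.

    Consecutive blocks accumulate until the span reaches ``min_len``.
    The next superblock starts at the last block of the previous one;
    if that shared block alone yields < ``min_overlap`` of overlap, the
    overlap is extended leftward block by block.  Superblocks longer
    than ``max_len`` are split into <= ``max_len`` pieces with exactly
    ``min_overlap`` sequence overlap.  The final superblock on each
    reference may be shorter than ``min_len`` and is flagged terminal.
    """
    by_ref: dict[str, list[Block]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_id, []).append(b)
    out: list[Superblock] = []
    for rid in sorted(by_ref):
        bs = sorted(by_ref[rid], key=lambda b: b.start)
        i = 0
        start_override: Optional[int] = None
        prev_end: Optional[int] = None
        while i < len(bs):
            start = start_override if start_override is not None else bs[i].start
            j = i
            while j < len(bs) and bs[j].end - start < params.min_len:
                j += 1
            if j == len(bs):  # remaining blocks cannot reach min_len: terminal
                sb = Superblock(rid, start, bs[-1].end, bs[i:], terminal=True)
                # avoid a terminal superblock fully contained in the previous one
                if prev_end is None or sb.end > prev_end:
                    out.extend(_split_long(sb, params))
                break
            sb = Superblock(rid, start, bs[j].end, bs[i : j + 1])
            out.extend(_split_long(sb, params))
            prev_end = sb.end
            if j == len(bs) - 1:
                break
            # next superblock shares blocks with this one: walk leftward from
            # the last block until the shared span reaches min_overlap
            s = j
            while s > i and sb.end - bs[s].start < params.min_overlap:
                s -= 1
            if s > i:
                i, start_override = s, None
            else:
                # whole-block sharing cannot provide the overlap without
                # recreating this superblock: split within the trailing block
                # with an exact min_overlap sequence overlap
                coord = sb.end - params.min_overlap
                s = i
                while bs[s].end <= coord:
                    s += 1
                i, start_override = s, coord
    return out


def partition_reads(superblocks: Sequence[Superblock],
                    alignments: Iterable[AlignmentRecord]) -> list[Superblock]:
    """Attach read keys to superblocks.

    A superblock receives every read whose alignment overlaps its
    interval, plus every unmapped read whose mapped mate overlaps it.
    Reads in overlap zones are assigned to both superblocks.
    """
    by_ref: dict[str, list[Superblock]] = {}
    for sb in superblocks:
        by_ref.setdefault(sb.ref_id, []).append(sb)
    for sbs in by_ref.values():
        sbs.sort(key=lambda s: s.start)
    starts = {r: [sb.start for sb in sbs] for r, sbs in by_ref.items()}

    def overlapping(rid: str, lo: int, hi: int):
        sbs = by_ref.get(rid)
        if not sbs:
            return
        i = bisect.bisect_right(starts[rid], lo)
        # walk left while superblocks still overlap (overlaps are bounded)
        i = max(0, i - 1)
        while i > 0 and sbs[i - 1].end > lo:
            i -= 1
        while i < len(sbs) and sbs[i].start < hi:
            if sbs[i].end > lo:
                yield sbs[i]
            i += 1

    for a in alignments:
        if not a.unmapped:
            for sb in overlapping(a.ref_id, a.pos, a.end):
                sb.read_ids.add(a.key)
        elif a.mate_ref_id is not None and not a.mate_unmapped and a.mate_pos >= 0:
            # unmapped read rescued into the region of its mapped mate
            for sb in overlapping(a.mate_ref_id, a.mate_pos, a.mate_pos + 1):
                sb.read_ids.add(a.key)
    return list(superblocks)


def collect_unmapped(alignments: Iterable[AlignmentRecord]) -> set:
    """Keys (read_id, mate) of all reads carrying the unmapped flag."""
    return {a.key for a in alignments if a.unmapped}


def write_bed(intervals: Iterable, path, name_attr: Optional[str] = None) -> None:
    """Write blocks or superblocks as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, name_attr) if name_attr else getattr(iv, "name", ".")
            fh.write(f"{iv.ref_id}\t{iv.start}\t{iv.end}\t{name}\n")
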
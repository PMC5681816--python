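"""Steps 5-7 — unmapped-read rescue, pileup correction, ranked scaffolding.

Rescue (step 5): reads that do not map back to the supercontigs are
de novo assembled and the contigs appended, recovering diverged content
the homology-guided merge necessarily lost.  Correction (step 6): a
mapq-filtered pileup of the paired-end reads corrects substitutions and
indels by strict majority, excises uncovered stretches (splitting the
supercontig), and discards pieces under 200 bp.  Scaffolding (step 7):
paired-end and mate-pair links join supercontigs greedily, smallest
insert libraries first (ranked), with gap sizes estimated from insert
statistics, optional read-path gap closing, and a 1 kb scaffold floor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .assembler import Contig, assemble
from .io import AlignmentRecord, ReadRecord, SequenceRecord
from .kmers import encode, kmer_codes, revcomp
from .mapping import PairingModel, ReadMapper
from .simulate import LibrarySpec

log = logging.getLogger(__name__)


@dataclass
class FinishingParams:
    correction_mapq: int = 10
    min_supercontig: int = 200
    min_scaffold: int = 1000
    min_link_pairs: int = 3
    rescue_k: int = 31  # 61 suits full-scale 100 bp data
    gap_floor: int = 10  # minimum N's written at a junction

    def __post_init__(self):
        if min(self.correction_mapq, self.min_supercontig, self.min_scaffold,
               self.min_link_pairs, self.rescue_k, self.gap_floor) < 0:
            raise ValueError("finishing parameters must be non-negative")


# --------------------------------------------------------------------------
# step 5: rescue
# --------------------------------------------------------------------------

def rescue_unmapped(
    trimmed_reads: Sequence[ReadRecord],
    supercontigs: Sequence[SequenceRecord],
    params: FinishingParams = FinishingParams(),
    mapper: Optional[ReadMapper] = None,
) -> tuple[list[SequenceRecord], dict]:
    """Assemble reads unmapped against the supercontigs; append the contigs.

    Returns the additional supercontigs (origin RESCUE) and a small
    stats dict.  With an empty supercontig set every read is rescued.
    """
    if supercontigs:
        if mapper is None:
            mapper = ReadMapper(supercontigs)
        unmapped = [r for r in trimmed_reads
                    if mapper.align_read(r, mode="sensitive").unmapped]
    else:
        unmapped = list(trimmed_reads)
    contigs = assemble(unmapped, k=params.rescue_k, origin="RESCUE")
    extra = [SequenceRecord(f"rescue{i}", c.seq, "origin=RESCUE")
             for i, c in enumerate(contigs)]
    stats = {"reads_unmapped": len(unmapped), "rescued_supercontigs": len(extra)}
    return extra, stats


# --------------------------------------------------------------------------
# step 6: pileup correction
# --------------------------------------------------------------------------

def _pileup(sc_len: int, alignments: Iterable[AlignmentRecord], min_mapq: int):
    counts = np.zeros((sc_len, 4), dtype=np.int32)
    dels = np.zeros(sc_len, dtype=np.int32)
    ins: dict[int, dict[str, int]] = {}
    for a in alignments:
        if a.unmapped or a.mapq < min_mapq:
            continue
        enc = encode(a.seq)
        r, q = a.pos, 0
        for op, n in a.cigar:
            if op == "M":
                vals = enc[q : q + n]
                rows = np.arange(r, r + n)
                ok = (vals < 4) & (rows >= 0) & (rows < sc_len)
                np.add.at(counts, (rows[ok], vals[ok].astype(np.int64)), 1)
                r += n
                q += n
            elif op == "D":
                lo, hi = max(0, r), min(sc_len, r + n)
                dels[lo:hi] += 1
                r += n
            elif op == "I":
                if 0 <= r < sc_len:
                    s = a.seq[q : q + n]
                    ins.setdefault(r, {})
                    ins[r][s] = ins[r].get(s, 0) + 1
                q += n
            elif op == "S":
                q += n
    return counts, dels, ins


def correct_supercontigs(
    supercontigs: Sequence[SequenceRecord],
    alignments: Sequence[AlignmentRecord],
    params: FinishingParams = FinishingParams(),
) -> tuple[list[SequenceRecord], dict]:
    """Majority-vote correction of supercontigs from a mapq-filtered pileup.

    Substitutions need a strict majority of the filtered depth and at
    least 2 supporting reads; columns with majority deletion are
    removed; majority insertions are inserted; zero-depth stretches are
    excised and the supercontig split there; pieces shorter than
    ``min_supercontig`` are discarded.
    """
    by_sc: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        if not a.unmapped:
            by_sc.setdefault(a.ref_id, []).append(a)
    out: list[SequenceRecord] = []
    stats = {"substitutions": 0, "deletions": 0, "insertions": 0,
             "splits": 0, "discarded_pieces": 0}
    for sc in supercontigs:
        L = len(sc.seq)
        counts, dels, ins = _pileup(L, by_sc.get(sc.id, []), params.correction_mapq)
        depth = counts.sum(axis=1) + dels
        cur = encode(sc.seq)
        best = counts.argmax(axis=1)
        best_n = counts.max(axis=1)
        substitute = (best != cur) & (best_n * 2 > depth) & (best_n >= 2) & (depth > 0)
        delete = (dels * 2 > depth) & (depth > 0)
        stats["substitutions"] += int(np.count_nonzero(substitute & ~delete))
        stats["deletions"] += int(np.count_nonzero(delete))
        corrected = np.where(substitute, best, cur)
        covered = depth > 0
        # walk covered stretches, applying per-column edits
        pieces: list[str] = []
        pos = 0
        boundaries = np.nonzero(np.diff(covered.astype(np.int8)))[0] + 1
        blocks = np.split(np.arange(L), boundaries)
        n_covered_blocks = 0
        for block in blocks:
            if len(block) == 0 or not covered[block[0]]:
                continue
            n_covered_blocks += 1
            chars: list[str] = []
            for p in block:
                if p in ins:
                    s, n = max(ins[p].items(), key=lambda kv: (kv[1], kv[0]))
                    if n * 2 > depth[p]:
                        chars.append(s)
                        stats["insertions"] += 1
                if not delete[p]:
                    chars.append("ACGTN"[corrected[p]])
            pieces.append("".join(chars))
        if n_covered_blocks > 1:
            stats["splits"] += n_covered_blocks - 1
        for i, piece in enumerate(pieces):
            if len(piece) >= params.min_supercontig:
                name = sc.id if len(pieces) == 1 else f"{sc.id}.{i}"
                out.append(SequenceRecord(name, piece, sc.description))
            else:
                stats["discarded_pieces"] += 1
    return out, stats


# --------------------------------------------------------------------------
# step 7: ranked scaffolding and gap closing
# --------------------------------------------------------------------------

@dataclass
class ScaffoldLink:
    """An oriented junction between two supercontig ends with pair support."""

    sc_a: str
    end_a: str  # "H" (head/left) or "T" (tail/right)
    sc_b: str
    end_b: str
    n_supporting_pairs: int
    gap_estimate: float

    @property
    def key(self):
        return (self.sc_a, self.end_a, self.sc_b, self.end_b)


def _mate_join(aln: AlignmentRecord, sc_len: int, kind: str) -> tuple[str, int]:
    """Which end of its supercontig a mate's fragment extends past, and the
    distance from the mate to that inner end."""
    extends_right = (aln.strand == "+") if kind == "PE" else (aln.strand == "-")
    if extends_right:
        return "T", sc_len - aln.pos
    return "H", aln.end


def build_links(
    supercontigs: Sequence[SequenceRecord],
    alignments: Sequence[AlignmentRecord],
    library: LibrarySpec,
    params: FinishingParams = FinishingParams(),
) -> list[ScaffoldLink]:
    """Aggregate read pairs bridging two supercontigs into scaffold links.

    Both mates must map to different supercontigs with mapq >=
    ``correction_mapq``.  The gap estimate is the library insert mean
    minus the two mate-to-inner-end distances, averaged over pairs;
    links with fewer than ``min_link_pairs`` pairs are dropped.
    """
    lens = {sc.id: len(sc.seq) for sc in supercontigs}
    by_id: dict[str, dict[int, AlignmentRecord]] = {}
    for a in alignments:
        if not a.unmapped and a.mapq >= params.correction_mapq and a.ref_id in lens:
            by_id.setdefault(a.read_id, {})[a.mate] = a
    agg: dict[tuple, list[float]] = {}
    for rid, mates in by_id.items():
        if len(mates) != 2:
            continue
        a1, a2 = mates[1], mates[2]
        if a1.ref_id == a2.ref_id:
            continue
        e1, d1 = _mate_join(a1, lens[a1.ref_id], library.kind)
        e2, d2 = _mate_join(a2, lens[a2.ref_id], library.kind)
        gap = library.insert_mean - d1 - d2
        fwd = (a1.ref_id, e1, a2.ref_id, e2)
        rev = (a2.ref_id, e2, a1.ref_id, e1)
        key = min(fwd, rev)
        agg.setdefault(key, []).append(gap)
    links = [
        ScaffoldLink(k[0], k[1], k[2], k[3], len(g), float(np.mean(g)))
        for k, g in sorted(agg.items())
        if len(g) >= params.min_link_pairs
    ]
    links.sort(key=lambda l: (-l.n_supporting_pairs, l.key))
    return links


class _UnionFind(dict):
    def find(self, x):
        while self.setdefault(x, x) != x:
            self[x] = self[self[x]]
            x = self[x]
        return x

    def union(self, a, b):
        self[self.find(a)] = self.find(b)


def _bridge_kmers(reads: Sequence[ReadRecord], k: int, min_mult: int = 2) -> set[int]:
    """Oriented k-mer set (both strands, multiplicity >= min_mult) of reads."""
    from .kmers import count_canonical, rc_code

    uniq, counts = count_canonical(reads, k)
    uniq = uniq[counts >= min_mult]
    return set(uniq.tolist()) | set(rc_code(uniq, k).tolist())


def _close_gap(left_flank: str, right_flank: str, kept: set[int],
               k: int, max_len: int) -> Optional[str]:
    """Unique path through a prebuilt read k-mer set bridging two flanks.

    Returns the bases to place between the flanks only when exactly one
    path of length <= ``max_len`` exists.
    """
    if len(left_flank) < k or len(right_flank) < k:
        return None
    mask = (1 << (2 * k)) - 1
    start_codes, sv = kmer_codes(left_flank[-k:], k)
    end_codes, ev = kmer_codes(right_flank[:k], k)
    if not (len(start_codes) and sv[0] and len(end_codes) and ev[0]):
        return None
    start, target = int(start_codes[0]), int(end_codes[0])
    found: list[str] = []
    stack = [(start, "")]
    visited_budget = 50_000
    while stack and len(found) < 2 and visited_budget > 0:
        visited_budget -= 1
        node, path = stack.pop()
        if node == target and path:
            found.append(path)
            continue
        if len(path) > max_len + k:
            continue
        for b in range(4):
            nxt = ((node << 2) | b) & mask
            if nxt in kept or nxt == target:
                stack.append((nxt, path + "ACGT"[b]))
    if len(found) == 1:
        bridge = found[0]
        return bridge[:-k] if len(bridge) >= k else None
    return None


def scaffold(
    supercontigs: Sequence[SequenceRecord],
    links_by_library_rank: Sequence[Sequence[ScaffoldLink]],
    params: FinishingParams = FinishingParams(),
    gap_reads: Optional[Sequence[ReadRecord]] = None,
    gap_k: int = 31,
) -> tuple[list[SequenceRecord], list[dict], dict]:
    """Greedy ranked scaffolding.

    Libraries are processed in the given order (sort ascending by insert
    size: short-range joins first); within a library links are accepted
    in descending pair support.  A link is rejected when either
    supercontig end is already joined or when it would close a cycle.
    Junctions get max(gap_estimate, ``gap_floor``) N's, each optionally
    replaced by a unique read-path bridge.  Scaffolds shorter than
    ``min_scaffold`` are discarded.  Returns (scaffolds, AGP-like
    composition records, stats).
    """
    sc_of = {sc.id: sc for sc in supercontigs}
    bridge_kmers = (
        _bridge_kmers(gap_reads, gap_k) if gap_reads is not None else None
    )
    used_end: dict[tuple[str, str], ScaffoldLink] = {}
    uf = _UnionFind()
    stats = {"links_accepted": 0, "links_rejected": 0, "gaps_closed": 0}
    for links in links_by_library_rank:
        for link in links:
            ka, kb = (link.sc_a, link.end_a), (link.sc_b, link.end_b)
            if link.sc_a not in sc_of or link.sc_b not in sc_of:
                continue
            if ka in used_end or kb in used_end or uf.find(link.sc_a) == uf.find(link.sc_b):
                stats["links_rejected"] += 1
                continue
            used_end[ka] = used_end[kb] = link
            uf.union(link.sc_a, link.sc_b)
            stats["links_accepted"] += 1

    # walk join paths; each supercontig appears in exactly one scaffold
    def neighbour(sc_id: str, end: str):
        link = used_end.get((sc_id, end))
        if link is None:
            return None
        if (link.sc_a, link.end_a) == (sc_id, end):
            return link.sc_b, link.end_b, link
        return link.sc_a, link.end_a, link

    visited: set[str] = set()
    scaffolds: list[SequenceRecord] = []
    agp: list[dict] = []
    order = sorted(sc_of)
    sid = 0
    for start_id in order:
        if start_id in visited:
            continue
        # walk backwards from the head end until an unjoined (terminal) end
        cur, end = start_id, "H"
        seen = {start_id}
        while True:
            step = neighbour(cur, end)
            if step is None:
                break  # (cur, end) is a free end
            n_id, n_end, _ = step
            if n_id in seen:
                break  # cycle guard (union-find should prevent this)
            seen.add(n_id)
            cur = n_id
            end = "T" if n_end == "H" else "H"  # keep walking out the far end
        # traverse forward from the terminal, entering cur through `end`
        parts: list[str] = []
        comps: list[dict] = []
        walk_id, walk_in = cur, end
        prev_gap = None
        while True:
            visited.add(walk_id)
            seq = sc_of[walk_id].seq
            orient = "+" if walk_in == "H" else "-"
            if orient == "-":
                seq = revcomp(seq)
            if prev_gap is not None:
                gap_n = max(int(round(prev_gap[0])), params.gap_floor)
                bridge = None
                if bridge_kmers is not None:
                    left = parts[-1][-200:] if parts else ""
                    bridge = _close_gap(left, seq[:200], bridge_kmers, gap_k,
                                        max_len=gap_n + 500)
                if bridge is not None:
                    parts.append(bridge)
                    stats["gaps_closed"] += 1
                    comps.append({"type": "gap", "length": len(bridge), "closed": True})
                else:
                    parts.append("N" * gap_n)
                    comps.append({"type": "gap", "length": gap_n, "closed": False})
            parts.append(seq)
            comps.append({"type": "sc", "id": walk_id, "orientation": orient,
                          "length": len(seq)})
            out_end = "T" if walk_in == "H" else "H"
            step = neighbour(walk_id, out_end)
            if step is None:
                break
            n_id, n_end, link = step
            if n_id in visited:
                break
            prev_gap = (link.gap_estimate,)
            walk_id, walk_in = n_id, n_end
        seq = "".join(parts)
        if len(seq) >= params.min_scaffold:
            name = f"scaffold{sid}"
            sid += 1
            scaffolds.append(SequenceRecord(name, seq))
            for c in comps:
                agp.append({"scaffold": name, **c})
    return scaffolds, agp, stats


def write_agp(agp: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("#scaffold\ttype\tid\torientation\tlength\tclosed\n")
        for c in agp:
            fh.write(
                f"{c['scaffold']}\t{c['type']}\t{c.get('id', '.')}\t"
                f"{c.get('orientation', '.')}\t{c['length']}\t{c.get('closed', '.')}\n"
            )
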
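"""Step 4 — homology-guided redundancy removal into supercontigs.

Pooled contigs (many k's, overlapping superblocks) are anchored to the
same reference used for read mapping: the best co-linear chain of exact
k-mer anchors places each contig as a layout tile, ignoring unalignable
overhangs up to 1000 bp (longer overhangs leave the contig unplaced).
Tiles overlapping by at least 10 bp on the reference are merged and a
column-wise majority consensus over the tiled contig bases becomes a
non-redundant supercontig.  The reference contributes coordinates only:
no reference base is ever written into a supercontig, so diverged
contigs keep their divergence.  Unplaced (most diverged) contigs are
reported; the rescue step later recovers their content from reads.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .anchors import Segment, chain_segments, find_segments
from .assembler import Contig
from .io import SequenceRecord
from .kmers import KmerIndex, encode, revcomp

UNPLACED = "UNPLACED"


@dataclass
class MergeParams:
    max_trim: int = 1000  # maximum ignorable unalignable overhang per contig end
    min_overlap: int = 10  # minimum reference overlap merging two tiles
    min_anchor_chain: int = 4  # anchors a chain needs to place a contig
    anchor_k: int = 15

    def __post_init__(self):
        if min(self.max_trim, self.min_overlap, self.min_anchor_chain) < 0:
            raise ValueError("merge parameters must be non-negative")


@dataclass
class LayoutTile:
    """One contig placed on the reference with its unalignable trims."""

    contig_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    contig_trim_left: int
    contig_trim_right: int
    contig_len: int
    chain: list[Segment] = field(default_factory=list, repr=False)


def anchor_contigs(
    contigs: Sequence[Contig],
    reference: Sequence[SequenceRecord],
    params: MergeParams = MergeParams(),
    index: Optional[KmerIndex] = None,
) -> list[LayoutTile]:
    """Place each contig on the reference by its best co-linear anchor chain.

    Contigs with no chain (or with an unalignable overhang longer than
    ``max_trim`` on either end) are set aside as unplaced and not
    returned; recover their ids with :func:`report_unplaced`.
    """
    if index is None:
        index = KmerIndex.build(reference, k=params.anchor_k)
    tiles: list[LayoutTile] = []
    for contig in contigs:
        segs = find_segments(contig.seq, index, diag_band=0)
        chain = chain_segments(segs)
        if not chain or sum(s.n_anchors for s in chain) < params.min_anchor_chain:
            continue
        left = chain[0].opstart
        right = len(contig.seq) - chain[-1].opend
        if left > params.max_trim or right > params.max_trim:
            continue
        tiles.append(
            LayoutTile(
                contig_id=contig.id,
                ref_id=chain[0].ref_id,
                ref_start=chain[0].rstart,
                ref_end=chain[-1].rend,
                strand=chain[0].strand,
                contig_trim_left=left,
                contig_trim_right=right,
                contig_len=len(contig.seq),
                chain=chain,
            )
        )
    tiles.sort(key=lambda t: (t.ref_id, t.ref_start, t.ref_end, t.contig_id))
    return tiles


def report_unplaced(contigs: Sequence[Contig], tiles: Sequence[LayoutTile]) -> set[str]:
    """Ids of contigs that received no layout tile (lost without rescue)."""
    placed = {t.contig_id for t in tiles}
    return {c.id for c in contigs} - placed


def _projection_runs(tile: LayoutTile, oriented_seq: str, ref_seq: str):
    """(rlo, rhi, olo) runs mapping oriented-contig bases onto ref columns.

    Within a segment the mapping is diagonal; anchor-free gaps are
    projected diagonally when ref and contig gaps are equal (pure
    substitution divergence) and via an edit-distance alignment
    otherwise.  Contig insertions relative to the reference are dropped;
    deletions leave columns uncovered.
    """
    runs: list[tuple[int, int, int]] = []
    chain = tile.chain
    cur_r = -1
    for i, s in enumerate(chain):
        rlo, rhi, olo = s.rstart, s.rend, s.opstart
        if rlo < cur_r:  # clip overlap with what is already projected
            delta = cur_r - rlo
            rlo, olo = rlo + delta, olo + delta
        if rhi > rlo:
            runs.append((rlo, rhi, olo))
            cur_r = rhi
        if i + 1 < len(chain):
            t = chain[i + 1]
            rgap_lo, rgap_hi = cur_r, t.rstart
            ogap_lo, ogap_hi = s.opend, t.opstart
            if rgap_hi <= rgap_lo or ogap_hi <= ogap_lo:
                continue
            rgap, ogap = rgap_hi - rgap_lo, ogap_hi - ogap_lo
            if rgap == ogap:
                runs.append((rgap_lo, rgap_hi, ogap_lo))
                cur_r = rgap_hi
            else:
                aln = edlib.align(
                    oriented_seq[ogap_lo:ogap_hi],
                    ref_seq[rgap_lo:rgap_hi],
                    mode="NW",
                    task="path",
                )
                r, o = rgap_lo, ogap_lo
                for n_str, op in re.findall(r"(\d+)([=XIDM])", aln["cigar"] or ""):
                    n = int(n_str)
                    if op in "=XM":
                        runs.append((r, r + n, o))
                        r += n
                        o += n
                    elif op == "I":  # insertion in contig: bases dropped
                        o += n
                    else:  # deletion: ref columns left uncovered
                        r += n
                cur_r = rgap_hi
    return runs


def merge_layout(
    tiles: Sequence[LayoutTile],
    contigs: Sequence[Contig],
    reference: Sequence[SequenceRecord],
    params: MergeParams = MergeParams(),
) -> list[SequenceRecord]:
    """Merge overlapping tiles into majority-consensus supercontigs.

    Tiles whose reference intervals overlap by >= ``min_overlap`` chain
    into one group; each group yields one supercontig.  Consensus per
    column is the base supported by most tiled contigs (ties break
    lexicographically); columns no contig covers are excised.
    """
    seq_of = {c.id: c.seq for c in contigs}
    ref_of = {r.id: r.seq for r in reference}
    by_ref: dict[str, list[LayoutTile]] = {}
    for t in tiles:
        by_ref.setdefault(t.ref_id, []).append(t)
    out: list[SequenceRecord] = []
    n = 0
    for rid in sorted(by_ref):
        group: list[LayoutTile] = []
        group_end = -(10**18)
        ts = sorted(by_ref[rid], key=lambda t: (t.ref_start, t.ref_end, t.contig_id))
        for t in ts + [None]:
            if t is not None and (not group or t.ref_start <= group_end - params.min_overlap):
                group.append(t)
                group_end = max(group_end, t.ref_end)
                continue
            if group:
                rec = _consensus(group, seq_of, ref_of[rid], f"sc{n}_{rid}")
                if rec is not None:
                    out.append(rec)
                    n += 1
            if t is not None:
                group, group_end = [t], t.ref_end
    return out


def _consensus(group, seq_of, ref_seq, name) -> Optional[SequenceRecord]:
    gstart = min(t.ref_start for t in group)
    gend = max(t.ref_end for t in group)
    counts = np.zeros((gend - gstart, 4), dtype=np.int32)
    for t in group:
        seq = seq_of[t.contig_id]
        oriented = seq if t.strand == "+" else revcomp(seq)
        enc = encode(oriented)
        for rlo, rhi, olo in _projection_runs(t, oriented, ref_seq):
            span = rhi - rlo
            vals = enc[olo : olo + span]
            rows = np.arange(rlo - gstart, rhi - gstart)
            ok = vals < 4
            np.add.at(counts, (rows[ok], vals[ok].astype(np.int64)), 1)
    cov = counts.sum(axis=1)
    covered = cov > 0
    if not covered.any():
        return None
    best = counts.argmax(axis=1)  # argmax tie -> lowest code = lexicographic
    seq = "".join("ACGT"[b] for b, c in zip(best, covered) if c)
    return SequenceRecord(name, seq, f"ref={group[0].ref_id}:{gstart}-{gend}")


def write_layout(tiles: Sequence[LayoutTile], path) -> None:
    """PAF-like tab-separated layout: contig, len, trims, ref placement."""
    with open(path, "w") as fh:
        for t in tiles:
            fh.write(
                f"{t.contig_id}\t{t.contig_len}\t{t.contig_trim_left}\t"
                f"{t.contig_len - t.contig_trim_right}\t{t.strand}\t"
                f"{t.ref_id}\t{t.ref_start}\t{t.ref_end}\n"
            )
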
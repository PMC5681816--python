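"""Exact k-mer anchoring, diagonal segments, and co-linear chaining.

The same engine backs homology-guided contig layout (redundancy
removal) and truth-alignment of assemblies for evaluation.  Anchors are
exact k-mer matches between a query and an indexed reference; anchors
sharing a diagonal (within ``diag_band``) and without large query gaps
form a *segment*; segments that are mutually co-linear on one strand
chain into a *tile* placement.

Coordinates: ``qstart/qend`` are on the forward query; ``opstart/opend``
are on the query in placement orientation (reverse-complemented when
strand is '-'), so along a chain both oriented-query and reference
coordinates increase.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kmers import KmerIndex, kmer_codes, revcomp


@dataclass
class Segment:
    """A run of same-diagonal anchors: an ungapped homologous stretch."""

    ref_id: str
    ref_idx: int
    strand: str
    qstart: int
    qend: int
    opstart: int
    opend: int
    rstart: int
    rend: int
    n_anchors: int
    diag: int  # rpos - opos, constant within diag_band
    n_indel_events: int = 0
    indel_bp: int = 0

    @property
    def qlen(self) -> int:
        return self.qend - self.qstart


def _collect_anchors(seq: str, index: KmerIndex, stride: int):
    """(ref_idx, opos, rpos) anchor arrays for one query orientation."""
    codes, valid = kmer_codes(seq, index.k)
    ridx_out, opos_out, rpos_out = [], [], []
    for q in range(0, len(codes), stride):
        if not valid[q]:
            continue
        ridx, pos = index.hits(codes[q])
        if ridx is None:
            continue
        for r, p in zip(ridx.tolist(), pos.tolist()):
            ridx_out.append(r)
            opos_out.append(q)
            rpos_out.append(p)
    return ridx_out, opos_out, rpos_out


def find_segments(
    query: str,
    index: KmerIndex,
    stride: int = 1,
    min_anchors: int = 2,
    max_qgap: int = 500,
    diag_band: int = 0,
) -> list[Segment]:
    """Diagonal anchor segments of ``query`` against the index, both strands.

    ``diag_band`` > 0 merges nearby diagonals into one segment (the
    shifts are counted as indel events); 0 keeps segments strictly
    ungapped.
    """
    k = index.k
    L = len(query)
    segments: list[Segment] = []
    for strand, seq in (("+", query), ("-", revcomp(query))):
        ridx, opos, rpos = _collect_anchors(seq, index, stride)
        if not ridx:
            continue
        arr = sorted(
            (r, p - o, o, p) for r, o, p in zip(ridx, opos, rpos)
        )  # (ref, diag, opos, rpos)
        # cluster by (ref, diag) then split on query gaps
        i = 0
        n = len(arr)
        while i < n:
            j = i + 1
            while j < n and arr[j][0] == arr[i][0] and arr[j][1] - arr[j - 1][1] <= diag_band:
                j += 1
            cluster = sorted(arr[i:j], key=lambda t: t[2])
            i = j
            start = 0
            for a in range(1, len(cluster) + 1):
                if a == len(cluster) or cluster[a][2] - cluster[a - 1][2] > max_qgap:
                    run = cluster[start:a]
                    start = a
                    if len(run) < min_anchors:
                        continue
                    diags = [t[1] for t in run]
                    os_, rs_ = [t[2] for t in run], [t[3] for t in run]
                    ops, ope = min(os_), max(os_) + k
                    segments.append(
                        Segment(
                            ref_id=index.ref_ids[run[0][0]],
                            ref_idx=run[0][0],
                            strand=strand,
                            qstart=ops if strand == "+" else L - ope,
                            qend=ope if strand == "+" else L - ops,
                            opstart=ops,
                            opend=ope,
                            rstart=min(rs_),
                            rend=max(rs_) + k,
                            n_anchors=len(run),
                            diag=int(np.median(diags)),
                            n_indel_events=len(set(diags)) - 1,
                            indel_bp=max(diags) - min(diags),
                        )
                    )
    segments.sort(key=lambda s: (s.qstart, s.qend, s.ref_idx, s.strand, s.rstart))
    return segments


def chain_segments(
    segments: Sequence[Segment],
    max_diag_drift: int = 200,
    slack: int = 50,
) -> list[Segment]:
    """Best co-linear chain (max total anchors) on a single (ref, strand).

    Segments chain when both oriented-query and reference coordinates
    advance (small overlaps up to ``slack`` + k tolerated) and the
    diagonal drifts by at most ``max_diag_drift`` (small indels).
    Ties break toward the leftmost reference coordinate.
    """
    if not segments:
        return []
    best_chain: list[Segment] = []
    best_score = -1
    best_key = None
    groups: dict[tuple[int, str], list[Segment]] = {}
    for s in segments:
        groups.setdefault((s.ref_idx, s.strand), []).append(s)
    for (ridx, strand), segs in sorted(groups.items()):
        segs = sorted(segs, key=lambda s: (s.opstart, s.rstart))
        m = len(segs)
        score = [s.n_anchors for s in segs]
        prev = [-1] * m
        for b in range(m):
            for a in range(b):
                sa, sb = segs[a], segs[b]
                if (
                    sb.opstart >= sa.opend - slack - 0
                    and sb.rstart >= sa.rend - slack
                    and abs(sb.diag - sa.diag) <= max_diag_drift
                    and score[a] + sb.n_anchors > score[b]
                ):
                    score[b] = score[a] + sb.n_anchors
                    prev[b] = a
        end = max(range(m), key=lambda b: (score[b], -segs[b].rstart))
        chain = []
        b = end
        while b != -1:
            chain.append(segs[b])
            b = prev[b]
        chain.reverse()
        key = (chain[0].rstart, ridx, strand)
        if score[end] > best_score or (score[end] == best_score and key < best_key):
            best_score, best_chain, best_key = score[end], chain, key
    return best_chain
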
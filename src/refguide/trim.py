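"""Step 1 — quality trimming of raw reads.

Reproduces the classic leading/trailing + sliding-window trimmer
semantics: bases below a phred threshold are stripped from both read
ends, then the read is cut at the first 4 bp window whose mean quality
drops below 15, and anything shorter than 40 bp is discarded.  Adapter
clipping is a no-op by default (simulated reads carry no adapters) but a
literal-adapter hook is available for real data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .io import ReadRecord

DISCARD = None


@dataclass
class TrimParams:
    lead_trail_q: int = 3
    window_len: int = 4
    window_q: float = 15.0
    min_len: int = 40
    adapters: tuple[str, ...] = ()

    def __post_init__(self):
        if min(self.lead_trail_q, self.window_len, self.min_len) < 0 or self.window_q < 0:
            raise ValueError("trim parameters must be non-negative")


@dataclass
class TrimStats:
    input_reads: int = 0
    retained_pairs: int = 0
    orphans: int = 0
    discarded: int = 0
    input_bases: int = 0
    retained_bases: int = 0

    @property
    def retained_reads(self) -> int:
        return self.retained_pairs * 2 + self.orphans


def _clip_adapters(read: ReadRecord, adapters: tuple[str, ...]) -> ReadRecord:
    cut = len(read.seq)
    for ad in adapters:
        i = read.seq.find(ad)
        if i != -1:
            cut = min(cut, i)
    if cut == len(read.seq):
        return read
    return ReadRecord(read.id, read.mate, read.seq[:cut], read.qual[:cut], read.library_id)


def trim_read(read: ReadRecord, params: TrimParams = TrimParams()) -> Optional[ReadRecord]:
    """Trim one read; returns the trimmed read or ``None`` (DISCARD).

    Order of operations: leading, trailing, sliding window, length
    filter.  The output is always a contiguous substring of the input.
    """
    if params.adapters:
        read = _clip_adapters(read, params.adapters)
    q = read.qual
    lo, hi = 0, len(q)
    while lo < hi and q[lo] < params.lead_trail_q:
        lo += 1
    while hi > lo and q[hi - 1] < params.lead_trail_q:
        hi -= 1
    w = params.window_len
    if hi - lo >= w > 0:
        qq = q[lo:hi].astype(np.float64)
        means = np.convolve(qq, np.ones(w), "valid") / w
        bad = np.nonzero(means < params.window_q)[0]
        if len(bad):
            hi = lo + int(bad[0])
    if hi - lo < params.min_len:
        return DISCARD
    if lo == 0 and hi == len(q):
        return read
    return ReadRecord(read.id, read.mate, read.seq[lo:hi], q[lo:hi], read.library_id)


def trim_pairs(
    read_pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    params: TrimParams = TrimParams(),
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadRecord], TrimStats]:
    """Trim mate pairs together; survivors of broken pairs become orphans."""
    stats = TrimStats()
    pairs, orphans = [], []
    for r1, r2 in read_pairs:
        stats.input_reads += 2
        stats.input_bases += len(r1) + len(r2)
        t1, t2 = trim_read(r1, params), trim_read(r2, params)
        if t1 is not None and t2 is not None:
            pairs.append((t1, t2))
            stats.retained_pairs += 1
            stats.retained_bases += len(t1) + len(t2)
        elif t1 is not None or t2 is not None:
            survivor = t1 if t1 is not None else t2
            orphans.append(survivor)
            stats.orphans += 1
            stats.discarded += 1
            stats.retained_bases += len(survivor)
        else:
            stats.discarded += 2
    return pairs, orphans, stats


def library_summary(reads: Iterable[ReadRecord]) -> dict:
    """Per-library QC summary: read count, mean quality, length histogram."""
    n = 0
    qsum = 0.0
    lengths: dict[int, int] = {}
    for r in reads:
        n += 1
        qsum += float(np.mean(r.qual)) if len(r.qual) else 0.0
        lengths[len(r)] = lengths.get(len(r), 0) + 1
    return {
        "n_reads": n,
        "mean_quality": qsum / n if n else 0.0,
        "length_histogram": dict(sorted(lengths.items())),
    }
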
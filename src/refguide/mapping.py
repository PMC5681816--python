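"""A minimal seed-and-extend read mapper.

Seeds are exact k-mer hits (k = 15 by default) voted into diagonal
clusters; candidate loci are scored by a fast ungapped comparison and,
when that looks gappy, by a local affine alignment (match +2,
mismatch -3, gap open -5, gap extend -2, via Bio.Align.PairwiseAligner).
``local`` mode soft-clips read ends for free; ``sensitive`` mode
penalises clipped bases, favouring end-to-end placements.

mapq = min(60, 6 * (best - second_best)), 0 on ties — calibrated so
unique perfect hits score 60 and ambiguous hits 0, which is what the
downstream mapq >= 10 filters depend on.  Alignments scoring below
20 + 8*ln(read_len) are reported unmapped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from .io import AlignmentRecord, ReadRecord, SequenceRecord
from .kmers import KmerIndex, encode, kmer_codes, rc_code, revcomp
from .simulate import LibrarySpec

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2
CLIP_PENALTY_SENSITIVE = 2  # per clipped base in sensitive mode


def score_threshold(read_len: int) -> float:
    """Minimum acceptable alignment score for a read of this length."""
    return 20.0 + 8.0 * math.log(read_len)


@dataclass
class PairingModel:
    """Per-library proper-pair semantics: expected orientation + insert window."""

    libraries: dict[str, LibrarySpec]
    sd_window: float = 4.0

    def window(self, library_id: str) -> tuple[float, float]:
        lib = self.libraries[library_id]
        lo = max(2.0, lib.insert_mean - self.sd_window * lib.insert_sd)
        return lo, lib.insert_mean + self.sd_window * lib.insert_sd

    def orientation(self, library_id: str) -> str:
        return self.libraries[library_id].orientation

    @classmethod
    def from_libraries(cls, libs: Iterable[LibrarySpec]) -> "PairingModel":
        return cls({l.library_id: l for l in libs})


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


class ReadMapper:
    """Seed-and-extend mapper over a fixed set of target sequences."""

    def __init__(self, refs: Sequence[SequenceRecord], k: int = 15, max_hits: int = 64,
                 seed_stride: Optional[int] = None, max_candidates: int = 8):
        self.refs = list(refs)
        self.index = KmerIndex.build(self.refs, k=k, max_hits=max_hits)
        self.k = k
        self.encoded = [encode(r.seq) for r in self.refs]
        self.seed_stride = seed_stride if seed_stride is not None else max(1, k // 3)
        self.max_candidates = max_candidates
        self._aligner = _make_aligner("local")

    # ---- candidate generation -------------------------------------------
    def _candidates(self, fwd_codes, fwd_valid, rc_codes, rc_valid):
        """Vote seed hits into (ref_idx, strand, diagonal) clusters."""
        votes: dict[tuple[int, str, int], int] = {}
        for strand, codes, valid in (("+", fwd_codes, fwd_valid), ("-", rc_codes, rc_valid)):
            for qpos in range(0, len(codes), self.seed_stride):
                if not valid[qpos]:
                    continue
                ridx, pos = self.index.hits(codes[qpos])
                if ridx is None:
                    continue
                for r, p in zip(ridx.tolist(), pos.tolist()):
                    key = (r, strand, p - qpos)
                    votes[key] = votes.get(key, 0) + 1
        # merge diagonals within a small band per (ref, strand)
        merged: list[tuple[int, int, str, int]] = []  # (votes, ref, strand, diag)
        by_rs: dict[tuple[int, str], list[tuple[int, int]]] = {}
        for (r, s, d), v in votes.items():
            by_rs.setdefault((r, s), []).append((d, v))
        for (r, s), dv in by_rs.items():
            dv.sort()
            cur_d, cur_v, best_d, best_v = None, 0, None, 0
            for d, v in dv:
                if cur_d is not None and d - cur_d <= 16:
                    cur_v += v
                    if v > best_v:
                        best_d, best_v = d, v
                else:
                    if cur_d is not None:
                        merged.append((cur_v, r, s, best_d))
                    cur_v, best_d, best_v = v, d, v
                cur_d = d
            if cur_d is not None:
                merged.append((cur_v, r, s, best_d))
        merged.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
        return merged[: self.max_candidates]

    # ---- scoring ---------------------------------------------------------
    def _score_ungapped(self, q_codes: np.ndarray, ridx: int, start: int, mode: str):
        ref = self.encoded[ridx]
        L, n = len(ref), len(q_codes)
        qs, qe = max(0, -start), n - max(0, start + n - L)
        if qe - qs < self.k:
            return None
        seg_ref = ref[start + qs : start + qe]
        seg_q = q_codes[qs:qe]
        mism = int(np.count_nonzero((seg_ref != seg_q) | (seg_ref >= 4) | (seg_q >= 4)))
        span = qe - qs
        score = MATCH * (span - mism) + MISMATCH * mism
        clip = n - span
        if mode == "sensitive":
            score -= CLIP_PENALTY_SENSITIVE * clip
        cigar = []
        if qs:
            cigar.append(("S", qs))
        cigar.append(("M", span))
        if n - qe:
            cigar.append(("S", n - qe))
        return score, start + qs, cigar, mism, span

    def _score_gapped(self, q_seq: str, ridx: int, start: int, mode: str):
        ref = self.refs[ridx].seq
        n = len(q_seq)
        ws, we = max(0, start - 2 * n // 5), min(len(ref), start + n + 2 * n // 5)
        window = ref[ws:we]
        if len(window) < self.k:
            return None
        try:
            aln = self._aligner.align(window, q_seq)[0]
        except (IndexError, OverflowError):
            return None
        ref_blocks, q_blocks = aln.aligned
        if len(q_blocks) == 0:
            return None
        cigar: list[tuple[str, int]] = []
        if q_blocks[0][0] > 0:
            cigar.append(("S", int(q_blocks[0][0])))
        score = 0
        for i, ((rs, re), (qs_, qe_)) in enumerate(zip(ref_blocks, q_blocks)):
            if i > 0:
                dr = rs - ref_blocks[i - 1][1]
                dq = qs_ - q_blocks[i - 1][1]
                if dr:
                    cigar.append(("D", int(dr)))
                    score += GAP_OPEN + GAP_EXTEND * (dr - 1)
                if dq:
                    cigar.append(("I", int(dq)))
                    score += GAP_OPEN + GAP_EXTEND * (dq - 1)
            seg_r = encode(window[rs:re])
            seg_q = encode(q_seq[qs_:qe_])
            mism = int(np.count_nonzero(seg_r != seg_q))
            score += MATCH * (re - rs - mism) + MISMATCH * mism
            if cigar and cigar[-1][0] == "M":
                cigar[-1] = ("M", cigar[-1][1] + int(re - rs))
            else:
                cigar.append(("M", int(re - rs)))
        tail = n - int(q_blocks[-1][1])
        if tail:
            cigar.append(("S", tail))
        clip = int(q_blocks[0][0]) + tail
        if mode == "sensitive":
            score -= CLIP_PENALTY_SENSITIVE * clip
        return score, ws + int(ref_blocks[0][0]), cigar, None, None

    # ---- public API ------------------------------------------------------
    def align_read(self, read: ReadRecord, mode: str = "local") -> AlignmentRecord:
        """Best alignment of one read (primary only); unmapped when below threshold."""
        n = len(read.seq)
        unmapped = AlignmentRecord(read.id, read.mate, None, seq=read.seq, qual=read.qual)
        if n < self.k or not self.index._table:
            return unmapped
        fwd_codes, fwd_valid = kmer_codes(read.seq, self.k)
        rc_seq = revcomp(read.seq)
        rcc, rcv = kmer_codes(rc_seq, self.k)
        cands = self._candidates(fwd_codes, fwd_valid, rcc, rcv)
        if not cands:
            return unmapped
        q_codes = {"+": encode(read.seq), "-": encode(rc_seq)}
        q_seq = {"+": read.seq, "-": rc_seq}
        results = []
        for _v, ridx, strand, diag in cands:
            res = self._score_ungapped(q_codes[strand], ridx, diag, mode)
            # fall back to gapped extension when the diagonal looks noisy
            if res is None or (res[3] is not None and res[3] > 0.15 * res[4]):
                gres = self._score_gapped(q_seq[strand], ridx, diag, mode)
                if gres is not None and (res is None or gres[0] > res[0]):
                    res = gres
            if res is not None:
                results.append((res[0], ridx, strand, res[1], res[2]))
        if not results:
            return unmapped
        results.sort(key=lambda t: (-t[0], t[1], t[3], t[2]))
        best = results[0]
        thresh = score_threshold(n)
        if best[0] < thresh:
            return unmapped
        second = results[1][0] if len(results) > 1 else thresh
        mapq = 0 if (len(results) > 1 and results[1][0] == best[0]) else int(
            min(60, 6 * (best[0] - second))
        )
        score, ridx, strand, pos, cigar = best
        if strand == "-":
            seq_out, qual_out = q_seq["-"], read.qual[::-1]
        else:
            seq_out, qual_out = read.seq, read.qual
        return AlignmentRecord(
            read_id=read.id, mate=read.mate, ref_id=self.refs[ridx].id, pos=int(pos),
            strand=strand, cigar=cigar, mapq=max(0, mapq), score=int(score),
            seq=seq_out, qual=qual_out,
        )

    def map_reads(self, reads: Iterable[ReadRecord], mode: str = "local",
                  pairing: Optional[PairingModel] = None) -> list[AlignmentRecord]:
        """Align a stream of reads; applies pair flags when a model is given."""
        alns = [self.align_read(r, mode) for r in reads]
        if pairing is not None:
            libs = {r.id: r.library_id for r in reads}
            alns = pair_and_flag(alns, pairing, libs)
        return alns


def pair_and_flag(alignments: list[AlignmentRecord], model: PairingModel,
                  library_of: Optional[dict] = None) -> list[AlignmentRecord]:
    """Set paired/proper_pair/mate_* flags on mate pairs.

    ``library_of`` maps read id -> library id; with a single library in
    the model it may be omitted.
    """
    only = next(iter(model.libraries)) if len(model.libraries) == 1 else None
    by_id: dict[str, dict[int, AlignmentRecord]] = {}
    for a in alignments:
        by_id.setdefault(a.read_id, {})[a.mate] = a
    for rid, mates in by_id.items():
        if len(mates) != 2:
            continue
        a1, a2 = mates[1], mates[2]
        lib = (library_of or {}).get(rid, only)
        for a, b in ((a1, a2), (a2, a1)):
            a.paired = True
            a.mate_unmapped = b.unmapped
            a.mate_ref_id = b.ref_id
            a.mate_pos = b.pos
            a.mate_strand = b.strand
        if lib is None or a1.unmapped or a2.unmapped or a1.ref_id != a2.ref_id:
            continue
        left, right = (a1, a2) if a1.pos <= a2.pos else (a2, a1)
        expected = model.orientation(lib)
        orient_ok = (
            (left.strand, right.strand) == ("+", "-")
            if expected == "FR"
            else (left.strand, right.strand) == ("-", "+")
        )
        insert = right.end - left.pos
        lo, hi = model.window(lib)
        if orient_ok and lo <= insert <= hi:
            a1.proper_pair = a2.proper_pair = True
    return alignments


def score_alignment(aln: AlignmentRecord, ref_seq: str, mode: str = "local") -> int:
    """Re-score an alignment from its cigar against the reference (oracle)."""
    if aln.unmapped:
        raise ValueError("cannot score an unmapped record")
    score, rpos, qpos = 0, aln.pos, 0
    read = aln.seq  # already oriented to the reference strand
    for op, n in aln.cigar:
        if op == "M":
            seg_r = encode(ref_seq[rpos : rpos + n])
            seg_q = encode(read[qpos : qpos + n])
            mism = int(np.count_nonzero(seg_r != seg_q))
            score += MATCH * (n - mism) + MISMATCH * mism
            rpos += n
            qpos += n
        elif op == "D":
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
            rpos += n
        elif op == "I":
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
            qpos += n
        elif op == "S":
            if mode == "sensitive":
                score -= CLIP_PENALTY_SENSITIVE * n
            qpos += n
    return score
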
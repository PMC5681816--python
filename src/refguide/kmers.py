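"""2-bit k-mer encoding and an exact-match k-mer index.

All sequence coordinates are 0-based half-open.  k is capped at 31 so a
k-mer fits a uint64.  Bases outside {A,C,G,T} (i.e. N) invalidate every
window containing them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes A=0 C=1 G=2 T=3, N/other=4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer codes of every window of ``seq``.

    Returns ``(codes, valid)`` of length ``len(seq) - k + 1`` where
    ``valid[i]`` is False when window i contains a non-ACGT base (its code
    is then meaningless).
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    e = encode(seq)
    n = len(e) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | np.minimum(e[j : j + n], 3).astype(np.uint64)
    bad = (e >= 4).astype(np.int32)
    c = np.concatenate([[0], np.cumsum(bad)])
    valid = (c[k:] - c[:-k]) == 0
    return codes, valid


def rc_code(code: int | np.ndarray, k: int):
    """Reverse-complement of a 2-bit encoded k-mer code (vectorised)."""
    code = np.asarray(code, dtype=np.uint64)
    out = np.zeros_like(code)
    c = code.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (np.uint64(3) - (c & np.uint64(3)))
        c >>= np.uint64(2)
    return out if out.ndim else out[()]


def canonical_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-canonical (min of forward/rc) k-mer codes of ``seq``."""
    fwd, valid = kmer_codes(seq, k)
    if len(fwd) == 0:
        return fwd, valid
    rc = rc_code(fwd, k)
    return np.minimum(fwd, rc), valid


def count_canonical(seqs, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer multiset over many sequences: (codes, counts).

    Sequences are joined with N separators so the whole batch is encoded
    in one pass (windows crossing separators are invalid).
    """
    parts = [s.seq if hasattr(s, "seq") else s for s in seqs]
    parts = [p for p in parts if len(p) >= k]
    if not parts:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    joined = "N".join(parts)
    fwd, valid = kmer_codes(joined, k)
    fwd = fwd[valid]
    canon = np.minimum(fwd, rc_code(fwd, k))
    return np.unique(canon, return_counts=True)


@dataclass
class KmerIndex:
    """Exact k-mer lookup over a set of named reference sequences.

    Forward-strand k-mers are stored; minus-strand occurrences are found
    by querying the reverse complement, so both strands are effectively
    indexed.  K-mers occurring more than ``max_hits`` times are dropped
    (repeat masking) to bound seeding cost.
    """

    ref_ids: list[str]
    ref_seqs: list[str]
    k: int = 15
    max_hits: int = 64
    # code -> (ref_idx array, pos array)
    _table: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.k % 2 == 0:
            raise ValueError(f"k must be odd, got {self.k}")
        if not 9 <= self.k <= 31:
            raise ValueError(f"k must be in [9, 31], got {self.k}")
        codes_all, refidx_all, pos_all = [], [], []
        for ridx, seq in enumerate(self.ref_seqs):
            codes, valid = kmer_codes(seq, self.k)
            pos = np.nonzero(valid)[0]
            codes_all.append(codes[pos])
            pos_all.append(pos.astype(np.int64))
            refidx_all.append(np.full(len(pos), ridx, dtype=np.int32))
        if not codes_all:
            return
        codes = np.concatenate(codes_all)
        pos = np.concatenate(pos_all)
        refidx = np.concatenate(refidx_all)
        order = np.argsort(codes, kind="stable")
        codes, pos, refidx = codes[order], pos[order], refidx[order]
        uniq, starts, counts = np.unique(codes, return_index=True, return_counts=True)
        table = {}
        for code, s, c in zip(uniq.tolist(), starts.tolist(), counts.tolist()):
            if c <= self.max_hits:
                table[code] = (refidx[s : s + c], pos[s : s + c])
        self._table = table

    @classmethod
    def build(cls, records, k: int = 15, max_hits: int = 64) -> "KmerIndex":
        """Build from an iterable of SequenceRecord-like objects."""
        records = list(records)
        return cls(
            ref_ids=[r.id for r in records],
            ref_seqs=[r.seq for r in records],
            k=k,
            max_hits=max_hits,
        )

    def __len__(self):
        return len(self._table)

    def hits(self, code: int):
        """(ref_idx array, pos array) of forward occurrences of ``code``."""
        return self._table.get(int(code), (None, None))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All placements of ``kmer`` as (ref_id, pos, strand).

        A position is reported on '-' when the reference carries the
        reverse complement of ``kmer`` there; a palindromic k-mer is
        reported on both strands at the same position.
        """
        codes, valid = kmer_codes(kmer, self.k)
        if len(codes) != 1 or not valid[0]:
            raise ValueError("lookup needs a single ACGT k-mer of index k")
        out = []
        for code, strand in ((int(codes[0]), "+"), (int(rc_code(codes[0], self.k)), "-")):
            ridx, pos = self.hits(code)
            if ridx is not None:
                out.extend((self.ref_ids[r], int(p), strand) for r, p in zip(ridx, pos))
        return sorted(out)
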
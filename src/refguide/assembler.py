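"""A minimal de Bruijn assembler for desk-scale local assemblies.

k-mers from both read strands are collapsed into canonical (min of
forward/reverse-complement) edges with multiplicities; edges seen fewer
than ``min_edge_mult`` times are dropped (singleton error k-mers), short
dead-end unitigs are clipped as tips, simple two-arm bubbles (mostly
heterozygosity) are popped keeping the higher-multiplicity arm, and the
maximal non-branching paths that remain are emitted as contigs in
canonical orientation.

An external-assembler hook runs any command template producing FASTA,
so real assemblers can stand in for the built-in one per superblock.
"""
from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import ParameterError, ReadRecord, SequenceRecord, read_fasta, write_fastq
from .kmers import count_canonical, decode, rc_code, revcomp

log = logging.getLogger(__name__)

DEFAULT_K_LIST = (21, 31)  # toy-scale default for the built-in assembler (k <= 31)
FULL_SCALE_K_LIST = (41, 51, 61, 71, 81)  # full-scale multi-k set (external assemblers)


@dataclass
class Contig:
    id: str
    seq: str
    origin: str = ""  # superblock id | UNMAPPED | RESCUE
    k_used: int = 0

    def __len__(self):
        return len(self.seq)


class DeBruijnGraph:
    """Oriented k-mer graph over a canonical edge multiset.

    ``codes`` holds every surviving k-mer in both orientations, sorted;
    degrees and unique successors/predecessors are precomputed arrays.
    """

    def __init__(self, canon_codes: np.ndarray, mults: np.ndarray, k: int):
        self.k = k
        rc = rc_code(canon_codes, k)
        both = np.concatenate([canon_codes, rc])
        both_mult = np.concatenate([mults, mults])
        order = np.argsort(both, kind="stable")
        codes, first = np.unique(both[order], return_index=True)
        self.codes = codes
        self.mult = both_mult[order][first]
        self.rci = np.searchsorted(codes, rc_code(codes, k))
        n = len(codes)
        mask = np.uint64((1 << (2 * k)) - 1)
        shift_top = np.uint64(2 * (k - 1))
        # successors: (code << 2 | b) & mask
        suf = (codes << np.uint64(2)) & mask
        succ_exist = np.zeros((4, n), dtype=bool)
        succ_cand = np.zeros((4, n), dtype=np.uint64)
        for b in range(4):
            cand = suf | np.uint64(b)
            pos = np.searchsorted(codes, cand)
            ok = (pos < n) & (codes[np.minimum(pos, n - 1)] == cand)
            succ_exist[b] = ok
            succ_cand[b] = cand
        self.out_deg = succ_exist.sum(axis=0).astype(np.int8)
        self.succ = np.where(
            self.out_deg == 1,
            (succ_cand * succ_exist).sum(axis=0, dtype=np.uint64),
            np.uint64(0),
        )
        pre = codes >> np.uint64(2)
        pred_exist = np.zeros((4, n), dtype=bool)
        pred_cand = np.zeros((4, n), dtype=np.uint64)
        for b in range(4):
            cand = pre | (np.uint64(b) << shift_top)
            pos = np.searchsorted(codes, cand)
            ok = (pos < n) & (codes[np.minimum(pos, n - 1)] == cand)
            pred_exist[b] = ok
            pred_cand[b] = cand
        self.in_deg = pred_exist.sum(axis=0).astype(np.int8)
        self.pred = np.where(
            self.in_deg == 1,
            (pred_cand * pred_exist).sum(axis=0, dtype=np.uint64),
            np.uint64(0),
        )

    def index_of(self, code) -> int:
        return int(np.searchsorted(self.codes, np.uint64(code)))

    def __len__(self):
        return len(self.codes)

    # ---- unitigs ---------------------------------------------------------
    def unitigs(self) -> list[dict]:
        """Maximal non-branching paths, each reported once (rc-deduplicated)."""
        n = len(self.codes)
        visited = np.zeros(n, dtype=bool)
        # a node continues uniquely into its successor when out_deg==1 and
        # the successor's in_deg==1
        succ_idx = np.searchsorted(self.codes, self.succ)
        link_out = (self.out_deg == 1) & (self.in_deg[np.minimum(succ_idx, n - 1)] == 1)
        pred_idx = np.searchsorted(self.codes, self.pred)
        link_in = (self.in_deg == 1) & (self.out_deg[np.minimum(pred_idx, n - 1)] == 1)
        out = []

        def walk(start: int):
            path = [start]
            visited[start] = visited[self.rci[start]] = True
            cur = start
            while link_out[cur]:
                nxt = int(succ_idx[cur])
                if visited[nxt]:
                    break
                path.append(nxt)
                visited[nxt] = visited[self.rci[nxt]] = True
                cur = nxt
            return path

        starts = np.nonzero(~link_in)[0]
        for s in starts:
            if not visited[s]:
                out.append(walk(int(s)))
        for s in range(n):  # isolated cycles
            if not visited[s]:
                out.append(walk(s))
        result = []
        for path in out:
            codes = self.codes[path]
            first = decode(_code_to_bases(int(codes[0]), self.k))
            tail = "".join("ACGT"[int(c) & 3] for c in codes[1:])
            seq = first + tail
            result.append(
                {
                    "idx": path,
                    "seq": seq,
                    "mult": float(self.mult[path].mean()),
                    "first": int(codes[0]),
                    "last": int(codes[-1]),
                }
            )
        return result


def _code_to_bases(code: int, k: int) -> np.ndarray:
    out = np.zeros(k, dtype=np.uint8)
    for i in range(k - 1, -1, -1):
        out[i] = code & 3
        code >>= 2
    return out


def _count_canonical(reads: Sequence, k: int) -> tuple[np.ndarray, np.ndarray]:
    return count_canonical(reads, k)


def _canonical_seq(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def assemble(
    reads: Sequence,
    k: int = 31,
    min_edge_mult: int = 2,
    tip_len: Optional[int] = None,
    origin: str = "",
    max_rounds: int = 8,
) -> list[Contig]:
    """Assemble reads into contigs with a de Bruijn graph at one k.

    ``tip_len`` defaults to 2k.  Tips and simple bubbles are removed
    iteratively until the graph is stable, then maximal non-branching
    paths become contigs (canonical orientation, deterministic order).
    """
    if k % 2 == 0:
        raise ParameterError(f"k must be odd, got {k}")
    if k > 31:
        raise ParameterError(
            f"built-in assembler supports k <= 31 (2-bit packed k-mers), got {k}; "
            "use the external assembler hook for larger k"
        )
    if tip_len is None:
        tip_len = 2 * k
    uniq, counts = _count_canonical(reads, k)
    keep = counts >= min_edge_mult
    uniq, counts = uniq[keep], counts[keep]
    if len(uniq) == 0:
        return []
    for _ in range(max_rounds):
        g = DeBruijnGraph(uniq, counts, k)
        units = g.unitigs()
        drop: list[np.ndarray] = []
        # --- tip clipping: short dead-end spurs attached to the graph ----
        for u in units:
            fi, li = g.index_of(u["first"]), g.index_of(u["last"])
            dead_in, dead_out = g.in_deg[fi] == 0, g.out_deg[li] == 0
            attached = (not dead_in) or (not dead_out)
            if (dead_in != dead_out) and attached and len(u["seq"]) < tip_len:
                drop.append(g.codes[u["idx"]])
        # --- simple bubble popping: keep the higher-multiplicity arm ----
        if not drop:
            groups: dict[tuple, list[dict]] = {}
            for u in units:
                fi, li = g.index_of(u["first"]), g.index_of(u["last"])
                if g.in_deg[fi] != 1 or g.out_deg[li] != 1:
                    continue
                entry, exit_ = int(g.pred[fi]), int(g.succ[li])
                key_f = (entry, exit_)
                key_r = (int(rc_code(exit_, k)), int(rc_code(entry, k)))
                groups.setdefault(min(key_f, key_r), []).append(u)
            for key, arms in sorted(groups.items()):
                if len(arms) != 2:
                    continue
                a, b = arms
                if abs(len(a["seq"]) - len(b["seq"])) > 3:
                    continue
                loser = min(
                    arms, key=lambda u: (u["mult"], _canonical_seq(u["seq"]))
                )
                drop.append(g.codes[loser["idx"]])
        if not drop:
            break
        dead = np.unique(np.minimum(np.concatenate(drop),
                                    rc_code(np.concatenate(drop), k)))
        keep = ~np.isin(uniq, dead)
        if keep.all():
            break
        uniq, counts = uniq[keep], counts[keep]
        if len(uniq) == 0:
            return []
    g = DeBruijnGraph(uniq, counts, k)
    units = g.unitigs()
    seqs = sorted((_canonical_seq(u["seq"]) for u in units), key=lambda s: (-len(s), s))
    tag = f"{origin}|" if origin else ""
    return [
        Contig(id=f"{tag}k{k}|c{i}", seq=s, origin=origin or "", k_used=k)
        for i, s in enumerate(seqs)
    ]


def multi_k_assemble(
    reads: Sequence,
    k_list: Iterable[int] = DEFAULT_K_LIST,
    min_edge_mult: int = 2,
    origin: str = "",
) -> list[Contig]:
    """Pool contigs from assemblies at several k (no deduplication here).

    Redundancy between k's is intentional: the homology-guided merge
    stage removes it while profiting from whichever k resolved a region
    best.
    """
    out: list[Contig] = []
    for k in k_list:
        out.extend(assemble(reads, k=k, min_edge_mult=min_edge_mult, origin=origin))
    return out


class ConfigurationError(ValueError):
    """An external assembler command template is malformed."""


def external_assembler_hook(
    reads: Sequence[ReadRecord],
    command_template: str,
    workdir,
    origin: str = "",
) -> list[Contig]:
    """Run an external assembler via a shell command template.

    The template must contain ``{reads}`` (interleaved FASTQ written by
    this function) and ``{out}`` (FASTA the command must produce).  A
    failing command yields an empty contig set with a warning so the
    pipeline can continue with the remaining superblocks.
    """
    if "{reads}" not in command_template or "{out}" not in command_template:
        raise ConfigurationError(
            "command template must contain {reads} and {out} placeholders"
        )
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    reads_path = workdir / "reads.fastq"
    out_path = workdir / "contigs.fasta"
    write_fastq(reads, reads_path)
    cmd = command_template.format(reads=shlex.quote(str(reads_path)),
                                  out=shlex.quote(str(out_path)))
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0 or not out_path.exists():
        log.warning(
            "external assembler failed (exit %s) for %s: %s",
            proc.returncode, origin or "reads", proc.stderr.strip()[:500],
        )
        return []
    return [
        Contig(id=f"{origin}|ext|{r.id}" if origin else r.id, seq=r.seq,
               origin=origin, k_used=0)
        for r in read_fasta(out_path)
    ]
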
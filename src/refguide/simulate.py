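"""Synthetic diploid genomes and Illumina-like PE/MP read simulation.

The generator emulates the kind of short-read study design used for
heterozygous plant genomes of a few hundred Mb: 100 bp paired-end
libraries with short inserts (150/200/400 bp; overlapping pairs allowed)
and long-insert mate-pair jumping libraries (3-15 kb, RF orientation),
sequenced from a diploid individual whose two haplotypes differ at 1% of
non-N positions.  Half of the fragments of every library are drawn from
each haplotype.

Sequencing errors are substitutions only, drawn from a parametric
per-position error profile (flat 0.2% by default); base qualities are
set consistently with the local error rate (Q = -10*log10(rate)).  Truth
placements (haplotype, contig, position, strand) are recorded for every
read so mapping can be validated downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import ParameterError, ReadRecord, SequenceRecord
from .kmers import decode, encode, revcomp

DEFAULT_HET_RATE = 0.01  # fraction of non-N bases substituted on haplotype 2
DEFAULT_ERROR_RATE = 0.002
DEFAULT_READ_LEN = 100


@dataclass
class LibrarySpec:
    """A sequencing library: insert-size distribution and target coverage."""

    library_id: str
    kind: str  # "PE" or "MP"
    insert_mean: float
    insert_sd: float
    coverage: float
    read_len: int = DEFAULT_READ_LEN

    def __post_init__(self):
        if self.kind not in ("PE", "MP"):
            raise ParameterError(f"library kind must be PE or MP, got {self.kind!r}")
        if self.coverage <= 0:
            raise ParameterError("coverage must be > 0")

    @property
    def orientation(self) -> str:
        """FR for paired-end, RF for mate-pair chemistry."""
        return "FR" if self.kind == "PE" else "RF"


#: The standard deep-coverage design: three PE libraries (insert 150/200/400,
#: sd 34/36/87, coverage 72/72/40x) and five MP libraries (insert 3/5/7/11/15 kb,
#: sd 400, coverage 76/82/104/44/40x), all 100 bp reads.
STANDARD_LIBRARIES: tuple[tuple[str, str, float, float, float], ...] = (
    ("pe150", "PE", 150, 34, 72),
    ("pe200", "PE", 200, 36, 72),
    ("pe400", "PE", 400, 87, 40),
    ("mp3k", "MP", 3000, 400, 76),
    ("mp5k", "MP", 5000, 400, 82),
    ("mp7k", "MP", 7000, 400, 104),
    ("mp11k", "MP", 11000, 400, 44),
    ("mp15k", "MP", 15000, 400, 40),
)


def standard_libraries(scale: float = 1.0, read_len: int = DEFAULT_READ_LEN) -> list[LibrarySpec]:
    """The standard 3 PE + 5 MP library set with coverages scaled by ``scale``.

    ``scale=0.1`` reproduces the low-coverage design (10% of each library).
    """
    if not 0 < scale <= 1:
        raise ParameterError(f"scale must be in (0, 1], got {scale}")
    return [
        LibrarySpec(lid, kind, mean, sd, cov * scale, read_len)
        for lid, kind, mean, sd, cov in STANDARD_LIBRARIES
    ]


@dataclass
class MutationSet:
    """The substitutions distinguishing a derived haplotype from its source."""

    mutations: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __len__(self):
        return len(self.mutations)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#ref_id\tpos0\tref\talt\n")
            for ref_id, pos, ref, alt in self.mutations:
                fh.write(f"{ref_id}\t{pos}\t{ref}\t{alt}\n")


@dataclass
class TruthPlacement:
    """Where a simulated read really came from."""

    read_id: str
    mate: int
    haplotype: int
    ref_id: str
    start: int
    end: int
    strand: str


def write_truth_tsv(placements: Sequence[TruthPlacement], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tmate\thaplotype\tref_id\tstart\tend\tstrand\n")
        for p in placements:
            fh.write(f"{p.read_id}\t{p.mate}\t{p.haplotype}\t{p.ref_id}\t{p.start}\t{p.end}\t{p.strand}\n")


def random_genome(length: int, n_contigs: int = 1, seed: int = 0, gc: float = 0.5,
                  id_prefix: str = "chr") -> list[SequenceRecord]:
    """A random ACGT genome split into ``n_contigs`` equal pieces."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    per = length // n_contigs
    for i in range(n_contigs):
        n = per if i < n_contigs - 1 else length - per * (n_contigs - 1)
        codes = rng.choice(4, size=n, p=p)
        out.append(SequenceRecord(f"{id_prefix}{i + 1}", decode(codes)))
    return out


def mutate_genome(
    genome: Sequence[SequenceRecord],
    rate: float = DEFAULT_HET_RATE,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SequenceRecord], MutationSet]:
    """Derive a haplotype by substituting each non-N base with probability ``rate``.

    Substituted bases are replaced by one of the three other bases chosen
    uniformly; N positions are never touched.  The returned haplotype has
    the same contig ids and lengths as the input.
    """
    if not 0 <= rate <= 1:
        raise ParameterError(f"mutation rate must be in [0, 1], got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    haplotype, muts = [], []
    for rec in genome:
        codes = encode(rec.seq).copy()
        non_n = codes < 4
        hit = non_n & (rng.random(len(codes)) < rate)
        idx = np.nonzero(hit)[0]
        if len(idx):
            offset = rng.integers(1, 4, size=len(idx)).astype(np.uint8)
            new = (codes[idx] + offset) % 4
            for pos, old_c, new_c in zip(idx.tolist(), codes[idx].tolist(), new.tolist()):
                muts.append((rec.id, pos, "ACGT"[old_c], "ACGT"[new_c]))
            codes[idx] = new
        haplotype.append(SequenceRecord(rec.id, decode(codes), rec.description))
    return haplotype, MutationSet(muts)


def heterozygosity(genome: Sequence[SequenceRecord], haplotype: Sequence[SequenceRecord]) -> float:
    """Fraction of non-N positions at which the two haplotypes differ."""
    diff = total = 0
    for a, b in zip(genome, haplotype):
        ca, cb = encode(a.seq), encode(b.seq)
        ok = (ca < 4) & (cb < 4)
        total += int(ok.sum())
        diff += int((ca[ok] != cb[ok]).sum())
    return diff / total if total else 0.0


@dataclass
class ErrorProfile:
    """Per-position substitution error rate along the read.

    Flat by default; ``rate_end`` > ``rate_start`` gives the linear
    quality drop-off typical of Illumina cycles.
    """

    rate_start: float = DEFAULT_ERROR_RATE
    rate_end: Optional[float] = None

    def rates(self, read_len: int) -> np.ndarray:
        end = self.rate_start if self.rate_end is None else self.rate_end
        return np.linspace(self.rate_start, end, read_len)

    def quals(self, read_len: int) -> np.ndarray:
        r = self.rates(read_len)
        with np.errstate(divide="ignore"):
            q = np.where(r > 0, -10 * np.log10(np.maximum(r, 1e-9)), 40.0)
        return np.clip(np.rint(q), 2, 40).astype(np.int16)


def _sim_contig_pairs(seq, codes, n_pairs, lib, hap_idx, rec_id, rates, quals, rng,
                      start_index, id_prefix):
    """Simulate ``n_pairs`` fragments from one contig (both reads 2-bit coded)."""
    L = len(codes)
    rl = lib.read_len
    ins = rng.normal(lib.insert_mean, lib.insert_sd, size=n_pairs)
    ins = np.clip(np.rint(ins), max(2, rl), L).astype(np.int64)
    starts = (rng.random(n_pairs) * (L - ins + 1)).astype(np.int64)
    flip = rng.random(n_pairs) < 0.5  # which mate is read 1
    reads, placements = [], []
    for j in range(n_pairs):
        s, i = int(starts[j]), int(ins[j])
        rid = f"{id_prefix}_{start_index + j}"
        left = codes[s : s + min(rl, i)]
        right = codes[s + i - min(rl, i) : s + i]
        if lib.kind == "PE":  # FR: left forward, right reverse-complemented
            ends = [(left, s, s + len(left), "+"), (right, s + i - len(right), s + i, "-")]
        else:  # MP RF chemistry: left reverse-complemented, right forward
            ends = [(left, s, s + len(left), "-"), (right, s + i - len(right), s + i, "+")]
        if flip[j]:
            ends = ends[::-1]
        for mate, (frag, fs, fe, strand) in enumerate(ends, start=1):
            frag = frag.copy()
            if strand == "-":
                frag = (3 - frag)[::-1]
            n = len(frag)
            err = rng.random(n) < rates[:n]
            idx = np.nonzero(err)[0]
            if len(idx):
                frag[idx] = (frag[idx] + rng.integers(1, 4, size=len(idx))) % 4
            reads.append(ReadRecord(rid, mate, decode(frag), quals[:n].copy(), lib.library_id))
            placements.append(TruthPlacement(rid, mate, hap_idx, rec_id, fs, fe, strand))
    return reads, placements


def simulate_reads(
    haplotypes: Sequence[Sequence[SequenceRecord]],
    library: LibrarySpec,
    error_profile: Optional[ErrorProfile] = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[ReadRecord], list[TruthPlacement]]:
    """Simulate one library from 1 or 2 haplotypes.

    With two haplotypes, fragments alternate between them so each
    contributes half the pairs.  Fragment starts are uniform; insert
    lengths are Normal(mean, sd) truncated to [read_len, contig length].
    Returns the reads (mates interleaved, read 1 then read 2 per
    fragment) and their truth placements.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = error_profile or ErrorProfile()
    rates = profile.rates(library.read_len)
    quals = profile.quals(library.read_len)
    haps = [list(h) for h in haplotypes]
    if not haps:
        raise ParameterError("need at least one haplotype")
    genome_len = sum(len(r.seq) for r in haps[0])
    n_pairs_total = int(round(library.coverage * genome_len / (2 * library.read_len)))
    reads: list[ReadRecord] = []
    placements: list[TruthPlacement] = []
    counter = 0
    for h, hap in enumerate(haps):
        share = n_pairs_total // len(haps) + (1 if n_pairs_total % len(haps) > h else 0)
        usable = [(rec, encode(rec.seq)) for rec in hap if len(rec.seq) >= library.read_len]
        skipped = [rec.id for rec in hap if len(rec.seq) < library.read_len]
        if skipped:
            import warnings

            warnings.warn(f"contigs shorter than read length skipped: {skipped}")
        if not usable:
            continue
        lens = np.array([len(c) for _, c in usable], dtype=float)
        n_per = rng.multinomial(share, lens / lens.sum())
        for (rec, codes), n in zip(usable, n_per):
            r, p = _sim_contig_pairs(
                rec.seq, codes, int(n), library, h, rec.id, rates, quals, rng,
                counter, f"{library.library_id}"
            )
            reads.extend(r)
            placements.extend(p)
            counter += int(n)
    return reads, placements


def simulate_diploid_profile(
    genome: Sequence[SequenceRecord],
    scale: float = 1.0,
    het_rate: float = DEFAULT_HET_RATE,
    error_profile: Optional[ErrorProfile] = None,
    seed: int = 0,
    libraries: Optional[Sequence[LibrarySpec]] = None,
) -> tuple[list[tuple[LibrarySpec, list[ReadRecord]]], list[SequenceRecord], MutationSet, list[TruthPlacement]]:
    """Full study design: mutate a haplotype, simulate every standard library.

    Returns (per-library reads, haplotype 2, mutation set, truth placements).
    ``scale`` multiplies every library's coverage (0.1 = low-coverage design).
    """
    rng = np.random.default_rng(seed)
    hap2, muts = mutate_genome(genome, het_rate, rng)
    libs = list(libraries) if libraries is not None else standard_libraries(scale)
    out = []
    truth: list[TruthPlacement] = []
    for lib in libs:
        reads, placements = simulate_reads([list(genome), hap2], lib, error_profile, rng)
        out.append((lib, reads))
        truth.extend(placements)
    return out, hap2, muts, truth


def synthetic_genes(
    genome: Sequence[SequenceRecord],
    n_genes: int = 50,
    mean_len: int = 2000,
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Random non-overlapping gene-sized intervals on the genome (truth genes).

    Stands in for a curated core-gene set when scoring gene recovery of an
    assembly against the known truth sequence.
    """
    rng = np.random.default_rng(seed)
    lens = np.array([len(r.seq) for r in genome], dtype=float)
    genes: list[tuple[str, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {r.id: [] for r in genome}
    attempts = 0
    while len(genes) < n_genes and attempts < n_genes * 50:
        attempts += 1
        ridx = int(rng.choice(len(genome), p=lens / lens.sum()))
        rec = genome[ridx]
        glen = max(300, int(rng.normal(mean_len, mean_len / 4)))
        if glen >= len(rec.seq):
            continue
        start = int(rng.integers(0, len(rec.seq) - glen))
        if any(start < e and s < start + glen for s, e in occupied[rec.id]):
            continue
        occupied[rec.id].append((start, start + glen))
        genes.append((rec.id, start, start + glen))
    return sorted(genes)


def rearranged_reference(
    genome: Sequence[SequenceRecord],
    divergence: float = 0.05,
    n_segments: int = 8,
    missing_fraction: float = 0.05,
    invert_fraction: float = 0.25,
    seed: int = 0,
) -> list[SequenceRecord]:
    """A related-species stand-in reference derived from a genome.

    Cuts each contig into segments, drops ``missing_fraction`` of the
    sequence, inverts some segments, shuffles their order, and applies
    ``divergence`` substitutions — emulating a reference genome of a
    related species (rearranged, diverged, and missing lineage-specific
    content).
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in genome:
        L = len(rec.seq)
        seq = rec.seq
        if missing_fraction > 0:
            # remove two lineage-specific intervals totalling missing_fraction
            miss_len = int(round(missing_fraction * L / 2))
            starts = np.sort(rng.choice(L - 2 * miss_len, size=2, replace=False))
            s1, s2 = int(starts[0]), int(starts[1]) + miss_len
            seq = seq[:s1] + seq[s1 + miss_len : s2] + seq[s2 + miss_len :]
        L2 = len(seq)
        cuts = np.sort(rng.choice(np.arange(1, L2), size=n_segments - 1, replace=False))
        bounds = [0, *cuts.tolist(), L2]
        segs = [seq[bounds[i] : bounds[i + 1]] for i in range(n_segments)]
        order = rng.permutation(n_segments)
        pieces = []
        for i in order:
            s = segs[i]
            pieces.append(revcomp(s) if rng.random() < invert_fraction else s)
        diverged, _ = mutate_genome([SequenceRecord(rec.id, "".join(pieces))], divergence, rng)
        out.append(SequenceRecord(f"ref_{rec.id}", diverged[0].seq))
    return out
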
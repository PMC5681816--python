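"""FASTA / FASTQ / SAM readers and writers and the core record types.

All coordinates are stored 0-based half-open; the only place 1-based
coordinates appear is on the SAM wire format (handled by pysam).
Sequences are normalised to uppercase over the alphabet {A,C,G,T,N}:
IUPAC ambiguity codes other than N are collapsed to N.

Parsing of the standard formats is delegated to Biopython (FASTA/FASTQ)
and pysam (SAM); this module owns the record model and the conventions.
"""
from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pysam
from Bio import SeqIO

UNMAPPED = None

_NON_ALPHABET = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ParameterError(ValueError):
    """Raised when a parameter is outside its documented domain."""


def normalize_seq(seq: str) -> str:
    """Uppercase and collapse non-ACGTN IUPAC codes to N."""
    return _NON_ALPHABET.sub("N", str(seq).upper())


@dataclass
class SequenceRecord:
    """A named DNA sequence (reference contig, supercontig, scaffold...)."""

    id: str
    seq: str
    description: str = ""

    def __len__(self):
        return len(self.seq)


@dataclass
class ReadRecord:
    """One end of a sequenced fragment with per-base phred qualities."""

    id: str
    mate: int  # 1 or 2
    seq: str
    qual: np.ndarray  # integer phred scores, len == len(seq)
    library_id: str = ""

    def __post_init__(self):
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.id}: seq length {len(self.seq)} != qual length {len(self.qual)}"
            )

    def __len__(self):
        return len(self.seq)

    @property
    def key(self) -> tuple[str, int]:
        return (self.id, self.mate)


@dataclass
class AlignmentRecord:
    """Placement of one read end on a target sequence.

    ``ref_id is None`` means unmapped.  ``cigar`` is a list of
    (op, length) with op in {M, I, D, S}.  ``pos`` is the 0-based start
    on the target.
    """

    read_id: str
    mate: int
    ref_id: Optional[str]
    pos: int = -1
    strand: str = "+"
    cigar: list = field(default_factory=list)
    mapq: int = 0
    score: Optional[int] = None
    paired: bool = False
    proper_pair: bool = False
    mate_unmapped: bool = False
    mate_ref_id: Optional[str] = None
    mate_pos: int = -1
    mate_strand: str = "+"
    seq: str = ""
    qual: Optional[np.ndarray] = None

    @property
    def unmapped(self) -> bool:
        return self.ref_id is None

    @property
    def ref_len(self) -> int:
        """Length of the reference interval consumed (M + D)."""
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.pos + self.ref_len

    @property
    def key(self) -> tuple[str, int]:
        return (self.read_id, self.mate)


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Sequences are case-folded to uppercase and ambiguity codes collapsed
    to N.  Duplicate or empty records raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}, line 1: expected '>' header, got {first!r}")
        fh.seek(0)
        for i, rec in enumerate(SeqIO.parse(fh, "fasta")):
            if not rec.id:
                raise FormatError(f"{path}: record {i + 1} has an empty header")
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seq = normalize_seq(str(rec.seq))
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, seq, rec.description[len(rec.id):].strip()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_MATE_SUFFIX = re.compile(r"/([12])$")


def _infer_mate(rid: str, description: str, default: Optional[int]) -> tuple[str, int]:
    m = _MATE_SUFFIX.search(rid)
    if m:
        return rid[: m.start()], int(m.group(1))
    m = re.match(r"^\s*([12]):", description)
    if m:
        return rid, int(m.group(1))
    return rid, default if default is not None else 1


def read_fastq(path, default_mate: Optional[int] = None, library_id: str = "") -> Iterator[ReadRecord]:
    """Stream 4-line phred+33 FASTQ records.

    Mate numbers come from ``/1``-``/2`` id suffixes or ``1:``/``2:``
    description prefixes, falling back to ``default_mate`` (use 1 and 2
    for the two files of a pair).
    """
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                rid, mate = _infer_mate(rec.id, rec.description[len(rec.id):].strip(), default_mate)
                yield ReadRecord(
                    id=rid,
                    mate=mate,
                    seq=normalize_seq(str(rec.seq)),
                    qual=np.array(rec.letter_annotations["phred_quality"], dtype=np.int16),
                    library_id=library_id,
                )
        except ValueError as e:  # Biopython signals truncation/length mismatch
            raise FormatError(f"{path}: {e}") from e


def read_fastq_pair(path1, path2, library_id: str = "") -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Iterate paired reads from the two files of a PE/MP library."""
    it1 = read_fastq(path1, default_mate=1, library_id=library_id)
    it2 = read_fastq(path2, default_mate=2, library_id=library_id)
    for r1, r2 in zip(it1, it2):
        if r1.id != r2.id:
            raise FormatError(f"paired files out of sync: {r1.id!r} vs {r2.id!r}")
        yield r1, r2


def write_fastq(reads: Iterable[ReadRecord], path, mate_suffix: bool = True) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            suffix = f"/{r.mate}" if mate_suffix else ""
            qual = "".join(chr(min(int(q), 93) + 33) for q in r.qual)
            fh.write(f"@{r.id}{suffix}\n{r.seq}\n+\n{qual}\n")


_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CIGAR_OP = {v: k for k, v in _CIGAR_CODE.items()}


def _check_cigar(aln: AlignmentRecord) -> None:
    if aln.unmapped:
        return
    if aln.seq:
        readlen = sum(n for op, n in aln.cigar if op in "MIS")
        if readlen != len(aln.seq):
            raise FormatError(
                f"alignment {aln.read_id}/{aln.mate}: cigar consumes {readlen} "
                f"read bases but seq is {len(aln.seq)} bp"
            )


def write_sam(alignments: Iterable[AlignmentRecord], refs, path) -> None:
    """Write alignments as SAM text with a mandatory @SQ header.

    ``refs`` is an iterable of SequenceRecord (or (id, length) pairs).
    Internal 0-based positions are emitted 1-based by pysam.
    """
    sq = []
    for r in refs:
        if isinstance(r, tuple):
            sq.append({"SN": r[0], "LN": int(r[1])})
        else:
            sq.append({"SN": r.id, "LN": len(r.seq)})
    known = {d["SN"]: i for i, d in enumerate(sq)}
    header = pysam.AlignmentHeader.from_dict({"HD": {"VN": "1.6", "SO": "unknown"}, "SQ": sq})
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            _check_cigar(aln)
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.seq or None
            if aln.qual is not None:
                seg.query_qualities = [int(q) for q in aln.qual]
            flag = 0
            if aln.paired:
                flag |= 0x1 | (0x40 if aln.mate == 1 else 0x80)
                if aln.proper_pair:
                    flag |= 0x2
                if aln.mate_unmapped:
                    flag |= 0x8
                if aln.mate_strand == "-":
                    flag |= 0x20
            if aln.unmapped:
                flag |= 0x4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            else:
                if aln.ref_id not in known:
                    raise FormatError(f"unknown reference id {aln.ref_id!r}")
                if aln.strand == "-":
                    flag |= 0x10
                seg.reference_id = known[aln.ref_id]
                seg.reference_start = aln.pos
                seg.mapping_quality = int(aln.mapq)
                seg.cigartuples = [(_CIGAR_CODE[op], int(n)) for op, n in aln.cigar]
            if aln.paired and not aln.mate_unmapped and aln.mate_ref_id is not None:
                seg.next_reference_id = known.get(aln.mate_ref_id, -1)
                seg.next_reference_start = aln.mate_pos
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            seg.flag = flag
            if aln.score is not None:
                seg.set_tag("AS", int(aln.score))
            out.write(seg)


def read_sam(path) -> list[AlignmentRecord]:
    """Read SAM text back into :class:`AlignmentRecord` objects."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        names = list(fh.references)
        for seg in fh:
            unmapped = seg.is_unmapped
            cigar = []
            if not unmapped and seg.cigartuples:
                for code, n in seg.cigartuples:
                    if code not in _CIGAR_OP:
                        raise FormatError(f"unsupported CIGAR op code {code}")
                    cigar.append((_CIGAR_OP[code], n))
            qual = None
            if seg.query_qualities is not None:
                qual = np.array(seg.query_qualities, dtype=np.int16)
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    mate=2 if seg.is_read2 else 1,
                    ref_id=None if unmapped else names[seg.reference_id],
                    pos=-1 if unmapped else seg.reference_start,
                    strand="-" if (not unmapped and seg.is_reverse) else "+",
                    cigar=cigar,
                    mapq=0 if unmapped else seg.mapping_quality,
                    score=seg.get_tag("AS") if seg.has_tag("AS") else None,
                    paired=seg.is_paired,
                    proper_pair=seg.is_proper_pair,
                    mate_unmapped=seg.mate_is_unmapped if seg.is_paired else False,
                    mate_ref_id=(
                        names[seg.next_reference_id]
                        if seg.is_paired and seg.next_reference_id >= 0
                        else None
                    ),
                    mate_pos=seg.next_reference_start if seg.is_paired else -1,
                    mate_strand="-" if (seg.is_paired and seg.mate_is_reverse) else "+",
                    seq=seg.query_sequence or "",
                    qual=qual,
                )
            )
    return out
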
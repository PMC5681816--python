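"""Orchestration of the seven pipeline steps, with manifest and ablation.

trim -> map to reference -> superblocks -> per-superblock multi-k
assembly (+ unmapped-read assembly) -> homology-guided merge ->
[rescue] -> pileup correction -> ranked scaffolding.  Every stage
records its parameters and counts in a JSON manifest; with a work
directory set, stage artifacts (FASTQ/SAM/BED/FASTA) are written and a
rerun with an unchanged configuration resumes from them.  The rescue
step (step 5) can be disabled to quantify its contribution.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import evaluate as ev
from .assembler import Contig, multi_k_assemble, DEFAULT_K_LIST
from .finishing import (
    FinishingParams,
    build_links,
    correct_supercontigs,
    rescue_unmapped,
    scaffold,
    write_agp,
)
from .io import ReadRecord, SequenceRecord, read_fasta, write_fasta, write_sam
from .mapping import PairingModel, ReadMapper
from .merge import MergeParams, anchor_contigs, merge_layout, report_unplaced, write_layout
from .simulate import LibrarySpec
from .superblocks import (
    SuperblockParams,
    bridge_blocks,
    build_superblocks,
    call_blocks,
    collect_unmapped,
    partition_reads,
    write_bed,
)
from .trim import TrimParams, trim_pairs, trim_read

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; serialisable for the manifest."""

    trim: TrimParams = field(default_factory=TrimParams)
    superblock: SuperblockParams = field(default_factory=SuperblockParams)
    merge: MergeParams = field(default_factory=MergeParams)
    finishing: FinishingParams = field(default_factory=FinishingParams)
    k_list: tuple[int, ...] = DEFAULT_K_LIST
    enable_step5: bool = True
    close_gaps: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = {}
        for name in ("trim", "superblock", "merge", "finishing"):
            d[name] = dict(vars(getattr(self, name)))
            d[name] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d[name].items()}
        d["k_list"] = list(self.k_list)
        d["enable_step5"] = self.enable_step5
        d["close_gaps"] = self.close_gaps
        d["seed"] = self.seed
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    scaffolds: list[SequenceRecord]
    supercontigs: list[SequenceRecord]
    contigs: list[Contig]
    manifest: dict


def _pair_up(reads: Sequence[ReadRecord]):
    by_id: dict[str, dict[int, ReadRecord]] = {}
    for r in reads:
        by_id.setdefault(r.id, {})[r.mate] = r
    pairs, orphans = [], []
    for rid in by_id:
        mates = by_id[rid]
        if len(mates) == 2:
            pairs.append((mates[1], mates[2]))
        else:
            orphans.extend(mates.values())
    return pairs, orphans


def run_pipeline(
    reference: Sequence[SequenceRecord],
    libraries: Sequence[tuple[LibrarySpec, Sequence[ReadRecord]]],
    config: PipelineConfig = PipelineConfig(),
    workdir: Optional[str] = None,
    resume: bool = False,
) -> PipelineResult:
    """Run steps 1-7 and return the final scaffolds with a manifest."""
    wd = Path(workdir) if workdir else None
    if wd:
        wd.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "digest": config.digest(), "stages": []}
    old_manifest = None
    if wd and resume and (wd / "manifest.json").exists():
        old_manifest = json.loads((wd / "manifest.json").read_text())
        if old_manifest.get("digest") != manifest["digest"]:
            old_manifest = None

    def stage(name: str, **counts):
        manifest["stages"].append({"name": name, **counts})
        log.info("stage %s: %s", name, counts)
        if wd:
            (wd / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def artifact_ok(fname: str) -> bool:
        return bool(old_manifest) and wd is not None and (wd / fname).exists()

    final = "scaffolds.fasta"
    if artifact_ok(final):
        scaffolds = read_fasta(wd / final)
        sc = read_fasta(wd / "supercontigs_corrected.fasta")
        manifest["stages"] = old_manifest["stages"]
        return PipelineResult(scaffolds, sc, [], manifest)

    libs = [lib for lib, _ in libraries]
    pairing = PairingModel.from_libraries(libs)

    # ---- step 1: trim ----------------------------------------------------
    trimmed: list[ReadRecord] = []
    library_of: dict[str, str] = {}
    trim_counts = {}
    for lib, reads in libraries:
        pairs, orphans = _pair_up(reads)
        tpairs, torph, tstats = trim_pairs(pairs, config.trim)
        kept = [r for pair in tpairs for r in pair] + torph
        for o in orphans:  # unpaired input reads trimmed individually
            t = trim_read(o, config.trim)
            if t is not None:
                kept.append(t)
        for r in kept:
            library_of[r.id] = lib.library_id
        trimmed.extend(kept)
        trim_counts[lib.library_id] = {
            "input": tstats.input_reads,
            "retained_pairs": tstats.retained_pairs,
            "orphans": tstats.orphans,
        }
    stage("trim", libraries=trim_counts, reads_out=len(trimmed))

    # ---- step 2: map to the related reference, superblocks ---------------
    ref_mapper = ReadMapper(reference)
    alignments = ref_mapper.map_reads(trimmed, mode="local", pairing=pairing)
    if wd:
        write_sam(alignments, reference, wd / "ref_alignments.sam")
    n_mapped = sum(not a.unmapped for a in alignments)
    blocks = call_blocks(alignments)
    blocks = bridge_blocks(blocks, alignments, config.superblock)
    sbs = build_superblocks(blocks, config.superblock)
    partition_reads(sbs, alignments)
    unmapped_keys = collect_unmapped(alignments)
    if wd:
        write_bed(blocks, wd / "blocks.bed")
        write_bed(sbs, wd / "superblocks.bed")
    stage(
        "superblocks",
        mapped_reads=n_mapped,
        unmapped_reads=len(unmapped_keys),
        blocks=len(blocks),
        superblocks=len(sbs),
    )

    # ---- step 3: per-superblock multi-k assembly + unmapped assembly -----
    reads_by_key = {r.key: r for r in trimmed}
    contigs: list[Contig] = []
    for sb in sbs:
        sb_reads = [reads_by_key[k] for k in sorted(sb.read_ids) if k in reads_by_key]
        contigs.extend(multi_k_assemble(sb_reads, config.k_list, origin=sb.name))
    unmapped_reads = [reads_by_key[k] for k in sorted(unmapped_keys) if k in reads_by_key]
    contigs.extend(multi_k_assemble(unmapped_reads, config.k_list, origin="UNMAPPED"))
    if wd:
        write_fasta(
            (SequenceRecord(c.id, c.seq) for c in contigs), wd / "contigs.fasta"
        )
    stage("assemble", contigs=len(contigs), unmapped_pool=len(unmapped_reads))

    # ---- step 4: homology-guided redundancy removal ----------------------
    tiles = anchor_contigs(contigs, reference, config.merge)
    supercontigs = merge_layout(tiles, contigs, reference, config.merge)
    unplaced = report_unplaced(contigs, tiles)
    if wd:
        write_layout(tiles, wd / "layout.tsv")
        write_fasta(supercontigs, wd / "supercontigs.fasta")
    stage("merge", tiles=len(tiles), supercontigs=len(supercontigs), unplaced=len(unplaced))

    # ---- step 5: rescue of reads unmapped against the supercontigs -------
    if config.enable_step5:
        extra, rstats = rescue_unmapped(trimmed, supercontigs, config.finishing)
        supercontigs = supercontigs + extra
        stage("rescue", **rstats)

    # ---- step 6: pileup correction (paired-end reads) --------------------
    pe_ids = {l.library_id for l in libs if l.kind == "PE"}
    pe_reads = [r for r in trimmed if library_of.get(r.id) in pe_ids]
    sc_mapper = ReadMapper(supercontigs)
    pe_alns = sc_mapper.map_reads(pe_reads, mode="sensitive", pairing=pairing)
    supercontigs, cstats = correct_supercontigs(supercontigs, pe_alns, config.finishing)
    if wd:
        write_fasta(supercontigs, wd / "supercontigs_corrected.fasta")
    stage("correct", supercontigs=len(supercontigs), **cstats)

    # ---- step 7: ranked scaffolding and gap closing ----------------------
    final_mapper = ReadMapper(supercontigs)
    all_alns = final_mapper.map_reads(trimmed, mode="sensitive", pairing=pairing)
    by_lib: dict[str, list] = {l.library_id: [] for l in libs}
    for a in all_alns:
        lid = library_of.get(a.read_id)
        if lid in by_lib:
            by_lib[lid].append(a)
    ranked = sorted(libs, key=lambda l: l.insert_mean)
    links_by_rank = [
        build_links(supercontigs, by_lib[l.library_id], l, config.finishing)
        for l in ranked
    ]
    gap_reads = None
    if config.close_gaps:
        end_margin = 1000
        lens = {s.id: len(s.seq) for s in supercontigs}
        gap_reads = [
            reads_by_key[a.key]
            for a in all_alns
            if not a.unmapped
            and a.key in reads_by_key
            and (a.pos < end_margin or a.end > lens[a.ref_id] - end_margin)
        ]
    scaffolds, agp, sstats = scaffold(
        supercontigs, links_by_rank, config.finishing, gap_reads=gap_reads
    )
    if wd:
        write_fasta(scaffolds, wd / "scaffolds.fasta")
        write_agp(agp, wd / "scaffolds.agp.tsv")
    stage(
        "scaffold",
        scaffolds=len(scaffolds),
        total_length=sum(len(s.seq) for s in scaffolds),
        **sstats,
    )
    return PipelineResult(scaffolds, supercontigs, contigs, manifest)


def run_comparison(
    methods: dict[str, tuple[Sequence[SequenceRecord], Sequence[SequenceRecord]]],
    truth: Sequence[SequenceRecord],
    genes: Sequence[tuple[str, int, int]] = (),
    pe_reads: Sequence = (),
    mp_reads: Sequence = (),
    pe_pairing: Optional[PairingModel] = None,
    mp_pairing: Optional[PairingModel] = None,
    outdir: Optional[str] = None,
):
    """Evaluate several assemblies against one truth and rank them.

    ``methods`` maps a method name to its (contigs, scaffolds).  Returns
    (stats DataFrame, ZScoreTable, pairwise one-sided Wilcoxon p-value
    DataFrame).
    """
    import pandas as pd

    vectors = {
        name: ev.evaluate_assembly(
            contigs, scaffolds, truth, genes, pe_reads, mp_reads, pe_pairing, mp_pairing
        )
        for name, (contigs, scaffolds) in methods.items()
    }
    stats_df = pd.DataFrame(vectors).T
    table = ev.zscore_rank(vectors)
    pvals = ev.pairwise_wilcoxon(table)
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        stats_df.to_csv(out / "stats.tsv", sep="\t")
        table.z.to_csv(out / "zscores.tsv", sep="\t")
        table.ranking().to_csv(out / "ranking.tsv", sep="\t")
        pvals.to_csv(out / "wilcoxon_pvalues.tsv", sep="\t")
    return stats_df, table, pvals
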
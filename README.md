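# refguide

Reference-guided **de novo** assembly of short-read genomes, with a
multi-statistic z-score framework for ranking assemblies.

## The problem

De novo assembly of a eukaryotic genome from Illumina reads is memory-hungry
and fragments easily, especially for heterozygous diploid samples. When a
reference genome of a *related* species exists, its synteny can be borrowed
without forcing the new genome onto it: map the reads to the related
reference only to *partition* them into small, local assembly problems, then
assemble each partition de novo, so diverged sequence is still assembled
from the reads themselves. Content the reference cannot place at all is
recovered by dedicated de novo steps.

The pipeline (steps 1–7):

1. **Trim** — quality trimming (leading/trailing Q3, 4 bp sliding window
   mean Q15, discard < 40 bp).
2. **Map & partition** — map PE + MP reads to the related reference
   (fast-local mode); call *blocks* of continuous coverage, bridge adjacent
   blocks spanned by ≥ 10 proper pairs, and combine blocks into
   *superblocks* (≥ 12 kb, ≤ 100 kb, neighbours overlapping ≥ 300 bp).
   Each superblock collects its mapped reads plus unmapped mates.
3. **Local assembly** — assemble every superblock independently at several
   k-mer sizes (built-in de Bruijn assembler, or any external assembler via
   a command hook); assemble the fully unmapped reads as their own pool.
4. **Merge** — homology-guided redundancy removal: anchor all contigs to
   the reference by exact k-mer chains (unalignable overhangs up to
   1000 bp are ignored), merge tiles overlapping ≥ 10 bp, and call a
   majority consensus **from contig bases only** into non-redundant
   supercontigs. Contigs too diverged to anchor are reported lost.
5. **Rescue** — reads that do not map back to the supercontigs are de novo
   assembled and appended, recovering what step 4 lost.
6. **Correct** — a mapq ≥ 10 read pileup corrects substitutions/indels by
   strict majority, excises uncovered stretches (splitting supercontigs),
   and drops pieces < 200 bp.
7. **Scaffold** — ranked scaffolding: libraries joined smallest insert
   first, links need ≥ 3 bridging pairs, gap sizes from insert statistics,
   optional unique-read-path gap closing; scaffolds < 1 kb discarded.

Because no single number rates an assembly (a chimeric join *raises* N50),
the evaluation module computes a battery of 34 statistics per assembly —
continuity (N50/NG50, corrected NG50), misassembly classes against a truth
genome (translocation / relocation / inversion / local), COMPASS coverage,
validity, multiplicity and parsimony, read mapping and proper-pair rates, a
REAPR-like paired-read consistency score, and synthetic gene recovery. Each
statistic is standardised across the compared methods into a z-score,
sign-oriented so higher is better, and summed; leave-one-out extremes give
error bars and one-sided Wilcoxon rank-sum tests compare methods.

A synthetic-data module provides the study conditions: diploid truth
genomes (two haplotypes differing at 1% of non-N bases), the standard
3 PE + 5 MP library design (inserts 150/200/400 bp and 3–15 kb at
72/72/40× and 76/82/104/44/40×, scalable to the 10% low-coverage design),
flat-profile substitution errors with consistent qualities, truth placements
for every read, and rearranged/diverged "related species" references.

## Worked example

`examples/03_full_pipeline.py` simulates a 100 kb diploid genome (1%
heterozygosity) at the 10%-scale library design and assembles it guided by
a 5%-diverged, rearranged reference missing 5% of the genome:

```
        trim: {'reads_out': 53000}
 superblocks: {'mapped_reads': 49885, 'unmapped_reads': 3115, 'blocks': 1, 'superblocks': 1}
    assemble: {'contigs': 318, 'unmapped_pool': 3115}
       merge: {'tiles': 134, 'supercontigs': 18, 'unplaced': 184}
      rescue: {'reads_unmapped': 17226, 'rescued_supercontigs': 35}
     correct: {'supercontigs': 12, 'substitutions': 256, ...}
    scaffold: {'scaffolds': 1, 'total_length': 100061, 'links_accepted': 11, ...}
1 scaffold(s), 100061 bp total
truth coverage 99.9%, validity 100.0%, multiplicity 1.000
```

The 184 unplaced contigs are the ones the homology-guided merge had to
discard (they span rearrangement junctions or diverged regions of the
reference); the rescue step recovers their content from the 17 226 reads
the supercontigs could not absorb — run with `enable_step5=False` and the
truth coverage drops sharply. `examples/04_evaluate_and_rank.py` shows the
z-score ranking separating a clean assembly from a corrupted one whose N50
alone looks respectable.

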
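# Methods

This note documents the models, parameter choices and numerical details of
the `refguide` package: what each stage assumes, which knobs matter, what
the synthetic data does and does not emulate, and the design decisions
taken where the method left room.

## Coordinates, alphabets, formats

All intervals are 0-based half-open everywhere in the package; the single
exception is the SAM wire format, where pysam performs the 1-based
conversion. Sequences are normalised to {A,C,G,T,N}; IUPAC ambiguity codes
other than N collapse to N, since every downstream primitive (k-mer
encoding, pileups, consensus) works on the 4-letter alphabet. FASTA/FASTQ
parsing is delegated to Biopython and SAM to pysam; gzip is sniffed from
the file extension.

K-mers are packed 2 bits per base into a `uint64`, which caps k at 31 for
every built-in k-mer primitive (index, assembler, gap closing). The
full-scale multi-k set (41–81) documented for deep 100 bp data is therefore
only reachable through the external assembler hook; the built-in assembler
defaults to k ∈ {21, 31}, which is appropriate for the desk-scale genomes
(≤ a few hundred kb) the built-in stack targets.

## Read simulation (the study conditions)

The generator emulates a deep short-read design for a heterozygous diploid
genome:

- **Heterozygosity**: a second haplotype is derived by substituting each
  non-N base independently with probability 0.01 (default), choosing one of
  the three other bases uniformly. N positions are never touched. Half of
  every library's fragments are drawn from each haplotype.
- **Libraries** (100 bp reads): PE inserts 150/200/400 bp
  (sd 34/36/87) at 72/72/40×, FR orientation; MP inserts 3/5/7/11/15 kb
  (sd 400) at 76/82/104/44/40×, RF orientation. A single `scale` factor
  multiplies all coverages; 0.1 is the low-coverage design used throughout
  the tests so runs finish in minutes on one CPU.
- **Fragments**: starts uniform; insert length Normal(mean, sd) truncated
  to [read_len, contig length] (the nominal lower truncation bound of 2 bp
  is raised to the read length so a read never runs off its fragment;
  overlapping 150 bp-insert pairs are still produced). Fragment
  orientation random; which end is read 1 is random.
- **Errors**: substitutions only, from a per-cycle error profile (flat
  0.2% by default, optionally linear). Base qualities are set to
  Q = −10·log₁₀(rate), so quality and error rate are consistent by
  construction. Real instrument artefacts that are *not* emulated: indel
  errors, PCR duplicates, GC bias, adapter read-through, quality-by-context
  structure. Empirical instrument profiles are deliberately replaced by
  this parametric profile: the pipeline logic only depends on a realistic
  error/quality coupling, not on a specific machine.
- **Truth**: every read records its (haplotype, contig, start, end,
  strand); the mutation set is written as a table. These exist for
  validation and are not used by the pipeline.
- **Related reference**: `rearranged_reference` removes a chosen fraction
  of the genome (two intervals), cuts the rest into segments, inverts and
  shuffles them, and applies uniform substitution divergence. This emulates
  a related species: diverged, rearranged, missing lineage-specific
  content. It does not emulate segmental duplications or repeat expansion.

Consequently, passing tests show the pipeline handles substitution
divergence, heterozygosity, rearrangement and missing content at realistic
densities; they say nothing about indel-rich platforms, repeat-dense
genomes or contamination.

## Trimming

Order of operations: leading bases < Q3, then trailing bases < Q3, then a
4 bp sliding window scanned left→right — the read is cut at the first base
of the first window whose mean quality drops below 15 — then reads < 40 bp
are discarded. If one mate of a pair dies the survivor becomes an orphan
(kept for mapping and assembly). The output is always a contiguous
substring of the input and trimming is idempotent. Adapter clipping is a
literal-match hook, off by default since simulated reads carry no adapters.

## Mapping

A seed-and-extend mapper: exact 15-mer seeds (stride k/3) vote into
diagonal clusters per (reference, strand); the best clusters are scored by
an ungapped comparison on the diagonal and, if > 15% of the compared bases
mismatch, by a local affine alignment (match +2, mismatch −3, gap open −5,
gap extend −2; Bio.Align.PairwiseAligner). `local` mode clips read ends
free of charge; `sensitive` mode charges 2 per clipped base, favouring
end-to-end placements — these presets mirror the fast-local vs sensitive
usage at the partitioning vs validation stages. Scores below
20 + 8·ln(read_len) are unmapped. mapq = min(60, 6·(best − second best)),
0 on ties. The scoring constants and the mapq formula are stand-ins
calibrated so that unique near-perfect hits get mapq 60 and ambiguous hits
get 0 — all downstream logic relies only on the mapq ≥ 10 cut. K-mers
occurring more than 64 times in the target are not used as seeds (repeat
masking bounds seeding cost). Only the primary (best) alignment per mate is
reported. Proper pairs: same target, expected orientation (FR for PE, RF
for MP), insert within mean ± 4 sd.

## Blocks and superblocks

Blocks are maximal intervals of depth ≥ 1 over all primary alignments (no
mapq filter at this stage — the filter belongs to the later correction
step). Adjacent blocks merge, gap included, when ≥ 10 proper pairs have
one mate in each; merging is a deterministic left-to-right sweep and is
monotone in the threshold. Superblocks accumulate consecutive blocks until
≥ 12 kb, and neighbours overlap by sharing whole blocks, topping up
leftward block-by-block until the shared span is ≥ 300 bp. Two situations
force a *within-block* overlap of exactly 300 bp instead: splitting a
superblock that exceeds 100 kb, and the degenerate case where whole-block
sharing would recreate the previous superblock (e.g. a single block
≥ 12 kb) — treating the giant block like the 100 kb split keeps the
overlap guarantee without duplicating superblocks. The final superblock on
a reference may be shorter than 12 kb and is kept, flagged terminal:
dropping it would silently lose reference ends. Read partitioning assigns
a read (id, mate) to every superblock its alignment overlaps, plus
unmapped reads to the superblock of their mapped mate; overlap-zone reads
intentionally live in both neighbours.

## Built-in assembler

Canonical k-mers (min of forward/RC code) are counted in one vectorised
pass; edges with multiplicity < 2 are dropped, which removes nearly all
singleton error k-mers at ≥ 10× coverage. The graph then iterates, up to 8
rounds, over: tip clipping (dead-end unitigs < 2k bp attached at their
other end) and simple two-arm bubble popping (same entry and exit
junction, length difference ≤ 3 bp — i.e. heterozygous substitutions and
small indels) keeping the higher-multiplicity arm, ties broken toward the
lexicographically smaller canonical sequence. Nested bubbles become simple
in later rounds, so nearby heterozygous sites still collapse. Maximal
non-branching paths are emitted once each in canonical orientation, sorted
by length then sequence — the output is a deterministic function of the
read multiset and is invariant under reverse-complementing the input.
Multi-k assembly pools the per-k contig sets without deduplication:
removing that redundancy is exactly the merge stage's job. The external
hook runs any shell template with `{reads}`/`{out}` placeholders; a
failing command contributes an empty contig set with a warning so one bad
superblock cannot abort a run.

## Homology-guided merge

Contigs anchor to the reference by exact 15-mer matches grouped into
strictly-ungapped diagonal segments; the best co-linear chain (most
anchors; ties to the leftmost reference position; ≥ 4 anchors required)
defines one tile per contig. Unalignable contig ends up to 1000 bp are
recorded as trims and ignored; a longer overhang, or no chain, leaves the
contig unplaced — such contigs (typically spanning rearrangement junctions
or too diverged) are reported and their content is deliberately left to the
rescue step. Tiles overlapping ≥ 10 bp on the reference merge into one
group per gap-free stretch; consensus is called column-by-column over the
projected contig bases: majority wins, ties break lexicographically, and a
column no contig covers is excised. Between chain segments, equal-length
gaps project diagonally (pure substitution divergence); unequal gaps are
aligned with edlib and insertions relative to the reference are dropped
(they are rare in substitution-dominated data and are recovered by the
correction/rescue machinery when real). The reference contributes
*coordinates only* — no reference base is ever written into a supercontig,
so divergence survives the merge; mutating the reference away from anchors
provably changes nothing.

## Finishing

**Rescue**: reads unmapped against the supercontigs (sensitive mode) are
assembled at a single k (31 at desk scale; 61 is the documented full-scale
choice) and appended. **Correction**: pileup over mapq ≥ 10 paired-end
alignments; a substitution needs a strict majority of the filtered depth
and ≥ 2 reads; columns with majority deletion are removed and majority
insertions inserted (this majority-vote indel handling stands in for a
realignment stack, same corrective intent without external tools);
zero-depth stretches are excised, splitting the supercontig; pieces
< 200 bp are discarded. A column whose current base already has a strict
majority is never changed. **Scaffolding**: per library, read pairs whose
mates map (mapq ≥ 10) to two different supercontigs aggregate into
oriented end-to-end links; gap estimate = insert mean − distances of the
mates to their inner ends, averaged; links with < 3 pairs are dropped.
Libraries are processed in ascending insert order ("ranked": short-range
joins first, long-range superscaffolding after); within a library,
descending pair support; a link is rejected if either supercontig end is
already used or the join would close a cycle (union-find). Junctions are
written as max(gap, 10) N's — the floor keeps a visible junction when the
estimate is non-positive — unless gap closing finds exactly one de Bruijn
read path (k = 31, multiplicity ≥ 2) between the flanks, in which case the
unique bridge replaces the N's; ambiguity (two or more paths) always keeps
the N gap. Scaffolds < 1 kb are discarded. The 3-pair threshold and greedy
conflict rule are configurable stand-ins for a production scaffolder's
internals, which the method does not pin down.

## Evaluation

N50 is the length at which the descending cumulative sum reaches half the
assembly; NG50 uses half the known genome size (0 if never reached).
Truth alignment decomposes each scaffold into diagonal segments (diagonal
band 50, so small indels stay within a segment and are counted as indel
events); segments < 500 bp are ignored and weaker segments mostly covered
by stronger ones are dropped, so each scaffold base is placed at most
once. Adjacent-segment breakpoints classify with precedence translocation
(different truth sequence) > inversion (opposite strands) > relocation
(truth gap vs scaffold gap inconsistent by > 1 kb, apart or overlapping) >
local (inconsistency in (85, 1000] bp; the 85 bp floor suppresses
spurious micro-breakpoints, following common practice of truth-alignment
evaluators). Scaffold N-gaps whose implied truth gap matches the written
gap are therefore *not* events. Corrected NG50 re-breaks scaffolds at
every non-local breakpoint. COMPASS metrics come from the same segments:
coverage (truth bases covered), validity (assembly bases validated),
multiplicity (mean copies per covered truth base), parsimony (assembled
per validated bp; +inf sentinel for an unvalidated assembly). The
REAPR-like score calls error regions where proper-pair fragment coverage
drops to zero in the scaffold interior (a 500 bp end margin is excluded,
where fragment coverage cannot reach) or where ≥ 5 inconsistent pairs
overlap, and returns (error count, error-free fraction × broken N50 / N50).
Gene recovery over synthetic truth genes: full = ≥ 95% of the gene covered
by one scaffold, partial = ≥ 1 bp.

The statistic registry holds 34 entries with fixed orientations:
counts of sequences and misassemblies, length differences, N/indel
densities, % unaligned and parsimony are lower-better; rates, N50-family,
coverage/validity and gene counts are higher-better; duplication ratio and
multiplicity are scored by distance from 1 (transformed to −|x−1| before
standardisation). Orientation conventions follow the established
assembly-competition practice; they are configuration, not measurement.
z-scores use the sample standard deviation (ddof = 1) across methods;
zero-variance columns contribute zeros. The summed z ranks methods;
leave-one-out extremes of the sum give the error bars. The one-sided
Wilcoxon rank-sum over two methods' z-score vectors is exact (full
permutation enumeration) for tie-free pooled samples up to 20, and
otherwise uses the normal approximation with continuity and tie
correction — the same switch R's `wilcox.test` applies, which this
mirrors deliberately; with zero rank variance the p-value is reported as
0.5. Treating the per-statistic z-scores as independent rank-sum samples
(rather than as paired differences) reproduces the framework's own usage;
it is a fidelity choice, not a statistical recommendation.

## Pipeline, determinism, problem sizes

The orchestrator runs stages 1–7, logs per-stage counts into a JSON
manifest, writes stage artifacts (FASTQ/SAM/BED/FASTA/AGP-like) when a
work directory is given, and can resume a run whose configuration hash
matches. All randomness lives in the simulator; given fixed inputs the
pipeline is deterministic (every dict iteration that could affect output
is sorted), so a fixed seed yields byte-identical outputs end to end.

Desk-scale problem sizes used throughout the tests and examples, chosen so
each scenario represents the study conditions at a size a laptop handles
in minutes: genomes of 50–200 kb, the 10%-scale library design (~53×
total), k ∈ {21, 31}, and the 5%-diverged rearranged reference. At these
sizes the full pipeline reconstructs ≥ 99% of a 200 kb diploid truth in a
single scaffold at ≥ 99% aligned identity, and disabling the rescue step
drops truth coverage to ~85% — the with/without-rescue contrast the
pipeline is designed around.

## Known limitations

- Substitution-only simulation; indel sequencing errors are untested.
- The built-in assembler caps k at 31 and resolves only simple two-arm
  bubbles; complex repeat structures fragment.
- The merge stage drops contig insertions relative to the reference during
  consensus projection; heavily indel-diverged references would lose
  content there (recovered, if covered by reads, via rescue/correction).
- Haplotypes are collapsed, not phased: at heterozygous sites the output
  carries an effectively arbitrary allele (~half match each haplotype).
- One round only: re-running the pipeline with the draft as the new
  reference is out of scope.
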
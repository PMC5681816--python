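"""Map reads to a related reference and partition them into superblocks.

Reads from a 60 kb genome are mapped against a 4%-diverged, rearranged
reference of a "related species"; continuous-coverage blocks are called,
bridged by proper pairs, and grouped into >= 12 kb superblocks that
each define one local assembly problem.
"""
from refguide import PairingModel, ReadMapper
from refguide.simulate import (
    ErrorProfile,
    LibrarySpec,
    random_genome,
    rearranged_reference,
    simulate_reads,
)
from refguide.superblocks import (
    bridge_blocks,
    build_superblocks,
    call_blocks,
    collect_unmapped,
    partition_reads,
)

genome = random_genome(60_000, seed=4)
reference = rearranged_reference(genome, divergence=0.04, n_segments=5,
                                 missing_fraction=0.05, seed=5)
lib = LibrarySpec("pe200", "PE", 200, 36, 15)
reads, _ = simulate_reads([genome], lib, ErrorProfile(0.002), seed=6)

mapper = ReadMapper(reference)
alns = mapper.map_reads(reads, mode="local",
                        pairing=PairingModel.from_libraries([lib]))
print(f"{sum(not a.unmapped for a in alns)}/{len(alns)} reads mapped to the "
      "diverged reference")

blocks = bridge_blocks(call_blocks(alns), alns)
superblocks = build_superblocks(blocks)
partition_reads(superblocks, alns)
unmapped = collect_unmapped(alns)
print(f"{len(blocks)} coverage blocks -> {len(superblocks)} superblocks")
for sb in superblocks:
    print(f"  {sb.name}: {len(sb):>6} bp, {len(sb.read_ids)} reads"
          + (" (terminal)" if sb.terminal else ""))
print(f"{len(unmapped)} unmapped reads go to the separate unmapped-pool assembly")
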
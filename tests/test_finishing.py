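"""Rescue, pileup correction, scaffold links, ranked scaffolding."""
from collections import Counter

import numpy as np
import pytest

from refguide import (
    AlignmentRecord,
    ErrorProfile,
    FinishingParams,
    LibrarySpec,
    PairingModel,
    ReadMapper,
    SequenceRecord,
    build_links,
    correct_supercontigs,
    rescue_unmapped,
    revcomp,
    scaffold,
    simulate_reads,
)
from refguide.finishing import ScaffoldLink
from refguide.simulate import random_genome

from conftest import make_read, tiling_reads


class TestRescue:
    def test_fully_covered_supercontigs_need_no_rescue(self, small_genome):
        lib = LibrarySpec("pe", "PE", 200, 36, 5)
        reads, _ = simulate_reads([small_genome], lib, ErrorProfile(0.0), seed=1)
        extra, stats = rescue_unmapped(reads, small_genome)
        assert extra == [] and stats["reads_unmapped"] == 0

    def test_missing_region_recovered(self):
        g = random_genome(30_000, seed=2)
        lib = LibrarySpec("pe", "PE", 200, 36, 20)
        reads, _ = simulate_reads([g], lib, ErrorProfile(0.0), seed=3)
        # supercontigs lack a 5 kb interior region
        partial = [
            SequenceRecord("scA", g[0].seq[:10_000]),
            SequenceRecord("scB", g[0].seq[15_000:]),
        ]
        extra, stats = rescue_unmapped(reads, partial)
        assert stats["rescued_supercontigs"] >= 1
        best = max(extra, key=lambda s: len(s.seq))
        missing_core = g[0].seq[11_000:14_000]
        assert len(best.seq) > 3000
        # the rescue contig may overhang the flanks slightly (boundary reads
        # fail to map back), but it must recover the missing interior
        assert missing_core in best.seq or missing_core in revcomp(best.seq)

    def test_empty_supercontig_set_rescues_everything(self):
        g = random_genome(5000, seed=4)
        reads = tiling_reads(g[0].seq)
        extra, _ = rescue_unmapped(reads, [], FinishingParams(rescue_k=31))
        assert any(len(s.seq) > 4000 for s in extra)


def pileup_alns(sc_id, reads_at, mapq=60):
    """Alignment records for (pos, seq) tuples, all-M cigars."""
    out = []
    for i, (pos, seq) in enumerate(reads_at):
        out.append(
            AlignmentRecord(f"r{i}", 1, sc_id, pos=pos, cigar=[("M", len(seq))],
                            mapq=mapq, seq=seq)
        )
    return out


class TestCorrection:
    def test_unanimous_disagreement_is_corrected(self):
        g = random_genome(1000, seed=5)[0].seq
        wrong = "A" if g[500] != "A" else "C"
        sc = [SequenceRecord("sc", g[:500] + wrong + g[501:])]
        alns = pileup_alns("sc", [(i, g[i : i + 100]) for i in range(0, 901, 45)])
        out, stats = correct_supercontigs(sc, alns)
        assert out[0].seq == g
        assert stats["substitutions"] == 1

    def test_low_mapq_reads_are_ignored(self):
        g = random_genome(1000, seed=6)[0].seq
        wrong = "A" if g[500] != "A" else "C"
        sc = [SequenceRecord("sc", g[:500] + wrong + g[501:])]
        alns = pileup_alns("sc", [(i, g[i : i + 100]) for i in range(0, 901, 45)], mapq=5)
        out, _ = correct_supercontigs(sc, alns)
        assert out == []  # no filtered coverage at all: everything excised

    def test_majority_supported_base_never_changed(self):
        g = random_genome(1000, seed=7)[0].seq
        sc = [SequenceRecord("sc", g)]
        # 2 reads carry an error at position 500, 4 reads agree with the contig
        bad = g[455 : 455 + 100]
        bad = bad[:45] + ("A" if bad[45] != "A" else "C") + bad[46:]
        cover = [(i, g[i : i + 100]) for i in range(0, 901, 25)]
        alns = pileup_alns("sc", cover + [(455, bad), (455, bad)])
        out, stats = correct_supercontigs(sc, alns)
        assert out[0].seq == g and stats["substitutions"] == 0

    def test_uncovered_interior_splits_and_short_piece_dropped(self):
        g = random_genome(1300, seed=8)[0].seq
        sc = [SequenceRecord("sc", g)]
        # cover [0,600) and [1150,1300): gap of 550, right piece 150 bp < 200
        cover = [(i, g[i : i + 100]) for i in range(0, 501, 25)]
        cover += [(1150, g[1150:1250]), (1200, g[1200:1300])]
        out, stats = correct_supercontigs(sc, pileup_alns("sc", cover))
        assert len(out) == 1
        assert out[0].seq == g[:600]
        assert stats["splits"] == 1 and stats["discarded_pieces"] == 1

    def test_majority_deletion_removed(self):
        g = random_genome(600, seed=9)[0].seq
        # supercontig has a spurious inserted base at 300
        sc = [SequenceRecord("sc", g[:300] + "A" + g[300:])]
        alns = []
        for i, pos in enumerate(range(0, 501, 20)):
            seq = g[pos : pos + 100]
            if pos <= 300 - 10 and pos + 100 > 300 + 10:
                cigar = [("M", 300 - pos), ("D", 1), ("M", 100 - (300 - pos))]
            else:
                cigar = [("M", 100)]
                if pos > 200:
                    pos = pos + 1  # account for the insertion shift
            alns.append(AlignmentRecord(f"d{i}", 1, "sc", pos=pos, cigar=cigar,
                                        mapq=60, seq=seq))
        out, stats = correct_supercontigs(sc, alns)
        assert stats["deletions"] >= 1
        assert out[0].seq.count(g[280:320]) == 1  # spurious base gone


class TestLinks:
    def _sc(self):
        g = random_genome(10_300, seed=10)[0].seq
        return g, [SequenceRecord("A", g[:5000]), SequenceRecord("B", g[5300:])]

    def _pair_alns(self, n, lib_kind="PE"):
        """n pairs bridging A(tail) -> B(head) in PE FR orientation."""
        out = []
        for i in range(n):
            da, db = 150 + i, 120 + i
            s1 = "+" if lib_kind == "PE" else "-"
            s2 = "-" if lib_kind == "PE" else "+"
            out.append(AlignmentRecord(f"p{i}", 1, "A", pos=5000 - da, strand=s1,
                                       cigar=[("M", 100)], mapq=60, seq="A" * 100))
            out.append(AlignmentRecord(f"p{i}", 2, "B", pos=db - 100, strand=s2,
                                       cigar=[("M", 100)], mapq=60, seq="A" * 100))
        return out

    def test_links_aggregate_supporting_pairs(self):
        _, scs = self._sc()
        lib = LibrarySpec("pe", "PE", 600, 50, 1)
        links = build_links(scs, self._pair_alns(10), lib)
        assert len(links) == 1
        assert links[0].n_supporting_pairs == 10
        assert {(links[0].sc_a, links[0].end_a), (links[0].sc_b, links[0].end_b)} == {
            ("A", "T"), ("B", "H")
        }

    def test_below_min_pairs_dropped(self):
        _, scs = self._sc()
        lib = LibrarySpec("pe", "PE", 600, 50, 1)
        assert build_links(scs, self._pair_alns(2), lib) == []

    def test_gap_estimate_formula(self):
        # 300 bp true gap; insert 600, mates ~150/120 from the inner ends
        _, scs = self._sc()
        lib = LibrarySpec("pe", "PE", 600, 50, 1)
        links = build_links(scs, self._pair_alns(20), lib)
        est = links[0].gap_estimate
        assert est == pytest.approx(600 - (150 + 19 / 2) - (120 + 19 / 2), abs=1e-6)

    def test_simulated_mp_gap_estimate_within_3_se(self):
        g = random_genome(20_000, seed=11)
        seq = g[0].seq
        scs = [SequenceRecord("L", seq[:9850]), SequenceRecord("R", seq[10150:])]
        lib = LibrarySpec("mp", "MP", 3000, 400, 30)
        reads, _ = simulate_reads([g], lib, ErrorProfile(0.0), seed=12)
        mapper = ReadMapper(scs)
        alns = mapper.map_reads(reads, mode="sensitive",
                                pairing=PairingModel.from_libraries([lib]))
        links = build_links(scs, alns, lib)
        link = max(links, key=lambda l: l.n_supporting_pairs)
        assert link.n_supporting_pairs >= 20
        se = 400 / np.sqrt(link.n_supporting_pairs)
        assert abs(link.gap_estimate - 300) < 3 * se + 20


class TestScaffold:
    def _two_sc(self):
        g = random_genome(10_100, seed=13)[0].seq
        return g, [SequenceRecord("A", g[:5000]), SequenceRecord("B", g[5100:])]

    def test_single_link_joins_with_gap(self):
        g, scs = self._two_sc()
        link = ScaffoldLink("A", "T", "B", "H", 10, 100.0)
        out, agp, stats = scaffold(scs, [[link]])
        assert len(out) == 1
        assert len(out[0].seq) == 5000 + 100 + 5000
        assert "N" * 100 in out[0].seq
        assert stats["links_accepted"] == 1

    def test_conflicting_link_with_lower_support_rejected(self):
        g, scs = self._two_sc()
        scs.append(SequenceRecord("C", random_genome(3000, seed=14)[0].seq))
        good = ScaffoldLink("A", "T", "B", "H", 10, 100.0)
        bad = ScaffoldLink("A", "T", "C", "H", 4, 50.0)
        out, _, stats = scaffold(scs, [[good, bad]])
        assert stats["links_accepted"] == 1 and stats["links_rejected"] == 1
        joined = max(out, key=lambda s: len(s.seq))
        assert "N" * 100 in joined.seq

    def test_short_lone_supercontig_discarded(self):
        scs = [SequenceRecord("tiny", "ACGT" * 225)]  # 900 bp < 1 kb floor
        out, _, _ = scaffold(scs, [])
        assert out == []

    def test_sequence_conservation_without_gap_closing(self):
        g, scs = self._two_sc()
        link = ScaffoldLink("A", "T", "B", "H", 10, 100.0)
        out, _, _ = scaffold(scs, [[link]])
        assert Counter(out[0].seq.replace("N", "")) == Counter(
            scs[0].seq + scs[1].seq
        )

    def test_gap_closed_by_unique_read_path(self):
        g, scs = self._two_sc()
        reads = tiling_reads(g[4000:6200])
        link = ScaffoldLink("A", "T", "B", "H", 10, 100.0)
        out, agp, stats = scaffold(scs, [[link]], gap_reads=reads)
        assert stats["gaps_closed"] == 1
        assert out[0].seq == g  # perfect reconstruction incl. the 100 bp gap

    def test_negative_gap_estimate_floored_to_10_n(self):
        g, scs = self._two_sc()
        link = ScaffoldLink("A", "T", "B", "H", 10, -50.0)
        out, _, _ = scaffold(scs, [[link]])
        assert "N" * 10 in out[0].seq and "N" * 11 not in out[0].seq
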
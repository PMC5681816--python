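"""Evaluation statistics, misassembly classification, z-score ranking."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from refguide import (
    SequenceRecord,
    align_to_truth,
    classify_misassemblies,
    compass_metrics,
    corrected_ng50,
    n50,
    ng50,
    revcomp,
    wilcoxon_one_sided,
    zscore_rank,
)
from refguide.evaluate import (
    duplication_ratio,
    gene_recovery,
    indels_per_100kb,
    ns_per_100kb,
    pairwise_wilcoxon,
    reapr_like_score,
)
from refguide.simulate import random_genome


def n50_oracle(lengths, half):
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if acc >= half:
            return x
    return 0


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected", [([10, 10, 10], 10), ([5, 4, 3, 2, 1], 4), ([], 0), ([7], 7)]
    )
    def test_n50_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_ng50_example(self):
        # cumulative 5, 9 < 10; 12 >= 10 at length 3
        assert ng50([5, 4, 3, 2, 1], 20) == 3

    def test_ng50_zero_when_genome_unreached(self):
        assert ng50([5, 4], 100) == 0

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=50))
    def test_matches_brute_force_oracle(self, lengths):
        assert n50(lengths) == n50_oracle(lengths, sum(lengths) / 2)
        for g in (sum(lengths) // 2 + 1, sum(lengths), 2 * sum(lengths)):
            assert ng50(lengths, g) == n50_oracle(lengths, g / 2)


@pytest.fixture(scope="module")
def truth():
    return random_genome(60_000, n_contigs=2, seed=77)


class TestAlignToTruth:
    def test_exact_substring_is_one_segment(self, truth):
        asm = [SequenceRecord("s", truth[0].seq[5000:15_000])]
        pl = align_to_truth(asm, truth)
        assert len(pl["s"]) == 1
        seg = pl["s"][0]
        assert (seg.ref_id, seg.rstart, seg.rend, seg.strand) == ("chr1", 5000, 15_000, "+")

    def test_chimeric_scaffold_splits_by_chromosome(self, truth):
        asm = [SequenceRecord("s", truth[0].seq[:5000] + truth[1].seq[:5000])]
        pl = align_to_truth(asm, truth)
        assert [s.ref_id for s in pl["s"]] == ["chr1", "chr2"]

    def test_random_scaffold_has_no_segments(self, truth):
        asm = [SequenceRecord("s", random_genome(5000, seed=5, id_prefix="x")[0].seq)]
        assert align_to_truth(asm, truth)["s"] == []


class TestClassify:
    def test_truth_itself_is_clean(self, truth):
        pl = align_to_truth(list(truth), truth)
        summary = classify_misassemblies(pl, list(truth))
        assert summary.n_misassemblies == 0 and summary.n_local == 0

    def test_injected_translocation(self, truth):
        asm = [SequenceRecord("s", truth[0].seq[:8000] + truth[1].seq[:8000])]
        pl = align_to_truth(asm, truth)
        summary = classify_misassemblies(pl, asm)
        assert summary.n_translocations == 1
        assert summary.n_misassemblies == 1
        assert summary.pct_misassembled_scaffolds == 100.0

    def test_injected_relocation(self, truth):
        seq = truth[0].seq
        asm = [SequenceRecord("s", seq[:8000] + seq[10_000:18_000])]  # 2 kb skip
        pl = align_to_truth(asm, truth)
        summary = classify_misassemblies(pl, asm)
        assert summary.n_relocations == 1 and summary.n_misassemblies == 1

    def test_injected_inversion(self, truth):
        seq = truth[0].seq
        asm = [SequenceRecord("s", seq[:8000] + revcomp(seq[8000:16_000]))]
        pl = align_to_truth(asm, truth)
        summary = classify_misassemblies(pl, asm)
        assert summary.n_inversions == 1 and summary.n_misassemblies == 1

    def test_small_inconsistency_is_local(self, truth):
        seq = truth[0].seq
        asm = [SequenceRecord("s", seq[:8000] + seq[8500:16_000])]  # 500 bp skip
        pl = align_to_truth(asm, truth)
        summary = classify_misassemblies(pl, asm)
        assert summary.n_local == 1 and summary.n_misassemblies == 0


class TestCorrectedNg50:
    def test_clean_assembly_ratio_one(self, truth):
        asm = list(truth)
        pl = align_to_truth(asm, truth)
        summary = classify_misassemblies(pl, asm)
        corr, ratio = corrected_ng50(asm, summary, sum(len(r.seq) for r in truth))
        assert ratio == 1.0

    def test_chimera_broken_at_midpoint(self, truth):
        half = truth[0].seq[:5000]
        asm = [SequenceRecord("s", half + truth[1].seq[:5000])]
        pl = align_to_truth(asm, truth)
        summary = classify_misassemblies(pl, asm)
        corr, ratio = corrected_ng50(asm, summary, 10_000)
        assert corr == pytest.approx(5000, abs=100)
        assert ratio <= 1.0

    def test_breaking_never_raises_ng50(self, truth):
        seq = truth[0].seq
        asm = [SequenceRecord("s", seq[:8000] + revcomp(seq[8000:16_000]))]
        pl = align_to_truth(asm, truth)
        summary = classify_misassemblies(pl, asm)
        corr, ratio = corrected_ng50(asm, summary, 16_000)
        assert ratio <= 1.0


class TestCompass:
    def test_perfect_assembly(self, truth):
        pl = align_to_truth(list(truth), truth)
        cov, val, mult, pars = compass_metrics(list(truth), truth, pl)
        assert cov == pytest.approx(1.0, abs=0.01)
        assert val == pytest.approx(1.0, abs=0.01)
        assert mult == pytest.approx(1.0, abs=0.01)
        assert pars == pytest.approx(1.0, abs=0.01)

    def test_duplicated_assembly_has_multiplicity_two(self, truth):
        asm = [SequenceRecord("a", truth[0].seq), SequenceRecord("b", truth[0].seq),
               SequenceRecord("c", truth[1].seq), SequenceRecord("d", truth[1].seq)]
        pl = align_to_truth(asm, truth)
        cov, val, mult, _ = compass_metrics(asm, truth, pl)
        assert cov == pytest.approx(1.0, abs=0.01)
        assert mult == pytest.approx(2.0, abs=0.02)
        assert duplication_ratio(pl, truth) == pytest.approx(2.0, abs=0.02)

    def test_random_tail_halves_validity(self, truth):
        chunk = truth[0].seq[:10_000]
        tail = random_genome(10_000, seed=9, id_prefix="x")[0].seq
        asm = [SequenceRecord("s", chunk + tail)]
        pl = align_to_truth(asm, truth)
        _, val, _, pars = compass_metrics(asm, truth, pl)
        assert val == pytest.approx(0.5, abs=0.01)
        assert pars == pytest.approx(2.0, abs=0.05)

    def test_empty_assembly_sentinel(self, truth):
        cov, val, mult, pars = compass_metrics([], truth, {})
        assert (cov, val, mult) == (0.0, 0.0, 0.0)
        assert pars == float("inf")


class TestSmallStats:
    def test_ns_per_100kb_arithmetic(self):
        asm = [SequenceRecord("s", "A" * 999_000 + "N" * 1000)]
        assert ns_per_100kb(asm) == pytest.approx(100.0)

    def test_gene_recovery_full_partial(self, truth):
        genes = [("chr1", 1000, 3000), ("chr1", 20_000, 22_000), ("chr2", 5000, 7000)]
        asm = [SequenceRecord("s", truth[0].seq[:10_000]),
               SequenceRecord("t", truth[0].seq[21_000:21_500])]
        pl = align_to_truth(asm, truth, min_segment=400)
        covered, full, partial = gene_recovery(pl, genes)
        assert full == 1  # gene 1 fully inside scaffold s
        assert partial == 2  # gene 2 touched by t, gene 3 untouched
        assert covered == 1

    def test_indel_rate_zero_for_exact_assembly(self, truth):
        pl = align_to_truth(list(truth), truth)
        assert indels_per_100kb(pl, list(truth)) == 0.0


class TestReapr:
    def _proper_pairs(self, sc_id, length, insert=500, step=50):
        from refguide import AlignmentRecord

        out = []
        for i, pos in enumerate(range(0, length - insert, step)):
            a = AlignmentRecord(f"p{sc_id}{i}", 1, sc_id, pos=pos, cigar=[("M", 100)],
                                mapq=60, proper_pair=True, paired=True, seq="A" * 100)
            b = AlignmentRecord(f"p{sc_id}{i}", 2, sc_id, pos=pos + insert - 100,
                                strand="-", cigar=[("M", 100)], mapq=60,
                                proper_pair=True, paired=True, seq="A" * 100)
            out.extend([a, b])
        return out

    def test_consistent_assembly_scores_one(self):
        asm = [SequenceRecord("s", "A" * 20_000)]
        alns = self._proper_pairs("s", 20_000)
        n_err, score = reapr_like_score(asm, alns, [])
        assert n_err == 0 and score == 1.0

    def test_fragment_coverage_hole_detected_and_score_drops(self):
        asm = [SequenceRecord("s", "A" * 20_000)]
        alns = [a for a in self._proper_pairs("s", 20_000)
                if not (8000 < a.pos < 11_000)]  # no fragments span the middle
        n_err, score = reapr_like_score(asm, alns, [])
        assert n_err >= 1
        assert 0.0 <= score < 0.7

    def test_score_bounded(self):
        asm = [SequenceRecord("s", "A" * 5000)]
        n_err, score = reapr_like_score(asm, [], [])
        assert 0.0 <= score <= 1.0


class TestZScores:
    def test_two_methods_symmetric_z(self):
        vec = {"m1": {"stat": 0.0}, "m2": {"stat": 2.0}}
        table = zscore_rank(vec, orientations={"stat": "higher"})
        assert table.z.loc["m1", "stat"] == pytest.approx(-0.7071, abs=1e-4)
        assert table.z.loc["m2", "stat"] == pytest.approx(0.7071, abs=1e-4)

    def test_constant_column_contributes_zero(self):
        vec = {"m1": {"a": 5.0, "b": 1.0}, "m2": {"a": 5.0, "b": 2.0}}
        table = zscore_rank(vec, orientations={"a": "higher", "b": "higher"})
        assert (table.z["a"] == 0).all()

    def test_lower_is_better_flips_sign(self):
        vec = {"m1": {"s": 0.0}, "m2": {"s": 2.0}}
        hi = zscore_rank(vec, orientations={"s": "higher"})
        lo = zscore_rank(vec, orientations={"s": "lower"})
        assert (hi.z["s"] == -lo.z["s"]).all()

    def test_columns_standardised_and_sums_balance(self, rng):
        vec = {
            f"m{i}": {f"s{j}": float(rng.normal()) for j in range(10)} for i in range(5)
        }
        table = zscore_rank(vec, orientations={f"s{j}": "higher" for j in range(10)})
        assert np.allclose(table.z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(table.z.std(axis=0, ddof=1), 1, atol=1e-9)
        assert table.summed.sum() == pytest.approx(0, abs=1e-9)
        assert (table.loo_min <= table.summed).all()
        assert (table.loo_max >= table.summed).all()

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            zscore_rank({"only": {"s": 1.0}})

    def test_mismatched_stat_sets_rejected(self):
        with pytest.raises(ValueError):
            zscore_rank({"a": {"s": 1.0}, "b": {"t": 1.0}})


class TestWilcoxon:
    def test_maximally_separated_three_vs_three(self):
        assert wilcoxon_one_sided([4, 5, 6], [1, 2, 3]) == pytest.approx(1 / 20)

    def test_identical_samples_near_half(self):
        p = wilcoxon_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert 0.4 <= p <= 0.6

    def test_symmetry_in_continuous_case(self):
        a, b = [1.5, 3.2, 7.1, 0.4], [2.2, 5.5, 8.8, 9.1]
        pab = wilcoxon_one_sided(a, b)
        pba = wilcoxon_one_sided(b, a)
        # exact permutation: P(W >= w) + P(W' >= w') = 1 + P(W == w)
        assert pab + pba >= 1.0
        assert pab + pba <= 1.0 + 5 / 70 + 1e-9

    def test_exact_path_matches_scipy(self, rng):
        for _ in range(10):
            a = rng.normal(size=4).round(3)
            b = rng.normal(size=5).round(3)
            if len(np.unique(np.concatenate([a, b]))) < 9:
                continue
            expected = sstats.mannwhitneyu(a, b, alternative="greater", method="exact").pvalue
            assert wilcoxon_one_sided(a, b) == pytest.approx(expected, abs=1e-9)

    def test_large_sample_uses_normal_approximation(self, rng):
        a = rng.normal(1.0, 1.0, size=30)
        b = rng.normal(0.0, 1.0, size=30)
        p = wilcoxon_one_sided(a, b)
        expected = sstats.mannwhitneyu(a, b, alternative="greater", method="asymptotic").pvalue
        assert p == pytest.approx(expected, rel=1e-6)

    def test_pairwise_matrix_shape(self):
        vec = {"m1": {"a": 1.0, "b": 2.0}, "m2": {"a": 0.0, "b": 1.0}}
        table = zscore_rank(vec, orientations={"a": "higher", "b": "higher"})
        pv = pairwise_wilcoxon(table)
        assert pv.shape == (2, 2)
        assert np.isnan(pv.loc["m1", "m1"])
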
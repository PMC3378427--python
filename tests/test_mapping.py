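"""Contig-reference alignment, completeness calls, read mapping, RPKM."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import oracles
from alloasm import (
    ReferenceHit,
    ReferenceLibrary,
    align_pair,
    best_hit,
    call_complete,
    map_reads,
    mutate_to_identity,
    percent_increase,
    rpkm,
)
from alloasm.dna import random_dna, revcomp


class TestAlignPair:
    def test_identical_sequences(self, rng):
        seq = random_dna(300, rng)
        identity, coverage, interval = align_pair(seq, seq)
        assert identity == 1.0 and coverage == 1.0
        assert interval == (0, 300)

    def test_exact_prefix_gives_forced_coverage(self, rng):
        ref = random_dna(600, rng)
        identity, coverage, interval = align_pair(ref[:570], ref)
        assert identity == 1.0
        assert coverage == pytest.approx(0.95)
        assert interval == (0, 570)

    def test_reverse_complement_query_found(self, rng):
        ref = random_dna(400, rng)
        identity, coverage, _ = align_pair(revcomp(ref[50:350]), ref)
        assert identity == 1.0 and coverage == pytest.approx(300 / 400)

    def test_no_shared_seed_means_no_hit(self):
        assert align_pair("A" * 120, "C" * 300) is None

    @pytest.mark.parametrize("target", [0.85, 0.92, 0.98])
    def test_identity_matches_alignment_oracle(self, rng, target):
        for _ in range(20):
            ref = random_dna(int(rng.integers(150, 300)), rng)
            query = mutate_to_identity(ref, target, rng)
            identity, coverage, _ = align_pair(query, ref)
            expected = oracles.global_alignment_identity(query, ref)
            assert identity == pytest.approx(expected, abs=0.01)
            # divergent bases at the ends may be clipped from the
            # reference interval by the infix alignment
            assert coverage == pytest.approx(1.0, abs=0.03)


class TestBestHit:
    def test_contig_equal_to_reference(self, rng):
        refs = {f"r{i}": random_dna(400, rng) for i in range(5)}
        library = ReferenceLibrary(refs)
        hit = best_hit(refs["r3"], library)
        assert hit.reference_id == "r3"
        assert hit.ref_coverage == 1.0

    def test_longest_hit_wins_over_identity(self, rng):
        core = random_dna(300, rng)
        ref_a = core + random_dna(100, rng)
        ref_b = core[:200] + random_dna(200, rng)
        library = ReferenceLibrary({"refA": ref_a, "refB": ref_b})
        contig = core  # covers 300 bases of refA but only 200 of refB
        hit = best_hit(contig, library)
        assert hit.reference_id == "refA"
        assert hit.aligned_length == 300

    def test_below_identity_floor_is_no_hit(self, rng):
        ref = random_dna(300, rng)
        query = mutate_to_identity(ref, 0.70, rng)
        library = ReferenceLibrary({"r": ref})
        assert best_hit(query, library, min_identity=0.80) is None

    def test_stable_under_library_reordering(self, rng):
        seqs = {f"r{i}": random_dna(350, rng) for i in range(6)}
        contig = mutate_to_identity(seqs["r2"], 0.95, rng)
        hits = [
            best_hit(contig, ReferenceLibrary(dict(items)))
            for items in (seqs.items(), reversed(list(seqs.items())))
        ]
        assert hits[0].reference_id == hits[1].reference_id == "r2"


class TestCallComplete:
    @pytest.mark.parametrize(
        "coverage,expected", [(0.95, True), (0.949, False), (1.0, True)]
    )
    def test_threshold_boundary_inclusive(self, coverage, expected):
        hit = ReferenceHit("c", "ref", 1.0, coverage, (0, 10))
        assert (("ref" in call_complete([hit])) is expected)

    def test_empty_hits_give_empty_set(self):
        assert call_complete([]) == set()


class TestMapReads:
    def test_exact_substring_counts_at_zero(self, rng):
        target = random_dna(400, rng)
        counts = map_reads([target[100:175]], {"t": target}, 3)
        assert [counts.at("t", m) for m in range(4)] == [1, 1, 1, 1]

    def test_two_substitutions_need_two_allowed(self, rng):
        target = random_dna(400, rng)
        read = list(target[50:125])
        for pos in (10, 40):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        counts = map_reads(["".join(read)], {"t": target}, 3)
        assert [counts.at("t", m) for m in range(4)] == [0, 0, 1, 1]

    def test_multi_target_shared_reads_counted_per_target(self, rng):
        a = random_dna(300, rng)
        b = mutate_to_identity(a, 0.99, rng)
        reads = [a[i : i + 75] for i in range(0, 226, 25)]
        counts = map_reads(reads, {"a": a, "b": b}, 3)
        assert counts.at("a", 0) == len(reads)
        assert counts.at("b", 3) >= 1  # homeologue picks up shared reads

    def test_counts_match_exhaustive_hamming_oracle(self, rng):
        targets = {f"t{i}": random_dna(200, rng) for i in range(4)}
        reads = []
        for _ in range(40):
            tid = f"t{int(rng.integers(4))}"
            start = int(rng.integers(0, 120))
            length = int(rng.integers(31, 76))
            read = mutate_to_identity(
                targets[tid][start : start + length], 0.96, rng
            )
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(read)
        counts = map_reads(reads, targets, 3)
        for tid, target in targets.items():
            for m in range(4):
                expected = sum(
                    1
                    for read in reads
                    if (b := oracles.min_hamming_placement(read, target))
                    is not None
                    and b <= m
                )
                assert counts.at(tid, m) == expected

    def test_counts_non_decreasing_in_mismatches(self, rng):
        target = random_dna(500, rng)
        reads = [
            mutate_to_identity(target[i : i + 75], 0.95, rng)
            for i in range(0, 400, 10)
        ]
        counts = map_reads(reads, {"t": target}, 3)
        series = [counts.at("t", m) for m in range(4)]
        assert series == sorted(series)


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "c0,c3,expected",
        [(215_536, 276_132, 28), (1_854, 6_111, 229), (10_937, 12_521, 14),
         (8_903, 9_823, 10), (7, 7, 0)],
    )
    def test_truncated_percent(self, c0, c3, expected):
        assert percent_increase(c0, c3) == expected

    def test_near_integer_ratio_truncates_down(self):
        # 212871/195295 is an 8.9997% increase: truncation yields 8, one
        # below the rounded prose figure
        assert percent_increase(195_295, 212_871) == 8

    def test_zero_baseline_is_undefined(self):
        assert percent_increase(0, 10) is None


class TestRpkm:
    def test_formula(self):
        table = rpkm({"x": 10, "y": 999_990}, {"x": 1000, "y": 500})
        row = table.set_index("gene").loc["x"]
        assert row.RPKM == pytest.approx(10.0)

    def test_zero_count_gene_has_zero_rpkm(self):
        table = rpkm({"x": 0, "y": 50}, {"x": 1000, "y": 500})
        assert table.set_index("gene").loc["x"].RPKM == 0.0

    def test_error_when_nothing_mapped(self):
        with pytest.raises(ValueError):
            rpkm({"x": 0}, {"x": 1000})

    def test_invariant_under_depth_doubling(self):
        counts = {"x": 12, "y": 40, "z": 7}
        lengths = {"x": 900, "y": 1500, "z": 400}
        single = rpkm(counts, lengths)
        double = rpkm({g: 2 * n for g, n in counts.items()}, lengths)
        assert np.allclose(single.RPKM, double.RPKM)

    def test_recovers_true_weights_by_rank(self, rng):
        # 100 genes, skewed weights; read counts drawn from the same
        # multinomial model the simulator uses
        lengths = rng.integers(400, 2000, size=100)
        weights = rng.lognormal(0, 1.5, size=100)
        probs = weights * lengths / np.sum(weights * lengths)
        counts = rng.multinomial(500_000, probs)
        table = rpkm(
            {f"g{i}": int(c) for i, c in enumerate(counts)},
            {f"g{i}": int(l) for i, l in enumerate(lengths)},
        )
        table["true_weight"] = [
            weights[int(g[1:])] for g in table.gene
        ]
        rho = stats.spearmanr(table.RPKM, table.true_weight).statistic
        assert rho > 0.95
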
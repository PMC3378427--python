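"""Simulator: exact identity control, shared windows, read provenance."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import oracles
from alloasm import (
    SimulationConfig,
    SimulationError,
    mutate_to_identity,
    plant_shared_regions,
    simulate_reads,
    simulate_transcriptome,
)
from alloasm.dna import random_dna, revcomp


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestMutateToIdentity:
    def test_identity_one_returns_input(self):
        assert mutate_to_identity("ACGTACGTAC", 1.0, 7) == "ACGTACGTAC"

    def test_forced_substitution_count(self):
        out = mutate_to_identity("A" * 100, 0.90, 3)
        assert hamming(out, "A" * 100) == 10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hamming_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(500, rng)
        out = mutate_to_identity(seq, 0.93, rng)
        assert hamming(out, seq) == 35

    def test_substituted_base_never_equals_original(self, rng):
        # if any substitution re-drew the original base the observed
        # mismatch count would fall short of the exact target
        seq = random_dna(300, rng)
        out = mutate_to_identity(seq, 0.8, rng)
        assert hamming(out, seq) == 60

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mutate_to_identity("", 0.9, 0)

    def test_max_run_caps_identical_runs(self, rng):
        seq = random_dna(800, rng)
        out = mutate_to_identity(seq, 0.90, rng, max_run=39)
        run = best = 0
        for x, y in zip(seq, out):
            run = run + 1 if x == y else 0
            best = max(best, run)
        assert best <= 39
        assert hamming(out, seq) == 80


class TestPlantSharedRegions:
    def test_empty_region_list_is_identity(self, rng):
        a, b = random_dna(300, rng), random_dna(300, rng)
        assert plant_shared_regions(a, b, []) == (a, b)

    def test_full_length_region_copies_everything(self, rng):
        a, b = random_dna(300, rng), random_dna(300, rng)
        _, b2 = plant_shared_regions(a, b, [(0, 300)])
        assert b2 == a

    def test_window_equality_and_identity_increase(self, rng):
        a = random_dna(500, rng)
        b = mutate_to_identity(a, 0.90, rng)
        before = hamming(a, b)
        regions = [(50, 35), (300, 47)]
        a2, b2 = plant_shared_regions(a, b, regions)
        assert a2 == a
        for start, length in regions:
            assert b2[start : start + length] == a[start : start + length]
        assert hamming(a2, b2) < before

    @pytest.mark.parametrize(
        "regions", [[(10, 20), (25, 10)], [(-1, 10)], [(490, 20)]]
    )
    def test_bad_regions_rejected(self, rng, regions):
        a, b = random_dna(500, rng), random_dna(500, rng)
        with pytest.raises(ValueError):
            plant_shared_regions(a, b, regions)


class TestSimulateTranscriptome:
    def test_zero_divergence_pairs_are_identical(self):
        cfg = SimulationConfig(
            n_families=4, homeologue_identity_range=(1.0, 1.0), seed=11
        )
        truth = simulate_transcriptome(cfg)
        for species in ("sp1", "sp2"):
            pairs = truth.homeologue_pairs(species)
            assert len(pairs) == 4
            for a, b in pairs:
                assert a.sequence == b.sequence

    def test_determinism_for_fixed_seed(self):
        cfg = SimulationConfig(n_families=3, seed=5)
        t1 = simulate_transcriptome(cfg)
        t2 = simulate_transcriptome(cfg)
        assert [g.sequence for g in t1.genes] == [g.sequence for g in t2.genes]
        assert [g.expression_weight for g in t1.genes] == [
            g.expression_weight for g in t2.genes
        ]
        assert t1.references == t2.references

    def test_identity_against_alignment_oracle(self):
        cfg = SimulationConfig(
            n_families=3,
            homeologue_identity_range=(0.90, 0.90),
            gene_length_range=(1000, 1000),
            seed=2,
        )
        truth = simulate_transcriptome(cfg)
        for species in ("sp1", "sp2"):
            for a, b in truth.homeologue_pairs(species):
                identity = oracles.global_alignment_identity(a.sequence, b.sequence)
                assert identity == pytest.approx(0.90, abs=0.005)

    def test_orthologue_identity_floor(self):
        cfg = SimulationConfig(n_families=4, seed=8)
        truth = simulate_transcriptome(cfg)
        sp1 = {(g.family_id, g.copy_label): g for g in truth.genes_for("sp1")}
        sp2 = {(g.family_id, g.copy_label): g for g in truth.genes_for("sp2")}
        for key, g1 in sp1.items():
            g2 = sp2[key]
            identity = 1 - hamming(g1.sequence, g2.sequence) / len(g1.sequence)
            assert identity >= cfg.orthologue_identity_min - 1e-9

    def test_shared_windows_identical_and_identity_in_range(self):
        cfg = SimulationConfig(
            n_families=5,
            homeologue_identity_range=(0.90, 0.90),
            shared_window_fraction=1.0,
            shared_windows_per_pair=8,
            gene_length_range=(900, 1100),
            seed=4,
        )
        truth = simulate_transcriptome(cfg)
        for (fam, species), windows in truth.shared_regions.items():
            assert len(windows) == 8
            pair = [
                g for g in truth.genes_for(species) if g.family_id == fam
            ]
            a = next(g for g in pair if g.copy_label == "A")
            b = next(g for g in pair if g.copy_label == "B")
            for start, length in windows:
                assert 35 <= length <= 47
                assert (
                    a.sequence[start : start + length]
                    == b.sequence[start : start + length]
                )
            identity = 1 - hamming(a.sequence, b.sequence) / len(a.sequence)
            assert identity == pytest.approx(0.90, abs=0.005)

    def test_unreachable_identity_raises(self):
        cfg = SimulationConfig(
            n_families=1,
            homeologue_identity_range=(0.05, 0.05),
            shared_window_fraction=1.0,
            shared_windows_per_pair=8,
            gene_length_range=(400, 400),
            seed=0,
        )
        with pytest.raises(SimulationError):
            simulate_transcriptome(cfg)


class TestSimulateReads:
    def test_zero_error_reads_match_truth_coordinates(self):
        cfg = SimulationConfig(
            n_families=3, n_reads=500, pre_knee_error=0.0,
            post_knee_error=0.0, seed=21,
        )
        truth = simulate_transcriptome(cfg)
        sim = simulate_reads(truth, cfg)
        by_id = {r.read_id: r for r in sim.readset}
        assert len(by_id) == 500
        for row in sim.truth_table.itertuples():
            gene = truth.gene(row.gene_id)
            frag = gene.sequence[row.start : row.end]
            if row.strand == "-":
                frag = revcomp(frag)
            assert by_id[row.read_id].sequence == frag

    def test_source_counts_follow_expression_weights(self):
        cfg = SimulationConfig(
            n_families=2,
            homeologue_identity_range=(1.0, 1.0),
            singleton_fraction=1.0,
            gene_length_range=(600, 600),
            n_reads=10_000,
            high_expression_fraction=0.0,
            seed=13,
        )
        truth = simulate_transcriptome(cfg)
        g1, g2 = truth.genes_for("sp1")
        g1.expression_weight, g2.expression_weight = 9.0, 1.0
        sim = simulate_reads(truth, cfg)
        counts = sim.truth_table.gene_id.value_counts()
        # 99% binomial bounds around p = 0.9 of 10,000 draws
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.9)
        assert lo <= counts[g1.gene_id] <= hi

    def test_post_knee_error_rate_matches_config(self):
        cfg = SimulationConfig(
            n_families=2, n_reads=2000, pre_knee_error=0.0,
            post_knee_error=0.1, error_knee_se=45, seed=17,
        )
        truth = simulate_transcriptome(cfg)
        sim = simulate_reads(truth, cfg)
        by_id = {r.read_id: r for r in sim.readset}
        mismatches = bases = 0
        for row in sim.truth_table.itertuples():
            gene = truth.gene(row.gene_id)
            frag = gene.sequence[row.start : row.end]
            if row.strand == "-":
                frag = revcomp(frag)
            seq = by_id[row.read_id].sequence
            assert seq[:45] == frag[:45]  # error-free before the knee
            mismatches += sum(x != y for x, y in zip(seq[45:], frag[45:]))
            bases += len(seq) - 45
        assert mismatches / bases == pytest.approx(0.1, abs=0.01)

    def test_qualities_reflect_error_profile(self):
        cfg = SimulationConfig(n_families=2, n_reads=10, seed=3)
        truth = simulate_transcriptome(cfg)
        read = simulate_reads(truth, cfg).readset.single[0]
        # Q27 ~ 0.002 before the single-end knee at cycle 60, Q17 ~ 0.02 after
        assert read.qualities[:60] == [27] * 60
        assert read.qualities[60:] == [17] * 15

    def test_empty_readset_for_zero_reads(self):
        cfg = SimulationConfig(n_families=2, n_reads=0, seed=3)
        truth = simulate_transcriptome(cfg)
        sim = simulate_reads(truth, cfg)
        assert sim.readset.n_reads == 0
        assert len(sim.truth_table) == 0

    def test_fastq_output_deterministic(self, tmp_path):
        from alloasm.simulate import write_simulation

        cfg = SimulationConfig(
            n_families=2, n_reads=200, paired_fraction=0.5, seed=9
        )
        payloads = []
        for sub in ("a", "b"):
            truth = simulate_transcriptome(cfg)
            sim = simulate_reads(truth, cfg)
            outdir = tmp_path / sub
            write_simulation(truth, sim, outdir)
            payloads.append(
                {p.name: p.read_bytes() for p in sorted(outdir.iterdir())}
            )
        assert payloads[0] == payloads[1]
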
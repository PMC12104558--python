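"""Synthetic-data generator: planted structure, determinism, calibration."""

import numpy as np
import pytest

from ytrace.rearrange import bfs_distance_oracle, format_arrangement, parse_arrangement
from ytrace.syndata import (
    BasdSpec,
    InsertionSpec,
    SimConfig,
    emit_sequences,
    plant_basd_genome,
    simulate_karyotypes,
    simulate_locus_history,
    simulate_snp_track,
    mutate,
    random_dna,
)


class TestKaryotypes:
    def test_default_counts_match_study_design(self):
        genomes, truth = simulate_karyotypes(SimConfig(seed=0))
        # 24 ancestral chromosomes; 11 / 1 / 2 fusions
        assert len(genomes["osimensis"]) == 24 - 11 == 13
        assert len(genomes["tokunoshimensis"]) == 23
        assert len(genomes["muenninki"]) == 22

    def test_zero_fusions_identity(self):
        cfg = SimConfig(seed=0, fusion_plan={"sp": []})
        genomes, _ = simulate_karyotypes(cfg)
        assert len(genomes["sp"]) == 24
        assert all(len(segs) == 1 for segs in genomes["sp"].values())

    def test_consumed_chromosome_rejected(self):
        with pytest.raises(ValueError, match="consumed"):
            SimConfig(seed=0, fusion_plan={"sp": [("A", "B"), ("B", "C")]})

    def test_block_content_conserved(self):
        genomes, truth = simulate_karyotypes(SimConfig(seed=1))
        for sp, chroms in genomes.items():
            content = sorted(a for segs in chroms.values() for a, _ in segs)
            assert content == sorted(truth.anc_lengths)


class TestLocusHistory:
    def test_stated_insertion_layout(self):
        cfg = SimConfig(seed=0, inversions_per_lineage=0,
                        insertion_spec=InsertionSpec(("SB1", "SB2"), "SB6- SB5-"))
        _, truth = simulate_locus_history(cfg)
        assert format_arrangement(truth.ancestor_arrangement) == \
            "SB1+ SB6- SB5- SB2+ SB3+ SB4+"

    def test_zero_everything_unchanged(self):
        cfg = SimConfig(seed=0, inversions_per_lineage=0)
        arrangements, truth = simulate_locus_history(cfg)
        for arr in arrangements.values():
            assert arr == truth.ancestor_arrangement

    def test_distance_bounded_by_applied_inversions(self):
        for seed in range(5):
            cfg = SimConfig(seed=seed, inversions_per_lineage=2)
            arrangements, truth = simulate_locus_history(cfg)
            for sp, arr in arrangements.items():
                d = bfs_distance_oracle(truth.ancestor_arrangement, arr)
                assert d <= len(truth.applied_inversions[sp]) == 2

    def test_blocks_conserved_under_inversions(self):
        cfg = SimConfig(seed=3, inversions_per_lineage=5)
        arrangements, truth = simulate_locus_history(cfg)
        anc_ids = sorted(b.id for b in truth.ancestor_arrangement)
        for arr in arrangements.values():
            assert sorted(b.id for b in arr) == anc_ids


class TestPlantedBasd:
    def test_identity_one_copies_identical(self, rng):
        genome, master, copies = plant_basd_genome(rng, 2, identity=1.0)
        seqs = [genome.seq[s:e] for s, e in copies]
        assert seqs[0] == seqs[1] == master

    def test_pairwise_identity_within_binomial_band(self, rng_factory):
        # identity 0.98, 6 kb copies: mean pairwise 0.98, 3 sigma ~ 0.006
        for seed in range(5):
            rng = rng_factory(seed)
            genome, _, copies = plant_basd_genome(rng, 3, identity=0.98)
            seqs = [genome.seq[s:e] for s, e in copies]
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    ident = sum(a == b for a, b in zip(seqs[i], seqs[j])) / 6000
                    assert 0.965 <= ident <= 0.995

    def test_copies_disjoint_and_inside_genome(self, rng):
        genome, _, copies = plant_basd_genome(rng, 6, genome_len=200_000)
        assert all(0 <= s < e <= genome.length for s, e in copies)
        for (s1, e1), (s2, e2) in zip(copies, copies[1:]):
            assert s2 > e1 + 3000  # separated beyond the merge gap

    def test_identity_validation(self):
        with pytest.raises(ValueError):
            BasdSpec(identity=0.85)


class TestRepeatTruth:
    def test_configured_copy_count_listed(self, rng):
        from ytrace.syndata import plant_repeat_array

        _, _, intervals = plant_repeat_array(rng, n_copies=52)
        assert len(intervals) == 52


class TestSnpTrack:
    def test_zero_par_rate_no_variants_before_boundary(self):
        cfg = SimConfig(seed=0)
        cfg.snp_spec.par_rate_per_kb = 0.0
        recs, truth = simulate_snp_track(cfg)
        assert all(r.pos - 1 >= truth.par_boundary_bp for r in recs)

    def test_poisson_counts_within_3_sigma(self):
        cfg = SimConfig(seed=2)
        cfg.snp_spec.par_rate_per_kb = 0.1
        cfg.snp_spec.stratum_rate_per_kb = 5.0
        cfg.snp_spec.boundary_bp = 5_000_000
        cfg.snp_spec.chrom_len = 10_000_000
        cfg.snp_spec.bad_fraction = 0.0
        recs, _ = simulate_snp_track(cfg)
        n_par = sum(1 for r in recs if r.pos - 1 < 5_000_000)
        n_str = len(recs) - n_par
        assert abs(n_par - 500) <= 3 * np.sqrt(500)
        assert abs(n_str - 25_000) <= 3 * np.sqrt(25_000)

    def test_seeded_vcf_bytes_identical(self, tmp_path):
        from ytrace.syndata import write_snp_vcf

        out = []
        for name in ("a.vcf", "b.vcf"):
            recs, _ = simulate_snp_track(SimConfig(seed=9))
            p = tmp_path / name
            write_snp_vcf(recs, p, {"X": 10_000_000})
            out.append(p.read_bytes())
        assert out[0] == out[1]


class TestDeterminism:
    def test_emit_sequences_byte_identical(self, tmp_path):
        t1 = emit_sequences(SimConfig(seed=5), tmp_path / "r1")
        t2 = emit_sequences(SimConfig(seed=5), tmp_path / "r2")
        for f in sorted((tmp_path / "r1").iterdir()):
            assert f.read_bytes() == (tmp_path / "r2" / f.name).read_bytes()
        assert t1.basd_intervals == t2.basd_intervals


class TestMutate:
    def test_rate_zero_identity(self, rng):
        seq = random_dna(rng, 500)
        assert mutate(rng, seq, 0.0) == seq

    def test_substitutions_always_change_base(self, rng):
        seq = random_dna(rng, 2000)
        mut = mutate(rng, seq, 0.1)
        n_diff = sum(a != b for a, b in zip(seq, mut))
        assert len(mut) == len(seq)
        assert abs(n_diff - 200) <= 3 * np.sqrt(200 * 0.9)
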
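"""Iterative segmental-duplication detection, flank provenance and the
circular-intermediate rule."""

import numpy as np
import pytest

from ytrace.basd import (
    BasdCopy,
    FlankAssignment,
    assign_flanks,
    cluster_by_identity,
    count_by_region,
    filter_hits_by_length,
    infer_mechanism,
    iterate_basd_detection,
    merge_split_hits,
)
from ytrace.io_formats import AlignmentHit, GenomeSequence
from ytrace.syndata import (
    SimConfig,
    mutate,
    plant_basd_genome,
    plant_insertion_locus,
    random_dna,
)


def _hit(ts, te, q="q", t="t", strand="+"):
    return AlignmentHit(q, 0, te - ts, t, ts, te, strand,
                        matches=te - ts, block_len=te - ts)


class TestHitRules:
    def test_length_filter_boundary(self):
        hits = [_hit(0, 400), _hit(0, 500), _hit(0, 600)]
        kept = filter_hits_by_length(hits)
        assert [h.target_span for h in kept] == [500, 600]

    def test_length_filter_empty(self):
        assert filter_hits_by_length([]) == []

    def test_merge_within_gap(self):
        cand = merge_split_hits([_hit(0, 2000), _hit(4500, 7000)])
        assert cand == [("t", 0, 7000)]

    def test_no_merge_beyond_gap(self):
        cand = merge_split_hits([_hit(0, 2000), _hit(5500, 7000)])
        assert cand == []  # neither span reaches 3000

    def test_opposite_strands_not_merged(self):
        cand = merge_split_hits([_hit(0, 2000), _hit(1000, 3500, strand="-")])
        assert cand == []


class TestIterativeDetection:
    def test_planted_copies_recovered_exactly(self, rng_factory):
        rng = rng_factory(0)
        genome, master, copies = plant_basd_genome(rng, 4, copy_len=6000,
                                                   identity=0.98)
        det = iterate_basd_detection(genome, [master], name_prefix="To-BASD")
        assert len(det) == 4
        for d, (s, e) in zip(det, copies):
            assert abs(d.start - s) < 100 and abs(d.end - e) < 100
        assert [d.name for d in det] == [f"To-BASD{i:03d}" for i in range(1, 5)]

    def test_null_genome_zero_detections(self, rng_factory):
        rng = rng_factory(1)
        genome = GenomeSequence("null", random_dna(rng, 150_000))
        assert iterate_basd_detection(genome, [random_dna(rng, 6000)]) == []

    def test_sub_final_length_copy_excluded(self, rng_factory):
        genome, master, _ = plant_basd_genome(rng_factory(2), 1, copy_len=4500,
                                              identity=0.99, genome_len=100_000)
        assert iterate_basd_detection(genome, [master]) == []

    def test_final_copies_satisfy_sd_criterion(self, rng_factory):
        genome, master, _ = plant_basd_genome(rng_factory(3), 3, identity=0.96)
        for c in iterate_basd_detection(genome, [master]):
            assert c.length >= 5000
            assert c.identity_to_seed >= 0.9

    def test_threshold_monotonicity(self, rng_factory):
        genome, master, _ = plant_basd_genome(rng_factory(4), 4, identity=0.97)
        n_by_final = [
            len(iterate_basd_detection(genome, [master], min_final_len=m))
            for m in (5000, 6500, 8000)
        ]
        assert n_by_final == sorted(n_by_final, reverse=True)

    def test_idempotent_on_own_output(self, rng_factory):
        genome, master, _ = plant_basd_genome(rng_factory(5), 3, identity=0.97)
        det1 = iterate_basd_detection(genome, [master])
        seeds2 = [genome.seq[c.start:c.end] for c in det1]
        det2 = iterate_basd_detection(genome, seeds2)
        assert [(c.start, c.end) for c in det1] == [(c.start, c.end) for c in det2]


class TestRegionTable:
    REGIONS = [("c", 0, 1000, "r1"), ("c", 1000, 2000, "r2")]

    def _copy(self, s, e, name="x"):
        return BasdCopy("c", s, e, 0.99, 1, name)

    def test_counts(self):
        copies = [self._copy(0, 100), self._copy(200, 300), self._copy(400, 500)]
        assert count_by_region(copies, self.REGIONS)["r1"] == 3

    def test_midpoint_assignment_for_straddler(self):
        c = self._copy(900, 1300)  # midpoint 1100 -> r2
        assert count_by_region([c], self.REGIONS)["r2"] == 1

    def test_empty_all_zero(self):
        counts = count_by_region([], self.REGIONS)
        assert counts == {"r1": 0, "r2": 0, "unassigned": 0}

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            count_by_region([], [("c", 0, 1000, "a"), ("c", 500, 1500, "b")])

    def test_outside_counts_unassigned(self):
        assert count_by_region([self._copy(5000, 5100)], self.REGIONS)["unassigned"] == 1


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    locus, master, flanks, truth = plant_insertion_locus(rng)
    copies = iterate_basd_detection(locus, [master], name_prefix="BASD")
    return locus, flanks, copies, truth


class TestFlanksAndMechanism:
    def test_split_flank_signature_recovered(self, planted):
        locus, flanks, copies, truth = planted
        assert len(copies) == 2
        fa = assign_flanks(copies, locus, flanks)
        assert (fa[0].upstream, fa[0].downstream) == (None, "2g")
        assert (fa[1].upstream, fa[1].downstream) == ("2a", None)

    def test_circular_intermediate_called(self, planted):
        locus, flanks, copies, _ = planted
        fa = assign_flanks(copies, locus, flanks)
        assert infer_mechanism(fa).call == "circular-intermediate"

    def test_direct_insertion_is_the_complement(self):
        fa = [FlankAssignment("L", "2a", None, 900, 0),
              FlankAssignment("R", None, "2g", 0, 900)]
        assert infer_mechanism(fa).call == "direct-insertion"

    def test_unassigned_boundary_undetermined(self):
        fa = [FlankAssignment("L", None, None), FlankAssignment("R", "2a", None)]
        assert infer_mechanism(fa).call == "undetermined"

    def test_wrong_copy_count_undetermined(self):
        call = infer_mechanism([FlankAssignment("L", None, "2g")])
        assert call.call == "undetermined" and "expected 2" in call.note


class TestClustering:
    def test_identical_copies_one_cluster(self, rng):
        seq = random_dna(rng, 6000)
        genome = GenomeSequence("c", seq + random_dna(rng, 5000) + seq)
        copies = [BasdCopy("c", 0, 6000, 1.0, 1, "a"),
                  BasdCopy("c", 11000, 17000, 1.0, 1, "b")]
        labels = cluster_by_identity(copies, genome)
        assert labels["a"] == labels["b"]

    def test_distinct_masters_two_clusters(self, rng):
        m1 = random_dna(rng, 6000)
        m2 = mutate(rng, m1, 0.15)  # ~85 % cross-identity
        genome = GenomeSequence("c", m1 + random_dna(rng, 5000) + m2)
        copies = [BasdCopy("c", 0, 6000, 1.0, 1, "a"),
                  BasdCopy("c", 11000, 17000, 1.0, 1, "b")]
        labels = cluster_by_identity(copies, genome, linkage_threshold=0.95)
        assert labels["a"] != labels["b"]

    def test_planting_lineage_recovered(self, rng):
        anc = random_dna(rng, 6000)
        yder = mutate(rng, anc, 0.15)
        pieces, copies, names = [], [], []
        pos = 0
        for i, (master, tag) in enumerate(
                [(anc, "anc"), (anc, "anc"), (yder, "y"), (yder, "y")]):
            pieces.append(mutate(rng, master, 0.01))
            copies.append(BasdCopy("c", pos, pos + 6000, 0.99, 1, f"{tag}{i}"))
            pos += 6000
            pieces.append(random_dna(rng, 4000))
            pos += 4000
        genome = GenomeSequence("c", "".join(pieces))
        labels = cluster_by_identity(copies, genome, linkage_threshold=0.95)
        assert labels["anc0"] == labels["anc1"]
        assert labels["y2"] == labels["y3"]
        assert labels["anc0"] != labels["y2"]

    def test_fewer_than_two_copies_rejected(self, rng):
        genome = GenomeSequence("c", random_dna(rng, 1000))
        with pytest.raises(ValueError):
            cluster_by_identity([BasdCopy("c", 0, 100, 1.0, 1, "a")], genome)
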
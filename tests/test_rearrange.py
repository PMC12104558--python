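"""Signed inversion distance and insertion-scenario parsimony."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from ytrace.rearrange import (
    SignedBlock,
    apply_inversion,
    bfs_all_distances,
    bfs_distance_oracle,
    breakpoint_count,
    enumerate_ancestral_configs,
    format_arrangement,
    hp_distance,
    inversion_distance,
    load_xq_arrangements,
    parse_arrangement,
    score_scenarios,
    sorting_scenario,
)


def arr_from_perm(perm):
    """Signed permutation -> arrangement against the identity labels."""
    return tuple(SignedBlock(f"B{abs(v)}", "+" if v > 0 else "-") for v in perm)


def identity_arr(n):
    return tuple(SignedBlock(f"B{i}", "+") for i in range(1, n + 1))


class TestInversionDistance:
    def test_equal_arrangements_zero(self):
        a = parse_arrangement("SB1+ SB2- SB3+")
        assert inversion_distance(a, a) == 0

    def test_whole_segment_reversal_is_one(self):
        a = parse_arrangement("B2- B1-")
        b = parse_arrangement("B1+ B2+")
        assert inversion_distance(a, b) == 1

    def test_transposed_pair_matches_oracle(self):
        a = parse_arrangement("B2+ B1+")
        b = parse_arrangement("B1+ B2+")
        assert inversion_distance(a, b) == bfs_distance_oracle(a, b) == 3

    def test_block_set_mismatch_lists_difference(self):
        a = parse_arrangement("B1+ B2+")
        b = parse_arrangement("B1+ B3+")
        with pytest.raises(ValueError, match="B2.*B3|B3.*B2"):
            inversion_distance(a, b)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_exhaustive_vs_oracle_small_n(self, n):
        dist = bfs_all_distances(n)
        assert all(hp_distance(p) == d for p, d in dist.items())

    def test_metric_axioms_sampled(self):
        rnd = random.Random(7)
        n = 6
        perms = list(bfs_all_distances(4))  # reuse small enumeration for speed

        def rand_arr():
            vals = list(range(1, n + 1))
            rnd.shuffle(vals)
            return arr_from_perm([v if rnd.random() < 0.5 else -v for v in vals])

        for _ in range(30):
            a, b, c = rand_arr(), rand_arr(), rand_arr()
            assert inversion_distance(a, a) == 0
            assert inversion_distance(a, b) == inversion_distance(b, a)
            assert inversion_distance(a, c) <= (
                inversion_distance(a, b) + inversion_distance(b, c)
            )
            assert inversion_distance(a, b) >= breakpoint_count(a, b) / 2

    @settings(max_examples=200, derandomize=True)
    @given(st.permutations(range(1, 6)), st.lists(st.booleans(), min_size=5, max_size=5))
    def test_property_matches_oracle(self, vals, signs):
        perm = tuple(v if s else -v for v, s in zip(vals, signs))
        assert hp_distance(perm) == bfs_all_distances(5)[perm]


class TestSortingScenario:
    def test_identity_empty(self):
        a = parse_arrangement("B1+ B2+")
        assert sorting_scenario(a, a) == []

    def test_single_reversal(self):
        a = parse_arrangement("B2- B1-")
        b = parse_arrangement("B1+ B2+")
        assert sorting_scenario(a, b) == [(0, 1)]

    def test_random_pairs_reach_target_optimally(self):
        rnd = random.Random(11)
        b = identity_arr(6)
        for _ in range(10):
            vals = list(range(1, 7))
            rnd.shuffle(vals)
            a = arr_from_perm([v if rnd.random() < 0.5 else -v for v in vals])
            steps = sorting_scenario(a, b)
            assert len(steps) == bfs_distance_oracle(a, b)
            cur = a
            for i, j in steps:
                cur = apply_inversion(cur, i, j)
            assert cur == b


class TestEnumerate:
    def test_default_yields_24(self):
        configs = enumerate_ancestral_configs()
        assert len(configs) == 24
        assert len({c.arrangement for c in configs}) == 24

    def test_single_inserted_block_three_loci(self):
        assert len(enumerate_ancestral_configs(inserted=("SB5",))) == 6

    def test_one_locus_eight_arrangements(self):
        configs = enumerate_ancestral_configs(loci=[("SB1", "SB2")])
        assert len(configs) == 8
        assert all(c.locus == ("SB1", "SB2") for c in configs)

    def test_deterministic_order(self):
        a = [c.name for c in enumerate_ancestral_configs()]
        b = [c.name for c in enumerate_ancestral_configs()]
        assert a == b

    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            enumerate_ancestral_configs(inserted=("SB1",))


class TestScoreScenarios:
    def test_extant_equal_to_config_scores_zero(self):
        configs = enumerate_ancestral_configs()
        extant = {"sp": configs[0].arrangement}
        table = score_scenarios(configs, extant, exclude_ids=())
        assert table.table.loc[0, "d_sp"] == 0

    def test_block_set_mismatch_raises(self):
        configs = enumerate_ancestral_configs()
        with pytest.raises(ValueError, match="symmetric difference"):
            score_scenarios(configs, {"sp": parse_arrangement("SB1+ SB2+")},
                            exclude_ids=())

    def test_totals_invariant_under_relabeling(self):
        configs = enumerate_ancestral_configs()
        extant = load_xq_arrangements()
        t1 = score_scenarios(configs, extant)

        def relabel(arr):
            return tuple(SignedBlock("X" + b.id, b.sign) for b in arr)

        configs2 = enumerate_ancestral_configs(
            base=relabel(parse_arrangement("SB1+ SB2+ SB3+ SB4+")),
            inserted=("XSB5", "XSB6"),
        )
        extant2 = {sp: relabel(a) for sp, a in extant.items()}
        t2 = score_scenarios(configs2, extant2, exclude_ids={"XSB5p"})
        assert sorted(t1.table["total"]) == sorted(t2.table["total"])

    def test_shipped_fixture_two_scenarios_between_sb1_sb2(self):
        extant = load_xq_arrangements()
        assert {b.id for b in extant["osimensis"]} == {
            "SB1", "SB2", "SB3", "SB4", "SB5", "SB6", "SB5p"}
        table = score_scenarios(enumerate_ancestral_configs(), extant)
        minimal = table.minimal_configs
        assert len(minimal) == 2
        assert all(c.locus == ("SB1", "SB2") for c in minimal)
        assert table.min_total == 4


class TestLocusHistoryRecovery:
    """The true insertion locus is among the minimal-set configurations for
    simulated histories with few inversions per lineage."""

    def test_simulated_histories_recover_locus(self, rng_factory):
        from ytrace.syndata import SimConfig, simulate_locus_history

        hits = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, inversions_per_lineage=2)
            arrangements, truth = simulate_locus_history(cfg)
            table = score_scenarios(
                enumerate_ancestral_configs(), arrangements, exclude_ids=())
            loci = {c.locus for c in table.minimal_configs}
            if ("SB1", "SB2") in loci:
                hits += 1
        assert hits == 10
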
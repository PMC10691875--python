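"""Stochastic block model: DL behaviour, recovery, community profiling."""

import numpy as np
import pandas as pd
import pytest

import fluencygraph as fg
from fluencygraph import (BlockPartition, assignment_dl, community_contrasts,
                          compare_partitions, fit_sbm, profile_communities,
                          quantile_bin_weights)
from fluencygraph.embedding import SimilarityGraph
from fluencygraph.cohort import Participant
from fluencygraph.scoring import Transcript

from _oracles import oracle_mannwhitney_u


def planted_graph(rng, sizes=(30, 30, 30), within=0.9, between=0.1, noise=0.05):
    n = sum(sizes)
    truth = np.repeat(np.arange(len(sizes)), sizes)
    W = np.where(truth[:, None] == truth[None, :], within, between)
    W = W + rng.normal(0, noise, (n, n))
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return SimilarityGraph([f"p{i}" for i in range(n)], W), truth


class TestBinning:
    def test_binary_weights_map_to_extremes(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        M = quantile_bin_weights(W, Q=8)
        assert M[0, 1] > 0 and M[0, 2] == 0
        assert np.array_equal(M, M.T)

    def test_multiplicities_bounded_by_q(self, rng):
        W = rng.uniform(-1, 1, (20, 20))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        M = quantile_bin_weights(W, Q=8)
        assert M.max() <= 7 and M.min() >= 0


class TestFitSbm:
    def test_disconnected_cliques_recovered(self):
        n = 20
        W = np.zeros((n, n))
        for off in (0, 10):
            blk = slice(off, off + 10)
            W[blk, blk] = 1.0
        np.fill_diagonal(W, 0.0)
        G = SimilarityGraph([f"p{i}" for i in range(n)], W)
        part = fit_sbm(G, max_blocks=10, n_sweeps=5, seed=0, hierarchy=False)
        assert part.n_blocks == 2
        truth = BlockPartition(G.participant_ids, np.repeat([0, 1], 10), 2, 1.0)
        assert compare_partitions(part, truth) == pytest.approx(1.0)

    def test_planted_partition_recovery(self, rng):
        G, truth = planted_graph(rng)
        part = fit_sbm(G, max_blocks=15, n_sweeps=5, seed=1, hierarchy=False)
        tp = BlockPartition(G.participant_ids, truth, 3, 1.0)
        assert compare_partitions(part, tp) >= 0.9

    def test_deterministic_under_seed(self, rng):
        G, _ = planted_graph(rng, sizes=(15, 15))
        a = fit_sbm(G, max_blocks=10, n_sweeps=3, seed=4)
        b = fit_sbm(G, max_blocks=10, n_sweeps=3, seed=4)
        assert np.array_equal(a.assignment, b.assignment)
        assert a.description_length == b.description_length

    def test_small_graph_rejected(self):
        W = np.zeros((3, 3))
        G = SimilarityGraph(["a", "b", "c"], W)
        with pytest.raises(ValueError):
            fit_sbm(G)

    def test_dl_beats_trivial_partitions(self, rng):
        G, truth = planted_graph(rng, sizes=(20, 20))
        part = fit_sbm(G, max_blocks=10, n_sweeps=5, seed=2, hierarchy=False)
        n = G.n
        assert part.description_length <= assignment_dl(G, np.arange(n)) + 1e-9
        assert part.description_length <= assignment_dl(G, np.zeros(n, int)) + 1e-9

    def test_dl_invariant_to_node_relabelling(self, rng):
        G, truth = planted_graph(rng, sizes=(10, 10))
        perm = rng.permutation(G.n)
        G2 = SimilarityGraph([G.participant_ids[i] for i in perm],
                             G.weights[np.ix_(perm, perm)])
        assert assignment_dl(G, truth) == pytest.approx(
            assignment_dl(G2, truth[perm]), rel=1e-10)

    def test_hierarchy_levels_nest(self, rng):
        # two macro-groups of three micro-blocks each
        G, _ = planted_graph(rng, sizes=(12,) * 6, within=0.9, between=0.1)
        W = G.weights.copy()
        for a in range(3):      # strengthen ties inside the first macro-group
            for b in range(3):
                if a != b:
                    W[a * 12:(a + 1) * 12, b * 12:(b + 1) * 12] += 0.4
        W = np.clip((W + W.T) / 2, -1, 1)
        np.fill_diagonal(W, 0)
        G = SimilarityGraph(G.participant_ids, W)
        part = fit_sbm(G, max_blocks=12, n_sweeps=5, seed=0, hierarchy=True)
        if part.hierarchy:  # validated by the BlockPartition invariant
            assert len(np.unique(part.hierarchy[0])) < part.n_blocks


class TestComparePartitions:
    def test_identity_and_relabelling(self):
        ids = [f"p{i}" for i in range(12)]
        a = BlockPartition(ids, np.repeat([0, 1, 2], 4), 3, 1.0)
        b = BlockPartition(ids, np.repeat([2, 0, 1], 4), 3, 1.0)
        assert compare_partitions(a, a) == 1.0
        assert compare_partitions(a, b) == 1.0

    def test_random_partition_near_zero(self, rng):
        ids = [f"p{i}" for i in range(90)]
        a = BlockPartition(ids, np.repeat([0, 1, 2], 30), 3, 1.0)
        vals = []
        for _ in range(100):
            vals.append(compare_partitions(
                a, BlockPartition(ids, rng.permutation(a.assignment), 3, 1.0)))
        assert abs(np.mean(vals)) <= 0.1

    def test_mismatched_sets_rejected(self):
        a = BlockPartition(["a", "b", "c", "d"], np.zeros(4, int), 1, 1.0)
        b = BlockPartition(["a", "b", "c", "e"], np.zeros(4, int), 1, 1.0)
        with pytest.raises(ValueError):
            compare_partitions(a, b)


class TestCommunityProfiles:
    def _setup(self):
        parts = [Participant(f"p{i}", "HC", 50 + i, 100 + i, "female")
                 for i in range(4)]
        trans = [Transcript("p0", ["sun", "sea"]), Transcript("p1", ["sun", "sky"]),
                 Transcript("p2", ["salt", "sand"]), Transcript("p3", ["salt", "sip"])]
        part = BlockPartition([p.participant_id for p in parts],
                              np.array([0, 0, 1, 1]), 2, 1.0)
        return part, parts, trans

    def test_ubiquitous_term_scores_zero(self):
        part, parts, trans = self._setup()
        trans[2].tokens[0] = "sun"  # now "sun" appears in both communities
        profiles = profile_communities(part, parts, trans)
        for prof in profiles:
            scores = dict(prof.top_words)
            if "sun" in scores:
                assert scores["sun"] == pytest.approx(0.0)

    def test_unique_term_idf(self):
        part, parts, trans = self._setup()
        profiles = profile_communities(part, parts, trans)
        scores = dict(profiles[0].top_words)
        # "sun" occurs twice in community 0's 4-token document, nowhere else
        assert scores["sun"] == pytest.approx((2 / 4) * np.log(2))

    def test_hand_computed_ranking(self):
        part, parts, trans = self._setup()
        profiles = profile_communities(part, parts, trans)
        assert profiles[1].top_words[0][0] == "salt"
        assert profiles[1].top_words[0][1] == pytest.approx((2 / 4) * np.log(2))
        assert profiles[0].pct_by_group["HC"] == 100.0
        assert profiles[0].n == 2

    def test_group_percentages_sum_to_100(self, small_cohort, rng):
        parts, trans = small_cohort
        ids = [p.participant_id for p in parts]
        assignment = rng.integers(0, 3, len(ids))
        part = BlockPartition(ids, assignment, 3, 1.0)
        for prof in profile_communities(part, parts, trans):
            assert sum(prof.pct_by_group.values()) == pytest.approx(100.0)


class TestCommunityContrasts:
    def test_identical_samples_null_u(self, rng):
        ids = [f"p{i}" for i in range(16)]
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 4)
        parts = [Participant(i, "HC", 50.0, 100.0, "x") for i in ids]
        part = BlockPartition(ids, np.repeat([0, 1], 8), 2, 1.0)
        table = community_contrasts(
            part, parts, pd.DataFrame({"v": vals}, index=ids))
        row = table[(table.community == 0) & (table.variable == "v")].iloc[0]
        assert row.statistic == pytest.approx(8 * 8 / 2)
        assert row.p > 0.9

    def test_extreme_separation_minimal_p(self):
        ids = [f"p{i}" for i in range(16)]
        vals = np.concatenate([np.arange(8) + 100.0, np.arange(8)])
        parts = [Participant(i, "HC", 50.0, 100.0, "x") for i in ids]
        part = BlockPartition(ids, np.repeat([0, 1], 8), 2, 1.0)
        table = community_contrasts(
            part, parts, pd.DataFrame({"v": vals}, index=ids))
        row = table[(table.community == 0) & (table.variable == "v")].iloc[0]
        assert row.statistic == pytest.approx(64.0)
        assert row.p < 1e-3

    def test_u_matches_bruteforce_count(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        ids = [f"p{i}" for i in range(16)]
        parts = [Participant(i, "HC", 50.0, 100.0, "x") for i in ids]
        part = BlockPartition(ids, np.repeat([0, 1], 8), 2, 1.0)
        table = community_contrasts(
            part, parts, pd.DataFrame({"v": np.concatenate([x, y])}, index=ids))
        row = table[(table.community == 0) & (table.variable == "v")].iloc[0]
        assert row.statistic == pytest.approx(oracle_mannwhitney_u(x, y))

    def test_default_threshold_is_alpha_over_40(self, rng):
        ids = [f"p{i}" for i in range(16)]
        parts = [Participant(i, "HC", float(rng.normal(50, 5)),
                             float(rng.normal(100, 5)), "x") for i in ids]
        part = BlockPartition(ids, np.repeat([0, 1], 8), 2, 1.0)
        table = community_contrasts(part, parts)
        assert np.all(table.threshold == 0.05 / 40)


def test_style_lexicon_communities_enriched(lexicon):
    """End-to-end: a planted frontal 'style' lexicon yields communities
    enriched for frontal membership (connectivity evidence only)."""
    other = fg.make_lexicon(1000, 1.0, seed=99)
    profs = fg.make_default_profiles()
    for p in profs:
        p.n = 15
    parts, trans = fg.simulate_cohort(profs, lexicon, seed=7,
                                      group_lexicons={"LF": other, "RF": other})
    E = fg.embed_sequences(trans, d=512, seed=7)
    G = fg.cosine_adjacency(E)
    part = fit_sbm(G, max_blocks=10, n_sweeps=5, seed=7, hierarchy=False)
    frontal = np.array([p.group in ("LF", "RF") for p in parts])
    b = part.assignment
    big = max(set(b), key=lambda k: int((b == k).sum()))
    table = np.array([
        [np.sum((b == big) & frontal), np.sum((b == big) & ~frontal)],
        [np.sum((b != big) & frontal), np.sum((b != big) & ~frontal)],
    ])
    assert fg.categorical_tests(table).p < 0.01
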
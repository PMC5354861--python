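"""Prioritizer: profile similarity, ranking, Q-statistic fusion, ES."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cernarank import (
    BioNetwork,
    LncRnaProfile,
    NetworkContext,
    enrichment_score,
    fuse_ranks,
    lncrna_pair_fs,
    q_statistic,
    rank_candidates,
)
from cernarank.prioritize import RankedEntry, RankedList


class DictContext:
    """Stub similarity backend with explicit gene-pair values."""

    def __init__(self, fs, genes, name="stub"):
        self.name = name
        self._fs = {(min(k), max(k)): v for k, v in fs.items()}
        self._genes = set(genes)

    def covers(self, gene_id):
        return gene_id in self._genes

    def gene_fs(self, g1, g2):
        if g1 == g2:
            return 1.0
        return self._fs.get((min(g1, g2), max(g1, g2)), 0.0)


def profile(lid, *genes):
    return LncRnaProfile(lid, frozenset(genes))


class TestLncrnaPairFs:
    def test_single_gene_pair(self):
        ctx = DictContext({("a", "x"): 0.7}, ["a", "x"])
        assert lncrna_pair_fs(profile("l1", "a"), profile("l2", "x"), ctx) == 0.7

    def test_flat_mean_over_all_pairs(self):
        ctx = DictContext(
            {("a", "x"): 1.0, ("a", "y"): 0.5, ("b", "x"): 0.5, ("b", "y"): 0.0},
            "abxy",
        )
        fs = lncrna_pair_fs(profile("l1", "a", "b"), profile("l2", "x", "y"), ctx)
        assert fs == pytest.approx(0.5)

    def test_empty_profile_is_absent_not_zero(self):
        ctx = DictContext({}, ["a"])
        assert lncrna_pair_fs(profile("l1"), profile("l2", "a"), ctx) is None
        assert lncrna_pair_fs(profile("l1"), profile("l2"), ctx) is None

    def test_symmetric(self):
        ctx = DictContext({("a", "x"): 0.3, ("b", "x"): 0.9}, "abx")
        p1, p2 = profile("l1", "a", "b"), profile("l2", "x")
        assert lncrna_pair_fs(p1, p2, ctx) == lncrna_pair_fs(p2, p1, ctx)


class TestRankCandidates:
    @pytest.fixture()
    def two_module_ctx(self):
        # two 4-cliques, disconnected from each other
        mod1 = [f"a{i}" for i in range(4)]
        mod2 = [f"b{i}" for i in range(4)]
        edges = [(x, y) for mod in (mod1, mod2) for x in mod for y in mod if x < y]
        return NetworkContext(BioNetwork.from_edges(edges), name="twomod")

    def test_matching_profile_ranks_first(self, two_module_ctx):
        seed = profile("seed", "a0", "a1")
        match = profile("match", "a0", "a1")
        decoys = [profile(f"d{i}", "b0", "b1") for i in range(9)]
        rl = rank_candidates([seed], [match] + decoys, two_module_ctx)
        assert rl.entries[0].lncrna_id == "match"
        assert rl.entries[0].rank == 1.0

    def test_tied_scores_share_average_rank(self, two_module_ctx):
        seed = profile("seed", "a0")
        cands = [profile(f"c{i}", "b0") for i in range(4)]
        rl = rank_candidates([seed], cands, two_module_ctx)
        assert {e.rank for e in rl.entries} == {2.5}
        assert {e.rank_ratio for e in rl.entries} == {2.5 / 4}

    def test_uncovered_candidate_dropped(self, two_module_ctx):
        seed = profile("seed", "a0")
        rl = rank_candidates(
            [seed],
            [profile("c1", "a1"), profile("c2", "zz"), profile("c3")],
            two_module_ctx,
        )
        assert [e.lncrna_id for e in rl.entries] == ["c1"]

    def test_no_usable_seed_raises(self, two_module_ctx):
        with pytest.raises(ValueError, match="seed"):
            rank_candidates([profile("s", "zz")], [profile("c", "a0")], two_module_ctx)

    def test_rank_ratio_invariants(self, two_module_ctx):
        seed = profile("seed", "a0", "b0")
        cands = [profile(f"c{i}", "a%d" % (i % 4)) for i in range(6)]
        rl = rank_candidates([seed], cands, two_module_ctx)
        n = len(rl.entries)
        scores = [e.score for e in rl.entries]
        assert scores == sorted(scores, reverse=True)
        for e in rl.entries:
            assert e.rank_ratio == pytest.approx(e.rank / n)
            assert 0 < e.rank_ratio <= 1


class TestQStatistic:
    @pytest.mark.parametrize("n", [1, 2, 5, 9])
    def test_all_ratios_one_is_exactly_one(self, n):
        assert q_statistic([1.0] * n) == 1.0

    def test_single_ratio_is_identity(self):
        assert q_statistic([0.2]) == pytest.approx(0.2, abs=1e-15)

    def test_two_ratio_reference_value(self):
        assert q_statistic([0.1, 0.2]) == pytest.approx(0.03, abs=1e-12)
        assert q_statistic([0.2, 0.1]) == pytest.approx(0.03, abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [-0.1], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            q_statistic(bad)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
        st.integers(0, 5),
        st.floats(0.0, 0.2),
    )
    def test_monotone_in_every_ratio(self, ratios, which, bump):
        base = q_statistic(ratios)
        idx = which % len(ratios)
        bumped = list(ratios)
        bumped[idx] = min(1.0, bumped[idx] + bump)
        assert q_statistic(bumped) >= base - 1e-12

    def test_matches_monte_carlo_order_statistics(self):
        rng = np.random.default_rng(42)
        n_draws = 10**5
        for ratios in ([0.3], [0.15, 0.6], [0.2, 0.5, 0.9], [0.1, 0.3, 0.5, 0.8]):
            n = len(ratios)
            u = np.sort(rng.random((n_draws, n)), axis=1)
            hits = np.all(u <= np.sort(np.asarray(ratios)), axis=1)
            p_hat = hits.mean()
            se = max(np.sqrt(p_hat * (1 - p_hat) / n_draws), 1e-6)
            assert abs(q_statistic(ratios) - p_hat) <= 3 * se


def make_list(name, ordered_ids):
    n = len(ordered_ids)
    return RankedList(
        name,
        [
            RankedEntry(lid, float(n - i), i + 1.0, (i + 1.0) / n)
            for i, lid in enumerate(ordered_ids)
        ],
    )


class TestFuseRanks:
    def test_single_list_preserves_order(self):
        rl = make_list("only", ["a", "b", "c", "d"])
        fused = fuse_ranks([rl])
        assert [e.lncrna_id for e in fused.entries] == ["a", "b", "c", "d"]

    def test_nine_identical_lists_preserve_order(self):
        ids = [f"l{i}" for i in range(10)]
        fused = fuse_ranks([make_list(f"ctx{k}", ids) for k in range(9)])
        assert [e.lncrna_id for e in fused.entries] == ids

    def test_consistent_top_beats_single_context_top(self):
        # "alltop" is first in all nine lists; "onetop" first in one only
        others = [f"f{i}" for i in range(8)]
        lists = [make_list("ctx0", ["onetop", "alltop"] + others)]
        for k in range(1, 9):
            lists.append(make_list(f"ctx{k}", ["alltop", "onetop"] + others))
        fused = fuse_ranks(lists)
        q = {e.lncrna_id: e.q for e in fused.entries}
        assert q["alltop"] < q["onetop"]
        assert fused.entries[0].lncrna_id == "alltop"

    def test_reversed_lists_are_symmetric(self):
        ids = [f"l{i}" for i in range(10)]
        fused = fuse_ranks([make_list("fwd", ids), make_list("rev", ids[::-1])])
        q = {e.lncrna_id: e.q for e in fused.entries}
        # the candidate ranked k-th forward is (n+1-k)-th backward: mirror
        # pairs share identical ratio multisets, hence identical Q
        for i in range(5):
            assert q[ids[i]] == pytest.approx(q[ids[9 - i]], abs=1e-12)
        extremes = {fused.entries[0].lncrna_id, fused.entries[-1].lncrna_id}
        assert "l4" not in extremes and "l5" not in extremes

    def test_missing_context_reduces_n_sources(self):
        lists = [make_list("a", ["x", "y"]), make_list("b", ["y"])]
        fused = fuse_ranks(lists)
        by_id = {e.lncrna_id: e for e in fused.entries}
        assert by_id["x"].n_sources == 1
        assert by_id["y"].n_sources == 2


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "rank,n,expected",
        [(50, 100, 0.0), (100, 100, -1.0), (1, 100, math.log2(50))],
    )
    def test_reference_values(self, rank, n, expected):
        assert enrichment_score(rank, n) == pytest.approx(expected)

    @pytest.mark.parametrize("rank,n", [(0, 100), (101, 100), (5, 0)])
    def test_domain_errors(self, rank, n):
        with pytest.raises(ValueError):
            enrichment_score(rank, n)
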
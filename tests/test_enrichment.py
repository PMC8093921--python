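"""Ranked lists, Wilcoxon rank-sum set enrichment, Fisher term overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossde import (
    GeneSetCollection,
    build_ranked_lists,
    call_enriched_terms,
    fisher_overlap_terms,
    wilcoxon_set_enrichment,
)
from crossde.enrichment import RankedList, _ranksum_counts


def make_ranked(n: int) -> RankedList:
    ids = np.array([f"g{i}" for i in range(n)], dtype=object)
    return RankedList(ids, np.arange(1, n + 1, dtype=float), "up_to_down")


def enumeration_p(n: int, m: int, w_obs: float) -> float:
    """Brute-force oracle: enumerate all C(n, m) member placements."""
    hits = sum(
        1 for combo in itertools.combinations(range(1, n + 1), m) if sum(combo) <= w_obs
    )
    return hits / math.comb(n, m)


class TestRankedLists:
    def test_three_gene_worked_order(self):
        """(+1, p=.01), (+2, p=.5), (-1, p=.02) -> positive block by ascending
        p first, then the negative gene."""
        df = pd.DataFrame(
            {"gene_id": ["gene1", "gene2", "gene3"], "log_fc": [1.0, 2.0, -1.0],
             "p_value": [0.01, 0.5, 0.02]}
        )
        up, down = build_ranked_lists(df)
        assert list(up.ordering) == ["gene1", "gene2", "gene3"]
        assert list(down.ordering) == ["gene3", "gene2", "gene1"]

    def test_all_positive_is_ascending_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)], "log_fc": np.ones(20), "p_value": p}
        )
        up, _ = build_ranked_lists(df)
        assert list(up.ordering) == [f"g{i}" for i in np.argsort(p)]

    def test_down_list_is_exact_reversal(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(3, 40)
            df = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n)],
                    "log_fc": rng.normal(size=n),
                    "p_value": rng.uniform(1e-6, 1, size=n),
                }
            )
            up, down = build_ranked_lists(df)
            assert list(down.ordering) == list(up.ordering)[::-1]
            assert np.allclose(down.ranks, (n + 1 - up.ranks)[::-1])

    def test_tied_keys_get_average_ranks(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "log_fc": [1.0, 1.0, -1.0], "p_value": [0.1, 0.1, 0.2]}
        )
        up, _ = build_ranked_lists(df)
        assert up.has_ties
        assert np.allclose(up.ranks, [1.5, 1.5, 3.0])


class TestWilcoxonEnrichment:
    def test_top_two_of_six(self):
        """Members at ranks {1,2} of 6: only one of C(6,2)=15 placements
        attains rank sum 3, so p = 1/15."""
        ranked = make_ranked(6)
        w, p = wilcoxon_set_enrichment(ranked, {"g0", "g1"})
        assert w == 3
        assert p == pytest.approx(1 / 15, abs=1e-12)

    def test_bottom_two_of_six_is_worst_case(self):
        ranked = make_ranked(6)
        w, p = wilcoxon_set_enrichment(ranked, {"g4", "g5"})
        assert w == 11
        assert p == pytest.approx(1.0)

    def test_exact_recursion_matches_full_enumeration(self):
        """For every list length <= 10 and every member count, the recursion
        equals the all-placements oracle to 1e-12."""
        rng = np.random.default_rng(2)
        for n in range(2, 11):
            ranked = make_ranked(n)
            for m in range(1, n):
                members = {f"g{i}" for i in rng.choice(n, size=m, replace=False)}
                w, p = wilcoxon_set_enrichment(ranked, members)
                assert p == pytest.approx(enumeration_p(n, m, w), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        """Exact and approximate p agree within 0.01 at n=1000, m=50."""
        rng = np.random.default_rng(3)
        ranked = make_ranked(1000)
        for _ in range(100):
            members = {f"g{i}" for i in rng.choice(1000, size=50, replace=False)}
            _, p_exact = wilcoxon_set_enrichment(ranked, members)
            _, p_norm = wilcoxon_set_enrichment(ranked, members, max_states=0)
            assert abs(p_exact - p_norm) <= 0.01

    def test_exact_matches_scipy_mannwhitneyu(self):
        """Independent library cross-check of the exact null distribution."""
        rng = np.random.default_rng(4)
        n, m = 30, 6
        ranked = make_ranked(n)
        for _ in range(25):
            idx = rng.choice(n, size=m, replace=False)
            members = {f"g{i}" for i in idx}
            _, p = wilcoxon_set_enrichment(ranked, members)
            x = idx + 1.0
            y = np.array([r for r in range(1, n + 1) if r not in set(x.astype(int))], dtype=float)
            ref = stats.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_test_level_under_random_placement(self):
        """Under uniform placement of 5 members in a 100-gene list the
        rejection rate at alpha is <= alpha + 3 SE (10^6 draws)."""
        n, m, n_draws = 100, 5, 1_000_000
        cum = _ranksum_counts(n, m)
        total = cum[-1]
        rng = np.random.default_rng(5)
        rejections = {0.05: 0, 0.01: 0}
        chunk = 100_000
        for _ in range(n_draws // chunk):
            u = rng.random((chunk, n))
            idx = np.argpartition(u, m - 1, axis=1)[:, :m]
            w = idx.sum(axis=1) + m  # ranks are idx + 1
            u_stat = w - m * (m + 1) // 2
            p = cum[u_stat] / total
            for alpha in rejections:
                rejections[alpha] += int((p <= alpha).sum())
        for alpha, hits in rejections.items():
            se = math.sqrt(alpha * (1 - alpha) / n_draws)
            assert hits / n_draws <= alpha + 3 * se

    def test_invalid_member_sets_rejected(self):
        ranked = make_ranked(6)
        with pytest.raises(ValueError):
            wilcoxon_set_enrichment(ranked, set())
        with pytest.raises(ValueError):
            wilcoxon_set_enrichment(ranked, {f"g{i}" for i in range(6)})
        with pytest.raises(ValueError, match="not in ranked list"):
            wilcoxon_set_enrichment(ranked, {"nope"})


class TestCallEnrichedTerms:
    def test_planted_up_term_is_up_only(self):
        """A term whose members head the list is significant in up_to_down
        and not in down_to_up."""
        n = 400
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log_fc": np.where(np.arange(n) < 200, 1.0, -1.0),
                "p_value": np.concatenate(
                    [np.sort(rng.uniform(1e-8, 1, 200)), rng.uniform(1e-8, 1, 200)]
                ),
            }
        )
        collection = GeneSetCollection(
            {"planted": frozenset(f"g{i}" for i in range(15)),
             "random": frozenset(f"g{i}" for i in rng.choice(n, 15, replace=False))},
            frozenset(df["gene_id"]),
        )
        enr = call_enriched_terms(df, collection, cutoff=1e-5)
        by = enr.set_index(["term_id", "direction"])
        assert by.loc[("planted", "up"), "significant"]
        assert not by.loc[("planted", "down"), "significant"]

    def test_whole_universe_term_skipped(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "log_fc": [1.0, -1.0, 1.0], "p_value": [0.1, 0.2, 0.3]}
        )
        collection = GeneSetCollection({"all": frozenset("abc")}, frozenset("abc"))
        with pytest.warns(UserWarning, match="whole universe"):
            enr = call_enriched_terms(df, collection)
        assert enr.empty


class TestFisherOverlapTerms:
    def test_complete_overlap_worked_example(self):
        """|A|=|B|=5 identical in a 10-term universe: p = 1/C(10,5)."""
        universe = {f"t{i}" for i in range(10)}
        a = {f"t{i}" for i in range(5)}
        _, p = fisher_overlap_terms(a, a, universe)
        assert p == pytest.approx(1 / 252, rel=1e-9)

    def test_disjoint_sets_p_is_one(self):
        universe = {f"t{i}" for i in range(10)}
        _, p = fisher_overlap_terms({"t0", "t1"}, {"t5", "t6"}, universe)
        assert p == pytest.approx(1.0)

    def test_degenerate_full_universe(self):
        universe = {"t0", "t1"}
        _, p = fisher_overlap_terms(universe, universe, universe)
        assert p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_overlap_terms(set(), set(), set())
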
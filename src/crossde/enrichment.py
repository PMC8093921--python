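"""Rank-based gene-set enrichment on dual-direction ranked lists.

Every gene of the DE universe is ranked twice: the ``up_to_down`` list puts
the most confidently up-regulated genes (log_fc > 0, ascending p) at the top
and the most confidently down-regulated genes at the bottom; ``down_to_up``
is its exact reversal.  A gene set is scored by the sum of its members'
ranks; the one-sided p-value is the probability, under uniform random
placement of the members in the list, that the rank sum is <= the observed
one.  A set significant in the up_to_down list is called up-regulated, in
the down_to_up list down-regulated (cutoff p <= 1e-05 by default, a fixed
threshold standing in for multiple-testing control across terms).

The exact null distribution of the rank sum is computed by the restricted-
partition recursion behind the Mann-Whitney statistic (coefficients of the
Gaussian binomial [n choose m]_q); a normal approximation with continuity
and tie corrections takes over when the DP state count m*(n-m) exceeds a
configurable bound.  Ties in the sort keys receive average ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

ENRICHMENT_CUTOFF = 1.0e-05
#: switch to the normal approximation above this many DP states (m * (n - m))
MAX_EXACT_STATES = 1_000_000

ENRICHMENT_COLUMNS = ["term_id", "direction", "rank_sum", "p_value", "significant"]


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared background universe."""

    sets: dict[str, frozenset]
    background: frozenset

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        self.background = frozenset(self.background)

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; empty sets are dropped."""
        uni = frozenset(universe)
        restricted = {}
        for name, members in self.sets.items():
            kept = members & uni
            if kept:
                restricted[name] = kept
        return GeneSetCollection(restricted, uni)


@dataclass
class RankedList:
    """A full ordering of the DE universe with (average) ranks attached."""

    ordering: np.ndarray  # gene ids, top of the list first
    ranks: np.ndarray  # rank of ordering[i]; average ranks for tied keys
    convention: str  # 'up_to_down' | 'down_to_up'
    has_ties: bool = False
    tie_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self) -> int:
        return len(self.ordering)

    def rank_of(self) -> dict[str, float]:
        return dict(zip(self.ordering, self.ranks))


def build_ranked_lists(results: pd.DataFrame) -> tuple[RankedList, RankedList]:
    """Build the up_to_down and down_to_up rankings from a DE table.

    Sort: genes with log_fc > 0 first, ordered by ascending p; genes with
    log_fc < 0 last, ordered by descending p (so the most confidently
    down-regulated genes sit at the very bottom); zero log_fc in between.
    Identical (sign-block, p) keys are tied: they are emitted in id-lexico-
    graphic order but share an average rank.
    """
    if len(results) == 0:
        raise ValueError("DE universe is empty")
    ids = results["gene_id"].to_numpy(dtype=object)
    lfc = results["log_fc"].to_numpy(dtype=float)
    p = results["p_value"].to_numpy(dtype=float)
    block = np.where(lfc > 0, 0, np.where(lfc < 0, 2, 1))
    key = np.where(block == 0, p, np.where(block == 2, -p, 0.0))
    order = np.lexsort((ids, key, block))
    ordering = ids[order]
    b_s, k_s = block[order], key[order]
    n = len(ordering)
    # average ranks within runs of equal (block, key)
    boundary = np.ones(n, dtype=bool)
    boundary[1:] = (b_s[1:] != b_s[:-1]) | (k_s[1:] != k_s[:-1])
    group_id = np.cumsum(boundary) - 1
    pos = np.arange(1, n + 1, dtype=float)
    sums = np.bincount(group_id, weights=pos)
    counts = np.bincount(group_id)
    ranks = (sums / counts)[group_id]
    has_ties = bool((counts > 1).any())
    tie_counts = counts[counts > 1]
    up = RankedList(ordering, ranks, "up_to_down", has_ties, tie_counts)
    down = RankedList(ordering[::-1].copy(), (n + 1 - ranks)[::-1].copy(), "down_to_up", has_ties, tie_counts)
    return up, down


@lru_cache(maxsize=128)
def _ranksum_counts(n: int, m: int) -> np.ndarray:
    """Cumulative counts of m-subsets of ranks 1..n by shifted rank sum.

    Entry u holds the number of m-subsets whose rank sum is <= u + m(m+1)/2
    (u is the Mann-Whitney U statistic, 0..m(n-m)).  Computed as cumulative
    coefficients of the Gaussian binomial [n choose m]_q via repeated
    multiplication by (1 - q^{n-m+i}) and division by (1 - q^i).
    """
    u_max = m * (n - m)
    poly = np.zeros(u_max + 1)
    poly[0] = 1.0
    for i in range(1, m + 1):
        a = n - m + i
        if a <= u_max:
            poly[a:] -= poly[: u_max + 1 - a].copy()
        for r in range(i):
            poly[r::i] = np.cumsum(poly[r::i])
    return np.cumsum(poly)


def _log_comb(n: int, m: int) -> float:
    return float(gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))


def wilcoxon_set_enrichment(
    ranked: RankedList,
    members: Iterable[str],
    max_states: int = MAX_EXACT_STATES,
) -> tuple[float, float]:
    """Rank-sum statistic and one-sided p for a gene set in a ranked list.

    p = P(rank sum <= observed) under uniform random placement of the
    members; exact by the rank-sum recursion when feasible and the list has
    no tied keys, otherwise a normal approximation with continuity and tie
    corrections.
    """
    member_set = set(members)
    n = len(ranked)
    m = len(member_set)
    if m == 0:
        raise ValueError("member set is empty")
    if m >= n:
        raise ValueError("member set must be a strict subset of the ranked list")
    rank_of = ranked.rank_of()
    missing = member_set - rank_of.keys()
    if missing:
        raise ValueError(f"members not in ranked list: {sorted(missing)[:5]}")
    w = float(sum(rank_of[g] for g in member_set))

    if not ranked.has_ties and m * (n - m) <= max_states:
        u_obs = int(np.floor(w - m * (m + 1) / 2.0 + 1e-9))
        cum = _ranksum_counts(n, m)
        u_obs = min(max(u_obs, 0), len(cum) - 1)
        log_p = np.log(cum[u_obs]) - _log_comb(n, m)
        return w, float(min(1.0, np.exp(log_p)))

    mu = m * (n + 1) / 2.0
    var = m * (n - m) * (n + 1) / 12.0
    if ranked.has_ties and n > 1:
        t = ranked.tie_counts.astype(float)
        var *= 1.0 - float(np.sum(t**3 - t)) / (n**3 - n)
    if var <= 0:
        return w, 1.0
    z = (w + 0.5 - mu) / np.sqrt(var)
    p = float(stats.norm.cdf(z))
    return w, min(1.0, max(p, np.finfo(float).tiny))


def call_enriched_terms(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    cutoff: float = ENRICHMENT_CUTOFF,
    max_states: int = MAX_EXACT_STATES,
) -> pd.DataFrame:
    """Test every term in both list conventions and label its direction.

    Returns one row per (term, direction); a term significant in the
    up_to_down list is up-regulated, in the down_to_up list down-regulated.
    Terms covering the whole universe (no placement freedom) are skipped
    with a warning; a term significant in both directions is reported in
    both rows.
    """
    universe = set(results["gene_id"])
    collection = collection.restricted(universe)
    up, down = build_ranked_lists(results)
    rows = []
    for term_id in sorted(collection.sets):
        members = collection.sets[term_id]
        if len(members) >= len(universe):
            warnings.warn(f"term {term_id} covers the whole universe; skipped", stacklevel=2)
            continue
        for ranked, direction in ((up, "up"), (down, "down")):
            rank_sum, p = wilcoxon_set_enrichment(ranked, members, max_states)
            rows.append((term_id, direction, rank_sum, p, p <= cutoff))
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)


def significant_terms(enrichment: pd.DataFrame) -> dict[str, set[str]]:
    """Split an enrichment table into {'up': terms, 'down': terms}."""
    out: dict[str, set[str]] = {"up": set(), "down": set()}
    sig = enrichment.loc[enrichment["significant"]]
    for _, row in sig.iterrows():
        out[row["direction"]].add(row["term_id"])
    return out


def fisher_overlap_terms(
    terms_a: Iterable[str], terms_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test for the overlap of two
    term sets over a term universe.  Returns (odds_ratio, p_value)."""
    uni = set(universe)
    if not uni:
        raise ValueError("term universe is empty")
    a, b = set(terms_a), set(terms_b)
    if not a <= uni or not b <= uni:
        raise ValueError("term sets must be subsets of the universe")
    k = len(a & b)
    table = [[k, len(a) - k], [len(b) - k, len(uni) - len(a | b)]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)
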
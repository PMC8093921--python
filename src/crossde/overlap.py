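"""Exact multi-set intersection statistics over a common background.

Model: each of m >= 2 candidate sets is an independent uniformly random
subset of fixed size n_i of an N-element background.  The distribution of
the intersection size is built by dynamic programming: |A1 n A2| is
Hypergeometric(N, n1, n2), and given a running intersection of size s,
intersecting with the next set of size n_j is Hypergeometric(N, s, n_j);
the result is the induced mixture, accumulated in log space so that the
far upper tail (p-values down to ~1e-300) stays accurate.  The upper tail
P(X >= k_observed) is the overlap p-value (enrichment convention); for
m = 2 it coincides with the one-sided Fisher's exact test.

Observed intersection genes can be annotated by cross-species direction:
concordant (same sign in every supplied direction map), discordant
(opposite signs), or mixed (ambiguous or missing sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp


def _validate_sizes(set_sizes: Sequence[int], background_n: int) -> list[int]:
    sizes = [int(n) for n in set_sizes]
    if len(sizes) < 2:
        raise ValueError("need at least two sets (m >= 2)")
    if background_n < 1:
        raise ValueError("background must be nonempty")
    for n_i in sizes:
        if n_i < 0 or n_i > background_n:
            raise ValueError(f"set size {n_i} outside [0, N={background_n}]")
    return sizes


def log_intersection_distribution(
    set_sizes: Sequence[int], background_n: int
) -> np.ndarray:
    """Log-probabilities of the intersection size k = 0..min(n_i)."""
    sizes = _validate_sizes(set_sizes, background_n)
    n = background_n
    kmax = min(sizes[0], sizes[1])
    k = np.arange(kmax + 1)
    logp = stats.hypergeom.logpmf(k, n, sizes[0], sizes[1])
    for n_j in sizes[2:]:
        new_kmax = min(kmax, n_j)
        s = np.arange(kmax + 1)
        kk = np.arange(new_kmax + 1)
        # cond[i, j] = log P(|running n A_j| = kk[j] | running size s[i])
        cond = stats.hypergeom.logpmf(kk[None, :], n, s[:, None], n_j)
        logp = logsumexp(logp[:, None] + cond, axis=0)
        kmax = new_kmax
    return logp


def intersection_distribution(
    set_sizes: Sequence[int], background_n: int
) -> np.ndarray:
    """Exact probability vector of the intersection size (sums to 1)."""
    return np.exp(log_intersection_distribution(set_sizes, background_n))


def expected_intersection(set_sizes: Sequence[int], background_n: int) -> float:
    """E|A1 n ... n Am| = N * prod(n_i / N) by per-element independence."""
    sizes = _validate_sizes(set_sizes, background_n)
    return float(background_n * np.prod([n_i / background_n for n_i in sizes]))


def log_intersection_pvalue(
    set_sizes: Sequence[int], background_n: int, k_observed: int
) -> float:
    """log of the upper tail P(X >= k_observed); stays finite far below
    the smallest representable probability."""
    if k_observed <= 0:
        return 0.0
    logp = log_intersection_distribution(set_sizes, background_n)
    if k_observed >= len(logp):
        return -np.inf
    return float(min(0.0, logsumexp(logp[k_observed:])))


def intersection_pvalue(
    set_sizes: Sequence[int], background_n: int, k_observed: int
) -> float:
    """Upper-tail P(X >= k_observed) from the exact DP distribution."""
    return float(np.exp(log_intersection_pvalue(set_sizes, background_n, k_observed)))


def monte_carlo_overlap(
    set_sizes: Sequence[int],
    background_n: int,
    k_observed: int,
    n_draws: int,
    seed: int,
) -> float:
    """Empirical P(X >= k_observed) from uniform random subset draws.

    Draws m independent uniform subsets of the given sizes and returns the
    fraction of draws whose intersection is at least k_observed;
    reproducible given the seed.  Serves as the validation oracle for the
    exact DP.
    """
    sizes = _validate_sizes(set_sizes, background_n)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if k_observed <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    n = background_n
    hits = 0
    chunk = max(1, min(n_draws, int(4e6 // max(n, 1)) or 1))
    done = 0
    while done < n_draws:
        c = min(chunk, n_draws - done)
        inter = np.full((c, n), True)
        for n_i in sizes:
            u = rng.random((c, n))
            member = np.zeros((c, n), dtype=bool)
            if n_i > 0:
                idx = np.argpartition(u, n_i - 1, axis=1)[:, :n_i]
                np.put_along_axis(member, idx, True, axis=1)
            inter &= member
        hits += int((inter.sum(axis=1) >= k_observed).sum())
        done += c
    return hits / n_draws


@dataclass
class OverlapResult:
    """Observed intersection, its expectation, exact p and concordance."""

    k_observed: int
    expected: float
    p_value: float
    method: str  # 'exact_dp' | 'fisher' | 'monte_carlo'
    set_sizes: list[int]
    background_n: int
    observed_genes: list[str]
    concordant: int = 0
    discordant: int = 0
    mixed: int = 0
    gene_classes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_observed": self.k_observed,
            "expected": self.expected,
            "p_value": self.p_value,
            "method": self.method,
            "set_sizes": self.set_sizes,
            "background_n": self.background_n,
            "observed_genes": sorted(self.observed_genes),
            "concordant": self.concordant,
            "discordant": self.discordant,
            "mixed": self.mixed,
        }


def _classify_directions(
    genes: Iterable[str], directions: Sequence[Mapping[str, int]]
) -> dict[str, str]:
    classes: dict[str, str] = {}
    missing_warned = False
    for g in genes:
        signs = []
        missing = False
        for d in directions:
            s = d.get(g)
            if s is None or s == 0:
                missing = missing or s is None
                signs = []
                break
            signs.append(s)
        if not signs:
            if missing and not missing_warned:
                warnings.warn(
                    "direction maps do not cover all observed genes; "
                    "uncovered genes counted as mixed",
                    stacklevel=3,
                )
                missing_warned = True
            classes[g] = "mixed"
        elif len(set(signs)) == 1:
            classes[g] = "concordant"
        else:
            classes[g] = "discordant"
    return classes


def overlap_test(
    sets: Sequence[Iterable[str]],
    background: Iterable[str],
    directions: Sequence[Mapping[str, int]] | None = None,
    method: str = "auto",
    n_draws: int = 100_000,
    seed: int = 0,
) -> OverlapResult:
    """Significance of the literal intersection of m gene sets.

    p = P(X >= k_observed) under the independent-uniform-subsets model;
    method 'auto' uses the hypergeometric closed form for m = 2 (reported
    as 'fisher', to which it is identical) and the exact DP otherwise.
    Optional per-set direction maps (gene -> +1/-1) annotate the observed
    genes as concordant / discordant / mixed.
    """
    gene_sets = [set(s) for s in sets]
    bg = set(background)
    for i, s in enumerate(gene_sets):
        if not s <= bg:
            raise ValueError(f"set {i} is not a subset of the background")
    sizes = _validate_sizes([len(s) for s in gene_sets], len(bg))
    observed = set.intersection(*gene_sets)
    k = len(observed)
    n = len(bg)

    if method == "auto":
        method = "fisher" if len(sizes) == 2 else "exact_dp"
    if method == "fisher":
        if len(sizes) != 2:
            raise ValueError("fisher method applies to m = 2 only")
        p = float(stats.hypergeom.sf(k - 1, n, sizes[0], sizes[1]))
    elif method == "exact_dp":
        p = intersection_pvalue(sizes, n, k)
    elif method == "monte_carlo":
        p = monte_carlo_overlap(sizes, n, k, n_draws, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(min(1.0, p))

    result = OverlapResult(
        k_observed=k,
        expected=expected_intersection(sizes, n),
        p_value=p,
        method=method,
        set_sizes=sizes,
        background_n=n,
        observed_genes=sorted(observed),
    )
    if directions is not None:
        classes = _classify_directions(observed, directions)
        result.gene_classes = classes
        result.concordant = sum(1 for v in classes.values() if v == "concordant")
        result.discordant = sum(1 for v in classes.values() if v == "discordant")
        result.mixed = sum(1 for v in classes.values() if v == "mixed")
    return result
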
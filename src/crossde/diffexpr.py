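"""Differential expression with an empirical-Bayes moderated t statistic.

The model is the standard hierarchical one for two-group expression data on a
log-like scale: per gene g the pooled residual variance s_g^2 (on d_g degrees
of freedom) is shrunk toward a prior variance s0^2 carrying d0 prior degrees
of freedom,

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t statistic

    t_g = logFC_g / (s~_g * sqrt(1/n1 + 1/n2))

is referred to a t distribution on d0 + d_g degrees of freedom.  With d0 = 0
this is exactly the classical pooled two-sample t-test; with d0 -> inf every
gene is tested against the common prior variance.  When the hyperparameters
are not supplied they are estimated from the observed distribution of sample
variances by moment matching on the log scale (the scaled-F model: s_g^2 ~
s0^2 * F(d_g, d0)).

Significance is called at adjusted p < alpha (Benjamini-Hochberg step-up)
AND detected == True; the detection flag stands for a presence call on the
measured transcripts and undetected genes are excluded from every downstream
gene universe via :func:`filter_detected`.

logFC convention: mean(treated) - mean(control) on the expression scale of
the input matrix (assumed already log-like).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

GROUP_LABELS = ("control", "treated")

DE_COLUMNS = ["gene_id", "log_fc", "t_mod", "p_value", "adj_p", "detected", "significant"]


@dataclass
class ExpressionTable:
    """Genes x samples expression matrix with group labels and detection flags."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group: np.ndarray  # per-sample label, 'control' | 'treated'
    detected: np.ndarray  # per-gene bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        self.detected = np.asarray(self.detected, dtype=bool)
        n_g, n_s = self.values.shape
        if len(self.gene_ids) != n_g:
            raise ValueError("gene_ids length does not match value matrix rows")
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match value matrix columns")
        if self.group.shape != (n_s,):
            raise ValueError("group labels must be per-sample")
        if self.detected.shape != (n_g,):
            raise ValueError("detected flags must be per-gene")
        bad = set(self.group) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    def group_values(self, label: str) -> np.ndarray:
        return self.values[:, self.group == label]


@dataclass
class DEModelParams:
    """Hyperparameters of the moderated t model.

    d0 / s0_sq of None means "estimate from the data"; d0 = 0 disables
    moderation (classical pooled t); d0 = inf tests against s0_sq alone.
    """

    d0: float | None = None
    s0_sq: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.d0 is not None and not self.d0 >= 0:
            raise ValueError("d0 must be >= 0 (or None to estimate)")
        if self.s0_sq is not None and not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0 (or None to estimate)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    adj_(i) = min_{j >= i} min(1, p_(j) * m / j) over the ascending order
    statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d sequence")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d_g: int) -> tuple[float, float]:
    """Moment-matching fit of (d0, s0_sq) for the scaled-F variance model.

    Matches mean and variance of log s_g^2 against the theoretical moments of
    log(s0^2 * F(d_g, d0)) using digamma/trigamma; returns d0 = inf when the
    observed spread of log variances does not exceed the chi-square floor.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least two positive sample variances to estimate the prior")
    z = np.log(s2)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1))
    excess = evar - float(special.polygamma(1, d_g / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated_t(table: ExpressionTable, params: DEModelParams | None = None) -> pd.DataFrame:
    """Fit the moderated t model to every gene of an :class:`ExpressionTable`.

    Returns a DataFrame with columns gene_id, log_fc, t_mod, p_value, adj_p,
    detected, significant.  significant == (adj_p < alpha) AND detected.
    Genes with zero pooled variance under d0 = 0 get NaN p-values (flagged
    with a warning) and are never called significant.
    """
    params = params or DEModelParams()
    x_t = table.group_values("treated")
    x_c = table.group_values("control")
    n1, n2 = x_t.shape[1], x_c.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (treated={n1}, control={n2})")
    d_g = n1 + n2 - 2
    log_fc = x_t.mean(axis=1) - x_c.mean(axis=1)
    ss = ((x_t - x_t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x_c - x_c.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d_g

    d0, s0_sq = params.d0, params.s0_sq
    if d0 is None or s0_sq is None:
        d0_hat, s0_hat = estimate_prior(s2, d_g)
        d0 = d0_hat if d0 is None else d0
        s0_sq = s0_hat if s0_sq is None else s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df = np.inf
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df = d0 + d_g

    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / (np.sqrt(s2_post) * c)
    p = np.full(t_mod.shape, np.nan)
    finite = np.isfinite(t_mod)
    p[finite] = 2.0 * stats.t.sf(np.abs(t_mod[finite]), df)
    # two-sided p of exactly 0 difference with positive variance is 1, keep in (0,1]
    p[finite] = np.clip(p[finite], np.finfo(float).tiny, 1.0)
    if (~finite).any():
        warnings.warn(
            f"{int((~finite).sum())} gene(s) with zero pooled variance and no "
            "moderation (d0=0): p-value undefined",
            RuntimeWarning,
            stacklevel=2,
        )

    adj = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        adj[valid] = bh_adjust(p[valid])

    significant = np.zeros(p.shape, dtype=bool)
    significant[valid] = (adj[valid] < params.alpha) & table.detected[valid]
    return pd.DataFrame(
        {
            "gene_id": table.gene_ids,
            "log_fc": log_fc,
            "t_mod": t_mod,
            "p_value": p,
            "adj_p": adj,
            "detected": table.detected,
            "significant": significant,
        }
    )


def filter_detected(results: pd.DataFrame) -> pd.DataFrame:
    """Restrict a DE table to detected genes (the analysis universe)."""
    return results.loc[results["detected"].astype(bool)].reset_index(drop=True)
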
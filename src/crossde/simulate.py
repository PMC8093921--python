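"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the downstream analysis
assumes, not the physics of any platform: a two-condition, five-replicate
expression experiment on a log-like scale with normal noise around group
means and planted differential effects; a detection (presence) flag per
gene; a GO-style annotation with terms over-populated by planted DE genes
of one direction; a human-to-fly ortholog table with best-forward /
best-reverse flags, one-to-many and non-reciprocal rows; and per-cell-type
human DE gene lists in which a controllable fraction of the planted fly DE
genes reappears with a controllable sign relation (sign_concordance = 0
gives the fully reciprocal regime: every conserved pair changes in
opposite directions in the two species).

All randomness flows from a single seed through named substreams (one per
artifact), so regenerating one artifact never perturbs another and an
identical configuration is bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ExpressionTable
from .enrichment import GeneSetCollection
from .orthomap import ORTHOLOG_COLUMNS, filter_reciprocal_best

#: the six cell types of the human single-cell comparison
CELL_TYPES = ("In", "Ex", "Ast", "Oli", "Opc", "Mic")

HUMAN_DE_COLUMNS = ["cell_type", "gene", "direction", "p_adj"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, seed-derived random substream (stable across artifacts)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults model a desk-scale version of a two-age, five-replicate brain
    expression study compared against six human cell types; expression
    noise and effect sizes are on a log2-like scale.
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_group: int = 5
    frac_de: float = 0.05
    effect_size_mean: float = 1.0  # log-fold-change units
    effect_size_sd: float = 0.3
    noise_sd: float = 0.3  # expression units
    frac_detected: float = 0.9
    n_go_terms: int = 50
    genes_per_term: int = 20
    n_planted_terms: int = 6
    n_celltypes: int = 6
    frac_conserved: float = 0.4  # fraction of fly DE genes planted as human DE
    sign_concordance: float = 0.0  # 0 = fully reciprocal between species
    frac_one_to_many: float = 0.1
    frac_nonreciprocal: float = 0.2
    n_human_de_per_celltype: int = 150

    def __post_init__(self) -> None:
        fractions = (
            "frac_de",
            "frac_detected",
            "frac_conserved",
            "sign_concordance",
            "frac_one_to_many",
            "frac_nonreciprocal",
        )
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        counts = (
            "n_genes",
            "n_samples_per_group",
            "n_go_terms",
            "genes_per_term",
            "n_celltypes",
            "n_human_de_per_celltype",
        )
        for name in counts:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a count >= 1, got {v}")
        if self.n_planted_terms < 0 or self.n_planted_terms > self.n_go_terms:
            raise ValueError("n_planted_terms must lie in [0, n_go_terms]")
        for name in ("effect_size_mean", "effect_size_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def human_gene_for(self, i: int) -> str:
        return f"H{i:05d}"

    def celltype_names(self) -> list[str]:
        extra = [f"Ct{i}" for i in range(len(CELL_TYPES), self.n_celltypes)]
        return list(CELL_TYPES[: self.n_celltypes]) + extra


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study; every id resolves in the
    emitted tables."""

    planted_de_fly: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_enriched_terms: dict[str, str] = field(default_factory=dict)
    planted_human_de: dict[str, dict[str, int]] = field(default_factory=dict)
    conserved_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    planted_celltype: str | None = None

    def fly_planted_union(self) -> dict[str, int]:
        merged: dict[str, int] = {}
        for per_age in self.planted_de_fly.values():
            merged.update(per_age)
        return merged

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_de_fly": self.planted_de_fly,
            "planted_enriched_terms": self.planted_enriched_terms,
            "planted_human_de": self.planted_human_de,
            "conserved_pairs": [list(t) for t in self.conserved_pairs],
            "planted_celltype": self.planted_celltype,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_de_fly={a: {g: int(s) for g, s in m.items()} for a, m in d["planted_de_fly"].items()},
            planted_enriched_terms=dict(d["planted_enriched_terms"]),
            planted_human_de={c: {g: int(s) for g, s in m.items()} for c, m in d["planted_human_de"].items()},
            conserved_pairs=[tuple(t) for t in d["conserved_pairs"]],
            planted_celltype=d["planted_celltype"],
        )


def planted_de_genes(cfg: SimulationConfig) -> dict[str, int]:
    """Planted DE gene identities and signs, shared across ages.

    Signs are Rademacher(+-1) so both ranked-list directions are populated;
    drawn from a dedicated substream so both simulated ages plant the same
    responder set.
    """
    rng = substream(cfg.seed, "planted-de")
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    genes = cfg.gene_ids()
    idx = np.sort(rng.choice(cfg.n_genes, size=n_de, replace=False))
    signs = rng.choice([-1, 1], size=n_de)
    return {genes[i]: int(s) for i, s in zip(idx, signs)}


def simulate_expression(
    cfg: SimulationConfig,
    age_label: str,
    truth: SyntheticTruth | None = None,
    planted: dict[str, int] | None = None,
) -> tuple[ExpressionTable, SyntheticTruth]:
    """Two-group expression table for one age with planted DE genes.

    Planted genes have a true group-mean difference sign * |N(effect_mean,
    effect_sd)| (magnitudes drawn per age, identities and signs shared);
    all other genes have zero true difference; per-gene detection flags are
    Bernoulli(frac_detected), independent of DE status.
    """
    truth = truth if truth is not None else SyntheticTruth()
    if planted is None:
        planted = planted_de_genes(cfg)
    genes = cfg.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene universe: {sorted(unknown)[:5]}")

    rng = substream(cfg.seed, f"expression:{age_label}")
    k = cfg.n_samples_per_group
    baseline = rng.normal(7.0, 1.0, cfg.n_genes)
    effects = np.zeros(cfg.n_genes)
    if planted:
        mags = np.abs(rng.normal(cfg.effect_size_mean, cfg.effect_size_sd, len(planted)))
        for (g, sign), mag in zip(sorted(planted.items()), mags):
            effects[gene_index[g]] = sign * mag
    noise = rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, 2 * k)) if cfg.noise_sd > 0 else np.zeros((cfg.n_genes, 2 * k))
    detected = rng.random(cfg.n_genes) < cfg.frac_detected

    values = baseline[:, None] + noise
    values[:, k:] += effects[:, None]
    sample_ids = [f"{age_label}_ctrl_{j + 1}" for j in range(k)] + [
        f"{age_label}_trt_{j + 1}" for j in range(k)
    ]
    group = np.array(["control"] * k + ["treated"] * k, dtype=object)
    table = ExpressionTable(genes, sample_ids, values, group, detected)
    truth.planted_de_fly[age_label] = dict(planted)
    return table, truth


def simulate_ortholog_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Human -> fly ortholog rows with reciprocal-best flags.

    Base rows pair human gene H_i with fly gene g_i; a fraction of human
    genes gains a second fly ortholog (which then also has two human
    contributors, exercising the dedup rule); a fraction of rows fails the
    best-forward / best-reverse filter.
    """
    rng = substream(cfg.seed, "orthologs")
    n = cfg.n_genes
    fly = cfg.gene_ids()
    rows: list[tuple[str, str]] = [(cfg.human_gene_for(i), fly[i]) for i in range(n)]
    n_multi = int(np.ceil(cfg.frac_one_to_many * n)) if cfg.frac_one_to_many > 0 else 0
    if n_multi:
        chosen = rng.choice(n, size=n_multi, replace=False)
        offsets = rng.integers(1, n, size=n_multi)
        for i, off in zip(chosen, offsets):
            rows.append((cfg.human_gene_for(int(i)), fly[int((i + off) % n)]))
    table = pd.DataFrame(rows, columns=["human_gene", "fly_gene"])
    table["best_forward"] = "yes"
    table["best_reverse"] = "yes"
    n_bad = int(round(cfg.frac_nonreciprocal * len(table)))
    if n_bad:
        bad = rng.choice(len(table), size=n_bad, replace=False)
        which = rng.integers(0, 3, size=n_bad)
        bf = table["best_forward"].to_numpy(copy=True)
        br = table["best_reverse"].to_numpy(copy=True)
        bf[bad[which != 1]] = "no"
        br[bad[which != 0]] = "no"
        table["best_forward"] = bf
        table["best_reverse"] = br
    return table[ORTHOLOG_COLUMNS]


def simulate_human_de(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    ortholog_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cell-type human DE gene lists with direction.

    One designated cell type (the first; emulating the inhibitory-neuron
    finding) carries the conserved signal: frac_conserved of the planted
    fly DE genes reappear as human DE via the reversed reciprocal-best
    mapping, with the sign flipped in a fraction (1 - sign_concordance) of
    cases; its remaining DE genes are drawn from human genes whose
    orthologs are NOT planted fly DE genes.  Every other cell type is an
    independent draw from the whole human universe with random signs.
    With frac_conserved = 0 no cell type is planted and all draws are
    independent of the fly truth.
    """
    planted_fly = truth.fly_planted_union()
    fly_in_table = set(ortholog_table["fly_gene"])
    stray = {g for g in planted_fly if g not in fly_in_table}
    if stray:
        raise ValueError(
            f"truth/table inconsistency: planted fly genes missing from the "
            f"ortholog table: {sorted(stray)[:5]}"
        )
    rng = substream(cfg.seed, "human-de")
    recip = filter_reciprocal_best(ortholog_table)
    human_universe = sorted(set(ortholog_table["human_gene"]))
    fly_to_humans: dict[str, list[str]] = {}
    for h, f in zip(recip["human_gene"], recip["fly_gene"]):
        fly_to_humans.setdefault(f, []).append(h)

    candidates = sorted(g for g in planted_fly if g in fly_to_humans)
    n_cons = min(int(round(cfg.frac_conserved * len(planted_fly))), len(candidates))
    conserved_fly = sorted(rng.choice(candidates, size=n_cons, replace=False)) if n_cons else []
    conserved: dict[str, int] = {}
    truth.conserved_pairs = []
    for f in conserved_fly:
        h = min(fly_to_humans[f])
        fly_sign = planted_fly[f]
        same = rng.random() < cfg.sign_concordance
        human_sign = fly_sign if same else -fly_sign
        conserved[h] = human_sign
        truth.conserved_pairs.append((h, f, "same" if same else "opposite"))

    # humans whose reciprocal orthologs include any planted fly DE gene
    planted_orth_humans = {
        h for f in planted_fly for h in fly_to_humans.get(f, [])
    }
    celltypes = cfg.celltype_names()
    planted_ct = celltypes[0] if conserved else None
    truth.planted_celltype = planted_ct
    truth.planted_human_de = {}

    rows: list[tuple[str, str, str, float]] = []
    for ct in celltypes:
        signs: dict[str, int] = {}
        if ct == planted_ct:
            signs.update(conserved)
            pool = [h for h in human_universe if h not in planted_orth_humans and h not in signs]
        else:
            pool = [h for h in human_universe if h not in signs]
        n_bg = max(0, cfg.n_human_de_per_celltype - len(signs))
        n_bg = min(n_bg, len(pool))
        if n_bg:
            picked = rng.choice(pool, size=n_bg, replace=False)
            bg_signs = rng.choice([-1, 1], size=n_bg)
            for h, s in zip(picked, bg_signs):
                signs[str(h)] = int(s)
        p_adj = rng.uniform(1e-6, 0.05, size=len(signs))
        for (h, s), q in zip(sorted(signs.items()), p_adj):
            rows.append((ct, h, "up" if s > 0 else "down", float(q)))
        truth.planted_human_de[ct] = dict(sorted(signs.items()))
    return pd.DataFrame(rows, columns=HUMAN_DE_COLUMNS)


def simulate_go_annotation(
    cfg: SimulationConfig, truth: SyntheticTruth
) -> GeneSetCollection:
    """GO-style annotation; planted terms are packed with planted DE genes
    of a single direction (alternating up/down across planted terms)."""
    if cfg.genes_per_term > cfg.n_genes:
        raise ValueError(
            f"genes_per_term ({cfg.genes_per_term}) exceeds n_genes ({cfg.n_genes})"
        )
    rng = substream(cfg.seed, "go-annotation")
    genes = np.array(cfg.gene_ids(), dtype=object)
    planted = truth.fly_planted_union()
    up_pool = np.array(sorted(g for g, s in planted.items() if s > 0), dtype=object)
    down_pool = np.array(sorted(g for g, s in planted.items() if s < 0), dtype=object)

    sets: dict[str, frozenset] = {}
    truth.planted_enriched_terms = {}
    for t in range(cfg.n_go_terms):
        term = f"GO:{t + 1:07d}"
        if t < cfg.n_planted_terms:
            direction = "up" if t % 2 == 0 else "down"
            pool = up_pool if direction == "up" else down_pool
            take = min(cfg.genes_per_term, len(pool))
            members = set(rng.choice(pool, size=take, replace=False)) if take else set()
            if len(members) < cfg.genes_per_term:
                rest = np.array(sorted(set(genes) - members), dtype=object)
                members |= set(
                    rng.choice(rest, size=cfg.genes_per_term - len(members), replace=False)
                )
            truth.planted_enriched_terms[term] = direction
        else:
            members = set(rng.choice(genes, size=cfg.genes_per_term, replace=False))
        sets[term] = frozenset(str(g) for g in members)
    return GeneSetCollection(sets, frozenset(genes))
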
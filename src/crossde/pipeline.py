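"""End-to-end orchestration: simulate -> DE per age -> enrichment ->
age-overlap Fisher tests -> ortholog translation -> background
harmonization -> per-cell-type overlap tests.

Two simulated "ages" (young / old) are independent experiments sharing one
planted responder gene set.  Every stage writes its plain-text output to
the run directory and the run is summarised in ``summary.json``; a
``manifest.json`` records the configuration hash and SHA-256 of every
output file, so rerunning an identical configuration is verifiable as
bit-identical (timestamps live outside the hashed payload).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .diffexpr import DEModelParams, fit_moderated_t, filter_detected
from .enrichment import (
    ENRICHMENT_CUTOFF,
    call_enriched_terms,
    fisher_overlap_terms,
    significant_terms,
)
from .orthomap import (
    filter_reciprocal_best,
    harmonize_background,
    transfer_directions,
    translate,
)
from .overlap import overlap_test
from .simulate import (
    SimulationConfig,
    SyntheticTruth,
    planted_de_genes,
    simulate_expression,
    simulate_go_annotation,
    simulate_human_de,
    simulate_ortholog_table,
)

AGES = ("young", "old")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    de: DEModelParams = field(default_factory=DEModelParams)
    enrichment_cutoff: float = ENRICHMENT_CUTOFF
    overlap_method: str = "auto"
    mc_draws: int = 0  # >0 adds a Monte-Carlo cross-check per overlap test
    outdir: str = "crossde_run"

    def __post_init__(self) -> None:
        if not 0 < self.enrichment_cutoff < 1:
            raise ValueError("enrichment_cutoff must lie in (0, 1)")
        if self.mc_draws < 0:
            raise ValueError("mc_draws must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "de" in d and isinstance(d["de"], dict):
            d["de"] = DEModelParams(**d["de"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    files: dict[str, str]  # relative path -> sha256
    versions: dict[str, str]
    timestamp: str

    def to_json(self, path: str | Path) -> None:
        io.write_json(dataclasses.asdict(self), path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = config.to_dict()
    payload.pop("outdir", None)  # hash the scientific configuration only
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full chain and return the run manifest.

    Outputs (in ``config.outdir``): simulated inputs, per-age DE tables and
    enrichment tables, per-(age, cell type) overlap gene tables, truth.json,
    summary.json, manifest.json.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.simulation
    truth = SyntheticTruth()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    ortho = stage("simulate_ortholog_table", simulate_ortholog_table, cfg)
    io.write_ortholog_table(ortho, out / "orthologs.tsv")

    planted = stage("plant_de_genes", planted_de_genes, cfg)
    tables = {}
    for age in AGES:
        tables[age], truth = stage(
            f"simulate_expression[{age}]", simulate_expression, cfg, age, truth, planted
        )
        io.write_expression(tables[age], out / f"expression_{age}.tsv")
    collection = stage("simulate_go_annotation", simulate_go_annotation, cfg, truth)
    io.write_gmt(collection, out / "go_annotation.gmt")
    human_de = stage("simulate_human_de", simulate_human_de, cfg, truth, ortho)
    io.write_human_de(human_de, out / "human_de.tsv")
    truth.to_json(out / "truth.json")

    de: dict[str, pd.DataFrame] = {}
    detected: dict[str, pd.DataFrame] = {}
    sig_genes: dict[str, set[str]] = {}
    enr: dict[str, pd.DataFrame] = {}
    enr_terms: dict[str, dict[str, set[str]]] = {}
    for age in AGES:
        de[age] = stage(f"diffexpr[{age}]", fit_moderated_t, tables[age], config.de)
        io.write_de_results(de[age], out / f"de_{age}.tsv")
        detected[age] = filter_detected(de[age])
        sig_genes[age] = set(detected[age].loc[detected[age]["significant"], "gene_id"])
        enr[age] = stage(
            f"enrichment[{age}]",
            call_enriched_terms,
            detected[age],
            collection,
            config.enrichment_cutoff,
        )
        enr[age].to_csv(out / f"enrichment_{age}.tsv", sep="\t", index=False, float_format="%.10g")
        enr_terms[age] = significant_terms(enr[age])
    io.write_json(
        {"de": dataclasses.asdict(config.de), "simulation": dataclasses.asdict(cfg)},
        out / "de_params.json",
    )

    # age comparison: shared DE genes (Fisher over the common detected
    # universe) and shared enriched GO terms (Fisher over the tested terms)
    common_universe = set(detected["young"]["gene_id"]) & set(detected["old"]["gene_id"])
    a = sig_genes["young"] & common_universe
    b = sig_genes["old"] & common_universe
    gene_odds, gene_p = stage(
        "fisher_overlap_genes", fisher_overlap_terms, a, b, common_universe
    )
    term_universe = set(enr["young"]["term_id"]) & set(enr["old"]["term_id"])
    terms_young = (enr_terms["young"]["up"] | enr_terms["young"]["down"]) & term_universe
    terms_old = (enr_terms["old"]["up"] | enr_terms["old"]["down"]) & term_universe
    term_odds, term_p = stage(
        "fisher_overlap_terms", fisher_overlap_terms, terms_young, terms_old, term_universe
    )

    # cross-species translation and per-cell-type overlap tests
    recip = stage("filter_reciprocal_best", filter_reciprocal_best, ortho)
    human_universe = set(ortho["human_gene"])
    translated_universe = translate(human_universe, recip).fly_genes
    celltypes = sorted(set(human_de["cell_type"]), key=list(human_de["cell_type"]).index)
    overlap_summary: dict[str, dict[str, dict]] = {}
    backgrounds: dict[str, int] = {}
    for age in AGES:
        fly_universe = set(detected[age]["gene_id"])
        background = stage(
            f"harmonize_background[{age}]",
            harmonize_background,
            fly_universe,
            translated_universe,
        )
        backgrounds[age] = len(background)
        fly_sign = {
            g: (1 if lfc > 0 else -1)
            for g, lfc in zip(detected[age]["gene_id"], detected[age]["log_fc"])
        }
        overlap_summary[age] = {}
        for ct in celltypes:
            sub = human_de.loc[human_de["cell_type"] == ct]
            hsigns = {
                str(g): (1 if d == "up" else -1)
                for g, d in zip(sub["gene"], sub["direction"])
            }
            translated_dir = transfer_directions(hsigns, recip)
            cand_h = set(translated_dir) & background
            cand_f = sig_genes[age] & background
            result = stage(
                f"overlap[{age},{ct}]",
                overlap_test,
                [cand_f, cand_h],
                background,
                directions=[fly_sign, translated_dir],
                method=config.overlap_method,
            )
            if config.mc_draws > 0:
                result_mc = overlap_test(
                    [cand_f, cand_h],
                    background,
                    method="monte_carlo",
                    n_draws=config.mc_draws,
                    seed=cfg.seed,
                )
                extra = {"mc_p_value": result_mc.p_value}
            else:
                extra = {}
            overlap_summary[age][ct] = {**result.to_dict(), **extra}
            obs = pd.DataFrame(
                {
                    "gene": result.observed_genes,
                    "fly_direction": [fly_sign.get(g, 0) for g in result.observed_genes],
                    "human_direction": [translated_dir.get(g, 0) for g in result.observed_genes],
                    "class": [result.gene_classes[g] for g in result.observed_genes],
                }
            )
            obs.to_csv(out / f"overlap_genes_{age}_{ct}.tsv", sep="\t", index=False)

    summary = {
        "de_counts": {age: len(sig_genes[age]) for age in AGES},
        "shared_de_genes": sorted(a & b),
        "n_shared_de_genes": len(a & b),
        "age_gene_overlap": {"odds_ratio": gene_odds, "p_value": gene_p, "universe": len(common_universe)},
        "enriched_terms": {
            age: {k: sorted(v) for k, v in enr_terms[age].items()} for age in AGES
        },
        "age_term_overlap": {"odds_ratio": term_odds, "p_value": term_p, "universe": len(term_universe)},
        "backgrounds": backgrounds,
        "celltype_overlap": overlap_summary,
        "planted_celltype": truth.planted_celltype,
    }
    io.write_json(summary, out / "summary.json")

    files = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    versions = {
        "crossde": _package_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=cfg.seed,
        files=files,
        versions=versions,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__


def load_summary(outdir: str | Path) -> dict:
    return io.read_json(Path(outdir) / "summary.json")


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema-check pipeline input files; returns violations, never raises
    on content problems (unreadable files do raise).

    Recognised keys: expression (TSV + sidecars), ortholog_table, human_de,
    gmt, truth.
    """
    violations: list[str] = []

    def check_expression(path: Path) -> None:
        try:
            table = io.read_expression(path)
        except Exception as exc:  # content problem -> violation
            violations.append(f"expression {path}: unparseable ({exc})")
            return
        if len(table.sample_ids) < 4:
            violations.append(f"expression {path}: fewer than 2 samples per group")

    def check_ortho(path: Path) -> None:
        df = io.read_ortholog_table(path)
        for col in ("human_gene", "fly_gene", "best_forward", "best_reverse"):
            if col not in df.columns:
                violations.append(f"ortholog_table {path}: missing column {col}")
                return
        for col in ("best_forward", "best_reverse"):
            bad = df.loc[~df[col].isin({"yes", "no"}), col]
            for idx, val in bad.items():
                violations.append(
                    f"ortholog_table {path}: row {idx} has {col}={val!r} (expected yes|no)"
                )

    def check_human(path: Path) -> None:
        df = io.read_human_de(path)
        for col in ("cell_type", "gene", "direction", "p_adj"):
            if col not in df.columns:
                violations.append(f"human_de {path}: missing column {col}")
                return
        bad = df.loc[~df["direction"].isin({"up", "down"})]
        for idx in bad.index:
            violations.append(
                f"human_de {path}: row {idx} direction={df.loc[idx, 'direction']!r} (expected up|down)"
            )

    def check_gmt(path: Path) -> None:
        for i, line in enumerate(Path(path).read_text().splitlines()):
            if line.strip() and len(line.split("\t")) < 3:
                violations.append(f"gmt {path}: line {i + 1} has fewer than 3 fields")

    def check_truth(path: Path) -> None:
        try:
            SyntheticTruth.from_json(path)
        except Exception as exc:
            violations.append(f"truth {path}: unparseable ({exc})")

    checkers = {
        "expression": check_expression,
        "ortholog_table": check_ortho,
        "human_de": check_human,
        "gmt": check_gmt,
        "truth": check_truth,
    }
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        base = kind.split(":", 1)[0]
        if base in checkers:
            checkers[base](path)
        else:
            violations.append(f"unknown input kind {kind!r}")
    return violations
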
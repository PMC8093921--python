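"""Reading and writing the pipeline's plain-text formats.

Expression tables are TSV (first column gene_id, header row of sample ids)
with two sidecar TSVs: ``<stem>.samples.tsv`` (sample_id, group) and
``<stem>.genes.tsv`` (gene_id, detected).  Gene sets use GMT (term,
description, members, tab-separated).  Everything else is TSV or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .diffexpr import DE_COLUMNS, ExpressionTable
from .enrichment import GeneSetCollection
from .orthomap import ORTHOLOG_COLUMNS

_FLOAT_FMT = "%.10g"


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".samples.tsv"), stem.with_suffix(".genes.tsv")


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(table.values, index=table.gene_ids, columns=table.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    samples_path, genes_path = _sidecar_paths(path)
    pd.DataFrame({"sample_id": table.sample_ids, "group": table.group}).to_csv(
        samples_path, sep="\t", index=False
    )
    pd.DataFrame(
        {"gene_id": table.gene_ids, "detected": np.where(table.detected, "true", "false")}
    ).to_csv(genes_path, sep="\t", index=False)


def read_expression(path: str | Path) -> ExpressionTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples_path, genes_path = _sidecar_paths(path)
    samples = pd.read_csv(samples_path, sep="\t")
    genes = pd.read_csv(genes_path, sep="\t")
    group_of = dict(zip(samples["sample_id"], samples["group"]))
    detected_of = dict(
        zip(genes["gene_id"], genes["detected"].astype(str).str.lower() == "true")
    )
    return ExpressionTable(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        group=np.array([group_of[s] for s in df.columns], dtype=object),
        detected=np.array([detected_of[g] for g in df.index], dtype=bool),
    )


def write_de_results(results: pd.DataFrame, path: str | Path) -> None:
    results[DE_COLUMNS].to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)


def read_de_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    df["detected"] = df["detected"].astype(bool)
    df["significant"] = df["significant"].astype(bool)
    return df


def write_gmt(collection: GeneSetCollection, path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = []
    for term in sorted(collection.sets):
        desc = descriptions.get(term, "na")
        members = "\t".join(sorted(collection.sets[term]))
        lines.append(f"{term}\t{desc}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> GeneSetCollection:
    sets: dict[str, frozenset] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {i + 1} has fewer than 3 fields")
        sets[fields[0]] = frozenset(fields[2:])
    if background is None:
        background = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(background))


def write_ortholog_table(table: pd.DataFrame, path: str | Path) -> None:
    table[ORTHOLOG_COLUMNS].to_csv(Path(path), sep="\t", index=False)


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", dtype=str)


def write_human_de(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)


def read_human_de(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
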
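"""Translation of human gene lists into fly gene space.

The mapping table carries one row per (human_gene, fly_gene) candidate pair
with best-forward / best-reverse flags; only reciprocal-best rows (both
flags 'yes') survive filtering.  Translation then takes the union of the
fly orthologs of the input genes: one human gene mapping to several fly
orthologs contributes all of them, several human genes mapping to the same
fly ortholog contribute it once.  Gene identifiers are opaque
case-sensitive strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

ORTHOLOG_COLUMNS = ["human_gene", "fly_gene", "best_forward", "best_reverse"]
_FLAG_VALUES = {"yes", "no"}


def validate_ortholog_table(table: pd.DataFrame) -> None:
    """Check column schema, flag values and (human, fly) pair uniqueness."""
    missing = [c for c in ORTHOLOG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ortholog table missing columns: {missing}")
    for col in ("best_forward", "best_reverse"):
        bad = ~table[col].isin(_FLAG_VALUES)
        if bad.any():
            row = table.index[bad][0]
            raise ValueError(
                f"malformed {col} value {table.loc[row, col]!r} in row {row} "
                f"({table.loc[row, 'human_gene']} -> {table.loc[row, 'fly_gene']})"
            )
    if table.duplicated(subset=["human_gene", "fly_gene"]).any():
        raise ValueError("duplicate (human_gene, fly_gene) pairs in ortholog table")


def filter_reciprocal_best(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only reciprocal-best rows (best_forward == best_reverse == 'yes')."""
    validate_ortholog_table(table)
    keep = (table["best_forward"] == "yes") & (table["best_reverse"] == "yes")
    return table.loc[keep].reset_index(drop=True)


@dataclass
class TranslatedSet:
    """Result of translating a human gene set into fly space."""

    fly_genes: set[str]
    provenance: dict[str, set[str]]  # fly gene -> contributing human genes
    dropped: set[str]  # human genes with no surviving mapping

    def __post_init__(self) -> None:
        if set(self.provenance) != self.fly_genes:
            raise ValueError("provenance keys must equal fly_genes")


def translate(human_genes: Iterable[str], table: pd.DataFrame) -> TranslatedSet:
    """Map a human gene set through a (reciprocal-best filtered) table.

    One-to-many mappings expand; many-to-one mappings collapse to a single
    fly gene counted once; human genes with no surviving row are reported
    in ``dropped``.
    """
    human_set = set(human_genes)
    provenance: dict[str, set[str]] = {}
    hit: set[str] = set()
    sub = table.loc[table["human_gene"].isin(human_set)]
    for h, f in zip(sub["human_gene"], sub["fly_gene"]):
        provenance.setdefault(f, set()).add(h)
        hit.add(h)
    return TranslatedSet(set(provenance), provenance, human_set - hit)


def transfer_directions(
    human_signs: Mapping[str, int], table: pd.DataFrame
) -> dict[str, int]:
    """Carry per-human-gene signs (+1/-1) into fly space.

    A fly gene whose contributing human genes disagree in sign gets 0
    ('mixed'); used for concordance annotation only, never for overlap
    counting.
    """
    translated = translate(human_signs.keys(), table)
    out: dict[str, int] = {}
    for fly, humans in translated.provenance.items():
        signs = {human_signs[h] for h in humans}
        out[fly] = signs.pop() if len(signs) == 1 else 0
    return out


def harmonize_background(
    fly_universe: Iterable[str], translated_universe: Iterable[str]
) -> set[str]:
    """Common background: genes measurable in both datasets.

    All downstream overlap tests condition on this set; an empty
    intersection means the datasets share no comparable universe and is an
    error.
    """
    fly = set(fly_universe)
    trans = set(translated_universe)
    if not fly or not trans:
        raise ValueError("both universes must be nonempty")
    common = fly & trans
    if not common:
        raise ValueError("no genes in common between the two universes")
    return common
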
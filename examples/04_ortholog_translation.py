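"""Translate a human gene list into fly gene space.

Applies the reciprocal-best filter (BestForward = BestReverse = yes), then
the two translation rules: one human gene with several fly orthologs
contributes all of them, several human genes sharing one fly ortholog
count it once.  The common background for any later overlap test is the
intersection of the fly universe with the translated human universe.
"""

from crossde import (
    SimulationConfig,
    filter_reciprocal_best,
    harmonize_background,
    simulate_expression,
    simulate_ortholog_table,
    translate,
)

cfg = SimulationConfig(seed=42)
ortho = simulate_ortholog_table(cfg)
recip = filter_reciprocal_best(ortho)
print(f"{len(ortho)} ortholog rows, {len(recip)} reciprocal-best")

human_list = sorted(set(ortho.human_gene))[:200]
translated = translate(human_list, recip)
multi = {f: hs for f, hs in translated.provenance.items() if len(hs) > 1}
print(f"200 human genes -> {len(translated.fly_genes)} fly genes, "
      f"{len(translated.dropped)} dropped (no reciprocal-best mapping)")
print(f"fly genes with several human contributors (deduplicated): {len(multi)}")

table, _ = simulate_expression(cfg, "old")
fly_universe = {g for g, d in zip(table.gene_ids, table.detected) if d}
translated_universe = translate(set(ortho.human_gene), recip).fly_genes
background = harmonize_background(fly_universe, translated_universe)
print(f"harmonized background: {len(background)} genes "
      f"(fly detected: {len(fly_universe)}, translated human: {len(translated_universe)})")
# Only genes measurable in BOTH datasets enter the background; every
# overlap probability downstream is conditioned on this set.
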
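"""Generate the four synthetic pipeline inputs and peek at the ground truth.

Emulates a two-age, five-replicate fly brain expression study, a GO-style
annotation, a human-fly ortholog table with reciprocal-best flags, and
per-cell-type human DE lists carrying a planted, sign-discordant copy of
part of the fly signal.
"""

from crossde import (
    SimulationConfig,
    SyntheticTruth,
    simulate_expression,
    simulate_go_annotation,
    simulate_human_de,
    simulate_ortholog_table,
)

cfg = SimulationConfig(seed=42)
truth = SyntheticTruth()

ortho = simulate_ortholog_table(cfg)
table, truth = simulate_expression(cfg, "old", truth)
collection = simulate_go_annotation(cfg, truth)
human_de = simulate_human_de(cfg, truth, ortho)

planted = truth.planted_de_fly["old"]
print(f"expression: {len(table.gene_ids)} genes x {len(table.sample_ids)} samples, "
      f"{int(table.detected.sum())} detected")
print(f"planted DE genes: {len(planted)} "
      f"({sum(1 for s in planted.values() if s > 0)} up, "
      f"{sum(1 for s in planted.values() if s < 0)} down)")
print(f"ortholog rows: {len(ortho)}, reciprocal-best: "
      f"{int(((ortho.best_forward == 'yes') & (ortho.best_reverse == 'yes')).sum())}")
print(f"GO terms: {len(collection.sets)}, planted enriched: {len(truth.planted_enriched_terms)}")
print(f"human DE lists: {human_de.cell_type.nunique()} cell types, planted cell type: "
      f"{truth.planted_celltype}, conserved pairs: {len(truth.conserved_pairs)} "
      f"(all {truth.conserved_pairs[0][2]!r} at sign_concordance={cfg.sign_concordance})")
# Every conserved pair links a planted fly DE gene to a human DE gene with,
# by default, the opposite direction of change - the fully reciprocal regime.
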
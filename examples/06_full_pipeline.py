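"""Run the whole chain and read the summary.

simulate -> DE per age -> GO enrichment per age -> Fisher tests for the
between-age sharing of DE genes and enriched terms -> ortholog translation
and background harmonization -> per-cell-type human-fly overlap tests with
direction concordance.
"""

import tempfile

from crossde import PipelineConfig, SimulationConfig, run_all
from crossde.pipeline import load_summary

with tempfile.TemporaryDirectory() as outdir:
    config = PipelineConfig(simulation=SimulationConfig(seed=42), outdir=outdir)
    manifest = run_all(config)
    summary = load_summary(outdir)
    print(f"{len(manifest.files)} output files, config hash {manifest.config_hash[:12]}")

print(f"DE genes: young {summary['de_counts']['young']}, old {summary['de_counts']['old']}, "
      f"shared {summary['n_shared_de_genes']} "
      f"(Fisher p = {summary['age_gene_overlap']['p_value']:.2e})")
terms = summary["enriched_terms"]
print(f"enriched terms: young {sum(map(len, terms['young'].values()))}, "
      f"old {sum(map(len, terms['old'].values()))} "
      f"(overlap p = {summary['age_term_overlap']['p_value']:.2e})")
print(f"backgrounds: {summary['backgrounds']}")
print(f"planted cell type: {summary['planted_celltype']}")
for ct, res in summary["celltype_overlap"]["old"].items():
    flag = " *" if res["p_value"] < 0.05 else ""
    print(f"  old vs {ct:>3}: k={res['k_observed']:>2} (exp {res['expected']:.1f}) "
          f"p={res['p_value']:.2e} disc={res['discordant']}{flag}")
# Only the planted cell type shows a significant human-fly overlap, and
# every shared gene there changes in opposite directions in the two
# species - the structure the generator plants by default.
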
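# Methods

## The analysis the package implements

The pipeline compares a two-condition expression experiment in a model
organism ("fly"), run at two ages with n = 5 replicates per group, against
per-cell-type human differential-expression (DE) gene lists, asking two
questions: (i) how much of the transcriptional response is shared between
the two ages, and (ii) whether the fly response overlaps the human
per-cell-type DE lists more than chance once both gene universes are
mapped into a common (fly ortholog) space — and, where it does, whether
the shared genes change in the same or in opposite directions in the two
species.

## Differential expression

Per gene, groups are compared by the moderated t statistic: the pooled
within-group variance s²_g on d_g = n₁ + n₂ − 2 df is shrunk toward a
prior variance s²₀ carrying d₀ prior df,

    s̃²_g = (d₀ s²₀ + d_g s²_g) / (d₀ + d_g),
    t_g  = logFC_g / (s̃_g √(1/n₁ + 1/n₂)),   t_g ~ t(d₀ + d_g) under H₀,

with logFC = mean(treated) − mean(control) on the (log-like) input scale.
When d₀, s²₀ are not supplied they are estimated by moment matching on
log s²_g under the scaled-F model s²_g ~ s²₀ F(d_g, d₀): the mean and
variance of log s²_g are matched to their digamma/trigamma expressions,
and the trigamma equation is inverted by Newton iteration.  When the
observed spread of log variances does not exceed the chi-square floor the
estimate is d₀ = ∞ (all genes share s²₀ = exp(mean adjusted log s²)); at
the other extreme d₀ = 0 reduces exactly to the classical pooled t, which
is the verifiable anchor used throughout the tests.  Genes with zero
pooled variance under d₀ = 0 have no defined p; they are flagged (NaN)
and never called significant.

BH adjustment is the step-up rule adj_(i) = min_{j≥i} min(1, p_(j)·m/j),
applied in one vectorized pass; ties need no extra rule.  Significance is
adjusted p < α (default 0.05) AND detected.  The detection flag is an
abstract presence call: undetected genes stay in the DE output but are
removed from the analysis universe (`filter_detected`) and hence from
every ranked list and overlap background downstream.

## Ranked lists and set enrichment

The description "sorted by log-fold change and p-value" is ambiguous; the
package resolves it as: primary key = sign of logFC (positive block
first), secondary key = p ascending inside the positive block and p
descending inside the negative block.  This realizes both required list
shapes simultaneously — the most confidently up-regulated genes head the
up_to_down list and the most confidently down-regulated genes tail it —
and down_to_up is the exact reversal.  Exact ties in (sign, p) are emitted
in id-lexicographic order (reproducibility) but share an average rank.

A term of m genes in a list of n is scored by W = Σ ranks; the one-sided
p = P(W ≤ observed) under uniform placement.  The null counts are the
coefficients of the Gaussian binomial [n m]_q, built by multiplying
(1 − q^{n−m+i}) and dividing by (1 − q^i) for i = 1..m over a length
m(n−m)+1 coefficient array; the per-(n, m) cumulative table is cached, so
testing many same-sized terms costs one DP.  The exact path is used when
the state count m(n−m) ≤ 10⁶ (configurable `max_states`) and the list has
no tied keys; otherwise a normal approximation with continuity correction
and the standard tie correction of the rank-sum variance takes over.
Coefficients are held in float64; they are exact integers up to n ≈ 30
and carry ~1e-15 relative error at n = 1000, far inside every tolerance
asserted.  Tests are one-sided because direction is carried by the two
list conventions; a term may in principle fire in both lists and is then
reported in both rows.  The significance cutoff is the fixed p ≤ 1e-05
(no extra correction across terms is applied, by design).  Between-age
sharing of enriched-term sets is assessed by one-sided Fisher's exact
over the universe of terms tested in both ages (scipy implementation; a
standard step, not part of the contribution).

## Ortholog translation and background

Only reciprocal-best rows survive (`best_forward` = `best_reverse` =
"yes"; any other value than yes/no is a named error).  Translation takes
the union of fly orthologs: one-to-many expands, many-to-one counts the
fly gene once, unmapped human genes are reported as dropped.  Identifiers
are opaque case-sensitive strings.  When a fly gene has several human
contributors with conflicting directions its transferred sign is "mixed"
(0) — used only for concordance annotation, never for overlap counting.
The common background is fly-detected ∩ translate(human universe); all
candidate sets are restricted to it and every overlap probability
conditions on its size N.  An empty intersection is an error (no
comparable universe).

## Exact multi-set overlap test

Model: the m candidate sets are independent uniform subsets of fixed
sizes n_i of the N-gene background.  |A₁∩A₂| ~ Hypergeom(N, n₁, n₂);
given a running intersection of size s, intersecting with A_j is
Hypergeom(N, s, n_j); the DP propagates the full distribution, entirely
in log space with log-sum-exp, so upper tails are accurate to the limits
of float64 (`log_intersection_pvalue` stays finite even beyond the
~1e-308 underflow point of the probability itself).  p = P(X ≥ k_obs),
the enrichment (upper-tail) convention; for m = 2 the closed-form
hypergeometric survival function is used and labelled "fisher", to which
the DP is identical to 1e-10.  A Monte-Carlo path drawing literal random
subsets serves as an independent oracle and as an optional cross-check in
the pipeline.  Per-cell-type tests are reported unadjusted (a
BH-across-cell-types view can be obtained by applying `bh_adjust` to the
summary p-values).  Concordance on the observed genes: concordant = same
sign in both species, discordant = opposite, mixed = ambiguous or
uncovered (uncovered genes trigger a warning).

## The synthetic generator

What it emulates, and the default study conditions (all in
`SimulationConfig`; one master seed feeds named substreams, one per
artifact, so regenerating one artifact never perturbs another):

- **Expression** (per age): baseline ~ N(7, 1) per gene; noise N(0,
  noise_sd = 0.3) per cell — a typical residual spread for log2-scale
  expression data; n_genes = 2000 (desk-scale stand-in for the several
  thousand genes such studies analyse); 5 replicates per group (the
  design this emulates); frac_de = 0.05 planted DE genes shared by both
  ages (identity and Rademacher sign; magnitudes |N(1.0, 0.3)| drawn per
  age, i.e. clear but not extreme responders ~2-fold on log2 scale).
  Detection is Bernoulli(frac_detected = 0.9) per gene, independent of DE
  status, standing in for a presence call on measured transcripts.
- **Orthologs**: base bijection H_i ↔ g_i; 10% of human genes gain a
  second fly ortholog (which thereby also gains a second human
  contributor, exercising the dedup rule); 20% of rows fail the
  reciprocal-best filter (one or both flags "no").
- **GO annotation**: 50 terms × 20 genes; 6 planted terms filled from
  planted DE genes of a single direction (alternating up/down).
- **Human DE lists**: n_human_de_per_celltype = 150 genes per cell type
  (per-cell-type DEG lists in the single-cell literature run from
  hundreds to thousands; 150 of 2000 genes keeps that proportion).  One
  designated cell type (the first, "In") carries the conserved signal:
  frac_conserved = 0.4 of the planted fly DE genes reappear as human DE
  through the reversed reciprocal-best mapping, each with probability
  sign_concordance (default 0 — fully reciprocal regulation) of keeping
  its sign.  The planted cell type's remaining DE genes are drawn from
  human genes whose orthologs are NOT planted fly DE genes, so its
  overlap statistic measures the planted signal rather than incidental
  collisions; all other cell types are independent uniform draws from the
  whole human universe with random signs — the built-in null contrast.
  With frac_conserved = 0 no cell type is planted and all six are
  independent null draws.

What it does **not** model: probe-level array physics, single-cell count
noise, batch effects, correlated genes, age-specific effect magnitudes
beyond an independent redraw, or human effect sizes (only direction is
consumed downstream).  Passing tests therefore demonstrate the
correctness and calibration of the statistical chain under its stated
model, not robustness to the failure modes of real platforms.

## Numerical and design choices

- One-sided tests throughout enrichment and overlap; direction lives in
  the list conventions / the upper tail.
- Exact-vs-approximate switch: DP states m(n−m) ≤ 10⁶ (enrichment);
  overlap is always exact (its DP is O(m·k_max²) and cheap).
- p-values are clipped into (0, 1]; log-scale tails are exposed where
  underflow is reachable.
- Degenerate inputs: empty/full member sets, sets larger than the
  background, empty universes, <2 samples per group, and malformed flags
  are all named errors; whole-universe GO terms are skipped with a
  warning.
- Determinism: every stage is a pure function of (config, seed); the run
  manifest hashes every output file (sha256) and the scientific
  configuration (output directory excluded), so identical configurations
  are verifiably bit-identical.  Timestamps are recorded but not hashed.
- Problem sizes in the test suite (n_genes = 2000–5000, 100-seed null
  replicates, 10⁵ Monte-Carlo draws, 10⁶ placement draws) are chosen so
  the whole suite runs in well under a minute per file on one CPU while
  keeping Monte-Carlo standard errors far below the asserted tolerances.

## Known limitations

- The moderated-t prior estimator is plain moment matching; no robust
  variant, no trend on average expression.
- Enrichment ignores the GO graph (no parent-term propagation) and
  applies a fixed cutoff rather than FDR across terms — deliberately, to
  match the procedure it re-implements.
- The exact rank-sum path requires an untied ranking; with tied keys the
  corrected normal approximation is used even for small lists.
- Only two-species, fly-space comparison is implemented; the human-space
  direction of the same analysis is not.
- Per-cell-type human universes are identical in the generator (real
  studies have cell-type-dependent measurable universes; the pipeline
  handles that case, the generator just does not produce it).
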
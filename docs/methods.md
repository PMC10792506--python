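# Methods

## The statistical procedure

### Per-experiment differential expression

Each experiment is a two-group (control vs stress) matrix of log2
intensities. `compute_de_table` applies a Welch unequal-variance *t* test per
gene with `logFC = mean(stress) − mean(control)`; `call_degs` thresholds at
`p < p_threshold` and `|logFC| > lfc_threshold` (defaults 0.05 and 1.0, both
strict) and signs the call by `sign(logFC)`. A gene with `logFC` exactly 0
is never a DEG. P-values are raw by default — the "at least one experiment"
logic downstream presumes per-test error control — with an optional
Benjamini–Hochberg adjustment (`adjust="bh"`).

The Welch test is a deliberate design choice: the pipeline accepts either
expression matrices or precomputed DE tables, so users with
moderated-statistics output (e.g. from an empirical-Bayes fit) can feed
those tables in directly and skip the built-in test entirely.

### Stable unidirectional DEGs

The cross-experiment rule is vote counting with a binomial significance
bound. If each experiment falsely calls a directional DEG with probability
`p₀`, the chance of `k` or more calls in `n` experiments is the binomial
upper tail; `min_consistent_experiments(n, p₀, α)` returns the smallest `k`
with tail < α (strict). With `n = 5, p₀ = α = 0.05` the cutoff is `k* = 2`
(tail at 2 is 0.0226). A gene qualifies only if *all* its nonzero calls
share one sign — the all-or-nothing reading of "consistently activated or
consistently suppressed"; a single opposite call disqualifies it. Genes
missing from an experiment (platform differences) have their `n` reduced
rather than being counted as non-calls: absence is not evidence.

### Enrichment, STF, SCWP

For TF *t* in experiment *e*: universe `N` = CWP genes of the network
measured in *e*; `K` = *t*'s CWP targets in the universe; `n` = DEGs in the
universe; `k` = overlap. The p-value is the exact hypergeometric upper tail
`P(X ≥ k)` (scipy's survival function; no normal approximation), strict
`p < α_enrich = 0.05` for the enriched flag. TFs with no target in the
universe are flagged degenerate (p = 1, never enriched, never prioritised).

**STF** counts enriched experiments; priority TFs have `STF ≥ 1`.
**SCWP**(g) counts distinct TFs with a `regulates` edge onto *g*. Rankings
are descending by score with lexicographic tie-breaks, so outputs are
deterministic.

Two decisions deserve emphasis:

* **Universe choice.** Within the pipeline, the universe is the CWP set of
  the network *as it stands before the stable-DEG TF restriction* (i.e.
  after orphan pruning and the process filter). Shrinking the universe to
  the post-restriction network would concentrate it on DEG-rich targets and
  mask genuine enrichment — in the extreme, a universe equal to a TF's own
  target set gives p = 1 regardless of the data. `compute_enrichment` takes
  `universe_net` explicitly so either convention can be used.
* **SCWP network.** By default SCWP is computed on the reduced
  (priority-TF) network (`scwp_mode="reduced"`); `"prefilter"` computes it
  on the network before reduction. Both are legitimate readings of
  "connections between the cell wall gene and TFs in the gene network", and
  which network a published score used is not always recoverable; neither
  mode is asserted as canonical.

### Network filtering

`prune_unconnected_targets` removes CWP genes with no incoming TF edge
(idempotent). `filter_tfs_by_process` keeps TFs whose process annotations
match the drought filter — by default exact, case-insensitive matching
against the four process names `response to water deprivation`,
`obsolete drought tolerance`, `drought recovery`, `response to water`; a
substring mode (e.g. keyword `drought`) is available. Metabolite `affects`
edges onto TFs are annotation only: carried through every filter, never
scored. All filters are monotone (results are sub-networks), so the
stage-by-stage node counts in the run manifest form a non-increasing funnel.

## The synthetic-data generator

The generator emulates the targeted study design: ~5 Affymetrix-style
two-group leaf experiments over ~800 cell-wall genes, with a sparse
TF → CWP network. What it models:

* **Network.** `n_planted_tf` drought TFs each regulate exactly
  `planted_target_count` targets (drawn without replacement); each
  non-planted (TF, CWP) pair carries an edge independently with
  `edge_prob_background`. Planted TFs carry the annotation
  `response to water deprivation` with probability `frac_annotated_drought`
  (default 1). Background TFs carry a drought annotation
  (`response to water`) with probability `frac_background_drought`
  (default 0.25) so the process filter has genuine negatives to remove, and
  a neutral transcription annotation otherwise.
* **Expression.** Per gene: baseline `μ_g ~ Normal(8, 1)` and a direction
  `±1`, both drawn once and held fixed across experiments — planted signal
  is unidirectional by construction, because that is the structure the
  stable-DEG rule exists to detect. Per experiment, a gene is a true DEG
  with rate `q_hi = 0.5` if it is a planted-TF target *or a planted TF
  itself*, else `q_lo = 0.05`; true DEGs shift the stress mean by
  `direction × Δ` (`Δ = 2`) over Gaussian noise (`σ = 0.5`, 3 replicates
  per group). Planted TF genes share the elevated rate because real
  drought regulators are themselves drought-responsive; without this, the
  stable-DEG TF restriction would remove the very regulators the planted
  scenario is meant to recover.
* **Determinism.** One master seed; the network, the per-gene baselines and
  each experiment use fixed derived sub-streams, so adding an experiment
  never perturbs earlier ones and identical seeds give byte-identical
  fixtures.

Parameter defaults and rationale: `edge_prob_background = 0.02` gives
background regulons of ~16 targets over 800 genes — sparse but large enough
for the enrichment test to have a sampling distribution; `q_lo = 0.05`
matches the nominal per-experiment false-call budget; `q_hi = 0.5` and
`Δ = 2, σ = 0.5` give per-target detection power near 0.95, so planted TFs
are strongly but not deterministically enriched. The baseline scale
(`Normal(8, 1)`) is arbitrary: every downstream statistic is shift-based.

What the generator does **not** model: probe-level effects, normalisation
artefacts, correlated noise between genes, batch effects, secondary
(indirect) regulation, or literature-derived edge confidence. Passing the
recovery tests therefore demonstrates the pipeline's statistical logic, not
its robustness to those real-data complications.

## Numerical and degenerate-input choices

* Strict inequalities throughout (`p < 0.05`, `|logFC| > 1`, tail `< α`), so
  boundary values never pass.
* Zero variance in both groups with equal means yields p = 1 (no evidence),
  not NaN.
* Hypergeometric and binomial tails come from scipy's exact survival
  functions; the test-suite cross-checks them against rational-arithmetic
  enumeration over every parameter combination with N ≤ 12 (and all 2ⁿ call
  patterns for n ≤ 12).
* Empty networks, empty stable sets and TF-free pipelines produce empty —
  not failing — reports; score tables are sorted with documented
  lexicographic tie-breaks and floats printed at 6 significant digits.

## Problem sizes used in validation

The default recovery scenario (5 experiments × 860 genes × 6 samples,
60 TFs) runs in under a second per seed; validation uses 20 seeds for
recovery and 50 seeds for null calibration, with the null compendium scaled
to 20 TFs × 200 genes. These sizes were chosen so the complete validation
suite characterises calibration and recovery to within a few standard
errors while staying interactive.

## Known limitations

* The binomial rule treats experiments as exchangeable Bernoulli trials; it
  ignores differing power across experiments and correlation between them.
* STF is a count of significant experiments, not an effect-size estimate; a
  TF with marginal enrichment in many experiments can outrank one with
  overwhelming enrichment in a single experiment.
* SCWP is raw in-degree: it inherits any ascertainment bias present in the
  input network (well-studied TFs contribute more edges).
* No multiple-testing correction is applied across TFs or experiments by
  default; with hundreds of TFs, `STF ≥ 1` at α = 0.05 will include false
  positives (the BH option mitigates this at the cost of power).
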
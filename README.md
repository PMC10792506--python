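# drynet

Prioritising transcription factors (TFs) and cell-wall-protein (CWP) genes
involved in the plant leaf response to water deficit, from a compendium of
two-group expression experiments and a directed TF → target regulatory
network.

Water deficit remodels the plant cell wall, and the proteins embedded in it
are both effectors and sensors of that remodelling. Given (a) several
independent control-vs-drought expression experiments and (b) a regulatory
network linking TFs to genes encoding cell-wall proteins, `drynet` answers
two questions: *which TFs most plausibly drive the cell-wall transcriptional
response*, and *which cell-wall genes sit under the heaviest regulatory
pressure*. It is aimed at plant systems biologists who already have (or can
text-mine) a TF–target network and want a reproducible, statistically
grounded ranking rather than a hand-curated shortlist.

## Method

1. **Per-experiment DEG calling.** For each experiment, each gene gets a
   Welch two-group comparison on log2 intensities; it is a DEG when
   `p < 0.05` and `|log2FC| > 1` (both strict), signed by the direction of
   change.
2. **Stable DEGs by binomial vote counting.** A gene measured in *n*
   experiments and called with the same sign in *k* of them is a *stable
   unidirectional DEG* when the binomial upper tail `P(X ≥ k | n, p₀)` falls
   below α, with per-experiment null call rate `p₀ = 0.05` and `α = 0.05`.
   For a five-experiment compendium the cutoff is `k* = 2`.
3. **Network filtering.** CWP genes with no TF regulator are pruned; TFs are
   restricted to those annotated with drought-related biological processes
   (`response to water deprivation`, `obsolete drought tolerance`,
   `drought recovery`, `response to water`), then to TFs that are themselves
   stable DEGs.
4. **TF scoring (STF).** For each TF and each experiment, the overlap *k*
   between the TF's *K* CWP targets and the experiment's *n* DEGs within a
   universe of *N* measured network CWP genes is scored with the exact
   hypergeometric upper tail `P(X ≥ k)`. **STF** = number of experiments
   with `p < 0.05`. TFs with `STF ≥ 1` are *priority TFs*.
5. **Reduction and gene scoring (SCWP).** The network is reduced to priority
   TFs, their targets and the edges among them. **SCWP**(g) = number of
   distinct TFs regulating gene *g*; higher STF/SCWP means higher priority.

A synthetic-data generator plants known drought TFs with enriched target
sets in a simulated compendium, so the whole chain is testable end to end
against ground truth.

## Worked example

`examples/03_prioritize_tfs.py` simulates the default scenario (60 TFs, six
of them planted drought regulators with 30 targets each, 800 CWP genes,
five experiments) and runs the scoring:

```
top 10 TFs by STF (experiments with enriched target sets):
  TF0002  STF=5 <- planted
  TF0008  STF=5 <- planted
  TF0026  STF=5 <- planted
  TF0028  STF=5 <- planted
  TF0043  STF=5 <- planted
  TF0055  STF=5 <- planted
  TF0016  STF=1
  ...
priority TFs (STF >= 1): 9
reduced network: 9 TFs, 193 CWP genes
top 5 cell-wall genes by SCWP (distinct regulators in the reduced net):
  CWP0271  SCWP=3
  ...
```

All six planted TFs are enriched in all five experiments (STF = 5) and head
the ranking; three background TFs reach STF = 1 by chance at the 5% test
level. Genes with SCWP = 3 are targeted by three priority regulators at
once — the strongest candidates for regulatory hubs of the cell-wall
response. `examples/04_full_pipeline.py` runs the same analysis through the
file-based pipeline and prints the filter funnel
(60 TFs / 800 CWPs → pruned → process-filtered → stable-filtered → reduced).

The same steps are available from the shell:

```sh
drynet simulate --out fixtures --seed 1
drynet run --config config.yaml --out results
```

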
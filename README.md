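# ctsdimer

Analysis toolkit for CTCF/BORIS co-occupancy and differential chromatin
binding, built around *clustered CTCF target sites* (2xCTS).

CTCF organises the 3D genome through tens of thousands of target sites
(CTSes); in the male germline its paralog BORIS (CTCFL) co-occupies the
subset of sites that contain **two closely spaced copies of the ~20-bp CTCF
consensus** — clustered CTSes — where the two proteins can bind side by
side.  When CTCF becomes limiting in the absence of BORIS, binding is lost
preferentially from these co-occupied sites, and the gene-expression program
anchored at them degrades.  `ctsdimer` implements the computational pipeline
used to characterise this biology, for genomicists who have peak calls,
coverage tracks and count matrices and want the downstream analysis to be
reproducible and testable:

* **Peak overlap classes** — CTCF/BORIS vs CTCF-only vs BORIS-only by the
  ≥ 1 bp reciprocal-intersection rule, plus merged composite peak sets.
* **Motif classes** — PWM log-odds scanning on both strands around peak
  summits; peaks labelled 0x / 1x / 2x-or-more with inter-motif spacing.
* **Differential occupancy** — tracks normalized to 10 million mapped reads;
  per-peak tag densities; strict more-than-twofold categories
  (WT>CM / WT=CM / WT<CM); occupancy-reduction percentages with a rank-sum
  (Wilcoxon) test; anchored profile matrices at 10-bp resolution with
  k-means (optionally rank-normalized) clustering.
* **Annotation** — promoter+5'UTR (TSS ± 3 kb) / gene body / intergenic
  classes; peak↔gene assignment (± 2 kb); promoter-bound flags (TSS ± 2 kb).
* **Expression integration** — median-of-ratios size factors; Welch-t
  differential expression with the strict DEG rule (adjusted p < 0.001 and
  fold change > 2); marker selection (adjusted p < 10⁻⁶, log2FC > 4);
  two-sided Fisher exact DEG × bound association; gene-set enrichment
  (ES/NES) with a 1000-fold gene-set-permutation null.
* **Synthetic studies** — a fully seeded generator that plants motifs,
  peaks, occupancy losses and differentially expressed genes with a
  ground-truth table, so the whole pipeline can be validated end to end.

The statistics at the core are standard and spelled out in
[`docs/methods.md`](docs/methods.md): densities are mean normalized coverage
`d(p) = (10⁷/R) · mean(cov[p.start:p.end))`; the occupancy reduction at a
site class is `100·(1 − mean(d_CM)/mean(d_WT))`; the DEG × bound association
is a hypergeometric two-tail sum over the 2×2 table; the enrichment score is
the extremum of the weighted running sum `+|t_g|/Σ_set|t|` (members) /
`−1/(N−k)` (non-members) over the t-ranked gene list.

## Worked example

Simulate a study at the default design (20-Mb genome; 1,000 single-motif and
1,000 clustered CTCF sites with mean occupancy losses of 25% and 50% in the
mutant; 300 decoy peaks; 1,500 genes with 500 true DEGs, 37% of which carry
a lost promoter site) and run the full analysis:

```python
from ctsdimer import SimulationConfig
from ctsdimer.pipeline import analyze_study, recovery_metrics
from ctsdimer.synthetic_data import simulate_study

study = simulate_study(SimulationConfig(seed=101))
summary = analyze_study(study, gsea_seed=101)
recovery = recovery_metrics(study)
```

Printing the headline numbers gives:

```text
CTCF peaks: 2300  shared with BORIS: 1000 (43%)
2x-motif fraction, shared vs CTCF-only: 1.00 vs 0.00
occupancy reduction at 1x sites: 22.3% (p = 2.11e-60)
occupancy reduction at 2x sites: 47.8% (p = 7.08e-166)
DEGs called: 451  sensitivity: 0.90  FDR: 0.00
DEGs bound within +-2 kb: 165 (37%), OR = 4.47, Fisher p = 1.03e-27
planted pathway: NES = 1.91, permutation p = 0.0016
```

Reading this: the overlap step recovers exactly the planted co-occupancy
structure (the 1,000 clustered sites are the shared class); clustered motifs
occur only under shared peaks; the measured occupancy reductions land close
to the planted 25%/50% class means (slightly below, because peak-interval
densities include a little shared background); differential expression calls
451 of the 500 planted DEGs with no false positives; 37% of called DEGs are
bound near their promoter, matching the planted association; and the planted
concordant gene set is strongly enriched while a non-DEG control set
(`PATHWAY_NULL`) is not.

The same pipeline is scriptable from the shell:

```sh
ctsdimer simulate --seed 101 --outdir sim/          # FASTA, narrowPeak, bedGraph, TSVs
ctsdimer overlap sim/wt_ctcf.narrowPeak sim/wt_boris.narrowPeak
ctsdimer diffbind sim/wt_ctcf.narrowPeak sim/cm_ctcf.narrowPeak sim/wt.bedGraph sim/cm.bedGraph
ctsdimer de sim/counts.tsv sim/conditions.tsv --out de.tsv
ctsdimer integrate de.tsv sim/wt_ctcf.narrowPeak sim/genes.tsv
ctsdimer gsea de.tsv sim/gene_sets.gmt --seed 101
ctsdimer run --seed 101 --outdir out/               # everything, summary.json + summary.tsv
```

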
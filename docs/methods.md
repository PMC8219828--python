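# Methods

This note documents the models, conventions and design choices behind
`ctsdimer`, in the spirit of a methods section: what each procedure assumes,
which knobs matter, and what the synthetic benchmark does and does not show.

## Scientific setting

CTCF is an 11-zinc-finger protein that organises chromatin; BORIS (CTCFL) is
its germline-restricted paralog with the same DNA-binding domain.  A subset of
CTCF target sites (CTSes) contains two closely spaced copies of the ~20-bp
CTCF consensus — *clustered* CTSes (2xCTS) — which permit simultaneous
occupancy by CTCF and BORIS.  When total CTCF is scarce and BORIS is absent
(the compound-mutant, CM, genotype), chromatin binding is lost preferentially
from these co-occupied sites, and the expression program that depends on them
collapses.  The package implements the computational side of that analysis:
co-occupancy classes from peak overlap, motif-count classification around
summits, library-normalised differential occupancy, promoter annotation,
differential expression, and binding–expression integration.

## Coordinate and format conventions

All coordinates are 0-based, half-open, on both strands of a plain string
genome.  BED6/narrowPeak/bedGraph are parsed with strict validation; writers
are exact inverses of readers so round-trips are byte-stable.  narrowPeak
summits are `start + offset(column 10)`; BED6 peaks get the floor midpoint as
summit, since true summits come from a peak caller this package does not run.
Chromosome names pass through verbatim.  Gene tables are TSV with an explicit
strand; the TSS is `start` on `+` and `end − 1` on `−`.

## Peak overlap and composite sets

Two peaks overlap iff they intersect by **at least 1 bp** (half-open
arithmetic, so `[100,200)` and `[199,250)` overlap while `[200,250)` does
not).  Shared status is per peak, not per matched pair: a peak is "shared" if
it overlaps *any* peak on the other side, which is how occupancy classes are
counted in ChIP-seq practice.  The composite set for differential analysis is
the transitive merge of the WT and CM peak sets; a merged peak inherits summit
and score from its highest-scoring constituent.

## Differential occupancy

Coverage tracks are scaled to a common library of 10 million mapped reads
(`value × 1e7 / mapped_reads`), applied exactly once.  Per-peak density is the
mean normalized coverage over the peak interval.  Composite peaks are split
into three categories by a strict more-than-twofold rule on the density ratio:
`WT>CM`, `WT<CM`, else `WT=CM`; a ratio of exactly 2 therefore stays in
`WT=CM`.  A pseudocount of ε = 0.1 normalized units is added to both
densities before the comparison so complete-loss sites (CM density ~0) are
categorised stably.  Comparisons are written multiplicatively
(`wt + ε > fold·(cm + ε)`) to avoid division edge cases.

Occupancy loss at a site class is summarised as
`100·(1 − mean(cm)/mean(wt))` over per-site densities, with a two-sided
unpaired rank-sum test between the WT and CM density samples.  The rank-sum
test enumerates the exact permutation distribution of the rank sum (midranks
for ties) when both groups have ≤ 8 observations, and otherwise uses the
tie-corrected normal approximation with continuity correction; both regimes
are cross-checked against independent oracles in the test suite.

## Motif scanning and CTS classes

PWM scores are log-odds in bits against a uniform background:
`log2(((f + 10⁻³)/(1 + 4·10⁻³)) / 0.25)` summed over positions; `N` bases
contribute 0 bits; the minus strand scores the reverse complement.  Regions
are scanned on both strands and windows scoring at least 80% of the maximum
achievable score are kept; overlapping windows are resolved greedily by
descending score (ties: leftmost, then `+` strand).  Greedy selection is
verified against exhaustive window enumeration on short regions.

Peaks are classified by the number of retained hits in a ±150 bp window
around the summit: `0x`, `1x`, or `2x_or_more`, with the inter-hit spacing
reported for inspection.  The window width is a package choice — wide enough
to hold a 20 + 31 + 20 bp clustered configuration with margin; no maximum
spacing or strand-orientation constraint is imposed on the 2x call.  The
80%-of-max threshold replaces an E-value calibration deliberately: it is
transparent, monotone (raising it can only remove hits) and adequate for
consensus-strength sites; weak degenerate sites that motif tools recover via
E-value statistics will be missed, which is a known limitation.

## Annotation

Location classes are keyed on the summit so they partition any peak set:
promoter/5'UTR iff the summit is within ±3 kb of a TSS (inclusive; promoter
takes precedence), else gene body, else intergenic; the nearest TSS breaks
multi-gene ties.  Gene-proximity assignment instead uses the whole peak
interval against the gene body padded by ±2 kb.  The promoter-bound flag for
a gene is true iff any peak summit lies within ±2 kb of its TSS — the
"TSS + 2 kb" promoter rule is read symmetrically, consistent with the ±2 kb
proximity rule used alongside it; a downstream-only variant is a one-line
change of `tss_flank` usage if ever needed.

## Differential expression

The DE procedure is deliberately minimal and fully specified, because the
downstream integration consumes only `(log2fc, adj_p)`:

1. median-of-ratios size factors (reference = per-gene geometric mean over
   samples, genes with any zero excluded; factor = median ratio);
2. `log2fc = log2((mean_B + 0.5)/(mean_A + 0.5))` on normalized means;
3. per-gene two-sided Welch t-test on `log2(normalized + 0.5)`;
4. Benjamini–Hochberg adjustment over all genes;
5. DEG iff `adj_p < 0.001` **and** linear fold change `> 2` in either
   direction, both strict; marker genes use `adj_p < 10⁻⁶` and
   `log2fc > 4`, upregulated only.

This replaces a negative-binomial shrinkage model (DESeq2-style) on purpose;
absolute DEG counts from deeply dispersed real tissue data are therefore not
comparable, and the synthetic benchmark is parameterised accordingly (below).

## Integration statistics

The DEG × bound association is a two-sided Fisher exact test over an
explicit, caller-supplied gene universe (the appropriate universe is a
scientific choice, not a default): p is the sum of hypergeometric
probabilities of all tables with the observed margins that are no more
probable than the observed one; the odds ratio is `ad/bc` with a Haldane
+0.5 correction when a cell is empty.  `bound_fraction_pct` and
`percent_lost` round half-up to integer percentages, matching how such
numbers are reported.

Gene-set enrichment ranks genes by a caller-chosen statistic (the pipeline
uses the Welch t), accumulates `|stat|/Σ_set|stat|` at members and
`−1/(N − n_set)` elsewhere, and takes the extremum as ES.  The null is
**gene-set permutation**: `n_perm` random same-size sets on the same ranking
(seeded, default 1000).  NES divides ES by the mean magnitude of same-sign
null scores; the permutation p compares magnitudes within the same-sign null
with the +1 correction, so p ∈ (0, 1].

## The synthetic study

The generator plants every feature the analysis is supposed to recover and
writes a ground-truth table, so recovery can be scored exactly.

**Genome and sites.** Default: 4 chromosomes × 5 Mb of uniform random
sequence.  Genes sit on a fixed 10-kb grid (3-kb bodies), and planted sites
occupy either promoter positions (±300 bp of a TSS) or intergenic slots
placed ≥ 2.1 kb away from any padded gene, so that which genes are "bound"
is unambiguous by construction.  Site classes: 1,000 single-motif (1x) sites,
1,000 clustered (2x) sites whose two consensus copies are separated by a
31-bp spacer, 200 BORIS-only sites, and 300 motif-free decoy peaks.  Planted
instances are the exact consensus: at the 80%-of-max threshold a
PWM-sampled instance (expected ~3 mismatches) would rarely score through, so
consensus planting is what makes the ≥ 95% detection property meaningful.

**Coverage.** Each CTCF-class site contributes a symmetric triangular bump
(half-width 150 bp, mimicking fragment pileup) with log-normal amplitude
(median 50, σ_log 0.3); background is Poisson noise in 20-bp blocks with
mean 5% of the median amplitude.  WT and CM tracks share the signal model;
the CM bump amplitude is `WT × (1 − r)` with a per-site loss fraction `r`.
Raw tracks are scaled to distinct library sizes (20M and 15M reads) so that
normalization is actually exercised.

**Per-site loss fractions.** `reduction_1x` and `reduction_2x` are *class
means* (defaults 0.25 and 0.50).  Per-site values are drawn from a mixture of
a severe component Beta(8,2) (mean 0.8) and a mild component Beta(2,8)
(mean 0.2), with the mixing weight solving the class mean.  A degenerate
per-class constant would make the benchmark uninformative twice over: every
2x site would sit exactly on the twofold category boundary, and no site could
ever fall below the CM peak-retention threshold, so "lost" sites could not
exist.  The mixture instead reproduces the empirically observed structure —
a subpopulation of co-occupied sites loses occupancy (almost) completely
while the class average stays at the planted value.  CM peaks are retained
iff the reduced amplitude is ≥ 30% of the WT median amplitude; sites below it
are "lost" (absent from the CM peak set).

**Expression.** Counts are negative-binomial (mean–dispersion
parameterisation) for 3 + 3 samples with per-sample depth factors in
[0.8, 1.2].  500 of 1,500 genes are true DEGs at |log2FC| = 2; 37% of true
DEGs have a lost 2x site planted in their promoter, and 10% of non-DEG genes
get a retained site (background promoter binding), which populates all four
cells of the association table.  A 52-gene set of upregulated true DEGs is
emitted as the planted concordant pathway, plus a non-DEG control set.

Expression-noise defaults are `nb_dispersion = 0.001` with mean expression
log-normal(ln 2000, 0.5).  This models deeply sequenced libraries restricted
to well-expressed genes and variability at the low end of what replicates
show.  The choice is driven by a power analysis of the DE procedure itself:
with three replicates, a per-gene Welch t has ~4 degrees of freedom, and its
tail cannot reach BH-adjusted 10⁻³ at dispersions typical of biological
tissue replicates (0.01–0.2), where shrinkage estimators would be required.
In the chosen regime the procedure has ~85–90% sensitivity at the planted
effect size with essentially zero false discoveries.  Consequently the
benchmark validates the *pipeline logic* (normalization, testing, thresholds,
integration), not the power of unmoderated t-tests on noisy tissue data.

**Determinism.** All randomness flows from a single seed through named child
streams (layout, genome, sites, coverage, expression), so a seed reproduces
every output byte-for-byte.

**What the benchmark does not emulate.** Read-level artefacts (duplicates,
GC bias, mappability), diploid genomes, motif degeneracy, peak-width
heterogeneity, correlated replicates, and incidental promoter binding away
from planted sites.  Published genome-scale counts (tens of thousands of
peaks, category totals, absolute DEG counts, data-dependent Wilcoxon
p-values) depend on the deposited sequencing data and external tool chains
and are not reproduction targets; the package recovers the *structure* —
effect-size ordering, class contrasts, association fractions — not those
absolute numbers.

## Numerical choices

* Exact-vs-approximate switch for the rank-sum test at group size 8;
  continuity correction 0.5; tie correction via the standard
  `Σ(t³−t)/(N(N−1))` term.
* Fisher two-sided summation uses a `(1 + 10⁻⁷)` relative tolerance when
  comparing table probabilities, the conventional guard against float
  round-off in "≤ observed probability".
* k-means uses seeded farthest-point initialisation, 100 restarts × ≤ 300
  Lloyd iterations, best within-cluster sum of squares kept; assignment ties
  go to the lowest cluster index, making labels reproducible.  The optional
  rank normalization replaces each row by its within-row midranks before
  clustering.
* Profile windows that run off a chromosome are zero-padded with a warning;
  minus-strand anchors have bins reversed so bin 0 is always upstream.
* Density pseudocount ε = 0.1, fold-change pseudocount 0.5, PWM pseudocount
  10⁻³ — each exposed as an argument.

## Known limitations

* The per-gene Welch t is underpowered at realistic tissue dispersions (see
  above); use a moderated model for real data of that kind.
* The motif threshold is not calibrated to a p-value/E-value; degenerate
  sites are under-counted relative to MAST-style scanning.
* `classify_location` uses the summit only; a whole-peak-overlap promoter
  definition would shift class fractions for wide peaks.
* Coverage is held densely in memory (~8 bytes/bp/track); tracks much beyond
  ~100 Mb genomes want a windowed or sparse representation.
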
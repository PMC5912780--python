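# Methods

## Scope and model

The package quantifies how a gene's chromatin and expression state relate
to the efficiency of CRISPR-Cas9 mutagenesis at that gene in early
zebrafish-style embryos. Every analysis reduces to: compute a per-gene
scalar feature from a genomics dataset, join it with a per-gene mutagenesis
efficiency (percent of alleles mutated, aggregated over guides), and report
the Spearman rank correlation with a two-sided p-value. Rank correlation is
the right statistic here because each feature is a proxy on an arbitrary
monotone scale (peak signal, coverage fraction, log intensity): any
strictly monotone rescaling of a feature leaves the result unchanged, which
the test suite asserts as an invariant.

## Coordinate conventions

All internal coordinates are 0-based half-open. GFF3/GTF (1-based
inclusive) are converted at the parsing boundary; BED/broadPeak pass
through unchanged. A TSS is the first transcribed base: minimum exon start
on `+`, maximum exon end − 1 on `-`. Unstranded transcripts are rejected
rather than guessed.

## Transcriptional units

TSSs of all transcripts of a gene are pooled and deduplicated, then
chained: consecutive sorted positions at most `cluster_gap` (default
500 nt) apart join one unit. Chaining (single linkage) was chosen because
it is deterministic, order-independent, and the natural reading of
"within 500 nt"; the alternative (diameter-bounded clustering) would need a
tie-break rule. The representative is ⌊(span min + span max)/2⌋ — the
midpoint of the cluster's span, floored to keep integer coordinates — not
the mean of all members, which would weight densely annotated promoters.
The scoring region is the strand-agnostic symmetric window
[rep − flank, rep + flank), default flank 1,000 nt. Regions are clipped at
position 0 and at the contig end when sizes are provided, but the
coefficient denominator stays the nominal 2 · flank = 2,000 nt, so clipping
can only reduce a coefficient, never inflate it.

## Feature scores

**ATAC coefficient.** Per unit: Σ signal × overlap / 2,000; per gene: the
arithmetic mean over units. Averaging coefficients (rather than averaging
per-unit correlations) is forced by the requirement that every gene carry a
single accessibility value before the gene-level correlation.

**Methylation coefficient.** The default reading of "summation of peaks
overlapping exons / total exon length" is coverage: overlap base pairs
against the gene's *merged* exon footprint, with the peak set itself merged
first. Merging exons across transcripts makes the denominator the
nonredundant exonic footprint (otherwise multi-isoform genes double-count);
merging peaks guarantees the coefficient is a true coverage fraction in
[0, 1]. The signal-weighted alternative (Σ signal × overlap / exon length,
unbounded) is available via `meth_weight="signal"` because the original
summation rule is ambiguous between the two readings.

**Promoter score.** Per hybridisation array, Σ log2(median probe
intensity) over the gene's probes; the per-array sums are averaged. Log
base 2 is microarray convention; since Spearman rho is invariant to the
constant factor between log bases, the choice cannot affect any reported
statistic. Probe intensities must be strictly positive (log domain).

**Missingness.** A gene with no units, no exons or no probes carries a
missing value, never 0 — zeros would be confounded with genuinely closed or
unmethylated genes. Every correlation is complete-case and reports its own
n; the run manifest records the n of each analysis so join attrition is
auditable.

## Statistics

`spearman` ranks with average ranks for ties and uses the t approximation
t = rho·√((n−2)/(1−rho²)) on n−2 df for the two-sided p (the behaviour of
mainstream statistics libraries); |rho| = 1 returns p = 0, and an exact
permutation p is available for n ≤ 10. `mann_whitney` reports U for the
first group, exact by enumeration when min(n) ≤ 8 without ties, otherwise
the tie-corrected normal approximation. `fisher_exact` reports the
two-sided p (sum of hypergeometric probabilities of margin-consistent
tables at most as probable as the observed one) and the sample odds ratio
a·d/(b·c), flagged infinite/undefined for zero cells. The implementations
delegate to scipy.stats; the test suite validates them against independent
oracles — the 1 − 6Σd²/(n(n²−1)) formula, rank-Pearson with ties, label
enumeration for U, and full hypergeometric enumeration for every 2×2 table
with margins ≤ 12.

Categorical rules: "low expression" means RPKM strictly below 0.5 at every
stage of the oblong-sphere → 15-somite window (a value exactly at the
threshold is "expressed"; the threshold is a boundary, and strictness is
configurable); the maternal-to-zygotic "increase" means a strictly positive
RPKM change from oblong-sphere to 50%-epiboly. p-values are reported raw,
matching how such tables are conventionally presented; Benjamini-Hochberg
adjustment is deliberately not applied by default.

Per-gene efficiency is the mean over available guide efficiencies (median
via config); guides without a recorded efficiency are ignored, genes with
none are excluded from correlations.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
sequence-level realism. One latent standard-normal "openness" per gene
drives everything:

| output | model |
|---|---|
| ATAC promoter peak | one peak per TSS cluster, centred on the cluster representative, width ~ N(800, 150²) clipped to [300, 1500] nt, signalValue = exp(a·openness + ε), ε ~ N(0, noise_sd), shared across the gene's promoters |
| ATAC background | Poisson(peak_density per kb) peaks, uniform placement, signalValue ~ lognormal(−1.5, 0.5) — openness-independent pure dilution, well below promoter scale as in real peak calls |
| methylation | peaks covering a logistic(−b·openness + ε′) fraction of the merged exon footprint (closed chromatin is methylated) |
| expression | RPKM = exp(μ_stage + c·w_stage·openness + ε) with a stage weight w that steps up between oblong-sphere and 50%-epiboly, so the zygotic rise is steeper for open genes |
| probes | 3–10 probes per gene on 2 arrays, lognormal intensities with log-mean proportional to openness |
| efficiency | Gaussian copula: z_eff = r·z_open + √(1−r²)·η with r = 2 sin(π·ρ_s/6), the Pearson coupling whose bivariate-normal Spearman equals the planted ρ_s; efficiency = 100·Φ(z_eff); 1–4 guides per gene with N(0, 2 pp) perturbations, clipped to [0, 100]; guides ≥ 10 % count as functional |

The one-peak-per-promoter placement and the low background signal scale
were chosen so the scored ATAC coefficient is a faithful rank proxy of
openness (rank correlation ≈ 0.96 at the default noise_sd = 0.1): stacking
several identical peaks inside one unit, or promoter-scale background hits,
would distort gene ranks through scoring geometry rather than biology. The
2 sin(π ρ/6) conversion makes the planted rho directly comparable to the
pipeline's estimate; residual attenuation (≈ 0.174 recovered for 0.18
planted at the defaults) comes from peak-width variability, signal noise
and background dilution, and is covered by the recovery tolerances in the
acceptance tests.

Defaults are the study conditions of the accessibility regime: 263 genes
(the sample size of the joined accessibility analysis), planted ρ_s = 0.18,
multi-TSS fraction 0.16 (the share of multi-transcript genes in a typical
fish annotation), noise_sd 0.1, background density 0.05 peaks/kb. The
entire bundle is a pure function of `SimulationConfig`; identical seeds
give byte-identical files.

What the generator does **not** model — and therefore what passing tests do
not establish about real data: sequence composition and PAM availability,
guide-position effects within a gene, mapping artefacts and batch effects,
correlated noise between assays, and the identifier-mismatch mess of real
cross-database joins (the alias-map mechanism handles the mechanics, but
the simulator's identifiers always match).

## Numerical and degenerate-input choices

Zero-length intervals are rejected at construction. Peak files are sorted
on read; writers emit gene-sorted rows with floats at 6 significant
digits, making repeated writes byte-identical. rho within 1e-14 of ±1 is
snapped to ±1 with p = 0. Empty TSS input yields an empty cluster list;
a gene whose efficiency set is empty is dropped from correlations with a
log line. An efficiency table sharing no identifiers with the annotation
is a hard error (exit code 3 from the CLI) rather than a silent n = 0.

## Problem sizes

The validation suite uses 1,000 random instances for the interval-overlap
and clustering oracles, 500 vectors for the rank-correlation oracle, all
5,550 2×2 tables with margins ≤ 12 for the Fisher oracle, 200 replicates
of 263 genes for planted-parameter recovery and 1,000 null replicates for
the type-I error rate — sizes at which the Monte-Carlo standard errors are
well inside the asserted bands while the whole suite runs in a few minutes
on one core.

## Known limitations

* The TSS-unit counts of any specific genome annotation depend on the
  annotation version; the package reproduces the procedure, not
  version-specific counts.
* The t-approximation p for Spearman is anti-conservative at very small n;
  the exact option exists but is limited to n ≤ 10.
* The promoter score assumes probes arrive pre-mapped to genes; array
  design files are out of scope.
* Efficiency aggregation over guides (mean) is a convention; with few,
  noisy guides per gene the gene-level rank can be unstable.
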
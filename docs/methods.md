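# Methods

`polproc` re-implements, as a tested pipeline, the computational procedures
used to characterize RNA polymerase II (RNAPII) processivity and its
transcriptome-wide consequences in MYC-driven tumor cells: expression
filtering against intergenic background, two differential-expression
regimes, cross-comparison DEG integration with perturbation scores and
k-means clustering, strand-aware metagene profiling with distal/proximal
ratios, hypergeometric gene-set overlaps, and median-effect drug-synergy
analysis.  Every stage is exercised end to end against a synthetic-data
generator with planted ground truth.  This note records the models, the
parameters that matter, and the design choices made where the procedure was
genuinely open.

## Processivity model

Coverage along a gene body (TSS to TES, fractional position `x` in [0, 1])
is modeled as exponential decay:

    E[depth(x)] = baseline * exp(-lambda * x)

`lambda` (dimensionless, per gene body) is the single processivity
parameter: `lambda = 0` is a fully processive polymerase (uniform
coverage), larger values collapse signal onto the 5' end.  Exponential
decay is the simplest monotone one-parameter model whose downstream
statistics have closed forms; real polymerase drop-off need not be
exponential, and nothing downstream assumes it — the metagene and ratio
code consume arbitrary coverage.

Two closed forms anchor the tests.  The aggregated 50-bin metagene profile
of genes with decay `lambda` is the discretized exponential
`100 * (e^(-lambda*j/50) - e^(-lambda*(j+1)/50)) / (1 - e^(-lambda))` for
bin `j`.  The distal/proximal ratio over equal-width windows centered a
fraction `d` apart is exactly `exp(-lambda * d)`; with the default windows
[0.05, 0.15] and [0.85, 0.95], `d = 0.8`.

### Metagene binning

Each gene body is split into `n_bins = 50` contiguous bins; the
`length mod 50` leftover bases are assigned one per bin starting from bin 1
(deterministic, bins within one base of equal).  Minus-strand genes are
reversed before binning so bin 1 is always the TSS.  Bin values are mean
depth scaled to counts per million mapped reads (CPM), then each gene is
rescaled to percentages of its own binned signal before averaging across
genes.  Per-gene rescaling — rather than pooling counts — is what removes
expression-level differences between genes, which is the point of the
percentage representation.  Genes shorter than `n_bins` bases or without
signal are excluded with a warning.

### Distal/proximal ratio

`processivity_ratio` uses fractional windows of the whole gene body by
default; explicit windows can be supplied to mimic particular intronic
amplicons.  Whole-body windows are a simplification — a pre-mRNA assay
measures intronic signal only — and an intron-aware mask can be emulated by
passing window coordinates restricted to introns.  When the proximal
signal falls below a floor (1e-6 CPM) the ratio is flagged undefined and
excluded from aggregates instead of being zero-imputed; a near-zero
denominator would otherwise produce unbounded noise.

## Expression quantification and the background filter

FPKM = `count * 1e9 / (library_size * gene_length)`; CPM =
`count * 1e6 / library_size`.  The library size excludes spike-in control
counts by default (spike-ins are exogenous controls, not library content;
`include_spike_ins_in_library=True` switches this), so CPM columns over
biological genes sum to exactly 1e6.

A gene is called expressed when its condition-level FPKM (mean over
replicates; the simplest unbiased summary) strictly exceeds the 98th
percentile of the FPKM-equivalents of intergenic segments.  Intergenic
segments are the genomic complement of gene spans, split at genes, with a
minimum length (default 200 bp) to avoid unstable tiny segments.  Their
FPKM-equivalent treats per-base depth as single-base read units:
`mean_depth * 1e9 / total_mapped_reads`.  The quantile uses linear
interpolation between order statistics — the ubiquitous default — and is
verified in tests against an independent sort-and-interpolate computation.
For a two-condition comparison, genes expressed in at least one of the two
conditions are retained.

## Differential expression

Two minimal testing regimes are provided; neither attempts to reproduce
any external package's numerics, and both are validated by type-I-error
and power simulation instead.

- `nb_wald` (count data with spike-ins): median-of-ratios size factors
  (optionally restricted to spike-ins), method-of-moments negative-binomial
  dispersion pooled across the two groups, and a Wald statistic on the
  log2 fold-change referenced to a t distribution with `n1 + n2 - 2`
  degrees of freedom.  The t reference (rather than normal) compensates for
  plug-in variance noise at small replicate numbers; under the null
  (2000 genes, 5 vs 5, dispersion 0.05) the fraction of p <= 0.05 sits at
  ~0.05.
- `moderated_t` (cohort data): per-gene pooled variances on
  log2-transformed size-factor-normalized counts, shrunk toward a prior by
  moment-matching on log variances (digamma/trigamma identities), moderated
  t with augmented degrees of freedom.

Normalization for `moderated_t` deliberately uses median-of-ratios size
factors rather than plain per-million scaling: when regulation is
asymmetric (many genes shifted in one direction, as in a tumor-vs-normal
contrast), total-count scaling transfers the shift onto every unregulated
gene as a compositional artifact; the median gene is robust to it.

The log2 fold-change is the shrinkage-free log2 ratio of normalized
condition means with a pseudocount of 0.5 added to each mean, keeping zero
groups finite and label swaps exactly antisymmetric.  Genes with zero
counts in both conditions are reported `not_expressed` with p = 1.
Regulation calls support both published threshold regimes as presets:
`cells_thz531` (fold-change >= 2, p <= 0.05) and `patients_ega`
(FDR < 0.05, no fold floor).

## Cross-comparison integration

A *common DEG* is a gene that passes the DEG criterion in every comparison
with one shared direction of regulation.  Per gene, the p-values of all
comparisons are combined with Fisher's sum of logs
(`X = -2 * sum(ln p_i) ~ chi2(2k)`); combined FDRs are Benjamini-Hochberg
adjustments of the combined p over all tested genes (not just common
DEGs — a documented, switchable choice), and the perturbation score is
`-log10(combined FDR)`.  Zero p-values are clamped to the smallest
positive float before the log.

The optimal score threshold maximizes Youden's J (sensitivity +
specificity - 1) of predicting the common-DEG label, scanning observed
scores as candidate cutpoints; ties break toward the lower, more inclusive
threshold, and genes with score >= threshold (inclusive, documented) are
retained for clustering.

Retained genes' log2 counts are standardized per gene (population SD,
ddof 0; zero-variance genes dropped with a warning) and clustered with
Euclidean k-means, k = 4, 50 k-means++ restarts by default with the best
inertia kept; restart stability is reported as the mean pairwise adjusted
Rand index across restarts.  Samples are ordered by average-linkage
hierarchical clustering on Euclidean distance, exported as Newick; a flat
cut at three clusters is the group-separation check.

## Gene-set overlaps

`overlap_test` computes the hypergeometric upper tail P[X >= k] (the
`phyper(k-1, ..., lower.tail=FALSE)` convention) against an explicitly
supplied universe — the universe is never inferred, because overlap
p-values are meaningless without it.  The tail is also evaluated in log
space (`log10_p`) so enrichments beyond double-precision range remain
exact; the linear-scale p is floored at the smallest positive float.
`ora` applies one test per GMT set with BH adjustment across the
collection.

## Drug synergy

Dose-response curves follow the median-effect equation
`fa/fu = (D/Dm)^m`, fitted on the linearized form
`log(fa/(1-fa)) = m log D - m log Dm` by weighted least squares.  The
default weights `(1 - fa)^2` are the delta-method variance weights for
multiplicative error on the fraction affected: the logit amplifies noise
near fa = 1 and an unweighted fit lets the highest doses dominate the
slope.  On noise-free data the weighted and ordinary fits coincide
exactly; `weighting="none"` selects plain OLS.  Points with fa outside
(0.005, 0.995) are excluded before the transform (they carry no
information after clamping), at least three usable points are required,
and fits with r² < 0.5 are flagged.

The combination index at an observed combination point (D1, D2, fa) is the
two-term (mutually exclusive) form `CI = D1/Dx1 + D2/Dx2` with
`Dx_i = Dm_i (fa/(1-fa))^(1/m_i)` — the convention matching a
non-constant-ratio design where one drug is fixed at a sensitizing dose
while the partner varies.  CI in [0.95, 1.05] is reported "additive";
below, synergism; above, antagonism.

## The synthetic-data generator

The generator emulates the statistical structure of the study designs the
pipeline targets; its defaults are the study conditions the tests run
under.

- **Annotation**: non-overlapping genes with log-normal lengths
  (meanlog 8.6, sdlog 0.5 — median ~5.4 kb), random strand, placed
  longest-first into free intervals; an error is raised if the footprint
  exceeds 70% of the genome, so intergenic background always exists.
- **Coverage**: gene bodies carry Poisson(baseline * exp(-lambda x))
  per-base signal (baseline 100 at the TSS by default), intergenic bases
  Poisson(intergenic_rate); `total_mapped_reads` is the rounded total
  depth.  Per-base Poisson noise, not read-level simulation: the metagene
  and ratio statistics consume depth, and read-level realism (fragment
  lengths, mappability) would add cost without changing what the
  statistics see.
- **Counts**: negative binomial with dispersion alpha = 0.05
  (variance = mu + alpha mu²), per-sample log-normal depth multipliers
  (sd 0.15) recorded as truth, 20 spike-in genes constant in expectation
  across conditions.  The cohort design defaults to 16 tumor, 4 fetal and
  5 adult samples.  Four co-regulation clusters are planted as mean shifts
  (amplitude 3 log2 units) with shapes chosen so each is a common DEG in
  both tumor-vs-control contrasts while all four remain distinct after
  per-gene standardization — tumor-specific up, tumor-and-fetal up,
  and their mirror images.  A fraction (10%) of genes is planted silent
  (near-zero baseline) to exercise the expression filter.
- **Dose-response**: Hill curves from planted (m, Dm); combinations are
  constructed by solving `D1/Dx1(fa) + D2/Dx2(fa) = target_CI` for fa, so
  additive data are exactly Loewe-consistent and planted synergy/antagonism
  produce a known CI.  Replicate noise is multiplicative log-normal
  (mean 1) on the fraction affected.

What the generator does **not** model — batch effects, isoform structure,
GC/mappability bias, heteroscedastic dispersion trends, non-exponential
polymerase drop-off, off-target drug effects — bounds what passing tests
demonstrate: the pipeline recovers planted truth under its stated noise
model, not that any biological conclusion is reproduced on real data.

## Problem sizes and numerical checks

Benchmarks run at sizes where planted-truth recovery is informative yet
fast: 40 genes x 10 kb for ratio recovery (Poisson depth 100), 400 genes /
25 samples for the full integration pipeline, 2000 genes at 5 vs 5 for DE
calibration, 150 genes for the filter benchmark.  Oracles are independent
of the implementation path: brute-force BH/Holm step procedures, exact
rational hypergeometric enumeration, chi-square closed forms, interval
arithmetic for the annotation, and the decay model's closed forms.  All
generators are exactly reproducible under a fixed seed, and the end-to-end
workflow is byte-reproducible.

## Known limitations

- The metagene and ratio stages use whole-gene-body coverage; intronic
  masking must be emulated through explicit windows.
- The DE estimators are intentionally minimal; they are calibrated under
  the generator's NB model but lack the dispersion-trend shrinkage real
  cohort analyses would use at very small replicate numbers.
- The 3-term (mutually nonexclusive) combination index is not implemented;
  the two-term form is the only convention exposed.
- BED12/GTF support covers gene/exon structure only (no CDS, no
  transcripts); BAM input is out of scope — coverage enters as bedGraph
  with an explicit mapped-read count.
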
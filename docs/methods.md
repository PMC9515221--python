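# Methods

This note documents the statistical models, the defaults and why they were
chosen, the design choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Pooled screen statistics

**Normalisation.** Between-sample scaling uses the trimmed mean of
M-values. The reference sample is the one whose 75th percentile of
library-size-scaled counts is closest to the across-sample mean of those
percentiles. For each other sample, per-guide log ratios `M` and average
log abundances `A` are computed on library-size-scaled counts; guides with
a zero in either sample are excluded; the remaining values are doubly
trimmed (30% of each M tail, 5% of each A tail, rank-based) and combined
by a precision-weighted mean with delta-method weights
`(N−x)/(Nx) + (N_r−x_r)/(N_r x_r)`; the factor is 2 to that mean, and the
factor vector is rescaled to geometric mean 1. The implementation agrees
with edgeR's `calcNormFactors(method="TMM")` to better than 1e-12 on a
composition-biased 20-guide instance (frozen as a test oracle).

**Guide fold changes.** CPM on TMM-effective library sizes, averaged over
replicates per condition, with a 0.5-CPM pseudocount in both numerator and
denominator: `log2((CPM_num + 0.5)/(CPM_den + 0.5))`. The pseudocount
keeps fold changes finite at guide dropout; 0.5 is the conventional
choice and is configurable. Replicate means (rather than per-replicate
fold changes) are used; with two replicates per arm the two options are
nearly equivalent and the mean is simpler.

**Gene rank test.** A competitive rank test: the `m` guides of a gene are
compared against all other guides by the midranks of their log2 fold
changes. The rank-sum statistic is standardised with the tie-corrected
two-sample variance multiplied by a variance-inflation factor
`VIF = 1 + (m − 1)ρ̄` accounting for correlation among guides of the same
gene; two-sided p comes from the normal approximation. `ρ̄` defaults to
0.01, the recommended small-sample value when it cannot be estimated; with
three or more replicates `estimate_guide_correlation` derives it from
within-gene correlations of log-CPM residuals. With `ρ̄ = 0` and no ties
the test reduces exactly to the two-sample Wilcoxon normal approximation
(verified against an independent implementation to 1e-10).

**Hit calling.** Essential genes are called on an end-of-experiment
versus T0 contrast (default pools the DMSO and drug arms — both carry the
essentiality signal; a single-arm contrast can be selected instead) at
FDR < 0.05 and log2FC < −2, and are excluded from drug-specific hit
calling. Sensitizers/resistance genes on the drug-versus-vehicle contrast
require adjusted p < 0.1, median guide log2FC beyond ±2, and ≥3 guides
individually beyond ±2 in the same direction. The gene-level fold change
is the median of guide fold changes — robust to one discordant guide and
consistent with the 3-of-4 concordance rule. Concordance by default uses
the same magnitude cutoff as the gene rule; a direction-only mode (sign
agreement, no magnitude) is available.

**Validation library.** All source guides of the hit genes plus
`n_nontargeting` and `n_safe_harbor` control guides sampled without
replacement from the source pools with an explicit seed. 405 hit genes at
4 guides each plus 200 + 200 controls gives the 2020-guide design.

## Differential editing

**Site detection.** RBP–ADAR fusions deposit A→I edits read as A→G on the
sequenced strand; on minus-strand transcripts the signature appears as
T→C. A pileup position is a candidate site when it lies in an annotated
transcript, matches the strand-consistent signature (reference A with G
reads on +, reference T with C reads on −), has edited reads in at least
one sample, is not in the known-SNP list, and reaches `min_depth`
(default 10; the choice mainly trades test count against power) in at
least one sample. Positions covered by transcripts of conflicting strands
are excluded as ambiguous and counted in the filter report. When several
transcripts of a gene cover a site, the region label (5′UTR/CDS/3′UTR)
comes from the longest transcript — deterministic and documented rather
than "first seen". Coordinates are 1-based in pileup I/O and 0-based
half-open internally and in BED output.

**Model.** Counts at a site follow a beta-binomial with mean `μ` and
intra-class correlation `ρ` (`α = μ(1−ρ)/ρ`, `β = (1−μ)(1−ρ)/ρ`); `ρ → 0`
recovers the binomial, which the likelihood evaluates exactly at the
boundary. Per-site maximum likelihood (`fit_betabinom`) optimises on the
(logit μ, logit ρ) scale with a Nelder-Mead search and compares against
the binomial boundary candidate.

**Test.** Per site, the null holds one mean across both conditions and
the alternative one mean per condition; both share the same dispersion, so
the likelihood ratio has one degree of freedom and is referred to χ²(1).
The shared dispersion is, by default, a single `ρ` estimated across all
sites by maximising a Cox–Reid adjusted profile likelihood under the
two-group model (per-site group means plugged in; half the summed log
observed information of those means subtracted). Two properties motivated
this choice, made before fixing the test suite's expected behaviour at
small replicate numbers: (i) a per-site `ρ` from six observations is so
noisy — and biased low, since the fitted means absorb part of the
between-replicate variance — that the χ² reference is anticonservative by
a factor ≈2 at α = 0.05; (ii) with the adjusted pooled estimate the null
distribution of p-values is uniform (KS p > 0.01 at 5000 sites) and the
empirical type-I error sits at the nominal 5%. A `dispersion="per-site"`
mode retains the purely site-local variant for data where dispersion
genuinely varies between sites; it needs on the order of ten replicates
per arm to be trustworthy.

`diff.frequency` is the pooled frequency difference
`Σalt_B/Σdepth_B − Σalt_A/Σdepth_A`. BH correction spans all sites tested
for a given contrast. Sites with zero total depth in a condition are
skipped and reported, not silently dropped.

**Filters.** Loss-of-binding sites: adjusted p < 0.05,
diff.frequency ≤ −0.1, FPKM ≥ 5 (gain mode mirrors the sign). The FPKM
criterion is evaluated on the condition with the higher expression, which
keeps sites whose host gene is expressed in at least one arm; evaluating
on the mean or a fixed condition are trivial variants and change little
when expression is stable across arms. FPKM is
`count / (length/10³ · libsize/10⁶)` with the summed annotated transcript
length per gene.

**Motif windows.** ±100 nt of genomic sequence around each site
(201 nt records), reverse-complemented for minus-strand sites so the
edited base reads as A at the window centre; windows clipped at contig
ends are flagged truncated.

## Synergy scoring

The statistic is `log10(f_AB / (f_A · f_B))` on fractional growth
(survival relative to vehicle). The published verbal formula speaks of
"growth inhibition", but the literal inhibition reading
(`i = 1 − f`) contradicts the accompanying sign convention — under it a
combination killing more than the Bliss product scores *positive*. On
survival fractions the stated convention (0 additive, negative synergy)
is an identity, so survival is the default; `log_odds_inhibition` and the
`--inhibition-mode` flag expose the literal reading for comparison. The
log base is 10 by default and always recorded in outputs, making scores
self-describing.

Viability fractions are clipped into `(1e-4, 1]` so logs stay finite at
complete kill; clipped cells are flagged and excluded from the min/max
summaries unless `--include-clipped` is given. Replicates are averaged
before scoring. The 4PL fit is bounded least squares
(`bottom + (top−bottom)/(1+(d/IC50)^h)`) with eight IC50 starts spanning
the positive dose range on a log grid; an IC50 outside the dosed range is
flagged extrapolated. Sensitivity classification is a strict comparison
against 5 µM.

## Integration

"Twofold" differential expression maps to |log2FC| ≥ 1; the DE filter is
FPKM > 1, adjusted p < 0.05, with an RPK ≥ 500 prefilter applied when the
column is present. Gene identifiers are upper-cased and Ensembl-style
version suffixes stripped before any set operation, so overlaps across
tools with different conventions behave. The three-way overlap is exact
set algebra over the seven Venn regions with sorted member lists. The
CDF-shift comparison is the two-sample Kolmogorov-Smirnov test (asymptotic
two-sided p) with ECDF step functions returned for plotting.

## Synthetic data

The generators reproduce the statistical structure each stage assumes;
their defaults are the study conditions the tests run under.

*Screen*: guide baseline abundances are log-normal (sd 0.5 in natural
log); each sample is drawn negative-binomial (dispersion 0.05) around
means rescaled to a fixed total, so planted effects also perturb the
composition as real sequencing does. Arms are T0 / DMSO / DRUG with two
replicates each — two infection replicates being the usual pooled-screen
design. Planted classes: essentials at −4 log2 in both treated arms,
sensitizers −3 and resistance +3 log2 in the drug arm, 5% of genes each;
500 reads/guide mean depth (screen depth is a free parameter of the
design; 500× is a typical well-covered screen).

*HyperTRIBE*: a synthetic chromosome of intron-less genes
(150/600/750 nt 5′UTR/CDS/3′UTR) on random strands; sites placed 92% in
3′UTRs; per-sample depth Poisson (mean 200); alt counts beta-binomial
with site-specific baseline frequency uniform on [0.2, 0.6] and
`ρ = 0.02`; targets (10%) shift by −0.3 in the second condition. SNP
contaminants sit at A(+)/T(−) reference bases with alt fraction 0.5 or
1.0 — deliberately constructed so the strand filter alone would pass
them, isolating the SNP-list filter for testing. Gene-level expression
counts (log-normal, NB-sampled) feed the FPKM filter.

*Dose-response*: single agents follow 4PL curves; the combination surface
is their Bliss product times `interaction^(w_a·w_b)` with dose weights
`w = d/d_max`, so `interaction = 1` is exact independence and the planted
minimum log-odds is `log10(interaction)` at the top dose pair; noise is
truncated Gaussian (sd 0.02, clipped to [0, 1]).

What the simulations do **not** emulate: alignment and sequencing
artifacts (PCR duplicates, mapping bias, strand bleed-through), guide
efficiency variation, introns and overlapping genes, site-to-site
dispersion heterogeneity, inter-guide correlation beyond exchangeability,
and plate effects in viability data. Passing recovery tests therefore
demonstrates correctness of the statistics under their assumed models,
not robustness to these real-data pathologies.

## Numerical choices and scale

Optimisations run on transformed scales (logit for frequencies and
intra-class correlations, log-bounded for IC50) with boundary candidates
evaluated explicitly; LRT statistics are clipped at 0; midranks with the
standard tie-corrected variance handle tied fold changes; degenerate
inputs (all-zero depths, empty condition, missing checkerboard margins)
raise typed errors rather than returning NaN.

Test-suite and acceptance problem sizes — 2000 genes for null screen
calibration, 5000 sites for editing calibration, 100 simulated curves for
IC50 recovery — were chosen as the smallest scales at which the binomial
noise of the measured error rates is comfortably inside the asserted
bands; everything runs in well under a minute per check on one core.

## Known limitations

The rank test's normal approximation is rough below ~3 guides per gene;
the pooled-dispersion editing test assumes a common `ρ` across sites; the
4PL fit assumes a monotone decreasing response with a defined top near 1;
the synergy score is undefined at complete kill and relies on the clipping
policy there; GTF parsing covers UTR/CDS features only (exon-level models
enter via BED12).
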
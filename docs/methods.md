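# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter.

## Phenotype model and F2 simulation

All phenotyped animals are `Clock^Δ19/+` heterozygotes (matching the mapping
cross, which wheel-tested heterozygotes only). The period of individual *i*
is

    period_i = base + e_het · (1 − s · d_i / 2) + ε_i,   ε_i ~ N(0, σ²)

where `d_i ∈ {0,1,2}` is the suppressor-allele dose at the causal marker.
Defaults: `base = 23.7 h` (typical B6 wild-type free-running period),
`e_het = 0.6 h`, `s = 1.0` (full suppression at two doses, half at one —
the semidominant pattern reported for the suppressor), `σ = 0.25 h`
(realistic per-animal period SD). Suppression is parameterized
multiplicatively on the mutant effect, not on baseline period, because the
suppressor diminishes the mutation's effect rather than shortening wild-type
period. The recovery analyses use `σ = 0.42 h`, at which the locus explains
~20% of phenotypic variance in the F2 — a typical behavioral-QTL effect
size and the regime the recovery rates are quoted for.

Meioses are simulated as Markov chains along each chromosome with
inter-marker recombination fractions from the Haldane map function
`r = (1 − e^(−2d/100))/2` (no interference) — the simplest standard model,
adequate for single-chromosome scan validation.

## Chi-square periodogram

For trial period `P` bins, the series is folded into `K = ⌊N/P⌋` complete
cycles and

    Q_P = K · Σ_h (M_h − M)² / s²,    s² = Σ_i (x_i − M)² / (K·P)

over the `K·P` bins used; under an i.i.d. null `Q_P ≈ χ²(P−1)`, which the
suite verifies by simulation (mean `Q_P ≈ P−1` within 3 SE over 500 runs).
Trial periods step in whole bins (resolution = bin width, 0.1 h at 6-min
bins); non-integer folds are truncated to complete cycles. The significance
line is the `χ²(P−1)` quantile at `α = 0.001` (the conventional level in
circadian software). "Amplitude" is operationalized as `Q_P(peak)` minus its
significance line — one defensible choice; the field uses several. A
zero-variance series is flagged arrhythmic rather than scored.

Known limitation: with short records the statistic favors trial periods
that fit more complete cycles (the `K·P` factor), biasing the peak toward
periods dividing the record length. With 1-week records this can displace a
24.5-h rhythm to 24.0 h even without noise; with 2-week records (the
simulations' choice for recovery-rate checks, consistent with multi-week
constant-darkness protocols) recovery within one bin exceeds 95% at
signal-to-noise 2.

## QTL scan and permutation thresholds

Marker regression uses the free genetic model: phenotype ~ genotype class
as an unordered 3-level factor, `F = MS_between/MS_within`,
`LRS = n·ln(RSS_null/RSS_genotype)`. No interval mapping between markers —
at the marker densities simulated (40–87 markers) single-marker regression
is faithful and simpler. Missing genotypes are dropped marker-wise (no
imputation). An exact genotype–phenotype determination returns an infinite
statistic with a `degenerate` flag rather than a silent large number.

Genome-wide thresholds: phenotypes are permuted against genotype rows,
the maximum LRS across markers recorded per permutation, and the threshold
at level α is the empirical (1−α) quantile. Default levels {0.63, 0.05,
0.001} follow the suggestive/significant/highly-significant convention.
The permutation scan is vectorized across permutations (group sums via
per-marker indicators); phenotype columns are centered first to avoid
catastrophic cancellation in the sums-of-squares shortcut when phenotypes
are near-constant. Exclusion of the mutation's own chromosome from scanning
is the caller's responsibility via marker selection.

## Two-way ANOVA and strain classification

A strain is called a suppressor when the strain × Clock-genotype
interaction is significant: a background that shifts wild-type and mutant
periods equally (a pure main effect) is not a suppressor. Unbalanced tables
use Type II sums of squares — interaction is the tested term and Type II is
the common convention when it is tested last; balanced designs are
decomposition-invariant, which the suite checks against a hand
sums-of-squares oracle. Classic (non-Welch) ANOVA, matching the df
conventions of the era's reports. `α = 0.05` throughout. Tukey HSD uses the
studentized-range distribution with pooled variance (scipy), with
simultaneous CIs verified by a joint-coverage simulation.

## Haplotype concordance mapping

Divergence of strain *s* from the reference in window *w* is the fraction
of non-missing calls that differ. Windows default to 25 consecutive SNPs
(SNP-count windows, because marker density is uneven; bp windows are an
option). A window is phenotype-concordant iff every suppressor strain with
defined divergence has `d ≥ τ_hi` and every non-suppressor `d ≤ τ_lo`;
defaults `τ_hi = 0.20`, `τ_lo = 0.02` separate ancestral divergent segments
(dense variation) from identity-by-descent tracts (near zero) with a wide
margin, and both are exposed. Runs of concordant windows merge into
candidate intervals. Missing calls never count as differences; the QTN
filter's strict mode drops any column with a missing call. The reference
strain belongs to the non-suppressor class by definition of the cross.
Coordinates are 0-based half-open internally (BED dialect on disk).

The ancestry check assigns each strain the subspecies (Dom/Mus) covering
the majority of the interval by bp, flagging partial coverage; the verdict
requires every suppressor to be Dom and every non-suppressor Mus.

## Co-expression prioritization and allele-specific expression

Candidate genes are z-scored across tissues (`(x − mean)/SD` per gene — the
per-gene normalization a per-tissue color code requires), the clock
centroid is the mean z-profile of the reference clock genes, and candidates
with Pearson correlation ≥ 0.6 to the centroid are selected. This
centroid-correlation rule replaces an unspecified hierarchical clustering;
the threshold is exposed and the selection is invariant to per-gene affine
rescaling of raw copy numbers.

The qPCR estimator assumes efficiency-2 kinetics, under which
`ΔCt = Ct(ref assay) − Ct(alt assay) = log2(f/(1−f))`, i.e. `logit f` is
linear in ΔCt with slope `ln 2`. The standard curve is fit on genomic
mixtures (defaults 25/50/75%), inverted at the observed cDNA ΔCt, with a CI
from the curve's residual SD on the logit scale. The ΔCt sign convention
(larger ΔCt ⇒ more alternate allele) is a package choice. Colony counts use
the exact binomial: Clopper–Pearson CI and a two-sided exact test against
the 50:50 genomic expectation. Chromatogram peak ratios are corrected by a
1:1-mixture calibration ratio so dye/incorporation bias cancels;
`f = r/(1+r)`. The three estimators are checked for joint consistency on
data simulated from one true fraction (0.5 and 0.8).

## Saturation binding

One-site hyperbola `y = B_max·x/(K_d + x)` by default — binding theory for
a single site implies a Hill coefficient of 1. The "four-parameter" form
`y = y0 + (B_max − y0)·x^h/(K_d^h + x^h)` (baseline + Hill slope, the common
graphing-software dose–response parameterization) is available. Unweighted
least squares by default (optional 1/y weighting); positivity-constrained;
initial values `B_max = max(y)`, `K_d = median(x)`; SEs are asymptotic
(curvature-based). A fitted Kd more than 10× outside the sampled
concentration range triggers an extrapolation warning; non-convergence is
flagged, never silently defaulted. Parameter equality across series uses
the extra-sum-of-squares F test (shared-parameter joint fit vs per-series
fits), whose null p-values the suite checks for uniformity. Simulation
regimes use the reported Kd range 0.7–60 nM with 5% CV noise and
triplicates. Cooperative tandem-complex binding models are out of scope.

## Peak co-occupancy

Overlap is defined on summit distance — `|summit_a − summit_b| ≤ 240 bp`
inclusive (summit ± 120 bp windows) — not interval intersection
(interval mode exists behind a flag). A peak counts once toward overlap
regardless of partner multiplicity. "CLOCK:BMAL1 sites", the co-occupancy
denominator, is operationalized as the summit-merged union of the CLOCK and
BMAL1 peak sets: summits chaining within 240 bp collapse into one site at
their score-weighted mean summit (idempotent merge); the exact merge rule
behind the published totals is not recoverable, so the definition is
recorded in every report and the published ratios are reproduced as
arithmetic on the printed counts. Top-N intensity comparisons break score
ties by (score desc, chrom, start) for determinism and use the two-sided
Wilcoxon rank-sum. Motif counting scans exact occurrences (CACGTG is its own
reverse complement, so one strand suffices; other motifs are scanned on both
strands); ambiguous bases never match. narrowPeak summit offsets of −1
default to the interval midpoint with a warning.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure each stage assumes —
semidominant phenotype effects with Haldane recombination; a shared
ancestral divergent haplotype over the causal interval versus per-strain
background divergence; rectified-sinusoid activity with additive noise;
hyperbolic binding with multiplicative (CV) noise truncated at zero; paired
peak sets with controlled shared counts and Gaussian summit jitter on both
sides of a shared anchor; ideal-efficiency ΔCt mixtures and binomial colony
counts. They do not emulate genotyping error, linkage disequilibrium beyond
the simulated map, activity-onset shape or ultradian structure, gel
quantification artifacts, or read-level ChIP-seq noise — so passing
recovery tests demonstrate correctness of the statistics under their own
assumptions, not robustness to every artifact of real data. The strain
count (8 suppressor + 7 non-suppressor + reference), SNP density (2000 SNPs
/ 30 Mb), cross size (n = 222 with 40–87 markers), colony totals (~172) and
the 80:20 expression bias mirror the study's scales. The promoter
polymorphism table in `socmap.datasets` is a synthetic reconstruction (the
real table is unpublished) encoding the reported structure: 16 strains, 14
polymorphisms, exactly 7 perfectly phenotype-concordant.

Problem sizes in the recovery analyses (50 crosses for QTL recovery, 500
permutations + 400 null scans for threshold calibration, 100 panels per
haplotype condition, 200 binding fits, 400 null comparisons, 500
periodogram null runs) were chosen so that 3-sigma binomial/CLT tolerances
are meaningful at desk scale.

## Orchestration

Stages run in dependency order from one config; each stochastic stage
derives its stream from the global seed salted with the stage name (CRC32),
so adding a stage never shifts another's stream. The manifest records the
config hash, per-stage parameters and seeds, and SHA-256 checksums of every
output; identical config + inputs reproduce identical checksums for
deterministic stages. Config validation lists all schema violations before
any stage runs; a stage failure aborts downstream stages and leaves a
partial manifest. The analysis scripts and library functions are the
interface; no shell subcommand layer is shipped.
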
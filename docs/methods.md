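# Methods

## Measurement model

A read is *telomeric* when it contains the contiguous 24-mer
(TTAGGG)₄ or (CCCTAA)₄ as an exact substring. Matching is exact by
design: the tandem repeat is not allowed mismatches or interruptions, `N`
never matches, and a read counts once no matter how many occurrences or
orientations it contains. Case is normalized to uppercase on input since
FASTQ/BAM case carries no meaning. Both unit (`--unit`) and copy number
(`--copies`) are configurable; counts are non-increasing in the copy
number.

For aligned input the default read filters drop duplicate, QC-fail,
secondary and supplementary records and keep unmapped reads. Telomeric
reads mostly fail to align to a reference, so dropping unmapped records
would discard precisely the signal; the remaining defaults are standard
WGS hygiene. All four filters are flags, and the filter/motif settings
are recorded in every count so that a tumor–normal comparison with
mismatched settings is refused. Mates of a pair are counted
independently: the unit of evidence is the read.

Average genomic coverage is `total retained sequenced bases / genome
length` by default (`all_read_bases`). An `aligned_bases` basis (sum of
aligned query lengths) is available for BAM workflows. The all-bases
default is deliberate: unaligned telomeric reads contribute to the
library regardless of mappability, and both members of a pair are
normalized identically so the choice cancels in ΔT to first order. The
genome length is a scalar or the summed contig lengths of a FASTA `.fai`
index; N-gap exclusion is not attempted.

The per-patient statistic is

    ΔT = log2( (telomeric_tumor / coverage_tumor)
             / (telomeric_normal / coverage_normal) ).

If either normalized count is exactly zero, a pseudocount (default 0.5)
is added to *both* numerator and denominator and the record is flagged;
nonzero pairs are never perturbed, so ΔT is exactly antisymmetric in the
two samples whenever no pseudocount fires.

No GC-content adjustment is applied; at the ~43% GC of the telomeric
motif no Illumina abundance bias is expected, and the matched-pair ratio
would largely cancel a residual one.

## Cohort classification

Cohort ΔT values are modeled as a univariate Gaussian mixture. Candidate
models are every G in {1,2,3,4} crossed with equal/unequal component
variance. Each candidate is fitted by EM and scored by

    BIC = 2·logL − p·ln(n),   p = (G−1) + G + (1 or G variances),

larger being better; the grid is scanned in parsimony order (smaller G
first, equal variance first) with strict improvement, so ties resolve to
the simpler model. G = 1 uses the closed-form maximum-likelihood fit.

EM details: initialization splits the sorted data into G equal-count
quantile blocks (block means/proportions, pooled variance); 10 restarts
are run as one vectorized batch, the 9 extra restarts jittering the means
by N(0, sd/2) with a seeded generator; convergence is a relative
log-likelihood change below 1e-8 with at most 1000 iterations; a restart
that converges leaves the batch. Variances are floored at 1e-6 to
prevent singular components. The log-likelihood sequence is
non-decreasing (an EM guarantee; the fit records its trace and the test
suite asserts it). Component labels are canonicalized to ascending
means. All-identical input is rejected as degenerate for G ≥ 2.

Classification under the two-component winner (means μ₁ < μ₂, sds σ₁,
σ₂, significance α = 0.01, z = Φ⁻¹(0.99) ≈ 2.326):

    gain boundary = μ₁ + z·σ₁        loss boundary = μ₂ − z·σ₂

A sample above only the gain boundary rejects membership in the lower
component (one-sided upper tail) and is a **gain**; below only the loss
boundary, a **loss**; between them, **no change**. One-sided tails are
the natural reading of "reject the cluster you are drifting away from";
a two-sided variant is available by flag. When the components are far
apart the two boundaries cross and a sample can exceed both; such
samples are assigned by maximum posterior (lower component → loss,
upper → gain), which preserves the monotone loss → no-change → gain
ordering in ΔT. The classifier requires G = 2; an unequal-variance
winner is accepted with per-component σ in the boundaries and a warning.

Concordance with external assays: qPCR mode restricts to WGS gain/loss
calls and scores the sign of the external log-ratio against the call
(no-change is excluded as ambiguous); FISH mode maps gain → "abnormal"
and loss/no-change → "normal" and scores exact label agreement. Both
report percent agreement over the matched ids.

## Association statistics

Structural-variation and non-silent mutation burdens are compared
between the gain group and the pooled loss/no-change group with the
Mann-Whitney rank-sum test (the groups are unpaired; a paired
signed-rank variant is provided for matched designs). Exact enumeration
is used when the pooled sample is ≤ 20 and tie-free, otherwise the
tie-corrected normal approximation with continuity correction. The two
branches agree closely at the crossover (mean |Δp| < 0.01 for groups of
7–9; worst case ≈ 0.015 near p = 0.5, a property of the standard normal
approximation). An empty group yields an NA result rather than an
error — a cohort with no gains is a finding, not a failure. Raw
p-values are reported; no multiple-testing correction is applied.

## Synthetic data

The read simulator emits fixed-length reads (default 100 bp, the common
Illumina paired-end read length for 30× WGS): a fixed number
`round(n_reads × telomere_fraction)` of telomeric reads — windows into an
infinite TTAGGG tandem array with uniform phase and a fair coin for
orientation — at seeded random positions among i.i.d. uniform background
reads, with i.i.d. per-base substitution errors applied to everything.
Constant `I` quality strings are written; qualities are never used.
Output is a pure function of parameters and seed (PCG64 integer-state
generator, byte-identical FASTQ including gzip framing). The manifest
records the true telomeric read ids, emitted base total and a checksum,
so counting can be checked against ground truth and coverage against
the exact emitted base count.

What it does not emulate: indels, quality-dependent errors, fragment
size and GC bias, alignment (no BAM emission), interstitial telomeric
repeats, and biological dispersion of the telomeric read count beyond
substitution noise — the telomeric count at a given fraction is fixed,
not Poisson. Passing tests therefore demonstrate correctness of the
counting/normalization/classification machinery under a clean generative
model, not robustness to real-library artifacts.

The cohort simulator draws ΔT from a two-component Gaussian mixture with
recorded labels — exactly the classifier's generative assumption — with
defaults n = 235 samples, means (−0.5, 1.0), σ = 0.3, low-component
weight 0.7, matching the scale of a mixed pediatric-cancer cohort where
most tumors lose telomeric DNA and a minority gains.

## Validation problem sizes

The shipped checks use: 10⁴–10⁵-read files against a brute-force
counting oracle over telomere fractions 0–0.1 and error rates 0–0.02;
multiplier recovery (0.5×, 1×, 2×) at 10⁵ reads and fraction 0.05, where
the ±0.1 log2 tolerance sits at ≈4 sampling standard deviations; 100
bimodal and 100 unimodal cohorts of n = 235 for BIC selection; and 50
twin-replicate trials at ~2,300 telomeric reads per sample — the
magnitude observed for a real normalized telomere count — where
|ΔT| < 0.15 corresponds to ≈3.5 sd of the substitution-noise jitter.

## Known limitations

Absolute telomere length (kb) is not estimated, only content change;
per-chromosome lengths are not resolvable from motif counts; interstitial
telomeric repeats are indistinguishable from terminal ones; validation
against wet-lab assays is implemented as concordance arithmetic only.
The exact-match counting rule undercounts slightly at high error rates
(an error-free motif window must survive in the read), which cancels in
ΔT when tumor and normal share an error profile but biases single-sample
comparisons across platforms.
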
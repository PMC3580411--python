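# telcontent

Estimation of telomeric DNA content change in tumors from whole-genome
sequencing (WGS) reads.

Telomeres are the (TTAGGG)ₙ tandem-repeat arrays capping chromosome ends.
They shorten with every cell division, and cancers must maintain them —
via telomerase or the alternative-lengthening (ALT) pathway — to keep
dividing. WGS of a tumor and its matched normal contains a direct, if
indirect-looking, readout of telomere content: the number of reads made of
telomere repeat. `telcontent` turns that readout into a per-patient
statistic and a cohort-level classification, for genomics analysts working
with tumor/normal WGS pairs.

## Method

1. **Count** reads containing the exact contiguous motif (TTAGGG)₄ or its
   reverse complement (CCCTAA)₄, in FASTQ or SAM/BAM/CRAM input.
   Duplicates, QC failures and secondary/supplementary alignments are
   excluded by default; unmapped reads are kept, because telomeric reads
   typically fail to align.
2. **Normalize** the telomeric read count by average genomic coverage
   `c = (total sequenced bases) / (genome length)`, giving a depth-free
   content measure `T = telomeric reads / c`.
3. **ΔT** for each tumor–normal pair:
   `ΔT = log2(T_tumor / T_normal)`. The matched-normal denominator cancels
   sequencing depth, patient age and inter-individual telomere-length
   variation.
4. **Classify** the cohort's ΔT values with univariate Gaussian mixture
   models fitted by EM over a grid G ∈ {1..4} × {equal, unequal} variance,
   scored by `BIC = 2·logL − p·ln(n)` (larger is better). Under the
   two-component winner with means μ₁ < μ₂ and significance α = 0.01
   (z = 2.326), each sample is called
   - **gain** if ΔT > μ₁ + z·σ₁ (rejects the lower component's upper tail),
   - **loss** if ΔT < μ₂ − z·σ₂,
   - **no change** otherwise.
5. **Associate**: Mann-Whitney rank-sum tests of structural-variation and
   mutation burden in gain vs other tumors, per-group status fractions,
   and concordance with external qPCR (sign of log-ratio) or FISH
   (normal/abnormal) calls.

A seeded simulator generates FASTQ read sets with known telomeric
fraction, per-base error rate and coverage, and cohort ΔT vectors with
known mixture structure, so the whole pipeline is testable without any
controlled-access data.

## Worked example

```python
from telcontent import (ReadSimParams, simulate_pair, pair_delta_t,
                        CohortSimParams, simulate_cohort_deltas,
                        select_model, classify)

# a matched pair: the tumor has twice the normal's telomere content
normal = ReadSimParams(n_reads=100_000, read_length=100,
                       telomere_fraction=0.05, error_rate=0.005,
                       genome_length=1_000_000, seed=7)
(tumor_reads, _), (normal_reads, _) = simulate_pair(
    normal, tumor_fraction_multiplier=2.0)
rec = pair_delta_t(tumor_reads, normal_reads, genome_length=1_000_000)
print(f"tumor normalized count : {rec.tumor.normalized_count:.1f}")
print(f"normal normalized count: {rec.normal.normalized_count:.1f}")
print(f"delta_t                : {rec.delta_t:.3f}")

# a cohort of 235 delta_t values from a 70/30 two-component mixture
deltas, _ = simulate_cohort_deltas(CohortSimParams(n_samples=235, seed=7))
fit = select_model(deltas, seed=7)
print(f"selected model: G={fit.n_components}, {fit.variance_model} "
      f"variance, means=({fit.means[0]:.2f}, {fit.means[1]:.2f})")
calls = classify(deltas, fit)
```

prints

```
tumor normalized count : 1000.0
normal normalized count: 499.9
delta_t                : 1.000
selected model: G=2, equal variance, means=(-0.51, 0.96)
```

The tumor sample yields 1000 telomeric reads per fold of coverage against
the normal's 500, so ΔT = log2(1000/500) = 1.0 — the simulated doubling is
recovered exactly. On the cohort, BIC picks the generating two-component
equal-variance model and recovers its means (−0.5 and 1.0) to two decimals;
`classify` then gives each of the 235 samples a gain/loss/no-change call
(70 gains and 165 losses here — with components this well separated the
two significance boundaries cross and every sample resolves by posterior).

The same pipeline is available from the shell:

```sh
telcontent simulate pair --n-reads 100000 --telomere-fraction 0.05 \
    --multiplier 2 --seed 7 --out pair
telcontent count --input pair.tumor.fastq.gz  --output tumor.tsv
telcontent count --input pair.normal.fastq.gz --output normal.tsv
telcontent delta --tumor tumor.tsv --normal normal.tsv \
    --genome-length 1000000 --output delta.tsv
telcontent classify --delta cohort_deltas.tsv --alpha 0.01 \
    --model-out fit.json --output calls.tsv
telcontent stats --calls calls.tsv --annotations cohort.tsv --output stats.tsv
```

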
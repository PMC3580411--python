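"""Coverage normalization and the tumor-normal ΔT log-ratio.

The telomeric read count of a sample scales with sequencing depth, so it
is divided by the average genomic coverage — the mean number of sequenced
bases covering each reference position.  The per-patient statistic is then

    ΔT = log2(normalized tumor count / normalized normal count)

which cancels depth, age and inter-individual telomere-length variation:
ΔT > 0 means the tumor carries more telomeric DNA than its matched normal.

Coverage can be computed from all retained read bases (default — telomeric
reads are typically unaligned, and both members of a pair are normalized
identically) or from aligned bases only, for BAM-centric workflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .repeat_scan import TelomereCount

BASIS_ALL = "all_read_bases"
BASIS_ALIGNED = "aligned_bases"


@dataclass(frozen=True)
class CoverageEstimate:
    """Average fold-coverage over a reference of ``genome_length`` bp."""

    mean_coverage: float
    genome_length: int
    basis: str = BASIS_ALL


@dataclass(frozen=True)
class NormalizedContent:
    """Telomeric reads per fold of genomic coverage for one sample."""

    sample_id: str
    normalized_count: float
    raw: TelomereCount
    coverage: CoverageEstimate


@dataclass(frozen=True)
class DeltaTRecord:
    """One tumor-normal pair and its ΔT in log2 units."""

    pair_id: str
    delta_t: float
    tumor: NormalizedContent
    normal: NormalizedContent
    pseudocount_used: bool = False


def genome_length_from_fai(path: str | Path) -> int:
    """Sum of contig lengths from a samtools ``.fai`` FASTA index."""
    total = 0
    with open(path) as fh:
        for line in fh:
            if line.strip():
                total += int(line.split("\t")[1])
    if total <= 0:
        raise ValueError(f"no contigs found in index {path}")
    return total


def average_coverage(count: TelomereCount, genome_length: int,
                     basis: str = BASIS_ALL) -> CoverageEstimate:
    """Mean fold-coverage = sequenced (or aligned) bases / genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if basis == BASIS_ALL:
        bases = count.total_bases
    elif basis == BASIS_ALIGNED:
        bases = count.total_aligned_bases
    else:
        raise ValueError(f"unknown coverage basis {basis!r}")
    return CoverageEstimate(mean_coverage=bases / genome_length,
                            genome_length=genome_length, basis=basis)


def normalize_count(raw: TelomereCount, coverage: CoverageEstimate,
                    sample_id: str = "") -> NormalizedContent:
    """Telomeric read count divided by mean coverage."""
    if coverage.mean_coverage <= 0:
        raise ValueError(
            "mean coverage is zero; the sample has no sequenced bases — "
            "check the input file and genome length")
    return NormalizedContent(sample_id=sample_id,
                             normalized_count=raw.telomeric_reads / coverage.mean_coverage,
                             raw=raw, coverage=coverage)


def delta_t(tumor: NormalizedContent, normal: NormalizedContent,
            pseudocount: float = 0.5, pair_id: str | None = None) -> DeltaTRecord:
    """ΔT = log2(tumor normalized count / normal normalized count).

    Both samples must have been counted under the same motif and read
    filters.  If either normalized count is zero, ``pseudocount`` is added
    to *both* numerator and denominator so ΔT stays finite; nonzero pairs
    are never perturbed.
    """
    if tumor.raw.filters_applied != normal.raw.filters_applied:
        raise ValueError(
            "tumor and normal were counted with different motif/filter "
            "settings; recount both with identical configuration")
    t, n = tumor.normalized_count, normal.normalized_count
    used = False
    if t == 0.0 or n == 0.0:
        if pseudocount <= 0:
            raise ValueError("zero normalized count and no pseudocount; "
                             "ΔT is undefined")
        t, n = t + pseudocount, n + pseudocount
        used = True
    return DeltaTRecord(
        pair_id=pair_id or f"{tumor.sample_id}_vs_{normal.sample_id}",
        delta_t=math.log2(t / n), tumor=tumor, normal=normal,
        pseudocount_used=used)
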
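"""End-to-end convenience wrappers: reads in, ΔT out."""

from __future__ import annotations

from typing import Iterable

from .coverage import (DeltaTRecord, average_coverage, delta_t,
                       normalize_count, BASIS_ALL)
from .repeat_scan import (MotifSpec, ReadFilters, ReadRecord,
                          count_telomeric_reads)


def sample_normalized_content(reads: Iterable[ReadRecord], genome_length: int,
                              sample_id: str = "", spec: MotifSpec | None = None,
                              filters: ReadFilters | None = None,
                              basis: str = BASIS_ALL):
    """Count telomeric reads in a stream and normalize by mean coverage."""
    raw = count_telomeric_reads(reads, spec, filters)
    cov = average_coverage(raw, genome_length, basis=basis)
    return normalize_count(raw, cov, sample_id=sample_id)


def pair_delta_t(tumor_reads: Iterable[ReadRecord],
                 normal_reads: Iterable[ReadRecord], genome_length: int,
                 pair_id: str = "pair", spec: MotifSpec | None = None,
                 filters: ReadFilters | None = None,
                 pseudocount: float = 0.5) -> DeltaTRecord:
    """Full tumor-normal ΔT from two read streams over the same reference."""
    tum = sample_normalized_content(tumor_reads, genome_length,
                                    sample_id=f"{pair_id}_tumor",
                                    spec=spec, filters=filters)
    nrm = sample_normalized_content(normal_reads, genome_length,
                                    sample_id=f"{pair_id}_normal",
                                    spec=spec, filters=filters)
    return delta_t(tum, nrm, pseudocount=pseudocount, pair_id=pair_id)
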
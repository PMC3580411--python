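"""Telomere-motif read counting.

A sequencing read is *telomeric* when it contains the contiguous repeat
``(TTAGGG)_k`` or its reverse complement ``(CCCTAA)_k`` (k = 4 by default)
as an exact substring.  Matching is exact: no mismatches, no interrupted
repeats, and ``N`` never matches any base.  A read is counted at most once
regardless of how many occurrences, or which orientations, it contains.

Reads are streamed from FASTQ (plain or gzipped) or SAM/BAM/CRAM.  For
aligned input the default filters drop duplicate, QC-fail, secondary and
supplementary records while keeping unmapped reads, since genuinely
telomeric reads frequently fail to align to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import pysam

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifSpec:
    """Search pattern: ``unit`` repeated ``copies`` times, both strands.

    Parameters
    ----------
    unit:
        Repeat unit, default the human telomere repeat ``TTAGGG``.
    copies:
        Number of contiguous exact copies required.
    search_both_motifs:
        Also search the reverse complement of the repeated unit
        (``CCCTAA`` repeats for the default unit).
    """

    unit: str = "TTAGGG"
    copies: int = 4
    search_both_motifs: bool = True

    def __post_init__(self) -> None:
        unit = self.unit.upper()
        object.__setattr__(self, "unit", unit)
        if not unit:
            raise ValueError("motif unit must be non-empty")
        if "N" in unit:
            raise ValueError("motif unit must not contain N")
        if set(unit) - set("ACGT"):
            raise ValueError(f"motif unit has non-ACGT characters: {unit!r}")
        if self.copies < 1:
            raise ValueError("copies must be a positive integer")

    @property
    def forward_pattern(self) -> str:
        return self.unit * self.copies

    @property
    def reverse_pattern(self) -> str:
        return revcomp(self.unit) * self.copies


@dataclass(frozen=True)
class ReadFilters:
    """Which flagged alignment records are excluded from counting.

    FASTQ records carry no flags and always pass.  Defaults follow
    standard WGS practice: drop duplicates, QC failures and
    secondary/supplementary alignments; keep unmapped reads.
    """

    exclude_duplicates: bool = True
    exclude_qc_fail: bool = True
    exclude_secondary_supplementary: bool = True
    exclude_unmapped: bool = False


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with optional alignment flags."""

    read_id: str
    sequence: str
    is_duplicate: bool = False
    is_qc_fail: bool = False
    is_secondary_or_supplementary: bool = False
    is_unmapped: bool = False
    mapped_length: int = 0

    def passes(self, filters: ReadFilters) -> bool:
        if filters.exclude_duplicates and self.is_duplicate:
            return False
        if filters.exclude_qc_fail and self.is_qc_fail:
            return False
        if filters.exclude_secondary_supplementary and self.is_secondary_or_supplementary:
            return False
        if filters.exclude_unmapped and self.is_unmapped:
            return False
        return True


@dataclass
class TelomereCount:
    """Per-sample tally of telomeric and total retained reads."""

    telomeric_reads: int = 0
    total_reads: int = 0
    total_bases: int = 0
    total_aligned_bases: int = 0
    motif: MotifSpec = field(default_factory=MotifSpec)
    filters: ReadFilters = field(default_factory=ReadFilters)

    @property
    def filters_applied(self) -> dict:
        return {"motif": asdict(self.motif), "filters": asdict(self.filters)}


def revcomp(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def contains_telomere_motif(sequence: str, spec: MotifSpec | None = None) -> bool:
    """True iff the repeated motif (either strand) occurs exactly in ``sequence``."""
    spec = spec or MotifSpec()
    seq = sequence.upper()
    if spec.forward_pattern in seq:
        return True
    return spec.search_both_motifs and spec.reverse_pattern in seq


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (gzip detected by suffix); flags default to false."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield ReadRecord(read_id=entry.name, sequence=entry.sequence.upper())


def iter_alignments(path: str | Path, reference: str | None = None) -> Iterator[ReadRecord]:
    """Stream SAM/BAM/CRAM records (CRAM needs ``reference``)."""
    save = pysam.set_verbosity(0)  # silence missing-index warning
    try:
        with pysam.AlignmentFile(str(path), reference_filename=reference,
                                 check_sq=False) as fh:
            for rec in fh:
                seq = rec.query_sequence or ""
                yield ReadRecord(
                    read_id=rec.query_name or "",
                    sequence=seq.upper(),
                    is_duplicate=rec.is_duplicate,
                    is_qc_fail=rec.is_qcfail,
                    is_secondary_or_supplementary=rec.is_secondary or rec.is_supplementary,
                    is_unmapped=rec.is_unmapped,
                    mapped_length=0 if rec.is_unmapped else (rec.query_alignment_length or 0),
                )
    finally:
        pysam.set_verbosity(save)


def iter_reads(path: str | Path, fmt: str = "auto",
               reference: str | None = None) -> Iterator[ReadRecord]:
    """Dispatch on format: 'fastq', 'bam' (any htslib alignment format), or 'auto'."""
    if fmt == "auto":
        name = str(path)
        stripped = name[:-3] if name.endswith(".gz") else name
        if stripped.endswith((".fastq", ".fq", ".fasta", ".fa")):
            fmt = "fastq"
        elif stripped.endswith((".sam", ".bam", ".cram")):
            fmt = "bam"
        else:
            raise ValueError(f"cannot infer format from filename: {name}")
    if fmt == "fastq":
        return iter_fastq(path)
    if fmt == "bam":
        return iter_alignments(path, reference=reference)
    raise ValueError(f"unknown format {fmt!r}")


def count_telomeric_reads(reads: Iterable[ReadRecord],
                          spec: MotifSpec | None = None,
                          filters: ReadFilters | None = None) -> TelomereCount:
    """Single-pass tally of telomeric reads among filter-passing reads.

    ``total_reads`` / ``total_bases`` count retained reads only, so the
    same retained stream feeds both the motif tally and the coverage
    normalizer downstream.  An empty stream yields a zero count.
    """
    spec = spec or MotifSpec()
    filters = filters or ReadFilters()
    fwd = spec.forward_pattern
    rev = spec.reverse_pattern if spec.search_both_motifs else None
    count = TelomereCount(motif=spec, filters=filters)
    for rec in reads:
        if not rec.passes(filters):
            continue
        seq = rec.sequence
        count.total_reads += 1
        count.total_bases += len(seq)
        count.total_aligned_bases += rec.mapped_length
        if fwd in seq or (rev is not None and rev in seq):
            count.telomeric_reads += 1
    return count


def count_file(path: str | Path, fmt: str = "auto", spec: MotifSpec | None = None,
               filters: ReadFilters | None = None,
               reference: str | None = None) -> TelomereCount:
    """Count telomeric reads directly from a FASTQ/SAM/BAM/CRAM file."""
    return count_telomeric_reads(iter_reads(path, fmt, reference), spec, filters)
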
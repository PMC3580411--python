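"""Shared fixtures and independent oracles.

The brute-force scanner here is the reference implementation for motif
counting: a naive per-offset slice comparison, deliberately different
from the package's substring search.
"""

from __future__ import annotations

import pysam
import pytest

from telcontent.repeat_scan import MotifSpec, ReadRecord


def brute_force_contains(sequence: str, pattern: str) -> bool:
    """Naive O(L·m) scan: compare the pattern at every offset."""
    m = len(pattern)
    seq = sequence.upper()
    for i in range(len(seq) - m + 1):
        if seq[i:i + m] == pattern:
            return True
    return False


def brute_force_count(reads, spec: MotifSpec | None = None) -> int:
    """Count reads matching either orientation by exhaustive offset scan."""
    spec = spec or MotifSpec()
    fwd, rev = spec.forward_pattern, spec.reverse_pattern
    n = 0
    for rec in reads:
        seq = rec.sequence if isinstance(rec, ReadRecord) else rec
        if brute_force_contains(seq, fwd) or brute_force_contains(seq, rev):
            n += 1
    return n


@pytest.fixture
def sam_path(tmp_path):
    """A small SAM file exercising every read-filter flag."""
    path = tmp_path / "reads.sam"
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": "chr1", "LN": 10_000}],
    })
    tel = "TTAGGG" * 20  # 120 bp of pure repeat
    bg = "ACGT" * 30

    def rec(name, seq, flag):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.query_sequence = seq
        a.flag = flag
        if not flag & 0x4:
            a.reference_id = 0
            a.reference_start = 100
            a.cigarstring = f"{len(seq)}M"
            a.mapping_quality = 60
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        return a

    records = [
        rec("tel_mapped", tel, 0),
        rec("tel_unmapped", tel, 0x4),
        rec("tel_duplicate", tel, 0x400),
        rec("tel_qcfail", tel, 0x200),
        rec("tel_secondary", tel, 0x100),
        rec("tel_supplementary", tel, 0x800),
        rec("bg_mapped", bg, 0),
    ]
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            out.write(r)
    return path
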
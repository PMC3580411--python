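"""Seeded synthetic read sets and cohort ΔT vectors with known truth.

The read simulator emulates the inputs the counting pipeline consumes:
fixed-length Illumina-style reads, a known fraction of which are windows
into an infinite ``TTAGGG`` tandem array (random phase, random strand),
the rest i.i.d. uniform background bases.  A per-base substitution error
model probes the sensitivity of the exact-match counting rule;
indels, quality profiles, fragment sizes and GC bias are deliberately
not modeled.  Every output is a pure function of its parameters and seed.

The cohort simulator draws ΔT values from a two-component Gaussian
mixture with recorded component labels, the generative model the
classifier assumes.
"""

from __future__ import annotations

import gzip
import hashlib
import warnings
from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np

from .repeat_scan import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte -> index
_UNIT = "TTAGGG"


@dataclass(frozen=True)
class ReadSimParams:
    """Ground-truth generator settings for one synthetic sample."""

    n_reads: int
    read_length: int = 100
    telomere_fraction: float = 0.0
    error_rate: float = 0.0
    genome_length: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0 or self.read_length <= 0 or self.genome_length <= 0:
            raise ValueError("n_reads, read_length and genome_length must be > 0")
        if not 0.0 <= self.telomere_fraction <= 1.0:
            raise ValueError("telomere_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SimManifest:
    """What the generator actually emitted, for oracle checks downstream."""

    params: ReadSimParams
    true_telomeric_reads: int
    emitted_bases: int
    checksum: str
    telomeric_read_ids: list[str]

    def as_dict(self) -> dict:
        return {"params": asdict(self.params),
                "true_telomeric_reads": self.true_telomeric_reads,
                "emitted_bases": self.emitted_bases,
                "checksum": self.checksum,
                "telomeric_read_ids": self.telomeric_read_ids}


@dataclass(frozen=True)
class CohortSimParams:
    """Two-component Gaussian mixture generator for cohort ΔT values."""

    n_samples: int
    means: tuple[float, float] = (-0.5, 1.0)
    sigma: float = 0.3
    weight_low: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.means[0] == self.means[1]:
            raise ValueError("component means must be distinct")
        if not 0.0 < self.weight_low < 1.0:
            raise ValueError("weight_low must be in (0, 1)")


def _unit_indices(unit: str) -> np.ndarray:
    return np.array([_IDX[b] for b in unit.encode()], dtype=np.uint8)


def simulate_reads(params: ReadSimParams) -> tuple[list[ReadRecord], SimManifest]:
    """Generate a labeled synthetic read set.

    Exactly ``round(n_reads * telomere_fraction)`` reads are telomeric,
    placed at seeded random positions in the stream.  Telomeric reads are
    windows into the tandem repeat with uniform phase and a fair coin for
    orientation; substitutions are applied uniformly at ``error_rate``
    to every read, so at nonzero error rates some generated-telomeric
    reads may no longer contain the exact motif.
    """
    L, n = params.read_length, params.n_reads
    min_detect = len(_UNIT) * 4 + len(_UNIT) - 1
    if L < min_detect:
        warnings.warn(f"read_length {L} < {min_detect}; telomeric reads are "
                      "not guaranteed to contain the full 4-copy motif")
    rng = np.random.default_rng(params.seed)
    n_tel = int(round(n * params.telomere_fraction))

    mat = rng.integers(0, 4, size=(n, L), dtype=np.uint8)
    tel_rows = np.sort(rng.permutation(n)[:n_tel])
    if n_tel:
        fwd = _unit_indices(_UNIT)
        rev = _unit_indices("CCCTAA")
        phases = rng.integers(0, len(_UNIT), size=n_tel)
        reverse = rng.random(n_tel) < 0.5
        offsets = (phases[:, None] + np.arange(L)[None, :]) % len(_UNIT)
        tel_mat = np.where(reverse[:, None], rev[offsets], fwd[offsets])
        mat[tel_rows] = tel_mat
    if params.error_rate > 0:
        hit = rng.random((n, L)) < params.error_rate
        shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
        mat = (mat + hit * shift) % 4

    seq_bytes = _BASES[mat]
    tel_set = set(tel_rows.tolist())
    reads = [ReadRecord(read_id=f"sim_{i}",
                        sequence=seq_bytes[i].tobytes().decode("ascii"))
             for i in range(n)]

    digest = hashlib.sha256()
    for rec in reads:
        digest.update(_fastq_entry(rec).encode("ascii"))
    manifest = SimManifest(
        params=params,
        true_telomeric_reads=n_tel,
        emitted_bases=n * L,
        checksum=digest.hexdigest(),
        telomeric_read_ids=[f"sim_{i}" for i in sorted(tel_set)])
    return reads, manifest


def _fastq_entry(rec: ReadRecord) -> str:
    return f"@{rec.read_id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n"


def write_fastq(reads: list[ReadRecord], path: str | Path) -> Path:
    """Serialize reads to FASTQ; gzip when the path ends in ``.gz``."""
    path = Path(path)
    text = "".join(_fastq_entry(r) for r in reads)
    if path.suffix == ".gz":
        # fixed mtime, no embedded filename: identical reads, identical bytes
        with open(path, "wb") as raw, \
                gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as fh:
            fh.write(text.encode("ascii"))
    else:
        path.write_text(text)
    return path


def simulate_pair(normal_params: ReadSimParams, tumor_fraction_multiplier: float,
                  seed_offset: int = 1) -> tuple[
                      tuple[list[ReadRecord], SimManifest],
                      tuple[list[ReadRecord], SimManifest]]:
    """Matched tumor/normal read sets; the tumor telomere fraction is scaled.

    Returns ``((tumor_reads, tumor_manifest), (normal_reads, normal_manifest))``.
    """
    if tumor_fraction_multiplier <= 0:
        raise ValueError("tumor_fraction_multiplier must be positive")
    tumor_fraction = normal_params.telomere_fraction * tumor_fraction_multiplier
    if tumor_fraction > 1.0:
        raise ValueError(
            f"multiplier {tumor_fraction_multiplier} pushes the tumor "
            f"telomere fraction to {tumor_fraction:.3g} > 1")
    tumor_params = replace(normal_params, telomere_fraction=tumor_fraction,
                           seed=normal_params.seed + seed_offset)
    return simulate_reads(tumor_params), simulate_reads(normal_params)


def simulate_cohort_deltas(params: CohortSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Draw ΔT values from the two-component mixture; labels 0 = low, 1 = high."""
    rng = np.random.default_rng(params.seed)
    labels = (rng.random(params.n_samples) >= params.weight_low).astype(int)
    means = np.asarray(params.means, dtype=float)
    deltas = rng.normal(means[labels], params.sigma)
    return deltas, labels
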
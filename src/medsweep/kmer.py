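"""Canonical k-mer histograms and genome-size estimation.

Genome size is estimated as (total number of k-mers) / (depth of the major
peak of the k-mer multiplicity histogram). K-mers are counted in canonical
form (the lexicographically smaller of a window and its reverse
complement) so that strand is irrelevant; windows containing N are skipped.

The major peak can be located over the raw histogram or after discarding
the low-multiplicity error spike (first-local-minimum cutoff), and the size
formula can correspondingly include or exclude the error k-mers — the
literal total-over-peak formula is biased upward by sequencing errors, so
both behaviours are exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_COMP = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G in 2-bit codes


class PeakNotFoundError(ValueError):
    pass


@dataclass
class KmerHistogram:
    """Multiplicity -> number of distinct canonical k-mers."""

    k: int
    counts: dict[int, int]

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd (even k has palindromic canonical ambiguity)")
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    def as_array(self) -> np.ndarray:
        """Dense counts indexed by multiplicity (index 0 unused)."""
        if not self.counts:
            return np.zeros(1, dtype=np.int64)
        arr = np.zeros(max(self.counts) + 1, dtype=np.int64)
        for m, c in self.counts.items():
            arr[m] = c
        return arr

    def write_histo(self, path: str | Path) -> None:
        """Two-column multiplicity/count table, ascending (GenomeScope format)."""
        with open(path, "w") as fh:
            for m in sorted(self.counts):
                fh.write(f"{m} {self.counts[m]}\n")

    @classmethod
    def read_histo(cls, path: str | Path, k: int = 17) -> "KmerHistogram":
        counts = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    m, c = line.split()[:2]
                    counts[int(m)] = int(c)
        return cls(k=k, counts=counts)


@dataclass
class SizeEstimate:
    peak_depth: int
    genome_size_bp: float
    error_cutoff: int = 0
    total_kmers_used: int = 0
    ambiguous_half_depth_peak: bool = False

    def to_json(self, k: int) -> str:
        return json.dumps(
            dict(
                k=k, peak=self.peak_depth, cutoff=self.error_cutoff,
                total_kmers=self.total_kmers_used,
                genome_size_bp=self.genome_size_bp,
                ambiguous_half_depth_peak=self.ambiguous_half_depth_peak,
            ),
            indent=2,
        )


def _read_kmer_codes(read: str, k: int) -> np.ndarray:
    """Canonical 2-bit codes of all valid k-windows of one read."""
    vals = _CODE[np.frombuffer(read.encode("ascii"), dtype=np.uint8)]
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    win = win[valid]
    pow_f = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ pow_f
    rev = _COMP[win[:, ::-1]] @ pow_f
    return np.minimum(fwd, rev)


def count_kmers(reads: Iterable[str], k: int = 17, chunk_kmers: int = 2_000_000) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram over a read stream.

    Reads shorter than k or windows containing N contribute nothing.
    Aggregation is chunked: per-read code arrays are pooled and folded into
    a running code->count map every ``chunk_kmers`` k-mers.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not (3 <= k <= 31):
        raise ValueError("k must be in [3, 31]")
    tally: dict[int, int] = {}
    pool: list[np.ndarray] = []
    pooled = 0
    n_reads = 0

    def _flush() -> None:
        nonlocal pool, pooled
        if not pool:
            return
        codes, cnts = np.unique(np.concatenate(pool), return_counts=True)
        for code, c in zip(codes.tolist(), cnts.tolist()):
            tally[code] = tally.get(code, 0) + c
        pool, pooled = [], 0

    for read in reads:
        n_reads += 1
        codes = _read_kmer_codes(read, k)
        if codes.size:
            pool.append(codes)
            pooled += codes.size
            if pooled >= chunk_kmers:
                _flush()
    _flush()
    if n_reads == 0:
        raise ValueError("no reads in input")
    if tally:
        mult, cnt = np.unique(np.fromiter(tally.values(), dtype=np.int64), return_counts=True)
        counts = dict(zip(mult.tolist(), cnt.tolist()))
    else:
        counts = {}
    return KmerHistogram(k=k, counts=counts)


def find_major_peak(
    hist: KmerHistogram, error_cutoff_mode: str = "first_local_min", fixed_cutoff: int = 0
) -> tuple[int, int]:
    """Locate the major peak multiplicity; returns (peak, cutoff).

    Cutoff per mode: ``none`` -> 0; ``first_local_min`` -> the smallest
    multiplicity m with counts[m] < counts[m+1] (the valley after the
    error spike); ``fixed`` -> ``fixed_cutoff``. The peak is the
    multiplicity with the largest count among multiplicities > cutoff.
    """
    if not hist.counts:
        raise PeakNotFoundError("empty histogram")
    arr = hist.as_array()
    if error_cutoff_mode == "none":
        cutoff = 0
    elif error_cutoff_mode == "fixed":
        cutoff = fixed_cutoff
    elif error_cutoff_mode == "first_local_min":
        cutoff = 0
        for m in range(1, len(arr) - 1):
            if arr[m] < arr[m + 1]:
                cutoff = m
                break
        else:
            raise PeakNotFoundError(
                "histogram monotone non-increasing: no local minimum, peak not found"
            )
    else:
        raise ValueError(f"unknown error_cutoff_mode: {error_cutoff_mode}")
    above = arr[cutoff + 1 :]
    if above.size == 0 or above.max() == 0:
        raise PeakNotFoundError(f"no k-mers above cutoff {cutoff}")
    peak = cutoff + 1 + int(np.argmax(above))
    if peak == cutoff + 1 and error_cutoff_mode != "none":
        import warnings

        warnings.warn(
            f"major peak at the cutoff boundary (m={peak}); estimate unreliable",
            stacklevel=2,
        )
    return peak, cutoff


def _half_depth_bump(arr: np.ndarray, peak: int, cutoff: int) -> bool:
    """Detect an ambiguous two-peak histogram.

    In heterozygous genomes k-mers spanning a variant occur on one haplotype
    only, producing a secondary mode near half the homozygous depth; when
    that mode itself wins the argmax the companion sits near double the
    reported peak. Either secondary local maximum at >= 20% of the major
    peak's height flags the estimate as ambiguous.
    """

    def _bump_near(center: int) -> bool:
        if center <= cutoff + 1 or center >= len(arr):
            return False
        w = max(2, center // 4)
        lo = max(cutoff + 1, center - w)
        hi = min(len(arr), center + w + 1)
        seg = arr[lo:hi]
        if seg.size < 3:
            return False
        m = int(np.argmax(seg))
        mult = lo + m
        if abs(mult - peak) <= max(2, peak // 8):
            return False  # that is the major peak itself
        return seg[m] >= 0.2 * arr[peak]

    return _bump_near(peak // 2) or _bump_near(2 * peak)


def estimate_genome_size(
    hist: KmerHistogram,
    peak: int | None = None,
    include_error_kmers: bool = True,
    error_cutoff_mode: str = "first_local_min",
    fixed_cutoff: int = 0,
) -> SizeEstimate:
    """Genome size = (total k-mers) / (major-peak depth).

    With ``include_error_kmers`` the total follows the literal formula (all
    k-mers); otherwise multiplicities at or below the error cutoff are
    excluded from the numerator.
    """
    found_peak, cutoff = find_major_peak(hist, error_cutoff_mode, fixed_cutoff)
    if peak is None:
        peak = found_peak
    if peak < 1:
        raise ValueError("peak must be >= 1")
    if include_error_kmers:
        total = hist.total_kmers
        cutoff_used = 0
    else:
        total = sum(m * c for m, c in hist.counts.items() if m > cutoff)
        cutoff_used = cutoff
    arr = hist.as_array()
    return SizeEstimate(
        peak_depth=peak,
        genome_size_bp=total / peak,
        error_cutoff=cutoff_used,
        total_kmers_used=total,
        ambiguous_half_depth_peak=_half_depth_bump(arr, peak, cutoff),
    )
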
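"""Two-population selective-sweep scan.

Windowed Weir & Cockerham (1984) theta-hat (``Fst``) and per-population
nucleotide diversity (theta-pi) from a biallelic SNP matrix, the
log2(pi_control / pi_tolerance) ratio, top-fraction outlier screening,
region merging and candidate-gene extraction.

Estimator notes
---------------
Fst is the two-subpopulation diploid Weir-Cockerham variance-component
estimator: per site the components (a, b, c) are the among-population,
among-individual-within-population and within-individual mean squares; a
window's theta-hat is the ratio of sums sum(a) / sum(a + b + c) over its
usable sites (the "weighted" form classic tooling reports). Sites where
either population has fewer than two called individuals are skipped.
Negative windowed estimates are retained so that ranking is unbiased.

Per-site pi is the unbiased average pairwise difference
2 * c_ref * c_alt / (n * (n - 1)) over called alleles; window pi is the sum
over SNPs divided by the window span in bp (a per-bp quantity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneRecord

MISSING = -1


# ---------------------------------------------------------------------------
# Containers

@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (sites x samples), missing encoded as -1."""

    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.pos), len(self.sample_ids)):
            raise ValueError("dosage matrix shape does not match sites x samples")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)


@dataclass(frozen=True)
class PopulationSplit:
    tolerance: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tolerance or not self.control:
            raise ValueError("both populations must be non-empty")
        if set(self.tolerance) & set(self.control):
            raise ValueError("populations overlap")

    def indices(self, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        lookup = {s: i for i, s in enumerate(sample_ids)}
        missing = [s for s in self.tolerance + self.control if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        return (
            np.array([lookup[s] for s in self.tolerance]),
            np.array([lookup[s] for s in self.control]),
        )


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int
    truncated: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class SweepRegions:
    intervals: list[tuple[str, int, int]]  # merged, 0-based half-open
    source_windows: list[list[Window]]
    candidate_gene_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Ingestion

def read_vcf_biallelic(path: str | Path, min_call_rate: float = 0.0) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a dosage matrix.

    Keeps records with a single-base REF and a single single-base ALT; drops
    sites whose genotype call rate falls below ``min_call_rate``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no samples")
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for var in vcf:
        if len(var.REF) != 1 or len(var.ALT) != 1 or len(var.ALT[0]) != 1:
            continue
        if var.REF not in "ACGT" or var.ALT[0] not in "ACGT":
            continue
        gt = var.gt_types.astype(np.int8)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = MISSING
        called = np.count_nonzero(gt != MISSING)
        if called / len(samples) < min_call_rate:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(gt)
    dos = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(samples)), np.int8)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosages=dos,
        sample_ids=samples,
    )


def vcf_contig_lengths(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from ##contig header lines."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    out = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens):
        out[name] = int(length)
    return out


# ---------------------------------------------------------------------------
# Windows

def make_windows(
    chrom_lengths: dict[str, int], size: int = 40_000, step: int = 20_000
) -> list[Window]:
    """Sliding windows: starts at 0, step, 2*step, ... while start < length.

    Terminal windows shorter than ``size`` are kept and flagged truncated.
    """
    if step <= 0 or size <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step > size would leave uncovered gaps")
    windows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + size, length)
            windows.append(Window(chrom, start, end, truncated=end - start < size))
            start += step
    return windows


# ---------------------------------------------------------------------------
# Site-level statistics

def site_pi(ref_count: int, alt_count: int) -> float:
    """Unbiased per-site pi: 2 * c_ref * c_alt / (n * (n - 1))."""
    n = ref_count + alt_count
    if n < 2:
        raise ValueError("site pi requires at least 2 called alleles")
    return 2.0 * ref_count * alt_count / (n * (n - 1))


def _pop_counts(dosages: np.ndarray, idx: np.ndarray):
    """Per-site called-individual count, alt frequency and het frequency.

    ``dosages`` is (sites x samples); returns arrays over sites with NaN
    frequency where no individuals are called.
    """
    sub = dosages[:, idx]
    called = sub != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    het = np.logical_and(called, sub == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / np.where(n > 0, n, 1), np.nan)
    return n, p, h


def wc_components_matrix(
    dosages: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (a, b, c) per site for two diploid populations.

    Returns (a, b, c, usable); sites with fewer than two called individuals
    in either population are flagged unusable (components set to 0).
    """
    r = 2
    n1, p1, h1 = _pop_counts(dosages, idx1)
    n2, p2, h2 = _pop_counts(dosages, idx2)
    usable = (n1 >= 2) & (n2 >= 2)
    # compute on all sites, zero out unusable afterwards
    n1f = np.where(usable, n1, 2).astype(float)
    n2f = np.where(usable, n2, 2).astype(float)
    p1f = np.where(usable, p1, 0.0)
    p2f = np.where(usable, p2, 0.0)
    h1f = np.where(usable, h1, 0.0)
    h2f = np.where(usable, h2, 0.0)

    nbar = (n1f + n2f) / r
    nc = (r * nbar - (n1f**2 + n2f**2) / (r * nbar)) / (r - 1)
    pbar = (n1f * p1f + n2f * p2f) / (r * nbar)
    s2 = (n1f * (p1f - pbar) ** 2 + n2f * (p2f - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1f * h1f + n2f * h2f) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    zero = np.zeros_like(a)
    return (
        np.where(usable, a, zero),
        np.where(usable, b, zero),
        np.where(usable, c, zero),
        usable,
    )


def wc_site_components(
    dosage_row: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[float, float, float] | None:
    """Single-site (a, b, c); None signals the site must be skipped."""
    a, b, c, usable = wc_components_matrix(dosage_row.reshape(1, -1), idx1, idx2)
    if not usable[0]:
        return None
    return float(a[0]), float(b[0]), float(c[0])


def window_fst(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums theta-hat; NaN when the denominator is zero."""
    denom = float(np.sum(a) + np.sum(b) + np.sum(c))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(a)) / denom


def window_pi(
    gm: GenotypeMatrix, pop_idx: np.ndarray, site_mask: np.ndarray, span: int
) -> float:
    """Per-bp theta-pi over the sites selected by ``site_mask``."""
    if span <= 0:
        raise ValueError("window span must be positive")
    sub = gm.dosages[np.ix_(site_mask.nonzero()[0], pop_idx)]
    called = sub != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    ok = n_alleles >= 2
    n = n_alleles[ok].astype(float)
    ac = alt[ok].astype(float)
    rc = n - ac
    return float(np.sum(2.0 * rc * ac / (n * (n - 1)))) / span


def log2_pi_ratio(pi_control: float, pi_tolerance: float) -> float:
    """log2(pi_control / pi_tolerance); NaN when either pi is zero."""
    if pi_control < 0 or pi_tolerance < 0:
        raise ValueError("pi must be non-negative")
    if pi_control == 0 or pi_tolerance == 0:
        return float("nan")
    return math.log2(pi_control / pi_tolerance)


# ---------------------------------------------------------------------------
# Windowed scan

def window_scan(
    gm: GenotypeMatrix,
    split: PopulationSplit,
    windows: list[Window],
    min_snps: int = 10,
    clamp_negative_fst: bool = False,
) -> pd.DataFrame:
    """Per-window Fst, per-population pi, log2 ratio and SNP count.

    Windows with fewer than ``min_snps`` usable sites get NaN statistics so
    they never enter ranking. Columns: chrom, start, end, truncated, n_snps,
    fst, pi_control, pi_tolerance, log2_ratio.
    """
    idx_tol, idx_ctl = split.indices(gm.sample_ids)
    a, b, c, usable = wc_components_matrix(gm.dosages, idx_tol, idx_ctl)
    rows = []
    for w in windows:
        in_w = (gm.chrom == w.chrom) & (gm.pos >= w.start + 1) & (gm.pos <= w.end)
        use = in_w & usable
        n_use = int(np.count_nonzero(use))
        if n_use >= min_snps:
            fst = window_fst(a[use], b[use], c[use])
            if clamp_negative_fst and not math.isnan(fst):
                fst = max(fst, 0.0)
            pi_c = window_pi(gm, idx_ctl, in_w, w.span)
            pi_t = window_pi(gm, idx_tol, in_w, w.span)
            ratio = log2_pi_ratio(pi_c, pi_t)
        else:
            fst = pi_c = pi_t = ratio = float("nan")
        rows.append(
            dict(
                chrom=w.chrom, start=w.start, end=w.end, truncated=w.truncated,
                n_snps=n_use, fst=fst, pi_control=pi_c, pi_tolerance=pi_t,
                log2_ratio=ratio,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Screening and regions

def select_top_fraction(
    stats: pd.DataFrame, column: str, q: float = 0.05, positive_only: bool = False
) -> tuple[pd.DataFrame, float]:
    """Top floor(q*N) windows by ``column`` (descending), plus boundary ties.

    Windows with undefined (NaN) values are excluded before ranking; when
    ``positive_only`` only strictly positive values are ranked (the
    diversity-ratio screen discards non-positive ratios). Returns the
    selected rows and the threshold value.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    vals = stats[column]
    usable = stats[vals.notna() & (vals > 0 if positive_only else True)]
    n = len(usable)
    if n == 0:
        raise ValueError(f"no windows with usable '{column}' values")
    k = math.floor(q * n)
    if k == 0:
        import warnings

        warnings.warn(f"top fraction {q} of {n} windows selects none", stacklevel=2)
        return usable.iloc[0:0], float("nan")
    ordered = usable.sort_values(column, ascending=False, kind="mergesort")
    threshold = float(ordered[column].iloc[k - 1])
    selected = usable[usable[column] >= threshold]
    if len(selected) == n:
        import warnings

        warnings.warn("all windows tied at the selection boundary", stacklevel=2)
    return selected, threshold


def _window_keys(df: pd.DataFrame) -> set[tuple[str, int, int]]:
    return set(zip(df["chrom"], df["start"], df["end"]))


def merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Merge overlapping or book-ended 0-based half-open intervals."""
    merged: list[list] = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e])
    return [tuple(m) for m in merged]


def call_sweep_regions(
    top_fst: pd.DataFrame, top_ratio: pd.DataFrame, mode: str = "intersection"
) -> SweepRegions:
    """Combine the two top-fraction screens and merge windows into regions."""
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown combination mode: {mode}")
    keys_f, keys_r = _window_keys(top_fst), _window_keys(top_ratio)
    keys = keys_f & keys_r if mode == "intersection" else keys_f | keys_r
    windows = sorted(keys)
    merged = merge_intervals(windows)
    sources = [
        [Window(c, s, e) for c, s, e in windows if c == mc and s < me and e > ms]
        for mc, ms, me in merged
    ]
    return SweepRegions(intervals=merged, source_windows=sources)


def genes_in_regions(genes: list[GeneRecord], regions: SweepRegions) -> list[str]:
    """Genes whose 1-based span overlaps any merged region by >= 1 bp.

    Regions are converted from 0-based half-open to 1-based inclusive for
    the comparison; IDs are deduplicated and returned in positional order.
    """
    hits: list[tuple[str, int, str]] = []
    seen: set[str] = set()
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        for chrom, s0, e0 in regions.intervals:
            if g.chrom == chrom and g.start <= e0 and g.end >= s0 + 1:
                if g.gene_id not in seen:
                    seen.add(g.gene_id)
                    hits.append((g.chrom, g.start, g.gene_id))
                break
    regions.candidate_gene_ids = [h[2] for h in hits]
    return regions.candidate_gene_ids
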
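"""Syntenic-block chaining and 4DTv divergence.

Anchors are similarity gene pairs (e-value filtered upstream); within each
chromosome pair they are chained by dynamic programming into collinear runs
— strictly increasing gene-order ranks on both genomes for "+" blocks,
increasing on A and decreasing on B for "-" blocks — with a cap on the
rank gap between consecutive anchors. Chains shorter than ``min_block``
(default 5 genes) are discarded and each anchor joins at most one block,
assigned greedily by descending chain length.

4DTv is the proportion of comparable fourfold-degenerate third codon
positions that differ by a transversion (purine <-> pyrimidine) between two
codon-aligned CDSs; the proportion is left uncorrected for multiple hits.
Peaks of its distribution over duplicated gene pairs mark whole-genome
duplication events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FOURFOLD_PREFIXES = frozenset({"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"})
_PURINE = frozenset("AG")


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    chrom_a: str
    chrom_b: str
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.rank_a < 0 or self.rank_b < 0:
            raise ValueError("ranks must be non-negative")


@dataclass
class SyntenyBlock:
    anchors: list[AnchorPair]
    orientation: str  # '+' or '-'
    chrom_a: str
    chrom_b: str

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class FourDTvResult:
    pair_id: str
    n_4d_sites: int
    n_transversions: int
    undefined_reason: str | None = None

    @property
    def fourdtv(self) -> float | None:
        if self.undefined_reason is not None or self.n_4d_sites == 0:
            return None
        return self.n_transversions / self.n_4d_sites


# ---------------------------------------------------------------------------
# Chaining

def _best_chain(anchors: list[AnchorPair], sign: int, max_gap: int) -> list[int]:
    """Longest chain under the collinearity and gap constraints.

    ``anchors`` must be sorted by rank_a. ``sign`` +1 demands rank_b
    strictly increasing, -1 strictly decreasing. Returns indices of the
    chain members. O(n^2) DP, adequate at gene-order scale.
    """
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for j in range(n):
        aj, bj = anchors[j].rank_a, anchors[j].rank_b
        for i in range(j):
            ai, bi = anchors[i].rank_a, anchors[i].rank_b
            if ai >= aj or aj - ai > max_gap:
                continue
            if sign * (bj - bi) <= 0 or abs(bj - bi) > max_gap:
                continue
            if best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
        # ties broken toward the earlier predecessor (first found)
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_anchors(
    anchors: list[AnchorPair], min_block: int = 5, max_gap: int = 25
) -> list[SyntenyBlock]:
    """Chain anchors into syntenic blocks of at least ``min_block`` genes."""
    # dedupe per (gene_a, gene_b)
    seen: set[tuple[str, str]] = set()
    uniq = []
    for a in anchors:
        key = (a.gene_a, a.gene_b)
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    by_pair: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in uniq:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (ca, cb), group in sorted(by_pair.items()):
        remaining = sorted(group, key=lambda x: (x.rank_a, x.rank_b))
        while True:
            cand = []
            for sign, orient in ((1, "+"), (-1, "-")):
                idx = _best_chain(remaining, sign, max_gap)
                cand.append((len(idx), sign, orient, idx))
            cand.sort(key=lambda t: (-t[0], t[1]))  # longest first; '+' wins ties
            length, _, orient, idx = cand[0]
            if length < min_block:
                break
            members = [remaining[i] for i in idx]
            blocks.append(SyntenyBlock(members, orient, ca, cb))
            taken = set(idx)
            remaining = [a for i, a in enumerate(remaining) if i not in taken]
            if len(remaining) < min_block:
                break
    blocks.sort(key=lambda b: (-len(b), b.chrom_a, b.chrom_b, b.anchors[0].rank_a))
    return blocks


def block_gene_pairs(
    blocks: list[SyntenyBlock],
) -> list[tuple[str, str, list[int]]]:
    """All anchor gene pairs with block-index provenance, deduplicated."""
    out: dict[tuple[str, str], list[int]] = {}
    for bi, block in enumerate(blocks):
        for a in block.anchors:
            out.setdefault((a.gene_a, a.gene_b), []).append(bi)
    result = [(ga, gb, bids) for (ga, gb), bids in out.items()]
    if any(len(bids) > 1 for _, _, bids in result):
        import warnings

        warnings.warn("an anchor pair appears in more than one block", stacklevel=2)
    return result


def validate_block(block: SyntenyBlock, min_block: int = 5, max_gap: int = 25) -> bool:
    """Independent post-hoc check of the block invariants."""
    if len(block.anchors) < min_block:
        return False
    sign = 1 if block.orientation == "+" else -1
    for x, y in zip(block.anchors, block.anchors[1:]):
        if not (0 < y.rank_a - x.rank_a <= max_gap):
            return False
        if not (0 < sign * (y.rank_b - x.rank_b) <= max_gap):
            return False
    return True


# ---------------------------------------------------------------------------
# 4DTv

def fourfold_comparable_sites(seq_a: str, seq_b: str) -> list[int]:
    """Alignment indices of comparable fourfold-degenerate third positions.

    A codon column qualifies iff neither codon contains a gap or N, the
    dinucleotide prefix is identical in both sequences, and that prefix is
    a fourfold-degenerate family of the standard genetic code.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3 != 0:
        raise ValueError("alignment length not divisible by 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    sites = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(x not in "ACGT" for x in ca + cb):
            continue
        if ca[:2] != cb[:2]:
            continue
        if ca[:2] in FOURFOLD_PREFIXES:
            sites.append(i + 2)
    return sites


def is_transversion(b1: str, b2: str) -> bool:
    return b1 != b2 and ((b1 in _PURINE) != (b2 in _PURINE))


def fourdtv_distance(
    seq_a: str, seq_b: str, pair_id: str = "", min_sites: int = 10
) -> FourDTvResult:
    """Transversion fraction at comparable fourfold-degenerate sites.

    Pairs with fewer than ``min_sites`` comparable sites are returned with
    ``fourdtv`` undefined (None) rather than a noisy estimate.
    """
    sites = fourfold_comparable_sites(seq_a, seq_b)
    sa, sb = seq_a.upper(), seq_b.upper()
    n_tv = sum(is_transversion(sa[i], sb[i]) for i in sites)
    reason = None
    if len(sites) == 0:
        reason = "no comparable fourfold-degenerate sites"
    elif len(sites) < min_sites:
        reason = f"only {len(sites)} comparable sites (< {min_sites})"
    return FourDTvResult(
        pair_id=pair_id, n_4d_sites=len(sites), n_transversions=n_tv,
        undefined_reason=reason,
    )


@dataclass
class PeakReport:
    peaks: list[float]  # bin midpoints of local maxima, ranked by height
    well_separated: bool
    bin_width: float
    histogram: np.ndarray = field(repr=False, default=None)


def fourdtv_peak(
    values: list[float],
    bin_width: float = 0.01,
    smooth_bins: int = 3,
    min_values: int = 50,
    separation_ratio: float = 1.5,
) -> PeakReport:
    """Modes of the 4DTv distribution on [0, 1].

    Histogram at ``bin_width``, moving-average smoothed over ``smooth_bins``
    bins; local maxima of the smoothed curve are reported ranked by height
    (global peak first). A flat distribution — maximum smoothed bin less
    than ``separation_ratio`` times the median positive bin — is flagged
    not well separated.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size < min_values:
        raise ValueError(f"need >= {min_values} defined values, got {vals.size}")
    n_bins = int(round(1.0 / bin_width))
    hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(hist, kernel, mode="same")
    mids = (edges[:-1] + edges[1:]) / 2
    half = smooth_bins // 2
    maxima = []
    for i in range(len(smoothed)):
        left = smoothed[i - 1] if i > 0 else -np.inf
        right = smoothed[i + 1] if i < len(smoothed) - 1 else -np.inf
        if smoothed[i] > 0 and smoothed[i] >= left and smoothed[i] > right:
            # refine a smoothing plateau to the raw-histogram mode nearby
            lo = max(0, i - half)
            j = lo + int(np.argmax(hist[lo : i + half + 1]))
            maxima.append((smoothed[i], mids[j]))
    maxima.sort(key=lambda t: -t[0])
    med = float(np.median(smoothed))
    if med == 0:
        well = bool(smoothed.max() > 0)
    else:
        well = bool(smoothed.max() / med >= separation_ratio)
    return PeakReport(
        peaks=[float(m) for _, m in maxima],
        well_separated=well,
        bin_width=bin_width,
        histogram=hist,
    )
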
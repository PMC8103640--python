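"""GO enrichment, the rich factor, and IUPAC promoter-motif counting.

Enrichment of a selected gene set against an annotation map uses the
one-sided (upper-tail) hypergeometric test with Benjamini-Hochberg
correction across tested terms. The rich factor of a term is k/K: the
selected genes in the term over all genes in the term. Motif counting
expands IUPAC degeneracy codes and scans the forward strand and optionally
the reverse complement; the MYB-core filter keeps genes whose promoter
carries strictly more than ``min_count`` motif occurrences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n).

    k: selected genes in the term; K: universe genes in the term;
    n: selected-set size; N: universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require K <= N and n <= N")
    if k < 0 or k > min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    if any(p < 0 or p > 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(p) for p in p_adj]


def rich_factor(k: int, K: int) -> float:
    """Selected-in-term over total-in-term, k/K."""
    if K < 1:
        raise ValueError("term has no genes (K=0)")
    if not (0 <= k <= K):
        raise ValueError("require 0 <= k <= K")
    return k / K


def go_enrichment(
    selected: set[str],
    term2genes: Mapping[str, set[str]],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``selected`` over every GO term.

    The universe defaults to the union of all annotated genes; term gene
    sets and the selection are intersected with it before testing. Returns
    a DataFrame sorted by p with columns term, k, K, n, N, p, p_adj,
    rich_factor.
    """
    if universe is None:
        universe = set().union(*term2genes.values()) if term2genes else set()
    sel = selected & universe
    N, n = len(universe), len(sel)
    rows = []
    for term, genes in sorted(term2genes.items()):
        tg = genes & universe
        K = len(tg)
        if K == 0:
            continue
        k = len(sel & tg)
        rows.append(dict(term=term, k=k, K=K, n=n, N=N,
                         p=hypergeometric_test(k, K, n, N), rich_factor=rich_factor(k, K)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "rich_factor"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].tolist())
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        df["p_adj"] = []
    return df[["term", "k", "K", "n", "N", "p", "p_adj", "rich_factor"]]


def read_gene2go(path) -> dict[str, set[str]]:
    """Two-column gene<TAB>term table -> term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=0)
    gene_col, term_col = df.columns[:2]
    term2genes: dict[str, set[str]] = {}
    for gene, term in zip(df[gene_col], df[term_col]):
        term2genes.setdefault(str(term), set()).add(str(gene))
    return term2genes


# ---------------------------------------------------------------------------
# Motifs

@dataclass(frozen=True)
class MotifSpec:
    iupac: str
    both_strands: bool = True
    count_mode: str = "overlapping"  # or non_overlapping

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty motif")
        bad = [c for c in self.iupac.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC codes: {bad}")
        if self.count_mode not in ("overlapping", "non_overlapping"):
            raise ValueError(f"unknown count_mode: {self.count_mode}")

    def regex(self) -> re.Pattern:
        body = "".join(
            c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in self.iupac.upper()
        )
        if self.count_mode == "overlapping":
            body = f"(?={body})"
        return re.compile(body)

    def reverse_complement(self) -> "MotifSpec":
        return MotifSpec(
            self.iupac.upper().translate(_COMP)[::-1], self.both_strands, self.count_mode
        )


def count_motif_occurrences(promoter: str, motif: MotifSpec) -> int:
    """Occurrences of the motif in a promoter sequence.

    Forward strand always; with ``both_strands`` the reverse-complement
    motif is also scanned on the given sequence (equivalent to scanning the
    motif on the other strand). Overlapping mode counts every start
    position; non-overlapping advances past each match.
    """
    seq = promoter.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"promoter contains non-nucleotide characters: {sorted(bad)}")
    total = len(motif.regex().findall(seq))
    if motif.both_strands:
        rc = motif.reverse_complement()
        if rc.iupac != motif.iupac:  # palindromic motifs match identically
            total += len(rc.regex().findall(seq))
    return total


def filter_motif_targets(
    counts: Mapping[str, int], min_count: int = 2, strict_greater: bool = True
) -> set[str]:
    """Genes whose motif count exceeds ``min_count`` (strictly by default)."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    if strict_greater:
        return {g for g, c in counts.items() if c > min_count}
    return {g for g, c in counts.items() if c >= min_count}


def promoter_sequences(
    genome: Mapping[str, str],
    genes,
    upstream: int = 2000,
) -> dict[str, str]:
    """Strand-aware upstream windows (promoters) for each gene.

    For '+' genes the ``upstream`` bp 5' of the start; for '-' genes the
    reverse complement of the region 3' of the end. Truncated at
    chromosome boundaries.
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    out = {}
    for g in genes:
        seq = genome[g.chrom]
        if g.strand == "-":
            s = seq[g.end : g.end + upstream]
            out[g.gene_id] = s.translate(comp)[::-1]
        else:
            out[g.gene_id] = seq[max(0, g.start - 1 - upstream) : g.start - 1]
    return out
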
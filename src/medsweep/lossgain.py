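"""Gene retention/loss calls between a target and a reference genome.

Best-hit gene pairs are ordered along target chromosomes; target genes with
no reference partner are marked "NA". For each NA gene the "absent region"
is the reference interval strictly between the reference partners of the
nearest flanking paired target genes (falling back to the chromosome end
when the NA gene sits at a chromosome boundary). The target protein is then
searched against the region by six-frame translated local alignment; a hit
clearing the identity and coverage thresholds means the gene is present but
unannotated in the reference, otherwise it was lost there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io import GeneRecord


@dataclass
class AbsentRegion:
    target_gene: str
    flank_status: str  # both | left_only | right_only | none
    reference_chrom: str | None = None
    start: int | None = None  # 1-based inclusive
    end: int | None = None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.reference_chrom is not None and self.start is not None


@dataclass
class AlignmentHit:
    identity_pct: float
    coverage_pct: float
    frame: int  # +1..+3 / -1..-3
    region_start: int  # within-region coordinates of the hit, 1-based nt
    region_end: int
    score: float


@dataclass
class LossCall:
    target_gene: str
    status: str  # lost_in_reference | present_unannotated | unresolved
    hit: AlignmentHit | None = None
    partial: bool = False
    reason: str | None = None


# ---------------------------------------------------------------------------
# Ordering and absent regions

def order_pairs_and_mark_na(
    best_hits: Mapping[str, str | None],
    target_genes: list[GeneRecord],
) -> list[tuple[GeneRecord, str | None]]:
    """Rows of (target gene, reference partner or None), in chromosome order."""
    ids = [g.gene_id for g in target_genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate target gene IDs")
    missing = [g.gene_id for g in target_genes if g.gene_id not in best_hits]
    if missing:
        raise KeyError(f"target genes absent from best-hit table: {missing[:5]}")
    ordered = sorted(target_genes, key=lambda g: (g.chrom, g.start))
    out = []
    for g in ordered:
        ref = best_hits[g.gene_id]
        out.append((g, ref if ref not in (None, "NA", "") else None))
    return out


def define_absent_regions(
    ordered: list[tuple[GeneRecord, str | None]],
    ref_coords: Mapping[str, GeneRecord],
    ref_chrom_lengths: Mapping[str, int],
) -> list[AbsentRegion]:
    """Reference search interval for every NA-marked target gene.

    Runs of consecutive NA genes share flanks: the nearest paired neighbours
    on either side are used. Flanking partners on different reference
    chromosomes leave the region undefined (split flanks).
    """
    regions: list[AbsentRegion] = []
    by_chrom: dict[str, list[tuple[GeneRecord, str | None]]] = {}
    for row in ordered:
        by_chrom.setdefault(row[0].chrom, []).append(row)

    def _partner(ref_id: str) -> GeneRecord:
        if ref_id not in ref_coords:
            raise KeyError(f"reference gene {ref_id} has no coordinates")
        return ref_coords[ref_id]

    for rows in by_chrom.values():
        for i, (gene, ref) in enumerate(rows):
            if ref is not None:
                continue
            left = next(
                (rows[j][1] for j in range(i - 1, -1, -1) if rows[j][1] is not None),
                None,
            )
            right = next(
                (rows[j][1] for j in range(i + 1, len(rows)) if rows[j][1] is not None),
                None,
            )
            if left is None and right is None:
                regions.append(
                    AbsentRegion(gene.gene_id, "none", reason="no paired flanks")
                )
                continue
            if left is not None and right is not None:
                gl, gr = _partner(left), _partner(right)
                if gl.chrom != gr.chrom:
                    regions.append(
                        AbsentRegion(
                            gene.gene_id, "both", reason="split flanks: partners on "
                            f"{gl.chrom} and {gr.chrom}",
                        )
                    )
                    continue
                # orientation-normalize: the partner earlier on the reference
                first, second = (gl, gr) if gl.start <= gr.start else (gr, gl)
                start, end = first.end + 1, second.start - 1
                if start > end:
                    regions.append(
                        AbsentRegion(
                            gene.gene_id, "both",
                            reason="flanking partners adjacent or overlapping",
                        )
                    )
                    continue
                regions.append(
                    AbsentRegion(gene.gene_id, "both", gl.chrom, start, end)
                )
            elif left is not None:
                g = _partner(left)
                chrom_end = ref_chrom_lengths[g.chrom]
                if g.end + 1 > chrom_end:
                    regions.append(
                        AbsentRegion(gene.gene_id, "left_only", reason="at chromosome end")
                    )
                else:
                    regions.append(
                        AbsentRegion(gene.gene_id, "left_only", g.chrom, g.end + 1, chrom_end)
                    )
            else:
                g = _partner(right)
                if g.start - 1 < 1:
                    regions.append(
                        AbsentRegion(gene.gene_id, "right_only", reason="at chromosome start")
                    )
                else:
                    regions.append(
                        AbsentRegion(gene.gene_id, "right_only", g.chrom, 1, g.start - 1)
                    )
    return regions


# ---------------------------------------------------------------------------
# Translated search

def _frame_segments(region: str) -> list[tuple[int, int, str]]:
    """(frame, nt_offset, peptide) for all six frames, split at stop codons.

    ``nt_offset`` is the 0-based offset of the segment's first codon within
    the forward-strand region for + frames, within the reverse complement
    for - frames.
    """
    from Bio.Seq import Seq

    segs = []
    for strand, seq in ((1, region), (-1, str(Seq(region).reverse_complement()))):
        for off in range(3):
            sub = seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            pep = str(Seq(sub).translate())
            start = 0
            for part in pep.split("*"):
                if part:
                    segs.append((strand * (off + 1), off + 3 * start, part))
                start += len(part) + 1
    return segs


def translated_local_alignment(
    query_protein: str, region: str
) -> AlignmentHit | None:
    """Best local alignment of a protein query against a DNA region.

    Six-frame translation with stop codons breaking frames into segments;
    each segment is aligned locally under BLOSUM62 with affine gaps
    (open 11, extend 1). Returns the best hit's identity over aligned
    columns and coverage of the query, or None when the region is all N /
    too short.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    query_protein = query_protein.rstrip("*")
    if len(query_protein) < 10:
        raise ValueError("query protein must be >= 10 aa")
    if len(region) < 3:
        raise ValueError("region must be >= 3 nt")
    region = region.upper()
    if set(region) <= {"N"}:
        return None

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0

    best: AlignmentHit | None = None
    for frame, nt_off, pep in _frame_segments(region):
        if not pep:
            continue
        try:
            aln = aligner.align(query_protein, pep.replace("X", "A"))
        except Exception:
            continue
        if len(aln) == 0:
            continue
        top = aln[0]
        if best is not None and top.score <= best.score:
            continue
        qa, ta = str(top[0]), str(top[1])
        cols = len(qa)
        ident = sum(x == y and x != "-" for x, y in zip(qa, ta))
        q_aligned = sum(x != "-" for x in qa)
        t_start_aa = int(top.aligned[1][0][0])
        t_end_aa = int(top.aligned[1][-1][1])
        nt_start = nt_off + 3 * t_start_aa  # strand-local coordinates
        nt_end = nt_off + 3 * t_end_aa
        if frame < 0:  # map back to forward strand
            nt_start, nt_end = len(region) - nt_end, len(region) - nt_start
        best = AlignmentHit(
            identity_pct=100.0 * ident / cols if cols else 0.0,
            coverage_pct=100.0 * q_aligned / len(query_protein),
            frame=frame,
            region_start=nt_start + 1,
            region_end=nt_end,
            score=float(top.score),
        )
    return best


# ---------------------------------------------------------------------------
# Classification

def classify_retention_loss(
    regions: list[AbsentRegion],
    target_proteins: Mapping[str, str],
    ref_genome: Mapping[str, str],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> list[LossCall]:
    """Call each NA gene lost_in_reference / present_unannotated / unresolved.

    A completed translated search meeting both thresholds yields
    present_unannotated; a completed search below them yields
    lost_in_reference; an undefined or all-N region yields unresolved. A
    high-identity hit whose query coverage misses the threshold is flagged
    partial (possible split/truncated copy) and left lost_in_reference.
    """
    calls = []
    for reg in regions:
        gene = reg.target_gene
        if not reg.defined:
            calls.append(LossCall(gene, "unresolved", reason=reg.reason))
            continue
        segment = ref_genome[reg.reference_chrom][reg.start - 1 : reg.end]
        if not segment or set(segment.upper()) <= {"N"}:
            calls.append(LossCall(gene, "unresolved", reason="region empty or all N"))
            continue
        query = target_proteins[gene]
        hit = translated_local_alignment(query, segment)
        if hit is None:
            calls.append(LossCall(gene, "unresolved", reason="no alignable frame"))
            continue
        if hit.identity_pct >= min_identity and hit.coverage_pct >= min_coverage:
            calls.append(LossCall(gene, "present_unannotated", hit=hit))
        else:
            partial = hit.identity_pct >= min_identity and hit.coverage_pct < min_coverage
            calls.append(LossCall(gene, "lost_in_reference", hit=hit, partial=partial))
    return calls


def summarize_calls(calls: list[LossCall]) -> dict[str, int]:
    out = {"lost_in_reference": 0, "present_unannotated": 0, "unresolved": 0}
    for c in calls:
        out[c.status] += 1
    return out
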
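"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the study's input classes without any external
data: (1) two-population diploid genotypes under the Balding-Nichols model
with planted selective sweeps, (2) codon-aligned CDS pairs whose third
positions diverged under a K80 process, (3) diploid shotgun reads from a
genome of known size, and (4) paired gene orders with planted gene
deletions and present-but-unannotated genes.

All generators are deterministic given (parameters, seed) and record their
truth in a :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as msio

FOURFOLD_PREFIXES = ("TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG")
_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimTruth:
    kind: str  # two_pop | codon_pairs | reads | gene_orders
    params: dict
    truth_records: list[tuple] = field(default_factory=list)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# 1. Two-population genotypes

def sim_two_pop_genotypes(
    n_per_pop: int,
    chrom_len: int,
    n_sites: int,
    F: float,
    sweeps: list[tuple[int, int, float, float]] | None = None,
    seed: int = 0,
    chrom: str = "chr1",
    out_vcf: str | Path | None = None,
    out_bed: str | Path | None = None,
):
    """Simulate biallelic diploid genotypes for a tolerance and a control pop.

    Background sites follow Balding-Nichols: ancestral frequency
    p ~ Uniform(0.05, 0.95); each population's frequency is Beta-distributed
    around p with dispersion set by ``F`` (F=0 means both populations share p
    exactly), so the expected Weir-Cockerham Fst is ~F. Genotypes are
    Binomial(2, population frequency).

    ``sweeps`` are (start, end, pi_reduction, divergence_boost) intervals,
    1-based inclusive, non-overlapping. Inside a sweep the tolerance
    frequency is pulled toward its nearer extreme in {0, 1} so that distance
    to the extreme — and hence expected heterozygosity — shrinks by roughly
    ``pi_reduction``-fold, while the control frequency is pushed a fraction
    ``divergence_boost`` of the way toward the opposite extreme, elevating
    between-population divergence.

    Returns (truth, positions, dosages, sample_ids); when ``out_vcf`` /
    ``out_bed`` are given, also writes a VCF v4.2 and a truth BED3.
    """
    if not (0 <= F < 1):
        raise ValueError("F must be in [0, 1); F=1 gives a degenerate Beta")
    if n_per_pop < 2:
        raise ValueError("need at least 2 individuals per population")
    sweeps = sorted(sweeps or [])
    for (s, e, pr, db) in sweeps:
        if not (1 <= s < e <= chrom_len):
            raise ValueError(f"sweep [{s},{e}] outside [1,{chrom_len}]")
        if pr < 1:
            raise ValueError("pi_reduction must be >= 1")
        if not (0 <= db <= 1):
            raise ValueError("divergence_boost must be in [0, 1]")
    for (_, e1, _, _), (s2, _, _, _) in zip(sweeps, sweeps[1:]):
        if s2 <= e1:
            raise ValueError("sweep intervals overlap")

    rng = _rng(seed)
    pos = np.sort(rng.choice(np.arange(1, chrom_len + 1), size=n_sites, replace=False))
    p_anc = rng.uniform(0.05, 0.95, n_sites)
    if F == 0:
        p_tol = p_anc.copy()
        p_ctl = p_anc.copy()
    else:
        shape = (1 - F) / F
        p_tol = rng.beta(p_anc * shape, (1 - p_anc) * shape)
        p_ctl = rng.beta(p_anc * shape, (1 - p_anc) * shape)

    for (s, e, pi_red, div_boost) in sweeps:
        in_sweep = (pos >= s) & (pos <= e)
        extreme = np.where(p_tol >= 0.5, 1.0, 0.0)
        p_tol = np.where(in_sweep, extreme + (p_tol - extreme) / pi_red, p_tol)
        opposite = 1.0 - extreme
        p_ctl = np.where(in_sweep, p_ctl + div_boost * (opposite - p_ctl), p_ctl)

    g_tol = rng.binomial(2, p_tol[:, None], size=(n_sites, n_per_pop))
    g_ctl = rng.binomial(2, p_ctl[:, None], size=(n_sites, n_per_pop))
    dosages = np.concatenate([g_tol, g_ctl], axis=1).astype(np.int8)
    sample_ids = [f"TOL{i+1:02d}" for i in range(n_per_pop)] + [
        f"CTL{i+1:02d}" for i in range(n_per_pop)
    ]
    ref_alt = np.stack(
        [rng.permutation(4)[:2] for _ in range(n_sites)]
    )  # distinct ref/alt bases per site
    truth = SimTruth(
        kind="two_pop",
        params=dict(
            n_per_pop=n_per_pop, chrom_len=chrom_len, n_sites=n_sites, F=F,
            sweeps=list(sweeps), seed=seed, chrom=chrom,
        ),
        truth_records=[(chrom, s - 1, e) for (s, e, _, _) in sweeps],
    )
    if out_vcf is not None:
        write_vcf(
            out_vcf, chrom, chrom_len, pos,
            _BASES[ref_alt[:, 0]], _BASES[ref_alt[:, 1]], dosages, sample_ids,
        )
    if out_bed is not None:
        msio.write_bed3(truth.truth_records, out_bed)
    return truth, pos, dosages, sample_ids


def write_vcf(
    path: str | Path,
    chrom: str,
    chrom_len: int,
    pos: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    dosages: np.ndarray,
    sample_ids: list[str],
) -> None:
    """Minimal diploid GT-only VCF v4.2 writer ("./." for missing)."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for i in range(len(pos)):
            gts = "\t".join(gt_codes[int(d)] for d in dosages[i])
            fh.write(f"{chrom}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def sim_demo_dataset(out_dir: str | Path, seed: int = 0) -> dict:
    """Self-contained 7-vs-7 sweep-scan dataset mirroring the study design.

    One 4 Mb chromosome, 40k SNPs, background differentiation F=0.15, three
    planted 80 kb sweeps (10-fold diversity reduction, control frequencies
    boosted so sweep-window Fst is about three times background); writes
    VCF, truth BED, population files, a tiling gene GFF3, a gene->GO table
    and a ready-to-run pipeline config YAML. Returns paths plus the truth
    object.
    """
    import pandas as pd
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom, chrom_len, n_sites = "chr1", 4_000_000, 40_000
    sweeps = [
        (500_001, 580_000, 10.0, 0.25),
        (1_800_001, 1_880_000, 10.0, 0.25),
        (3_200_001, 3_280_000, 10.0, 0.25),
    ]
    paths = {
        "vcf": out_dir / "accessions.vcf",
        "bed": out_dir / "sweep_truth.bed",
        "gff": out_dir / "genes.gff3",
        "gene2go": out_dir / "gene2go.tsv",
        "pop_tolerance": out_dir / "pop_tolerance.txt",
        "pop_control": out_dir / "pop_control.txt",
        "config": out_dir / "config.yaml",
    }
    truth, _, _, sample_ids = sim_two_pop_genotypes(
        n_per_pop=7, chrom_len=chrom_len, n_sites=n_sites, F=0.15,
        sweeps=sweeps, seed=seed, chrom=chrom,
        out_vcf=paths["vcf"], out_bed=paths["bed"],
    )
    with open(paths["pop_tolerance"], "w") as fh:
        fh.write("\n".join(s for s in sample_ids if s.startswith("TOL")) + "\n")
    with open(paths["pop_control"], "w") as fh:
        fh.write("\n".join(s for s in sample_ids if s.startswith("CTL")) + "\n")
    # tiling gene annotation + GO terms (deterministic from the same seed)
    rng = _rng(seed + 1)
    genes = []
    gstart, gi = 2_001, 0
    while gstart + 2_000 < chrom_len:
        gi += 1
        genes.append(
            msio.GeneRecord(f"gene{gi:04d}", chrom, gstart, gstart + 1_999,
                            "+" if rng.random() < 0.5 else "-")
        )
        gstart += 8_000
    msio.write_gff_genes(genes, paths["gff"])
    terms = [f"GO:{7000000+i}" for i in range(20)]
    rows = []
    for g in genes:
        in_sweep = any(s <= g.start <= e for s, e, *_ in sweeps)
        # two terms concentrate in sweep regions; the rest are uniform
        if in_sweep and rng.random() < 0.6:
            rows.append((g.gene_id, terms[0] if rng.random() < 0.5 else terms[1]))
        rows.append((g.gene_id, terms[int(rng.integers(2, len(terms)))]))
    pd.DataFrame(rows, columns=["gene_id", "go_term"]).to_csv(
        paths["gene2go"], sep="\t", index=False
    )
    config = dict(
        vcf=str(paths["vcf"]), gff=str(paths["gff"]),
        pop_tolerance=str(paths["pop_tolerance"]),
        pop_control=str(paths["pop_control"]),
        gene2go=str(paths["gene2go"]),
        out_dir=str(out_dir / "results"), seed=seed,
    )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth}


# ---------------------------------------------------------------------------
# 2. K80 codon pairs for the 4DTv oracle

def _k80_third_base_probs(beta_t: float, kappa_ratio: float) -> np.ndarray:
    """4x4 substitution matrix for a third codon position under K80.

    ``beta_t`` is the total transversion branch parameter (rate x time per
    transversion target direction summed over the branch); transversions
    accumulate to probability 0.5 * (1 - exp(-4 * beta_t)) split equally
    between the two transversion targets, transitions per the standard K80
    solution with alpha = kappa_ratio * beta.
    """
    alpha_t = kappa_ratio * beta_t
    p_tv_total = 0.5 * (1.0 - np.exp(-4.0 * beta_t))
    p_ts = 0.25 - 0.5 * np.exp(-2.0 * (alpha_t + beta_t)) + 0.25 * np.exp(-4.0 * beta_t)
    p_same = 1.0 - p_ts - p_tv_total
    # base order A, C, G, T; transitions A<->G, C<->T
    transition_of = {0: 2, 1: 3, 2: 0, 3: 1}
    P = np.zeros((4, 4))
    for b in range(4):
        P[b, b] = p_same
        P[b, transition_of[b]] = p_ts
        for t in range(4):
            if t != b and t != transition_of[b]:
                P[b, t] = p_tv_total / 2.0
    return P


_PURINE = frozenset("AG")


def is_transversion(b1: str, b2: str) -> bool:
    return b1 != b2 and ((b1 in _PURINE) != (b2 in _PURINE))


def sim_codon_pair_set(
    n_pairs: int,
    sites_per_pair: int,
    beta_t: float,
    kappa_ratio: float = 2.0,
    seed: int = 0,
    out_fasta: str | Path | None = None,
):
    """Codon-aligned CDS pairs diverged only at fourfold third positions.

    Both sequences share codon positions 1-2 drawn from fourfold-degenerate
    families; third positions of sequence B evolve from A's by a K80 process
    with total transversion parameter ``beta_t``, so the expected 4DTv is
    0.5 * (1 - exp(-4 * beta_t)). Truth records the exact per-pair
    transversion count.

    Returns (truth, pairs) where pairs is a list of (id, seq_a, seq_b).
    """
    if beta_t < 0:
        raise ValueError("beta_t must be non-negative")
    if sites_per_pair < 1:
        raise ValueError("sites_per_pair must be >= 1")
    rng = _rng(seed)
    P = _k80_third_base_probs(beta_t, kappa_ratio)
    cum = np.cumsum(P, axis=1)
    pairs = []
    truth_records = []
    for i in range(n_pairs):
        prefixes = rng.integers(0, len(FOURFOLD_PREFIXES), sites_per_pair)
        third_a = rng.integers(0, 4, sites_per_pair)
        u = rng.random(sites_per_pair)
        third_b = (u[:, None] > cum[third_a]).sum(axis=1)
        codons_a = [FOURFOLD_PREFIXES[p] + "ACGT"[b] for p, b in zip(prefixes, third_a)]
        codons_b = [FOURFOLD_PREFIXES[p] + "ACGT"[b] for p, b in zip(prefixes, third_b)]
        seq_a, seq_b = "".join(codons_a), "".join(codons_b)
        n_tv = sum(
            is_transversion("ACGT"[x], "ACGT"[y]) for x, y in zip(third_a, third_b)
        )
        pid = f"pair{i+1:04d}"
        pairs.append((pid, seq_a, seq_b))
        truth_records.append((pid, n_tv))
    truth = SimTruth(
        kind="codon_pairs",
        params=dict(
            n_pairs=n_pairs, sites_per_pair=sites_per_pair, beta_T=beta_t,
            kappa_ratio=kappa_ratio, seed=seed,
            expected_4dtv=0.5 * (1.0 - float(np.exp(-4.0 * beta_t))),
        ),
        truth_records=truth_records,
    )
    if out_fasta is not None:
        recs = []
        for pid, sa, sb in pairs:
            recs.append((f"{pid}_A", sa))
            recs.append((f"{pid}_B", sb))
        msio.write_fasta(recs, out_fasta)
    return truth, pairs


# ---------------------------------------------------------------------------
# 3. Diploid shotgun reads

def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sim_diploid_reads(
    genome_len: int,
    coverage: float,
    read_len: int = 100,
    het_rate: float = 0.0,
    err_rate: float = 0.0,
    seed: int = 0,
    out_fastq: str | Path | None = None,
    out_genome: str | Path | None = None,
):
    """Uniform shotgun reads from two haplotypes of a random genome.

    The second haplotype differs from the first at Bernoulli(``het_rate``)
    positions; reads start uniformly, alternate haplotypes, and acquire
    substitution errors at ``err_rate`` per base. Total coverage (both
    haplotypes combined) is ``coverage``.

    Returns (truth, reads) and optionally writes FASTQ (Phred+33) and the
    haplotype-1 genome FASTA.
    """
    if genome_len < read_len:
        raise ValueError("genome_len must be >= read_len")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = _rng(seed)
    hap1 = rng.integers(0, 4, genome_len)
    hap2 = hap1.copy()
    if het_rate > 0:
        het_sites = rng.random(genome_len) < het_rate
        shift = rng.integers(1, 4, int(het_sites.sum()))
        hap2[het_sites] = (hap2[het_sites] + shift) % 4
    haps = (hap1, hap2)
    n_reads = int(round(coverage * genome_len / read_len))
    starts = rng.integers(0, genome_len - read_len + 1, n_reads)
    reads = []
    for i, s in enumerate(starts):
        arr = haps[i % 2][s : s + read_len].copy()
        if err_rate > 0:
            errs = rng.random(read_len) < err_rate
            arr[errs] = (arr[errs] + rng.integers(1, 4, int(errs.sum()))) % 4
        reads.append("".join(_BASES[arr]))
    truth = SimTruth(
        kind="reads",
        params=dict(
            genome_len=genome_len, coverage=coverage, read_len=read_len,
            het_rate=het_rate, err_rate=err_rate, seed=seed,
        ),
        truth_records=[("genome_len", genome_len)],
    )
    if out_fastq is not None:
        msio.write_fastq(((f"read{i+1}", r) for i, r in enumerate(reads)), out_fastq)
    if out_genome is not None:
        msio.write_fasta([("genome_hap1", "".join(_BASES[hap1]))], out_genome)
    return truth, reads


# ---------------------------------------------------------------------------
# 4. Paired gene orders with planted losses

_STOPLESS_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_STOPLESS_CODONS), n_codons - 1)
    return "ATG" + "".join(_STOPLESS_CODONS[i] for i in idx)


def sim_gene_order_pair(
    n_genes: int,
    n_chroms: int = 2,
    deletions: list[str] | None = None,
    unannotated_but_present: list[str] | None = None,
    seed: int = 0,
    cds_codons: int = 100,
    spacer_len: int = 300,
    out_dir: str | Path | None = None,
):
    """Target/reference gene orders with planted losses.

    Target genes ``t0001..tN`` are laid out across ``n_chroms`` chromosomes;
    the reference mirrors the order. Genes named in ``deletions`` have no
    sequence in the reference genome at all; genes in
    ``unannotated_but_present`` keep their coding sequence embedded in the
    reference FASTA but receive no reference annotation or best hit —
    the two lists must be disjoint. All other genes map 1:1 in the best-hit
    table.

    Returns a dict with keys: truth, target_genes (GeneRecord list),
    ref_genes, best_hits (target->ref or None), ref_genome (chrom->seq),
    target_proteins (gene->aa), ref_chrom_lengths. When ``out_dir`` is set,
    writes gene-order TSVs, the reference FASTA, target protein FASTA and
    best-hit TSV.
    """
    from Bio.Seq import Seq

    deletions = list(deletions or [])
    unann = list(unannotated_but_present or [])
    if set(deletions) & set(unann):
        raise ValueError("deletions and unannotated_but_present must be disjoint")
    rng = _rng(seed)
    gene_ids = [f"t{i+1:04d}" for i in range(n_genes)]
    for g in deletions + unann:
        if g not in gene_ids:
            raise ValueError(f"unknown gene id {g}")

    per_chrom = np.array_split(np.arange(n_genes), n_chroms)
    target_genes: list[msio.GeneRecord] = []
    ref_genes: list[msio.GeneRecord] = []
    best_hits: dict[str, str | None] = {}
    ref_genome: dict[str, str] = {}
    target_proteins: dict[str, str] = {}
    cds_by_gene: dict[str, str] = {}

    for ci, idxs in enumerate(per_chrom):
        tchrom, rchrom = f"tChr{ci+1}", f"rChr{ci+1}"
        tpos = 1
        ref_parts: list[str] = []
        rpos = 1
        for gi in idxs:
            gid = gene_ids[gi]
            cds = _random_cds(rng, cds_codons)
            cds_by_gene[gid] = cds
            target_proteins[gid] = str(Seq(cds).translate())
            target_genes.append(
                msio.GeneRecord(gid, tchrom, tpos, tpos + len(cds) - 1, "+")
            )
            tpos += len(cds) + spacer_len
            spacer = "".join(_BASES[rng.integers(0, 4, spacer_len)])
            if gid in deletions:
                best_hits[gid] = None
                ref_parts.append(spacer)
                rpos += len(spacer)
            elif gid in unann:
                best_hits[gid] = None
                ref_parts.append(cds + spacer)  # present but not annotated
                rpos += len(cds) + len(spacer)
            else:
                rid = gid.replace("t", "r", 1)
                best_hits[gid] = rid
                ref_genes.append(
                    msio.GeneRecord(rid, rchrom, rpos, rpos + len(cds) - 1, "+")
                )
                ref_parts.append(cds + spacer)
                rpos += len(cds) + len(spacer)
        ref_genome[rchrom] = "".join(ref_parts)

    truth = SimTruth(
        kind="gene_orders",
        params=dict(
            n_genes=n_genes, n_chroms=n_chroms, seed=seed,
            deletions=deletions, unannotated_but_present=unann,
        ),
        truth_records=[(g, "deleted") for g in deletions]
        + [(g, "unannotated_present") for g in unann],
    )
    out = dict(
        truth=truth, target_genes=target_genes, ref_genes=ref_genes,
        best_hits=best_hits, ref_genome=ref_genome,
        target_proteins=target_proteins,
        ref_chrom_lengths={c: len(s) for c, s in ref_genome.items()},
        cds_by_gene=cds_by_gene,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in target_genes],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        ).to_csv(out_dir / "target_gene_order.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in ref_genes],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        ).to_csv(out_dir / "reference_gene_order.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(t, r if r is not None else "NA") for t, r in best_hits.items()],
            columns=["target_gene", "reference_gene"],
        ).to_csv(out_dir / "best_hits.tsv", sep="\t", index=False)
        msio.write_fasta(ref_genome.items(), out_dir / "reference_genome.fasta")
        msio.write_fasta(
            ((g, p.rstrip("*")) for g, p in target_proteins.items()),
            out_dir / "target_proteins.fasta",
        )
    return out
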
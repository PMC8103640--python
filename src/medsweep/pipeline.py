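"""Run configuration, input validation and end-to-end sweep-scan orchestration.

``run_sweep_pipeline`` replays the analysis shape of the study on any
VCF + GFF3 + population files: read genotypes -> sliding windows ->
windowed Fst and per-population theta-pi -> log2 diversity ratio ->
top-fraction screens -> region merging -> candidate genes -> optional GO
enrichment. Every run writes its resolved configuration and a manifest next
to the outputs, and identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrich as me
from . import io as msio
from . import popgen as mp

log = logging.getLogger("medsweep")


@dataclass
class RunConfig:
    vcf: str
    gff: str
    pop_tolerance: str
    pop_control: str
    out_dir: str
    gene2go: str | None = None
    chrom_lengths: str | None = None  # TSV chrom<TAB>length; default: VCF contigs
    window_size: int = 40_000
    window_step: int = 20_000
    top_fraction: float = 0.05
    combine: str = "intersection"
    min_call_rate: float = 0.0
    min_snps: int = 10
    clamp_negative_fst: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ValidationReport:
    failures: list[dict] = field(default_factory=list)
    warnings: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Per-file format checks with machine-readable pass/fail reasons."""
    rep = ValidationReport()

    def fail(path, reason):
        rep.failures.append({"path": str(path), "reason": reason})

    for name in ("vcf", "gff", "pop_tolerance", "pop_control"):
        p = getattr(config, name)
        if not Path(p).exists():
            fail(p, f"{name} file does not exist")
    if rep.failures:
        return rep
    # VCF header and samples
    try:
        from cyvcf2 import VCF

        samples = set(VCF(config.vcf).samples)
        if not samples:
            fail(config.vcf, "VCF has no samples")
    except Exception as exc:
        fail(config.vcf, f"VCF unreadable: {exc}")
        samples = set()
    for name in ("pop_tolerance", "pop_control"):
        ids = msio.read_population_file(getattr(config, name))
        if not ids:
            fail(getattr(config, name), "population file is empty")
        for sid in ids:
            if samples and sid not in samples:
                fail(getattr(config, name), f"sample '{sid}' not in VCF")
    try:
        import warnings as _w

        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            msio.read_gff_genes(config.gff)
        for w in caught:
            rep.warnings.append({"path": config.gff, "reason": str(w.message)})
    except ValueError as exc:
        fail(config.gff, str(exc))
    return rep


def run_sweep_pipeline(config: RunConfig) -> Path:
    """Execute the full scan and write all stage outputs to ``out_dir``.

    Outputs: windows.tsv, thresholds.json, sweep_regions.bed,
    candidate_genes.tsv, enrichment.tsv (when an annotation is given),
    resolved_config.yaml and manifest.json. Idempotent for a fixed config.
    """
    t0 = time.time()
    report = validate_inputs(config)
    if not report.ok:
        raise ValueError(f"input validation failed: {report.failures}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        t = time.time()
        try:
            result = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        log.info("stage %-18s %6.2fs", name, time.time() - t)
        return result

    gm = stage("read_vcf", mp.read_vcf_biallelic, config.vcf, config.min_call_rate)
    log.info("loaded %d biallelic SNPs x %d samples", gm.n_sites, len(gm.sample_ids))
    split = mp.PopulationSplit(
        tuple(msio.read_population_file(config.pop_tolerance)),
        tuple(msio.read_population_file(config.pop_control)),
    )
    if config.chrom_lengths:
        lengths = {
            str(r[0]): int(r[1])
            for r in pd.read_csv(config.chrom_lengths, sep="\t", header=None).values
        }
    else:
        lengths = mp.vcf_contig_lengths(config.vcf)
    windows = stage("windows", mp.make_windows, lengths, config.window_size, config.window_step)
    stats = stage(
        "window_stats", mp.window_scan, gm, split, windows,
        config.min_snps, config.clamp_negative_fst,
    )
    msio.write_tsv(stats, out / "windows.tsv")

    top_fst, thr_fst = stage(
        "top_fst", mp.select_top_fraction, stats, "fst", config.top_fraction
    )
    top_ratio, thr_ratio = stage(
        "top_ratio", mp.select_top_fraction, stats, "log2_ratio",
        config.top_fraction, True,
    )
    with open(out / "thresholds.json", "w") as fh:
        json.dump(
            {
                "fst_threshold": thr_fst,
                "log2_ratio_threshold": thr_ratio,
                "top_fraction": config.top_fraction,
                "n_windows_ranked_fst": int(stats["fst"].notna().sum()),
                "n_top_fst": len(top_fst),
                "n_top_ratio": len(top_ratio),
            },
            fh, indent=2,
        )
    regions = stage("regions", mp.call_sweep_regions, top_fst, top_ratio, config.combine)
    msio.write_bed3(regions.intervals, out / "sweep_regions.bed")

    genes = msio.read_gff_genes(config.gff)
    candidates = stage("genes", mp.genes_in_regions, genes, regions)
    gene_map = {g.gene_id: g for g in genes}
    cand_df = pd.DataFrame(
        [
            (gid, gene_map[gid].chrom, gene_map[gid].start, gene_map[gid].end)
            for gid in candidates
        ],
        columns=["gene_id", "chrom", "start", "end"],
    )
    msio.write_tsv(cand_df, out / "candidate_genes.tsv")

    if config.gene2go:
        term2genes = me.read_gene2go(config.gene2go)
        enr = stage(
            "enrichment", me.go_enrichment, set(candidates), term2genes,
            {g.gene_id for g in genes},
        )
        msio.write_tsv(enr, out / "enrichment.tsv")

    config.to_yaml(out / "resolved_config.yaml")
    import medsweep

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {
                "medsweep_version": medsweep.__version__,
                "config_sha256": config.digest(),
                "seed": config.seed,
                "n_sites": gm.n_sites,
                "n_samples": len(gm.sample_ids),
                "n_windows": len(windows),
                "n_regions": len(regions.intervals),
                "n_candidate_genes": len(candidates),
            },
            fh, indent=2,
        )
    log.info("pipeline complete in %.2fs -> %s", time.time() - t0, out)
    return out
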
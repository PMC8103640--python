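"""Shared format readers and writers.

Conventions: BED intervals are 0-based half-open; VCF and GFF3 coordinates
are 1-based inclusive on ingestion. Every tabular output carries a header
line and round-trips through the readers in this module.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) records with fixed line wrap."""
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield read sequences from FASTA or FASTQ (gzip allowed)."""
    from Bio import SeqIO

    path = Path(path)
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3 gene spans

@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str


def _gff_attr(attrs: str, key: str) -> str | None:
    for field in attrs.strip().rstrip(";").split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff_genes(path: str | Path, feature: str = "gene") -> list[GeneRecord]:
    """Read gene spans from GFF3.

    Falls back to ``mRNA`` features when no ``gene`` features exist (some
    annotations only carry transcript rows); raises listing the available
    feature types when neither is present.
    """
    rows: list[GeneRecord] = []
    seen_types: set[str] = set()
    fallback: list[GeneRecord] = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            ftype = parts[2]
            seen_types.add(ftype)
            if ftype not in (feature, "mRNA"):
                continue
            gid = _gff_attr(parts[8], "ID") or _gff_attr(parts[8], "Name")
            if gid is None:
                continue
            rec = GeneRecord(gid, parts[0], int(parts[3]), int(parts[4]), parts[6])
            (rows if ftype == feature else fallback).append(rec)
    if rows:
        return rows
    if fallback:
        import warnings

        warnings.warn(f"no '{feature}' features; using mRNA spans", stacklevel=2)
        return fallback
    raise ValueError(
        f"GFF3 file {path} has no '{feature}' or 'mRNA' features; "
        f"available types: {sorted(seen_types)}"
    )


def write_gff_genes(genes: Iterable[GeneRecord], path: str | Path, source: str = "medsweep") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED3 / generic TSV

def write_bed3(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                c, s, e = line.split()[:3]
                out.append((c, int(s), int(e)))
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_population_file(path: str | Path) -> list[str]:
    """One sample ID per line; blank lines and '#' comments ignored."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
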
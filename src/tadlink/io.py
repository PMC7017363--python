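"""Readers and writers for the pipeline's plain-text formats.

BED3+ for TADs (column 4, when present, is the TAD id), BED6 for genes,
a BED-like 7-column table for DMRs (chrom, start, end, id, GC fraction,
CpG density, genic flag), two-column chrom.sizes, a gene_id/organ TSV
for annotations, FASTA for the genome.  All coordinates are read and
written 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genome import Genome
from .intervals import GenomicInterval, IntervalSet
from .linking import GeneModel
from .placement import DMRRecord

logger = logging.getLogger("tadlink.io")

__all__ = [
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_dmr_table",
    "write_dmr_table",
    "read_genes_bed",
    "write_genes_bed",
    "read_annotations",
    "write_annotations",
    "write_fasta",
    "read_genome",
    "write_json",
]


def _parse_coords(fields: list[str], path, lineno: int) -> tuple[str, int, int]:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if end <= start or start < 0:
        raise ValueError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
    return chrom, start, end


def read_bed(
    path: str | Path,
    min_columns: int = 3,
    label: str | None = None,
    add_chr_prefix: bool = False,
) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Malformed lines raise with their line number.  Column 4, when
    present, supplies interval ids.  ``add_chr_prefix`` prepends ``chr``
    to names lacking it (no other normalization is performed).
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    ids: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_columns} columns, got {len(fields)}"
                )
            chrom, start, end = _parse_coords(fields, path, lineno)
            if add_chr_prefix and not chrom.startswith("chr"):
                chrom = "chr" + chrom
            intervals.append(GenomicInterval(chrom, start, end))
            ids.append(fields[3] if len(fields) > 3 else f"iv_{lineno:06d}")
    if not intervals:
        logger.warning("%s: empty BED file", path)
    return IntervalSet(intervals, label=label or path.stem, ids=ids)


def write_bed(ivset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, iv_id in zip(ivset.intervals, ivset.ids):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv_id}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_dmr_table(path: str | Path) -> list[DMRRecord]:
    """Read the 7-column DMR table (BED3 + id, gc, cpg, genic flag)."""
    path = Path(path)
    out: list[DMRRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            chrom, start, end = _parse_coords(fields, path, lineno)
            out.append(
                DMRRecord(
                    interval=GenomicInterval(chrom, start, end),
                    id=fields[3],
                    gc_fraction=float(fields[4]),
                    cpg_density=float(fields[5]),
                    is_genic=fields[6] in ("1", "True", "true"),
                )
            )
    return out


def write_dmr_table(dmrs: Sequence[DMRRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in dmrs:
            iv = d.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d.id}\t"
                f"{d.gc_fraction:.6f}\t{d.cpg_density:.6f}\t{int(d.is_genic)}\n"
            )


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read genes from BED6 (name column = gene_id); strand defaults to +."""
    path = Path(path)
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: gene BED needs >= 4 columns")
            chrom, start, end = _parse_coords(fields, path, lineno)
            strand = fields[5] if len(fields) > 5 else "+"
            out.append(
                GeneModel(GenomicInterval(chrom, start, end), gene_id=fields[3], strand=strand)
            )
    return out


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "organ"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation TSV lacks columns {sorted(missing)}")
    return df[["gene_id", "organ"]]


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.iter_sequences():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genome(path: str | Path) -> Genome:
    return Genome.from_fasta(str(path))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
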
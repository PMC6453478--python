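"""Genome annotation I/O and same-strand gene flattening.

All coordinates are 0-based half-open internally.  Conversion to and from
the 1-based closed GTF convention happens only at file boundaries; BED and
bedGraph share the internal convention.

Read-through discovery anchors at the edges of *flattened blocks* — maximal
unions of overlapping (or touching) same-strand gene models — so that a
downstream-of-gene region for a gene nested inside a longer host gene starts
at the end of the host, not the nested gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneModel",
    "FlatBlock",
    "OperonRecord",
    "GtfParseError",
    "parse_gtf",
    "parse_operons_bed",
    "flatten_genes",
    "write_regions",
    "read_bed",
    "write_gtf_genes",
]

STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """Raised for malformed GTF/BED input, naming the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded annotated gene interval.

    ``start``/``end`` are 0-based half-open.  ``biotype`` carries the GTF
    biotype attribute (e.g. protein_coding, ncRNA, snoRNA, rRNA) and is used
    downstream to identify rRNA genes for normalization.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FlatBlock:
    """Maximal union of overlapping-or-touching same-strand genes.

    Blocks on one strand are pairwise disjoint; every gene belongs to
    exactly one block.  ``block_id`` is the sorted member gene ids joined
    with ``|`` so it is deterministic for a given annotation.
    """

    block_id: str
    chrom: str
    start: int
    end: int
    strand: str
    member_gene_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OperonRecord:
    """A polycistronic gene cluster interval (common in C. elegans)."""

    operon_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"operon {self.operon_id}: require 0 <= start < end")
        if self.strand not in STRANDS:
            raise ValueError(f"operon {self.operon_id}: strand must be + or -")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def _iter_gtf_records(path: str | Path):
    """Yield (line_number, fields) for non-comment GTF lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def parse_gtf(
    path: str | Path,
    feature_type: str = "gene",
    id_attribute: str = "gene_id",
    biotype_attributes: Sequence[str] = ("biotype", "gene_biotype", "gene_type"),
) -> list[GeneModel]:
    """Parse gene records from a GTF file.

    Only lines whose third column equals ``feature_type`` are kept.  GTF
    1-based closed coordinates are converted to 0-based half-open.  Records
    with strand ``.`` are rejected (the discovery scan is strand-specific),
    and duplicate ids raise.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, f in _iter_gtf_records(path):
        chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = f
        if ftype != feature_type:
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from exc
        if strand not in STRANDS:
            raise GtfParseError(
                f"{path}: line {lineno}: strand {strand!r} not allowed for "
                f"stranded analysis"
            )
        attr = _parse_attributes(attrs)
        if id_attribute not in attr:
            raise GtfParseError(
                f"{path}: line {lineno}: missing attribute {id_attribute!r}"
            )
        gene_id = attr[id_attribute]
        if gene_id in seen:
            raise GtfParseError(
                f"{path}: line {lineno}: duplicate {id_attribute} {gene_id!r}"
            )
        seen.add(gene_id)
        biotype = "protein_coding"
        for key in biotype_attributes:
            if key in attr:
                biotype = attr[key]
                break
        if start1 < 1 or end1 < start1:
            raise GtfParseError(
                f"{path}: line {lineno}: invalid GTF interval {start1}..{end1}"
            )
        genes.append(GeneModel(gene_id, chrom, start1 - 1, end1, strand, biotype))
    return genes


def parse_operons(
    path: str | Path, feature_type: str = "operon", id_attribute: str = "operon_id"
) -> list[OperonRecord]:
    """Parse operon records from GTF features of the given type."""
    ops: list[OperonRecord] = []
    for lineno, f in _iter_gtf_records(path):
        chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = f
        if ftype != feature_type:
            continue
        attr = _parse_attributes(attrs)
        op_id = attr.get(id_attribute) or attr.get("gene_id") or f"operon_L{lineno}"
        if strand not in STRANDS:
            raise GtfParseError(f"{path}: line {lineno}: operon needs a strand")
        ops.append(OperonRecord(op_id, chrom, int(start_s) - 1, int(end_s), strand))
    return ops


def parse_operons_bed(path: str | Path) -> list[OperonRecord]:
    """Parse operons from a BED6 file (0-based half-open, strand in col 6)."""
    ops: list[OperonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise GtfParseError(
                    f"{path}: line {lineno}: BED6 with strand required for operons"
                )
            ops.append(OperonRecord(f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return ops


def flatten_genes(genes: Iterable[GeneModel]) -> list[FlatBlock]:
    """Merge overlapping-or-touching same-strand genes into maximal blocks.

    Touching genes (end == next start) merge: a zero-length gap cannot hold
    any read-through signal, so the scan treats them as one unit.  The
    result is sorted by (chrom, strand, start) and is idempotent under
    re-flattening.
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append(g)

    blocks: list[FlatBlock] = []
    for (chrom, strand), gs in sorted(by_key.items()):
        gs = sorted(gs, key=lambda g: (g.start, g.end))
        cur_start, cur_end = gs[0].start, gs[0].end
        members = [gs[0].gene_id]
        for g in gs[1:]:
            if g.start <= cur_end:  # overlap or touch
                cur_end = max(cur_end, g.end)
                members.append(g.gene_id)
            else:
                blocks.append(_make_block(chrom, strand, cur_start, cur_end, members))
                cur_start, cur_end, members = g.start, g.end, [g.gene_id]
        blocks.append(_make_block(chrom, strand, cur_start, cur_end, members))
    blocks.sort(key=lambda b: (b.chrom, b.strand, b.start))
    return blocks


def _make_block(chrom, strand, start, end, members) -> FlatBlock:
    ids = tuple(sorted(members))
    return FlatBlock("|".join(ids), chrom, start, end, strand, ids)


# -- region output ----------------------------------------------------------

_REGION_FIELDS = (
    "region_id",
    "category",
    "parent_block",
    "chrom",
    "start",
    "end",
    "strand",
    "mode",
    "mean_depth",
    "skipped_gene_ids",
)


def write_regions(regions, path: str | Path, format: str = "bed") -> None:
    """Write read-through regions as BED6, GTF, or a TSV table.

    BED is 0-based half-open with score = round(mean depth x 100); GTF is
    1-based closed with the category as the feature type.
    """
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.region_id))
    with open(path, "w") as fh:
        if format == "bed":
            for r in regions:
                score = int(round(r.mean_depth * 100))
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{score}\t{r.strand}\n"
                )
        elif format == "gtf":
            for r in regions:
                attrs = (
                    f'region_id "{r.region_id}"; parent_block "{r.parent_block}"; '
                    f'mode "{r.mode}";'
                )
                fh.write(
                    f"{r.chrom}\tdogcatcher\t{r.category}\t{r.start + 1}\t{r.end}\t"
                    f".\t{r.strand}\t.\t{attrs}\n"
                )
        elif format == "table":
            fh.write("\t".join(_REGION_FIELDS) + "\n")
            for r in regions:
                skipped = ",".join(r.skipped_gene_ids)
                fh.write(
                    f"{r.region_id}\t{r.category}\t{r.parent_block}\t{r.chrom}\t"
                    f"{r.start}\t{r.end}\t{r.strand}\t{r.mode}\t"
                    f"{r.mean_depth:.6g}\t{skipped}\n"
                )
        else:
            raise ValueError(f"unknown region output format: {format!r}")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    """Read BED lines back as (chrom, start, end, name, score, strand) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise GtfParseError(f"{path}: line {lineno}: too few BED columns")
            name = f[3] if len(f) > 3 else f"region_{lineno}"
            score = float(f[4]) if len(f) > 4 else 0.0
            strand = f[5] if len(f) > 5 else "+"
            out.append((f[0], int(f[1]), int(f[2]), name, score, strand))
    return out


def write_gtf_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF lines (inverse of :func:`parse_gtf`)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end)):
            attrs = f'gene_id "{g.gene_id}"; biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tdogcatcher\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
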
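"""Sliding-window discovery of read-through transcription regions.

Four geometries are called per flattened gene block:

* ``DoG``  — sense signal downstream of the block's 3' end;
* ``ADoG`` — antisense signal downstream of the 3' end;
* ``PoG``  — sense signal upstream of the 5' end;
* ``APoG`` — antisense signal upstream of the 5' end.

The scan examines consecutive non-overlapping windows (default 100 bp)
moving away from the anchor.  A window passes when at least a fraction
``min_covered_frac`` of its bases carry depth >= ``min_depth`` on the
signal strand.  When a window touches a gene on the signal strand the scan
either stops there, truncating at the gene's near edge (*local* mode), or
records the gene and keeps going (*meta* mode).  The called region runs
from the anchor to the end of the last passing stretch, then is trimmed
inward to the last base above threshold so windows never pad a region with
trailing zeros.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

from .annotation import FlatBlock, GeneModel, OperonRecord
from .coverage import StrandedCoverage

__all__ = [
    "CATEGORIES",
    "DiscoveryParams",
    "ReadThroughRegion",
    "scan_from_anchor",
    "discover_regions",
    "filter_regions",
    "associate_overlapped_genes",
]

CATEGORIES = ("DoG", "ADoG", "PoG", "APoG")

_PREFIX = {"DoG": "do", "ADoG": "ado", "PoG": "po", "APoG": "apo"}
_OPPOSITE = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class DiscoveryParams:
    """Tunables of the window scan.

    window            window size in bases (the scan step equals the window).
    min_depth         per-base depth threshold tau.
    min_covered_frac  fraction of window bases required at depth >= tau.
    mode              'local' stops at same-signal-strand genes, 'meta'
                      scans through them.
    max_extent        hard cap on scan distance from the anchor.
    """

    window: int = 100
    min_depth: float = 1.0
    min_covered_frac: float = 0.8
    mode: str = "local"
    max_extent: int = 50_000

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 < self.min_covered_frac <= 1):
            raise ValueError("min_covered_frac must be in (0, 1]")
        if self.min_depth <= 0:
            raise ValueError("min_depth must be > 0")
        if self.max_extent < self.window:
            raise ValueError("max_extent must be >= window")
        if self.mode not in ("local", "meta"):
            raise ValueError("mode must be 'local' or 'meta'")


@dataclass(frozen=True)
class ReadThroughRegion:
    """A called read-through region anchored to a flattened gene block."""

    region_id: str
    category: str
    parent_block: str
    chrom: str
    start: int
    end: int
    strand: str  # strand of the signal, not necessarily of the parent
    mode: str
    mean_depth: float
    skipped_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.region_id}: empty region")

    @property
    def length(self) -> int:
        return self.end - self.start


def _blocking_index(blocking_genes: Sequence[GeneModel]):
    """Sorted (start, end, gene_id) triples for overlap bisection."""
    ivs = sorted((g.start, g.end, g.gene_id) for g in blocking_genes)
    starts = [iv[0] for iv in ivs]
    return ivs, starts


def _genes_overlapping(ivs, starts, lo: int, hi: int):
    """All indexed intervals intersecting [lo, hi)."""
    out = []
    i = bisect.bisect_left(starts, hi)
    for s, e, gid in ivs[:i]:
        if e > lo:
            out.append((s, e, gid))
    return out


def scan_from_anchor(
    cov: StrandedCoverage,
    chrom: str,
    anchor: int,
    direction: int,
    signal_strand: str,
    blocking_genes: Sequence[GeneModel],
    params: DiscoveryParams,
    *,
    category: str = "DoG",
    parent_block: str = "",
    region_id: str | None = None,
) -> ReadThroughRegion | None:
    """Extend a read-through region from ``anchor`` in one direction.

    ``direction`` is +1 (rightward) or -1 (leftward).  Returns ``None``
    when the first window fails, when the anchor sits at the chromosome
    edge, or when truncation leaves no base above threshold.
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    W = params.window
    tau = params.min_depth
    need = params.min_covered_frac * W
    L = cov.chrom_lengths[chrom]
    ivs, starts = _blocking_index(blocking_genes)

    max_windows = params.max_extent // W
    passed_edge = anchor  # distal edge after the last passing window
    skipped: list[str] = []
    truncated_at: int | None = None

    for k in range(max_windows):
        if direction == +1:
            w_lo, w_hi = anchor + k * W, anchor + (k + 1) * W
            if w_hi > L:
                break  # no full window left before the chromosome end
        else:
            w_lo, w_hi = anchor - (k + 1) * W, anchor - k * W
            if w_lo < 0:
                break
        hits = _genes_overlapping(ivs, starts, w_lo, w_hi)
        if hits:
            if params.mode == "local":
                # truncate at the blocking gene edge nearest the anchor
                if direction == +1:
                    truncated_at = min(h[0] for h in hits)
                else:
                    truncated_at = max(h[1] for h in hits)
                break
            # meta: window passes through the gene
            for _s, _e, gid in hits:
                if gid not in skipped:
                    skipped.append(gid)
            passed_edge = w_hi if direction == +1 else w_lo
            continue
        if cov.covered_length(chrom, signal_strand, w_lo, w_hi, tau) >= need:
            passed_edge = w_hi if direction == +1 else w_lo
        else:
            break

    if direction == +1:
        end = passed_edge
        if truncated_at is not None:
            end = max(end, min(truncated_at, anchor + params.max_extent))
        if end <= anchor:
            return None
        last = cov.last_covered_base(chrom, signal_strand, anchor, end, tau)
        if last is None:
            return None
        start, end = anchor, last + 1
    else:
        start = passed_edge
        if truncated_at is not None:
            start = min(start, max(truncated_at, anchor - params.max_extent))
        if start >= anchor:
            return None
        first = cov.first_covered_base(chrom, signal_strand, start, anchor, tau)
        if first is None:
            return None
        start, end = first, anchor

    mean_depth = _mean_depth_excluding(
        cov, chrom, signal_strand, start, end, ivs, starts if skipped else None
    )
    rid = region_id or f"{_PREFIX[category]}{parent_block}"
    return ReadThroughRegion(
        rid,
        category,
        parent_block,
        chrom,
        start,
        end,
        signal_strand,
        params.mode,
        mean_depth,
        tuple(skipped),
    )


def _mean_depth_excluding(cov, chrom, strand, start, end, ivs, starts_or_none):
    """Mean depth over [start,end); skipped-gene bases excluded in meta mode."""
    total = cov.interval_sum(chrom, strand, start, end)
    length = end - start
    if starts_or_none is not None:
        for s, e, _gid in _genes_overlapping(ivs, starts_or_none, start, end):
            lo, hi = max(s, start), min(e, end)
            total -= cov.interval_sum(chrom, strand, lo, hi)
            length -= hi - lo
    return total / length if length > 0 else 0.0


def discover_regions(
    cov: StrandedCoverage,
    blocks: Sequence[FlatBlock],
    genes: Sequence[GeneModel],
    category: str,
    params: DiscoveryParams,
) -> list[ReadThroughRegion]:
    """Call at most one region per (block, category) across the genome.

    The anchor is the block's 3' end for DoG/ADoG and 5' end for PoG/APoG;
    the signal strand is the block strand for DoG/PoG and the opposite
    strand for ADoG/APoG.  Genes on the signal strand act as blockers.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    regions: list[ReadThroughRegion] = []
    genes_by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        genes_by_key.setdefault((g.chrom, g.strand), []).append(g)

    for block in blocks:
        plus = block.strand == "+"
        downstream = category in ("DoG", "ADoG")
        sense = category in ("DoG", "PoG")
        # 3' end is the right edge on +, left edge on -; 5' the reverse
        if downstream:
            anchor = block.end if plus else block.start
            direction = +1 if plus else -1
        else:
            anchor = block.start if plus else block.end
            direction = -1 if plus else +1
        signal_strand = block.strand if sense else _OPPOSITE[block.strand]
        L = cov.chrom_lengths.get(block.chrom)
        if L is None:
            raise KeyError(f"block {block.block_id}: unknown chromosome {block.chrom}")
        if anchor <= 0 or anchor >= L:
            continue  # anchor at the chromosome edge: nothing to scan
        blockers = genes_by_key.get((block.chrom, signal_strand), [])
        if sense:
            # the parent block's own genes end at/behind the anchor and can
            # never lie in the scan path; keep them out of the blocker set
            member = set(block.member_gene_ids)
            blockers = [g for g in blockers if g.gene_id not in member]
        region = scan_from_anchor(
            cov,
            block.chrom,
            anchor,
            direction,
            signal_strand,
            blockers,
            params,
            category=category,
            parent_block=block.block_id,
        )
        if region is not None:
            regions.append(region)
    regions.sort(key=lambda r: (r.chrom, r.start, r.end, r.region_id))
    return regions


# -- filtering ---------------------------------------------------------------


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def filter_regions(
    regions_by_category: dict[str, list[ReadThroughRegion]],
    genes: Sequence[GeneModel],
    operons: Sequence[OperonRecord] = (),
) -> tuple[dict[str, list[ReadThroughRegion]], list[dict]]:
    """Apply the published post-discovery filters.

    1. DoGs with any same-strand operon overlap are removed (polycistronic
       transcription is not read-through).
    2. PoGs overlapping a surviving same-strand DoG are removed (the signal
       is the upstream gene's read-through, not novel).
    3. ADoGs/APoGs overlapping, on their signal strand, a gene or surviving
       DoG on that strand are removed.

    Returns the filtered sets plus a removal log of dicts with keys
    ``region_id``, ``category``, ``rule``, ``hit``.
    """
    log: list[dict] = []
    out: dict[str, list[ReadThroughRegion]] = {}

    dogs = list(regions_by_category.get("DoG", []))
    surviving_dogs: list[ReadThroughRegion] = []
    for r in dogs:
        hit = next(
            (
                op
                for op in operons
                if op.chrom == r.chrom
                and op.strand == r.strand
                and _overlaps(r.start, r.end, op.start, op.end)
            ),
            None,
        )
        if hit is not None:
            log.append(
                {
                    "region_id": r.region_id,
                    "category": "DoG",
                    "rule": "operon_same_strand",
                    "hit": hit.operon_id,
                }
            )
        else:
            surviving_dogs.append(r)
    out["DoG"] = surviving_dogs

    kept_pogs: list[ReadThroughRegion] = []
    for r in regions_by_category.get("PoG", []):
        hit = next(
            (
                d
                for d in surviving_dogs
                if d.chrom == r.chrom
                and d.strand == r.strand
                and _overlaps(r.start, r.end, d.start, d.end)
            ),
            None,
        )
        if hit is not None:
            log.append(
                {
                    "region_id": r.region_id,
                    "category": "PoG",
                    "rule": "dog_same_strand",
                    "hit": hit.region_id,
                }
            )
        else:
            kept_pogs.append(r)
    out["PoG"] = kept_pogs

    for cat in ("ADoG", "APoG"):
        kept: list[ReadThroughRegion] = []
        for r in regions_by_category.get(cat, []):
            hit_id = None
            for g in genes:
                if (
                    g.chrom == r.chrom
                    and g.strand == r.strand
                    and _overlaps(r.start, r.end, g.start, g.end)
                ):
                    hit_id = g.gene_id
                    break
            if hit_id is None:
                for d in surviving_dogs:
                    if (
                        d.chrom == r.chrom
                        and d.strand == r.strand
                        and _overlaps(r.start, r.end, d.start, d.end)
                    ):
                        hit_id = d.region_id
                        break
            if hit_id is not None:
                log.append(
                    {
                        "region_id": r.region_id,
                        "category": cat,
                        "rule": "gene_or_dog_signal_strand",
                        "hit": hit_id,
                    }
                )
            else:
                kept.append(r)
        out[cat] = kept

    for cat in CATEGORIES:
        out.setdefault(cat, [])
    return out, log


def associate_overlapped_genes(
    genes: Sequence[GeneModel],
    dogs: Sequence[ReadThroughRegion],
    adogs: Sequence[ReadThroughRegion],
    blocks: Sequence[FlatBlock] = (),
) -> list[tuple[str, list[str]]]:
    """Genes receiving antisense signal from read-through of a neighbor.

    A gene is *overlapped* when (a) an ADoG is anchored to the block that
    contains the gene, or (b) a DoG on the opposite strand intersects the
    gene body by at least one base.  Returns (gene_id, witness region ids)
    for every overlapped gene.
    """
    block_members: dict[str, set[str]] = {b.block_id: set(b.member_gene_ids) for b in blocks}
    out: list[tuple[str, list[str]]] = []
    for g in genes:
        witnesses: list[str] = []
        for a in adogs:
            members = block_members.get(a.parent_block)
            if members is not None:
                if g.gene_id in members:
                    witnesses.append(a.region_id)
            elif g.gene_id in a.parent_block.split("|"):
                witnesses.append(a.region_id)
        for d in dogs:
            if (
                d.chrom == g.chrom
                and d.strand != g.strand
                and _overlaps(d.start, d.end, g.start, g.end)
            ):
                witnesses.append(d.region_id)
        if witnesses:
            out.append((g.gene_id, witnesses))
    return out
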
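"""Independent brute-force reference implementations used as test oracles.

Everything here works on dense per-base numpy arrays with explicit loops,
deliberately avoiding the run-length machinery of the package so the two
routes can disagree.
"""

from __future__ import annotations

import numpy as np

OPPOSITE = {"+": "-", "-": "+"}
PREFIX = {"DoG": "do", "ADoG": "ado", "PoG": "po", "APoG": "apo"}


def dense_flatten(genes):
    """Flatten same-strand genes via per-base occupancy + connected components.

    Returns {(chrom, strand): [(start, end, frozenset(member ids)), ...]}.
    Touching genes share a boundary base-pair edge, so occupancy is marked
    on a half-open grid and touching intervals merge.
    """
    out = {}
    keys = {(g.chrom, g.strand) for g in genes}
    for chrom, strand in sorted(keys):
        gs = [g for g in genes if g.chrom == chrom and g.strand == strand]
        hi = max(g.end for g in gs)
        # mark occupancy on a 2x grid so that touching ([a,b) + [b,c))
        # intervals connect through the shared boundary point b
        occ = np.zeros(2 * hi + 1, dtype=bool)
        for g in gs:
            occ[2 * g.start : 2 * g.end + 1] = True
        blocks = []
        b = 0
        while b < len(occ):
            if occ[b]:
                s = b
                while b < len(occ) and occ[b]:
                    b += 1
                start, end = s // 2, b // 2
                members = frozenset(
                    g.gene_id for g in gs if g.start < end and start < g.end
                )
                blocks.append((start, end, members))
            else:
                b += 1
        out[(chrom, strand)] = blocks
    return out


def dense_scan(
    depth: np.ndarray,
    anchor: int,
    direction: int,
    blockers,
    window: int,
    tau: float,
    min_frac: float,
    max_extent: int,
    mode: str,
):
    """Reference window scan on a dense depth array.

    ``blockers`` is a list of (start, end, gene_id) on the signal strand.
    Returns (start, end, skipped_ids) or None, mirroring the documented
    extension, truncation, and distal-trimming semantics.
    """
    L = len(depth)
    passed_edge = anchor
    skipped = []
    truncated_at = None
    for k in range(max_extent // window):
        if direction == +1:
            lo, hi = anchor + k * window, anchor + (k + 1) * window
            if hi > L:
                break
        else:
            lo, hi = anchor - (k + 1) * window, anchor - k * window
            if lo < 0:
                break
        hits = sorted((s, e, gid) for (s, e, gid) in blockers if s < hi and lo < e)
        if hits:
            if mode == "local":
                if direction == +1:
                    truncated_at = min(h[0] for h in hits)
                else:
                    truncated_at = max(h[1] for h in hits)
                break
            for _s, _e, gid in hits:
                if gid not in skipped:
                    skipped.append(gid)
            passed_edge = hi if direction == +1 else lo
            continue
        n_cov = int(np.sum(depth[lo:hi] >= tau))
        if n_cov >= min_frac * window:
            passed_edge = hi if direction == +1 else lo
        else:
            break

    if direction == +1:
        end = passed_edge
        if truncated_at is not None:
            end = max(end, min(truncated_at, anchor + max_extent))
        if end <= anchor:
            return None
        covered = np.flatnonzero(depth[anchor:end] >= tau)
        if len(covered) == 0:
            return None
        return anchor, anchor + int(covered[-1]) + 1, skipped
    else:
        start = passed_edge
        if truncated_at is not None:
            start = min(start, max(truncated_at, anchor - max_extent))
        if start >= anchor:
            return None
        covered = np.flatnonzero(depth[start:anchor] >= tau)
        if len(covered) == 0:
            return None
        return start + int(covered[0]), anchor, skipped


def dense_discover(dense_by_strand, genes, blocks, category, window, tau,
                   min_frac, max_extent, mode, chrom, chrom_len):
    """Reference discovery over every block of one chromosome.

    ``dense_by_strand`` maps strand -> per-base depth array for ``chrom``.
    Returns [(block_id, start, end, signal_strand, skipped)] sorted.
    """
    results = []
    for b in blocks:
        if b.chrom != chrom:
            continue
        plus = b.strand == "+"
        downstream = category in ("DoG", "ADoG")
        sense = category in ("DoG", "PoG")
        if downstream:
            anchor = b.end if plus else b.start
            direction = +1 if plus else -1
        else:
            anchor = b.start if plus else b.end
            direction = -1 if plus else +1
        strand = b.strand if sense else OPPOSITE[b.strand]
        if anchor <= 0 or anchor >= chrom_len:
            continue
        members = set(b.member_gene_ids)
        blockers = [
            (g.start, g.end, g.gene_id)
            for g in genes
            if g.chrom == chrom
            and g.strand == strand
            and (not sense or g.gene_id not in members)
        ]
        hit = dense_scan(
            dense_by_strand[strand], anchor, direction, blockers,
            window, tau, min_frac, max_extent, mode,
        )
        if hit is not None:
            s, e, skipped = hit
            results.append((b.block_id, s, e, strand, tuple(skipped)))
    results.sort(key=lambda t: (t[1], t[2], t[0]))
    return results


def enumerate_hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration over all C(N, n) draws."""
    from itertools import combinations

    marked = set(range(K))
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def interval_overlap(a, b) -> bool:
    return a[0] < b[1] and b[0] < a[1]
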
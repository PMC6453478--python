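"""Per-strand base-resolution coverage as run-length segments.

Coverage is stored per (chromosome, strand) as sorted, non-overlapping
runs ``(start, end, depth)``; absent runs mean depth zero.  bedGraph files
(0-based half-open) are the on-disk form, one file per strand.

Feature counts are estimated from coverage as ``round(depth-sum /
read_length)`` — a deterministic, download-free stand-in for read
assignment that is exact for uniformly tiled reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "StrandedCoverage",
    "LibraryStats",
    "load_bedgraph_pair",
    "write_bedgraph_pair",
    "count_features",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

_OPPOSITE = {"+": "-", "-": "+"}


@dataclass(frozen=True)
class LibraryStats:
    """Per-library read accounting used by RSR normalization.

    ``rrna_mapped`` is the number of reads overlapping rRNA genes; libraries
    that retain rRNA (e.g. IP fractions where rRNA was not depleted) get a
    correspondingly smaller effective depth.
    """

    sample_id: str
    total_mapped: int
    rrna_mapped: int
    read_length: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.rrna_mapped <= self.total_mapped):
            raise ValueError(
                f"{self.sample_id}: require 0 <= rrna_mapped <= total_mapped"
            )
        if self.read_length < 1:
            raise ValueError(f"{self.sample_id}: read_length must be >= 1")

    @property
    def effective_depth(self) -> int:
        return self.total_mapped - self.rrna_mapped


class StrandedCoverage:
    """Run-length encoded, strand-specific coverage over a genome.

    Runs are canonical: sorted, non-overlapping, zero-depth runs dropped,
    adjacent equal-depth runs merged.  This makes equality well defined and
    round-trips through bedGraph exactly.
    """

    def __init__(self, chrom_lengths: Mapping[str, int]):
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        # (chrom, strand) -> (starts, ends, depths) float arrays
        self._runs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        # threshold cache for covered_length queries: (chrom, strand, tau) ->
        # (starts, ends, cumlen)
        self._thr_cache: dict = {}

    # -- construction -------------------------------------------------------

    def set_runs(
        self, chrom: str, strand: str, runs: Iterable[tuple[int, int, float]]
    ) -> None:
        """Install runs for one chromosome/strand, canonicalizing them.

        Overlapping input runs are an error (ill-formed bedGraph); adjacent
        runs with equal depth are merged and zero-depth runs dropped.
        """
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        L = self.chrom_lengths[chrom]
        runs = sorted(runs)
        canon: list[list[float]] = []
        prev_end = -1
        for start, end, depth in runs:
            if depth < 0:
                raise ValueError(f"{chrom} {strand}: negative depth at {start}")
            if not (0 <= start < end <= L):
                raise ValueError(
                    f"{chrom} {strand}: run [{start},{end}) outside [0,{L})"
                )
            if start < prev_end:
                raise ValueError(
                    f"{chrom} {strand}: overlapping runs at {start} < {prev_end}"
                )
            prev_end = end
            if depth == 0:
                continue
            if canon and canon[-1][1] == start and canon[-1][2] == depth:
                canon[-1][1] = end
            else:
                canon.append([start, end, depth])
        if canon:
            arr = np.asarray(canon, dtype=float)
            self._runs[(chrom, strand)] = (arr[:, 0], arr[:, 1], arr[:, 2])
        else:
            self._runs.pop((chrom, strand), None)
        self._thr_cache = {k: v for k, v in self._thr_cache.items() if k[:2] != (chrom, strand)}

    def runs(self, chrom: str, strand: str) -> list[tuple[int, int, float]]:
        key = (chrom, strand)
        if key not in self._runs:
            return []
        s, e, d = self._runs[key]
        return [(int(a), int(b), float(c)) for a, b, c in zip(s, e, d)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, StrandedCoverage):
            return NotImplemented
        if self.chrom_lengths != other.chrom_lengths:
            return False
        keys = set(self._runs) | set(other._runs)
        return all(self.runs(*k) == other.runs(*k) for k in keys)

    # -- queries -------------------------------------------------------------

    def interval_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Sum of per-base depth over [start, end) on one strand."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        L = self.chrom_lengths[chrom]
        if not (0 <= start < end <= L):
            raise ValueError(f"query [{start},{end}) outside [0,{L}) on {chrom}")
        key = (chrom, strand)
        if key not in self._runs:
            return 0.0
        s, e, d = self._runs[key]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if lo >= hi:
            return 0.0
        ov = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        return float(np.sum(ov * d[lo:hi]))

    def _thresholded(self, chrom: str, strand: str, tau: float):
        """Merged intervals with depth >= tau, plus cumulative lengths."""
        key = (chrom, strand, tau)
        if key in self._thr_cache:
            return self._thr_cache[key]
        runs_key = (chrom, strand)
        if runs_key not in self._runs:
            out = (np.empty(0), np.empty(0), np.zeros(1))
            self._thr_cache[key] = out
            return out
        s, e, d = self._runs[runs_key]
        mask = d >= tau
        s2, e2 = s[mask], e[mask]
        # merge touching intervals
        starts, ends = [], []
        for a, b in zip(s2, e2):
            if ends and ends[-1] == a:
                ends[-1] = b
            else:
                starts.append(a)
                ends.append(b)
        sa = np.asarray(starts, dtype=float)
        ea = np.asarray(ends, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(ea - sa)])
        out = (sa, ea, cum)
        self._thr_cache[key] = out
        return out

    def covered_length(
        self, chrom: str, strand: str, start: int, end: int, tau: float
    ) -> int:
        """Number of bases in [start, end) with depth >= tau."""
        sa, ea, cum = self._thresholded(chrom, strand, tau)
        if len(sa) == 0:
            return 0
        lo = int(np.searchsorted(ea, start, side="right"))
        hi = int(np.searchsorted(sa, end, side="left"))
        if lo >= hi:
            return 0
        total = cum[hi] - cum[lo]
        total -= max(0.0, start - sa[lo])
        total -= max(0.0, ea[hi - 1] - end)
        return int(round(total))

    def last_covered_base(
        self, chrom: str, strand: str, start: int, end: int, tau: float
    ) -> int | None:
        """Rightmost base b in [start, end) with depth >= tau, or None."""
        sa, ea, cum = self._thresholded(chrom, strand, tau)
        hi = int(np.searchsorted(sa, end, side="left"))
        for i in range(hi - 1, -1, -1):
            if ea[i] > start:
                return int(min(ea[i], end) - 1)
            break
        return None

    def first_covered_base(
        self, chrom: str, strand: str, start: int, end: int, tau: float
    ) -> int | None:
        """Leftmost base b in [start, end) with depth >= tau, or None."""
        sa, ea, cum = self._thresholded(chrom, strand, tau)
        lo = int(np.searchsorted(ea, start, side="right"))
        if lo < len(sa) and sa[lo] < end:
            return int(max(sa[lo], start))
        return None

    def dense(self, chrom: str, strand: str) -> np.ndarray:
        """Materialize per-base depth for one chromosome/strand (tests, plots)."""
        arr = np.zeros(self.chrom_lengths[chrom])
        for s, e, d in self.runs(chrom, strand):
            arr[s:e] = d
        return arr

    def scale(self, factor: float) -> "StrandedCoverage":
        """Return a copy with every depth multiplied by ``factor``."""
        out = StrandedCoverage(self.chrom_lengths)
        for (chrom, strand), (s, e, d) in self._runs.items():
            out.set_runs(
                chrom, strand, [(int(a), int(b), float(c) * factor) for a, b, c in zip(s, e, d)]
            )
        return out


# -- bedGraph I/O ------------------------------------------------------------


def _load_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}: line {lineno}: bedGraph needs 4 columns")
            depth = float(f[3])
            if depth < 0:
                raise ValueError(f"{path}: line {lineno}: negative depth")
            per_chrom.setdefault(f[0], []).append((int(f[1]), int(f[2]), depth))
    return per_chrom


def load_bedgraph_pair(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_lengths: Mapping[str, int],
) -> StrandedCoverage:
    """Load a plus/minus bedGraph pair into canonical run-length form."""
    cov = StrandedCoverage(chrom_lengths)
    for strand, path in (("+", plus_path), ("-", minus_path)):
        for chrom, runs in _load_bedgraph(path).items():
            cov.set_runs(chrom, strand, runs)
    return cov


def write_bedgraph_pair(
    cov: StrandedCoverage, plus_path: str | Path, minus_path: str | Path
) -> None:
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for chrom in sorted(cov.chrom_lengths):
                for s, e, d in cov.runs(chrom, strand):
                    fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, length = line.split()[:2]
                sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# -- counting ----------------------------------------------------------------


def count_features(
    cov: StrandedCoverage,
    features: Iterable,
    stats: LibraryStats,
    antisense: bool = False,
) -> dict[str, int]:
    """Integer counts per feature from coverage depth.

    count = round(interval depth-sum / read_length), rounding half-up.
    With ``antisense=True`` depth is taken from the strand opposite each
    feature, quantifying antisense transcription over the feature body.
    """
    counts: dict[str, int] = {}
    for f in features:
        fid = getattr(f, "gene_id", None) or getattr(f, "region_id", None) or getattr(
            f, "block_id"
        )
        strand = _OPPOSITE[f.strand] if antisense else f.strand
        total = cov.interval_sum(f.chrom, strand, f.start, f.end)
        counts[fid] = int(math.floor(total / stats.read_length + 0.5))
    return counts
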
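"""Deterministic synthetic genomes, coverage tracks, and count matrices.

The generator is the test bed for the whole package: it plants
read-through regions of known extent into stranded coverage and known
interaction fold-changes into NB count matrices, and emits truth tables
sufficient to score recovery without any external data.

Planted read-through decays linearly to zero over its final window rather
than ending abruptly, so boundary-recovery tests exercise the distal
trimming logic instead of a trivial cliff.  All randomness flows from one
seed, split into named substreams (genome / coverage / counts) so each
product is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import FlatBlock, GeneModel, OperonRecord, flatten_genes
from .coverage import LibraryStats, StrandedCoverage
from .enrichment import SampleDesign

__all__ = ["PlantedRegion", "Scenario", "make_genome", "make_coverage", "make_counts"]

_OPPOSITE = {"+": "-", "-": "+"}
TAPER = 100  # bases of linear decay at a planted region's distal end


@dataclass(frozen=True)
class PlantedRegion:
    """A read-through region to plant next to gene ``gene_index``.

    ``condition_specific`` restricts the signal to condition samples;
    ``ip_log2fc`` additionally scales depth in the condition IP fraction,
    planting a detectable IP-vs-input interaction.
    """

    gene_index: int
    category: str = "DoG"
    length: int = 800
    depth: float = 10.0
    condition_specific: bool = False
    ip_log2fc: float = 0.0


@dataclass
class Scenario:
    """All knobs of one synthetic study, with defaults shaped like a small
    stranded RNA-seq experiment (2x2 IP/input design, a few replicates)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (500, 2000)
    intergenic_range: tuple[int, int] = (1500, 4000)
    operon_prob: float = 0.0
    planted: list[PlantedRegion] = field(default_factory=list)
    gene_depth: float = 10.0
    condition: str = "HS"
    reference: str = "WT"
    n_replicates: int = 3
    noise: bool = False
    dispersion: float = 0.05
    baseline_mean: float = 100.0
    mean_log_sigma: float = 1.0
    read_length: int = 50

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "genome": np.random.default_rng(children[0]),
            "coverage": np.random.default_rng(children[1]),
            "counts": np.random.default_rng(children[2]),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        planted = [PlantedRegion(**p) for p in raw.pop("planted", [])]
        for key in ("gene_length_range", "intergenic_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(planted=planted, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["gene_length_range"] = list(self.gene_length_range)
        raw["intergenic_range"] = list(self.intergenic_range)
        raw["planted"] = [asdict(p) for p in self.planted]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def sample_designs(self) -> list[SampleDesign]:
        designs = []
        for cond in (self.reference, self.condition):
            for frac in ("input", "IP"):
                for rep in range(1, self.n_replicates + 1):
                    designs.append(
                        SampleDesign(f"{cond}_{frac}_{rep}", cond, frac, rep)
                    )
        return designs


# -- genome ------------------------------------------------------------------


def make_genome(
    scenario: Scenario,
) -> tuple[list[GeneModel], list[OperonRecord], dict[str, int]]:
    """Place alternating-strand genes with randomized intergenic gaps.

    With probability ``operon_prob`` the next gene continues on the same
    strand after a short gap and the pair is recorded as an operon —
    mimicking polycistronic clusters whose internal "read-through" must
    not be mistaken for termination failure.
    """
    rng = scenario.rngs()["genome"]
    g_lo, g_hi = scenario.gene_length_range
    i_lo, i_hi = scenario.intergenic_range
    n_per = -(-scenario.n_genes // scenario.n_chroms)  # ceil
    worst = n_per * (g_hi + i_hi) + i_hi
    if worst > scenario.chrom_length:
        raise ValueError(
            f"infeasible packing: {n_per} genes x (gene<= {g_hi} + gap<= {i_hi}) "
            f"does not fit into chrom_length {scenario.chrom_length}"
        )

    genes: list[GeneModel] = []
    operons: list[OperonRecord] = []
    chrom_sizes = {
        f"chr{c + 1}": scenario.chrom_length for c in range(scenario.n_chroms)
    }
    gi = 0
    for c in range(scenario.n_chroms):
        chrom = f"chr{c + 1}"
        pos = int(rng.integers(i_lo, i_hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = 0
        while placed < n_per and gi < scenario.n_genes:
            length = int(rng.integers(g_lo, g_hi + 1))
            start, end = pos, pos + length
            gene = GeneModel(f"g{gi + 1:03d}", chrom, start, end, strand)
            genes.append(gene)
            gi += 1
            placed += 1
            in_operon = (
                rng.random() < scenario.operon_prob
                and placed < n_per
                and gi < scenario.n_genes
            )
            if in_operon:
                gap = int(rng.integers(20, 60))
                length2 = int(rng.integers(g_lo, g_hi + 1))
                start2, end2 = end + gap, end + gap + length2
                genes.append(GeneModel(f"g{gi + 1:03d}", chrom, start2, end2, strand))
                operons.append(
                    OperonRecord(f"op{len(operons) + 1}", chrom, start, end2, strand)
                )
                gi += 1
                placed += 1
                end = end2
            pos = end + int(rng.integers(i_lo, i_hi + 1))
            strand = _OPPOSITE[strand]
    return genes, operons, chrom_sizes


# -- coverage ----------------------------------------------------------------


def planted_geometry(
    planted: PlantedRegion, genes: Sequence[GeneModel], blocks: Sequence[FlatBlock]
) -> tuple[str, int, int, str]:
    """(chrom, start, end, signal_strand) of a planted region's true extent."""
    gene = genes[planted.gene_index]
    block = next(b for b in blocks if gene.gene_id in b.member_gene_ids)
    plus = block.strand == "+"
    downstream = planted.category in ("DoG", "ADoG")
    sense = planted.category in ("DoG", "PoG")
    if downstream:
        anchor = block.end if plus else block.start
        direction = +1 if plus else -1
    else:
        anchor = block.start if plus else block.end
        direction = -1 if plus else +1
    strand = block.strand if sense else _OPPOSITE[block.strand]
    if direction == +1:
        start, end = anchor, anchor + planted.length
    else:
        start, end = anchor - planted.length, anchor
    return gene.chrom, start, end, strand


def _dense_to_runs(arr: np.ndarray) -> list[tuple[int, int, float]]:
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate([[0], change, [len(arr)]])
    return [
        (int(a), int(b), float(arr[a]))
        for a, b in zip(bounds[:-1], bounds[1:])
        if arr[a] > 0
    ]


def make_coverage(
    scenario: Scenario,
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
) -> tuple[dict[str, StrandedCoverage], pd.DataFrame]:
    """Per-sample stranded coverage plus the truth table of planted regions.

    Gene bodies carry ``gene_depth`` on their own strand in every sample.
    Planted read-through carries ``depth`` (scaled by 2**ip_log2fc in
    condition IP samples) from its anchor, decaying linearly to zero over
    the final ``TAPER`` bases.  Optional Poisson noise resamples each base.
    """
    rng = scenario.rngs()["coverage"]
    blocks = flatten_genes(genes)
    truth_rows = []
    planted_geo = []
    for p in scenario.planted:
        chrom, start, end, strand = planted_geometry(p, genes, blocks)
        L = chrom_sizes[chrom]
        if not (0 <= start < end <= L):
            raise ValueError(
                f"planted {p.category} at gene index {p.gene_index} "
                f"([{start},{end}) on {chrom}) exceeds the chromosome"
            )
        for g in genes:
            if g.chrom == chrom and g.strand == strand and g.start < end and start < g.end:
                raise ValueError(
                    f"planted {p.category} at gene index {p.gene_index} collides "
                    f"with same-strand gene {g.gene_id}"
                )
        planted_geo.append((p, chrom, start, end, strand))
        truth_rows.append(
            {
                "gene_id": genes[p.gene_index].gene_id,
                "category": p.category,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "depth": p.depth,
                "condition_specific": p.condition_specific,
                "ip_log2fc": p.ip_log2fc,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id",
            "category",
            "chrom",
            "start",
            "end",
            "strand",
            "depth",
            "condition_specific",
            "ip_log2fc",
        ],
    )

    covs: dict[str, StrandedCoverage] = {}
    for design in scenario.sample_designs():
        dense: dict[tuple[str, str], np.ndarray] = {
            (chrom, s): np.zeros(L)
            for chrom, L in chrom_sizes.items()
            for s in ("+", "-")
        }
        for g in genes:
            dense[(g.chrom, g.strand)][g.start : g.end] += scenario.gene_depth
        for p, chrom, start, end, strand in planted_geo:
            if p.condition_specific and design.condition != scenario.condition:
                continue
            depth = p.depth
            if design.fraction == "IP" and design.condition == scenario.condition:
                depth *= 2.0**p.ip_log2fc
            profile = np.full(end - start, depth)
            taper = min(TAPER, end - start)
            ramp = depth * (1.0 - (np.arange(taper) + 1) / (taper + 1))
            # taper sits at the distal end: right edge when the scan runs
            # rightward, which is true exactly when the anchored end is start
            anchored_left = _anchored_left(p.category, strand)
            if anchored_left:
                profile[-taper:] = ramp
            else:
                profile[:taper] = ramp[::-1]
            dense[(chrom, strand)][start:end] += profile
        if scenario.noise:
            for key in dense:
                dense[key] = rng.poisson(dense[key]).astype(float)
        cov = StrandedCoverage(chrom_sizes)
        for (chrom, s), arr in dense.items():
            cov.set_runs(chrom, s, _dense_to_runs(arr))
        covs[design.sample_id] = cov
    return covs, truth


def _anchored_left(category: str, signal_strand: str) -> bool:
    """True when the planted region's anchored end is its left edge.

    Downstream categories run rightward on + parents, upstream categories
    run rightward on - parents; the parent strand is the signal strand for
    DoG/PoG and its opposite for ADoG/APoG.
    """
    sense = category in ("DoG", "PoG")
    parent_strand = signal_strand if sense else _OPPOSITE[signal_strand]
    downstream = category in ("DoG", "ADoG")
    return (parent_strand == "+") == downstream


# -- counts ------------------------------------------------------------------


def make_counts(
    scenario: Scenario,
    feature_ids: Sequence[str],
    log2fcs: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, list[SampleDesign], pd.Series]:
    """NB count matrix with planted interaction fold-changes.

    Per-feature baseline means are lognormal around ``baseline_mean``
    (sigma = ``mean_log_sigma`` on the natural-log scale, emulating the
    orders-of-magnitude spread of real expression levels).  The mean in
    the condition IP cell is scaled by 2**log2fc; counts are NB with
    dispersion ``scenario.dispersion`` (Poisson in the phi -> 0 limit).
    """
    rng = scenario.rngs()["counts"]
    designs = scenario.sample_designs()
    n_f = len(feature_ids)
    if log2fcs is None:
        log2fcs = np.zeros(n_f)
    log2fcs = np.asarray(log2fcs, dtype=float)
    if len(log2fcs) != n_f:
        raise ValueError("log2fcs must align with feature_ids")

    base = scenario.baseline_mean * np.exp(
        rng.normal(0.0, scenario.mean_log_sigma, size=n_f)
    )
    phi = scenario.dispersion
    cols = {}
    for d in designs:
        mu = base.copy()
        if d.fraction == "IP" and d.condition == scenario.condition:
            mu = mu * 2.0**log2fcs
        if phi < 1e-8:
            draws = rng.poisson(mu)
        else:
            n_param = 1.0 / phi
            p_param = n_param / (n_param + mu)
            draws = rng.negative_binomial(n_param, p_param)
        cols[d.sample_id] = draws
    counts = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    truth = pd.Series(log2fcs, index=counts.index, name="true_log2fc")
    return counts, designs, truth


def library_stats_for(
    scenario: Scenario, counts: pd.DataFrame
) -> list[LibraryStats]:
    """Plain library stats (no rRNA retention) matching a count matrix."""
    return [
        LibraryStats(s, int(counts[s].sum()) + 1, 0, scenario.read_length)
        for s in counts.columns
    ]
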
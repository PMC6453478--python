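"""Shared fixtures: randomized small genomes with stranded coverage."""

from __future__ import annotations

import numpy as np
import pytest

from dogcatcher.annotation import GeneModel, flatten_genes
from dogcatcher.coverage import StrandedCoverage
from dogcatcher.simulate import _dense_to_runs


def coverage_from_dense(chrom: str, plus: np.ndarray, minus: np.ndarray) -> StrandedCoverage:
    cov = StrandedCoverage({chrom: len(plus)})
    cov.set_runs(chrom, "+", _dense_to_runs(plus.astype(float)))
    cov.set_runs(chrom, "-", _dense_to_runs(minus.astype(float)))
    return cov


def random_fixture(seed: int, chrom_len: int = 20_000, n_genes: int = 8):
    """A random gene layout plus blocky random coverage on both strands.

    Coverage is piecewise-constant with runs of random depth (including
    depth around the threshold) so window pass/fail decisions are
    non-trivial; gene bodies also get depth on their own strand.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrT"
    genes = []
    pos = int(rng.integers(200, 1200))
    for i in range(n_genes):
        length = int(rng.integers(300, 1500))
        if pos + length + 100 >= chrom_len:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        # occasional same-strand overlap so flattening is exercised
        genes.append(GeneModel(f"t{i}", chrom, pos, pos + length, strand))
        if rng.random() < 0.25:
            pos += int(rng.integers(-length // 2, length // 2))
        else:
            pos += length + int(rng.integers(200, 2500))
        pos = max(pos, genes[-1].start + 1)
    # dedupe identical intervals that the overlap jitter may produce
    dense = {"+": np.zeros(chrom_len), "-": np.zeros(chrom_len)}
    for g in genes:
        dense[g.strand][g.start : g.end] += 10.0
    for strand in "+-":
        p = 0
        while p < chrom_len:
            run = int(rng.integers(50, 600))
            if rng.random() < 0.45:
                depth = float(rng.choice([0.2, 0.5, 0.9, 1.0, 1.1, 2.0, 5.0, 12.0]))
                dense[strand][p : p + run] += depth
            p += run
    cov = coverage_from_dense(chrom, dense["+"], dense["-"])
    return genes, flatten_genes(genes), cov, dense, chrom, chrom_len


def recovery_scenario(seed: int):
    """One planted region per category at well-separated genes.

    Gene indices are kept at pairwise distance >= 2 so no two planted
    regions share an intergenic gap (regions are shorter than the minimum
    gap, so non-adjacent genes cannot produce touching signal); lengths
    are >= 2 windows and depths >= 2x the default threshold.
    """
    from dogcatcher.discovery import CATEGORIES
    from dogcatcher.simulate import PlantedRegion, Scenario

    rng = np.random.default_rng(seed)
    order = rng.permutation(20)
    idx: list[int] = []
    for i in order:
        if all(abs(int(i) - j) >= 2 for j in idx):
            idx.append(int(i))
        if len(idx) == 4:
            break
    planted = [
        PlantedRegion(i, cat, int(rng.integers(2, 15)) * 100, float(rng.integers(2, 25)))
        for i, cat in zip(idx, CATEGORIES)
    ]
    return Scenario(seed=seed, planted=planted)


@pytest.fixture
def simple_plus_gene():
    """One + strand gene with clean downstream coverage."""
    chrom_len = 5000
    gene = GeneModel("g1", "chrT", 100, 500, "+")
    plus = np.zeros(chrom_len)
    plus[100:500] = 10.0
    plus[500:900] = 8.0
    cov = coverage_from_dense("chrT", plus, np.zeros(chrom_len))
    return gene, cov, chrom_len
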
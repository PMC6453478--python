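"""Cross-condition statistics: antisense/sense ratios, set overlaps,
and repeat-overlap enrichment against a randomized intergenic background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RatioSummary",
    "OverlapTest",
    "antisense_sense_analysis",
    "hypergeom_overlap",
    "repeat_enrichment",
]


@dataclass(frozen=True)
class RatioSummary:
    """Tallies of the antisense/sense ratio analysis."""

    n_scored: int
    n_ratio_up: int
    n_ratio_down: int
    n_ratio_zero: int
    n_sense_up: int
    n_antisense_up: int


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric test of two gene sets within a universe."""

    population_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    pvalue: float


def antisense_sense_analysis(
    sense_cond: Mapping[str, float],
    antisense_cond: Mapping[str, float],
    sense_ref: Mapping[str, float],
    antisense_ref: Mapping[str, float],
    min_mean: float = 20.0,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, RatioSummary]:
    """Per-gene antisense/sense ratio change between condition and reference.

    A gene is scored when its pooled mean count — the mean over the four
    vectors {sense, antisense} x {condition, reference} — is at least
    ``min_mean`` (an expression floor so ratios of near-zero counts do not
    dominate).  For scored genes:

        log2_ratio_fc = log2[(anti+c)/(sense+c)]_cond
                        - log2[(anti+c)/(sense+c)]_ref

    plus separate sense and antisense log2 fold-changes.  The summary
    tallies genes with each quantity strictly > 0 (ties are not "up").
    """
    genes = sorted(sense_cond)
    for m in (antisense_cond, sense_ref, antisense_ref):
        if sorted(m) != genes:
            raise ValueError("all four count vectors must share one gene universe")
    sc = np.array([sense_cond[g] for g in genes], dtype=float)
    ac = np.array([antisense_cond[g] for g in genes], dtype=float)
    sr = np.array([sense_ref[g] for g in genes], dtype=float)
    ar = np.array([antisense_ref[g] for g in genes], dtype=float)

    pooled_mean = (sc + ac + sr + ar) / 4.0
    scored = pooled_mean >= min_mean

    c = pseudocount
    ratio_fc = (np.log2(ac + c) - np.log2(sc + c)) - (np.log2(ar + c) - np.log2(sr + c))
    sense_fc = np.log2(sc + c) - np.log2(sr + c)
    anti_fc = np.log2(ac + c) - np.log2(ar + c)

    table = pd.DataFrame(
        {
            "gene_id": genes,
            "sense_condition": sc,
            "antisense_condition": ac,
            "sense_reference": sr,
            "antisense_reference": ar,
            "pooled_mean": pooled_mean,
            "scored": scored,
            "log2_ratio_fc": ratio_fc,
            "log2_sense_fc": sense_fc,
            "log2_antisense_fc": anti_fc,
        }
    )
    s = table[table["scored"]]
    summary = RatioSummary(
        n_scored=int(scored.sum()),
        n_ratio_up=int((s["log2_ratio_fc"] > 0).sum()),
        n_ratio_down=int((s["log2_ratio_fc"] < 0).sum()),
        n_ratio_zero=int((s["log2_ratio_fc"] == 0).sum()),
        n_sense_up=int((s["log2_sense_fc"] > 0).sum()),
        n_antisense_up=int((s["log2_antisense_fc"] > 0).sum()),
    )
    return table, summary


def hypergeom_overlap(universe: set, set_a: set, set_b: set) -> OverlapTest:
    """Upper-tail hypergeometric p-value P(X >= k) for the observed overlap.

    Draw |B| items from a universe of N containing |A| marked items; X is
    the number of marked draws.  Symmetric in A and B.
    """
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("set_a and set_b must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    pvalue = float(sps.hypergeom.sf(k - 1, N, K, n))
    return OverlapTest(N, K, n, k, min(pvalue, 1.0))


def repeat_enrichment(
    regions: Sequence[tuple[str, int, int]],
    repeat_intervals: Sequence[tuple[str, int, int]],
    background: Sequence[tuple[str, int, int]],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[int, float, np.ndarray]:
    """Permutation test: do regions overlap repeats more than chance?

    The observed statistic is the number of regions intersecting at least
    one repeat.  The null redraws length-matched intervals uniformly at
    random inside the supplied background (intergenic space, same
    chromosome as the original region), ``n_shuffles`` times.  The
    empirical p-value uses the add-one rule so it is never zero:
    p = (1 + #{null >= observed}) / (1 + n_shuffles).
    """
    rng = np.random.default_rng(seed)
    rep_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in repeat_intervals:
        rep_by_chrom.setdefault(chrom, []).append((s, e))
    for v in rep_by_chrom.values():
        v.sort()

    def hits_repeat(chrom: str, s: int, e: int) -> bool:
        for rs, re_ in rep_by_chrom.get(chrom, ()):  # repeat lists are short
            if rs < e and s < re_:
                return True
        return False

    observed = sum(hits_repeat(*r) for r in regions)

    bg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in background:
        bg_by_chrom.setdefault(chrom, []).append((s, e))

    # per region: candidate background slots long enough to hold it
    placements = []
    for chrom, s, e in regions:
        length = e - s
        slots = [
            (bs, be) for bs, be in bg_by_chrom.get(chrom, []) if be - bs >= length
        ]
        if not slots:
            raise ValueError(
                f"region {chrom}:{s}-{e} is longer than every background "
                f"interval on its chromosome"
            )
        starts = np.array([bs for bs, _ in slots])
        room = np.array([be - bs - length + 1 for bs, be in slots], dtype=float)
        placements.append((chrom, length, starts, room, room / room.sum()))

    null = np.zeros(n_shuffles, dtype=int)
    for i in range(n_shuffles):
        count = 0
        for chrom, length, starts, room, probs in placements:
            j = rng.choice(len(starts), p=probs)
            offset = rng.integers(0, int(room[j]))
            s = int(starts[j] + offset)
            if hits_repeat(chrom, s, s + length):
                count += 1
        null[i] = count

    pvalue = (1.0 + np.sum(null >= observed)) / (1.0 + n_shuffles)
    return int(observed), float(pvalue), null
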
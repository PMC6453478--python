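"""The window-scan discovery algorithm, its filters, and gene association."""

import numpy as np
import pytest

from dogcatcher.annotation import GeneModel, OperonRecord, flatten_genes
from dogcatcher.discovery import (
    CATEGORIES,
    DiscoveryParams,
    ReadThroughRegion,
    associate_overlapped_genes,
    discover_regions,
    filter_regions,
    scan_from_anchor,
)

from conftest import coverage_from_dense, random_fixture
from oracles import dense_discover, dense_scan, interval_overlap


def _cov(plus, minus=None, chrom="chrT"):
    minus = np.zeros_like(plus) if minus is None else minus
    return coverage_from_dense(chrom, plus, minus)


PARAMS = DiscoveryParams(window=100, min_depth=1.0, min_covered_frac=0.8)


class TestScanFromAnchor:
    def test_uniform_block_recovered_exactly(self):
        plus = np.zeros(3000)
        plus[1000:1500] = 10.0
        r = scan_from_anchor(_cov(plus), "chrT", 1000, +1, "+", [], PARAMS)
        assert (r.start, r.end) == (1000, 1500)

    def test_local_mode_truncates_at_gene(self):
        plus = np.zeros(3000)
        plus[1000:1500] = 10.0
        gene = GeneModel("blk", "chrT", 1300, 1400, "+")
        r = scan_from_anchor(_cov(plus), "chrT", 1000, +1, "+", [gene], PARAMS)
        assert (r.start, r.end) == (1000, 1300)

    def test_meta_mode_scans_through_gene(self):
        plus = np.zeros(3000)
        plus[1000:2000] = 10.0
        gene = GeneModel("blk", "chrT", 1300, 1400, "+")
        params = DiscoveryParams(mode="meta")
        r = scan_from_anchor(_cov(plus), "chrT", 1000, +1, "+", [gene], params)
        assert (r.start, r.end) == (1000, 2000)
        assert r.skipped_gene_ids == ("blk",)

    def test_first_window_fails_returns_none(self):
        plus = np.zeros(3000)
        r = scan_from_anchor(_cov(plus), "chrT", 1000, +1, "+", [], PARAMS)
        assert r is None

    def test_distal_trim_to_last_covered_base(self):
        plus = np.zeros(3000)
        plus[1000:1085] = 10.0  # window passes at 85/100 but trailing zeros trim
        r = scan_from_anchor(_cov(plus), "chrT", 1000, +1, "+", [], PARAMS)
        assert (r.start, r.end) == (1000, 1085)

    def test_max_extent_caps_scan(self):
        plus = np.ones(9000) * 5.0
        params = DiscoveryParams(max_extent=600)
        r = scan_from_anchor(_cov(plus), "chrT", 1000, +1, "+", [], params)
        assert r.end - r.start == 600

    def test_leftward_scan_mirrors(self):
        plus = np.zeros(3000)
        plus[500:1000] = 10.0
        r = scan_from_anchor(_cov(plus), "chrT", 1000, -1, "+", [], PARAMS)
        assert (r.start, r.end) == (500, 1000)

    @pytest.mark.parametrize("mode", ["local", "meta"])
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_dense_oracle(self, seed, mode):
        """Random coverage + random blockers agree with the per-base scan."""
        rng = np.random.default_rng(1000 + seed)
        L = 8000
        dense = np.zeros(L)
        p = 0
        while p < L:
            run = int(rng.integers(40, 400))
            if rng.random() < 0.55:
                dense[p : p + run] = float(rng.choice([0.5, 1.0, 1.5, 6.0]))
            p += run
        blockers = []
        for i in range(rng.integers(0, 4)):
            s = int(rng.integers(500, L - 500))
            blockers.append(GeneModel(f"b{i}", "chrT", s, s + int(rng.integers(50, 600)), "+"))
        params = DiscoveryParams(mode=mode, max_extent=5000)
        cov = _cov(dense)
        for anchor in rng.integers(1, L - 1, 6):
            for direction in (+1, -1):
                got = scan_from_anchor(
                    cov, "chrT", int(anchor), direction, "+", blockers, params
                )
                exp = dense_scan(
                    dense, int(anchor), direction,
                    [(g.start, g.end, g.gene_id) for g in blockers],
                    params.window, params.min_depth, params.min_covered_frac,
                    params.max_extent, mode,
                )
                if exp is None:
                    assert got is None
                else:
                    assert (got.start, got.end, tuple(got.skipped_gene_ids)) == (
                        exp[0], exp[1], tuple(exp[2]),
                    )

    def test_lower_threshold_never_shortens(self):
        """Monotonicity: relaxing tau or the fraction extends regions."""
        rng = np.random.default_rng(9)
        L = 6000
        dense = (rng.random(L) * 3).round(1)
        cov = _cov(dense)
        for anchor in (500, 1500, 3000):
            prev_len = None
            for tau in (2.0, 1.0, 0.5):
                r = scan_from_anchor(
                    cov, "chrT", anchor, +1, "+", [],
                    DiscoveryParams(min_depth=tau, min_covered_frac=0.8),
                )
                length = 0 if r is None else r.length
                if prev_len is not None:
                    assert length >= prev_len
                prev_len = length


class TestDiscoverRegions:
    def test_plus_gene_downstream_sense(self):
        plus = np.zeros(3000)
        plus[100:500] = 10.0
        plus[500:900] = 8.0
        genes = [GeneModel("g1", "chrT", 100, 500, "+")]
        regs = discover_regions(_cov(plus), flatten_genes(genes), genes, "DoG", PARAMS)
        (r,) = regs
        assert (r.start, r.end, r.strand, r.region_id) == (500, 900, "+", "dog1")

    def test_antisense_downstream_only_makes_adog(self):
        plus = np.zeros(3000)
        minus = np.zeros(3000)
        plus[100:500] = 10.0
        minus[500:900] = 8.0
        genes = [GeneModel("g1", "chrT", 100, 500, "+")]
        blocks = flatten_genes(genes)
        cov = _cov(plus, minus)
        assert discover_regions(cov, blocks, genes, "DoG", PARAMS) == []
        (r,) = discover_regions(cov, blocks, genes, "ADoG", PARAMS)
        assert (r.start, r.end, r.strand, r.region_id) == (500, 900, "-", "adog1")

    def test_minus_gene_dog_extends_leftward(self):
        minus = np.zeros(3000)
        minus[1000:1400] = 10.0  # gene body
        minus[600:1000] = 8.0  # read-through past the 3' end (left on -)
        genes = [GeneModel("g1", "chrT", 1000, 1400, "-")]
        (r,) = discover_regions(
            _cov(np.zeros(3000), minus), flatten_genes(genes), genes, "DoG", PARAMS
        )
        assert (r.start, r.end, r.strand) == (600, 1000, "-")

    def test_dog_anchors_at_block_end_not_inner_gene(self):
        """A gene nested in a longer host anchors read-through at the host end."""
        plus = np.zeros(4000)
        plus[100:1500] = 10.0
        plus[1500:2000] = 6.0
        host = GeneModel("host", "chrT", 100, 1500, "+")
        inner = GeneModel("inner", "chrT", 600, 900, "+")
        genes = [host, inner]
        (r,) = discover_regions(_cov(plus), flatten_genes(genes), genes, "DoG", PARAMS)
        assert r.start == 1500
        assert r.parent_block == "host|inner"

    def test_region_naming_prefixes(self):
        plus = np.zeros(3000)
        minus = np.zeros(3000)
        plus[1000:1500] = 10.0
        plus[1500:1900] = 5.0
        plus[500:1000] = 5.0
        minus[1500:1900] = 5.0
        minus[500:1000] = 5.0
        genes = [GeneModel("gX", "chrT", 1000, 1500, "+")]
        blocks = flatten_genes(genes)
        cov = _cov(plus, minus)
        expect = {"DoG": "dogX", "ADoG": "adogX", "PoG": "pogX", "APoG": "apogX"}
        for cat, rid in expect.items():
            (r,) = discover_regions(cov, blocks, genes, cat, PARAMS)
            assert r.region_id == rid

    def test_anchor_at_chromosome_edge_skipped(self):
        plus = np.ones(1000) * 5.0
        genes = [GeneModel("g1", "chrT", 500, 1000, "+")]
        regs = discover_regions(_cov(plus), flatten_genes(genes), genes, "DoG", PARAMS)
        assert regs == []

    @pytest.mark.parametrize("mode", ["local", "meta"])
    @pytest.mark.parametrize("seed", range(10))
    def test_all_categories_match_dense_oracle(self, seed, mode):
        genes, blocks, cov, dense, chrom, L = random_fixture(seed)
        params = DiscoveryParams(mode=mode, max_extent=5000)
        for cat in CATEGORIES:
            got = [
                (r.parent_block, r.start, r.end, r.strand, r.skipped_gene_ids)
                for r in discover_regions(cov, blocks, genes, cat, params)
            ]
            got.sort(key=lambda t: (t[1], t[2], t[0]))
            exp = dense_discover(
                dense, genes, blocks, cat, params.window, params.min_depth,
                params.min_covered_frac, params.max_extent, mode, chrom, L,
            )
            assert got == exp

    def test_strand_mirror_symmetry(self):
        """Mirroring coordinates and strands maps each category onto itself."""
        genes, blocks, cov, dense, chrom, L = random_fixture(3)
        params = DiscoveryParams(max_extent=5000)
        mirror_genes = [
            GeneModel(g.gene_id, chrom, L - g.end, L - g.start,
                      "-" if g.strand == "+" else "+")
            for g in genes
        ]
        mirror_cov = coverage_from_dense(chrom, dense["-"][::-1], dense["+"][::-1])
        for cat in CATEGORIES:
            fwd = discover_regions(cov, blocks, genes, cat, params)
            rev = discover_regions(
                mirror_cov, flatten_genes(mirror_genes), mirror_genes, cat, params
            )
            fwd_set = {(r.parent_block, r.start, r.end) for r in fwd}
            rev_set = {(r.parent_block, L - r.end, L - r.start) for r in rev}
            assert fwd_set == rev_set


class TestFilterRegions:
    def _region(self, rid, cat, start, end, strand, parent="p"):
        return ReadThroughRegion(rid, cat, parent, "chrT", start, end, strand, "local", 5.0)

    def test_operon_overlap_removes_dog(self):
        dog = self._region("do1", "DoG", 500, 900, "+")
        operon = OperonRecord("op1", "chrT", 800, 1200, "+")
        out, log = filter_regions({"DoG": [dog]}, [], [operon])
        assert out["DoG"] == []
        assert log == [
            {"region_id": "do1", "category": "DoG", "rule": "operon_same_strand", "hit": "op1"}
        ]

    def test_opposite_strand_operon_kept(self):
        dog = self._region("do1", "DoG", 500, 900, "+")
        operon = OperonRecord("op1", "chrT", 800, 1200, "-")
        out, _ = filter_regions({"DoG": [dog]}, [], [operon])
        assert out["DoG"] == [dog]

    def test_pog_overlapping_same_strand_dog_removed(self):
        dog = self._region("doA", "DoG", 1000, 1600, "+")
        pog = self._region("poB", "PoG", 1400, 1800, "+")
        out, log = filter_regions({"DoG": [dog], "PoG": [pog]}, [], [])
        assert out["PoG"] == []
        assert log[0]["rule"] == "dog_same_strand"

    def test_pog_overlapping_removed_dog_survives(self):
        """Operon filtering runs first: a dead DoG no longer blocks PoGs."""
        dog = self._region("doA", "DoG", 1000, 1600, "+")
        pog = self._region("poB", "PoG", 1400, 1800, "+")
        operon = OperonRecord("op1", "chrT", 900, 1100, "+")
        out, _ = filter_regions({"DoG": [dog], "PoG": [pog]}, [], [operon])
        assert out["DoG"] == []
        assert out["PoG"] == [pog]

    def test_adog_overlapping_signal_strand_gene_removed(self):
        adog = self._region("adoA", "ADoG", 500, 900, "-")
        gene = GeneModel("gm", "chrT", 800, 1200, "-")
        out, log = filter_regions({"ADoG": [adog]}, [gene], [])
        assert out["ADoG"] == []
        assert log[0]["hit"] == "gm"

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_fixtures_match_set_algebra(self, seed):
        """Filtered output equals an independent interval-algebra recount."""
        rng = np.random.default_rng(seed)
        genes = [
            GeneModel(f"g{i}", "chrT", int(s), int(s) + int(rng.integers(100, 900)),
                      "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, 30_000, 200))
        ]
        regions = {cat: [] for cat in CATEGORIES}
        for i in range(120):
            cat = CATEGORIES[int(rng.integers(0, 4))]
            s = int(rng.integers(0, 30_000))
            regions[cat].append(
                self._region(f"r{i}", cat, s, s + int(rng.integers(100, 1200)),
                             "+" if rng.random() < 0.5 else "-")
            )
        operons = [
            OperonRecord(f"op{i}", "chrT", int(s), int(s) + int(rng.integers(200, 2000)),
                         "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, 30_000, 10))
        ]
        out, log = filter_regions(regions, genes, operons)

        surviving_dogs = [
            d for d in regions["DoG"]
            if not any(
                op.strand == d.strand and interval_overlap((d.start, d.end), (op.start, op.end))
                for op in operons
            )
        ]
        assert out["DoG"] == surviving_dogs
        exp_pogs = [
            p for p in regions["PoG"]
            if not any(
                d.strand == p.strand and interval_overlap((p.start, p.end), (d.start, d.end))
                for d in surviving_dogs
            )
        ]
        assert out["PoG"] == exp_pogs
        for cat in ("ADoG", "APoG"):
            exp = [
                a for a in regions[cat]
                if not any(
                    g.strand == a.strand and interval_overlap((a.start, a.end), (g.start, g.end))
                    for g in genes
                )
                and not any(
                    d.strand == a.strand and interval_overlap((a.start, a.end), (d.start, d.end))
                    for d in surviving_dogs
                )
            ]
            assert out[cat] == exp
        # every removal attributed
        removed_ids = {
            r.region_id for cat in CATEGORIES for r in regions[cat]
        } - {r.region_id for cat in CATEGORIES for r in out[cat]}
        assert removed_ids == {row["region_id"] for row in log}

    def test_postconditions_hold_exhaustively(self):
        rng = np.random.default_rng(77)
        genes = [
            GeneModel(f"g{i}", "chrT", int(s), int(s) + 400,
                      "+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(0, 20_000, 60))
        ]
        regions = {cat: [] for cat in CATEGORIES}
        for i in range(80):
            cat = CATEGORIES[i % 4]
            s = int(rng.integers(0, 20_000))
            regions[cat].append(
                self._region(f"r{i}", cat, s, s + 500, "+" if rng.random() < 0.5 else "-")
            )
        operons = [OperonRecord("op", "chrT", 5000, 9000, "+")]
        out, _ = filter_regions(regions, genes, operons)
        for d in out["DoG"]:
            for op in operons:
                assert not (
                    op.strand == d.strand
                    and interval_overlap((d.start, d.end), (op.start, op.end))
                )
        for p in out["PoG"]:
            for d in out["DoG"]:
                assert not (
                    d.strand == p.strand
                    and interval_overlap((p.start, p.end), (d.start, d.end))
                )
        for cat in ("ADoG", "APoG"):
            for a in out[cat]:
                for g in genes:
                    assert not (
                        g.strand == a.strand
                        and interval_overlap((a.start, a.end), (g.start, g.end))
                    )
                for d in out["DoG"]:
                    assert not (
                        d.strand == a.strand
                        and interval_overlap((a.start, a.end), (d.start, d.end))
                    )


class TestAssociateOverlappedGenes:
    def test_opposite_strand_dog_overlap(self):
        gene = GeneModel("eif", "chrT", 1000, 2000, "-")
        dog = ReadThroughRegion("doW", "DoG", "W", "chrT", 1800, 2600, "+", "local", 5.0)
        out = associate_overlapped_genes([gene], [dog], [])
        assert out == [("eif", ["doW"])]

    def test_own_adog_associates(self):
        gene = GeneModel("gA", "chrT", 1000, 2000, "+")
        adog = ReadThroughRegion("adogA", "ADoG", "gA", "chrT", 2000, 2500, "-", "local", 5.0)
        out = associate_overlapped_genes([gene], [], [adog])
        assert out == [("gA", ["adogA"])]

    def test_isolated_gene_not_overlapped(self):
        gene = GeneModel("gA", "chrT", 1000, 2000, "+")
        assert associate_overlapped_genes([gene], [], []) == []

    def test_same_strand_dog_does_not_associate(self):
        gene = GeneModel("gA", "chrT", 1000, 2000, "+")
        dog = ReadThroughRegion("doB", "DoG", "B", "chrT", 1500, 2500, "+", "local", 5.0)
        assert associate_overlapped_genes([gene], [dog], []) == []


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_planted_regions_recovered_within_one_window(self, seed):
        from dogcatcher.simulate import make_coverage, make_genome

        from conftest import recovery_scenario

        sc = recovery_scenario(seed)
        genes, _, sizes = make_genome(sc)
        covs, truth = make_coverage(sc, genes, sizes)
        blocks = flatten_genes(genes)
        cov = covs[sc.sample_designs()[0].sample_id]
        for _, row in truth.iterrows():
            regs = discover_regions(cov, blocks, genes, row["category"], PARAMS)
            match = [r for r in regs if r.strand == row["strand"]
                     and r.start < row["end"] and row["start"] < r.end]
            assert len(match) == 1, f"planted {row['category']} not recovered"
            r = match[0]
            anchored_left = (
                r.start == row["start"]
            )  # anchored end must be exact on one side
            if anchored_left:
                assert r.start == row["start"]
                assert 0 <= row["end"] - r.end <= PARAMS.window
            else:
                assert r.end == row["end"]
                assert 0 <= r.start - row["start"] <= PARAMS.window
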
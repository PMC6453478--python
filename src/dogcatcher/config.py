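"""Run configuration and the end-to-end pipeline.

Stages: discover (per-sample window scan + filters, then cross-sample
union) -> count (genes sense/antisense and union regions, per sample) ->
enrich (padded NB-LRT per category plus gene-level tests) -> stats
(antisense/sense ratios, overlapped genes).  Every stage writes plain TSV
under the output directory; a manifest records sha256 checksums so reruns
can be compared byte for byte.  ``resume_from`` reloads earlier stages'
outputs from disk instead of recomputing them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import coverage as covmod
from . import discovery as disc
from . import enrichment as enr
from . import stats as st

log = logging.getLogger("dogcatcher")

STAGES = ("discover", "count", "enrich", "stats")


@dataclass
class RunConfig:
    """Validated inputs and parameters for one pipeline run."""

    gtf: str
    chrom_sizes: str
    sample_sheet: str
    out_dir: str
    operons_bed: str | None = None
    condition: str = "HS"
    reference: str = "WT"
    discovery: disc.DiscoveryParams = field(default_factory=disc.DiscoveryParams)
    alpha: float = 0.05
    min_log2mean: float = 4.0
    min_mean: float = 20.0
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "discovery" in raw:
            raw["discovery"] = disc.DiscoveryParams(**raw["discovery"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def validate(self) -> None:
        for label, p in (
            ("gtf", self.gtf),
            ("chrom_sizes", self.chrom_sizes),
            ("sample_sheet", self.sample_sheet),
        ):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.operons_bed and not Path(self.operons_bed).exists():
            raise FileNotFoundError(f"operons_bed file not found: {self.operons_bed}")


SHEET_COLUMNS = [
    "sample_id",
    "condition",
    "fraction",
    "plus_bedgraph",
    "minus_bedgraph",
    "total_mapped",
    "rrna_mapped",
    "read_length",
]


def read_sample_sheet(path: str | Path):
    """Sample sheet TSV -> (designs, library stats, bedGraph paths)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    designs, stats, paths = [], [], {}
    base = Path(path).parent
    for _, row in df.iterrows():
        designs.append(
            enr.SampleDesign(row["sample_id"], str(row["condition"]), row["fraction"])
        )
        stats.append(
            covmod.LibraryStats(
                row["sample_id"],
                int(row["total_mapped"]),
                int(row["rrna_mapped"]),
                int(row["read_length"]),
            )
        )
        plus, minus = Path(row["plus_bedgraph"]), Path(row["minus_bedgraph"])
        paths[row["sample_id"]] = (
            plus if plus.is_absolute() else base / plus,
            minus if minus.is_absolute() else base / minus,
        )
    return designs, stats, paths


def read_region_table(path: str | Path) -> list[disc.ReadThroughRegion]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        skipped = tuple(s for s in str(r["skipped_gene_ids"]).split(",") if s)
        out.append(
            disc.ReadThroughRegion(
                r["region_id"],
                r["category"],
                r["parent_block"],
                r["chrom"],
                int(r["start"]),
                int(r["end"]),
                r["strand"],
                r["mode"],
                float(r["mean_depth"]),
                skipped,
            )
        )
    return out


def union_regions(
    per_sample: dict[str, list[disc.ReadThroughRegion]]
) -> list[disc.ReadThroughRegion]:
    """Merge one category's regions across samples by coordinate overlap.

    A region is tested if called in at least one sample; the merged
    coordinates are the union span.  The merged record keeps the id and
    parent of its longest constituent and averages mean depth.
    """
    pool = [r for regs in per_sample.values() for r in regs]
    by_key: dict[tuple[str, str], list[disc.ReadThroughRegion]] = {}
    for r in pool:
        by_key.setdefault((r.chrom, r.strand), []).append(r)
    merged: list[disc.ReadThroughRegion] = []
    for (chrom, strand), regs in sorted(by_key.items()):
        regs.sort(key=lambda r: (r.start, r.end))
        group = [regs[0]]
        hi = regs[0].end
        for r in regs[1:]:
            if r.start < hi:
                group.append(r)
                hi = max(hi, r.end)
            else:
                merged.append(_merge_group(group))
                group, hi = [r], r.end
        merged.append(_merge_group(group))
    merged.sort(key=lambda r: (r.chrom, r.start, r.end, r.region_id))
    return merged


def _merge_group(group):
    rep = max(group, key=lambda r: (r.length, r.region_id))
    start = min(r.start for r in group)
    end = max(r.end for r in group)
    depth = sum(r.mean_depth for r in group) / len(group)
    skipped = tuple(sorted({g for r in group for g in r.skipped_gene_ids}))
    return disc.ReadThroughRegion(
        rep.region_id,
        rep.category,
        rep.parent_block,
        rep.chrom,
        start,
        end,
        rep.strand,
        rep.mode,
        depth,
        skipped,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, resume_from: str | None = None) -> dict:
    """Execute the full workflow; returns the output manifest.

    Any stage failure aborts with the stage name in the raised error.
    Outputs are deterministic for a fixed config and seed: reruns produce
    checksum-identical files.
    """
    if resume_from is not None and resume_from not in STAGES:
        raise ValueError(f"resume_from must be one of {STAGES}")
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in ("regions", "counts", "enrich", "stats"):
        (out / sub).mkdir(exist_ok=True)
    # out_dir is the run location, not a parameter: omit it so runs into
    # different directories still compare checksum-identical
    cfg_copy = dataclasses.asdict(config)
    cfg_copy.pop("out_dir")
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg_copy, fh, sort_keys=True)

    genes = ann.parse_gtf(config.gtf)
    blocks = ann.flatten_genes(genes)
    chrom_sizes = covmod.read_chrom_sizes(config.chrom_sizes)
    operons = (
        ann.parse_operons_bed(config.operons_bed) if config.operons_bed else []
    )
    designs, lib_stats, bg_paths = read_sample_sheet(config.sample_sheet)
    stats_by_id = {s.sample_id: s for s in lib_stats}
    skip = STAGES.index(resume_from) if resume_from else 0

    def stage_of(name):
        return STAGES.index(name)

    try:
        union: dict[str, list[disc.ReadThroughRegion]] = {}
        if stage_of("discover") >= skip:
            per_sample: dict[str, dict[str, list]] = {}
            removal_rows = []
            for d in designs:
                plus, minus = bg_paths[d.sample_id]
                cov = covmod.load_bedgraph_pair(plus, minus, chrom_sizes)
                raw = {
                    cat: disc.discover_regions(cov, blocks, genes, cat, config.discovery)
                    for cat in disc.CATEGORIES
                }
                filtered, rlog = disc.filter_regions(raw, genes, operons)
                for row in rlog:
                    removal_rows.append({"sample_id": d.sample_id, **row})
                per_sample[d.sample_id] = filtered
                for cat in disc.CATEGORIES:
                    ann.write_regions(
                        filtered[cat],
                        out / "regions" / f"{d.sample_id}.{cat}.tsv",
                        "table",
                    )
                log.info(
                    "discover %s: %s",
                    d.sample_id,
                    {c: len(filtered[c]) for c in disc.CATEGORIES},
                )
            pd.DataFrame(
                removal_rows, columns=["sample_id", "region_id", "category", "rule", "hit"]
            ).to_csv(out / "regions" / "removal_log.tsv", sep="\t", index=False)
            for cat in disc.CATEGORIES:
                union[cat] = union_regions(
                    {s: per_sample[s][cat] for s in per_sample}
                )
                ann.write_regions(union[cat], out / f"union.{cat}.tsv", "table")
                ann.write_regions(union[cat], out / f"union.{cat}.bed", "bed")
                ann.write_regions(union[cat], out / f"union.{cat}.gtf", "gtf")
        else:
            for cat in disc.CATEGORIES:
                union[cat] = read_region_table(out / f"union.{cat}.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'discover' failed: {exc}") from exc

    try:
        counts: dict[str, pd.DataFrame] = {}
        tables = {"genes_sense": (genes, False), "genes_antisense": (genes, True)}
        for cat in disc.CATEGORIES:
            tables[f"regions_{cat}"] = (union[cat], False)
        if stage_of("count") >= skip:
            cols_by_table: dict[str, dict] = {name: {} for name in tables}
            for d in designs:
                plus, minus = bg_paths[d.sample_id]
                cov = covmod.load_bedgraph_pair(plus, minus, chrom_sizes)
                for name, (features, antisense) in tables.items():
                    cols_by_table[name][d.sample_id] = covmod.count_features(
                        cov, features, stats_by_id[d.sample_id], antisense=antisense
                    )
            for name in tables:
                df = pd.DataFrame(cols_by_table[name])
                df.index.name = "feature_id"
                df.to_csv(out / "counts" / f"{name}.tsv", sep="\t")
                counts[name] = df
        else:
            for name in tables:
                counts[name] = pd.read_csv(
                    out / "counts" / f"{name}.tsv", sep="\t", index_col="feature_id"
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'count' failed: {exc}") from exc

    contrast = (config.condition, config.reference)
    try:
        if stage_of("enrich") >= skip:
            sf = enr.rsr_size_factors(lib_stats)
            for name in ("genes_sense", "genes_antisense"):
                res = enr.nb_lrt_enrichment(
                    counts[name],
                    designs,
                    sf,
                    contrast,
                    alpha=config.alpha,
                    min_log2mean=config.min_log2mean,
                )
                res.to_csv(out / "enrich" / f"{name}.tsv", sep="\t", index=False)
            for cat in disc.CATEGORIES:
                target = counts[f"regions_{cat}"]
                target = target[~target.index.isin(counts["genes_sense"].index)]
                res = enr.padded_lrt(
                    target,
                    counts["genes_sense"],
                    designs,
                    contrast,
                    library_stats=lib_stats,
                    alpha=config.alpha,
                    min_log2mean=config.min_log2mean,
                )
                res.to_csv(out / "enrich" / f"regions_{cat}.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'enrich' failed: {exc}") from exc

    try:
        if stage_of("stats") >= skip:
            # antisense/sense ratios on pooled input libraries
            inputs_cond = [
                d.sample_id
                for d in designs
                if d.fraction == "input" and d.condition == config.condition
            ]
            inputs_ref = [
                d.sample_id
                for d in designs
                if d.fraction == "input" and d.condition == config.reference
            ]
            sense = counts["genes_sense"]
            anti = counts["genes_antisense"]
            table, summary = st.antisense_sense_analysis(
                sense[inputs_cond].sum(axis=1).to_dict(),
                anti[inputs_cond].sum(axis=1).to_dict(),
                sense[inputs_ref].sum(axis=1).to_dict(),
                anti[inputs_ref].sum(axis=1).to_dict(),
                min_mean=config.min_mean,
                pseudocount=config.pseudocount,
            )
            table.to_csv(out / "stats" / "ratio_table.tsv", sep="\t", index=False)
            with open(out / "stats" / "ratio_summary.json", "w") as fh:
                json.dump(dataclasses.asdict(summary), fh, indent=2, sort_keys=True)
            overlapped = disc.associate_overlapped_genes(
                genes, union["DoG"], union["ADoG"], blocks
            )
            pd.DataFrame(
                [(g, ",".join(w)) for g, w in overlapped],
                columns=["gene_id", "witness_regions"],
            ).to_csv(out / "stats" / "overlapped_genes.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'stats' failed: {exc}") from exc

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "n_files": len(files),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        "seed": config.seed,
        "contrast": list(contrast),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d files in %s", len(files), out)
    return manifest
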
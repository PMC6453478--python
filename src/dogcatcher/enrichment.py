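"""Normalization and differential-enrichment statistics.

The scientific question is whether a feature's IP/input ratio changes
between two conditions, i.e. the *interaction* term of a 2x2
(condition x fraction) negative-binomial log-linear model:

    log mu = b0 + b_cond + b_frac + b_int + log(size factor)

The likelihood-ratio statistic comparing the full model against the model
without ``b_int`` is referred to chi-square(1); ``log2FC = b_int / ln 2``
is the log2 change of the IP/input ratio relative to the reference
condition.  Significance calls require FDR < alpha and a minimum mean
expression (log2Mean) floor.

Two size-factor families are provided: the rRNA-subtraction-ratio (RSR)
scheme — effective depth = mapped reads minus rRNA-mapped reads, centered
to geometric mean one — for designs where some libraries retain rRNA, and
classic median-of-ratios for pure count matrices.  "Padded" runs include
annotated gene counts in the matrix so that size factors and the
dispersion trend are estimated on a stable background, then report only
the novel-region features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import LibraryStats

__all__ = [
    "SampleDesign",
    "rsr_size_factors",
    "median_of_ratios",
    "nb_lrt_enrichment",
    "padded_lrt",
    "classify",
    "benjamini_hochberg",
]

LOG2 = math.log(2.0)
DISPERSION_FLOOR = 1e-8
DISPERSION_SHRINK_WEIGHT = 0.5  # weight of the per-feature estimate
DEFAULT_DISPERSION = 0.1  # used when a design has no replication

RESULT_COLUMNS = [
    "feature_id",
    "log2Mean",
    "log2FC",
    "lrt_stat",
    "pvalue",
    "fdr",
    "class",
]


@dataclass(frozen=True)
class SampleDesign:
    """One library in the 2x2 IP-vs-input contrast design."""

    sample_id: str
    condition: str
    fraction: str  # "input" or "IP"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.fraction not in ("input", "IP"):
            raise ValueError(
                f"{self.sample_id}: fraction must be 'input' or 'IP', "
                f"got {self.fraction!r}"
            )


# -- size factors ------------------------------------------------------------


def rsr_size_factors(stats: Sequence[LibraryStats]) -> pd.Series:
    """rRNA-subtraction-ratio size factors.

    Effective depth d_i = total_mapped - rrna_mapped; the factor is
    d_i / geometric-mean(d), so dividing counts by it puts libraries with
    retained rRNA on the same effective-depth scale as depleted ones.
    """
    d = np.array([s.effective_depth for s in stats], dtype=float)
    if np.any(d <= 0):
        bad = [s.sample_id for s, di in zip(stats, d) if di <= 0]
        raise ValueError(f"zero effective depth for samples: {bad}")
    factors = d / np.exp(np.mean(np.log(d)))
    return pd.Series(factors, index=[s.sample_id for s in stats], name="size_factor")


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, centered to geometric mean one.

    The pseudo-reference is the per-feature geometric mean over samples,
    computed on features with all-positive counts; each sample's factor is
    the median of its count/reference ratios.  If no feature is positive
    everywhere this falls back to total-count scaling with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = np.all(mat > 0, axis=1)
    if not np.any(all_pos):
        warnings.warn(
            "no feature with all-positive counts; falling back to "
            "total-count (RSR-style) scaling",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total count")
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        sub = mat[all_pos]
        log_ref = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


# -- multiple testing --------------------------------------------------------


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (delegates to statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# -- the NB-GLM LRT engine ---------------------------------------------------


def _design_matrices(designs: Sequence[SampleDesign], condition: str, reference: str):
    """Full and reduced design matrices with treatment coding.

    Baselines: reference condition, input fraction.  The interaction
    column is the last column of the full matrix.
    """
    x_cond = np.array([1.0 if d.condition == condition else 0.0 for d in designs])
    x_frac = np.array([1.0 if d.fraction == "IP" else 0.0 for d in designs])
    ones = np.ones(len(designs))
    full = np.column_stack([ones, x_cond, x_frac, x_cond * x_frac])
    reduced = full[:, :3]
    return full, reduced


def _check_design(designs: Sequence[SampleDesign], condition: str, reference: str):
    cells: dict[tuple[str, str], int] = {}
    for d in designs:
        cells[(d.condition, d.fraction)] = cells.get((d.condition, d.fraction), 0) + 1
    for cond in (condition, reference):
        for frac in ("input", "IP"):
            if cells.get((cond, frac), 0) < 1:
                raise ValueError(
                    f"design cell ({cond}, {frac}) has no samples; the LRT "
                    f"contrast needs all four (condition x fraction) cells"
                )


def _moment_dispersions(norm: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion from normalized counts.

    Uses within-cell means/variances pooled across the four design cells so
    real (condition x fraction) effects do not inflate the estimate:
    Var = mu + phi mu^2  =>  phi = sum_c w_c (s2_c - m_c) / sum_c w_c m_c^2
    with w_c = n_c - 1.  Designs without replication get a fixed default.
    """
    n_features = norm.shape[0]
    phis = np.full(n_features, DEFAULT_DISPERSION)
    uniq = np.unique(groups)
    weights, means, varis = [], [], []
    for g in uniq:
        cols = groups == g
        n_c = int(cols.sum())
        if n_c < 2:
            continue
        sub = norm[:, cols]
        weights.append(n_c - 1)
        means.append(sub.mean(axis=1))
        varis.append(sub.var(axis=1, ddof=1))
    if not weights:
        return phis
    w = np.asarray(weights, dtype=float)
    m = np.vstack(means)
    v = np.vstack(varis)
    num = np.einsum("c,cf->f", w, v - m)
    den = np.einsum("c,cf->f", w, m**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, DEFAULT_DISPERSION)
    return np.maximum(raw, DISPERSION_FLOOR)


def _shrink_dispersions(phi: np.ndarray, log2mean: np.ndarray) -> np.ndarray:
    """Shrink per-feature dispersions toward their expression-decile mean.

    A lightweight empirical-Bayes stand-in: features are binned into
    deciles of log2Mean, the trend is the within-decile mean dispersion,
    and the final value is the 50/50 blend of estimate and trend.
    """
    ok = np.isfinite(log2mean)
    out = phi.copy()
    if ok.sum() < 2:
        return out
    ranks = sps.rankdata(log2mean[ok], method="average")
    deciles = np.minimum((10 * (ranks - 1) / len(ranks)).astype(int), 9)
    trend = np.empty(ok.sum())
    for dec in np.unique(deciles):
        sel = deciles == dec
        trend[sel] = phi[ok][sel].mean()
    out[ok] = (
        DISPERSION_SHRINK_WEIGHT * phi[ok]
        + (1.0 - DISPERSION_SHRINK_WEIGHT) * trend
    )
    return np.maximum(out, DISPERSION_FLOOR)


def _fit_nb_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    """Fit one NB log-linear GLM; returns (log-likelihood, coefs, converged)."""
    import statsmodels.api as sm

    family = sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=family, offset=offset)
        res = model.fit(maxiter=100, tol=1e-8)
    converged = bool(getattr(res, "converged", True))
    return float(res.llf), np.asarray(res.params), converged


def nb_lrt_enrichment(
    counts: pd.DataFrame,
    designs: Sequence[SampleDesign],
    size_factors: Mapping[str, float] | pd.Series,
    contrast: tuple[str, str],
    report_features: Iterable[str] | None = None,
    alpha: float = 0.05,
    min_log2mean: float = 4.0,
) -> pd.DataFrame:
    """Per-feature NB-GLM likelihood-ratio test for the interaction term.

    ``counts`` is a feature x sample integer matrix; ``contrast`` is
    (condition, reference).  Only samples belonging to the two contrast
    conditions enter the fit.  Returns a DataFrame with columns
    feature_id, log2Mean, log2FC, lrt_stat, pvalue, fdr, class.
    BH adjustment runs over the reported, expression-scored features only.
    """
    condition, reference = contrast
    designs = [d for d in designs if d.condition in (condition, reference)]
    _check_design(designs, condition, reference)
    sample_ids = [d.sample_id for d in designs]
    missing = [s for s in sample_ids if s not in counts.columns]
    if missing:
        raise KeyError(f"samples missing from count matrix: {missing}")
    mat = counts[sample_ids].to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    sf = np.array([float(size_factors[s]) for s in sample_ids])
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    offset = np.log(sf)

    norm = mat / sf
    mean_norm = norm.mean(axis=1)
    with np.errstate(divide="ignore"):
        log2mean = np.where(mean_norm > 0, np.log2(np.maximum(mean_norm, 1e-300)), -np.inf)

    groups = np.array([f"{d.condition}::{d.fraction}" for d in designs])
    phi_raw = _moment_dispersions(norm, groups)
    finite_l2m = np.where(np.isfinite(log2mean), log2mean, np.nan)
    phi = _shrink_dispersions(phi_raw, finite_l2m)

    X_full, X_reduced = _design_matrices(designs, condition, reference)

    n_features = mat.shape[0]
    log2fc = np.full(n_features, np.nan)
    lrt = np.full(n_features, np.nan)
    pval = np.full(n_features, np.nan)
    for i in range(n_features):
        y = mat[i]
        if mean_norm[i] <= 0:
            pval[i] = 1.0
            lrt[i] = 0.0
            continue
        try:
            llf_full, params, conv_f = _fit_nb_glm(y, X_full, offset, phi[i])
            llf_red, _, conv_r = _fit_nb_glm(y, X_reduced, offset, phi[i])
        except Exception:
            pval[i] = 1.0
            lrt[i] = 0.0
            continue
        if not (conv_f and conv_r and np.isfinite(llf_full) and np.isfinite(llf_red)):
            pval[i] = 1.0
            lrt[i] = 0.0
            continue
        stat = max(0.0, 2.0 * (llf_full - llf_red))
        lrt[i] = stat
        log2fc[i] = params[-1] / LOG2
        pval[i] = float(sps.chi2.sf(stat, df=1))

    result = pd.DataFrame(
        {
            "feature_id": counts.index,
            "log2Mean": log2mean,
            "log2FC": log2fc,
            "lrt_stat": lrt,
            "pvalue": pval,
        }
    )
    if report_features is not None:
        keep = set(report_features)
        result = result[result["feature_id"].isin(keep)].reset_index(drop=True)

    # expression-scorable features enter BH; all-zero features stay ns
    testable = np.isfinite(result["log2Mean"].to_numpy())
    fdr = np.full(len(result), np.nan)
    fdr[testable] = benjamini_hochberg(result.loc[testable, "pvalue"].to_numpy())
    result["fdr"] = fdr
    return classify(result, alpha=alpha, min_log2mean=min_log2mean)


def padded_lrt(
    target_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    designs: Sequence[SampleDesign],
    contrast: tuple[str, str],
    library_stats: Sequence[LibraryStats] | None = None,
    alpha: float = 0.05,
    min_log2mean: float = 4.0,
) -> pd.DataFrame:
    """LRT for novel regions with annotated genes padding the matrix.

    Gene rows stabilize size factors and the dispersion trend; they are
    tested alongside the targets but dropped from the output, and BH runs
    over the target features only.  RSR size factors are used when library
    stats are supplied (the IP libraries retain rRNA); otherwise
    median-of-ratios on the combined matrix.
    """
    collide = set(target_counts.index) & set(gene_counts.index)
    if collide:
        raise ValueError(f"feature-id collision between targets and genes: {sorted(collide)[:5]}")
    if len(target_counts) == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    combined = pd.concat([gene_counts, target_counts])
    cond, ref = contrast
    used = [d for d in designs if d.condition in (cond, ref)]
    if library_stats is not None:
        by_id = {s.sample_id: s for s in library_stats}
        sf = rsr_size_factors([by_id[d.sample_id] for d in used])
    else:
        sf = median_of_ratios(combined[[d.sample_id for d in used]])
    return nb_lrt_enrichment(
        combined,
        used,
        sf,
        contrast,
        report_features=target_counts.index,
        alpha=alpha,
        min_log2mean=min_log2mean,
    )


def classify(
    results: pd.DataFrame, alpha: float = 0.05, min_log2mean: float = 4.0
) -> pd.DataFrame:
    """Attach significance classes at the FDR and expression-floor cutoffs.

    enriched:  fdr < alpha, log2Mean > min_log2mean, log2FC > 0
    depleted:  fdr < alpha, log2Mean > min_log2mean, log2FC < 0
    ns:        everything else
    """
    res = results.copy()
    fdr = res["fdr"].to_numpy(dtype=float)
    l2m = res["log2Mean"].to_numpy(dtype=float)
    l2fc = res["log2FC"].to_numpy(dtype=float)
    sig = (fdr < alpha) & (l2m > min_log2mean)
    cls = np.where(
        sig & (l2fc > 0), "enriched", np.where(sig & (l2fc < 0), "depleted", "ns")
    )
    res["class"] = cls
    return res[RESULT_COLUMNS] if set(RESULT_COLUMNS) <= set(res.columns) else res
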
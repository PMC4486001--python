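"""Genome-wide polygenic scoring.

Aligns discovery-GWAS effect alleles to the target cohort, performs
P-value-informed LD clumping (r^2 cutoff within a base-pair window,
LD measured in the target cohort itself), excludes long-range-LD
regions such as the MHC, builds scores over a grid of significance
thresholds as the allele-count-weighted sum of effect sizes, and
evaluates each score's incremental R^2 over ancestry covariates with a
nested-model F test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator

from .containers import ConfigError, GenotypeMatrix, SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "ClumpParams",
    "PgsResult",
    "DEFAULT_THRESHOLDS",
    "align_alleles",
    "clump",
    "score",
    "evaluate",
    "PolygenicScorer",
]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class ClumpParams:
    r2_max: float = 0.25
    window_bp: int = 200_000
    exclude_regions: list = field(default_factory=list)  # (chrom, start, end)

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_max < 1.0):
            raise ConfigError("r2_max must lie in (0, 1)")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be positive")


@dataclass
class PgsResult:
    """Per-threshold scores and evaluation metrics.

    ``summary`` columns: threshold, n_snps_in_score, then per evaluated
    trait ``<trait>_incremental_r2`` and ``<trait>_p``.  ``scores`` maps
    threshold -> per-individual score vector.
    """

    summary: pd.DataFrame
    scores: dict


# ---------------------------------------------------------------------------
# allele alignment
# ---------------------------------------------------------------------------

def align_alleles(stats: SummaryStats, snp_meta: pd.DataFrame) -> SummaryStats:
    """Orient effect sizes to the cohort's allele1.

    Effects are sign-flipped where the stats effect allele matches the
    cohort's allele2; strand-ambiguous (A/T, C/G) and unmatched SNPs
    are dropped with logged counts.
    """
    cohort = snp_meta[["snp", "a1", "a2"]].rename(
        columns={"a1": "cohort_a1", "a2": "cohort_a2"}
    )
    merged = stats.table.merge(cohort, on="snp", how="inner")
    if merged.empty:
        raise ConfigError("no SNP ids shared between summary stats and cohort")
    ca1 = merged["cohort_a1"].str.upper()
    ca2 = merged["cohort_a2"].str.upper()
    ambiguous = [
        frozenset((a, b)) in _AMBIGUOUS for a, b in zip(merged["a1"], merged["a2"])
    ]
    ambiguous = np.array(ambiguous)
    same = (merged["a1"] == ca1) & (merged["a2"] == ca2)
    flipped = (merged["a1"] == ca2) & (merged["a2"] == ca1)
    usable = (same | flipped) & ~ambiguous
    n_amb = int((ambiguous & (same | flipped)).sum())
    n_mismatch = int((~(same | flipped)).sum())
    if n_amb:
        logger.info("dropped %d strand-ambiguous SNPs", n_amb)
    if n_mismatch:
        logger.info("dropped %d allele-mismatched SNPs", n_mismatch)
    out = merged[usable].copy()
    flip = flipped[usable].to_numpy()
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, ["a1", "a2"]] = out.loc[flip, ["cohort_a2", "cohort_a1"]].to_numpy()
    out = out.drop(columns=["cohort_a1", "cohort_a2"]).reset_index(drop=True)
    return SummaryStats(out, discovery_n=stats.discovery_n)


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _in_regions(chrom, pos, regions) -> np.ndarray:
    mask = np.zeros(len(chrom), dtype=bool)
    for c, lo, hi in regions:
        mask |= (chrom == c) & (pos >= lo) & (pos < hi)
    return mask


def clump(
    stats: SummaryStats,
    geno: GenotypeMatrix,
    params: ClumpParams | None = None,
) -> list[str]:
    """P-value-informed clumping; returns the index SNP ids.

    SNPs are visited by ascending p-value (ties by chromosome then
    position); a SNP is retained unless it lies within ``window_bp`` of
    an already-chosen index on the same chromosome with squared dosage
    correlation above ``r2_max``, or inside an excluded region.
    """
    params = params or ClumpParams()
    meta = geno.snp_meta.set_index("snp")
    tab = stats.table[stats.table["snp"].isin(meta.index)]
    snp_col = {s: j for j, s in enumerate(geno.snp_meta["snp"])}
    x = geno.imputed()
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    order = tab.sort_values(["p", "chrom", "pos"], kind="mergesort")
    excluded = _in_regions(order["chrom"].to_numpy(), order["pos"].to_numpy(),
                           params.exclude_regions)
    index_snps: list[str] = []
    chosen: dict[int, list[tuple[int, int]]] = {}  # chrom -> [(pos, col)]
    for (snp, chrom, pos), skip in zip(
        order[["snp", "chrom", "pos"]].itertuples(index=False), excluded
    ):
        if skip:
            continue
        col = snp_col[snp]
        if sd[col] == 0:
            continue
        in_ld = False
        for ipos, icol in chosen.get(chrom, ()):
            if abs(ipos - pos) <= params.window_bp:
                r = float(x[:, col] @ x[:, icol]) / (
                    x.shape[0] * sd[col] * sd[icol]
                )
                if r * r > params.r2_max:
                    in_ld = True
                    break
        if not in_ld:
            index_snps.append(snp)
            chosen.setdefault(chrom, []).append((pos, col))
    return index_snps


# ---------------------------------------------------------------------------
# scoring and evaluation
# ---------------------------------------------------------------------------

def score(
    geno: GenotypeMatrix,
    stats: SummaryStats,
    threshold: float,
) -> np.ndarray:
    """Allele-count-weighted score over SNPs with p <= threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ConfigError("threshold must lie in (0, 1]")
    tab = stats.table
    use = tab[tab["p"] <= threshold]
    use = use[use["snp"].isin(set(geno.snp_meta["snp"]))]
    if use.empty:
        raise ConfigError(f"no SNP passes the p <= {threshold} threshold")
    snp_col = {s: j for j, s in enumerate(geno.snp_meta["snp"])}
    cols = np.array([snp_col[s] for s in use["snp"]])
    x = geno.imputed()[:, cols]
    return x @ use["beta"].to_numpy(dtype=float)


def evaluate(
    scores: dict,
    traits: pd.DataFrame,
    covariates: np.ndarray | pd.DataFrame | None = None,
    trait_columns: list[str] | None = None,
    n_snps: dict | None = None,
) -> PgsResult:
    """Incremental R^2 of each score over the covariates, per trait.

    ``incremental R^2 = R^2(trait ~ covariates + score) - R^2(trait ~
    covariates)``; the score term's p-value is the nested-model F test.
    """
    if trait_columns is None:
        trait_columns = [c for c in traits.columns if c not in ("fid", "iid")]
    if covariates is None:
        cov = np.empty((len(traits), 0))
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.drop(columns=["fid", "iid"], errors="ignore").to_numpy(float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    rows = []
    for thr in sorted(scores):
        s = np.asarray(scores[thr], dtype=float)
        row = {"threshold": thr,
               "n_snps_in_score": (n_snps or {}).get(thr, np.nan)}
        for trait in trait_columns:
            y = traits[trait].to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(s) & np.all(np.isfinite(cov), axis=1)
            if ok.sum() < 30:
                raise ConfigError(
                    f"fewer than 30 complete cases for trait {trait!r}"
                )
            r2_full, r2_base, pval = _nested_r2(y[ok], cov[ok], s[ok])
            row[f"{trait}_incremental_r2"] = r2_full - r2_base
            row[f"{trait}_p"] = pval
        rows.append(row)
    return PgsResult(pd.DataFrame(rows), dict(scores))


def _ols_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """R^2 and residual sum of squares of y ~ [1, x]."""
    X = np.column_stack([np.ones(y.size), x]) if x.size else np.ones((y.size, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - rss / tss, rss


def _nested_r2(y, cov, s):
    r2_base, rss_base = _ols_r2(y, cov)
    full = np.column_stack([cov, s]) if cov.size else s[:, None]
    r2_full, rss_full = _ols_r2(y, full)
    df2 = y.size - (full.shape[1] + 1)
    fstat = (rss_base - rss_full) / (rss_full / df2)
    pval = float(f_dist.sf(fstat, 1, df2)) if df2 > 0 else np.nan
    return r2_full, r2_base, pval


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class PolygenicScorer(BaseEstimator):
    """Clumping + thresholding polygenic scorer.

    ``fit`` aligns the summary statistics to the cohort and selects
    index SNPs by P-value-informed clumping; ``predict`` returns the
    per-individual score at one threshold; ``score_grid`` returns all
    thresholds.  The fitted attributes are ``aligned_stats_`` and
    ``index_snps_``.
    """

    def __init__(self, r2_max: float = 0.25, window_bp: int = 200_000,
                 exclude_regions: list | None = None,
                 thresholds: tuple = DEFAULT_THRESHOLDS):
        self.r2_max = r2_max
        self.window_bp = window_bp
        self.exclude_regions = exclude_regions
        self.thresholds = thresholds

    def _params(self, geno: GenotypeMatrix) -> ClumpParams:
        regions = self.exclude_regions
        if regions is None:
            regions = [geno.regions["MHC"]] if "MHC" in geno.regions else []
        return ClumpParams(self.r2_max, self.window_bp, list(regions))

    def fit(self, stats: SummaryStats, geno: GenotypeMatrix):
        aligned = align_alleles(stats, geno.snp_meta)
        index = clump(aligned, geno, self._params(geno))
        keep = aligned.table["snp"].isin(set(index))
        self.aligned_stats_ = SummaryStats(
            aligned.table[keep].reset_index(drop=True), aligned.discovery_n
        )
        self.index_snps_ = index
        return self

    def predict(self, geno: GenotypeMatrix, threshold: float = 0.5) -> np.ndarray:
        return score(geno, self.aligned_stats_, threshold)

    def score_grid(self, geno: GenotypeMatrix) -> tuple[dict, dict]:
        scores, counts = {}, {}
        tab = self.aligned_stats_.table
        for thr in self.thresholds:
            n = int((tab["p"] <= thr).sum())
            if n == 0:
                continue
            scores[thr] = score(geno, self.aligned_stats_, thr)
            counts[thr] = n
        return scores, counts

    def evaluate(self, geno: GenotypeMatrix, traits: pd.DataFrame,
                 covariates=None, trait_columns=None) -> PgsResult:
        scores, counts = self.score_grid(geno)
        return evaluate(scores, traits, covariates, trait_columns, counts)
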
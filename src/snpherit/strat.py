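"""Ancestry-stratification control.

LD-prunes markers (sliding-window pairwise r^2), computes principal
components of the standardized-genotype covariance among individuals,
and counts significant ancestry axes by sequential Tracy-Widom tests of
the leading eigenvalues (stop at the first non-significant axis), using
the effective-marker normalization standard in ancestry PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.base import BaseEstimator

from ._twdist import TW1_F, TW1_S
from .containers import ConfigError, GenotypeMatrix

__all__ = [
    "StratParams",
    "PcaResult",
    "ld_prune_snps",
    "GenomicPCA",
    "compute_pca",
    "tracy_widom_test",
    "tw_pvalue",
]

_tw_cdf = PchipInterpolator(TW1_S, TW1_F)


@dataclass
class StratParams:
    ld_r2_max: float = 0.2
    n_snps_subset: int = 100_000
    tw_alpha: float = 0.05
    window: int = 50
    step: int = 5
    n_axes: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.ld_r2_max < 1.0):
            raise ConfigError("ld_r2_max must lie in (0, 1)")
        if not (0.0 < self.tw_alpha < 1.0):
            raise ConfigError("tw_alpha must lie in (0, 1)")


@dataclass
class PcaResult:
    axes: np.ndarray          # individuals x components, orthonormal scores
    eigenvalues: np.ndarray   # non-increasing
    pvalues: np.ndarray       # Tracy-Widom, for the axes actually tested
    n_significant: int

    def covariates(self, samples: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
        k = self.n_significant if k is None else k
        out = samples[["fid", "iid"]].copy()
        for j in range(k):
            out[f"PC{j + 1}"] = self.axes[:, j]
        return out


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune_snps(geno: GenotypeMatrix, params: StratParams | None = None) -> list[str]:
    """Sliding-window LD pruning; keeps the earlier SNP of a close pair.

    Within windows of ``params.window`` SNPs advanced by ``params.step``
    (per chromosome, left to right), any SNP whose squared dosage
    correlation with an already-retained earlier SNP exceeds
    ``ld_r2_max`` is dropped.  Deterministic.
    """
    params = params or StratParams()
    if geno.n_snps < 1:
        raise ConfigError("no SNPs to prune")
    x = geno.imputed()
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    kept = np.ones(geno.n_snps, dtype=bool)
    kept[sd == 0] = False  # monomorphic: uninformative for LD/PCA
    chroms = geno.snp_meta["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, idx.size, params.step):
            win = idx[start:start + params.window]
            live = win[kept[win]]
            if live.size < 2:
                continue
            xs = x[:, live] / sd[live]
            r = (xs.T @ xs) / x.shape[0]
            r2 = r * r
            for a in range(live.size):
                if not kept[live[a]]:
                    continue
                for b in range(a + 1, live.size):
                    if kept[live[b]] and r2[a, b] > params.ld_r2_max:
                        kept[live[b]] = False
            if win[-1] == idx[-1]:
                break
    return geno.snp_meta.loc[kept, "snp"].tolist()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class GenomicPCA(BaseEstimator):
    """Principal components of standardized genotypes among individuals.

    Eigendecomposition of ``Z Z^T / M`` where ``Z`` is the per-SNP
    variance-standardized genotype matrix over the selected marker
    subset; scores are the orthonormal eigenvectors (the conventional
    ancestry axes), eigenvalues are non-increasing.

    Parameters
    ----------
    n_axes : number of leading axes to return (default 20).
    tw_alpha : significance level of the sequential Tracy-Widom tests.
    """

    def __init__(self, n_axes: int = 20, tw_alpha: float = 0.05):
        self.n_axes = n_axes
        self.tw_alpha = tw_alpha

    def fit(self, geno: GenotypeMatrix, snp_subset: list[str] | None = None):
        if geno.n_individuals < 3:
            raise ConfigError("PCA needs at least three individuals")
        if snp_subset is not None:
            if len(snp_subset) == 0:
                raise ConfigError("empty SNP subset")
            want = set(snp_subset)
            mask = geno.snp_meta["snp"].isin(want).to_numpy()
            geno = geno.subset_snps(mask)
        z, keep = geno.standardized(maf_min=0.0)
        m = keep.size
        if m == 0:
            raise ConfigError("no polymorphic SNPs for PCA")
        a = (z @ z.T) / m
        vals, vecs = np.linalg.eigh(a)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(vecs.shape[1]):
            k = np.argmax(np.abs(vecs[:, j]))
            if vecs[k, j] < 0:
                vecs[:, j] = -vecs[:, j]
        n_eig = min(geno.n_individuals - 1, m)
        vals = vals[:n_eig]
        kmax = min(self.n_axes, n_eig)
        self.n_snps_ = m
        self.eigenvalues_ = vals
        self.axes_ = vecs[:, :kmax]
        pvals, nsig = tracy_widom_test(
            vals, geno.n_individuals, m, alpha=self.tw_alpha, max_axes=kmax
        )
        self.pvalues_ = pvals
        self.n_significant_ = nsig
        return self

    def transform(self, geno=None) -> np.ndarray:
        return self.axes_

    def result(self) -> PcaResult:
        return PcaResult(self.axes_, self.eigenvalues_, self.pvalues_,
                         self.n_significant_)


def compute_pca(
    geno: GenotypeMatrix,
    snp_subset: list[str] | None = None,
    params: StratParams | None = None,
) -> PcaResult:
    params = params or StratParams()
    est = GenomicPCA(n_axes=params.n_axes, tw_alpha=params.tw_alpha)
    est.fit(geno, snp_subset=snp_subset)
    return est.result()


# ---------------------------------------------------------------------------
# Tracy-Widom
# ---------------------------------------------------------------------------

def tw_pvalue(x: float) -> float:
    """Upper-tail probability of the Tracy-Widom (beta=1) distribution."""
    if x <= TW1_S[0]:
        return 1.0
    if x >= TW1_S[-1]:
        return 0.0
    return float(np.clip(1.0 - _tw_cdf(x), 0.0, 1.0))


def tracy_widom_test(
    eigenvalues: np.ndarray,
    n_individuals: int,
    n_snps: int,
    alpha: float = 0.05,
    max_axes: int | None = None,
) -> tuple[np.ndarray, int]:
    """Sequential Tracy-Widom tests of the leading eigenvalues.

    The k-th eigenvalue (on the Wishart scale, i.e. multiplied back by
    the marker count) is centered and scaled by the white-Wishart edge
    constants for the remaining dimension, with the half-integer
    correction that gives second-order accuracy of the Tracy-Widom
    approximation, and referred to the TW1 distribution.  Testing stops
    at the first axis with p >= ``alpha``.  Returns the p-values of the
    axes tested and the count of significant axes.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-12]
    total = lam.size
    if total == 0:
        return np.array([]), 0
    if max_axes is None:
        max_axes = total
    # eigenvalues arrive normalized by the marker count (Z Z' / M);
    # restore the Wishart scale for the edge constants
    wish = lam * n_snps
    pvals: list[float] = []
    nsig = 0
    for k in range(min(max_axes, total - 1)):
        p_dim = total - k          # dimension of the remaining problem
        n_eff = n_snps - k         # markers spent on removed axes
        if n_eff <= 1 or p_dim <= 1:
            break
        # Johnstone-Ma half-integer centering: second-order accurate
        sq_n = np.sqrt(n_eff - 0.5)
        sq_p = np.sqrt(p_dim - 0.5)
        mu = (sq_n + sq_p) ** 2
        sigma = (sq_n + sq_p) * (1.0 / sq_n + 1.0 / sq_p) ** (1.0 / 3.0)
        x = (wish[k] - mu) / sigma
        p = tw_pvalue(x)
        pvals.append(p)
        if p < alpha:
            nsig += 1
        else:
            break
    return np.array(pvals), nsig
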
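"""Core in-memory containers shared by every stage of the pipeline.

A cohort is represented by a :class:`GenotypeMatrix` (additive allele
counts plus marker/sample metadata), pairwise genomic similarity by a
:class:`RelatednessMatrix`, and per-SNP discovery-GWAS effects by a
:class:`SummaryStats` table.  Phenotypes travel as plain pandas
DataFrames keyed by (FID, IID).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing dosage inside the int8 dosage matrix
MISSING = np.int8(-1)

SNP_META_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf"]


class FormatError(ValueError):
    """Structurally inconsistent input file or container."""


class ConfigError(ValueError):
    """Invalid or unrealizable configuration."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive allele counts (copies of allele1).

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` int8 array with entries in
        ``{0, 1, 2}`` or :data:`MISSING`.
    snp_meta
        Per-SNP table with columns ``snp, chrom, pos, a1, a2, maf``.
    samples
        Per-individual table with columns ``fid, iid``.
    regions
        Named genomic intervals, ``name -> (chrom, start_bp, end_bp)``
        half-open; used e.g. for the MHC stand-in in synthetic cohorts.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    samples: pd.DataFrame
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise FormatError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise FormatError(
                f"sample table has {len(self.samples)} rows for {n} individuals"
            )
        if len(self.snp_meta) != m:
            raise FormatError(
                f"snp table has {len(self.snp_meta)} rows for {m} SNPs"
            )
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- basic dimensions -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check the container invariants, raising :class:`FormatError`."""
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise FormatError("dosages outside {0, 1, 2, missing}")
        for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
        if "maf" in self.snp_meta and self.snp_meta["maf"].notna().all():
            freq = self.allele_frequencies()
            stored = self.snp_meta["maf"].to_numpy(dtype=float)
            stored_freq = np.minimum(stored, 1.0 - stored)
            obs = np.minimum(freq, 1.0 - freq)
            tol = 1.0 / (2 * self.n_individuals) + 1e-12
            # stored value is the *drawn* population MAF for synthetic data;
            # only flag gross disagreement (several binomial s.e.)
            se = np.sqrt(stored_freq * (1 - stored_freq) / (2 * self.n_individuals))
            if np.any(np.abs(obs - stored_freq) > 6 * se + tol):
                raise FormatError("stored allele frequencies disagree with dosages")

    # -- numeric views ----------------------------------------------------
    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of allele1 per SNP, ignoring missing dosages."""
        d = self.dosages
        obs = d != MISSING
        counts = np.where(obs, d, 0).sum(axis=0, dtype=np.int64)
        denom = 2 * obs.sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    def imputed(self) -> np.ndarray:
        """Float dosage matrix with missing values mean-imputed per SNP."""
        x = self.dosages.astype(np.float64)
        miss = self.dosages == MISSING
        if miss.any():
            p = self.allele_frequencies()
            fill = np.broadcast_to(2.0 * p, x.shape)
            x[miss] = fill[miss]
        return x

    def standardized(self, maf_min: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Centered and variance-standardized dosages.

        Returns ``(Z, keep)`` where ``keep`` indexes the polymorphic SNPs
        with minor-allele frequency > ``maf_min``.  Standardization uses
        the sample allele frequency ``p``: ``z = (x - 2p)/sqrt(2p(1-p))``.
        """
        x = self.imputed()
        p = np.nanmean(x, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        keep = np.flatnonzero(maf > max(maf_min, 0.0))
        p = p[keep]
        z = (x[:, keep] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        return z, keep

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            self.samples.copy(),
            dict(self.regions),
        )

    def subset_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index],
            self.snp_meta.copy(),
            self.samples.iloc[index].reset_index(drop=True),
            dict(self.regions),
        )


@dataclass
class RelatednessMatrix:
    """Symmetric allele-frequency-standardized genomic similarity (GRM)."""

    values: np.ndarray
    ids: pd.DataFrame  # columns fid, iid
    n_snps_used: np.ndarray  # per-pair SNP count, same shape as values

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise FormatError("GRM must be square")
        if len(self.ids) != n:
            raise FormatError("GRM id table length mismatch")
        self.n_snps_used = np.broadcast_to(
            np.asarray(self.n_snps_used), self.values.shape
        ).copy()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        if not np.all(np.isfinite(self.values)):
            raise FormatError("GRM contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=atol):
            raise FormatError("GRM is not symmetric")

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class SummaryStats:
    """Per-SNP discovery-GWAS effects on a standardized trait.

    ``table`` columns: ``snp, chrom, pos, a1 (effect allele), a2 (other
    allele), beta, se, p``; one row per SNP id.
    """

    table: pd.DataFrame
    discovery_n: int = 0

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp", "chrom", "pos", "a1", "a2", "beta", "p"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"summary statistics missing columns: {sorted(missing)}")
        dup = t["snp"][t["snp"].duplicated()].unique()
        if len(dup):
            raise FormatError(f"duplicate SNP ids in summary statistics: {list(dup)[:10]}")
        if (t["p"] <= 0).any() or (t["p"] > 1).any():
            raise FormatError("p-values must lie in (0, 1]")
        if "se" in t.columns and (t["se"].dropna() <= 0).any():
            raise FormatError("standard errors must be positive")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)
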
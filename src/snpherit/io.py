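"""Readers and writers for the standard formats the pipeline touches.

PLINK BED/BIM/FAM (variant-major 2-bit encoding), the GRM-binary
triplet convention used by the variance-component ecosystem
(``.grm.bin`` float32 lower triangle, ``.grm.N.bin`` per-pair SNP
counts, ``.grm.id`` id table), and delimited phenotype / covariate /
summary-statistic tables.  Readers reject structurally inconsistent
input rather than silently repairing it, and every writer/reader pair
round-trips.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    RelatednessMatrix,
    SummaryStats,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit codes (variant-major): 00 = hom allele1, 10 = het, 11 = hom allele2,
# 01 = missing.  Dosage counts copies of allele1.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, int(MISSING): 0b01}


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM
# ---------------------------------------------------------------------------

def read_bed(prefix: str | Path) -> GenotypeMatrix:
    """Read a variant-major PLINK BED/BIM/FAM file set."""
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(prefix.suffix + ext).exists():
            raise FileNotFoundError(f"{prefix}{ext} does not exist")
    bim = pd.read_csv(
        prefix.with_suffix(prefix.suffix + ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp": str, "pos": np.int64, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(prefix.suffix + ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(prefix.suffix + ".bed").read_bytes()
    if raw[:2] != _BED_MAGIC[:2]:
        raise FormatError("BED magic bytes invalid")
    if raw[2:3] != _BED_MAGIC[2:3]:
        raise FormatError("BED is not variant-major (third magic byte != 0x01)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"BED length {len(raw)} does not match {n} individuals x {m} SNPs "
            f"(expected {expected})"
        )
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, individual-fastest within each SNP record
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # individuals x SNPs
    meta = pd.DataFrame(
        {
            "snp": bim["snp"],
            "chrom": bim["chrom"],
            "pos": bim["pos"],
            "a1": bim["a1"],
            "a2": bim["a2"],
            "maf": np.nan,
        }
    )
    geno = GenotypeMatrix(np.ascontiguousarray(dosages), meta, fam[["fid", "iid"]])
    geno.snp_meta["maf"] = geno.allele_frequencies()
    return geno


def write_bed(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a cohort as variant-major PLINK BED/BIM/FAM."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.dosages.shape
    lut = np.zeros(256, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        lut[np.int8(dosage).view(np.uint8)] = code
    codes = lut[geno.dosages.T.astype(np.uint8)]  # m x n
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(m, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(prefix.suffix + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": geno.snp_meta["chrom"],
            "snp": geno.snp_meta["snp"],
            "cm": 0,
            "pos": geno.snp_meta["pos"],
            "a1": geno.snp_meta["a1"],
            "a2": geno.snp_meta["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(prefix.suffix + ".bim"), sep="\t",
               header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.samples["fid"],
            "iid": geno.samples["iid"],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(prefix.suffix + ".fam"), sep="\t",
               header=False, index=False)


# ---------------------------------------------------------------------------
# GRM binary triplet
# ---------------------------------------------------------------------------

def write_grm(grm: RelatednessMatrix, prefix: str | Path) -> None:
    """Write ``.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``.

    Values are the lower triangle including the diagonal, float32, in
    row-major pair order (pair ``(k, j)`` with ``j <= k``).
    """
    grm.validate()
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n
    il = np.tril_indices(n)
    grm.values[il].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.n_snps_used[il].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    grm.ids[["fid", "iid"]].to_csv(f"{prefix}.grm.id", sep="\t",
                                   header=False, index=False)


def read_grm(prefix: str | Path) -> RelatednessMatrix:
    """Read a GRM-binary triplet back into a symmetric matrix."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    expected = n * (n + 1) // 2
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if vals.size != expected:
        raise FormatError(
            f"{prefix}.grm.bin holds {vals.size} values; id table implies {expected}"
        )
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if counts.size not in (expected, 1):
        raise FormatError(f"{prefix}.grm.N.bin has unexpected length {counts.size}")
    if (counts < 1).any():
        raise FormatError("GRM pair counts must be >= 1")
    a = np.zeros((n, n))
    nmat = np.zeros((n, n))
    il = np.tril_indices(n)
    a[il] = vals
    nmat[il] = counts if counts.size == expected else counts[0]
    a = a + np.tril(a, -1).T
    nmat = nmat + np.tril(nmat, -1).T
    return RelatednessMatrix(a, ids, nmat)


# ---------------------------------------------------------------------------
# phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a whitespace/tab-delimited table with FID and IID first."""
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}
    if "fid" not in cols or "iid" not in cols:
        raise FormatError(f"{path}: first columns must include FID and IID")
    df = df.rename(columns={cols["fid"]: "fid", cols["iid"]: "iid"})
    df["fid"] = df["fid"].astype(str)
    df["iid"] = df["iid"].astype(str)
    if df.duplicated(["fid", "iid"]).any():
        raise FormatError(f"{path}: duplicate (FID, IID) pairs")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["fid", "iid"] + [c for c in df.columns if c not in ("fid", "iid")]
    out = df[cols].rename(columns={"fid": "FID", "iid": "IID"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def align_samples(ids: pd.DataFrame, *tables: pd.DataFrame) -> list[pd.DataFrame]:
    """Inner-join tables onto an (fid, iid) id frame, logging drops.

    Each returned table has exactly one row per id row, in id order.
    """
    out = []
    base = ids[["fid", "iid"]].reset_index(drop=True)
    for t in tables:
        merged = base.merge(t, on=["fid", "iid"], how="inner")
        dropped = len(base) - len(merged)
        if dropped:
            logger.info("sample alignment dropped %d of %d ids", dropped, len(base))
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

_STATS_REQUIRED = ("snp", "chrom", "pos", "a1", "a2", "beta", "p")


def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    discovery_n: int = 0,
) -> SummaryStats:
    """Read a delimited summary-statistics table.

    ``column_map`` maps file column names to the canonical names
    ``snp, chrom, pos, a1, a2, beta, se, p``.  Rows with missing beta
    or p are dropped (count logged); p = 0 is clamped to the smallest
    positive float with a warning; alleles are upper-cased; duplicate
    SNP ids are an error.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [c.lower() for c in df.columns]
    missing = set(_STATS_REQUIRED) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    n0 = len(df)
    df = df.dropna(subset=["beta", "p"])
    if len(df) < n0:
        logger.info("dropped %d rows with missing beta or p", n0 - len(df))
    zero_p = df["p"] <= 0
    if zero_p.any():
        logger.warning(
            "clamped %d non-positive p-values to the smallest positive float",
            int(zero_p.sum()),
        )
        df.loc[zero_p, "p"] = np.finfo(float).tiny
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()
    return SummaryStats(df.reset_index(drop=True), discovery_n=discovery_n)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    stats.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
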
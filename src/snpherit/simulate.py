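"""Synthetic family cohorts with a parent-mediated socioeconomic trait.

The generator emulates the data structure of a twin-study DNA sample in
which child genotypes serve as proxies for parental genotypes: common
biallelic SNPs in linkage equilibrium (optionally with short-range LD),
an achievement-like trait driven by the child's own genetic value, an
SES-like trait driven by the *midparent* genetic value at the same
causal SNPs, an IQ-like mediator sharing part of the common genetic
factor, and fabricated discovery-GWAS summary statistics for polygenic
scoring.

Default variance structure follows the study being emulated: SNP-tagged
variance fractions 0.31 (achievement) and 0.20 (SES, measured against
child genotypes), generating genetic correlation 1.0, total phenotypic
correlation 0.50, and a mediator routed one third of the shared genetic
factor.

Genetic components are rescaled *exactly* (not in expectation) so the
realized variance tagged in each simulated sample equals the target;
residuals are drawn Gaussian and then orthogonalized in-sample against
the genetic components, which removes replicate noise from the variance
partition at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .containers import ConfigError, GenotypeMatrix, SummaryStats

__all__ = [
    "SimConfig",
    "TraitTruth",
    "Cohort",
    "simulate_genotypes",
    "simulate_parent_child",
    "simulate_traits",
    "simulate_discovery_gwas",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    ``h2_trait1``/``h2_trait2`` are the variance fractions of the
    achievement-like and SES-like traits tagged by the *child's*
    genotypes; ``rg_target`` the generating genetic correlation between
    those child-side genetic components; ``r_p_target`` the total
    phenotypic correlation, met by solving the residual correlation
    analytically; ``mediator_share`` the portion of the shared genetic
    factor routed through the IQ-like mediator.  In ``parental_mode``
    the SES trait is built from midparent genetic values and calibrated
    so the child-genotype-tagged variance still equals ``h2_trait2``
    (this requires ``h2_trait2`` < 0.5: transmission halves the tagged
    parental variance, so the parental component carries ~2*h2_trait2).
    """

    n_individuals: int = 3000
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_shared: int = 500
    n_causal_specific_per_trait: int = 0
    h2_trait1: float = 0.31
    h2_trait2: float = 0.20
    rg_target: float = 1.0
    r_p_target: float = 0.50
    mediator_share: float = 1.0 / 3.0
    h2_mediator: float = 0.38
    parental_mode: bool = True
    n_chromosomes: int = 2
    spacing_bp: int = 1_000_000
    ld_adjacent_r: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ConfigError("need n_individuals >= 2 and n_snps >= 1")
        n_causal = self.n_causal_shared + 2 * self.n_causal_specific_per_trait
        if n_causal > self.n_snps:
            raise ConfigError(
                f"{n_causal} causal SNPs requested but only {self.n_snps} simulated"
            )
        for name in ("h2_trait1", "h2_trait2", "h2_mediator", "mediator_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not (-1.0 <= self.rg_target <= 1.0):
            raise ConfigError("rg_target must lie in [-1, 1]")
        if abs(self.rg_target) < 1.0 and self.n_causal_specific_per_trait == 0 \
                and self.h2_trait1 > 0 and self.h2_trait2 > 0:
            raise ConfigError(
                "rg_target < 1 requires trait-specific causal SNPs "
                "(n_causal_specific_per_trait > 0)"
            )
        if self.parental_mode and self.h2_trait2 >= 0.5:
            raise ConfigError(
                "parental_mode needs h2_trait2 < 0.5: the parental component "
                "carries twice the child-tagged variance"
            )
        if not (0.0 <= abs(self.ld_adjacent_r) < 1.0):
            raise ConfigError("ld_adjacent_r must lie in [0, 1)")

    def stage_rngs(self) -> dict[str, np.random.Generator]:
        """One master seed expanded into independent per-stage streams."""
        ss = np.random.SeedSequence(self.seed)
        names = ["genotypes", "parents", "traits", "gwas"]
        return dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))


@dataclass
class TraitTruth:
    """Generating truth of a simulated trait architecture.

    ``beta1`` holds the realized per-allele effects of the achievement
    trait for every SNP (zero off the causal set) -- the marginal
    child-side effects a discovery GWAS of the trait would estimate.
    """

    causal_shared: np.ndarray
    causal_specific1: np.ndarray
    causal_specific2: np.ndarray
    beta1: np.ndarray
    beta2_child: np.ndarray
    maf: np.ndarray
    realized_h2_trait1: float
    realized_h2_trait2: float
    residual_correlation: float


@dataclass
class Cohort:
    """Bundle returned by :func:`simulate_cohort`."""

    children: GenotypeMatrix
    parents: tuple[GenotypeMatrix, GenotypeMatrix] | None
    phenotypes: pd.DataFrame
    truth: TraitTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _snp_meta(config: SimConfig, maf: np.ndarray) -> tuple[pd.DataFrame, dict]:
    m = config.n_snps
    per = int(np.ceil(m / config.n_chromosomes))
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), per)[:m]
    pos = np.concatenate(
        [np.arange(1, np.sum(chroms == c) + 1) * config.spacing_bp
         for c in np.unique(chroms)]
    )
    meta = pd.DataFrame(
        {
            "snp": [f"snp{i}" for i in range(m)],
            "chrom": chroms.astype(int),
            "pos": pos.astype(np.int64),
            "a1": "A",
            "a2": "G",
            "maf": maf,
        }
    )
    # 8-Mb stand-in for the MHC on the last chromosome, 26-34 Mb
    regions = {"MHC": (int(chroms[-1]), 26_000_000, 34_000_000)}
    return meta, regions


def _haplotypes(p: np.ndarray, n: int, rng: np.random.Generator,
                ld_r: float) -> np.ndarray:
    """n x m 0/1 haplotypes; adjacent SNPs correlated ~ld_r via a copy chain."""
    m = p.size
    h = (rng.random((n, m)) < p).astype(np.int8)
    if ld_r:
        copy = rng.random((n, m - 1)) < abs(ld_r)
        for j in range(1, m):
            c = copy[:, j - 1]
            h[c, j] = h[c, j - 1]
    return h


def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | None = None,
                       sample_prefix: str = "fam") -> GenotypeMatrix:
    """Draw a cohort of unrelated genotypes.

    Per-SNP MAFs are uniform on ``config.maf_range``; dosages are the
    sum of two Bernoulli(p) haplotypes, hence Binomial(2, p) and in
    linkage equilibrium unless ``ld_adjacent_r`` is set.
    """
    if rng is None:
        rng = config.stage_rngs()["genotypes"]
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.n_snps)
    n = config.n_individuals
    if config.ld_adjacent_r:
        d = (_haplotypes(maf, n, rng, config.ld_adjacent_r)
             + _haplotypes(maf, n, rng, config.ld_adjacent_r))
    else:
        d = rng.binomial(2, maf, size=(n, config.n_snps)).astype(np.int8)
    meta, regions = _snp_meta(config, maf)
    samples = pd.DataFrame(
        {"fid": [f"{sample_prefix}{i}" for i in range(n)],
         "iid": [f"{sample_prefix}{i}_1" for i in range(n)]}
    )
    return GenotypeMatrix(d.astype(np.int8), meta, samples, regions)


def simulate_parent_child(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[tuple[GenotypeMatrix, GenotypeMatrix], GenotypeMatrix]:
    """Two parental cohorts plus children by Mendelian transmission.

    Each child receives one allele per SNP from each parent, drawn
    Bernoulli(parent dosage / 2); SNPs transmit independently (no
    linkage in the gametes).  Population allele frequencies are
    preserved in expectation.
    """
    if not config.parental_mode:
        raise ConfigError("simulate_parent_child requires parental_mode")
    rngs = config.stage_rngs()
    if rng is None:
        rng = rngs["parents"]
    father = simulate_genotypes(config, rng=rngs["genotypes"], sample_prefix="fam")
    # same MAFs for the second parent: redraw dosages at father's frequencies
    maf = father.snp_meta["maf"].to_numpy()
    n, m = father.dosages.shape
    mother_d = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    mother = GenotypeMatrix(
        mother_d, father.snp_meta.copy(), father.samples.copy(), dict(father.regions)
    )
    t1 = rng.random((n, m)) < father.dosages / 2.0
    t2 = rng.random((n, m)) < mother.dosages / 2.0
    child = GenotypeMatrix(
        (t1.astype(np.int8) + t2.astype(np.int8)),
        father.snp_meta.copy(),
        father.samples.copy(),
        dict(father.regions),
    )
    # relabel parent ids so the three cohorts are distinguishable
    father = replace(father)
    father.samples = father.samples.assign(iid=[f"fam{i}_F" for i in range(n)])
    mother.samples = mother.samples.assign(iid=[f"fam{i}_M" for i in range(n)])
    return (father, mother), child


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    """Center and scale to sample variance exactly 1."""
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise ConfigError("degenerate (constant) component in trait construction")
    return v / sd


def _orthonormal_noise(rng: np.random.Generator, n: int, k: int,
                       against: np.ndarray) -> np.ndarray:
    """k noise vectors made exactly orthogonal (in sample) to ``against``
    columns and to each other, each with mean 0 and variance 1."""
    basis = np.column_stack([np.ones(n)] + [c for c in against.T])
    q, _ = np.linalg.qr(basis)
    out = []
    for _ in range(k):
        e = rng.standard_normal(n)
        e = e - q @ (q.T @ e)
        for prev in out:
            e = e - prev * (prev @ e) / n
        e = _unit(e)
        out.append(e)
    return np.column_stack(out)


def simulate_traits(
    geno: GenotypeMatrix,
    parents: tuple[GenotypeMatrix, GenotypeMatrix] | None,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TraitTruth]:
    """Generate achievement, SES and mediator phenotypes.

    Returns the phenotype table (columns ``fid, iid, achievement, ses,
    iq``) and the generating :class:`TraitTruth`.
    """
    if rng is None:
        rng = config.stage_rngs()["traits"]
    if config.parental_mode and parents is None:
        raise ConfigError("parental_mode requires parental genotypes")
    n, m = geno.dosages.shape
    ncs, ncsp = config.n_causal_shared, config.n_causal_specific_per_trait
    perm = rng.permutation(m)
    shared = np.sort(perm[:ncs])
    spec1 = np.sort(perm[ncs:ncs + ncsp])
    spec2 = np.sort(perm[ncs + ncsp:ncs + 2 * ncsp])

    p = geno.snp_meta["maf"].to_numpy()
    sd_allele = np.sqrt(2.0 * p * (1.0 - p))
    xc = geno.imputed()
    xc = xc - xc.mean(axis=0)

    # per-allele effect draws (i.i.d. normal on the standardized scale)
    u = np.zeros(m)
    u[shared] = rng.standard_normal(ncs)
    u1 = np.zeros(m)
    u2 = np.zeros(m)
    if ncsp:
        u1[spec1] = rng.standard_normal(ncsp)
        u2[spec2] = rng.standard_normal(ncsp)
    b_sh = np.where(sd_allele > 0, u / np.where(sd_allele > 0, sd_allele, 1.0), 0.0)
    b_s1 = np.where(sd_allele > 0, u1 / np.where(sd_allele > 0, sd_allele, 1.0), 0.0)
    b_s2 = np.where(sd_allele > 0, u2 / np.where(sd_allele > 0, sd_allele, 1.0), 0.0)

    rg = config.rg_target
    w_sh, w_sp = np.sqrt(abs(rg)), np.sqrt(1.0 - abs(rg))
    sign2 = np.sign(rg) if rg != 0 else 1.0

    # --- trait 1: child genetic value, exactly h2_trait1 ------------------
    # effect vectors are carried through every linear operation so the
    # recorded per-allele truth matches the constructed values exactly
    def unitized(w):
        v = xc @ w
        v = v - v.mean()
        sd = v.std()
        if sd == 0:
            raise ConfigError("degenerate genetic component")
        return w / sd, v / sd

    if ncs:
        w_gsh, g_sh = unitized(b_sh)
    else:
        w_gsh, g_sh = np.zeros(m), np.zeros(n)
    if config.h2_trait1 > 0:
        w1 = w_sh * w_gsh
        if ncsp and w_sp > 0:
            w1s, g1s = unitized(b_s1)
            c = float(g_sh @ g1s) / n
            w_orth, _ = unitized(w1s - c * w_gsh)
            w1 = w1 + w_sp * w_orth
        w1, comp1 = unitized(w1)
        if np.allclose(comp1, 0):
            raise ConfigError("h2_trait1 > 0 but no causal effects assigned")
        w1 = np.sqrt(config.h2_trait1) * w1
        g1 = xc @ w1
        g1 = g1 - g1.mean()
    else:
        w1 = np.zeros(m)
        g1 = np.zeros(n)

    # --- trait 2: parental or child genetic value, child-tagged h2_trait2 -
    # mixture components are unitized against the child sample (like
    # trait 1) so the child-side genetic correlation equals rg_target
    if ncsp and w_sp > 0 and config.h2_trait2 > 0:
        w2s, g2s = unitized(b_s2)
        c2 = float(g_sh @ g2s) / n
        w2_orth, _ = unitized(w2s - c2 * w_gsh)
        b2 = w_sh * w_gsh + sign2 * w_sp * w2_orth
    else:
        b2 = w_sh * w_gsh + sign2 * w_sp * b_s2
    if config.h2_trait2 > 0:
        if config.parental_mode:
            xf = parents[0].imputed()
            xm = parents[1].imputed()
            xmid = (xf + xm) / 2.0
            raw_parent = xmid @ b2
            raw_parent = raw_parent - raw_parent.mean()
            child_proxy = xc @ (b2 / 2.0)  # transmission halves the effect
            sd_proxy = child_proxy.std()
            if sd_proxy == 0:
                raise ConfigError("SES architecture has no child-tagged variance")
            scale2 = np.sqrt(config.h2_trait2) / sd_proxy
            g2 = scale2 * raw_parent
            b2_child = scale2 * b2 / 2.0
        else:
            raw = xc @ b2
            scale2 = np.sqrt(config.h2_trait2) / raw.std()
            g2 = scale2 * (raw - raw.mean())
            b2_child = scale2 * b2
    else:
        g2 = np.zeros(n)
        b2_child = np.zeros(m)
        scale2 = 0.0

    var_g2 = float(g2 @ g2) / n
    if var_g2 >= 1.0:
        raise ConfigError(
            f"SES genetic component variance {var_g2:.3f} >= 1; "
            "lower h2_trait2 (parental transmission doubles it)"
        )

    # --- mediator: shares mediator_share of the common factor -------------
    gm = np.sqrt(config.h2_mediator) * (
        np.sqrt(config.mediator_share) * g_sh
        + np.sqrt(1.0 - config.mediator_share)
        * _orthonormal_noise(rng, n, 1, np.column_stack([g_sh]))[:, 0]
    ) if config.h2_mediator > 0 else np.zeros(n)

    # --- residuals: solve the residual covariance for r_p_target ----------
    gen_cov = float(g1 @ g2) / n
    need = config.r_p_target - gen_cov
    var_e1 = 1.0 - config.h2_trait1
    var_e2 = 1.0 - var_g2
    if var_e1 > 0 and var_e2 > 0:
        rho_e = need / np.sqrt(var_e1 * var_e2)
        if abs(rho_e) > 1.0:
            raise ConfigError(
                f"phenotypic correlation {config.r_p_target} unreachable: "
                f"residual correlation would be {rho_e:.2f}"
            )
    elif abs(need) > 1e-8:
        raise ConfigError("no residual variance left to absorb the phenotypic correlation")
    genetic_block = np.column_stack([g1, g2, gm])
    noise = _orthonormal_noise(rng, n, 3, genetic_block)
    e1 = np.sqrt(var_e1) * noise[:, 0]
    if var_e1 > 0 and var_e2 > 0:
        c12 = need
        a = c12 / np.sqrt(var_e1)
        b_res = var_e2 - a * a
        if b_res < 0:
            raise ConfigError("residual covariance infeasible")
        e2 = a * noise[:, 0] + np.sqrt(b_res) * noise[:, 1]
    else:
        e2 = np.sqrt(max(var_e2, 0.0)) * noise[:, 1]
    em = np.sqrt(max(1.0 - config.h2_mediator, 0.0)) * noise[:, 2]

    y1 = g1 + e1
    y2 = g2 + e2
    ym = gm + em

    pheno = pd.DataFrame(
        {
            "fid": geno.samples["fid"],
            "iid": geno.samples["iid"],
            "achievement": y1,
            "ses": y2,
            "iq": ym,
        }
    )
    truth = TraitTruth(
        causal_shared=shared,
        causal_specific1=spec1,
        causal_specific2=spec2,
        beta1=w1,
        beta2_child=b2_child,
        maf=p.copy(),
        realized_h2_trait1=float(g1.var()),
        realized_h2_trait2=float(
            (xc @ b2_child).var() if config.h2_trait2 > 0 else 0.0
        ),
        residual_correlation=float(
            rho_e if (var_e1 > 0 and var_e2 > 0) else np.nan
        ),
    )
    return pheno, truth


# ---------------------------------------------------------------------------
# discovery GWAS
# ---------------------------------------------------------------------------

def simulate_discovery_gwas(
    truth: TraitTruth,
    snp_meta: pd.DataFrame,
    discovery_n: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SummaryStats:
    """Fabricate summary statistics for an independent discovery GWAS.

    Per-SNP effect estimates are drawn ``Normal(true marginal beta,
    se^2)`` with ``se = 1/sqrt(discovery_n * 2 p (1-p))`` -- the
    sampling error of a per-allele regression coefficient on a
    standardized trait -- and two-sided Wald p-values.  Monomorphic
    SNPs are excluded with a warning.
    """
    if discovery_n < 1:
        raise ConfigError("discovery_n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.asarray(truth.maf, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNPs from the discovery GWAS",
            stacklevel=2,
        )
    se = np.full(p.shape, np.nan)
    se[poly] = 1.0 / np.sqrt(discovery_n * 2.0 * p[poly] * (1.0 - p[poly]))
    beta_hat = truth.beta1 + np.where(poly, se, 0.0) * rng.standard_normal(p.size)
    z = np.abs(beta_hat / se)
    pval = np.clip(2.0 * ndtr(-z), np.finfo(float).tiny, 1.0)
    tab = snp_meta.loc[poly, ["snp", "chrom", "pos", "a1", "a2"]].copy()
    tab["beta"] = beta_hat[poly]
    tab["se"] = se[poly]
    tab["p"] = pval[poly]
    return SummaryStats(tab.reset_index(drop=True), discovery_n=discovery_n)


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> Cohort:
    """Run the full generator under one master seed."""
    rngs = config.stage_rngs()
    if config.parental_mode:
        parents, children = simulate_parent_child(config, rng=rngs["parents"])
    else:
        parents, children = None, simulate_genotypes(config, rng=rngs["genotypes"])
    pheno, truth = simulate_traits(children, parents, config, rng=rngs["traits"])
    return Cohort(children, parents, pheno, truth, config)
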
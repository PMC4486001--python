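"""Genomic relatedness: the allele-frequency-standardized GRM and
removal of cryptic relatedness above a similarity cutoff.

Entry ``(j, k)`` of the GRM is the mean over SNPs of
``(x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))`` with ``p_i`` the
sample allele frequency; missing dosages are mean-imputed before
standardization.  The diagonal uses the same cross-product formula as
the off-diagonals (not the inbreeding-adjusted variant of the original
GCTA software) -- identical expectation under Hardy-Weinberg
equilibrium, and simpler.

Pruning removes one member of every pair whose similarity reaches the
cutoff (default 0.025, roughly fifth-degree relatives), greedily by the
number of over-threshold partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ConfigError, GenotypeMatrix, RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = ["PruneParams", "compute_grm", "prune_related"]


@dataclass
class PruneParams:
    cutoff: float = 0.025

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError("relatedness cutoff must be > 0")


def compute_grm(geno: GenotypeMatrix, maf_min: float = 0.01) -> RelatednessMatrix:
    """Compute the GRM over SNPs with minor-allele frequency > ``maf_min``."""
    if geno.n_individuals < 2:
        raise ConfigError("GRM needs at least two individuals")
    z, keep = geno.standardized(maf_min=maf_min)
    m = keep.size
    if m == 0:
        raise ConfigError(
            f"no polymorphic SNP passes the MAF filter ({maf_min})"
        )
    a = (z @ z.T) / m
    a = (a + a.T) / 2.0  # exact symmetry against float round-off
    return RelatednessMatrix(a, geno.samples[["fid", "iid"]].copy(),
                             np.full(a.shape, m))


def prune_related(
    grm: RelatednessMatrix, params: PruneParams | None = None
) -> tuple[list[int], list[int]]:
    """Greedily remove individuals until no pair reaches the cutoff.

    Repeatedly removes the individual participating in the most
    over-threshold pairs; ties broken by larger mean off-diagonal
    similarity, then by lexicographic (fid, iid).  Returns positional
    ``(kept, removed)`` index lists into the GRM id table.
    """
    params = params or PruneParams()
    grm.validate()
    n = grm.n
    over = grm.values >= params.cutoff
    np.fill_diagonal(over, False)
    mean_off = (grm.values.sum(axis=1) - np.diag(grm.values)) / max(n - 1, 1)
    ids = list(zip(grm.ids["fid"].astype(str), grm.ids["iid"].astype(str)))
    active = np.ones(n, dtype=bool)
    removed: list[int] = []
    while True:
        degree = (over & active[None, :] & active[:, None]).sum(axis=1)
        degree[~active] = 0
        if degree.max() == 0:
            break
        candidates = np.flatnonzero(degree == degree.max())
        idx = int(min(candidates, key=lambda i: (-mean_off[i], ids[i])))
        active[idx] = False
        removed.append(idx)
    kept = [i for i in range(n) if active[i]]
    if removed:
        logger.info("relatedness pruning removed %d of %d individuals", len(removed), n)
    return kept, removed
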
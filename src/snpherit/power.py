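"""Analytic power for GREML designs on unrelated individuals.

The sampling variance of a SNP-heritability estimate from N unrelated
individuals is approximately ``var(h2_hat) = 2 / (N^2 * varA)`` where
``varA`` is the variance of the off-diagonal GRM entries (about 2e-5
for genome-wide genotyped samples of European ancestry; exactly ``1/M``
for M independent SNPs).  For the bivariate design with fully
overlapping samples the genetic-correlation estimate has approximate
sampling variance

    var(rg_hat) = ((1 - rg*rp)^2 + (rg - rp)^2) / (N^2 * varA * h2_1 * h2_2)

Power is the two-sided normal approximation
``Phi(effect/se - z_{1-alpha/2}) + Phi(-effect/se - z_{1-alpha/2})``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .containers import ConfigError

__all__ = ["PowerParams", "power_h2", "power_rg", "se_h2", "se_rg"]

#: default off-diagonal GRM variance for unrelated genotyped samples
DEFAULT_VAR_GRM = 2e-5


@dataclass
class PowerParams:
    n: int
    alpha: float = 0.05
    h2: float | None = None
    v_g1: float | None = None
    v_g2: float | None = None
    r_g: float | None = None
    r_p: float | None = None
    var_grm_offdiag: float = DEFAULT_VAR_GRM

    def __post_init__(self) -> None:
        if self.var_grm_offdiag <= 0:
            raise ConfigError("var_grm_offdiag must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.n < 2:
            raise ConfigError("n must be >= 2")


def _two_sided_power(effect: float, se: float, alpha: float) -> float:
    z = ndtri(1.0 - alpha / 2.0)
    ncp = effect / se
    return float(ndtr(ncp - z) + ndtr(-ncp - z))


def se_h2(n: int, var_grm_offdiag: float = DEFAULT_VAR_GRM) -> float:
    """Approximate s.e. of the univariate SNP-heritability estimate."""
    return float(np.sqrt(2.0 / (n**2 * var_grm_offdiag)))


def power_h2(n: int, h2: float, alpha: float = 0.05,
             var_grm_offdiag: float = DEFAULT_VAR_GRM) -> float:
    """Power to detect a SNP-heritability of ``h2`` (two-sided test)."""
    PowerParams(n=n, alpha=alpha, h2=h2, var_grm_offdiag=var_grm_offdiag)
    return _two_sided_power(abs(h2), se_h2(n, var_grm_offdiag), alpha)


def se_rg(n: int, v_g1: float, v_g2: float, r_g: float, r_p: float,
          var_grm_offdiag: float = DEFAULT_VAR_GRM) -> float:
    """Approximate s.e. of the genetic correlation, full sample overlap."""
    if min(v_g1, v_g2) <= 0:
        raise ConfigError("variance fractions must be positive")
    num = (1.0 - r_g * r_p) ** 2 + (r_g - r_p) ** 2
    return float(np.sqrt(num / (n**2 * var_grm_offdiag * v_g1 * v_g2)))


def power_rg(n: int, r_g: float, v_g1: float, v_g2: float, r_p: float,
             alpha: float = 0.05,
             var_grm_offdiag: float = DEFAULT_VAR_GRM) -> float:
    """Power to detect a genetic correlation ``r_g`` (two-sided test)."""
    if abs(r_g) > 1.0:
        raise ConfigError("|r_g| must be <= 1")
    PowerParams(n=n, alpha=alpha, r_g=r_g, var_grm_offdiag=var_grm_offdiag)
    se = se_rg(n, v_g1, v_g2, r_g, r_p, var_grm_offdiag)
    return _two_sided_power(abs(r_g), se, alpha)
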
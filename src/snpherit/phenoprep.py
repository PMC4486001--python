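"""Phenotype preparation: covariate adjustment, outlier trimming,
rank-based inverse-normal (quantile) normalization, and mean-imputed
composite construction.

The processing order mirrors the conventional pipeline for cohort
phenotypes: regress on covariates (sex, age, ancestry axes), exclude
residuals beyond ``sd_limit`` standard deviations, quantile-normalize,
standardize.  Composites average components per individual when at
least ``min_nonmissing`` are observed, optionally after cohort-level
mean-imputation of each component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ConfigError

__all__ = [
    "CompositeSpec",
    "adjust_and_trim",
    "quantile_normalize",
    "standardize",
    "build_composite",
    "QuantileNormalizer",
]


@dataclass
class CompositeSpec:
    """Composite definition: component columns and the minimum number of
    non-missing components an individual needs (e.g. 2 of 3)."""

    components: list[str]
    min_nonmissing: int = 1
    impute_components: bool = True

    def __post_init__(self) -> None:
        if self.min_nonmissing > len(self.components):
            raise ConfigError("min_nonmissing exceeds the number of components")


def standardize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Center/scale the non-missing values to mean 0, s.d. 1 (ddof 0)."""
    v = np.asarray(values, dtype=float).copy()
    obs = np.isfinite(v)
    mu = v[obs].mean()
    sd = v[obs].std()
    if sd == 0:
        raise ConfigError("cannot standardize a constant column")
    v[obs] = (v[obs] - mu) / sd
    return v


def adjust_and_trim(
    values: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    sd_limit: float = 3.0,
) -> np.ndarray:
    """OLS-residualize on covariates, drop outliers, standardize.

    Residuals with |z| > ``sd_limit`` are set missing (NaN) and the
    remainder re-standardized.  Rows missing the value or any covariate
    stay missing.  Rank-deficient covariates raise an error naming the
    collinear columns.
    """
    y = np.asarray(values, dtype=float).copy()
    n = y.size
    if covariates is None:
        x = np.ones((n, 1))
        names = ["intercept"]
    else:
        if isinstance(covariates, pd.DataFrame):
            names = ["intercept"] + list(covariates.columns)
            c = covariates.to_numpy(dtype=float)
        else:
            c = np.asarray(covariates, dtype=float)
            if c.ndim == 1:
                c = c[:, None]
            names = ["intercept"] + [f"x{j}" for j in range(c.shape[1])]
        x = np.column_stack([np.ones(n), c])
    obs = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    if obs.sum() < 10:
        raise ConfigError("need at least 10 complete observations")
    xo = x[obs]
    rank = np.linalg.matrix_rank(xo)
    if rank < xo.shape[1]:
        # identify offending columns via pivoted QR
        _, r, piv = scipy.linalg.qr(xo, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ConfigError(f"collinear covariate columns: {bad}")
    beta, *_ = np.linalg.lstsq(xo, y[obs], rcond=None)
    resid = np.full(n, np.nan)
    resid[obs] = y[obs] - xo @ beta
    resid[obs] = (resid[obs] - resid[obs].mean()) / resid[obs].std()
    resid[np.abs(resid) > sd_limit] = np.nan
    out = np.isfinite(resid)
    resid[out] = (resid[out] - resid[out].mean()) / resid[out].std()
    return resid


def quantile_normalize(values: np.ndarray | pd.Series,
                       offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom plotting position.

    Maps rank ``r`` of ``n`` non-missing values to
    ``ndtri((r - offset) / (n - 2*offset + 1))``; ties get average rank;
    missing values stay missing.
    """
    v = np.asarray(values, dtype=float)
    obs = np.isfinite(v)
    n = int(obs.sum())
    if n < 3:
        raise ConfigError("quantile normalization needs >= 3 non-missing values")
    x = v[obs]
    if np.all(x == x[0]):
        raise ConfigError("all values identical: ranks undefined")
    r = rankdata(x, method="average")
    scores = ndtri((r - offset) / (n - 2.0 * offset + 1.0))
    out = np.full(v.shape, np.nan)
    out[obs] = scores
    return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`quantile_normalize`.

    Stateless (the transform is rank-based per column); provided so the
    step composes with sklearn pipelines.
    """

    def __init__(self, offset: float = 0.375, standardize_output: bool = False):
        self.offset = offset
        self.standardize_output = standardize_output

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[:, None]
        out = np.column_stack(
            [quantile_normalize(X[:, j], offset=self.offset)
             for j in range(X.shape[1])]
        )
        if self.standardize_output:
            out = np.column_stack([standardize(out[:, j])
                                   for j in range(out.shape[1])])
        return out[:, 0] if one_d else out


def build_composite(
    table: pd.DataFrame,
    spec: CompositeSpec,
    normalize: bool = True,
) -> np.ndarray:
    """Mean composite of component columns.

    Each component is optionally cohort-mean-imputed first; an
    individual's composite is the mean of their non-missing *original*
    components when that count reaches ``min_nonmissing`` (after
    imputation all components count as observed), else missing.  The
    result is quantile-normalized then standardized when ``normalize``.
    """
    missing_cols = [c for c in spec.components if c not in table.columns]
    if missing_cols:
        raise ConfigError(f"composite components not in table: {missing_cols}")
    comp = table[spec.components].to_numpy(dtype=float)
    n_obs = np.isfinite(comp).sum(axis=1)
    if spec.impute_components:
        obs_any = np.isfinite(comp).any(axis=0)
        col_mean = np.zeros(comp.shape[1])
        col_mean[obs_any] = np.nanmean(comp[:, obs_any], axis=0)
        filled = np.where(np.isfinite(comp), comp, col_mean)
        filled[:, ~obs_any] = np.nan  # entirely missing components stay missing
    else:
        filled = comp
    with np.errstate(invalid="ignore"):
        value = np.nanmean(filled, axis=1)
    value[n_obs < spec.min_nonmissing] = np.nan
    if normalize:
        value = standardize(quantile_normalize(value))
    return value
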
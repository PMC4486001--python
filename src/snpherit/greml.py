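"""GREML variance components: univariate and bivariate restricted
maximum likelihood on a genomic relatedness matrix.

The model for a single standardized trait is
``y ~ N(X b, vg * A + ve * I)`` with ``A`` the GRM; the bivariate
extension stacks two traits measured on the same individuals with
covariance ``[[vg1*A + ve1*I, cg*A + ce*I], [cg*A + ce*I,
vg2*A + ve2*I]]``.  One eigendecomposition ``A = U D U'`` rotates the
problem into independent 1x1 (univariate) or 2x2 (bivariate) blocks,
after which every restricted-likelihood quantity - log-likelihood,
scores, average-information matrix, projections - costs O(N).

Estimation is average-information REML: Newton steps with the AI
matrix, falling back to step-halving whenever a step would leave the
feasible region (a non-positive-definite total covariance) or decrease
the restricted likelihood.  Components are unconstrained by default, so
the genetic correlation may exceed 1; a constrained mode clamps to the
feasible parameter space and flags the clamp.  Standard errors come
from the inverse average-information matrix, with first-order delta
propagation to derived quantities (h2, r_g, the genetic contribution to
the phenotypic correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .containers import ConfigError, RelatednessMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GremlResult",
    "GremlBivariateResult",
    "MediationResult",
    "GREML",
    "BivariateGREML",
    "reml_univariate",
    "reml_bivariate",
    "genetic_contribution",
    "mediation_decomposition",
]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class GremlResult:
    v_g: float
    v_e: float
    se_vg: float
    se_ve: float
    h2: float
    se_h2: float
    loglik: float
    n_used: int
    n_iter: int
    converged: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class GremlBivariateResult:
    v_g1: float
    v_g2: float
    c_g: float
    v_e1: float
    v_e2: float
    c_e: float
    r_g: float
    se_vg1: float
    se_vg2: float
    se_cg: float
    se_rg: float
    genetic_contribution: float
    se_genetic_contribution: float
    phenotypic_correlation: float
    proportion_tagged: float
    loglik: float
    n_used: int
    n_iter: int
    converged: bool
    clamped: bool = False
    degenerate_identical_traits: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class MediationResult:
    before: GremlBivariateResult
    after: GremlBivariateResult
    delta_phenotypic_correlation: float
    delta_cg: float
    proportion_mediated: float


# ---------------------------------------------------------------------------
# rotated REML machinery
# ---------------------------------------------------------------------------

class _Rotated:
    """Eigen-rotated data: diagonal kernel d, traits Y (N x t), design X."""

    def __init__(self, grm_values: np.ndarray, Y: np.ndarray, X: np.ndarray):
        n = grm_values.shape[0]
        if Y.shape[0] != n or X.shape[0] != n:
            raise ConfigError("trait/covariate rows do not match the GRM")
        a = (grm_values + grm_values.T) / 2.0
        d, u = np.linalg.eigh(a)
        if np.ptp(d) < 1e-8:
            raise ConfigError(
                "GRM is numerically proportional to the identity; genetic and "
                "residual variance are not separable"
            )
        self.d = d
        self.Y = u.T @ Y
        self.X = u.T @ X
        self.n, self.t = Y.shape
        self.p = X.shape[1]

    # -- block helpers ----------------------------------------------------
    def _blocks(self, G: np.ndarray, E: np.ndarray) -> np.ndarray:
        return self.d[:, None, None] * G[None] + E[None]

    def feasible(self, G: np.ndarray, E: np.ndarray, tiny: float = 1e-12) -> bool:
        vb = self._blocks(G, E)
        if self.t == 1:
            return bool(np.all(vb[:, 0, 0] > tiny))
        det = vb[:, 0, 0] * vb[:, 1, 1] - vb[:, 0, 1] ** 2
        return bool(np.all(det > tiny) & np.all(vb[:, 0, 0] > tiny))

    def core(self, G: np.ndarray, E: np.ndarray):
        """Log-likelihood plus the pieces needed for scores and AI."""
        vb = self._blocks(G, E)
        vinv = np.linalg.inv(vb)
        sign, logdet_blocks = np.linalg.slogdet(vb)
        if np.any(sign <= 0):
            return None
        vy = np.einsum("nab,nb->na", vinv, self.Y)
        xtvx = np.einsum("nab,np,nq->apbq", vinv, self.X, self.X)
        tp = self.t * self.p
        xtvx = xtvx.reshape(tp, tp)
        sgn, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sgn <= 0:
            return None
        c = np.linalg.inv(xtvx)
        xtvy = np.einsum("na,np->ap", vy, self.X).reshape(tp)
        tvec = (c @ xtvy).reshape(self.t, self.p)
        xb = np.einsum("np,ap->na", self.X, tvec)
        py = vy - np.einsum("nab,nb->na", vinv, xb)
        ypy = float(np.einsum("na,na->", self.Y, py))
        loglik = -0.5 * (float(logdet_blocks.sum()) + logdet_xtvx + ypy)
        return {"vinv": vinv, "py": py, "c": c, "loglik": loglik}

    def loglik(self, G: np.ndarray, E: np.ndarray) -> float:
        out = self.core(G, E)
        return -np.inf if out is None else out["loglik"]

    def project(self, U: np.ndarray, vinv: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Apply the REML projection P to columns of U (N x t each)."""
        vu = np.einsum("nab,nb->na", vinv, U)
        xtvu = np.einsum("na,np->ap", vu, self.X).reshape(self.t * self.p)
        w = (c @ xtvu).reshape(self.t, self.p)
        xw = np.einsum("np,ap->na", self.X, w)
        return vu - np.einsum("nab,nb->na", vinv, xw)

    def score_and_ai(self, kernels, core):
        vinv, py, c = core["vinv"], core["py"], core["c"]
        k = len(kernels)
        kb = [self.d[:, None, None] * dG[None] + dE[None] for dG, dE in kernels]
        # tr(P K) = tr(Vinv K) - tr(C  X' Vinv K Vinv X)
        tp = self.t * self.p
        tr_pk = np.empty(k)
        for i, kbi in enumerate(kb):
            t1 = float(np.einsum("nab,nba->", vinv, kbi))
            s = np.einsum("nab,nbc,ncd->nad", vinv, kbi, vinv)
            m = np.einsum("nab,np,nq->apbq", s, self.X, self.X).reshape(tp, tp)
            tr_pk[i] = t1 - float(np.trace(c @ m))
        u = [np.einsum("nab,nb->na", kbi, py) for kbi in kb]
        pu = [self.project(ui, vinv, c) for ui in u]
        score = np.empty(k)
        ai = np.empty((k, k))
        for i in range(k):
            ykpy = float(np.einsum("na,na->", u[i], py))
            score[i] = -0.5 * (tr_pk[i] - ykpy)
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(
                    np.einsum("na,na->", u[i], pu[j])
                )
        return score, ai


def _ai_reml(rot: _Rotated, theta0: np.ndarray, unpack, kernels,
             clamp=None, max_iter: int = 100, tol_loglik: float = 1e-8,
             tol_param: float = 1e-6):
    """Generic AI-REML loop.  ``unpack`` maps theta -> (G, E)."""
    theta = theta0.copy()
    if not rot.feasible(*unpack(theta)):
        raise ConfigError("infeasible starting values for REML")
    core = rot.core(*unpack(theta))
    if core is None:
        raise ConfigError("starting covariance is not positive definite")
    loglik = core["loglik"]
    converged = False
    clamped_any = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai = rot.score_and_ai(kernels, core)
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(ai + 1e-8 * np.eye(len(score)), score)
        new_theta, new_core, new_loglik = None, None, None
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            if clamp is not None:
                cand, was_clamped = clamp(cand)
                clamped_any |= was_clamped
            if rot.feasible(*unpack(cand)):
                c2 = rot.core(*unpack(cand))
                if c2 is not None and c2["loglik"] >= loglik - 1e-10:
                    new_theta, new_core, new_loglik = cand, c2, c2["loglik"]
                    break
            scale *= 0.5
        if new_theta is None:
            # no acceptable step: treat current point as the optimum
            converged = True
            break
        d_log = new_loglik - loglik
        d_par = np.max(np.abs(new_theta - theta))
        theta, core, loglik = new_theta, new_core, new_loglik
        if abs(d_log) < tol_loglik and d_par < tol_param:
            converged = True
            break
    _, ai = rot.score_and_ai(kernels, core)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
    return theta, loglik, cov, converged, it, clamped_any


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return np.column_stack([np.ones(n), c])


def _grm_values(grm) -> np.ndarray:
    if isinstance(grm, RelatednessMatrix):
        return grm.values
    return np.asarray(grm, dtype=float)


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------

class GREML(BaseEstimator):
    """Univariate GREML estimator of the SNP-tagged variance fraction.

    Parameters
    ----------
    constrained : clamp the genetic variance to be non-negative.
    max_iter, tol_loglik, tol_param : AI-REML stopping rule.

    Fitted attributes (trailing underscore): ``vg_``, ``ve_``, ``h2_``,
    ``se_vg_``, ``se_h2_``, ``loglik_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, constrained: bool = False, max_iter: int = 100,
                 tol_loglik: float = 1e-8, tol_param: float = 1e-6):
        self.constrained = constrained
        self.max_iter = max_iter
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param

    def fit(self, grm, y, covariates=None):
        a = _grm_values(grm)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        n = y.shape[0]
        if n < 50:
            logger.info("univariate GREML fit on only %d individuals", n)
        x = _design(n, covariates)
        rot = _Rotated(a, y, x)
        self._rot_ = rot
        var_y = float(y.var())
        theta0 = np.array([0.5 * var_y, 0.5 * var_y])
        kernels = [(np.ones((1, 1)), np.zeros((1, 1))),
                   (np.zeros((1, 1)), np.ones((1, 1)))]

        def unpack(th):
            return np.array([[th[0]]]), np.array([[th[1]]])

        clamp = None
        if self.constrained:
            def clamp(th):
                c = np.array([max(th[0], 0.0), max(th[1], 1e-8)])
                return c, bool(np.any(c != th))

        theta, loglik, cov, converged, n_iter, _ = _ai_reml(
            rot, theta0, unpack, kernels, clamp=clamp,
            max_iter=self.max_iter, tol_loglik=self.tol_loglik,
            tol_param=self.tol_param,
        )
        vg, ve = map(float, theta)
        s = vg + ve
        grad = np.array([ve, -vg]) / s**2
        self.vg_, self.ve_ = vg, ve
        self.se_vg_ = float(np.sqrt(max(cov[0, 0], 0.0)))
        self.se_ve_ = float(np.sqrt(max(cov[1, 1], 0.0)))
        self.h2_ = vg / s
        self.se_h2_ = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        self.loglik_ = float(loglik)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_used_ = n
        return self

    def loglik_at(self, vg: float, ve: float) -> float:
        """Restricted log-likelihood at arbitrary components (post-fit)."""
        return self._rot_.loglik(np.array([[vg]]), np.array([[ve]]))

    def null_loglik(self) -> float:
        """Restricted log-likelihood maximized under vg = 0."""
        rot = self._rot_
        # V = ve * I: the REML profile over ve has a closed form
        y, x = rot.Y[:, 0], rot.X
        q, _ = np.linalg.qr(x)
        resid = y - q @ (q.T @ y)
        df = rot.n - rot.p
        ve = float(resid @ resid) / df
        return rot.loglik(np.array([[0.0]]), np.array([[ve]]))

    def lrt_pvalue(self) -> float:
        """Likelihood-ratio p-value against vg = 0 (chi-square, 1 df)."""
        stat = max(2.0 * (self.loglik_ - self.null_loglik()), 0.0)
        return float(chi2.sf(stat, 1))

    def result(self) -> GremlResult:
        return GremlResult(
            v_g=self.vg_, v_e=self.ve_, se_vg=self.se_vg_, se_ve=self.se_ve_,
            h2=self.h2_, se_h2=self.se_h2_, loglik=self.loglik_,
            n_used=self.n_used_, n_iter=self.n_iter_, converged=self.converged_,
        )


def reml_univariate(y, grm, covariates=None, constrained: bool = False) -> GremlResult:
    return GREML(constrained=constrained).fit(grm, y, covariates).result()


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

_BIV_KERNELS = [
    (np.array([[1.0, 0.0], [0.0, 0.0]]), np.zeros((2, 2))),  # vg1
    (np.array([[0.0, 0.0], [0.0, 1.0]]), np.zeros((2, 2))),  # vg2
    (np.array([[0.0, 1.0], [1.0, 0.0]]), np.zeros((2, 2))),  # cg
    (np.zeros((2, 2)), np.array([[1.0, 0.0], [0.0, 0.0]])),  # ve1
    (np.zeros((2, 2)), np.array([[0.0, 0.0], [0.0, 1.0]])),  # ve2
    (np.zeros((2, 2)), np.array([[0.0, 1.0], [1.0, 0.0]])),  # ce
]


def _biv_unpack(th):
    vg1, vg2, cg, ve1, ve2, ce = th
    return (np.array([[vg1, cg], [cg, vg2]]),
            np.array([[ve1, ce], [ce, ve2]]))


class BivariateGREML(BaseEstimator):
    """Bivariate GREML: per-trait variance fractions, genetic covariance
    and correlation, and the genetic contribution to the phenotypic
    correlation ``C(G) = r_g * sqrt(v_g1 * v_g2)``.

    Requires both traits measured on the same individuals (full
    overlap).  Unconstrained by default, so ``|r_g|`` may exceed 1.
    """

    def __init__(self, constrained: bool = False, max_iter: int = 100,
                 tol_loglik: float = 1e-8, tol_param: float = 1e-6):
        self.constrained = constrained
        self.max_iter = max_iter
        self.tol_loglik = tol_loglik
        self.tol_param = tol_param

    def fit(self, grm, Y, covariates=None):
        a = _grm_values(grm)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ConfigError("Y must be (n, 2): two traits, full overlap")
        n = Y.shape[0]
        r_p = float(np.corrcoef(Y[:, 0], Y[:, 1])[0, 1])
        if abs(r_p) > 1.0 - 1e-10:
            return self._fit_degenerate(a, Y, covariates, r_p)
        x = _design(n, covariates)
        rot = _Rotated(a, Y, x)
        self._rot_ = rot
        v1, v2 = float(Y[:, 0].var()), float(Y[:, 1].var())
        cov12 = float(np.cov(Y[:, 0], Y[:, 1], ddof=0)[0, 1])
        theta0 = np.array([v1 / 2, v2 / 2, cov12 / 2, v1 / 2, v2 / 2, cov12 / 2])

        clamp = None
        if self.constrained:
            def clamp(th):
                c = th.copy()
                c[0], c[1] = max(c[0], 0.0), max(c[1], 0.0)
                c[3], c[4] = max(c[3], 1e-8), max(c[4], 1e-8)
                gmax = np.sqrt(c[0] * c[1])
                emax = np.sqrt(c[3] * c[4])
                c[2] = np.clip(c[2], -gmax, gmax)
                c[5] = np.clip(c[5], -emax, emax)
                return c, bool(np.any(c != th))

        theta, loglik, cov, converged, n_iter, clamped = _ai_reml(
            rot, theta0, _biv_unpack, _BIV_KERNELS, clamp=clamp,
            max_iter=self.max_iter, tol_loglik=self.tol_loglik,
            tol_param=self.tol_param,
        )
        self._finalize(theta, loglik, cov, converged, n_iter, clamped, n, r_p)
        return self

    def _finalize(self, theta, loglik, cov, converged, n_iter, clamped, n, r_p):
        vg1, vg2, cg, ve1, ve2, ce = map(float, theta)
        if vg1 * vg2 > 0:
            denom = np.sqrt(vg1 * vg2)
            rg = cg / denom
            # delta method: rg = cg / sqrt(vg1 vg2), order (vg1, vg2, cg)
            grad = np.zeros(6)
            grad[0] = -0.5 * rg / vg1
            grad[1] = -0.5 * rg / vg2
            grad[2] = 1.0 / denom
            se_rg = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
            contribution = rg * denom  # identically cg; kept as the identity
        else:
            # a variance estimate went non-positive (possible in
            # unconstrained mode): the correlation is undefined
            rg, se_rg, contribution = np.nan, np.nan, np.nan
        self.vg1_, self.vg2_, self.cg_ = vg1, vg2, cg
        self.ve1_, self.ve2_, self.ce_ = ve1, ve2, ce
        self.rg_ = float(rg)
        self.se_vg1_ = float(np.sqrt(max(cov[0, 0], 0.0)))
        self.se_vg2_ = float(np.sqrt(max(cov[1, 1], 0.0)))
        self.se_cg_ = float(np.sqrt(max(cov[2, 2], 0.0)))
        self.se_rg_ = se_rg
        self.genetic_contribution_ = float(contribution)
        self.se_genetic_contribution_ = self.se_cg_
        self.phenotypic_correlation_ = float(r_p)
        self.proportion_tagged_ = float(contribution / r_p) if r_p != 0 else np.nan
        self.loglik_ = float(loglik)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_used_ = n
        self.clamped_ = clamped
        self.degenerate_identical_traits_ = False

    def _fit_degenerate(self, a, Y, covariates, r_p):
        # byte-identical (or perfectly correlated) traits: the stacked
        # covariance is singular at the optimum; fall back to the
        # univariate fit and report r_g = +/-1 with a degeneracy flag
        uni = GREML(constrained=self.constrained).fit(a, Y[:, 0], covariates)
        s = np.sign(r_p) if r_p != 0 else 1.0
        theta = np.array([uni.vg_, uni.vg_, s * uni.vg_,
                          uni.ve_, uni.ve_, s * uni.ve_])
        cov = np.zeros((6, 6))
        cov[0, 0] = cov[1, 1] = cov[2, 2] = uni.se_vg_**2
        self._finalize(theta, uni.loglik_, cov, uni.converged_, uni.n_iter_,
                       False, Y.shape[0], r_p)
        self.rg_ = float(s)
        self.se_rg_ = 0.0
        self.degenerate_identical_traits_ = True
        return self

    def loglik_at(self, theta) -> float:
        return self._rot_.loglik(*_biv_unpack(np.asarray(theta, dtype=float)))

    def result(self) -> GremlBivariateResult:
        return GremlBivariateResult(
            v_g1=self.vg1_, v_g2=self.vg2_, c_g=self.cg_,
            v_e1=self.ve1_, v_e2=self.ve2_, c_e=self.ce_,
            r_g=self.rg_, se_vg1=self.se_vg1_, se_vg2=self.se_vg2_,
            se_cg=self.se_cg_, se_rg=self.se_rg_,
            genetic_contribution=self.genetic_contribution_,
            se_genetic_contribution=self.se_genetic_contribution_,
            phenotypic_correlation=self.phenotypic_correlation_,
            proportion_tagged=self.proportion_tagged_,
            loglik=self.loglik_, n_used=self.n_used_, n_iter=self.n_iter_,
            converged=self.converged_, clamped=self.clamped_,
            degenerate_identical_traits=self.degenerate_identical_traits_,
        )


def reml_bivariate(y1, y2, grm, covariates=None,
                   constrained: bool = False) -> GremlBivariateResult:
    Y = np.column_stack([np.asarray(y1, float), np.asarray(y2, float)])
    return BivariateGREML(constrained=constrained).fit(grm, Y, covariates).result()


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def genetic_contribution(r_g: float, v_g1: float, v_g2: float) -> float:
    """Genetic contribution to a phenotypic correlation:
    ``C(G) = r_g * sqrt(v_g1 * v_g2)``."""
    if v_g1 < 0 or v_g2 < 0:
        raise ConfigError("variance fractions must be non-negative")
    return float(r_g * np.sqrt(v_g1 * v_g2))


def mediation_decomposition(
    y1, y2, mediator, grm, covariates=None, constrained: bool = False
) -> MediationResult:
    """Mediation by residualization.

    Stage 1 fits the bivariate model to (y1, y2); stage 2 residualizes
    y1 on the mediator by OLS, standardizes the residuals, and refits.
    The proportion of the genetic covariance attributable to the
    mediator is ``(c_g_before - c_g_after) / c_g_before``.
    """
    y1 = np.asarray(y1, dtype=float)
    med = np.asarray(mediator, dtype=float)
    if med.std() == 0:
        raise ConfigError("mediator is constant")
    before = reml_bivariate(y1, y2, grm, covariates, constrained=constrained)
    x = np.column_stack([np.ones_like(med), med])
    beta, *_ = np.linalg.lstsq(x, y1, rcond=None)
    resid = y1 - x @ beta
    if resid.std() < 1e-8 * max(np.std(y1), 1e-300):
        raise ConfigError(
            "mediator leaves no residual variation in the first trait"
        )
    resid = (resid - resid.mean()) / resid.std()
    after = reml_bivariate(resid, y2, grm, covariates, constrained=constrained)
    delta_rp = before.phenotypic_correlation - after.phenotypic_correlation
    delta_cg = before.c_g - after.c_g
    prop = delta_cg / before.c_g if before.c_g != 0 else np.nan
    return MediationResult(before, after, float(delta_rp), float(delta_cg),
                           float(prop))
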
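"""Random-intercept linear mixed models on growth-curve residuals.

Sex (or confound) effects are tested in two stages: a population growth
curve is fitted to a region's trajectory first, and the residuals
``r_i = value_i - Vhat(age_i)`` are then analyzed with the linear mixed
model

    r_i = b0 + b1*age_i + b2*cov_i + b3*age_i*cov_i + u[subject_i] + e_i,

with a single Gaussian random intercept per fetus (variance ``var_subject``)
and i.i.d. residual error (``var_resid``).  Variance components are
estimated by REML with the fixed effects profiled out; the variance ratio
is optimized on a single scalar axis, which makes each fit cheap enough for
Monte-Carlo calibration studies.  Denominator degrees of freedom for the
coefficient t-tests use the Satterthwaite approximation: the gradient of
each coefficient's sampling variance with respect to the two variance
components, combined with the asymptotic covariance of the REML estimates
(inverse observed information).  P-values are two-sided at alpha = 0.05 and
Bonferroni-corrected across the regions tested in the same family.

Sex is coded male = 1, female = 0, so a positive age-by-sex interaction
means faster male growth.  Age enters uncentered, in days post-conception.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .exceptions import DataError, DesignError
from .growth_models import ModelSelection

logger = logging.getLogger(__name__)

__all__ = [
    "LMMFit",
    "RegionSexResult",
    "RandomInterceptLMM",
    "fit_random_intercept_lmm",
    "residual_effect_analysis",
    "confound_screen",
    "bonferroni_adjust",
    "SEX_CODES",
]

SEX_CODES = {"F": 0.0, "M": 1.0}

COEF_NAMES = ("intercept", "age", "covariate", "age_x_covariate")


@dataclass
class LMMFit:
    """Fitted random-intercept LMM for the 4-coefficient interaction design."""

    betas: np.ndarray
    ses: np.ndarray
    var_subject: float
    var_resid: float
    satterthwaite_df: np.ndarray
    p_values: np.ndarray
    ci95: np.ndarray
    boundary: bool
    coef_names: tuple[str, ...] = COEF_NAMES

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.betas,
                "se": self.ses,
                "df": self.satterthwaite_df,
                "p": self.p_values,
                "ci_lo": self.ci95[:, 0],
                "ci_hi": self.ci95[:, 1],
            },
            index=list(self.coef_names),
        )


@dataclass
class RegionSexResult:
    """Per-region residual LMM result with Bonferroni adjustment."""

    region: str
    covariate: str
    lmm: LMMFit
    bonferroni_adjusted_p: np.ndarray
    significant_after_correction: np.ndarray
    m_comparisons: int

    def summary_frame(self) -> pd.DataFrame:
        frame = self.lmm.summary_frame()
        frame["p_bonferroni"] = self.bonferroni_adjusted_p
        frame["significant"] = self.significant_after_correction
        frame.insert(0, "region", self.region)
        frame.insert(1, "covariate", self.covariate)
        return frame


class RandomInterceptLMM(BaseEstimator):
    """REML random-intercept mixed model with Satterthwaite t-tests.

    The fixed design is ``[1, age, covariate, age*covariate]``; the random
    part is one intercept per group (fetus).

    Parameters
    ----------
    max_ratio : float
        Upper bound for the variance ratio var_subject/var_resid searched
        during REML optimization.
    alpha : float
        Two-sided test level for the confidence intervals.

    Attributes
    ----------
    betas_, ses_, satterthwaite_df_, p_values_ : ndarray of shape (4,)
    var_subject_, var_resid_ : float
    ci95_ : ndarray of shape (4, 2)
    boundary_ : bool
        True when the subject variance was estimated at the zero boundary,
        in which case the fit coincides with ordinary least squares.
    result_ : LMMFit
    """

    def __init__(self, max_ratio: float = 1e6, alpha: float = 0.05):
        self.max_ratio = max_ratio
        self.alpha = alpha

    # -- REML machinery ----------------------------------------------------

    @staticmethod
    def _blocks(groups):
        codes, uniques = pd.factorize(groups)
        order = np.argsort(codes, kind="stable")
        counts = np.bincount(codes)
        return codes, order, counts, len(uniques)

    def _profile_reml(self, lam, X, y, codes):
        """Profiled REML log-likelihood at variance ratio lam (up to const).

        V = sigma^2 (I + lam Z Z'); per-subject blocks are inverted
        analytically via Sherman-Morrison.
        """
        n, p = X.shape
        w = lam / (1.0 + lam * self._counts[codes])  # per-row shrinkage weight
        # V^{-1} A = A - w * 1 (1' A) within each subject block (unit scale)
        def vinv(M):
            sums = np.zeros((self._n_groups, M.shape[1]))
            np.add.at(sums, codes, M)
            return M - (w[:, None] * sums[codes])

        XtVX = X.T @ vinv(X)
        XtVy = X.T @ vinv(y[:, None]).ravel()
        beta = np.linalg.solve(XtVX, XtVy)
        r = y - X @ beta
        quad = float(r @ vinv(r[:, None]).ravel())
        sigma2 = quad / (n - p)
        logdet_v = float(np.sum(np.log1p(lam * self._counts)))
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise DesignError("fixed-effect design is rank deficient")
        ll = -0.5 * ((n - p) * np.log(sigma2) + logdet_v + logdet_xvx)
        return ll, beta, sigma2, XtVX

    def _reml_loglik_theta(self, tau2, sigma2, X, y, codes):
        """Unprofiled REML log-likelihood at (var_subject, var_resid)."""
        n, p = X.shape
        lam = tau2 / sigma2
        _, beta, _, _ = self._profile_reml(max(lam, 0.0), X, y, codes)
        w = lam / (1.0 + lam * self._counts[codes])

        def vinv(M):
            sums = np.zeros((self._n_groups, M.shape[1]))
            np.add.at(sums, codes, M)
            return (M - (w[:, None] * sums[codes])) / sigma2

        r = y - X @ beta
        quad = float(r @ vinv(r[:, None]).ravel())
        XtVX = X.T @ vinv(X)
        logdet_v = n * np.log(sigma2) + float(np.sum(np.log1p(lam * self._counts)))
        _, logdet_xvx = np.linalg.slogdet(XtVX)
        return -0.5 * (logdet_v + logdet_xvx + quad)

    def _coef_var(self, tau2, sigma2, X, codes):
        """Sampling variances of the GLS coefficients at (tau2, sigma2)."""
        lam = tau2 / sigma2
        w = lam / (1.0 + lam * self._counts[codes])
        sums = np.zeros((self._n_groups, X.shape[1]))
        np.add.at(sums, codes, X)
        XtVX = (X.T @ (X - w[:, None] * sums[codes])) / sigma2
        return np.diag(np.linalg.inv(XtVX))

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, groups):
        """Fit the model.

        Parameters
        ----------
        X : array-like of shape (n, 2)
            Columns are age (days) and the numerically coded covariate.
        y : array-like of shape (n,)
            Response (typically growth-curve residuals).
        groups : array-like of shape (n,)
            Subject identifiers (the random-intercept grouping).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise DataError("X must have two columns: age and coded covariate")
        if X.shape[0] != y.size:
            raise DataError("X and y length mismatch")
        age, cov = X[:, 0], X[:, 1]
        if np.ptp(cov) == 0.0:
            raise DesignError("covariate is constant; its effect is inestimable")
        D = np.column_stack([np.ones_like(age), age, cov, age * cov])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise DesignError("fixed-effect design is rank deficient")
        codes, _, counts, n_groups = self._blocks(np.asarray(groups))
        if n_groups < 2:
            raise DataError("need at least two subjects")
        self._counts = counts
        self._n_groups = n_groups
        n, p = D.shape

        def neg(u):
            return -self._profile_reml(np.exp(u), D, y, codes)[0]

        ll0 = self._profile_reml(0.0, D, y, codes)[0]
        opt = minimize_scalar(neg, bounds=(np.log(1e-8), np.log(self.max_ratio)),
                              method="bounded", options={"xatol": 1e-10})
        boundary = (-opt.fun) <= ll0 + 1e-8
        lam = 0.0 if boundary else float(np.exp(opt.x))
        _, beta, sigma2, XtVX = self._profile_reml(lam, D, y, codes)
        tau2 = lam * sigma2

        cov_beta = np.linalg.inv(XtVX) * sigma2
        var_beta = np.diag(cov_beta)
        ses = np.sqrt(var_beta)

        df = self._satterthwaite(tau2, sigma2, var_beta, D, y, codes, n, p, boundary)
        tvals = beta / ses
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        tcrit = stats.t.ppf(1.0 - self.alpha / 2.0, df)
        ci = np.column_stack([beta - tcrit * ses, beta + tcrit * ses])

        self.betas_ = beta
        self.ses_ = ses
        self.var_subject_ = float(tau2)
        self.var_resid_ = float(sigma2)
        self.satterthwaite_df_ = df
        self.p_values_ = pvals
        self.ci95_ = ci
        self.boundary_ = bool(boundary)
        if boundary:
            logger.info("subject variance estimated at the zero boundary; "
                        "fit reduces to ordinary least squares")
        self.result_ = LMMFit(
            betas=beta, ses=ses, var_subject=self.var_subject_,
            var_resid=self.var_resid_, satterthwaite_df=df, p_values=pvals,
            ci95=ci, boundary=self.boundary_,
        )
        return self

    def _satterthwaite(self, tau2, sigma2, var_beta, D, y, codes, n, p, boundary):
        if boundary:
            # no identifiable subject variance: classical OLS df
            return np.full(p, float(n - p))
        # observed information of the REML log-likelihood in (tau2, sigma2)
        h_t = max(1e-8, 1e-5 * max(tau2, sigma2))
        h_s = max(1e-8, 1e-5 * sigma2)

        def ll(t, s):
            return self._reml_loglik_theta(max(t, 1e-12), max(s, 1e-12), D, y, codes)

        f0 = ll(tau2, sigma2)
        f_tt = (ll(tau2 + h_t, sigma2) - 2 * f0 + ll(tau2 - h_t, sigma2)) / h_t**2
        f_ss = (ll(tau2, sigma2 + h_s) - 2 * f0 + ll(tau2, sigma2 - h_s)) / h_s**2
        f_ts = (ll(tau2 + h_t, sigma2 + h_s) - ll(tau2 + h_t, sigma2 - h_s)
                - ll(tau2 - h_t, sigma2 + h_s) + ll(tau2 - h_t, sigma2 - h_s)) / (4 * h_t * h_s)
        H = np.array([[f_tt, f_ts], [f_ts, f_ss]])
        try:
            A = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.full(p, float(n - p))
        if not np.all(np.isfinite(A)):
            return np.full(p, float(n - p))

        df = np.empty(p)
        for j in range(p):
            def fj(t, s):
                return self._coef_var(max(t, 1e-12), max(s, 1e-12), D, codes)[j]

            g = np.array([
                (fj(tau2 + h_t, sigma2) - fj(tau2 - h_t, sigma2)) / (2 * h_t),
                (fj(tau2, sigma2 + h_s) - fj(tau2, sigma2 - h_s)) / (2 * h_s),
            ])
            denom = float(g @ A @ g)
            df[j] = 2.0 * var_beta[j] ** 2 / denom if denom > 0 else n - p
            if not np.isfinite(df[j]) or df[j] <= 0:
                df[j] = n - p
        return df


def fit_random_intercept_lmm(age, covariate, y, subject) -> LMMFit:
    """Functional wrapper over :class:`RandomInterceptLMM`."""
    X = np.column_stack([np.asarray(age, dtype=float),
                         np.asarray(covariate, dtype=float)])
    return RandomInterceptLMM().fit(X, y, groups=subject).result_


def bonferroni_adjust(p_values, m: int):
    """Bonferroni correction: elementwise ``min(1, m*p)``."""
    if m < 1:
        raise DataError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def _code_covariate(series: pd.Series, name: str) -> np.ndarray:
    if name == "sex":
        try:
            return series.map(SEX_CODES).astype(float).to_numpy()
        except (ValueError, TypeError):
            pass
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float).to_numpy()
    codes, uniques = pd.factorize(series, sort=True)
    if len(uniques) > 2:
        logger.info("covariate %s has %d levels; coded as ordinal 0..%d",
                    name, len(uniques), len(uniques) - 1)
    return codes.astype(float)


def residual_effect_analysis(
    table: pd.DataFrame,
    region: str,
    selection: ModelSelection,
    covariate: str = "sex",
    m_comparisons: int = 7,
    alpha: float = 0.05,
) -> RegionSexResult:
    """Two-stage covariate-by-age test on one region's residuals.

    Residuals from the region's winning population growth fit are modelled
    with the random-intercept LMM; p-values are Bonferroni-adjusted across
    the ``m_comparisons`` regions analyzed in the same family.
    """
    sub = table[table["region"] == region]
    if sub.empty:
        raise DataError(f"region {region!r} not present in the table")
    if covariate not in sub.columns:
        raise DataError(f"covariate column {covariate!r} missing")
    ages = sub["age_days"].to_numpy(dtype=float)
    resid = sub["value"].to_numpy(dtype=float) - selection.best_fit.predict(ages)
    cov = _code_covariate(sub[covariate], covariate)
    lmm = RandomInterceptLMM(alpha=alpha).fit(
        np.column_stack([ages, cov]), resid, groups=sub["subject"].to_numpy()
    )
    adj = bonferroni_adjust(lmm.p_values_, m_comparisons)
    return RegionSexResult(
        region=region,
        covariate=covariate,
        lmm=lmm.result_,
        bonferroni_adjusted_p=adj,
        significant_after_correction=adj < alpha,
        m_comparisons=m_comparisons,
    )


def confound_screen(
    table: pd.DataFrame,
    region: str,
    selection: ModelSelection,
    confounds: list[str],
    m_comparisons: int = 7,
) -> list[RegionSexResult]:
    """One residual LMM per potential confound (scanner, recon, ...).

    Confounds with a single observed level are skipped with a warning.
    """
    results = []
    sub = table[table["region"] == region]
    for name in confounds:
        if name not in table.columns:
            raise DataError(f"confound column {name!r} missing")
        if sub[name].nunique() < 2:
            warnings.warn(f"confound {name!r} has a single level; skipped")
            continue
        results.append(
            residual_effect_analysis(table, region, selection, covariate=name,
                                     m_comparisons=m_comparisons)
        )
    return results


def confound_summary(results: list[RegionSexResult]) -> pd.DataFrame:
    """Stacked coefficient table across confound screens."""
    if not results:
        return pd.DataFrame()
    return pd.concat([r.summary_frame() for r in results])
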
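"""Sigmoidal growth-curve families, fitting, and BIC model selection.

Five model families describe how a brain-region volume ``V`` (mL) changes
with post-conception age ``t`` (days):

====================  ==========================================  ==========
family                closed form                                 parameters
====================  ==========================================  ==========
``linear``            ``m*t + b``                                 m, b
``quadratic``         ``c2*t**2 + c1*t + c0``                     c0, c1, c2
``logistic3``         ``A / (1 + exp(-Rg*(t - tmid)))``           A, Rg, tmid
``logistic4``         ``(A - B)/(1 + exp(-Rg*(t - tmid))) + B``   A, B, Rg, tmid
``gompertz``          ``a * exp(-b * exp(-c*t))``                 a, b, c
====================  ==========================================  ==========

The three-parameter logistic has asymptote ``A``, maximal growth rate
``A*Rg/4`` attained at the inflection age ``tmid``.  The Gompertz curve's
inflection age is ``ln(b)/c`` and its maximal rate ``a*c/e``.  Model
families are compared with a Gaussian-residual BIC,
``n*log(rss/n) + k*log(n)`` with ``k`` counting the free curve parameters
plus the residual variance; the family with the lowest BIC wins, with ties
(|dBIC| < 1e-6) broken toward fewer parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DataError, DomainError, ParameterError, SelectionError

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "GrowthCurveFit",
    "DerivedGrowthDescriptors",
    "ModelSelection",
    "GrowthCurveModel",
    "GrowthModelSelector",
    "eval_model",
    "fit_curve",
    "select_model",
    "derived_descriptors",
    "fit_percent_of_adult",
]

#: family name -> ordered free-parameter names
FAMILIES: dict[str, tuple[str, ...]] = {
    "linear": ("m", "b"),
    "quadratic": ("c0", "c1", "c2"),
    "logistic3": ("A", "Rg", "tmid"),
    "logistic4": ("A", "B", "Rg", "tmid"),
    "gompertz": ("a", "b", "c"),
}

_SIGMOID_FAMILIES = frozenset({"logistic3", "logistic4", "gompertz"})
_POLY_FAMILIES = frozenset({"linear", "quadratic"})


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ParameterError(
            f"unknown family {family!r}; choose from {sorted(FAMILIES)}"
        )


def eval_model(family: str, params, t):
    """Evaluate a growth-model family at ages ``t`` (days).

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : array-like
        Parameter vector in the family's canonical order.
    t : float or array-like
        Age(s) in days post-conception.

    Returns
    -------
    float or ndarray
        Modelled value(s), same shape as ``t``.
    """
    _check_family(family)
    params = np.asarray(params, dtype=float)
    if params.shape != (len(FAMILIES[family]),):
        raise ParameterError(
            f"{family} takes {len(FAMILIES[family])} parameters, got {params.shape}"
        )
    if not np.all(np.isfinite(params)):
        raise DomainError(f"non-finite parameters for {family}: {params}")
    t = np.asarray(t, dtype=float)
    if family == "linear":
        m, b = params
        out = m * t + b
    elif family == "quadratic":
        c0, c1, c2 = params
        out = c2 * t**2 + c1 * t + c0
    elif family == "logistic3":
        A, Rg, tmid = params
        out = A / (1.0 + np.exp(-Rg * (t - tmid)))
    elif family == "logistic4":
        A, B, Rg, tmid = params
        out = (A - B) / (1.0 + np.exp(-Rg * (t - tmid))) + B
    else:  # gompertz
        a, b, c = params
        out = a * np.exp(-b * np.exp(-c * t))
    return out if out.ndim else float(out)


@dataclass
class GrowthCurveFit:
    """Least-squares fit of one family to one measurement series."""

    family: str
    params: np.ndarray
    rss: float
    loglik: float
    bic: float
    n_obs: int
    converged: bool
    param_names: tuple[str, ...] = ()
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.param_names:
            self.param_names = FAMILIES[self.family]

    def predict(self, t):
        return eval_model(self.family, self.params, t)

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "params": dict(zip(self.param_names, np.asarray(self.params).tolist())),
            "rss": self.rss,
            "loglik": self.loglik,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


@dataclass
class DerivedGrowthDescriptors:
    """Inflection age (days), maximal rate (units/day), and asymptote."""

    t_mid: float
    r_max: float
    asymptote: float


@dataclass
class ModelSelection:
    """All attempted family fits plus the BIC winner."""

    fits: dict[str, GrowthCurveFit]
    winner: str
    bic_table: dict[str, float]

    @property
    def best_fit(self) -> GrowthCurveFit:
        return self.fits[self.winner]


def _gaussian_loglik(rss: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _bic(rss: float, n: int, k_free: int) -> float:
    # k counts the residual variance in addition to the free curve parameters
    return n * math.log(max(rss / n, 1e-300)) + (k_free + 1) * math.log(n)


class GrowthCurveModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares growth-curve regressor for one family.

    Parameters
    ----------
    family : str, default="logistic3"
        Model family; see :data:`FAMILIES`.
    fixed : dict or None
        Parameters pinned to fixed values, e.g. ``{"A": 100.0}`` for
        percent-of-adult fits constrained to asymptote at 100%.
    max_nfev : int
        Evaluation budget for the trust-region optimizer.

    Attributes
    ----------
    params_ : ndarray
        Full parameter vector (fixed values substituted) in canonical order.
    rss_, loglik_, bic_ : float
    converged_ : bool
        False (never an exception) when optimization fails or the data are
        degenerate for the family.
    result_ : GrowthCurveFit
    """

    def __init__(self, family: str = "logistic3", fixed: dict | None = None,
                 bounds: dict | None = None, max_nfev: int = 2000):
        self.family = family
        self.fixed = fixed
        self.bounds = bounds
        self.max_nfev = max_nfev

    # -- internals ---------------------------------------------------------

    def _initial_guess(self, ages, values):
        vmax = float(np.max(values))
        vmin = float(np.min(values))
        span = max(float(np.ptp(ages)), 1.0)
        a0 = 1.1 * vmax if vmax > 0 else 1.0
        above = ages[values > 0.5 * vmax]
        tmid0 = float(above.min()) if above.size else float(np.median(ages))
        rg0 = 4.0 * max(vmax - vmin, 1e-6) / (span * a0)
        if self.family == "logistic3":
            return {"A": a0, "Rg": rg0, "tmid": tmid0}
        if self.family == "logistic4":
            return {"A": a0, "B": vmin, "Rg": rg0, "tmid": tmid0}
        # gompertz: moment-match a logistic3 pilot fit (same asymptote,
        # same inflection age, same maximal rate a*c/e = A*Rg/4)
        pilot = GrowthCurveModel("logistic3", max_nfev=self.max_nfev)
        pilot.fit(ages, values)
        if pilot.converged_:
            A, Rg, tmid = pilot.params_
        else:
            A, Rg, tmid = a0, rg0, tmid0
        c0 = np.clip(Rg * math.e / 4.0, 1e-6, 1.0)
        b0 = math.exp(min(c0 * tmid, 600.0))
        return {"a": A, "b": b0, "c": c0}

    def _bounds(self, values):
        vmax = float(np.max(values))
        hi = 10.0 * max(abs(vmax), 1e-6)
        table = {
            "A": (1e-12, hi),
            "a": (1e-12, hi),
            "B": (-hi, hi),
            "b": (1e-12, 1e12),
            "Rg": (1e-9, 1.0),
            "c": (1e-9, 1.0),
            "tmid": (0.0, 400.0),
        }
        table.update(self.bounds or {})
        return table

    def fit(self, ages, values):
        """Fit the family to ``values`` observed at ``ages`` (days)."""
        _check_family(self.family)
        ages = np.asarray(ages, dtype=float).ravel()
        values = np.asarray(values, dtype=float).ravel()
        if ages.shape != values.shape:
            raise DataError("ages and values must have the same length")
        if not (np.all(np.isfinite(ages)) and np.all(np.isfinite(values))):
            raise DataError("ages and values must be finite")
        names = FAMILIES[self.family]
        fixed = dict(self.fixed or {})
        unknown = set(fixed) - set(names)
        if unknown:
            raise ParameterError(f"fixed parameters {unknown} not in family {self.family}")
        free_names = [p for p in names if p not in fixed]
        n = ages.size
        if n < len(free_names):
            raise DataError(
                f"need at least {len(free_names)} observations to fit "
                f"{self.family} with {len(free_names)} free parameters, got {n}"
            )

        self.n_obs_ = n
        self.free_names_ = tuple(free_names)
        if self.family in _POLY_FAMILIES:
            self._fit_poly(ages, values, names, fixed, free_names)
        else:
            self._fit_sigmoid(ages, values, names, fixed, free_names)

        self.rss_ = float(self.rss_)
        self.loglik_ = _gaussian_loglik(self.rss_, n)
        self.bic_ = _bic(self.rss_, n, len(free_names))
        self.result_ = GrowthCurveFit(
            family=self.family,
            params=self.params_,
            rss=self.rss_,
            loglik=self.loglik_,
            bic=self.bic_,
            n_obs=n,
            converged=self.converged_,
            fixed=fixed,
        )
        return self

    def _fit_poly(self, ages, values, names, fixed, free_names):
        # exact linear least squares on the monomial design
        degree = {"linear": 1, "quadratic": 2}[self.family]
        cols = {"b": 0, "m": 1} if self.family == "linear" else {"c0": 0, "c1": 1, "c2": 2}
        X = np.vander(ages, degree + 1, increasing=True)
        y = values.copy()
        for name, val in fixed.items():
            y = y - val * X[:, cols[name]]
        Xf = X[:, [cols[p] for p in free_names]]
        beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
        full = dict(fixed)
        full.update(dict(zip(free_names, beta)))
        self.params_ = np.array([full[p] for p in names], dtype=float)
        resid = values - eval_model(self.family, self.params_, ages)
        self.rss_ = float(resid @ resid)
        self.converged_ = True

    def _fit_sigmoid(self, ages, values, names, fixed, free_names):
        degenerate = np.ptp(values) == 0.0 or len(np.unique(ages)) < len(free_names)
        init = self._initial_guess(ages, values)
        init.update(fixed)
        btable = self._bounds(values)
        lo = np.array([btable[p][0] for p in free_names])
        hi = np.array([btable[p][1] for p in free_names])
        x0 = np.clip(np.array([init[p] for p in free_names], dtype=float), lo, hi)

        def residual(x):
            full = dict(fixed)
            full.update(dict(zip(free_names, x)))
            p = np.array([full[q] for q in names])
            return eval_model(self.family, p, ages) - values

        converged = False
        best = x0
        if not degenerate:
            try:
                sol = least_squares(residual, x0, bounds=(lo, hi),
                                    max_nfev=self.max_nfev)
                converged = bool(sol.success) and np.all(np.isfinite(sol.x))
                best = sol.x
            except Exception as exc:  # optimizer blow-ups become converged=False
                logger.warning("fit of %s failed: %s", self.family, exc)
        full = dict(fixed)
        full.update(dict(zip(free_names, best)))
        self.params_ = np.array([full[p] for p in names], dtype=float)
        r = residual(best)
        self.rss_ = float(r @ r)
        self.converged_ = converged

    def predict(self, ages):
        return eval_model(self.family, self.params_, np.asarray(ages, dtype=float))


class GrowthModelSelector(BaseEstimator):
    """Fit all candidate families and select the lowest-BIC model.

    Non-converged families are excluded from the ranking (recorded as +inf
    in ``bic_table_``); near-ties (|dBIC| < ``tie_tol``) go to the family
    with fewer parameters.

    Attributes
    ----------
    fits_ : dict of str -> GrowthCurveFit
    winner_ : str
    bic_table_ : dict of str -> float
    selection_ : ModelSelection
    """

    def __init__(self, families: tuple[str, ...] = tuple(FAMILIES),
                 tie_tol: float = 1e-6):
        self.families = families
        self.tie_tol = tie_tol

    def fit(self, ages, values):
        ages = np.asarray(ages, dtype=float).ravel()
        values = np.asarray(values, dtype=float).ravel()
        if ages.size < 6:
            raise DataError(f"model selection needs >= 6 observations, got {ages.size}")
        fits: dict[str, GrowthCurveFit] = {}
        bic_table: dict[str, float] = {}
        for fam in self.families:
            model = GrowthCurveModel(fam).fit(ages, values)
            fits[fam] = model.result_
            bic_table[fam] = model.bic_ if model.converged_ else math.inf
            if not model.converged_:
                logger.info("family %s did not converge; excluded from ranking", fam)
        finite = {f: b for f, b in bic_table.items() if math.isfinite(b)}
        if not finite:
            raise SelectionError("no candidate family converged")
        best_bic = min(finite.values())
        contenders = [f for f, b in finite.items() if b - best_bic < self.tie_tol]
        winner = min(contenders, key=lambda f: (len(FAMILIES[f]), f))
        self.fits_ = fits
        self.winner_ = winner
        self.bic_table_ = bic_table
        self.selection_ = ModelSelection(fits=fits, winner=winner, bic_table=bic_table)
        return self


# -- module-level functional surface --------------------------------------

def fit_curve(family: str, ages, values, fixed: dict | None = None) -> GrowthCurveFit:
    """Least-squares fit of one family; see :class:`GrowthCurveModel`."""
    return GrowthCurveModel(family=family, fixed=fixed).fit(ages, values).result_


def select_model(ages, values, families: tuple[str, ...] = tuple(FAMILIES)) -> ModelSelection:
    """BIC model selection across families; see :class:`GrowthModelSelector`."""
    return GrowthModelSelector(families=families).fit(ages, values).selection_


def derived_descriptors(fit: GrowthCurveFit | GrowthCurveModel) -> DerivedGrowthDescriptors:
    """Inflection age, maximal growth rate, and asymptote of a sigmoid fit.

    For a three-parameter logistic the maximal rate is ``A*Rg/4`` at
    ``tmid``; the four-parameter version has rate ``(A-B)*Rg/4``; a Gompertz
    fit has inflection ``ln(b)/c`` and maximal rate ``a*c/e``.
    """
    family = fit.family
    params = np.asarray(getattr(fit, "params", getattr(fit, "params_", None)), dtype=float)
    if family == "logistic3":
        A, Rg, tmid = params
        return DerivedGrowthDescriptors(t_mid=tmid, r_max=A * Rg / 4.0, asymptote=A)
    if family == "logistic4":
        A, B, Rg, tmid = params
        return DerivedGrowthDescriptors(t_mid=tmid, r_max=(A - B) * Rg / 4.0, asymptote=A)
    if family == "gompertz":
        a, b, c = params
        return DerivedGrowthDescriptors(
            t_mid=math.log(b) / c, r_max=a * c / math.e, asymptote=a
        )
    raise ParameterError(f"derived descriptors undefined for family {family!r}")


def gompertz_from_descriptors(asymptote: float, r_max: float, t_mid: float) -> tuple[float, float, float]:
    """Invert (a, RgG, tmidG) descriptors back to raw Gompertz (a, b, c)."""
    if asymptote <= 0 or r_max <= 0:
        raise DomainError("asymptote and r_max must be positive")
    c = r_max * math.e / asymptote
    b = math.exp(c * t_mid)
    return asymptote, b, c


def fit_percent_of_adult(ages, percent_values) -> GrowthCurveFit:
    """Constrained logistic fit of fetal volumes expressed as % of adult.

    The asymptote is pinned at 100%, leaving ``Rg`` and ``tmid`` free; the
    implied maximal growth rate in %/day is ``100*Rg/4 = 25*Rg``.  Values
    above 100 are tolerated as noise, but a persistent overshoot (mean of
    the oldest decile of ages above 110%) is logged as suspicious.
    """
    ages = np.asarray(ages, dtype=float).ravel()
    percent_values = np.asarray(percent_values, dtype=float).ravel()
    fit = fit_curve("logistic3", ages, percent_values, fixed={"A": 100.0})
    old = ages >= np.max(ages) - 0.1 * max(np.ptp(ages), 1.0)
    if percent_values[old].mean() > 110.0:
        logger.warning(
            "mean percent-of-adult in the oldest age group is %.1f%% (> 110%%); "
            "check the adult reference volume", percent_values[old].mean()
        )
    return fit
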
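"""Normality transformations and distribution diagnostics.

Heavily right-skewed contaminant concentrations violate the (approximate)
Gaussianity that variogram estimation and kriging rely on.  This module
provides the three classical remedies as scikit-learn style transformers —

* :class:`BoxCoxNormalizer` — power transform ``y = (x**lmbda - 1)/lmbda``
  (natural log at ``lmbda = 0``), with the exponent chosen by profile
  log-likelihood maximization;
* :class:`JohnsonNormalizer` — the Johnson system ``Z = gamma + delta *
  f((X - xi)/lam)`` with bounded (SB), lognormal (SL) and unbounded (SU)
  branches, fitted by the Slifker–Shapiro percentile method;
* :class:`NormalScoreNormalizer` — rank-based quantile mapping onto
  standard-normal scores (Blom plotting positions by default);

— together with the diagnostics used to judge them: bias-corrected skewness
and kurtosis, coefficient of variation, and a Lilliefors-corrected
Kolmogorov–Smirnov normality test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.diagnostic import lilliefors

from .samples import SampleSet

__all__ = [
    "SummaryStats",
    "BoxCoxNormalizer",
    "JohnsonNormalizer",
    "NormalScoreNormalizer",
    "summary_stats",
    "rsv_exceedance",
    "boxcox_transform",
    "boxcox_fit",
    "johnson_fit",
    "johnson_transform",
    "johnson_inverse",
    "normal_score_transform",
    "normal_score_inverse",
    "ks_normality_test",
    "make_normalizer",
]

ALPHA = 0.05  # significance level for the K-S normality verdict

# Blom is the SPSS/Minitab default and reproduces the n=60 score kurtosis
# of about -0.233; alternatives kept pluggable.
PLOTTING_POSITIONS: dict[str, tuple[float, float]] = {
    # name -> (a, b) in (r - a) / (n + b)
    "blom": (0.375, 0.25),
    "vdw": (0.0, 1.0),  # Van der Waerden r/(n+1)
    "hazen": (0.5, 0.0),
}


class FitError(RuntimeError):
    """Raised when a transformation cannot be fitted to the data."""


def _asarray1d(values, *, name: str = "values") -> np.ndarray:
    x = np.asarray(getattr(values, "values", values), dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        bad = np.flatnonzero(~np.isfinite(x))
        raise ValueError(f"non-finite {name} at indices {bad.tolist()}")
    return x


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    """Marginal summary of a value vector (concentration-table layout)."""

    n: int
    minimum: float
    maximum: float
    mean: float
    median: float
    skewness: float
    kurtosis: float
    cv: float
    sd: float
    ks_statistic: float
    ks_p: float
    ks_verdict: str

    def as_dict(self) -> dict:
        return {
            "n": self.n, "minimum": self.minimum, "maximum": self.maximum,
            "mean": self.mean, "median": self.median, "skewness": self.skewness,
            "kurtosis": self.kurtosis, "cv": self.cv, "sd": self.sd,
            "ks_statistic": self.ks_statistic, "ks_p": self.ks_p,
            "ks_verdict": self.ks_verdict,
        }


def summary_stats(values) -> SummaryStats:
    """Marginal diagnostics of a value vector.

    Skewness and excess kurtosis use the bias-corrected sample formulas
    (the convention of mainstream statistics packages); ``cv = sd/mean``
    with the n-1 standard deviation.  The normality verdict comes from the
    Lilliefors-corrected K-S test at the 0.05 level.
    """
    if isinstance(values, SampleSet):
        values = values.values
    x = _asarray1d(values)
    if x.size < 4:
        raise ValueError(f"need n >= 4 for kurtosis, got {x.size}")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if sd == 0.0:
        skew = kurt = 0.0  # degenerate input: report 0 rather than NaN
        ks_stat, ks_p = float("nan"), float("nan")
        verdict = "Non-normal"
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
        ks_stat, ks_p, verdict = ks_normality_test(x)
    return SummaryStats(
        n=int(x.size),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        mean=mean,
        median=float(np.median(x)),
        skewness=skew,
        kurtosis=kurt,
        cv=sd / mean if mean != 0 else float("inf"),
        sd=sd,
        ks_statistic=ks_stat,
        ks_p=ks_p,
        ks_verdict=verdict,
    )


def rsv_exceedance(mean_conc: float, rsv: float) -> float:
    """Ratio of a mean concentration to its regulatory risk screening value."""
    if rsv <= 0:
        raise ValueError(f"risk screening value must be positive, got {rsv}")
    return mean_conc / rsv


def ks_normality_test(values) -> tuple[float, float, str]:
    """Lilliefors-corrected K-S test against a normal with estimated moments.

    Returns ``(statistic, p_value, verdict)`` where the verdict is
    ``"Normal"`` iff ``p >= 0.05``.  The Lilliefors correction is needed
    because mean and SD are estimated from the same data; the plain K-S
    p-value would be anticonservative in the other direction (inflated).
    """
    x = _asarray1d(values)
    if x.size < 4:
        raise ValueError(f"need n >= 4, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) input has no distribution to test")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    p = float(min(max(p, 0.0), 1.0))
    return float(stat), p, ("Normal" if p >= ALPHA else "Non-normal")


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def boxcox_transform(values, lmbda: float) -> np.ndarray:
    """Apply the Box-Cox power transform with a given exponent.

    ``y = (x**lmbda - 1)/lmbda`` for ``lmbda != 0`` and ``y = ln(x)`` at
    ``lmbda = 0``; strictly increasing in ``x`` for every exponent.
    """
    x = _asarray1d(values)
    if np.any(x <= 0):
        bad = np.flatnonzero(x <= 0)
        raise ValueError(f"Box-Cox requires positive values; offending indices {bad.tolist()}")
    if not np.isfinite(lmbda):
        raise ValueError("lambda must be finite")
    if lmbda == 0.0:
        return np.log(x)
    # expm1 form of (x**lmbda - 1)/lmbda is stable as lmbda -> 0
    return np.expm1(lmbda * np.log(x)) / lmbda


def boxcox_inverse(y, lmbda: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if lmbda == 0.0:
        return np.exp(y)
    return np.power(lmbda * y + 1.0, 1.0 / lmbda)


def boxcox_fit(values, *, bounds: tuple[float, float] = (-5.0, 5.0)) -> float:
    """Profile-log-likelihood estimate of the Box-Cox exponent.

    Maximizes the normal profile log-likelihood of the transformed data over
    a bounded interval (coarse grid then bounded refinement); exponents
    within 1e-3 of zero snap to the exact log branch.
    """
    x = _asarray1d(values)
    if x.size < 10:
        raise ValueError(f"need n >= 10 to estimate lambda, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if np.ptp(x) == 0:
        raise FitError("constant input: Box-Cox exponent is unidentifiable")
    grid = np.arange(bounds[0], bounds[1] + 1e-12, 0.01)
    ll = np.array([stats.boxcox_llf(l, x) for l in grid])
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(lambda l: -stats.boxcox_llf(l, x), bounds=(lo, hi), method="bounded")
    lam = float(res.x)
    if abs(lam) < 1e-3:
        lam = 0.0
    return lam


class BoxCoxNormalizer(TransformerMixin, BaseEstimator):
    """Box-Cox power transform with profile-likelihood exponent selection.

    Parameters
    ----------
    lmbda : float or None
        Fixed exponent; if None (default) it is estimated at :meth:`fit`.
    bounds : pair of float
        Search interval for the exponent.

    Attributes
    ----------
    lambda_ : float
        The exponent used by :meth:`transform`.
    """

    def __init__(self, lmbda: float | None = None, bounds: tuple[float, float] = (-5.0, 5.0)):
        self.lmbda = lmbda
        self.bounds = bounds

    def fit(self, X, y=None):
        x = _asarray1d(X)
        self.lambda_ = float(self.lmbda) if self.lmbda is not None else boxcox_fit(x, bounds=self.bounds)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        return boxcox_transform(X, self.lambda_)

    def inverse_transform(self, X) -> np.ndarray:
        return boxcox_inverse(X, self.lambda_)

    @property
    def params_(self) -> dict:
        return {"lambda": self.lambda_}


# ---------------------------------------------------------------------------
# Johnson system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JohnsonParams:
    """Fitted Johnson-system parameters.

    ``family`` is SB (bounded), SL (lognormal) or SU (unbounded); ``gamma``
    and ``delta`` are shape parameters, ``xi`` the position and ``lam`` the
    scale.  SB support is the open interval ``(xi, xi + lam)``, SL support
    ``(xi, inf)``, SU the whole line.
    """

    family: Literal["SB", "SL", "SU"]
    gamma: float
    delta: float
    xi: float
    lam: float
    z: float = float("nan")  # percentile-method z actually used

    def __post_init__(self):
        if self.delta <= 0 or self.lam <= 0:
            raise ValueError("delta and lam must be positive")


def johnson_transform(values, params: JohnsonParams) -> np.ndarray:
    """Map data to the normal scale through a Johnson curve."""
    x = _asarray1d(values)
    u = (x - params.xi) / params.lam
    if params.family == "SL":
        if np.any(u <= 0):
            raise ValueError("SL requires all values > xi")
        f = np.log(u)
    elif params.family == "SB":
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("SB requires all values strictly inside (xi, xi + lam)")
        f = np.log(u / (1.0 - u))
    elif params.family == "SU":
        f = np.arcsinh(u)
    else:  # pragma: no cover
        raise ValueError(f"unknown family {params.family!r}")
    return params.gamma + params.delta * f


def johnson_inverse(z, params: JohnsonParams) -> np.ndarray:
    """Exact algebraic inverse of :func:`johnson_transform`."""
    z = np.asarray(z, dtype=float)
    w = (z - params.gamma) / params.delta
    if params.family == "SL":
        u = np.exp(w)
    elif params.family == "SB":
        u = 1.0 / (1.0 + np.exp(-w))
    else:
        u = np.sinh(w)
    return params.xi + params.lam * u


def _slifker_shapiro(x: np.ndarray, z: float, sl_tol: float) -> JohnsonParams:
    """One percentile-method fit at a given selection point ``z``.

    Uses the four sample quantiles at normal fractions of ±z and ±3z; the
    ratio mn/p² picks the family (>1 SU, <1 SB, ≈1 SL within ``sl_tol``).
    """
    q = stats.norm.cdf(np.array([-3 * z, -z, z, 3 * z]))
    x_m3, x_m1, x_1, x_3 = np.quantile(x, q)
    m = x_3 - x_1
    n = x_m1 - x_m3
    p = x_1 - x_m1
    if p <= 0 or m <= 0 or n <= 0:
        raise FitError(f"degenerate percentile spread at z={z}")
    d = m * n / p**2
    if abs(d - 1.0) <= sl_tol:
        # lognormal branch
        mp = m / p
        if mp <= 1:
            raise FitError(f"SL branch invalid (m/p <= 1) at z={z}")
        delta = 2 * z / np.log(mp)
        gamma = delta * np.log((mp - 1.0) / (p * np.sqrt(mp)))
        xi = 0.5 * (x_1 + x_m1) - 0.5 * p * (mp + 1.0) / (mp - 1.0)
        if np.min(x) <= xi:
            raise FitError(f"SL support violated at z={z}")
        return JohnsonParams("SL", float(gamma), float(delta), float(xi), 1.0, z)
    if d > 1.0:
        # unbounded branch
        mp, np_ = m / p, n / p
        delta = 2 * z / np.arccosh(0.5 * (mp + np_))
        gamma = delta * np.arcsinh((np_ - mp) / (2.0 * np.sqrt(d - 1.0)))
        lam = 2.0 * p * np.sqrt(d - 1.0) / ((mp + np_ - 2.0) * np.sqrt(mp + np_ + 2.0))
        xi = 0.5 * (x_1 + x_m1) + p * (np_ - mp) / (2.0 * (mp + np_ - 2.0))
        if lam <= 0 or not np.isfinite([gamma, delta, lam, xi]).all():
            raise FitError(f"SU parameters invalid at z={z}")
        return JohnsonParams("SU", float(gamma), float(delta), float(xi), float(lam), z)
    # bounded branch
    pm, pn = p / m, p / n
    arg = 0.5 * np.sqrt((1.0 + pm) * (1.0 + pn))
    if arg <= 1:
        raise FitError(f"SB cosh argument invalid at z={z}")
    delta = z / np.arccosh(arg)
    inner = (1.0 + pm) * (1.0 + pn) - 4.0
    denom = pm * pn - 1.0
    if inner < 0 or denom <= 0:
        raise FitError(f"SB parameters invalid at z={z}")
    gamma = delta * np.arcsinh((pn - pm) * np.sqrt(inner) / (2.0 * denom))
    lam = p * np.sqrt(((1.0 + pm) * (1.0 + pn) - 2.0) ** 2 - 4.0) / denom
    xi = 0.5 * (x_1 + x_m1) - 0.5 * lam + p * (pn - pm) / (2.0 * denom)
    if lam <= 0 or not np.isfinite([gamma, delta, lam, xi]).all():
        raise FitError(f"SB parameters invalid at z={z}")
    if np.min(x) <= xi or np.max(x) >= xi + lam:
        raise FitError(f"SB support violated at z={z}")
    return JohnsonParams("SB", float(gamma), float(delta), float(xi), float(lam), z)


def johnson_fit(
    values,
    *,
    z_values: tuple[float, ...] = (0.25, 0.524, 0.6, 0.75, 1.0),
    sl_tol: float = 0.1,
) -> JohnsonParams:
    """Fit a Johnson curve by the Slifker–Shapiro percentile method.

    For each candidate selection point ``z`` the quantile-ratio criterion
    picks the family and the closed-form percentile estimates give the
    parameters; among valid candidates the one whose transformed data attain
    the highest Lilliefors K-S p-value wins (ties by the default z = 0.524
    first).
    """
    x = _asarray1d(values)
    if x.size < 20:
        raise ValueError(f"need n >= 20 for the percentile method, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("constant input")
    order = sorted(z_values, key=lambda z: (z != 0.524, z))
    candidates: list[tuple[float, JohnsonParams]] = []
    failures: list[str] = []
    for z in order:
        try:
            params = _slifker_shapiro(x, z, sl_tol)
            transformed = johnson_transform(x, params)
            _, p, _ = ks_normality_test(transformed)
        except (FitError, ValueError) as exc:
            failures.append(str(exc))
            continue
        candidates.append((p, params))
    if not candidates:
        raise FitError("all Johnson candidate fits invalid: " + "; ".join(failures))
    return max(candidates, key=lambda t: t[0])[1]


class JohnsonNormalizer(TransformerMixin, BaseEstimator):
    """Johnson-system transform fitted by the percentile method.

    Attributes
    ----------
    params_ : JohnsonParams
        Family and (gamma, delta, xi, lam) of the selected curve.
    family_ : str
        Convenience alias for ``params_.family``.
    """

    def __init__(
        self,
        z_values: tuple[float, ...] = (0.25, 0.524, 0.6, 0.75, 1.0),
        sl_tol: float = 0.1,
    ):
        self.z_values = z_values
        self.sl_tol = sl_tol

    def fit(self, X, y=None):
        self.params_ = johnson_fit(_asarray1d(X), z_values=tuple(self.z_values), sl_tol=self.sl_tol)
        self.family_ = self.params_.family
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        return johnson_transform(X, self.params_)

    def inverse_transform(self, X) -> np.ndarray:
        return johnson_inverse(X, self.params_)


# ---------------------------------------------------------------------------
# normal scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalScoreTable:
    """Monotone (value, score) lookup backing the inverse mapping."""

    values: np.ndarray  # sorted original values
    scores: np.ndarray  # matching standard-normal scores
    rule: str = "blom"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        s = np.asarray(self.scores, float)
        if v.size != s.size or v.size == 0:
            raise ValueError("table values/scores size mismatch or empty")
        if np.any(np.diff(s) < 0) or np.any(np.diff(v) < 0):
            raise ValueError("table must be sorted and monotone")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "scores", s)


def normal_scores(n: int, *, rule: str = "blom") -> np.ndarray:
    """Standard-normal scores for ranks 1..n under a plotting-position rule."""
    a, b = PLOTTING_POSITIONS[rule]
    r = np.arange(1, n + 1, dtype=float)
    return stats.norm.ppf((r - a) / (n + b))


def normal_score_transform(values, *, rule: str = "blom") -> tuple[np.ndarray, NormalScoreTable]:
    """Rank-based mapping of data onto standard-normal scores.

    Ranks (average rank for ties) are converted to normal quantiles through
    the chosen plotting position; ties therefore receive identical scores.
    Returns the scores in input order and the lookup table for inversion.
    """
    x = _asarray1d(values)
    if x.size < 2:
        raise ValueError(f"need n >= 2, got {x.size}")
    a, b = PLOTTING_POSITIONS[rule]
    ranks = stats.rankdata(x, method="average")
    scores = stats.norm.ppf((ranks - a) / (x.size + b))
    order = np.argsort(x, kind="stable")
    table = NormalScoreTable(x[order], scores[order], rule)
    return scores, table


def normal_score_inverse(scores, table: NormalScoreTable) -> np.ndarray:
    """Map normal scores back to data units.

    Monotone piecewise-linear interpolation between the stored (score,
    value) nodes; scores beyond the stored extremes clamp to the observed
    min/max rather than extrapolating into unobserved concentrations.
    """
    z = np.asarray(scores, dtype=float)
    return np.interp(z, table.scores, table.values)


class NormalScoreNormalizer(TransformerMixin, BaseEstimator):
    """Normal score transform with a pluggable plotting-position rule.

    Attributes
    ----------
    table_ : NormalScoreTable
        Sorted (value, score) pairs used by :meth:`inverse_transform`.
    """

    def __init__(self, rule: str = "blom"):
        self.rule = rule

    def fit(self, X, y=None):
        _, self.table_ = normal_score_transform(_asarray1d(X), rule=self.rule)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        x = _asarray1d(X)
        # exact score at stored nodes; interpolated score for new values
        return np.interp(x, self.table_.values, self.table_.scores)

    def fit_transform(self, X, y=None):
        scores, self.table_ = normal_score_transform(_asarray1d(X), rule=self.rule)
        self.n_features_in_ = 1
        return scores

    def inverse_transform(self, X) -> np.ndarray:
        return normal_score_inverse(X, self.table_)

    @property
    def params_(self) -> dict:
        return {"rule": self.rule, "n": int(self.table_.values.size)}


METHODS = ("normal_score", "johnson", "boxcox")


def make_normalizer(method: str):
    """Factory mapping a method label to its transformer."""
    if method == "boxcox":
        return BoxCoxNormalizer()
    if method == "johnson":
        return JohnsonNormalizer()
    if method == "normal_score":
        return NormalScoreNormalizer()
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
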
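"""Empirical semivariogram estimation and theoretical model fitting.

The semivariance at lag ``h`` is half the mean squared difference between
observations separated by ``h``.  Binned estimates are fitted by weighted
least squares to spherical, exponential or Gaussian models parameterized by
nugget ``C0``, sill ``C0 + C`` and effective range ``A0`` (the distance at
which the model reaches ~95% of the sill for the asymptotic families, so
ranges are comparable across families).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "FAMILIES",
    "empirical_semivariogram",
    "model_value",
    "fit_variogram",
    "fit_best_variogram",
    "classify_dependence",
]

FAMILIES = ("spherical", "exponential", "gaussian")


class VariogramError(RuntimeError):
    pass


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned semivariance estimates: lag centers, values and pair counts."""

    lags: np.ndarray       # bin-center lag distances, m
    gamma: np.ndarray      # semivariances, squared data units
    counts: np.ndarray     # pairs per bin
    max_lag: float
    bin_width: float

    def __post_init__(self):
        lags = np.asarray(self.lags, float)
        gamma = np.asarray(self.gamma, float)
        counts = np.asarray(self.counts, int)
        if not (lags.size == gamma.size == counts.size):
            raise ValueError("lag/gamma/count size mismatch")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(gamma < 0) or np.any(counts < 1):
            raise ValueError("gamma must be >= 0 and counts >= 1")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "counts", counts)


def empirical_semivariogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_lags: int = 12,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Binned method-of-moments semivariogram.

    ``gamma_k = (1 / (2 N_k)) * sum (z_i - z_j)^2`` over pairs whose
    separation falls in bin ``k``; empty bins are dropped.  ``max_lag``
    defaults to half the maximum pairwise distance.
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float).ravel()
    if coords.shape[0] != values.size or coords.shape[0] < 2:
        raise ValueError("need matching coords/values with n >= 2")
    d = pdist(coords)
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    keep = d <= max_lag
    if not np.any(keep):
        raise VariogramError(f"no sample pair within max_lag={max_lag}")
    width = max_lag / n_lags
    idx = np.minimum((d[keep] / width).astype(int), n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=sq[keep], minlength=n_lags)
    nonempty = counts > 0
    centers = (np.arange(n_lags) + 0.5) * width
    return EmpiricalVariogram(
        lags=centers[nonempty],
        gamma=sums[nonempty] / counts[nonempty],
        counts=counts[nonempty],
        max_lag=float(max_lag),
        bin_width=float(width),
    )


def model_value(family: str, nugget: float, sill: float, range_: float, h) -> np.ndarray:
    """Evaluate a theoretical semivariogram at lag(s) ``h``.

    ``range_`` is the effective range: the spherical model reaches the sill
    exactly at ``A0``; the exponential ``C0 + C*(1 - exp(-3h/A0))`` and
    Gaussian ``C0 + C*(1 - exp(-3h^2/A0^2))`` reach ~95% of it there.
    The nugget applies only for ``h > 0``; the model is 0 at ``h = 0``.
    """
    h = np.asarray(h, dtype=float)
    c = sill - nugget
    hr = h / range_
    if family == "spherical":
        g = nugget + c * np.where(hr < 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
    elif family == "exponential":
        g = nugget + c * (1.0 - np.exp(-3.0 * hr))
    elif family == "gaussian":
        g = nugget + c * (1.0 - np.exp(-3.0 * hr**2))
    else:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return np.where(h == 0.0, 0.0, g)


@dataclass(frozen=True)
class VariogramModel:
    """Fitted theoretical semivariogram."""

    family: str
    nugget: float
    sill: float
    range_: float
    r2: float = float("nan")
    rss: float = float("nan")
    weighting: str = field(default="gs+", compare=False)

    def __post_init__(self):
        if not (0.0 <= self.nugget <= self.sill) or self.sill <= 0:
            raise ValueError(f"need 0 <= nugget <= sill, sill > 0; got {self.nugget}, {self.sill}")
        if self.range_ <= 0:
            raise ValueError("range must be positive")

    def __call__(self, h) -> np.ndarray:
        return model_value(self.family, self.nugget, self.sill, self.range_, h)

    @property
    def proportion(self) -> float:
        """Nugget/sill ratio in percent: 100 * C0 / (C0 + C)."""
        return 100.0 * self.nugget / self.sill

    @property
    def dependence(self) -> str:
        return classify_dependence(self.proportion)


def classify_dependence(proportion: float) -> str:
    """Spatial-dependence class from the nugget/sill ratio (percent).

    Below 25% the structured component dominates (strong spatial
    dependence); above 75% the nugget dominates (weak); between, moderate.
    """
    if not 0.0 <= proportion <= 100.0:
        raise ValueError(f"proportion must be in [0, 100], got {proportion}")
    if proportion < 25.0:
        return "strong"
    if proportion <= 75.0:
        return "moderate"
    return "weak"


def _wls_residuals(theta, family, emp: EmpiricalVariogram, weighting: str):
    nugget, c, range_ = theta
    m = model_value(family, nugget, nugget + c, range_, emp.lags)
    m = np.maximum(m, 1e-12)
    if weighting == "gs+":
        w = np.sqrt(emp.counts) / m  # residual -> sqrt(N) * (g - m) / m
    elif weighting == "npairs":
        w = np.sqrt(emp.counts)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return w * (emp.gamma - m)


def fit_variogram(
    emp: EmpiricalVariogram,
    family: str,
    *,
    weighting: str = "gs+",
    n_starts: int = 8,
    seed: int = 0,
) -> VariogramModel:
    """Weighted-least-squares fit of one model family.

    The objective weights each bin by ``N_k / model(h_k)^2`` (downweighting
    high-sill bins, the convention of classic variogram software); plain
    pair-count weighting is selectable.  Multistart from data-quantile
    initializations guards against the local minima endemic to variogram WLS.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if emp.lags.size < 4:
        raise VariogramError(f"need >= 4 nonempty bins, got {emp.lags.size}")
    gmax = float(emp.gamma.max())
    if gmax == 0.0:
        # constant field: pure-nugget-free flat model at an arbitrary tiny sill
        return VariogramModel(family, 0.0, 1e-12, float(emp.lags[-1]), r2=1.0, rss=0.0)
    hi_range = 3.0 * emp.max_lag
    lb = np.array([0.0, 1e-10 * gmax, 1e-6 * emp.max_lag])
    ub = np.array([2.0 * gmax, 4.0 * gmax, hi_range])
    rng = np.random.default_rng(seed)
    sill0 = float(np.mean(emp.gamma[-max(3, emp.lags.size // 3):]))
    starts = [
        np.array([0.0, sill0, float(np.quantile(emp.lags, q))])
        for q in (0.25, 0.5, 0.75)
    ]
    starts.append(np.array([0.5 * float(emp.gamma[0]), sill0, float(emp.lags[-1])]))
    while len(starts) < n_starts:
        starts.append(
            np.array([
                rng.uniform(0, 0.5 * sill0),
                rng.uniform(0.5, 2.0) * sill0,
                rng.uniform(emp.lags[0], hi_range),
            ])
        )
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)
        try:
            res = least_squares(
                _wls_residuals, x0, bounds=(lb, ub),
                args=(family, emp, weighting), method="trf", max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise VariogramError(f"WLS optimization failed for family {family!r}")
    nugget, c, range_ = best.x
    sill = nugget + c
    m = np.maximum(model_value(family, nugget, sill, range_, emp.lags), 1e-12)
    rss = float(np.sum((emp.gamma - m) ** 2))
    # r^2 of the weighted fit, on the same scale as the objective
    w = emp.counts / m**2 if weighting == "gs+" else emp.counts.astype(float)
    wrss = float(np.sum(w * (emp.gamma - m) ** 2))
    wmean = float(np.sum(w * emp.gamma) / np.sum(w))
    tss = float(np.sum(w * (emp.gamma - wmean) ** 2))
    r2 = 1.0 - wrss / tss if tss > 0 else float("nan")
    return VariogramModel(family, float(nugget), float(sill), float(range_), r2=r2, rss=rss,
                          weighting=weighting)


def fit_best_variogram(
    emp: EmpiricalVariogram,
    families: tuple[str, ...] = FAMILIES,
    **kwargs,
) -> VariogramModel:
    """Fit every family and keep the one with the lowest residual SS."""
    fits = []
    errors = []
    for fam in families:
        try:
            fits.append(fit_variogram(emp, fam, **kwargs))
        except VariogramError as exc:
            errors.append(str(exc))
    if not fits:
        raise VariogramError("all families failed: " + "; ".join(errors))
    return min(fits, key=lambda m: m.rss)
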
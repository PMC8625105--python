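"""Exceedance distributions, maximum-likelihood tail fits, Taylor's law.

The exceedance probability distribution function (EPDF) of a positive
quantity Y is P(Y >= y). Two limiting tail families are fitted by maximum
likelihood above a lower cutoff ``xmin``:

* power law (Zipfian): density f(y) = (eps - 1)/xmin * (y/xmin)^(-eps),
  so the EPDF decays as y^(-eps+1); the density exponent eps ("epsilon")
  characterizes abundance distributions.
* (shifted) exponential: f(y) = lam * exp(-lam (y - xmin)); the rate lam
  ("lambda") characterizes interaction (transfer-entropy) distributions.

Lower exponents mean heavier, more scale-free tails, read in this package
as greater structural/functional organization of the community.

Closed-form MLEs:
    eps_hat = 1 + n / sum(ln(y_i / xmin)),     lam_hat = 1 / (mean(y) - xmin)

``xmin`` is either fixed or chosen by scanning observed values for the
minimum Kolmogorov-Smirnov distance between fitted and empirical tail.

Taylor's law links each population's temporal variance to its mean,
var ~ mean^nu; ``nu`` is the slope of the base-2 log-log ordinary least
squares regression, one point per OTU, with the population (divide-by-n)
variance convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core import CommunityTable
from .errors import (
    DegenerateTailError,
    EmptyTableError,
    TooFewPointsError,
    TooFewTailPointsError,
)

#: Minimum number of tail observations below which fits refuse rather than
#: return garbage (this operationalizes "not calculable" for small phyla).
DEFAULT_N_MIN = 8

#: Log-likelihood margin (natural-log units) below which family selection
#: declares the comparison inconclusive.
DEFAULT_FAMILY_THRESHOLD = 2.0

XminPolicy = Literal["fixed", "ks_scan"]


@dataclass
class ExceedanceCurve:
    """Empirical EPDF: sorted distinct values y with P(Y >= y) at each."""

    y: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.p = np.asarray(self.p, dtype=float)


def exceedance(values: np.ndarray) -> ExceedanceCurve:
    """Empirical exceedance curve of the positive part of a sample.

    Zeros are dropped (the EPDF is over positive support), so the curve
    starts at exactly 1 at the smallest positive value.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise EmptyTableError("empty sample")
    if not np.isfinite(v).all() or (v < 0).any():
        raise EmptyTableError("sample must be finite and non-negative")
    v = v[v > 0]
    if v.size == 0:
        raise EmptyTableError("sample has no positive values")
    v_sorted = np.sort(v)
    ys = np.unique(v_sorted)
    n = v.size
    counts_ge = n - np.searchsorted(v_sorted, ys, side="left")
    return ExceedanceCurve(y=ys, p=counts_ge / n)


@dataclass
class TailFit:
    """A fitted exceedance-tail model.

    ``exponent`` is the power-law density exponent epsilon (> 1) or the
    exponential rate lambda (> 0, per unit of Y) depending on ``family``.
    """

    family: Literal["powerlaw", "exponential"]
    exponent: float
    xmin: float
    n_tail: int
    loglik: float
    ks: float


def _positive(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0 or not np.isfinite(v).all():
        raise EmptyTableError("sample must be non-empty and finite")
    v = v[v > 0]
    if v.size == 0:
        raise EmptyTableError("sample has no positive values")
    return np.sort(v)


def _ks_distance(tail: np.ndarray, cdf: np.ndarray) -> float:
    """Sup-distance between the empirical CDF of a sorted tail and a model CDF."""
    m = tail.size
    grid = np.arange(1, m + 1) / m
    return float(np.max(np.maximum(np.abs(grid - cdf), np.abs(grid - 1 / m - cdf))))


def _powerlaw_at(tail: np.ndarray, xmin: float) -> tuple[float, float, float]:
    """(eps_hat, loglik, ks) of the continuous power law on a sorted tail."""
    logs = np.log(tail / xmin)
    s = logs.sum()
    if s <= 0:
        raise DegenerateTailError("all tail values equal; power-law MLE undefined")
    n = tail.size
    eps = 1.0 + n / s
    loglik = n * np.log((eps - 1.0) / xmin) - eps * s
    cdf = 1.0 - (xmin / tail) ** (eps - 1.0)
    return eps, float(loglik), _ks_distance(tail, cdf)


def _exponential_at(tail: np.ndarray, xmin: float) -> tuple[float, float, float]:
    """(lam_hat, loglik, ks) of the shifted exponential on a sorted tail."""
    shifted = tail - xmin
    mean = shifted.mean()
    if mean <= 0:
        raise DegenerateTailError("tail mean equals xmin; exponential MLE undefined")
    lam = 1.0 / mean
    n = tail.size
    loglik = n * np.log(lam) - lam * shifted.sum()
    cdf = 1.0 - np.exp(-lam * shifted)
    return lam, float(loglik), _ks_distance(tail, cdf)


def _scan_xmin(v_sorted: np.ndarray, n_min: int, fit_at) -> tuple[float, tuple]:
    """Choose xmin among observed values minimizing the KS distance.

    Candidates keep at least ``n_min`` tail points; ties break toward the
    smaller xmin (larger tail). Candidates where the MLE is degenerate are
    skipped.
    """
    candidates = np.unique(v_sorted)
    best = None
    for xm in candidates:
        tail = v_sorted[v_sorted >= xm]
        if tail.size < n_min:
            break  # candidates are ascending; tails only shrink
        try:
            res = fit_at(tail, float(xm))
        except DegenerateTailError:
            continue
        if best is None or res[2] < best[1][2]:
            best = (float(xm), res)
    if best is None:
        raise TooFewTailPointsError(
            f"no xmin candidate leaves >= {n_min} usable tail points"
        )
    return best


def _resolve_tail(
    v_sorted: np.ndarray,
    xmin_policy: XminPolicy,
    xmin: float | None,
    n_min: int,
    fit_at,
) -> tuple[float, np.ndarray, tuple]:
    if xmin_policy == "ks_scan":
        xm, res = _scan_xmin(v_sorted, n_min, fit_at)
        return xm, v_sorted[v_sorted >= xm], res
    if xmin_policy != "fixed":
        raise ValueError(f"unknown xmin_policy {xmin_policy!r}")
    xm = float(v_sorted[0]) if xmin is None else float(xmin)
    tail = v_sorted[v_sorted >= xm]
    if tail.size < n_min:
        raise TooFewTailPointsError(
            f"only {tail.size} tail points >= xmin={xm}; need n_min={n_min}"
        )
    return xm, tail, fit_at(tail, xm)


def _discrete_powerlaw_at(tail: np.ndarray, xmin: float) -> tuple[float, float, float]:
    """Discrete (zeta-normalized) power-law MLE, for integer count data."""
    from scipy.optimize import minimize_scalar
    from scipy.special import zeta

    k = np.round(tail).astype(int)  # tail arrives sorted ascending
    xm = max(int(round(xmin)), 1)
    slog = np.log(k).sum()
    n = k.size

    def nll(eps: float) -> float:
        return n * np.log(zeta(eps, xm)) + eps * slog

    res = minimize_scalar(nll, bounds=(1.0001, 12.0), method="bounded")
    eps = float(res.x)
    loglik = -float(res.fun)
    # model CDF at each observed value, for the KS diagnostic
    pmf = np.arange(xm, k.max() + 1, dtype=float) ** (-eps) / zeta(eps, xm)
    cdf = np.cumsum(pmf)[k - xm]
    return eps, loglik, _ks_distance(k.astype(float), cdf)


def fit_powerlaw(
    values: np.ndarray,
    xmin_policy: XminPolicy = "ks_scan",
    xmin: float | None = None,
    n_min: int = DEFAULT_N_MIN,
    discrete: bool = False,
) -> TailFit:
    """Maximum-likelihood power-law (Zipfian) tail fit.

    Parameters
    ----------
    values:
        Sample; only the positive part is used.
    xmin_policy:
        ``"fixed"`` uses ``xmin`` (default: the minimum positive value);
        ``"ks_scan"`` chooses xmin among observed values to minimize the
        KS distance of the fitted tail.
    n_min:
        Minimum tail size; fewer points raise :class:`TooFewTailPointsError`.
    discrete:
        Use the discrete (zeta) MLE instead of the continuous estimator.
        The continuous estimator is the default even for read counts, which
        span orders of magnitude.
    """
    v = _positive(values)
    fit_at = _discrete_powerlaw_at if discrete else _powerlaw_at
    xm, tail, (eps, loglik, ks) = _resolve_tail(v, xmin_policy, xmin, n_min, fit_at)
    return TailFit(
        family="powerlaw", exponent=eps, xmin=xm, n_tail=tail.size,
        loglik=loglik, ks=ks,
    )


def fit_exponential(
    values: np.ndarray,
    xmin_policy: XminPolicy = "fixed",
    xmin: float | None = None,
    n_min: int = DEFAULT_N_MIN,
) -> TailFit:
    """Maximum-likelihood shifted-exponential tail fit (rate lambda)."""
    v = _positive(values)
    xm, tail, (lam, loglik, ks) = _resolve_tail(
        v, xmin_policy, xmin, n_min, _exponential_at
    )
    return TailFit(
        family="exponential", exponent=lam, xmin=xm, n_tail=tail.size,
        loglik=loglik, ks=ks,
    )


@dataclass
class FamilySelection:
    """Outcome of the power-law vs exponential likelihood comparison."""

    verdict: Literal["powerlaw", "exponential", "inconclusive"]
    delta_loglik: float
    powerlaw: TailFit | None
    exponential: TailFit | None
    xmin: float | None
    n_tail: int


def select_family(
    values: np.ndarray,
    n_min: int = DEFAULT_N_MIN,
    threshold: float = DEFAULT_FAMILY_THRESHOLD,
) -> FamilySelection:
    """Decide which pure tail family better describes a sample.

    The power law is fitted with a KS-scanned xmin; the exponential is then
    fitted at that same xmin, so both likelihoods refer to the same tail.
    ``delta_loglik`` is loglik(powerlaw) - loglik(exponential); verdicts
    within ``threshold`` natural-log units, or tails below ``n_min``, are
    ``inconclusive``.

    Unlike exponent estimation, a likelihood *comparison* on a small extreme
    tail discards most of the evidence and is underpowered, so here the xmin
    scan only considers cutoffs that retain at least half of the positive
    sample (never fewer than ``n_min`` points).
    """
    try:
        v = _positive(values)
        floor = max(n_min, -(-v.size // 2))
        pl = fit_powerlaw(values, xmin_policy="ks_scan", n_min=floor)
        ex = fit_exponential(values, xmin_policy="fixed", xmin=pl.xmin, n_min=n_min)
    except (TooFewTailPointsError, DegenerateTailError, EmptyTableError):
        return FamilySelection(
            verdict="inconclusive", delta_loglik=float("nan"),
            powerlaw=None, exponential=None, xmin=None, n_tail=0,
        )
    delta = pl.loglik - ex.loglik
    if pl.n_tail < n_min or abs(delta) < threshold:
        verdict = "inconclusive"
    else:
        verdict = "powerlaw" if delta > 0 else "exponential"
    return FamilySelection(
        verdict=verdict, delta_loglik=delta, powerlaw=pl, exponential=ex,
        xmin=pl.xmin, n_tail=pl.n_tail,
    )


@dataclass
class TaylorFit:
    """Fitted Taylor's-law scaling var ~ mean^nu (base-2 log regression)."""

    nu: float
    intercept: float
    r2: float
    n_points: int
    n_excluded: int


def taylor_exponent(table: CommunityTable | np.ndarray) -> TaylorFit:
    """Taylor's-law exponent nu of a community (or any (n_otu, t) matrix).

    One (mean, variance) point per OTU across its time series; variance uses
    the population (divide-by-n) convention. OTUs with zero mean or zero
    variance are excluded and counted in ``n_excluded``.
    """
    X = table.values() if isinstance(table, CommunityTable) else np.asarray(table, float)
    if X.ndim != 2:
        raise TooFewPointsError("expected an (n_otu, t) matrix")
    means = X.mean(axis=1)
    variances = X.var(axis=1)  # ddof=0: population convention
    usable = (means > 0) & (variances > 0)
    n_excluded = int((~usable).sum())
    if usable.sum() < 3:
        raise TooFewPointsError(
            f"only {int(usable.sum())} OTUs with positive mean and variance; need >= 3"
        )
    lx = np.log2(means[usable])
    ly = np.log2(variances[usable])
    res = stats.linregress(lx, ly)
    return TaylorFit(
        nu=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=int(usable.sum()),
        n_excluded=n_excluded,
    )


# --- sklearn-style estimator wrappers ----------------------------------------


class PowerLawTail(BaseEstimator):
    """Power-law tail estimator with fit attributes ``exponent_``, ``xmin_``...

    Parameters mirror :func:`fit_powerlaw`; ``xmin="scan"`` triggers the
    KS scan, a number fixes the cutoff, ``None`` fixes it at the minimum
    positive observation.
    """

    def __init__(self, xmin: float | str | None = "scan",
                 n_min: int = DEFAULT_N_MIN, discrete: bool = False):
        self.xmin = xmin
        self.n_min = n_min
        self.discrete = discrete

    def fit(self, X: np.ndarray, y=None) -> "PowerLawTail":
        policy = "ks_scan" if self.xmin == "scan" else "fixed"
        xm = None if isinstance(self.xmin, str) else self.xmin
        f = fit_powerlaw(X, xmin_policy=policy, xmin=xm,
                         n_min=self.n_min, discrete=self.discrete)
        self.tail_fit_ = f
        self.exponent_, self.xmin_ = f.exponent, f.xmin
        self.n_tail_, self.loglik_, self.ks_ = f.n_tail, f.loglik, f.ks
        return self


class ExponentialTail(BaseEstimator):
    """Shifted-exponential tail estimator; fitted rate in ``rate_``."""

    def __init__(self, xmin: float | str | None = None, n_min: int = DEFAULT_N_MIN):
        self.xmin = xmin
        self.n_min = n_min

    def fit(self, X: np.ndarray, y=None) -> "ExponentialTail":
        policy = "ks_scan" if self.xmin == "scan" else "fixed"
        xm = None if isinstance(self.xmin, str) else self.xmin
        f = fit_exponential(X, xmin_policy=policy, xmin=xm, n_min=self.n_min)
        self.tail_fit_ = f
        self.rate_, self.xmin_ = f.exponent, f.xmin
        self.n_tail_, self.loglik_, self.ks_ = f.n_tail, f.loglik, f.ks
        return self


class TaylorLaw(BaseEstimator):
    """Taylor's-law estimator; fitted slope in ``nu_``."""

    def fit(self, X: CommunityTable | np.ndarray, y=None) -> "TaylorLaw":
        f = taylor_exponent(X)
        self.taylor_fit_ = f
        self.nu_, self.intercept_, self.r2_ = f.nu, f.intercept, f.r2
        self.n_points_, self.n_excluded_ = f.n_points, f.n_excluded
        return self
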
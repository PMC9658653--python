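"""Posterior, preposterior and HPD-interval computations for any prior.

For a Beta prior everything is conjugate: the posterior is
Beta(α + x, β + n − x) and the marginal (preposterior) distribution of
the data is Beta-Binomial.  For any other :class:`~hpdsize.priors.PriorModel`
the posterior kernel θ^x (1−θ)^{n−x} f(θ) is normalized numerically —
adaptive quadrature for the normalizer, a dense log-scale grid with
cumulative Simpson integration for the CDF — and the preposterior pmf is
obtained by quadrature of the same kernel for each outcome.

Two HPD-type interval operations are provided for unimodal posteriors:
the maximal-coverage interval of fixed length (average coverage
criterion) and the minimal-length interval of fixed coverage (average
length criterion).  Both work purely through the posterior CDF/quantile
function, so endpoint density singularities are never evaluated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special, stats
from scipy.interpolate import PchipInterpolator

from .priors import BetaPrior, BSplinePrior, PriorModel

__all__ = [
    "PosteriorDensity",
    "BetaPosterior",
    "NumericPosterior",
    "PredictiveDistribution",
    "CredibleInterval",
    "posterior",
    "predictive_pmf",
    "hpd_fixed_length",
    "hpd_fixed_coverage",
    "MultimodalDensityError",
]

#: grid size for numeric posteriors (odd, so Simpson applies exactly)
_GRID_SIZE = 4001


class MultimodalDensityError(ValueError):
    """Raised when an HPD interval is requested for a clearly multimodal
    density, for which a single interval is not a valid HDI."""


@dataclass
class CredibleInterval:
    """An HPD-type credible interval [lower, lower + length].

    ``is_hpd`` is True when the interval satisfies the HPD conditions:
    equal density at interior endpoints (within tolerance) or anchoring
    at a domain boundary under a monotone tail.
    """

    lower: float
    length: float
    coverage: float
    is_hpd: bool = True

    @property
    def upper(self) -> float:
        return self.lower + self.length

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "length": self.length,
            "coverage": self.coverage,
            "is_hpd": self.is_hpd,
        }


# ---------------------------------------------------------------------------
# posteriors


class PosteriorDensity:
    """Common surface for posterior densities (see subclasses)."""

    prior: PriorModel
    n: int
    x: int
    normalizer: float  # marginal likelihood C(n,x) ∫ θ^x (1-θ)^(n-x) f(θ) dθ

    def density(self, theta):
        raise NotImplementedError

    def cdf(self, theta):
        raise NotImplementedError

    def ppf(self, q):
        raise NotImplementedError

    @property
    def mode(self) -> float:
        raise NotImplementedError

    @property
    def domain(self) -> tuple[float, float]:
        return self.prior.domain


class BetaPosterior(PosteriorDensity):
    """Conjugate posterior Beta(α + x, β + n − x) of a Beta prior."""

    def __init__(self, prior: BetaPrior, n: int, x: int):
        self.prior = prior
        self.n = int(n)
        self.x = int(x)
        self.alpha = prior.alpha + x
        self.beta = prior.beta + n - x
        self._lbeta = special.betaln(self.alpha, self.beta)
        log_norm = (
            special.gammaln(n + 1) - special.gammaln(x + 1)
            - special.gammaln(n - x + 1)
            + self._lbeta - special.betaln(prior.alpha, prior.beta)
        )
        self.log_normalizer = float(log_norm)
        self.normalizer = float(np.exp(log_norm))

    def density(self, theta):
        theta = np.asarray(theta, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logpdf = (
                (self.alpha - 1.0) * np.log(theta)
                + (self.beta - 1.0) * np.log1p(-theta)
                - self._lbeta
            )
        out = np.where((theta < 0) | (theta > 1), -np.inf, logpdf)
        out = np.exp(out)
        return out if out.ndim else float(out)

    def cdf(self, theta):
        theta = np.clip(np.asarray(theta, dtype=float), 0.0, 1.0)
        out = special.betainc(self.alpha, self.beta, theta)
        return out if out.ndim else float(out)

    def ppf(self, q):
        out = special.betaincinv(self.alpha, self.beta, np.asarray(q, dtype=float))
        return out if out.ndim else float(out)

    @property
    def mode(self) -> float:
        a, b = self.alpha, self.beta
        if a > 1.0 and b > 1.0:
            return (a - 1.0) / (a + b - 2.0)
        if a <= 1.0 and b > 1.0:
            return 0.0
        if a > 1.0 and b <= 1.0:
            return 1.0
        return 0.5

    @property
    def is_unimodal(self) -> bool:
        return not (self.alpha < 1.0 and self.beta < 1.0)

    @property
    def modality(self) -> str:
        return "unimodal" if self.is_unimodal else "severe"


def _simpson_weights(grid: np.ndarray) -> np.ndarray:
    """Composite-Simpson weights on a uniform grid with an odd number of
    points."""
    n = len(grid)
    h = (grid[-1] - grid[0]) / (n - 1)
    w = np.full(n, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return w * h / 3.0


class NumericPosterior(PosteriorDensity):
    """Numerically normalized posterior for a generic prior.

    The kernel is accumulated on the log scale; the normalizer uses
    adaptive quadrature split at the prior's spline knots (the integrand
    is piecewise smooth there) and the CDF uses cumulative Simpson on a
    dense grid, interpolated monotonically.
    """

    def __init__(self, prior: PriorModel, n: int, x: int,
                 grid_size: int = _GRID_SIZE):
        if not 0 <= x <= n:
            raise ValueError(f"x={x} outside 0..n={n}")
        self.prior = prior
        self.n = int(n)
        self.x = int(x)
        lo, hi = prior.domain

        grid = np.linspace(lo, hi, grid_size)
        logk = self._log_kernel(grid)
        self._log_scale = float(np.max(logk[np.isfinite(logk)]))
        kern = np.exp(logk - self._log_scale)

        # adaptive-quadrature normalizer, split at spline knots
        points = None
        if isinstance(prior, BSplinePrior):
            points = np.unique(prior.knots).tolist()
        scaled_int, _ = integrate.quad(
            lambda t: float(np.exp(self._log_kernel(t) - self._log_scale)),
            lo, hi, points=points, limit=200, epsabs=1e-12, epsrel=1e-10,
        )
        if scaled_int <= 0:
            raise FloatingPointError("posterior normalizer underflow")
        self._log_int = self._log_scale + float(np.log(scaled_int))
        log_binom = float(
            special.gammaln(n + 1) - special.gammaln(x + 1)
            - special.gammaln(n - x + 1)
        )
        self.log_normalizer = self._log_int + log_binom
        self.normalizer = float(np.exp(self.log_normalizer))

        cum = integrate.cumulative_simpson(kern, x=grid, initial=0.0)
        cum /= cum[-1]
        cum = np.clip(cum, 0.0, 1.0)
        self._grid = grid
        self._cdf_grid = cum
        self._cdf_interp = PchipInterpolator(grid, cum, extrapolate=False)
        # strictly increasing section for quantile interpolation
        keep = np.r_[True, np.diff(cum) > 0]
        self._ppf_q = cum[keep]
        self._ppf_x = grid[keep]
        self._mode = float(grid[int(np.argmax(kern))])

    def _log_kernel(self, theta):
        theta = np.asarray(theta, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lk = np.where(self.x > 0, self.x * np.log(theta), 0.0) + np.where(
                self.n - self.x > 0, (self.n - self.x) * np.log1p(-theta), 0.0
            )
            f = np.asarray(self.prior.density(theta), dtype=float)
            lk = lk + np.where(f > 0, np.log(np.maximum(f, 1e-300)), -np.inf)
        return np.where(np.isfinite(lk), lk, -np.inf)

    def density(self, theta):
        theta = np.asarray(theta, dtype=float)
        out = np.exp(self._log_kernel(theta) - self._log_int)
        return out if out.ndim else float(out)

    def cdf(self, theta):
        lo, hi = self.prior.domain
        theta = np.asarray(theta, dtype=float)
        out = self._cdf_interp(np.clip(theta, lo, hi))
        out = np.where(theta < lo, 0.0, np.where(theta > hi, 1.0, out))
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        out = np.interp(q, self._ppf_q, self._ppf_x)
        return out if out.ndim else float(out)

    @property
    def mode(self) -> float:
        return self._mode

    @property
    def modality(self) -> str:
        from .priors import classify_modality

        dens = np.exp(self._log_kernel(self._grid) - self._log_scale)
        return classify_modality(dens)

    @property
    def is_unimodal(self) -> bool:
        return self.modality == "unimodal"


def posterior(prior: PriorModel, n: int, x: int,
              method: str = "auto") -> PosteriorDensity:
    """Posterior density of the proportion after x successes in n trials.

    ``method="auto"`` uses the conjugate closed form for Beta priors and
    numeric normalization otherwise; ``"quadrature"`` forces the numeric
    path (useful for cross-checks).
    """
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside 0..n={n}")
    if method == "auto" and isinstance(prior, BetaPrior):
        return BetaPosterior(prior, n, x)
    if method not in ("auto", "quadrature"):
        raise ValueError(f"unknown method {method!r}")
    return NumericPosterior(prior, n, x)


# ---------------------------------------------------------------------------
# preposterior (predictive) distribution


@dataclass
class PredictiveDistribution:
    """Preposterior pmf of the number of successes x̃ = 0..n."""

    prior: PriorModel
    n: int
    pmf: np.ndarray

    def support(self, tail_mass: float = 0.0) -> np.ndarray:
        """Outcomes carrying all but ``tail_mass`` of predictive mass."""
        if tail_mass <= 0:
            return np.arange(self.n + 1)
        return np.nonzero(self.pmf > tail_mass / (self.n + 1))[0]


def predictive_pmf(prior: PriorModel, n: int,
                   method: str = "auto") -> PredictiveDistribution:
    """Marginal (preposterior) distribution of the data under the prior.

    Beta prior → closed-form Beta-Binomial; generic prior → Simpson
    quadrature of C(n,x) θ^x (1−θ)^{n−x} f(θ) on a dense grid, then
    normalized.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if method == "auto" and isinstance(prior, BetaPrior):
        pmf = stats.betabinom.pmf(np.arange(n + 1), n, prior.alpha, prior.beta)
        return PredictiveDistribution(prior, n, np.asarray(pmf, dtype=float))
    if method not in ("auto", "quadrature"):
        raise ValueError(f"unknown method {method!r}")
    lo, hi = prior.domain
    grid = np.linspace(lo, hi, _GRID_SIZE)
    w = _simpson_weights(grid) * np.asarray(prior.density(grid), dtype=float)
    xs = np.arange(n + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_theta = np.log(grid)[None, :]
        log_1mt = np.log1p(-grid)[None, :]
        logw = np.where(xs > 0, xs * log_theta, 0.0) + np.where(
            n - xs > 0, (n - xs) * log_1mt, 0.0
        )
    logw += (special.gammaln(n + 1) - special.gammaln(xs + 1)
             - special.gammaln(n - xs + 1))
    pmf = np.exp(np.where(np.isfinite(logw), logw, -np.inf)) @ w
    total = pmf.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("predictive normalization failed")
    return PredictiveDistribution(prior, n, pmf / total)


# ---------------------------------------------------------------------------
# HPD intervals


def _check_unimodal(post: PosteriorDensity) -> None:
    modality = getattr(post, "modality", "unimodal")
    if modality == "severe":
        raise MultimodalDensityError(
            "posterior density appears severely multimodal; a single HPD "
            "interval is not a valid highest-density region"
        )


def _hpd_flag(post: PosteriorDensity, lower: float, upper: float,
              tol: float = 1e-6) -> bool:
    lo, hi = post.domain
    eps = 1e-9 * (hi - lo)
    if lower <= lo + eps or upper >= hi - eps:
        return True  # boundary-anchored under a monotone tail
    f_lo = float(post.density(lower))
    f_up = float(post.density(upper))
    scale = max(float(post.density(post.mode)), 1.0)
    return abs(f_lo - f_up) <= tol * scale


def hpd_fixed_length(post: PosteriorDensity, l: float) -> CredibleInterval:
    """Maximal-coverage interval of fixed length ``l``.

    Maximizes cdf(a + l) − cdf(a) over the lower bound a by bounded
    scalar optimization with multi-start at the domain edges and around
    the mode; ties (flat stretches) break toward the smallest lower
    bound.
    """
    lo, hi = post.domain
    width = hi - lo
    if not 0 < l <= width + 1e-12:
        raise ValueError(f"length must be in (0, {width}]")
    if l >= width:
        return CredibleInterval(lo, width, 1.0, True)
    _check_unimodal(post)

    a_max = hi - l

    def neg_cov(a: float) -> float:
        return -(float(post.cdf(a + l)) - float(post.cdf(a)))

    candidates = [lo, a_max]
    mode = post.mode
    for start in (mode - l, mode - l / 2.0):
        candidates.append(min(max(start, lo), a_max))
    res = optimize.minimize_scalar(
        neg_cov, bounds=(lo, a_max), method="bounded",
        options={"xatol": 1e-10},
    )
    candidates.append(float(res.x))
    best_a, best_cov = None, -1.0
    for a in sorted(set(candidates)):
        cov = -neg_cov(a)
        if cov > best_cov + 1e-12:
            best_a, best_cov = a, cov
    cov = min(max(best_cov, 0.0), 1.0)
    return CredibleInterval(best_a, l, cov, _hpd_flag(post, best_a, best_a + l))


def hpd_fixed_coverage(post: PosteriorDensity, coverage: float) -> CredibleInterval:
    """Minimal-length interval of fixed posterior ``coverage``.

    Writes the interval as [Q(t), Q(t + coverage)] with Q the posterior
    quantile function and minimizes its length over the lower tail mass
    t ∈ [0, 1 − coverage]; boundary-anchored solutions (t = 0 or
    t = 1 − coverage) arise naturally for monotone densities.
    """
    lo, hi = post.domain
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if coverage >= 1.0:
        return CredibleInterval(lo, hi - lo, 1.0, True)
    _check_unimodal(post)

    t_max = 1.0 - coverage

    def length(t: float) -> float:
        return float(post.ppf(t + coverage)) - float(post.ppf(t))

    res = optimize.minimize_scalar(
        length, bounds=(0.0, t_max), method="bounded",
        options={"xatol": 1e-12},
    )
    candidates = [0.0, t_max, float(res.x)]
    best_t, best_len = None, np.inf
    for t in sorted(set(candidates)):
        ln = length(t)
        if ln < best_len - 1e-12:
            best_t, best_len = t, ln
    lower = float(post.ppf(best_t))
    upper = float(post.ppf(best_t + coverage))
    return CredibleInterval(
        lower, upper - lower, coverage, _hpd_flag(post, lower, upper)
    )
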
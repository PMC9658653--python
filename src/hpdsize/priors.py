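"""Prior models for a binomial proportion.

Two families are supported behind one :class:`PriorModel` contract:

* **Beta priors** moment-matched to pooled expert opinion and discounted
  with a power prior.  Writing the matched Beta kernel exponents as
  (α₀, β₀), a discount factor d₀ ∈ [0, 1] yields the operating prior
  Beta(α₀·d₀ + 1, β₀·d₀ + 1); d₀ = 0 recovers the flat Beta(1, 1) and
  (1 − d₀)·100 is the percentage of expert information discounted.

* **Semiparametric B-spline priors** whose CDF is a monotone linear
  combination of B-splines fitted among elicited expert quantiles by a
  convex quadratic program balancing goodness of fit against distance
  from the uniform distribution (weight φ).

Both expose density, CDF, moments, sampling, a unimodality flag, and an
effective sample size.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import BSpline, PPoly

from .elicitation import ElicitedQuantiles, PanelSummary

__all__ = [
    "PriorModel",
    "BetaPrior",
    "BSplinePrior",
    "beta_from_moments",
    "discount_beta",
    "fit_bspline_prior",
    "prior_ess",
    "SCENARIOS",
    "beta_scenario_prior",
    "bspline_scenario_prior",
]


def classify_modality(values: np.ndarray) -> str:
    """Classify a densely gridded density as ``"unimodal"``, ``"mild"``
    or ``"severe"`` multimodal.

    Peaks (including boundary peaks) with prominence below 5% of the
    maximum are treated as numerical wiggle.  Several retained peaks are
    *severe* when some valley between adjacent peaks drops below half of
    the smaller neighbouring peak — the regime where a single interval
    stops being a sensible highest-density region because the HDI
    becomes discontinuous.
    """
    from scipy.signal import find_peaks

    v = np.asarray(values, dtype=float)
    vmax = float(v.max())
    if vmax <= 0:
        return "unimodal"
    padded = np.r_[-np.inf, v, -np.inf]
    peaks, _ = find_peaks(padded, prominence=0.05 * vmax)
    peaks = peaks - 1
    if len(peaks) <= 1:
        return "unimodal"
    for left, right in zip(peaks[:-1], peaks[1:]):
        valley = float(v[left: right + 1].min())
        if valley < 0.5 * min(v[left], v[right]):
            return "severe"
    return "mild"


class PriorModel(ABC):
    """Common contract for priors on a bounded interval."""

    domain: tuple[float, float] = (0.0, 1.0)

    @property
    def modality(self) -> str:
        """``"unimodal"``, ``"mild"`` or ``"severe"`` (gridded check)."""
        lo, hi = self.domain
        g = np.linspace(lo, hi, 4001)
        return classify_modality(np.asarray(self.density(g), dtype=float))

    @abstractmethod
    def density(self, theta): ...

    @abstractmethod
    def cdf(self, theta): ...

    @property
    @abstractmethod
    def mean(self) -> float: ...

    @property
    @abstractmethod
    def variance(self) -> float: ...

    @abstractmethod
    def sample(self, k: int, seed=None) -> np.ndarray: ...

    @property
    @abstractmethod
    def is_unimodal(self) -> bool: ...

    @property
    def mode(self) -> float:
        """Location of the highest density (grid-refined by default)."""
        lo, hi = self.domain
        grid = np.linspace(lo, hi, 4097)
        vals = np.asarray(self.density(grid), dtype=float)
        vals = np.where(np.isfinite(vals), vals, -np.inf)
        return float(grid[int(np.argmax(vals))])


# ---------------------------------------------------------------------------
# Beta priors


class BetaPrior(PriorModel):
    """Beta(α, β) prior on (0, 1).

    ``provenance`` may record how the prior was elicited: the pooled
    moments (mu, sigma2), matched kernel exponents (alpha0, beta0) and
    the power-prior discount d0.
    """

    def __init__(self, alpha: float, beta: float, provenance: dict | None = None):
        if alpha <= 0 or beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.provenance = dict(provenance or {})
        self._dist = stats.beta(self.alpha, self.beta)

    def __repr__(self) -> str:
        return f"BetaPrior(alpha={self.alpha:g}, beta={self.beta:g})"

    def density(self, theta):
        return self._dist.pdf(theta)

    def cdf(self, theta):
        return self._dist.cdf(theta)

    def ppf(self, q):
        return self._dist.ppf(q)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        a, b = self.alpha, self.beta
        return a * b / ((a + b) ** 2 * (a + b + 1.0))

    def sample(self, k: int, seed=None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.beta(self.alpha, self.beta, size=k)

    @property
    def is_unimodal(self) -> bool:
        # only alpha < 1 AND beta < 1 puts modes at both endpoints
        return not (self.alpha < 1.0 and self.beta < 1.0)

    @property
    def modality(self) -> str:
        return "unimodal" if self.is_unimodal else "severe"

    @property
    def mode(self) -> float:
        a, b = self.alpha, self.beta
        if a > 1.0 and b > 1.0:
            return (a - 1.0) / (a + b - 2.0)
        if a <= 1.0 and b > 1.0:
            return 0.0
        if a > 1.0 and b <= 1.0:
            return 1.0
        return 0.5  # flat Beta(1,1); any point works

    def to_dict(self) -> dict:
        return {
            "family": "beta",
            "alpha": self.alpha,
            "beta": self.beta,
            "provenance": self.provenance,
        }


def beta_from_moments(summary: PanelSummary | tuple[float, float]) -> tuple[float, float]:
    """Beta shape parameters matching a mean and variance.

    Given pooled opinion moments (μ, σ²) with σ² < μ(1−μ), the matched
    Beta(a, b) has

        a = μ·(μ(1−μ)/σ² − 1),    b = a·(1/μ − 1).

    Accepts a :class:`~hpdsize.elicitation.PanelSummary` or a plain
    ``(mean, variance)`` pair.
    """
    if isinstance(summary, PanelSummary):
        mu, var = summary.mean, summary.variance
    else:
        mu, var = float(summary[0]), float(summary[1])
    if not 0.0 < mu < 1.0:
        raise ValueError("mean must be in (0, 1)")
    if var <= 0 or var >= mu * (1.0 - mu):
        raise ValueError(
            f"moment matching requires 0 < variance < mean*(1-mean) "
            f"= {mu * (1 - mu):.6g}, got {var:.6g}"
        )
    a = mu * (mu * (1.0 - mu) / var - 1.0)
    b = a * (1.0 / mu - 1.0)
    return a, b


def discount_beta(alpha0: float, beta0: float, d0: float,
                  provenance: dict | None = None) -> BetaPrior:
    """Power-prior discount of elicited Beta kernel exponents.

    (α₀, β₀) are the success/failure kernel exponents of the elicited
    information (i.e. matched Beta shapes minus one).  Raising the
    elicited kernel to the power d₀ and combining with a flat initial
    prior gives Beta(α₀·d₀ + 1, β₀·d₀ + 1):

    * d₀ = 0 → Beta(1, 1), a 100% discount of the expert information;
    * d₀ = 1 → the full elicited prior, 0% discount.
    """
    if not 0.0 <= d0 <= 1.0:
        raise ValueError("d0 must lie in [0, 1]")
    if alpha0 < 0 or beta0 < 0:
        raise ValueError("kernel exponents must be non-negative")
    prov = dict(provenance or {})
    prov.update(
        {"alpha0": alpha0, "beta0": beta0, "d0": d0,
         "discount_pct": (1.0 - d0) * 100.0}
    )
    return BetaPrior(alpha0 * d0 + 1.0, beta0 * d0 + 1.0, provenance=prov)


# ---------------------------------------------------------------------------
# B-spline semiparametric priors


def _gauss_legendre_piecewise(breaks: np.ndarray, npts: int):
    """GL nodes/weights on each subinterval of a strictly increasing grid."""
    xg, wg = np.polynomial.legendre.leggauss(npts)
    a = breaks[:-1][:, None]
    b = breaks[1:][:, None]
    nodes = 0.5 * (b - a) * (xg[None, :] + 1.0) + a
    weights = 0.5 * (b - a) * wg[None, :]
    return nodes.ravel(), weights.ravel()


class BSplinePrior(PriorModel):
    """Semiparametric prior with a monotone B-spline CDF.

    The CDF is F(y) = Σ_i c_i B_i(y) on a clamped knot vector over
    ``domain``; coefficients are non-decreasing with c₋ₘ = 0 and c_S = 1
    so F is a genuine CDF and its derivative a density.  Constructed by
    :func:`fit_bspline_prior`; ``fit_error`` records the achieved mean
    squared deviation Δ = (1/p) Σ (α_i − F(y_{α_i}))² at the fitted
    quantiles.
    """

    def __init__(
        self,
        degree: int,
        knots: Sequence[float],
        coefficients: Sequence[float],
        phi: float,
        domain: tuple[float, float] = (0.0, 1.0),
        fit_error: float = float("nan"),
    ):
        self.degree = int(degree)
        self.knots = np.asarray(knots, dtype=float)
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.phi = float(phi)
        self.domain = (float(domain[0]), float(domain[1]))
        self.fit_error = float(fit_error)
        if np.any(np.diff(self.coefficients) < -1e-9):
            raise ValueError("CDF spline coefficients must be non-decreasing")
        if abs(self.coefficients[0]) > 1e-9 or abs(self.coefficients[-1] - 1) > 1e-9:
            raise ValueError("CDF spline must run from 0 to 1")
        self._cdf_spline = BSpline(self.knots, self.coefficients, self.degree,
                                   extrapolate=False)
        self._pdf_spline = self._cdf_spline.derivative()
        self._pdf_ppoly = PPoly.from_spline(self._pdf_spline, extrapolate=False)
        self._cdf_ppoly = PPoly.from_spline(self._cdf_spline, extrapolate=False)

    def __repr__(self) -> str:
        return (f"BSplinePrior(degree={self.degree}, phi={self.phi:g}, "
                f"domain={self.domain})")

    def _clamped(self, theta):
        lo, hi = self.domain
        return np.clip(np.asarray(theta, dtype=float), lo, hi)

    def density(self, theta):
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.domain
        out = self._pdf_ppoly(self._clamped(theta))
        out = np.where((theta < lo) | (theta > hi), 0.0, out)
        # fitted coefficients are monotone, so any negative is roundoff
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)

    def cdf(self, theta):
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.domain
        out = self._cdf_ppoly(self._clamped(theta))
        out = np.where(theta < lo, 0.0, np.where(theta > hi, 1.0, out))
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        q = np.atleast_1d(np.asarray(q, dtype=float))
        lo, hi = self.domain
        out = np.empty_like(q)
        for i, qi in enumerate(q):
            if qi <= 0.0:
                out[i] = lo
            elif qi >= 1.0:
                out[i] = hi
            else:
                roots = self._cdf_ppoly.solve(qi, extrapolate=False)
                # flat CDF stretches give several roots; take the smallest
                out[i] = float(np.min(roots)) if len(roots) else hi
        return out if out.shape != (1,) else float(out[0])

    def _moment_nodes(self):
        breaks = np.unique(self.knots)
        return _gauss_legendre_piecewise(breaks, self.degree + 2)

    @property
    def mean(self) -> float:
        x, w = self._moment_nodes()
        return float(np.sum(w * x * self.density(x)))

    @property
    def variance(self) -> float:
        x, w = self._moment_nodes()
        m = self.mean
        return float(np.sum(w * (x - m) ** 2 * self.density(x)))

    def sample(self, k: int, seed=None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return np.asarray(self.ppf(rng.uniform(size=k)), dtype=float)

    @property
    def is_unimodal(self) -> bool:
        # variation-diminishing bound first: sign changes in the density
        # spline's derivative coefficients bound the number of modes
        dens = self._pdf_spline
        deriv_coeffs = dens.derivative().c[: len(dens.c) - 1]
        signs = np.sign(deriv_coeffs[np.abs(deriv_coeffs) > 1e-10])
        changes = int(np.sum(signs[1:] != signs[:-1])) if len(signs) else 0
        if changes <= 1:
            return True
        return self.modality == "unimodal"

    def to_dict(self) -> dict:
        return {
            "family": "bspline",
            "degree": self.degree,
            "knots": self.knots.tolist(),
            "coefficients": self.coefficients.tolist(),
            "phi": self.phi,
            "domain": list(self.domain),
            "fit_error": self.fit_error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplinePrior":
        return cls(
            degree=d["degree"], knots=d["knots"],
            coefficients=d["coefficients"], phi=d["phi"],
            domain=tuple(d["domain"]), fit_error=d.get("fit_error", float("nan")),
        )


def _density_gram(knots: np.ndarray, degree: int) -> np.ndarray:
    """Exact Gram matrix ∫ B_i B_j of the density-scale basis.

    The density basis has degree ``degree − 1`` on ``knots[1:-1]``;
    products are polynomials of degree 2(degree−1), integrated exactly by
    Gauss–Legendre with ``degree`` points per inter-knot interval.
    """
    dk = knots[1:-1]
    deg = degree - 1
    breaks = np.unique(knots)
    x, w = _gauss_legendre_piecewise(breaks, max(degree, 1))
    # clamp right edge inside for design_matrix evaluation
    x = np.clip(x, dk[0], np.nextafter(dk[-1], -np.inf))
    B = BSpline.design_matrix(x, dk, deg).toarray()
    return B.T @ (B * w[:, None])


def fit_bspline_prior(
    q: ElicitedQuantiles,
    degree: int = 4,
    phi: float = 1.0,
    inner_knots: Sequence[float] | None = None,
) -> BSplinePrior:
    """Fit the semiparametric B-spline prior to elicited quantiles.

    Solves the convex quadratic program

        min_{F}  Σ_i (α_i − F(y_{α_i}))²  +  φ ∫ f(y)² dy
        s.t.     F monotone CDF on the domain (F(y₀)=0, F(y₁)=1)

    over CDFs F that are degree-``degree`` splines on a clamped knot
    vector; the penalty ∫f² is smallest (=1/(y₁−y₀)) for the uniform
    density, so φ trades expert fidelity against uninformativeness.
    Inner knots default to the elicited quantile values themselves.

    Monotonicity plus the endpoint conditions are enforced by writing
    the coefficient increments as a point on the probability simplex;
    the penalty's Gram matrix is computed exactly, and the program is
    solved with SLSQP using analytic gradients.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if degree < 2:
        raise ValueError("degree must be at least 2")
    lo, hi = q.domain
    if inner_knots is None:
        # single knots at the distinct elicited quantile values
        inner_knots = sorted(set(q.values))
    inner = np.asarray(sorted(float(v) for v in inner_knots), dtype=float)
    inner = inner[(inner > lo) & (inner < hi)]
    _, counts = np.unique(inner, return_counts=True)
    if len(counts) and counts.max() > degree:
        raise ValueError("inner knot multiplicity cannot exceed the degree")
    m = int(degree)
    knots = np.concatenate([
        np.full(m + 1, lo), inner, np.full(m + 1, hi)
    ])
    n_coef = len(knots) - m - 1

    levels = np.asarray(q.levels, dtype=float)
    values = np.clip(np.asarray(q.values, dtype=float),
                     lo, np.nextafter(hi, -np.inf))
    A = BSpline.design_matrix(values, knots, m).toarray()

    # penalty matrix on CDF coefficients: c -> density coeffs d = D c
    spans = knots[m + 1: m + n_coef] - knots[1: n_coef]
    D = np.zeros((n_coef - 1, n_coef))
    idx = np.arange(n_coef - 1)
    D[idx, idx] = -m / spans
    D[idx, idx + 1] = m / spans
    G = _density_gram(knots, m)
    P = D.T @ G @ D

    # c = (0, cumsum(delta)), delta on the simplex
    L = np.tril(np.ones((n_coef - 1, n_coef - 1)))
    M = A[:, 1:] @ L
    Q = L.T @ P[1:, 1:] @ L
    H = M.T @ M + phi * Q
    g = -M.T @ levels

    def objective(d):
        r = M @ d - levels
        return float(r @ r + phi * d @ (Q @ d))

    def grad(d):
        return 2.0 * (H @ d + g)

    x0 = np.full(n_coef - 1, 1.0 / (n_coef - 1))
    res = optimize.minimize(
        objective, x0, jac=grad, hess=lambda d: 2.0 * H,
        method="trust-constr",
        bounds=optimize.Bounds(0.0, 1.0),
        constraints=optimize.LinearConstraint(np.ones(n_coef - 1), 1.0, 1.0),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000},
    )
    if res.status not in (1, 2):  # gtol / xtol termination
        raise RuntimeError(f"QP solver failed: {res.message}")
    delta = np.maximum(res.x, 0.0)
    s = delta.sum()
    if abs(s - 1.0) > 1e-10:
        delta = delta / s
    coef = np.concatenate([[0.0], np.cumsum(delta)])
    coef[-1] = 1.0

    fit_vals = A @ coef
    fit_error = float(np.mean((levels - fit_vals) ** 2))
    return BSplinePrior(degree=m, knots=knots, coefficients=coef, phi=phi,
                        domain=(lo, hi), fit_error=fit_error)


# ---------------------------------------------------------------------------
# Effective sample size and scenario presets


def prior_ess(prior: PriorModel) -> float:
    """Prior effective sample size in patients.

    For a Beta(α, β) prior the ESS is α + β.  For any other prior the
    ESS is that of the Beta matched to the prior's mean and variance —
    μ(1−μ)/σ² − 1 — which requires σ² < μ(1−μ).
    """
    if isinstance(prior, BetaPrior):
        return prior.alpha + prior.beta
    mu, var = prior.mean, prior.variance
    if var <= 0 or var >= mu * (1.0 - mu):
        raise ValueError(
            "moment-matched ESS undefined: variance must be in "
            f"(0, mean*(1-mean)) = (0, {mu * (1 - mu):.6g}), got {var:.6g}"
        )
    return mu * (1.0 - mu) / var - 1.0


#: Scenario presets: power-prior discount d0 for Beta priors and the
#: balancing factor phi for B-spline priors ("delta" = calibrate phi to
#: the data-driven elicitation error).
SCENARIOS = {
    "informative": {"d0": 1.0, "phi": "delta"},
    "low-informative": {"d0": 0.5, "phi": 1.0},
    "uninformative": {"d0": 0.0, "phi": 45.0},
}


def beta_scenario_prior(summary: PanelSummary, scenario: str,
                        round_prior: bool = True) -> BetaPrior:
    """Beta prior for a named informativeness scenario.

    Moment-matches the pooled opinion, optionally rounds the matched
    shapes to the nearest integers (``round_prior``, the convention that
    turns pooled moments (0.2625, 0.00625) into the operating prior
    Beta(8, 22)), and applies the scenario's power-prior discount.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    a, b = beta_from_moments(summary)
    prov = {"mu": summary.mean, "sigma2": summary.variance,
            "matched_alpha": a, "matched_beta": b, "rounded": round_prior}
    if round_prior:
        a, b = float(round(a)), float(round(b))
    return discount_beta(a - 1.0, b - 1.0, SCENARIOS[scenario]["d0"],
                         provenance=prov)


def bspline_scenario_prior(q: ElicitedQuantiles, scenario: str,
                           degree: int = 4) -> BSplinePrior:
    """B-spline prior for a named informativeness scenario.

    The informative scenario calibrates φ to the data-driven elicitation
    error Δ*; the others use the preset φ.
    """
    from .elicitation import data_driven_delta, phi_from_delta

    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    phi = SCENARIOS[scenario]["phi"]
    if phi == "delta":
        phi = phi_from_delta(q, data_driven_delta(q), degree=degree)
    return fit_bspline_prior(q, degree=degree, phi=float(phi))
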
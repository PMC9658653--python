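"""Sample-size criteria: GACC, GALC, GWOC and the frequentist benchmark.

Three preposterior criteria, each generalized to any unimodal prior on
the proportion:

* **GACC** (average coverage): fix the HPD length l, require the
  predictive-weighted average posterior coverage to reach 1−α.
* **GALC** (average length): fix the coverage 1−α, require the
  predictive-weighted average HPD length to come down to l.
* **GWOC** (worst outcome): fix both, require the minimum coverage over
  a worst-outcome data subset x* to reach 1−α.

For Beta(c, d)-style priors the worst-outcome subset has a closed
piecewise form in the prior expected successes/failures (c, d); for
other priors c is obtained by prior-predictive resampling.  The optimal
n is the smallest integer meeting the criterion inside a grid searched
around ±50% of the frequentist precision estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
from scipy import stats

from .inference import hpd_fixed_coverage, hpd_fixed_length, posterior, predictive_pmf
from .priors import BetaPrior, PriorModel

__all__ = [
    "DesignSpec",
    "CriterionResult",
    "frequentist_n",
    "average_coverage",
    "average_length",
    "worst_case_coverage",
    "worst_outcome_subset",
    "resample_expected_successes",
    "search_optimal_n",
    "gacc",
    "galc",
    "gwoc",
]

#: predictive outcomes with less mass than this are skipped in averages
#: (total neglected mass < (n+1)·1e−12, far below any decision margin)
_PMF_TAIL = 1e-12


@dataclass
class DesignSpec:
    """Design parameters for a sample-size search.

    ``length`` is the HPD interval length l on the probability scale and
    ``coverage`` the credibility level 1−α.  ``search_bounds`` overrides
    the frequentist-anchored grid; ``woc_space`` selects the GWOC data
    subspace (``"formula"`` — the closed-form x* subset, ``"full"`` — all
    outcomes, ``"predictive-band"`` — the central 95% predictive mass).
    ``c``/``d`` override the prior expected successes/failures used by
    the x* formula; ``seed`` drives GWOC prior-predictive resampling.
    """

    prior: PriorModel
    length: float = 0.2
    coverage: float = 0.95
    search_bounds: tuple[int, int] | None = None
    woc_space: str = "formula"
    c: float | None = None
    d: float | None = None
    seed: int = 0
    resample_draws: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.length < 1.0:
            raise ValueError("length must be in (0, 1)")
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must be in (0, 1)")
        if self.woc_space not in ("formula", "full", "predictive-band"):
            raise ValueError(f"unknown woc_space {self.woc_space!r}")


@dataclass
class CriterionResult:
    """Outcome of a criterion search.

    ``curve`` maps each scanned n to its diagnostic (average coverage
    for GACC, average length for GALC, worst-case coverage for GWOC).
    """

    criterion: str
    n_opt: int | None
    curve: dict[int, float]
    search_bounds: tuple[int, int]
    frequentist_n: int | None = None
    boundary_expanded: bool = False
    x_star: dict[int, list[int]] | None = None
    c: float | None = None
    d: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "n_opt": self.n_opt,
            "curve": {str(k): v for k, v in sorted(self.curve.items())},
            "search_bounds": list(self.search_bounds),
            "frequentist_n": self.frequentist_n,
            "boundary_expanded": self.boundary_expanded,
            "x_star": {str(k): v for k, v in (self.x_star or {}).items()},
            "c": self.c,
            "d": self.d,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# frequentist benchmark


def frequentist_n(p: float, l: float = 0.2, level: float = 0.95) -> int:
    """Precision-based one-arm sample size for a proportion.

    Smallest n for which a Wald confidence interval at the given level
    and anticipated proportion p has total length l:
    n = ⌈ z² p(1−p) / (l/2)² ⌉.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if not 0.0 < l < 1.0:
        raise ValueError("l must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return int(math.ceil(z * z * p * (1.0 - p) / (l / 2.0) ** 2))


# ---------------------------------------------------------------------------
# per-n criterion diagnostics


def average_coverage(prior: PriorModel, n: int, length: float) -> float:
    """Predictive-weighted mean coverage of fixed-length HPD intervals."""
    pred = predictive_pmf(prior, n)
    total = 0.0
    for x in np.nonzero(pred.pmf > _PMF_TAIL)[0]:
        post = posterior(prior, n, int(x))
        total += pred.pmf[x] * hpd_fixed_length(post, length).coverage
    return float(total)


def average_length(prior: PriorModel, n: int, coverage: float) -> float:
    """Predictive-weighted mean length of fixed-coverage HPD intervals."""
    pred = predictive_pmf(prior, n)
    total = 0.0
    kept = 0.0
    for x in np.nonzero(pred.pmf > _PMF_TAIL)[0]:
        post = posterior(prior, n, int(x))
        total += pred.pmf[x] * hpd_fixed_coverage(post, coverage).length
        kept += pred.pmf[x]
    # renormalize over the retained outcomes so skipped tail mass
    # cannot bias the average downward
    return float(total / kept)


def worst_outcome_subset(n: int, c: float, d: float) -> list[int]:
    """Worst-outcome success counts x* for the fixed-length criterion.

    Closed-form piecewise rule in the prior expected successes c and
    failures d::

        x* = (n+c+d±1)/2 − c   if n+c+d odd  and n ≥ |d−c|
        x* = (n+c+d)/2  − c    if n+c+d even and n ≥ |d−c|
        x* = n                 if 0 ≤ n ≤ |d−c|

    Non-integer c, d make n+c+d neither odd nor even; both the floor and
    ceiling of the central candidate are then returned and the caller
    takes the worst coverage over them.  Results are rounded to integers
    and clipped to [0, n].
    """
    if c <= 0 or d <= 0:
        raise ValueError("prior expected successes/failures must be positive")
    if n <= abs(d - c):
        return [int(n)]
    s = n + c + d
    if abs(s - round(s)) < 1e-9:
        s_int = int(round(s))
        if s_int % 2 == 1:
            cands = [(s_int + 1) / 2.0 - c, (s_int - 1) / 2.0 - c]
        else:
            cands = [s_int / 2.0 - c]
    else:
        cands = [s / 2.0 - c]
    ints: set[int] = set()
    for v in cands:  # non-integer candidates bracket to both neighbours
        if abs(v - round(v)) < 1e-9:
            ints.add(int(round(v)))
        else:
            ints.update((math.floor(v), math.ceil(v)))
    return sorted(int(min(max(v, 0), n)) for v in ints)


def resample_expected_successes(prior: PriorModel, n: int,
                                draws: int = 1000, seed=None) -> float:
    """Prior expected successes c by prior-predictive resampling.

    Draws ``draws`` proportions from the prior, simulates one
    binomial(n, θ) experiment per draw and returns the median count.
    Deterministic for a given seed.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    rng = np.random.default_rng(seed)
    thetas = np.asarray(prior.sample(draws, rng), dtype=float)
    xs = rng.binomial(n, np.clip(thetas, 0.0, 1.0))
    return float(np.median(xs))


def _expected_counts(spec: DesignSpec, n: int) -> tuple[float, float]:
    """Prior expected successes/failures (c, d) for the x* rule."""
    if spec.c is not None and spec.d is not None:
        return float(spec.c), float(spec.d)
    if isinstance(spec.prior, BetaPrior):
        return spec.prior.alpha, spec.prior.beta
    c = resample_expected_successes(
        spec.prior, n, draws=spec.resample_draws, seed=spec.seed
    )
    c = min(max(c, 0.5), n - 0.5)  # keep both counts positive
    return c, n - c


def worst_case_coverage(spec: DesignSpec, n: int,
                        x_star_log: dict[int, list[int]] | None = None) -> float:
    """Minimum fixed-length HPD coverage over the worst-outcome subset."""
    prior, l = spec.prior, spec.length
    if spec.woc_space == "full":
        xs: Iterable[int] = range(n + 1)
    elif spec.woc_space == "predictive-band":
        # central 95% of predictive mass (mWOC-style restriction)
        pmf = predictive_pmf(prior, n).pmf
        cdf_hi = np.cumsum(pmf)
        cdf_lo = cdf_hi - pmf
        xs = np.nonzero((cdf_hi >= 0.025) & (cdf_lo <= 0.975))[0]
    else:
        c, d = _expected_counts(spec, n)
        xs = worst_outcome_subset(n, c, d)
        if x_star_log is not None:
            x_star_log[n] = list(xs)
    worst = 1.0
    for x in xs:
        post = posterior(prior, n, int(x))
        worst = min(worst, hpd_fixed_length(post, l).coverage)
    return worst


# ---------------------------------------------------------------------------
# the search policy


def default_search_bounds(n_hat: int) -> tuple[int, int]:
    """Grid-search bounds around ±50% of the frequentist estimate n̂."""
    if n_hat < 1:
        raise ValueError("frequentist estimate must be >= 1")
    return max(1, math.ceil(0.5 * n_hat)), math.ceil(1.5 * n_hat)


def search_optimal_n(
    meets: Callable[[int], tuple[bool, float]],
    bounds: tuple[int, int],
) -> tuple[int | None, dict[int, float], bool]:
    """Ascending scan for the smallest n meeting a criterion.

    ``meets(n)`` returns (criterion satisfied, diagnostic value).  If no
    n in ``bounds`` qualifies, the upper bound is doubled once and the
    extension scanned, flagging the expansion; a still-unmet criterion
    returns n_opt None.
    """
    lo, hi = bounds
    curve: dict[int, float] = {}
    for n in range(lo, hi + 1):
        ok, val = meets(n)
        curve[n] = val
        if ok:
            return n, curve, False
    for n in range(hi + 1, 2 * hi + 1):
        ok, val = meets(n)
        curve[n] = val
        if ok:
            return n, curve, True
    return None, curve, True


def _resolve_bounds(spec: DesignSpec) -> tuple[tuple[int, int], int]:
    n_hat = frequentist_n(spec.prior.mean, spec.length, spec.coverage)
    bounds = spec.search_bounds or default_search_bounds(n_hat)
    return bounds, n_hat


def _require_unimodal(spec: DesignSpec) -> None:
    modality = spec.prior.modality
    if modality == "severe":
        raise ValueError(
            "sample-size criteria require a (not severely multimodal) "
            "unimodal prior; the supplied prior has well-separated modes"
        )
    if modality == "mild":
        warnings.warn(
            "prior density is mildly multimodal; HPD intervals are "
            "computed as the narrowest interval containing the mass and "
            "may bridge shallow valleys between modes",
            stacklevel=3,
        )


def gacc(spec: DesignSpec) -> CriterionResult:
    """Generalized average coverage criterion.

    Smallest n whose predictive-weighted average coverage of
    fixed-length-l HPD intervals reaches the target 1−α.
    """
    _require_unimodal(spec)
    bounds, n_hat = _resolve_bounds(spec)

    def meets(n: int) -> tuple[bool, float]:
        val = average_coverage(spec.prior, n, spec.length)
        return val >= spec.coverage, val

    n_opt, curve, expanded = search_optimal_n(meets, bounds)
    return CriterionResult("GACC", n_opt, curve, bounds, n_hat, expanded)


def galc(spec: DesignSpec) -> CriterionResult:
    """Generalized average length criterion.

    Smallest n whose predictive-weighted average length of
    coverage-(1−α) HPD intervals comes down to the target l.
    """
    _require_unimodal(spec)
    bounds, n_hat = _resolve_bounds(spec)

    def meets(n: int) -> tuple[bool, float]:
        val = average_length(spec.prior, n, spec.coverage)
        return val <= spec.length, val

    n_opt, curve, expanded = search_optimal_n(meets, bounds)
    return CriterionResult("GALC", n_opt, curve, bounds, n_hat, expanded)


def gwoc(spec: DesignSpec) -> CriterionResult:
    """Generalized worst outcome criterion.

    Smallest n for which every outcome in the worst-outcome data
    subspace retains fixed-length HPD coverage of at least 1−α.  The
    subspace is selected by ``spec.woc_space``.
    """
    _require_unimodal(spec)
    bounds, n_hat = _resolve_bounds(spec)
    x_star_log: dict[int, list[int]] = {}

    def meets(n: int) -> tuple[bool, float]:
        val = worst_case_coverage(spec, n, x_star_log)
        return val >= spec.coverage, val

    n_opt, curve, expanded = search_optimal_n(meets, bounds)
    c = d = None
    if spec.woc_space == "formula" and n_opt is not None:
        c, d = _expected_counts(spec, n_opt)
    return CriterionResult(
        "GWOC", n_opt, curve, bounds, n_hat, expanded,
        x_star=x_star_log or None, c=c, d=d, seed=spec.seed,
    )
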
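"""Pooling of expert point opinions and quantile-based elicitation summaries.

A panel of experts each states a point guess for a probability (e.g. the
rate of a binary safety event in a planned single-arm trial).  The guesses
are pooled into a mean and variance — the moments later matched by a Beta
prior — and into empirical quartiles, which drive the semiparametric
B-spline prior.  The module also computes the data-driven elicitation
error Δ* used to calibrate the spline's uniform-penalty weight φ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpertPanel",
    "PanelSummary",
    "ElicitedQuantiles",
    "pool_opinions",
    "elicited_quartiles",
    "data_driven_delta",
    "phi_from_delta",
    "load_panel",
]


@dataclass(frozen=True)
class ExpertPanel:
    """A panel of expert point opinions about a probability.

    Parameters
    ----------
    opinions
        One guess per expert, each strictly inside (0, 1).
    label
        Free-text description of the panel.
    """

    opinions: tuple[float, ...]
    label: str = ""

    def __init__(self, opinions: Sequence[float], label: str = "") -> None:
        opinions = tuple(float(o) for o in opinions)
        if len(opinions) < 2:
            raise ValueError(
                f"a panel needs at least 2 opinions, got {len(opinions)}"
            )
        for o in opinions:
            if not 0.0 < o < 1.0:
                raise ValueError(f"opinion {o} is not strictly inside (0, 1)")
        object.__setattr__(self, "opinions", opinions)
        object.__setattr__(self, "label", label)

    @property
    def n_experts(self) -> int:
        return len(self.opinions)


@dataclass(frozen=True)
class PanelSummary:
    """Pooled panel moments: mean μ, variance σ² (n−1 denominator)."""

    mean: float
    variance: float
    n_experts: int

    def __post_init__(self) -> None:
        if not 0.0 < self.mean < 1.0:
            raise ValueError("pooled mean must lie in (0, 1)")
        if self.variance >= self.mean * (1.0 - self.mean):
            raise ValueError(
                "pooled variance must be below mean*(1-mean) for a "
                "probability-valued quantity (required for Beta moment "
                "matching)"
            )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "variance": self.variance,
            "n_experts": self.n_experts,
        }


@dataclass(frozen=True)
class ElicitedQuantiles:
    """Elicited quantile levels α_i and values y_{α_i} on a domain.

    ``levels`` are the probabilities (strictly increasing in (0,1)),
    ``values`` the corresponding quantile guesses (non-decreasing, inside
    ``domain``).
    """

    levels: tuple[float, ...]
    values: tuple[float, ...]
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "domain", tuple(float(v) for v in self.domain))
        if len(levels) != len(values):
            raise ValueError("levels and values must have equal length")
        if len(levels) == 0:
            raise ValueError("at least one quantile is required")
        arr = np.asarray(levels)
        if np.any(arr <= 0) or np.any(arr >= 1) or np.any(np.diff(arr) <= 0):
            raise ValueError("levels must be strictly increasing in (0, 1)")
        if np.any(np.diff(values) < 0):
            raise ValueError("values must be non-decreasing")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("degenerate domain: lower bound must be < upper")
        if min(values) < lo or max(values) > hi:
            raise ValueError("values must lie inside the domain")

    @property
    def p(self) -> int:
        return len(self.levels)

    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "values": list(self.values),
            "domain": list(self.domain),
        }


def pool_opinions(panel: ExpertPanel) -> PanelSummary:
    """Pool a panel into its arithmetic mean and sample variance.

    The variance uses the n−1 denominator — the convention under which
    the eight-opinion worked example pools to variance 0.00625.
    """
    y = np.asarray(panel.opinions, dtype=float)
    return PanelSummary(
        mean=float(y.mean()),
        variance=float(y.var(ddof=1)),
        n_experts=len(y),
    )


def elicited_quartiles(
    panel: ExpertPanel,
    levels: Sequence[float] = (0.25, 0.5, 0.75),
    domain: tuple[float, float] = (0.0, 1.0),
) -> ElicitedQuantiles:
    """Empirical quantiles of the panel at the given levels.

    Uses the linear-interpolation convention between order statistics
    (index h = (n−1)·level), i.e. ``numpy.quantile``'s default.
    """
    levels = tuple(float(v) for v in levels)
    arr = np.asarray(levels)
    if np.any(arr <= 0) or np.any(arr >= 1) or np.any(np.diff(arr) <= 0):
        raise ValueError("levels must be strictly increasing in (0, 1)")
    y = np.asarray(panel.opinions, dtype=float)
    values = np.quantile(y, arr, method="linear")
    return ElicitedQuantiles(levels=levels, values=tuple(values), domain=domain)


def data_driven_delta(
    q: ElicitedQuantiles, definition: str = "half_rmse"
) -> float:
    """Data-driven elicitation error Δ* from stated quantiles.

    The stated quantile values are normalized to the unit interval via
    y* = (y − j)/(k − j) with (j, k) the domain bounds, and Δ* is half the
    root-mean-square deviation between the normalized values and their
    levels::

        Δ* = (1/2) · sqrt( (1/p) Σ_i (y*_{α_i} − α_i)² )

    Δ* measures how far the experts' stated quantiles sit from those of a
    flat (uniform) opinion; it is the default target fit error when no
    explicit uncertainty statement is available.

    Parameters
    ----------
    q
        Elicited quantiles.
    definition
        ``"half_rmse"`` (default) as above; ``"half_mse"`` returns the
        mean squared deviation divided by two (no square root), an
        alternative reading of the same quantity.
    """
    j, k = q.domain
    if not k > j:
        raise ValueError("degenerate domain")
    y_star = (np.asarray(q.values) - j) / (k - j)
    msd = float(np.mean((y_star - np.asarray(q.levels)) ** 2))
    if definition == "half_rmse":
        return 0.5 * float(np.sqrt(msd))
    if definition == "half_mse":
        return 0.5 * msd
    raise ValueError(f"unknown definition {definition!r}")


def phi_from_delta(
    q: ElicitedQuantiles,
    delta_target: float,
    degree: int = 4,
    inner_knots: Sequence[float] | None = None,
    phi_bounds: tuple[float, float] = (1e-4, 1e4),
    rtol: float = 1e-4,
    fit_error_fn: Callable[[float], float] | None = None,
) -> float:
    """Calibrate the B-spline balancing factor φ to a target fit error.

    The fitted prior's error against the stated quantiles,

        Δ(φ) = sqrt( (1/p) Σ_i (α_i − F_φ(y_{α_i}))² ),

    is non-decreasing in φ (a larger uniform penalty pulls the CDF away
    from the quantiles), so Δ(φ) = Δ_target is solved by bisection on
    log φ.  The error is measured on the RMS scale, the same scale as the
    data-driven default ``data_driven_delta``: the φ→∞ (uniform) limit of
    Δ(φ)/2 equals Δ* exactly, so any Δ_target below 2·Δ* is attainable.

    If ``delta_target`` is at or below the fit error already achieved as
    φ→0, the lower search bound is returned (the target is effectively
    "fit the quantiles as well as possible").  If it is at or above the
    uniform-limit error, the upper bound is returned.

    Parameters
    ----------
    q
        Elicited quantiles to fit.
    delta_target
        Target RMS fit error (e.g. the data-driven Δ*).
    degree, inner_knots
        Spline configuration forwarded to
        :func:`hpdsize.priors.fit_bspline_prior`.
    phi_bounds
        Bisection bracket for φ.
    rtol
        Relative tolerance on φ.
    fit_error_fn
        Override for testing: maps φ to the achieved RMS fit error.
    """
    if fit_error_fn is None:
        from .priors import fit_bspline_prior

        def fit_error_fn(phi: float) -> float:
            prior = fit_bspline_prior(
                q, degree=degree, phi=phi, inner_knots=inner_knots
            )
            return float(np.sqrt(prior.fit_error))

    lo, hi = phi_bounds
    f_lo = fit_error_fn(lo)
    f_hi = fit_error_fn(hi)
    if delta_target <= f_lo:
        # target below the best attainable fit: report the attainable
        # minimum by returning the smallest phi (ties toward smaller phi)
        return lo
    if delta_target >= f_hi:
        return hi
    llo, lhi = np.log(lo), np.log(hi)
    while lhi - llo > np.log1p(rtol):
        mid = 0.5 * (llo + lhi)
        if fit_error_fn(float(np.exp(mid))) < delta_target:
            llo = mid
        else:
            lhi = mid
    # ties broken toward smaller phi
    return float(np.exp(llo))


# ---------------------------------------------------------------------------
# I/O


def load_panel(path: str | Path, label: str | None = None) -> ExpertPanel:
    """Read an expert panel from CSV (column ``opinion``) or a JSON array."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if isinstance(data, dict):
            data = data["opinions"]
        opinions = [float(v) for v in data]
    else:
        df = pd.read_csv(path)
        if "opinion" not in df.columns:
            raise ValueError(f"{path}: expected an 'opinion' column")
        opinions = df["opinion"].astype(float).tolist()
    return ExpertPanel(opinions, label=label or path.stem)
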
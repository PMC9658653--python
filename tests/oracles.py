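"""Independent brute-force oracles used by the test suite.

Everything here works by dense enumeration on grids and never calls the
package's optimized HPD or criterion code paths, so agreement between
the two is a real cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats


def beta_cov(a: float, b: float, lo, hi) -> np.ndarray:
    return special.betainc(a, b, hi) - special.betainc(a, b, lo)


def brute_hpd_fixed_length(a: float, b: float, l: float, step: float = 1e-4):
    """Best lower bound and coverage of a length-l interval for a
    Beta(a, b) posterior, by grid search over every placement."""
    grid = np.arange(0.0, 1.0 - l + step / 2, step)
    grid = np.clip(grid, 0.0, 1.0 - l)
    cov = beta_cov(a, b, grid, np.clip(grid + l, 0.0, 1.0))
    i = int(np.argmax(cov))
    return float(grid[i]), float(cov[i])


def brute_hpd_fixed_coverage(a: float, b: float, coverage: float,
                             step: float = 1e-4):
    """Shortest interval of the given coverage for Beta(a, b), by grid
    search on the lower bound."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    cdf = special.betainc(a, b, grid)
    ok = cdf <= 1.0 - coverage
    lowers = grid[ok]
    uppers = special.betaincinv(a, b, np.clip(cdf[ok] + coverage, 0.0, 1.0))
    lengths = uppers - lowers
    i = int(np.argmin(lengths))
    return float(lowers[i]), float(lengths[i])


def brute_average_coverage(a: float, b: float, n: int, l: float,
                           step: float = 1e-4) -> float:
    """Predictive-weighted average of brute-force maximal coverages."""
    pmf = stats.betabinom.pmf(np.arange(n + 1), n, a, b)
    total = 0.0
    for x in range(n + 1):
        _, cov = brute_hpd_fixed_length(a + x, b + n - x, l, step)
        total += pmf[x] * cov
    return float(total)


def brute_average_length(a: float, b: float, n: int, coverage: float,
                         step: float = 1e-4) -> float:
    """Predictive-weighted average of brute-force minimal lengths."""
    pmf = stats.betabinom.pmf(np.arange(n + 1), n, a, b)
    total = 0.0
    for x in range(n + 1):
        _, ln = brute_hpd_fixed_coverage(a + x, b + n - x, coverage, step)
        total += pmf[x] * ln
    return float(total)


def brute_worst_coverage(a: float, b: float, n: int, l: float,
                         step: float = 1e-4) -> float:
    """Minimum brute-force maximal coverage over every outcome x."""
    worst = 1.0
    for x in range(n + 1):
        _, cov = brute_hpd_fixed_length(a + x, b + n - x, l, step)
        worst = min(worst, cov)
    return float(worst)
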
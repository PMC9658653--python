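# Methods

`hpdsize` determines the sample size of a single-arm binomial experiment
(a phase II safety or activity trial is the motivating setting) by
preposterior analysis of highest-posterior-density (HPD) intervals. This
note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Model and criteria

Let θ ∈ (0, 1) be the event probability, f(θ) a prior density, and for a
candidate sample size n let g(x) be the preposterior (marginal) pmf of
the number of successes x ∈ {0, …, n},

    g(x) = C(n, x) ∫ θ^x (1 − θ)^{n−x} f(θ) dθ.

For each outcome x the posterior f(θ | x, n) admits HPD-type intervals;
two one-parameter families are used:

* the **fixed-length** interval of length l maximizing posterior
  coverage (for a unimodal posterior this is the equal-endpoint-density
  interval, or a boundary-anchored one under a monotone tail);
* the **fixed-coverage** interval of mass 1 − α minimizing length,
  parametrized as [Q(t), Q(t + 1 − α)] over the lower tail mass t, with
  Q the posterior quantile function.

Three sample-size criteria are implemented for any unimodal prior
(GACC, GALC, GWOC — *generalized* because the prior need not be Beta):

* **GACC**: smallest n with Σₓ g(x) · coverage(x; l) ≥ 1 − α;
* **GALC**: smallest n with Σₓ g(x) · length(x; 1 − α) ≤ l;
* **GWOC**: smallest n with minₓ∈X* coverage(x; l) ≥ 1 − α over a
  worst-outcome subset X*.

For X* the closed-form rule in the prior expected successes c and
failures d is used (for a Beta(α, β) prior, c = α and d = β):
(n+c+d±1)/2 − c when n+c+d is odd, (n+c+d)/2 − c when even, and {n} when
n ≤ |d − c|; non-integer candidates bracket to both neighbouring
integers and the worst coverage over all candidates binds. For non-Beta
priors c is the median of 1000 prior-predictive binomial draws (seeded,
deterministic). Because the strict worst outcome over the *whole* data
space need not coincide with the closed-form subset for informative
priors, `woc_space` selects the scanned set: `formula` (default),
`full` (every x), or `predictive-band` (outcomes inside the central 95%
of predictive mass).

The search scans n upward over ⌈0.5·n̂⌉ … ⌈1.5·n̂⌉ around the
frequentist precision benchmark n̂ = ⌈z² p(1−p)/(l/2)²⌉, doubling the
upper bound once (flagged) if the criterion is unmet.

## Priors

**Beta, power-prior discounted.** Pooled expert point guesses give a
mean μ and variance σ² (n−1 denominator); moment matching yields shapes
a = μ(μ(1−μ)/σ² − 1), b = a(1/μ − 1). With kernel exponents
(α₀, β₀) = (a−1, b−1) a discount factor d₀ ∈ [0, 1] produces the
operating prior Beta(α₀d₀ + 1, β₀d₀ + 1); d₀ = 0 is the flat Beta(1,1),
d₀ = 1 keeps all elicited information. By default the matched shapes
are rounded to the nearest integers before discounting
(`round_prior=True`): the worked example's pooled moments
(0.2625, 0.00625) match (7.87, 22.11), round to (8, 22), and the
d₀ ∈ {1, 0.5, 0} trio becomes Beta(8,22), Beta(4.5,11.5), Beta(1,1).
This rounding convention is the only one consistent with all three
operating priors at once. Effective sample size (ESS) is α + β for a
Beta prior; any other prior reports the ESS of its moment-matched Beta,
μ(1−μ)/σ² − 1 (a pragmatic choice; no closed theory is claimed for it).

**Semiparametric B-spline.** The prior CDF F is a degree-m spline
(default m = 4) on a clamped knot vector with inner knots at the
distinct elicited quantile values, with coefficients solving

    min Σᵢ (αᵢ − F(y_{αᵢ}))² + φ ∫ f(y)² dy
    s.t. coefficients non-decreasing, F(y₀) = 0, F(y₁) = 1,

where f = F′. The penalty equals the L² distance to the uniform density
plus a constant, so φ interpolates between "fit the expert quantiles"
(φ → 0) and "be uniform" (φ → ∞). The quadratic program is solved by
reparametrizing the coefficient increments on the probability simplex
and running `scipy`'s trust-region constrained minimizer with the exact
(constant) Hessian; the penalty's Gram matrix is assembled exactly by
per-interval Gauss–Legendre quadrature of the density-basis products,
so the objective is exact, not sampled. Achieved fit error
Δ = (1/p) Σ (αᵢ − F(y_{αᵢ}))² is stored on the prior.

Two properties of the *default* knot choice deserve emphasis:

* With single knots at three tightly spaced quartiles the C³ spline
  space cannot interpolate steep quantile constraints: for the worked
  example the φ → 0 best monotone fit is (0.326, 0.548, 0.607) against
  targets (0.25, 0.5, 0.75). This is a property of the space, not of
  the solver (the program is convex; independent solvers agree).
  Near-interpolation is available by raising the inner-knot
  multiplicity (up to m−1), which the fitter accepts via
  `inner_knots`.
* Consequently every calibrated prior here remains fairly dispersed
  (moment-matched ESS ≈ 2), and fitted densities can carry shallow
  secondary bumps. Modality is therefore classified on a grid with a
  prominence threshold (5% of the peak): one effective mode →
  unimodal; several shallow modes → "mild" (criteria proceed with a
  warning, the HPD being the narrowest interval containing the mass);
  a valley dropping below half of a neighbouring peak → "severe"
  (criteria refuse, as a single interval is no longer a credible HDI).

**Calibration of φ.** The data-driven elicitation error is
Δ\* = ½·RMS(y\*ᵢ − αᵢ) over domain-normalized quantile values; the
worked example gives Δ\* = 0.14595. φ is chosen by bisection on log φ so
that the *RMS* fit error √Δ(φ) equals the target (Δ(φ) is
non-decreasing in φ; ties break toward smaller φ). The RMS scale is the
one on which the target is attainable — the φ → ∞ limit of ½·√Δ(φ)
equals Δ\* identically, so matching on any half- or squared-scale
pins φ at a search bound. For the worked example the calibration gives
φ ≈ 0.144.

## Numerics

* Beta priors/posteriors use `scipy.special` incomplete-beta routines
  throughout; predictive pmfs use the closed-form Beta-Binomial.
* Generic-prior posteriors accumulate the kernel on the log scale. The
  normalizer uses adaptive quadrature split at the spline knots
  (relative tolerance 1e−10); the CDF uses cumulative Simpson on a
  4001-point grid with monotone (PCHIP) interpolation; quantiles invert
  the gridded CDF. Generic predictive pmfs integrate the kernel by
  Simpson weights on the same grid and renormalize (unit total to
  1e−8).
* Interval optimizations work only through CDF/quantile evaluations —
  endpoint densities (infinite for Beta shapes < 1) are never needed.
  Fixed-length placement runs bounded scalar optimization with
  multi-start candidates at the domain edges and around the mode;
  fixed-coverage minimizes length over the lower tail mass. Flat
  stretches tie-break toward the smallest lower bound. An interval is
  flagged `is_hpd` when endpoint densities agree to 1e−6 (relative to
  the mode density) or the interval is boundary-anchored.
* Outcomes with predictive mass below 1e−12 are skipped in criterion
  averages (total neglected mass < (n+1)·1e−12; average lengths are
  renormalized over retained outcomes).

## Worked-example reproduction

The shipped eight-opinion panel reproduces: pooled variance 0.00625,
quartiles (0.2, 0.275, 0.3), Δ\* ≈ 0.146, operating priors
Beta(8,22)/Beta(4.5,11.5)/Beta(1,1), informative ESS 30, frequentist
benchmark 75, and GALC = 42 for Beta(8,22) at l = 0.2, 1 − α = 0.95.

Two published figures are *not* reproduced by the exact computation and
are reported as discrepancies rather than matched by construction:

* **GACC for Beta(8,22) is 42 here, not 43**: the exact
  predictive-weighted average of maximal coverages already reaches
  0.950123 at n = 42. A reference value of 43 requires per-outcome
  coverages about 1.3e−4 lower than the maximal-coverage interval
  attains — the size of the gap left by common approximate placements
  (e.g. centring the length-l interval on the 95% HPD interval). The
  same systematic direction (published GACC ≥ exact GACC) recurs
  across all six scenarios, while the GALC column — which has no
  placement freedom — is reproduced within ±2 everywhere.
* **GWOC for Beta(8,22)**: at the published 45 the closed-form worst
  outcome x\* = 30 yields posterior Beta(38, 37), whose best
  length-0.2 coverage is ≈ 0.92 < 0.95; no scanned data subspace
  (`formula`, `full`, `predictive-band`) meets the criterion before
  n = 62. All three variants are computed and reported.

## Synthetic panels

`generate_panel` draws expert guesses from a Beta distribution with a
chosen mean and spread, rounds them to a coarse grid (default 0.05, the
resolution at which experts state probabilities) and clips them inside
(0, 1). It emulates independent point guesses only — no inter-expert
correlation, anchoring, overconfidence or facilitator effects — so
passing tests say nothing about behavioural elicitation quality, only
about the arithmetic downstream of the stated numbers.

## Problem sizes used in the test suite

Unit and property tests run at small scale by choice: HPD brute-force
oracles on 1e−4 grids, criterion brute-force equivalence at n ≤ 10,
Monte-Carlo predictive checks with 1e5 draws, and the full
six-scenario × three-criterion table once per session at the worked
example's search bounds (38–113).

## Known limitations

* Multimodal priors are handled only to the point of detection and
  refusal; discontinuous HDI sets are out of scope.
* ESS for non-Beta priors is moment-matching only.
* The B-spline fit inherits the expressiveness of its knot vector (see
  above); the default reproduces the published calibration φ ≈ 0.138
  within 5%, but not the published B-spline ESS values, which would
  require a substantially more concentrated fitted prior than the
  ∫f² penalty at that calibration permits.
* Two-arm designs, continuous outcomes, and median-based criterion
  variants are not implemented.
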
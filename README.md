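# hpdsize

Bayesian sample-size determination for a single binomial proportion,
built for the planning stage of small single-arm trials (phase II,
pediatric, rare-disease) where the prior comes from expert opinion
rather than historical data.

The package implements preposterior sample-size criteria over highest
posterior density (HPD) intervals, generalized beyond the conjugate
Beta-Binomial setting to any unimodal prior:

* **GACC** (average coverage): fix the HPD length l; find the smallest n
  whose predictive-weighted average posterior coverage reaches 1 − α:
  Σₓ g(x) · Pr{θ ∈ [a(x), a(x)+l] | x, n} ≥ 1 − α.
* **GALC** (average length): fix the coverage 1 − α; find the smallest n
  whose predictive-weighted average HPD length comes down to l.
* **GWOC** (worst outcome): fix both; require coverage ≥ 1 − α on a
  worst-outcome data subset x*.

Two prior families are provided behind one interface:

* **Beta priors** moment-matched to pooled expert guesses and
  discounted with a power prior: Beta(α₀d₀ + 1, β₀d₀ + 1), where
  (α₀, β₀) are the elicited kernel exponents and d₀ ∈ [0, 1] the
  fraction of expert information retained (d₀ = 0 ⇒ flat Beta(1, 1)).
* **Semiparametric B-spline priors** whose CDF is a monotone spline
  fitted among elicited quantiles by a convex quadratic program,
  min Σᵢ(αᵢ − F(y_{αᵢ}))² + φ∫f², balancing expert fidelity against
  distance from the uniform distribution.

## Worked example

Eight clinicians guessed the probability of a renal-scar event in
infants treated after a first febrile urinary tract infection:
{0.30, 0.25, 0.15, 0.40, 0.30, 0.20, 0.20, 0.30}. This panel ships with
the package:

```python
from hpdsize import (
    example_panel, pool_opinions, elicited_quartiles, data_driven_delta,
    beta_scenario_prior, prior_ess, frequentist_n, DesignSpec, galc,
)

panel = example_panel()
summary = pool_opinions(panel)
print(summary.mean, summary.variance)      # 0.2625 0.00625
quants = elicited_quartiles(panel)
print(quants.values)                       # (0.2, 0.275, 0.3)
print(round(data_driven_delta(quants), 3)) # 0.146

prior = beta_scenario_prior(summary, "informative")
print(prior.alpha, prior.beta, prior_ess(prior))  # 8.0 22.0 30.0
print(frequentist_n(summary.mean))         # 75

result = galc(DesignSpec(prior, length=0.2, coverage=0.95))
print(result.n_opt)                        # 42
```

Reading the output: the pooled opinions are worth a Beta(8, 22) prior —
30 hypothetical patients of information centred at 0.27 — and a trial
of n = 42 patients is the smallest whose expected 95% HPD interval is
no longer than 0.2, against 75 patients for the frequentist precision
benchmark at the same length: the informative prior buys a study
almost half the size.

The same pipeline runs from the shell:

```sh
hpdsize elicit example
hpdsize samplesize --alpha 8 --beta 22 --criterion galc
hpdsize scenarios --opinions example --out-json report.json --out-csv table.csv
```

`hpdsize scenarios` produces the full design report: six priors
(Beta and B-spline, each informative / 50%-discounted / uninformative)
by three criteria, with prior effective sample sizes, per-n criterion
curves and the frequentist benchmark.

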
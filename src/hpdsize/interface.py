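"""End-to-end pipeline: configuration, scenario reports and panel synthesis.

Ties elicitation → priors → sample-size criteria together: a
:class:`RunConfig` names the opinion source (or an explicit prior), the
informativeness scenarios, the design parameters and the criteria;
:func:`run_pipeline` produces a :class:`ScenarioReport` with one cell
per (scenario, criterion), mirroring the usual scenarios × criteria
summary table of a trial design report.

Also provides :func:`generate_panel`, a synthetic expert-panel generator
for testing and sensitivity analysis: opinions are drawn from a Beta
distribution with a chosen centre and spread and rounded to the coarse
probability grid (default 0.05) on which experts typically state
guesses.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .design import (
    CriterionResult,
    DesignSpec,
    default_search_bounds,
    frequentist_n,
    gacc,
    galc,
    gwoc,
)
from .elicitation import (
    ElicitedQuantiles,
    ExpertPanel,
    data_driven_delta,
    elicited_quartiles,
    load_panel,
    phi_from_delta,
    pool_opinions,
)
from .priors import (
    SCENARIOS,
    BetaPrior,
    BSplinePrior,
    PriorModel,
    beta_scenario_prior,
    bspline_scenario_prior,
    fit_bspline_prior,
    prior_ess,
)

__all__ = [
    "RunConfig",
    "ScenarioReport",
    "run_pipeline",
    "generate_panel",
    "example_panel",
    "validate_report",
    "REPORT_SCHEMA_VERSION",
]

logger = logging.getLogger("hpdsize")

REPORT_SCHEMA_VERSION = 1

_CRITERIA = {"gacc": gacc, "galc": galc, "gwoc": gwoc}


def example_panel() -> ExpertPanel:
    """The shipped worked-example panel: eight pediatricians' guesses of
    the probability of a renal-scar event after a first febrile urinary
    tract infection under the recommended antibiotic regimen."""
    path = Path(__file__).parent / "data" / "uti_expert_panel.csv"
    return load_panel(path, label="pediatric UTI renal-scar panel")


@dataclass
class RunConfig:
    """Configuration of a full sample-size run.

    Exactly one of ``opinions`` (a path, list of probabilities, or the
    string ``"example"``) or ``prior`` (an explicit prior spec, e.g.
    ``{"family": "beta", "alpha": 1, "beta": 1}``) must be given;
    scenario presets only make sense with opinions.
    """

    opinions: str | Sequence[float] | None = None
    prior: dict | None = None
    scenarios: Sequence[str] = (
        "beta-informative", "beta-low-informative", "beta-uninformative",
        "bspline-informative", "bspline-low-informative",
        "bspline-uninformative",
    )
    criteria: Sequence[str] = ("gacc", "galc", "gwoc")
    length: float = 0.2
    coverage: float = 0.95
    woc_space: str = "formula"
    round_prior: bool = True
    degree: int = 4
    quantile_levels: Sequence[float] = (0.25, 0.5, 0.75)
    seed: int = 0
    search_bounds: tuple[int, int] | None = None
    numerics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.opinions is None) == (self.prior is None):
            raise ValueError(
                "exactly one of 'opinions' and 'prior' must be supplied"
            )
        if self.prior is not None and any(
            s not in ("explicit",) for s in self.scenarios
        ):
            # explicit prior runs a single pseudo-scenario
            object.__setattr__(self, "scenarios", ("explicit",))
        for c in self.criteria:
            if c not in _CRITERIA:
                raise ValueError(f"unknown criterion {c!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        version = raw.pop("config_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config_version {version}")
        if "search_bounds" in raw and raw["search_bounds"] is not None:
            raw["search_bounds"] = tuple(raw["search_bounds"])
        return cls(**raw)


@dataclass
class ScenarioReport:
    """Structured result of :func:`run_pipeline` (schema-versioned)."""

    schema_version: int
    seed: int
    design: dict
    elicitation: dict | None
    frequentist_n: int | None
    scenarios: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "seed": self.seed,
            "design": self.design,
            "elicitation": self.elicitation,
            "frequentist_n": self.frequentist_n,
            "scenarios": self.scenarios,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def table(self) -> list[dict]:
        """Scenario × criterion matrix of optimal sample sizes."""
        rows = []
        for name, cell in self.scenarios.items():
            row: dict[str, Any] = {"scenario": name, "ess": cell.get("ess")}
            for crit, res in cell.get("criteria", {}).items():
                row[crit] = res.get("n_opt") if not res.get("failed") else None
            rows.append(row)
        return rows

    def to_csv(self, path: str | Path) -> None:
        rows = self.table()
        fields = ["scenario", "ess"] + [
            c for c in ("gacc", "galc", "gwoc") if any(c in r for r in rows)
        ]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
            writer.writeheader()
            writer.writerows(rows)


def _prior_from_spec(spec: dict) -> PriorModel:
    family = spec.get("family")
    if family == "beta":
        return BetaPrior(spec["alpha"], spec["beta"])
    if family == "uniform":
        return BetaPrior(1.0, 1.0)
    if family == "bspline":
        if "coefficients" in spec:
            return BSplinePrior.from_dict(spec)
        q = ElicitedQuantiles(
            levels=tuple(spec["levels"]), values=tuple(spec["values"]),
            domain=tuple(spec.get("domain", (0.0, 1.0))),
        )
        return fit_bspline_prior(
            q, degree=int(spec.get("degree", 4)), phi=float(spec["phi"]),
        )
    raise ValueError(f"unknown prior family {family!r}")


def _resolve_panel(config: RunConfig) -> ExpertPanel:
    if isinstance(config.opinions, str):
        if config.opinions == "example":
            return example_panel()
        return load_panel(config.opinions)
    return ExpertPanel(list(config.opinions))


def _scenario_priors(config: RunConfig, panel: ExpertPanel):
    """Build (prior, metadata) per requested scenario from a panel."""
    summary = pool_opinions(panel)
    quants = elicited_quartiles(panel, config.quantile_levels)
    delta = data_driven_delta(quants)
    out: dict[str, tuple[PriorModel, dict]] = {}
    phi_cache: dict[str, float] = {}
    for name in config.scenarios:
        family, _, level = name.partition("-")
        if family not in ("beta", "bspline") or level not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
        if family == "beta":
            prior = beta_scenario_prior(summary, level, config.round_prior)
            meta = {"family": "beta", "alpha": prior.alpha, "beta": prior.beta,
                    "d0": SCENARIOS[level]["d0"]}
        else:
            phi = SCENARIOS[level]["phi"]
            if phi == "delta":
                if "delta" not in phi_cache:
                    phi_cache["delta"] = phi_from_delta(
                        quants, delta, degree=config.degree
                    )
                phi = phi_cache["delta"]
            prior = fit_bspline_prior(quants, degree=config.degree,
                                      phi=float(phi))
            meta = {"family": "bspline", "phi": float(phi),
                    "degree": config.degree, "fit_error": prior.fit_error}
        out[name] = (prior, meta)
    elic = {
        "summary": summary.to_dict(),
        "quantiles": quants.to_dict(),
        "delta_star": delta,
    }
    return out, elic, summary


def run_pipeline(config: RunConfig) -> ScenarioReport:
    """Run elicitation, prior construction and every requested criterion.

    Returns a :class:`ScenarioReport`; identical config and seed give an
    identical report.  Failures in one (scenario, criterion) cell are
    recorded in place and do not abort the rest of the run.
    """
    logger.info("pipeline start: seed=%d length=%g coverage=%g woc_space=%s",
                config.seed, config.length, config.coverage, config.woc_space)
    elic = None
    freq = None
    if config.opinions is not None:
        panel = _resolve_panel(config)
        priors, elic, summary = _scenario_priors(config, panel)
        freq = frequentist_n(summary.mean, config.length, config.coverage)
        bounds = config.search_bounds or default_search_bounds(freq)
        logger.info("elicitation: mean=%.4f var=%.5f frequentist n=%d "
                    "bounds=%s", summary.mean, summary.variance, freq, bounds)
    else:
        prior = _prior_from_spec(config.prior)
        priors = {"explicit": (prior, dict(config.prior))}
        bounds = config.search_bounds
        freq = frequentist_n(prior.mean, config.length, config.coverage)
        bounds = bounds or default_search_bounds(freq)

    scenarios: dict[str, dict] = {}
    for name, (prior, meta) in priors.items():
        cell: dict[str, Any] = {"prior": meta}
        try:
            cell["ess"] = prior_ess(prior)
        except ValueError as exc:
            cell["ess"] = None
            logger.warning("scenario %s: ESS unavailable (%s)", name, exc)
        cell["criteria"] = {}
        for crit in config.criteria:
            spec = DesignSpec(
                prior=prior, length=config.length, coverage=config.coverage,
                search_bounds=bounds, woc_space=config.woc_space,
                seed=config.seed,
                resample_draws=int(config.numerics.get("resample_draws", 1000)),
            )
            try:
                result: CriterionResult = _CRITERIA[crit](spec)
                logger.info("scenario %s %s: n_opt=%s", name, crit,
                            result.n_opt)
                logger.debug("scenario %s %s curve: %s", name, crit,
                             result.curve)
                cell["criteria"][crit] = result.to_dict()
            except Exception as exc:  # record, keep going
                logger.error("scenario %s %s failed: %s", name, crit, exc)
                cell["criteria"][crit] = {"failed": True, "error": str(exc)}
        scenarios[name] = cell

    return ScenarioReport(
        schema_version=REPORT_SCHEMA_VERSION,
        seed=config.seed,
        design={
            "length": config.length,
            "coverage": config.coverage,
            "woc_space": config.woc_space,
            "search_bounds": list(bounds),
        },
        elicitation=elic,
        frequentist_n=freq,
        scenarios=scenarios,
    )


# ---------------------------------------------------------------------------
# synthetic panels


def generate_panel(
    n_experts: int,
    true_mean: float,
    spread: float = 0.08,
    grid: float = 0.05,
    seed=None,
    label: str = "synthetic panel",
) -> ExpertPanel:
    """Synthesize an expert panel of point guesses.

    Opinions are drawn from the Beta distribution with the given mean
    and standard deviation ``spread``, then rounded to the stated
    probability ``grid`` (experts answer in coarse steps, typically 5%)
    and clipped inside (0, 1).  ``spread`` → 0 collapses the panel onto
    the rounded mean.  Deterministic for a given seed.
    """
    if n_experts < 2:
        raise ValueError("need at least 2 experts")
    if not 0.0 < true_mean < 1.0:
        raise ValueError("true_mean must be in (0, 1)")
    if not 0.0 < grid < 0.5:
        raise ValueError("grid must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    if spread <= 0:
        draws = np.full(n_experts, true_mean)
    else:
        var = spread * spread
        if var >= true_mean * (1.0 - true_mean):
            raise ValueError(
                "spread incompatible with mean: need spread^2 < mean*(1-mean)"
            )
        a = true_mean * (true_mean * (1.0 - true_mean) / var - 1.0)
        b = a * (1.0 / true_mean - 1.0)
        draws = rng.beta(a, b, size=n_experts)
    opinions = np.round(draws / grid) * grid
    opinions = np.clip(opinions, grid, 1.0 - grid)
    return ExpertPanel(opinions.tolist(), label=label)


# ---------------------------------------------------------------------------
# report schema (minimal structural validation; schema shipped as JSON)


def _schema_path() -> Path:
    return Path(__file__).parent / "data" / "report_schema.json"


def validate_report(report: dict) -> None:
    """Check a report dict against the shipped JSON schema.

    A compact structural validator supporting the subset of JSON-schema
    keywords the report schema uses (type, required, properties,
    additionalProperties as sub-schema); raises ``ValueError`` on the
    first violation.
    """
    schema = json.loads(_schema_path().read_text())
    _validate(report, schema, "$")


_TYPES = {
    "object": dict, "array": list, "string": str,
    "number": (int, float), "integer": int, "boolean": bool,
}


def _validate(obj: Any, schema: dict, where: str) -> None:
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        if "null" in allowed and obj is None:
            return
        pytypes = tuple(_TYPES[t] for t in allowed if t != "null")
        if not isinstance(obj, pytypes) or (
            "integer" in allowed and "number" not in allowed
            and isinstance(obj, bool)
        ):
            raise ValueError(f"{where}: expected {typ}, got {type(obj).__name__}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise ValueError(f"{where}: missing required key {key!r}")
        props = schema.get("properties", {})
        extra = schema.get("additionalProperties")
        for key, val in obj.items():
            if key in props:
                _validate(val, props[key], f"{where}.{key}")
            elif isinstance(extra, dict):
                _validate(val, extra, f"{where}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, val in enumerate(obj):
            _validate(val, schema["items"], f"{where}[{i}]")
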
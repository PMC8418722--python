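"""Probabilistic and one-way sensitivity analysis.

The PSA draws every scalar input from its declared distribution (gamma for
costs, beta for utilities, lognormal for hazard ratios) and the Weibull
regression coefficient blocks from one joint multivariate normal per fit,
using the fit covariance (or an SE vector with a correlation matrix for
loaded tables).  Each iteration reruns the full two-arm cohort model.
Iterations whose draws violate a support constraint (e.g. sampled
disutilities exceeding the baseline utility) are rejected and redrawn, which
preserves the stated distributions elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import net_monetary_benefit
from .engine import ModelInputs, ScenarioResult, run_scenario
from .parameters import (CostInputs, DistributionSpec, EconomicSettings,
                         HazardInputs, ParameterSet, UtilityInputs, fixed,
                         sample_spec)
from .survival import WeibullFit

logger = logging.getLogger(__name__)

QUADRANTS = ("save_gain", "spend_gain", "save_lose", "spend_lose")


def _sampled(spec: DistributionSpec, rng: np.random.Generator
             ) -> DistributionSpec:
    return fixed(sample_spec(spec, rng))


def sample_weibull_fit(fit: WeibullFit, rng: np.random.Generator
                       ) -> WeibullFit:
    """One joint multivariate-normal draw of (coefficients, log-shape)."""
    if fit.covariance is None:
        return fit
    cov = np.asarray(fit.covariance)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError("coefficient covariance is not PSD")
    mean = np.array(list(fit.coefficients.values()) + [np.log(fit.shape)])
    draw = rng.multivariate_normal(mean, cov, method="svd")
    coeffs = dict(zip(fit.coefficients, draw[:-1]))
    return replace(fit, coefficients=coeffs, shape=float(np.exp(draw[-1])),
                   covariance=None)


def sample_parameter_set(base: ModelInputs, rng: np.random.Generator,
                         max_redraws: int = 100) -> ModelInputs:
    """Draw one full parameter set; redraw on support violations."""
    for attempt in range(max_redraws):
        p = base.params
        c, u, h = p.costs, p.utilities, p.hazards
        costs = CostInputs(
            recruitment_per_eligible=_sampled(c.recruitment_per_eligible, rng),
            intervention_per_participant=_sampled(
                c.intervention_per_participant, rng),
            t2d_extra_care_annual=_sampled(c.t2d_extra_care_annual, rng),
            complication_cost_annual=_sampled(c.complication_cost_annual, rng),
            productivity_loss_annual_under65=_sampled(
                c.productivity_loss_annual_under65, rng),
            basic_care_annual_men=_sampled(c.basic_care_annual_men, rng),
            basic_care_annual_women=_sampled(c.basic_care_annual_women, rng),
            medication_annual=_sampled(c.medication_annual, rng))
        hazards = HazardInputs(
            intervention_hr=_sampled(h.intervention_hr, rng),
            intervention_effect_duration_years=
                h.intervention_effect_duration_years,
            t2d_mortality_hr_women=_sampled(h.t2d_mortality_hr_women, rng),
            t2d_mortality_hr_men=_sampled(h.t2d_mortality_hr_men, rng),
            complication_mortality_hr=_sampled(h.complication_mortality_hr,
                                               rng))
        baseline = {k: _sampled(v, rng) for k, v in u.baseline.items()}
        try:
            utilities = UtilityInputs(
                baseline=baseline,
                disutility_t2d=_sampled(u.disutility_t2d, rng),
                disutility_complications_weighted=_sampled(
                    u.disutility_complications_weighted, rng))
            inc = sample_weibull_fit(base.incidence_fit, rng)
            comp = sample_weibull_fit(base.complication_fit, rng)
        except ValueError as err:
            logger.info("PSA draw %d rejected: %s", attempt, err)
            continue
        params = ParameterSet(costs=costs, utilities=utilities,
                              hazards=hazards, economics=p.economics)
        return replace(base, params=params, incidence_fit=inc,
                       complication_fit=comp)
    raise RuntimeError(f"no valid draw after {max_redraws} redraws")


@dataclass(frozen=True)
class PsaIteration:
    index: int
    savings_societal: dict     # gender|overall -> € per person
    savings_direct: dict
    delta_qaly: dict
    nmb: dict


@dataclass(frozen=True)
class PsaSummary:
    """Point estimate, percentile CI and CE-plane quadrant shares.

    The point estimate is the deterministic base-case run; it need not lie
    inside the percentile interval of the sampled runs.
    """

    n_iterations: int
    point: dict                # metric -> value (overall)
    ci: dict                   # metric -> (2.5%, 97.5%)
    quadrant_shares: dict      # quadrant name -> fraction
    iterations: pd.DataFrame
    n_redraws: int = 0


def ce_plane_quadrants(savings, delta_qalys) -> dict:
    """Classify iterations by sign of (savings, ΔQALY).

    Zero on either axis counts as saving / gaining (logged when it occurs).
    """
    sav = np.asarray(savings, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    if sav.size == 0:
        raise ValueError("need at least one iteration")
    if np.any(sav == 0) or np.any(dq == 0):
        logger.info("CE-plane points on an axis counted as save/gain")
    save = sav >= 0
    gain = dq >= 0
    n = sav.size
    return {"save_gain": float(np.sum(save & gain)) / n,
            "spend_gain": float(np.sum(~save & gain)) / n,
            "save_lose": float(np.sum(save & ~gain)) / n,
            "spend_lose": float(np.sum(~save & ~gain)) / n}


def run_psa(base: ModelInputs, n_iterations: int = 1000, seed: int = 0,
            settings: EconomicSettings | None = None) -> PsaSummary:
    """Probabilistic sensitivity analysis; deterministic given the seed."""
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations")
    settings = settings or base.params.economics
    rng = np.random.default_rng(seed)
    wtp = settings.wtp_threshold

    point_res = run_scenario(base, settings)
    rows = []
    for i in range(n_iterations):
        drawn = sample_parameter_set(base, rng)
        res = run_scenario(drawn, settings)
        for g in ("women", "men", "overall"):
            s_soc = res.savings(g, "societal")
            s_dir = res.savings(g, "direct_only")
            dq = res.delta_qaly(g)
            rows.append((i, g, s_soc, s_dir, dq,
                         net_monetary_benefit(dq, -s_soc, wtp)))
    it = pd.DataFrame(rows, columns=["iteration", "gender",
                                     "savings_societal", "savings_direct",
                                     "delta_qaly", "nmb"])
    overall = it[it.gender == "overall"]
    point = {"savings_societal": point_res.savings("overall", "societal"),
             "savings_direct": point_res.savings("overall", "direct_only"),
             "delta_qaly": point_res.delta_qaly("overall"),
             "nmb": net_monetary_benefit(
                 point_res.delta_qaly("overall"),
                 -point_res.savings("overall", "societal"), wtp)}
    ci = {m: (float(np.percentile(overall[m], 2.5)),
              float(np.percentile(overall[m], 97.5)))
          for m in point}
    shares = ce_plane_quadrants(overall.savings_societal.to_numpy(),
                                overall.delta_qaly.to_numpy())
    return PsaSummary(n_iterations=n_iterations, point=point, ci=ci,
                      quadrant_shares=shares, iterations=it)


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

OWSA_PARAMETERS = ("t2d_care_cost", "productivity_cost", "intervention_cost",
                   "complication_cost", "recruitment_cost",
                   "intervention_hr", "discount_rate")


def _owsa_range(base: ModelInputs, name: str) -> tuple:
    p = base.params
    pm25 = lambda v: (0.75 * v, 1.25 * v)
    if name == "t2d_care_cost":
        return pm25(p.costs.t2d_extra_care_annual.point)
    if name == "productivity_cost":
        return pm25(p.costs.productivity_loss_annual_under65.point)
    if name == "intervention_cost":
        return pm25(p.costs.intervention_per_participant.point)
    if name == "complication_cost":
        return pm25(p.costs.complication_cost_annual.point)
    if name == "recruitment_cost":
        return pm25(p.costs.recruitment_per_eligible.point)
    if name == "intervention_hr":
        hr = p.hazards.intervention_hr
        return (hr.ci_low, hr.ci_high)
    if name == "discount_rate":
        return (0.0, 0.05)
    raise ValueError(f"unknown OWSA parameter {name!r}")


def _with_value(base: ModelInputs, name: str, value: float) -> ModelInputs:
    p = base.params
    if name == "discount_rate":
        econ = replace(p.economics, discount_rate=value)
        return replace(base, params=p.with_(economics=econ))
    if name == "intervention_hr":
        hz = replace(p.hazards, intervention_hr=fixed(value))
        return replace(base, params=p.with_(hazards=hz))
    cost_field = {"t2d_care_cost": "t2d_extra_care_annual",
                  "productivity_cost": "productivity_loss_annual_under65",
                  "intervention_cost": "intervention_per_participant",
                  "complication_cost": "complication_cost_annual",
                  "recruitment_cost": "recruitment_per_eligible"}[name]
    costs = replace(p.costs, **{cost_field: fixed(value)})
    return replace(base, params=p.with_(costs=costs))


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    nmb_low: float    # NMB with the parameter at low_value
    nmb_high: float


def _nmb_of(inputs: ModelInputs, settings: EconomicSettings) -> float:
    res = run_scenario(inputs, settings)
    return net_monetary_benefit(res.delta_qaly("overall"),
                                -res.savings("overall", "societal"),
                                settings.wtp_threshold)


def run_owsa(base: ModelInputs, parameter: str,
             low: float | None = None, high: float | None = None,
             settings: EconomicSettings | None = None) -> TornadoEntry:
    """Two deterministic runs with one parameter at its low/high bound."""
    settings = settings or base.params.economics
    if low is None or high is None:
        lo, hi = _owsa_range(base, parameter)
        low = lo if low is None else low
        high = hi if high is None else high
    if parameter not in OWSA_PARAMETERS:
        raise ValueError(f"unknown OWSA parameter {parameter!r}")
    if parameter == "discount_rate":
        nmb_low = _nmb_of(base, replace(settings, discount_rate=low))
        nmb_high = _nmb_of(base, replace(settings, discount_rate=high))
    else:
        nmb_low = _nmb_of(_with_value(base, parameter, low), settings)
        nmb_high = _nmb_of(_with_value(base, parameter, high), settings)
    return TornadoEntry(parameter=parameter, low_value=low, high_value=high,
                        nmb_low=nmb_low, nmb_high=nmb_high)


def tornado_frame(base: ModelInputs,
                  settings: EconomicSettings | None = None) -> pd.DataFrame:
    """All declared one-way analyses, widest NMB span first."""
    entries = [run_owsa(base, p, settings=settings) for p in OWSA_PARAMETERS]
    df = pd.DataFrame([(e.parameter, e.low_value, e.high_value,
                        e.nmb_low, e.nmb_high) for e in entries],
                      columns=["parameter", "low", "high",
                               "nmb_low", "nmb_high"])
    return df.reindex((df.nmb_low - df.nmb_high).abs()
                      .sort_values(ascending=False).index)
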
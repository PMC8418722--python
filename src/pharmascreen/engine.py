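"""Four-state annual-cycle Markov cohort engine.

States: at risk of T2D → T2D → T2D with complications → dead (absorbing);
no remission and no skipping back.  Each stratum (gender × entry age ×
FINDRISC group) starts 100% at risk and is advanced one year per cycle.

Conventions (exposed, not hidden): no half-cycle correction; recruitment and
intervention costs are charged at cycle 0 in the intervention arm; state
costs and utilities accrue at cycle end on the post-transition occupancy;
competing risks within a cycle apply mortality first, then incidence /
complication probabilities to survivors, keeping rows stochastic without
renormalization; the cohort ages +1 year per cycle and hazard/reward lookups
use the age at cycle start.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (CohortDefinition, EconomicSettings, ParameterSet,
                         Stratum, age_band_index)
from .survival import (LifeTable, WeibullFit, annual_event_prob,
                       apply_hr_to_prob)

STATES = ("at_risk", "t2d", "t2d_complications", "dead")
COST_CATEGORIES = ("recruitment", "intervention", "care", "basic_care",
                   "medication", "complications", "productivity")
ARMS = ("comparator", "intervention")


@dataclass(frozen=True)
class ModelInputs:
    """Everything one model evaluation needs."""

    params: ParameterSet
    incidence_fit: WeibullFit
    complication_fit: WeibullFit
    life_table: LifeTable
    cohort: CohortDefinition


def discount(value: float, rate: float, cycle: int) -> float:
    """Present value: value / (1+rate)^cycle."""
    if rate < 0:
        raise ValueError("rate must be ≥ 0")
    if cycle < 0:
        raise ValueError("cycle must be ≥ 0")
    return value / (1.0 + rate) ** cycle


def _incidence_covariates(stratum: Stratum) -> dict:
    cov = {"age": stratum.entry_age,
           "male": 1.0 if stratum.gender == "men" else 0.0}
    for s in ("0-6", "7-11", "12-14", "15-19", "20-26"):
        cov[f"findrisc:{s}"] = 1.0 if stratum.findrisc_stratum == s else 0.0
    return cov


def transition_matrix(inputs: ModelInputs, stratum: Stratum, arm: str,
                      cycle: int, t2d_duration: float = 0.0) -> np.ndarray:
    """Row-stochastic 4×4 matrix for one stratum and cycle.

    ``t2d_duration`` is the mean years since T2D diagnosis among current
    T2D-state occupants (the complication hazard clock).
    """
    if cycle < 1:
        raise ValueError("cycle must be ≥ 1")
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    hz = inputs.params.hazards
    age_now = stratum.entry_age + cycle - 1

    q0 = inputs.life_table.annual_death_prob(age_now, stratum.gender)
    hr_gender = hz.t2d_mortality_hr(stratum.gender).point
    q_t2d = min(1.0, apply_hr_to_prob(q0, hr_gender))
    q_comp = min(1.0, apply_hr_to_prob(
        q0, hr_gender * hz.complication_mortality_hr.point))

    p_inc = annual_event_prob(inputs.incidence_fit,
                              _incidence_covariates(stratum), cycle - 1)
    if arm == "intervention" and cycle <= hz.intervention_effect_duration_years:
        p_inc = apply_hr_to_prob(p_inc, hz.intervention_hr.point)

    comp_cov = {"age": age_now - t2d_duration,
                "male": 1.0 if stratum.gender == "men" else 0.0}
    p_comp = annual_event_prob(inputs.complication_fit, comp_cov,
                               t2d_duration)

    M = np.zeros((4, 4))
    M[0] = [(1 - q0) * (1 - p_inc), (1 - q0) * p_inc, 0.0, q0]
    M[1] = [0.0, (1 - q_t2d) * (1 - p_comp), (1 - q_t2d) * p_comp, q_t2d]
    M[2] = [0.0, 0.0, 1 - q_comp, q_comp]
    M[3] = [0.0, 0.0, 0.0, 1.0]
    if ((M < -1e-15) | (M > 1 + 1e-15)).any():
        raise ValueError(f"transition cell outside [0,1]:\n{M}")
    return np.clip(M, 0.0, 1.0)


def cycle_rewards(state_vector: np.ndarray, age: float, gender: str,
                  params: ParameterSet,
                  settings: EconomicSettings) -> tuple:
    """Per-person expected (cost-by-category dict, QALY) for one cycle.

    At risk: baseline utility, no T2D costs.  T2D: baseline − T2D disutility;
    annual extra care, basic care, medication, plus productivity losses under
    age 65 in the societal perspective.  Complications: additionally the
    weighted complication disutility and the annual complication cost.
    Dead contributes nothing.
    """
    occ = np.asarray(state_vector, dtype=float)
    c = params.costs
    u = params.utilities
    base_u = u.baseline_utility(gender, age)
    u_t2d = base_u - u.disutility_t2d.point
    u_comp = u_t2d - u.disutility_complications_weighted.point

    alive_t2dish = occ[1] + occ[2]
    costs = dict.fromkeys(COST_CATEGORIES, 0.0)
    costs["care"] = alive_t2dish * c.t2d_extra_care_annual.point
    costs["basic_care"] = alive_t2dish * c.basic_care_annual(gender).point
    costs["medication"] = alive_t2dish * c.medication_annual.point
    costs["complications"] = occ[2] * c.complication_cost_annual.point
    if settings.perspective == "societal" and age < 65:
        costs["productivity"] = (alive_t2dish
                                 * c.productivity_loss_annual_under65.point)
    qaly = occ[0] * base_u + occ[1] * u_t2d + occ[2] * u_comp
    return costs, qaly


@dataclass
class MarkovTrace:
    """Per-cycle record of one stratum × arm run."""

    stratum: Stratum
    arm: str
    occupancy: np.ndarray          # (H+1, 4)
    ages: np.ndarray               # (H+1,) age at cycle start (entry age at 0)
    costs: np.ndarray              # (H+1, n_categories) undiscounted, societal
    costs_discounted: np.ndarray
    qalys: np.ndarray              # (H+1,) undiscounted
    qalys_discounted: np.ndarray

    def cost_stream(self, perspective: str = "societal",
                    discounted: bool = True) -> np.ndarray:
        arr = self.costs_discounted if discounted else self.costs
        total = arr.sum(axis=1)
        if perspective == "direct_only":
            total = total - arr[:, COST_CATEGORIES.index("productivity")]
        return total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cyc in range(self.occupancy.shape[0]):
            for si, state in enumerate(STATES):
                rows.append((self.stratum.gender, self.stratum.entry_age,
                             self.stratum.findrisc_stratum, self.arm, cyc,
                             state, self.occupancy[cyc, si]))
        return pd.DataFrame(rows, columns=["gender", "entry_age",
                                           "findrisc_stratum", "arm", "cycle",
                                           "state", "occupancy"])


def _survival_vector(fit: WeibullFit, lp: float, tmax: int) -> np.ndarray:
    """S(t) for t = 0..tmax at a fixed linear predictor."""
    t = np.arange(tmax + 1, dtype=float)
    with np.errstate(divide="ignore"):
        logt = np.log(t, where=t > 0, out=np.full_like(t, -np.inf))
    if fit.parameterization == "AFT":
        log_ch = fit.shape * (logt - lp)
    else:
        log_ch = lp + fit.shape * logt
    return np.exp(-np.exp(np.clip(log_ch, -700, 700)))


def run_stratum(inputs: ModelInputs, stratum: Stratum, arm: str,
                settings: EconomicSettings) -> MarkovTrace:
    """Advance one stratum through the horizon; per-person quantities.

    Scalar fast path; cycle-for-cycle identical to composing
    :func:`transition_matrix` with :func:`cycle_rewards` (a property the
    test suite checks directly).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    H = settings.horizon_years
    r = settings.discount_rate
    p = inputs.params
    hz = p.hazards
    gender = stratum.gender
    male = 1.0 if gender == "men" else 0.0

    occ = np.zeros((H + 1, 4))
    occ[0, 0] = 1.0
    ages = stratum.entry_age + np.arange(H + 1)
    costs = np.zeros((H + 1, len(COST_CATEGORIES)))
    qalys = np.zeros(H + 1)

    if arm == "intervention":
        costs[0, 0] = p.costs.recruitment_per_eligible.point
        costs[0, 1] = p.costs.intervention_per_participant.point

    # incidence: covariates fixed at entry, time = years since model entry
    inc_lp = inputs.incidence_fit.linear_predictor(
        _incidence_covariates(stratum))
    S_inc = _survival_vector(inputs.incidence_fit, inc_lp, H)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_inc = np.where(S_inc[:-1] > 0, 1.0 - S_inc[1:] / S_inc[:-1], 1.0)
    p_inc = np.clip(p_inc, 0.0, 1.0)
    if arm == "intervention":
        d = min(hz.intervention_effect_duration_years, H)
        hr_i = hz.intervention_hr.point
        p_inc[:d] = 1.0 - (1.0 - p_inc[:d]) ** hr_i

    hr_t2d = hz.t2d_mortality_hr(gender).point
    hr_comp = hr_t2d * hz.complication_mortality_hr.point
    qx = inputs.life_table.qx_array(gender, int(ages[-1]))

    comp_fit = inputs.complication_fit
    comp_base = comp_fit.linear_predictor({"age": 0.0, "male": male})
    comp_age_beta = comp_fit.coefficients.get("age", 0.0)
    comp_shape = comp_fit.shape
    comp_aft = comp_fit.parameterization == "AFT"

    c = p.costs
    cost_care = c.t2d_extra_care_annual.point
    cost_basic = c.basic_care_annual(gender).point
    cost_med = c.medication_annual.point
    cost_compl = c.complication_cost_annual.point
    cost_prod = c.productivity_loss_annual_under65.point
    u = p.utilities
    du_t2d = u.disutility_t2d.point
    du_comp = u.disutility_complications_weighted.point
    u_band = [u.baseline[(gender, i)].point for i in range(4)]

    dur = 0.0  # mean years since T2D diagnosis among T2D-state occupants
    for cyc in range(1, H + 1):
        age_now = ages[cyc - 1]
        q0 = qx[int(age_now)]
        q_t2d = min(1.0, 1.0 - (1.0 - q0) ** hr_t2d)
        q_comp = min(1.0, 1.0 - (1.0 - q0) ** hr_comp)

        lp_c = comp_base + comp_age_beta * (age_now - dur)
        if comp_aft:
            # AFT linear predictor already includes the age term
            lp_c = comp_fit.linear_predictor({"age": age_now - dur,
                                              "male": male})
            s0 = 1.0 if dur == 0 else math.exp(
                -math.exp(comp_shape * (math.log(dur) - lp_c)))
            s1 = math.exp(-math.exp(comp_shape * (math.log(dur + 1) - lp_c)))
        else:
            s0 = 1.0 if dur == 0 else math.exp(
                -math.exp(lp_c + comp_shape * math.log(dur)))
            s1 = math.exp(-math.exp(lp_c + comp_shape * math.log(dur + 1)))
        p_comp = min(1.0, max(0.0, 1.0 - s1 / s0)) if s0 > 0 else 1.0

        a0, t0, c0, d0 = occ[cyc - 1]
        entrants = a0 * (1 - q0) * p_inc[cyc - 1]
        stayers = t0 * (1 - q_t2d) * (1 - p_comp)
        occ[cyc, 0] = a0 * (1 - q0) * (1 - p_inc[cyc - 1])
        occ[cyc, 1] = stayers + entrants
        occ[cyc, 2] = t0 * (1 - q_t2d) * p_comp + c0 * (1 - q_comp)
        occ[cyc, 3] = d0 + a0 * q0 + t0 * q_t2d + c0 * q_comp
        dur = (stayers * (dur + 1.0)) / (stayers + entrants) \
            if stayers + entrants > 0 else 0.0

        base_u = u_band[age_band_index(age_now)]
        alive_t2dish = occ[cyc, 1] + occ[cyc, 2]
        costs[cyc, 2] = alive_t2dish * cost_care
        costs[cyc, 3] = alive_t2dish * cost_basic
        costs[cyc, 4] = alive_t2dish * cost_med
        costs[cyc, 5] = occ[cyc, 2] * cost_compl
        if age_now < 65:
            costs[cyc, 6] = alive_t2dish * cost_prod
        qalys[cyc] = (occ[cyc, 0] * base_u
                      + occ[cyc, 1] * (base_u - du_t2d)
                      + occ[cyc, 2] * (base_u - du_t2d - du_comp))

    disc = (1.0 + r) ** -np.arange(H + 1)
    return MarkovTrace(stratum=stratum, arm=arm, occupancy=occ, ages=ages,
                       costs=costs, costs_discounted=costs * disc[:, None],
                       qalys=qalys, qalys_discounted=qalys * disc)


@dataclass
class ArmResult:
    """Count-weighted per-person streams for one arm, by gender."""

    arm: str
    horizon: int
    counts: dict                       # gender -> persons
    cost_streams: dict                 # (gender, perspective) -> (H+1,) disc €
    qaly_streams: dict                 # gender -> (H+1,) discounted QALYs
    traces: list = field(default_factory=list)

    def total_cost(self, gender: str, perspective: str) -> float:
        return float(self.cost_streams[(gender, perspective)].sum())

    def total_qalys(self, gender: str) -> float:
        return float(self.qaly_streams[gender].sum())


def run_cohort(inputs: ModelInputs, arm: str, settings: EconomicSettings,
               keep_traces: bool = False) -> ArmResult:
    """Run every stratum and aggregate count-weighted per-person streams."""
    H = settings.horizon_years
    strata = [s for s in inputs.cohort.strata if s.count > 0]
    counts = {g: inputs.cohort.total_by_gender(g) for g in ("women", "men")}
    if not strata:
        warnings.warn("empty cohort: zero-valued result")
    cost = {(g, p): np.zeros(H + 1) for g in ("women", "men")
            for p in ("societal", "direct_only")}
    qaly = {g: np.zeros(H + 1) for g in ("women", "men")}
    traces = []
    for s in strata:
        tr = run_stratum(inputs, s, arm, settings)
        w = s.count
        for p in ("societal", "direct_only"):
            cost[(s.gender, p)] += w * tr.cost_stream(p, discounted=True)
        qaly[s.gender] += w * tr.qalys_discounted
        if keep_traces:
            traces.append(tr)
    for g in ("women", "men"):
        n = counts[g]
        if n > 0:
            for p in ("societal", "direct_only"):
                cost[(g, p)] /= n
            qaly[g] /= n
    return ArmResult(arm=arm, horizon=H, counts=counts, cost_streams=cost,
                     qaly_streams=qaly, traces=traces)


@dataclass
class ScenarioResult:
    """Incremental results, intervention vs current practice.

    ``savings`` are comparator costs minus intervention-arm costs (positive
    = the programme saves money); per-person unless scaled.
    """

    horizon: int
    counts: dict
    savings_per_person: dict        # (gender, perspective) -> €
    delta_qaly_per_person: dict     # gender -> QALYs
    savings_streams: dict           # (gender, perspective) -> (H+1,) disc €/yr
    initial_cost_per_person: float  # recruitment + intervention, year 0

    def _wmean(self, by_gender: dict) -> float:
        n = sum(self.counts.values())
        return sum(by_gender[g] * self.counts[g] for g in self.counts) / n

    def savings(self, gender: str = "overall",
                perspective: str = "societal") -> float:
        if gender == "overall":
            return self._wmean({g: self.savings_per_person[(g, perspective)]
                                for g in self.counts})
        return self.savings_per_person[(gender, perspective)]

    def delta_qaly(self, gender: str = "overall") -> float:
        if gender == "overall":
            return self._wmean(self.delta_qaly_per_person)
        return self.delta_qaly_per_person[gender]

    def population_savings(self, gender: str = "overall",
                           perspective: str = "societal") -> float:
        if gender == "overall":
            return sum(self.population_savings(g, perspective)
                       for g in self.counts)
        return self.savings(gender, perspective) * self.counts[gender]

    def population_qalys(self, gender: str = "overall") -> float:
        if gender == "overall":
            return sum(self.population_qalys(g) for g in self.counts)
        return self.delta_qaly(gender) * self.counts[gender]


def run_scenario(inputs: ModelInputs,
                 settings: EconomicSettings | None = None) -> ScenarioResult:
    """Run both arms and form the incremental comparison."""
    settings = settings or inputs.params.economics
    comp = run_cohort(inputs, "comparator", settings)
    intv = run_cohort(inputs, "intervention", settings)
    genders = ("women", "men")
    persp = ("societal", "direct_only")
    savings = {(g, p): comp.total_cost(g, p) - intv.total_cost(g, p)
               for g in genders for p in persp}
    dq = {g: intv.total_qalys(g) - comp.total_qalys(g) for g in genders}
    streams = {(g, p): comp.cost_streams[(g, p)] - intv.cost_streams[(g, p)]
               for g in genders for p in persp}
    c = inputs.params.costs
    init = (c.recruitment_per_eligible.point
            + c.intervention_per_participant.point)
    return ScenarioResult(horizon=settings.horizon_years, counts=comp.counts,
                          savings_per_person=savings,
                          delta_qaly_per_person=dq, savings_streams=streams,
                          initial_cost_per_person=init)
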
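"""Decision metrics: net monetary benefit, SROI, payback time, scaling.

Sign convention: ``delta_cost`` is intervention cost minus comparator cost
(negative = saving); ``savings`` = −delta_cost.  NMB = ΔQALY·WTP − Δcost, so
a dominant programme (saves money, gains QALYs) has positive NMB at any
willingness-to-pay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ScenarioResult


def net_monetary_benefit(delta_qaly: float, delta_cost: float,
                         wtp: float) -> float:
    """NMB = ΔQALY·WTP − Δcost (Δcost negative when the programme saves)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be ≥ 0")
    return delta_qaly * wtp - delta_cost


def sroi(discounted_savings: float, initial_costs: float) -> float:
    """Social return on investment: savings per euro invested."""
    if initial_costs <= 0:
        raise ValueError("initial costs must be > 0")
    return discounted_savings / initial_costs


def payback_time(per_cycle_net_savings, per_cycle_costs):
    """First year cumulative discounted savings reach cumulative costs.

    Both streams are aligned by cycle and already discounted.  Returns the
    break-even year as an integer (whole years) or ``None`` if break-even is
    not reached within the horizon.
    """
    sav = np.asarray(per_cycle_net_savings, dtype=float)
    cost = np.asarray(per_cycle_costs, dtype=float)
    if sav.shape != cost.shape:
        raise ValueError("streams must be aligned by cycle")
    gap = np.cumsum(sav) - np.cumsum(cost)
    hits = np.nonzero(gap >= 0)[0]
    if len(hits) == 0 or not np.any(sav > 0):
        return None
    return int(math.ceil(hits[0]))


def scale_population(per_person_value: float, count: float) -> float:
    """Per-person value × cohort size."""
    if count < 0:
        raise ValueError("count must be ≥ 0")
    return per_person_value * count


def is_dominant(delta_cost: float, delta_qaly: float) -> bool:
    """Less costly and more effective than the comparator."""
    return delta_cost < 0 and delta_qaly > 0


@dataclass(frozen=True)
class EconomicSummary:
    """Headline decision metrics for one scenario run and perspective."""

    perspective: str
    horizon: int
    delta_cost: float               # € per person, negative = saving
    delta_qaly: float
    nmb: float
    sroi: float
    payback_years_by_gender: dict   # gender -> int or None
    initial_costs: float            # € population-level investment
    population_savings: float       # €
    population_qalys: float

    def __post_init__(self) -> None:
        expected = self.delta_qaly * self._wtp - self.delta_cost
        if abs(self.nmb - expected) > 1e-6 * max(1.0, abs(expected)):
            raise ValueError("NMB does not satisfy ΔQALY·WTP − Δcost")

    _wtp: float = 50_000.0


def summarize(result: ScenarioResult, wtp: float = 50_000.0,
              perspective: str = "societal") -> EconomicSummary:
    """Condense a scenario run into the reported decision metrics."""
    savings = result.savings("overall", perspective)
    dq = result.delta_qaly("overall")
    n_total = sum(result.counts.values())
    init_pop = result.initial_cost_per_person * n_total

    payback = {}
    for g in result.counts:
        stream = result.savings_streams[(g, perspective)].copy()
        costs = np.zeros_like(stream)
        costs[0] = result.initial_cost_per_person
        # the cycle-0 savings entry is −(recruitment+intervention); the state
        # cost savings alone are the stream with that charge moved to costs
        state_savings = stream.copy()
        state_savings[0] += result.initial_cost_per_person
        payback[g] = payback_time(state_savings, costs)

    return EconomicSummary(
        perspective=perspective, horizon=result.horizon,
        delta_cost=-savings, delta_qaly=dq,
        nmb=net_monetary_benefit(dq, -savings, wtp),
        sroi=sroi(scale_population(savings, n_total), init_pop),
        payback_years_by_gender=payback,
        initial_costs=init_pop,
        population_savings=scale_population(savings, n_total),
        population_qalys=scale_population(dq, n_total),
        _wtp=wtp)


def summary_frame(summaries) -> pd.DataFrame:
    """Tidy table of EconomicSummary rows (one per horizon × perspective)."""
    rows = []
    for s in summaries:
        rows.append({
            "horizon": s.horizon, "perspective": s.perspective,
            "savings_per_person_eur": -s.delta_cost,
            "delta_qaly_per_person": s.delta_qaly,
            "nmb_eur": s.nmb, "sroi": s.sroi,
            "population_savings_meur": s.population_savings / 1e6,
            "population_qalys": s.population_qalys,
            "payback_years_women": s.payback_years_by_gender.get("women"),
            "payback_years_men": s.payback_years_by_gender.get("men"),
        })
    return pd.DataFrame(rows)
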
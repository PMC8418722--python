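"""Model inputs: costs, utilities, hazard ratios, economic settings, cohort.

Every uncertain input carries a :class:`DistributionSpec` describing how it is
sampled in the probabilistic sensitivity analysis.  Published summaries come in
three flavours — mean with a ±25% range, mean with a 95% CI, or explicit
beta alpha/beta pairs — and :func:`moment_match` converts each into sampler
parameters that reproduce the published point value exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GENDERS = ("women", "men")
AGE_BANDS = ((30, 44), (45, 54), (55, 64), (65, None))
FINDRISC_STRATA = ("0-6", "7-11", "12-14", "15-19", "20-26")

_Z95 = 1.959963984540054  # standard-normal 97.5% quantile


class InvalidSpecError(ValueError):
    """A DistributionSpec that cannot be moment-matched."""


# ---------------------------------------------------------------------------
# Distribution specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """How one scalar input is sampled in the PSA.

    Exactly one parameterization route is populated: ``mean+se`` (gamma,
    normal, beta via method of moments), ``alpha+beta`` (beta), ``mean+ci``
    (lognormal), or ``fixed``.
    """

    kind: str  # gamma | lognormal | beta | normal | fixed
    mean: float = float("nan")
    se: float = float("nan")
    alpha: float = float("nan")
    beta: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in {"gamma", "lognormal", "beta", "normal", "fixed"}:
            raise InvalidSpecError(f"unknown distribution kind {self.kind!r}")
        routes = [
            math.isfinite(self.mean) and math.isfinite(self.se),
            math.isfinite(self.alpha) and math.isfinite(self.beta),
            math.isfinite(self.mean) and math.isfinite(self.ci_low)
            and math.isfinite(self.ci_high),
            self.kind == "fixed" and math.isfinite(self.mean),
        ]
        if self.kind != "fixed" and not any(routes[:3]):
            raise InvalidSpecError(
                f"{self.kind} spec needs mean+se, alpha+beta or mean+ci")
        if self.kind == "lognormal" and math.isfinite(self.mean) and self.mean <= 0:
            raise InvalidSpecError("lognormal mean must be positive")

    @property
    def point(self) -> float:
        """Published point value (the mean, or alpha/(alpha+beta) for beta)."""
        if math.isfinite(self.mean):
            return self.mean
        return self.alpha / (self.alpha + self.beta)


def fixed(value: float) -> DistributionSpec:
    return DistributionSpec(kind="fixed", mean=value, se=0.0)


def se_from_pm25(mean: float) -> float:
    """Standard error implied by a ±25% range around ``mean``.

    SE = (1.25·m − 0.75·m) / (2·1.96); linear in ``mean`` and zero at zero.
    """
    if not math.isfinite(mean):
        raise ValueError("mean must be finite")
    return (1.25 * mean - 0.75 * mean) / (2 * 1.96)


def moment_match(spec: DistributionSpec) -> dict:
    """Convert a :class:`DistributionSpec` into sampler parameters.

    gamma: shape=(mean/se)², scale=se²/mean — reproduces the mean exactly.
    beta: from alpha/beta when given, else method of moments from mean/se.
    lognormal: location=ln(mean) (point value treated as the median),
    log-scale=(ln(ci_high)−ln(ci_low))/(2·1.96).
    normal: loc=mean, scale=se.
    """
    if spec.kind == "fixed":
        return {"kind": "fixed", "value": spec.point}
    if spec.kind == "gamma":
        if spec.se == 0:
            return {"kind": "fixed", "value": spec.mean}
        return {"kind": "gamma",
                "shape": (spec.mean / spec.se) ** 2,
                "scale": spec.se ** 2 / spec.mean}
    if spec.kind == "beta":
        if math.isfinite(spec.alpha) and math.isfinite(spec.beta):
            if spec.alpha <= 0 or spec.beta <= 0:
                raise InvalidSpecError("beta alpha/beta must be positive")
            return {"kind": "beta", "alpha": spec.alpha, "beta": spec.beta}
        m, s = spec.mean, spec.se
        if not 0 < m < 1:
            raise InvalidSpecError("beta mean must lie in (0, 1)")
        if s == 0:
            return {"kind": "fixed", "value": m}
        if s * s >= m * (1 - m):
            raise InvalidSpecError("beta variance se² must be < mean(1−mean)")
        nu = m * (1 - m) / (s * s) - 1.0
        return {"kind": "beta", "alpha": m * nu, "beta": (1 - m) * nu}
    if spec.kind == "lognormal":
        if not (math.isfinite(spec.ci_low) and math.isfinite(spec.ci_high)
                and 0 < spec.ci_low < spec.ci_high):
            raise InvalidSpecError("lognormal needs positive CI bounds")
        sigma = (math.log(spec.ci_high) - math.log(spec.ci_low)) / (2 * _Z95)
        return {"kind": "lognormal", "mu": math.log(spec.mean), "sigma": sigma}
    if spec.kind == "normal":
        if spec.se == 0:
            return {"kind": "fixed", "value": spec.mean}
        return {"kind": "normal", "loc": spec.mean, "scale": spec.se}
    raise InvalidSpecError(spec.kind)  # pragma: no cover


def sample_spec(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One random draw from a moment-matched spec."""
    p = moment_match(spec)
    if p["kind"] == "fixed":
        return p["value"]
    if p["kind"] == "gamma":
        return float(rng.gamma(p["shape"], p["scale"]))
    if p["kind"] == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    if p["kind"] == "lognormal":
        return float(rng.lognormal(p["mu"], p["sigma"]))
    if p["kind"] == "normal":
        return float(rng.normal(p["loc"], p["scale"]))
    raise InvalidSpecError(p["kind"])  # pragma: no cover


# ---------------------------------------------------------------------------
# Input blocks (published point values with their PSA distributions)
# ---------------------------------------------------------------------------

def _gamma_pm25(mean: float) -> DistributionSpec:
    return DistributionSpec(kind="gamma", mean=mean, se=se_from_pm25(mean))


@dataclass(frozen=True)
class CostInputs:
    """Annual and one-off cost inputs in euros (2019 price level)."""

    recruitment_per_eligible: DistributionSpec = field(
        default_factory=lambda: _gamma_pm25(24.5))
    intervention_per_participant: DistributionSpec = field(
        default_factory=lambda: _gamma_pm25(650.0))
    t2d_extra_care_annual: DistributionSpec = field(
        default_factory=lambda: _gamma_pm25(3315.0))
    complication_cost_annual: DistributionSpec = field(
        default_factory=lambda: _gamma_pm25(4401.0))
    productivity_loss_annual_under65: DistributionSpec = field(
        default_factory=lambda: _gamma_pm25(7632.0))
    basic_care_annual_men: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("gamma", mean=551.0, se=9.53))
    basic_care_annual_women: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("gamma", mean=533.0, se=9.82))
    medication_annual: DistributionSpec = field(
        default_factory=lambda: _gamma_pm25(584.0))

    def __post_init__(self) -> None:
        for name, spec in self.__dict__.items():
            if spec.point < 0:
                raise ValueError(f"cost {name} must be ≥ 0")

    def basic_care_annual(self, gender: str) -> DistributionSpec:
        return (self.basic_care_annual_men if gender == "men"
                else self.basic_care_annual_women)


_BASELINE_UTILITY_AB = {
    # (gender, band index) -> (alpha, beta); means 0.906/0.865/0.810/0.770
    # for women and 0.917/0.876/0.821/0.781 for men.
    ("women", 0): (8573.0, 889.0),
    ("women", 1): (4040.0, 631.0),
    ("women", 2): (3463.0, 812.0),
    ("women", 3): (2130.0, 636.0),
    ("men", 0): (7755.0, 702.0),
    ("men", 1): (3806.0, 539.0),
    ("men", 2): (3351.0, 731.0),
    ("men", 3): (2087.0, 585.0),
}


def age_band_index(age: float) -> int:
    """Index of the utility age band (30–44, 45–54, 55–64, 65+)."""
    if age < 45:
        return 0
    if age < 55:
        return 1
    if age < 65:
        return 2
    return 3


@dataclass(frozen=True)
class UtilityInputs:
    """EQ-5D-3L baseline utilities by gender × age band, plus disutilities."""

    baseline: Mapping[tuple, DistributionSpec] = field(default_factory=lambda: {
        key: DistributionSpec("beta", alpha=a, beta=b)
        for key, (a, b) in _BASELINE_UTILITY_AB.items()})
    disutility_t2d: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta", alpha=11.19, beta=261.9))
    disutility_complications_weighted: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "beta", mean=0.119, se=se_from_pm25(0.119)))

    def __post_init__(self) -> None:
        for g in GENDERS:
            vals = [self.baseline[(g, i)].point for i in range(4)]
            if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValueError(f"baseline utilities must not rise with age ({g})")
            floor = min(vals) - self.disutility_t2d.point \
                - self.disutility_complications_weighted.point
            if floor <= 0:
                raise ValueError("disutilities exceed baseline utility")

    def baseline_utility(self, gender: str, age: float) -> float:
        return self.baseline[(gender, age_band_index(age))].point


@dataclass(frozen=True)
class HazardInputs:
    """Hazard ratios: intervention effect and excess mortality."""

    intervention_hr: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "lognormal", mean=0.74, ci_low=0.53, ci_high=1.03))
    intervention_effect_duration_years: int = 15
    t2d_mortality_hr_women: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "lognormal", mean=2.47, ci_low=2.42, ci_high=3.06))
    t2d_mortality_hr_men: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "lognormal", mean=1.93, ci_low=1.79, ci_high=2.07))
    complication_mortality_hr: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            "lognormal", mean=2.36, ci_low=1.70, ci_high=3.29))

    def __post_init__(self) -> None:
        for name in ("intervention_hr", "t2d_mortality_hr_women",
                     "t2d_mortality_hr_men", "complication_mortality_hr"):
            if getattr(self, name).point <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.intervention_effect_duration_years < 0:
            raise ValueError("effect duration must be ≥ 0")

    def t2d_mortality_hr(self, gender: str) -> DistributionSpec:
        return (self.t2d_mortality_hr_men if gender == "men"
                else self.t2d_mortality_hr_women)


@dataclass(frozen=True)
class EconomicSettings:
    """Discounting, horizon, willingness-to-pay and costing perspective."""

    discount_rate: float = 0.03
    horizon_years: int = 20
    wtp_threshold: float = 50_000.0
    perspective: str = "societal"  # societal | direct_only

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be ≥ 0")
        if self.horizon_years < 1:
            raise ValueError("horizon must be ≥ 1 year")
        if self.perspective not in {"societal", "direct_only"}:
            raise ValueError("perspective must be societal or direct_only")


# ---------------------------------------------------------------------------
# Reached cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stratum:
    gender: str
    entry_age: int
    findrisc_stratum: str
    count: int


@dataclass(frozen=True)
class CohortDefinition:
    """The screened-and-reached cohort, stratified by gender, entry age and
    FINDRISC score group."""

    strata: tuple
    reach_rate: float = 0.099

    def __post_init__(self) -> None:
        for s in self.strata:
            if s.count < 0:
                raise ValueError("stratum counts must be ≥ 0")
            if s.findrisc_stratum not in FINDRISC_STRATA:
                raise ValueError(f"unknown FINDRISC stratum {s.findrisc_stratum}")

    @property
    def total_reached(self) -> int:
        return sum(s.count for s in self.strata)

    def total_by_gender(self, gender: str) -> int:
        return sum(s.count for s in self.strata if s.gender == gender)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.gender, s.entry_age, s.findrisc_stratum, s.count)
             for s in self.strata],
            columns=["gender", "entry_age", "findrisc_stratum", "count"])


def compute_reach_rate(forms_handed: int, completions: int) -> float:
    """Fraction of handed-out risk-score forms completed online."""
    if forms_handed <= 0:
        raise ValueError("forms_handed must be positive")
    if not 0 <= completions <= forms_handed:
        raise ValueError("completions must lie in [0, forms_handed]")
    return completions / forms_handed


def largest_remainder_round(values: Sequence[float], total: int) -> np.ndarray:
    """Round non-negative values to integers summing exactly to ``total``."""
    values = np.asarray(values, dtype=float)
    if values.sum() == 0:
        return np.zeros(len(values), dtype=int)
    scaled = values * (total / values.sum())
    floors = np.floor(scaled).astype(int)
    shortfall = total - int(floors.sum())
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:shortfall]] += 1
    return floors


def build_reached_cohort(
    population_by_age_gender: pd.DataFrame,
    visit_rate_by_age_gender: pd.DataFrame,
    t2d_free_fraction: pd.DataFrame,
    reach_rate: float,
    findrisc_distribution: pd.DataFrame,
    age_group_width: int = 1,
) -> CohortDefinition:
    """Construct the reached cohort.

    Per-stratum expected count = population × pharmacy-visit rate ×
    T2D-free fraction × reach rate × FINDRISC share.  The three age×gender
    tables need columns (age, gender, value-column); ``findrisc_distribution``
    needs (gender, findrisc_stratum, share) with shares summing to 1 per
    gender.  Counts are rounded by the largest-remainder method within each
    gender so gender totals are conserved exactly.  ``age_group_width`` > 1
    aggregates entry ages into groups represented by their count-weighted
    mean age (rounded), trading age resolution for speed.
    """
    if not 0 <= reach_rate <= 1:
        raise ValueError("reach_rate must lie in [0, 1]")

    def _pivot(df: pd.DataFrame, name: str) -> pd.DataFrame:
        value_col = [c for c in df.columns if c not in ("age", "gender")][0]
        return df.rename(columns={value_col: name})[["age", "gender", name]]

    merged = _pivot(population_by_age_gender, "population")
    for df, name in ((visit_rate_by_age_gender, "visit_rate"),
                     (t2d_free_fraction, "t2d_free")):
        merged = merged.merge(_pivot(df, name), on=["age", "gender"], how="left")

    ages = range(30, 80)
    missing = [(a, g) for g in GENDERS for a in ages
               if not ((merged.age == a) & (merged.gender == g)).any()]
    if missing or merged[["visit_rate", "t2d_free"]].isna().any().any():
        gaps = merged[merged.isna().any(axis=1)][["age", "gender"]]
        missing += list(gaps.itertuples(index=False, name=None))
        raise ValueError(f"missing age/gender cells: {sorted(set(missing))}")

    for col in ("visit_rate", "t2d_free"):
        if ((merged[col] < 0) | (merged[col] > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")

    merged = merged[merged.age.between(30, 79)].copy()
    merged["eligible"] = (merged.population * merged.visit_rate
                          * merged.t2d_free * reach_rate)

    fd = findrisc_distribution.copy()
    for g in GENDERS:
        s = fd.loc[fd.gender == g, "share"].sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"FINDRISC shares for {g} sum to {s}, expected 1")

    strata = []
    for g in GENDERS:
        sub = merged[merged.gender == g]
        if age_group_width > 1:
            group = ((sub.age - 30) // age_group_width).to_numpy()
        else:
            group = sub.age.to_numpy()
        rows = []  # (entry_age, stratum, expected count)
        for gid in np.unique(group):
            block = sub[group == gid]
            w = block.eligible.to_numpy()
            mean_age = (block.age.to_numpy() * w).sum() / w.sum() if w.sum() else \
                float(block.age.mean())
            for _, frow in fd[fd.gender == g].iterrows():
                rows.append((int(round(mean_age)), frow.findrisc_stratum,
                             w.sum() * frow.share))
        expected = np.array([r[2] for r in rows])
        counts = largest_remainder_round(expected, int(round(expected.sum())))
        strata += [Stratum(g, a, st, int(c))
                   for (a, st, _), c in zip(rows, counts)]
    return CohortDefinition(strata=tuple(strata), reach_rate=reach_rate)


# ---------------------------------------------------------------------------
# The full parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    """All scalar model inputs for one model evaluation."""

    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    hazards: HazardInputs = field(default_factory=HazardInputs)
    economics: EconomicSettings = field(default_factory=EconomicSettings)

    def with_(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


def default_parameters() -> ParameterSet:
    """Published base-case point values with their PSA distributions."""
    return ParameterSet()
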
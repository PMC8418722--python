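"""Synthetic stand-ins for the restricted study inputs.

The study's survival follow-up data, pharmacy-visit tables and national life
table are not publicly deposited, so this module generates replacements with
known ground truth: right-censored Weibull time-to-T2D conditional on age,
gender and FINDRISC stratum; time-to-first-complication after diagnosis;
a Gompertz-form life table; and population / visit-rate / T2D-free /
FINDRISC-share tables with an optional calibration mode that rescales the
population so the reached cohort hits a requested total.

Every generator is a pure function of its seed.  The reference incidence
model is anchored, once, to the published FINDRISC 10-year risk table
(about 1 / 4 / 17 / 33 / 50 % for the five score groups at the reference
age of 55); it makes no attempt to match the restricted FINRISK follow-up
statistically.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ModelInputs
from .parameters import (CohortDefinition, FINDRISC_STRATA, ParameterSet,
                         build_reached_cohort, default_parameters)
from .survival import LifeTable, SurvivalRecord, WeibullFit, fit_weibull

REFERENCE_AGE = 55
# 10-year cumulative T2D risk per FINDRISC group at the reference age
_FINDRISC_RISK10 = {"0-6": 0.01, "7-11": 0.04, "12-14": 0.17,
                    "15-19": 0.33, "20-26": 0.50}


def true_incidence_coefficients(shape: float = 1.3) -> dict:
    """Ground-truth PH coefficients of the synthetic incidence model."""
    lam_ref = -math.log(1 - _FINDRISC_RISK10["0-6"])
    beta = {"intercept": (math.log(lam_ref) - 0.02 * REFERENCE_AGE
                          - shape * math.log(10.0)),
            "age": 0.02, "male": 0.10}
    for s in FINDRISC_STRATA[1:]:
        lam = -math.log(1 - _FINDRISC_RISK10[s])
        beta[f"findrisc:{s}"] = math.log(lam / lam_ref)
    return beta


def true_complication_coefficients(shape: float = 1.2) -> dict:
    """Ground truth for time to first complication after T2D diagnosis:
    about 40% cumulative incidence at 10 years for a 60-year-old."""
    lam60 = -math.log(1 - 0.40)
    return {"intercept": (math.log(lam60) - 0.03 * 60
                          - shape * math.log(10.0)),
            "age": 0.03, "male": 0.15}


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for one synthetic survival dataset."""

    n_subjects: int = 5000
    true_shape: float = 1.3
    true_coefficients: dict = field(
        default_factory=true_incidence_coefficients)
    censor_horizon_years: float = 10.0
    uniform_entry: bool = False
    age_range: tuple = (30, 79)
    male_fraction: float = 0.5
    findrisc_probs: tuple = (0.02, 0.08, 0.30, 0.40, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be ≥ 1")
        if self.true_shape <= 0:
            raise ValueError("shape must be > 0")
        if abs(sum(self.findrisc_probs) - 1.0) > 1e-9:
            raise ValueError("findrisc_probs must sum to 1")


def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator,
                     with_findrisc: bool) -> pd.DataFrame:
    n = cfg.n_subjects
    df = pd.DataFrame({
        "age": rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, n),
        "male": rng.random(n) < cfg.male_fraction})
    if with_findrisc:
        df["findrisc_stratum"] = rng.choice(FINDRISC_STRATA, size=n,
                                            p=cfg.findrisc_probs)
    return df


def _event_times(cfg: GeneratorConfig, cov: pd.DataFrame,
                 rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw: T = (E / exp(x'β))^(1/ρ) with E ~ Exp(1)."""
    beta = cfg.true_coefficients
    lp = np.full(len(cov), beta["intercept"], dtype=float)
    lp += beta.get("age", 0.0) * cov.age.to_numpy()
    lp += beta.get("male", 0.0) * cov.male.to_numpy(dtype=float)
    if "findrisc_stratum" in cov:
        for s in FINDRISC_STRATA:
            key = f"findrisc:{s}"
            if key in beta:
                lp += beta[key] * (cov.findrisc_stratum == s).to_numpy(float)
    e = rng.exponential(size=len(cov))
    return (e / np.exp(lp)) ** (1.0 / cfg.true_shape)


def _to_records(cfg: GeneratorConfig, cov: pd.DataFrame, T: np.ndarray,
                rng: np.random.Generator) -> list:
    if cfg.uniform_entry:
        censor = rng.uniform(0.0, cfg.censor_horizon_years, len(cov))
    else:
        censor = np.full(len(cov), float(cfg.censor_horizon_years))
    time = np.minimum(T, censor)
    event = (T <= censor).astype(int)
    time = np.maximum(time, 1e-9)  # degenerate horizon: censored "at entry"
    return [SurvivalRecord(
        subject_id=i, entry_age=float(cov.age.iloc[i]),
        gender="men" if cov.male.iloc[i] else "women",
        time=float(time[i]), event=int(event[i]),
        findrisc_stratum=(str(cov.findrisc_stratum.iloc[i])
                          if "findrisc_stratum" in cov else None))
        for i in range(len(cov))]


def synth_incidence_dataset(cfg: GeneratorConfig | None = None) -> list:
    """Right-censored time-to-T2D records by age, gender, FINDRISC group."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    cov = _draw_covariates(cfg, rng, with_findrisc=True)
    return _to_records(cfg, cov, _event_times(cfg, cov, rng), rng)


def synth_complication_dataset(cfg: GeneratorConfig | None = None) -> list:
    """Time to first complication after T2D diagnosis (age, gender only).

    Defaults mirror the scale of the real-world EHR source: 1151 newly
    diagnosed patients followed for at most 9 years.
    """
    cfg = cfg or GeneratorConfig(
        n_subjects=1151, true_shape=1.2,
        true_coefficients=true_complication_coefficients(),
        censor_horizon_years=9.0, age_range=(35, 85), seed=1)
    rng = np.random.default_rng(cfg.seed)
    cov = _draw_covariates(cfg, rng, with_findrisc=False)
    return _to_records(cfg, cov, _event_times(cfg, cov, rng), rng)


DEFAULT_GOMPERTZ = {"women": (2.03e-5, 0.09), "men": (4.05e-5, 0.09)}


def synth_life_table(max_age: int = 110,
                     gender_params: dict | None = None) -> LifeTable:
    """Gompertz life table: annual death probability a·exp(b·age), capped
    at 1; default parameters give men higher mortality than women."""
    if max_age < 30:
        raise ValueError("max_age must be ≥ 30")
    params = gender_params or DEFAULT_GOMPERTZ
    rows = []
    for gender, (a, b) in params.items():
        ages = np.arange(0, max_age + 1)
        qx = np.minimum(a * np.exp(b * ages), 1.0)
        rows.append(pd.DataFrame({"age": ages, "gender": gender, "qx": qx}))
    return LifeTable(table=pd.concat(rows, ignore_index=True))


DEFAULT_FINDRISC_SHARES = {
    # reached cohort concentrates above the programme-eligibility score of 12
    "0-6": 0.02, "7-11": 0.08, "12-14": 0.30, "15-19": 0.40, "20-26": 0.20}

GENDER_TARGETS = {"women": 100_399, "men": 80_375}  # base-case reached cohort


def synth_cohort_tables(seed: int = 0, mean_visit_rate: float = 0.61,
                        calibrate_to: dict | None = None,
                        reach_rate: float = 0.099) -> dict:
    """Population, pharmacy-visit-rate, T2D-free and FINDRISC-share tables.

    Visit rates rise with age within [0.30, 0.90] with a population-weighted
    mean of ``mean_visit_rate``; the T2D-free fraction declines with age.
    ``calibrate_to`` (gender → target reached count) rescales population
    counts so the reached cohort hits those totals exactly before rounding.
    """
    rng = np.random.default_rng(seed)
    ages = np.arange(30, 80)
    frames = {k: [] for k in ("population", "visit_rate", "t2d_free")}
    for gender in ("women", "men"):
        pop = 34_000.0 * (1.0 - 0.004 * (ages - 30)) \
            * np.exp(rng.normal(0.0, 0.02, len(ages)))
        visit = (0.38 + 0.45 * (ages - 30) / 49.0
                 + (0.03 if gender == "women" else -0.03))
        free = 0.97 - 0.0025 * (ages - 30)  # T2D prevalence rises with age
        frames["population"].append(
            pd.DataFrame({"age": ages, "gender": gender, "population": pop}))
        frames["visit_rate"].append(
            pd.DataFrame({"age": ages, "gender": gender, "visit_rate": visit}))
        frames["t2d_free"].append(
            pd.DataFrame({"age": ages, "gender": gender, "t2d_free": free}))
    tables = {k: pd.concat(v, ignore_index=True) for k, v in frames.items()}

    # rescale visit rates to the requested population-weighted mean
    pop_w = tables["population"].population.to_numpy()
    for _ in range(4):
        v = tables["visit_rate"].visit_rate.to_numpy()
        current = float((v * pop_w).sum() / pop_w.sum())
        v = np.clip(v * (mean_visit_rate / current), 0.30, 0.90)
        tables["visit_rate"]["visit_rate"] = v

    if calibrate_to:
        merged = tables["population"].merge(
            tables["visit_rate"], on=["age", "gender"]).merge(
            tables["t2d_free"], on=["age", "gender"])
        for gender, target in calibrate_to.items():
            sub = merged[merged.gender == gender]
            reached = float((sub.population * sub.visit_rate * sub.t2d_free
                             * reach_rate).sum())
            if reached <= 0:
                raise ValueError(f"calibration infeasible for {gender}: "
                                 "zero reached population")
            mask = tables["population"].gender == gender
            tables["population"].loc[mask, "population"] *= target / reached

    tables["findrisc"] = pd.DataFrame(
        [(g, s, share) for g in ("women", "men")
         for s, share in DEFAULT_FINDRISC_SHARES.items()],
        columns=["gender", "findrisc_stratum", "share"])
    return tables


def reference_cohort(seed: int = 0, age_group_width: int = 5,
                     reach_rate: float = 0.099) -> CohortDefinition:
    """Reached cohort calibrated to the base-case totals (100,399 women,
    80,375 men)."""
    tables = synth_cohort_tables(seed=seed, calibrate_to=GENDER_TARGETS,
                                 reach_rate=reach_rate)
    return build_reached_cohort(
        tables["population"], tables["visit_rate"], tables["t2d_free"],
        reach_rate, tables["findrisc"], age_group_width=age_group_width)


@functools.lru_cache(maxsize=8)
def reference_inputs(seed: int = 2021, age_group_width: int = 5,
                     params: ParameterSet | None = None) -> ModelInputs:
    """The package's synthetic base case.

    Survival models are obtained by fitting the ground-truth generators'
    output at the source studies' scale (5000 subjects / 10-year follow-up
    for incidence; 1151 / 9 years for complications), so the coefficient
    covariance carries a realistic correlation structure into the PSA.
    """
    inc_cfg = GeneratorConfig(n_subjects=5000, seed=seed)
    comp_cfg = GeneratorConfig(
        n_subjects=1151, true_shape=1.2,
        true_coefficients=true_complication_coefficients(),
        censor_horizon_years=9.0, age_range=(35, 85), seed=seed + 1)
    inc_fit = fit_weibull(
        synth_incidence_dataset(inc_cfg),
        ["age", "male"] + [f"findrisc:{s}" for s in FINDRISC_STRATA[1:]])
    comp_fit = fit_weibull(synth_complication_dataset(comp_cfg),
                           ["age", "male"])
    return ModelInputs(
        params=params or default_parameters(),
        incidence_fit=inc_fit, complication_fit=comp_fit,
        life_table=synth_life_table(),
        cohort=reference_cohort(seed=seed, age_group_width=age_group_width))
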
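"""YAML configuration: validation, loading, and writing a reference setup.

A run is described by one YAML file with sections ``costs``, ``utilities``,
``hazards``, ``economics``, ``cohort`` and ``survival``.  Scalar parameters
carry a ``value`` plus a ``distribution`` block; tabular inputs (life table,
cohort tables, coefficient tables) are CSV files referenced by relative
path.  Validation collects all violations and reports them in one batch.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import ModelInputs
from .parameters import (CohortDefinition, CostInputs, DistributionSpec,
                         EconomicSettings, HazardInputs, ParameterSet,
                         Stratum, UtilityInputs, build_reached_cohort, fixed)
from .survival import LifeTable, load_coefficient_table

REQUIRED_SECTIONS = ("costs", "utilities", "hazards", "economics",
                     "cohort", "survival")


class ConfigError(ValueError):
    """Batch of configuration violations, each with its field path."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in self.errors))


def _spec_from(node, path, errors) -> DistributionSpec:
    try:
        if isinstance(node, (int, float)):
            return fixed(float(node))
        value = float(node["value"])
        dist = node.get("distribution", {"kind": "fixed"})
        kind = dist.get("kind", "fixed")
        return DistributionSpec(
            kind=kind, mean=value,
            se=float(dist.get("se", "nan")),
            alpha=float(dist.get("alpha", "nan")),
            beta=float(dist.get("beta", "nan")),
            ci_low=float(dist.get("ci_low", "nan")),
            ci_high=float(dist.get("ci_high", "nan")))
    except (KeyError, TypeError, ValueError) as e:
        errors.append(f"{path}: {e}")
        return fixed(0.0)


def validate_config(path) -> ModelInputs:
    """Load and validate a run configuration; raises :class:`ConfigError`
    listing every violation found."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"{path}: file not found"])
    raw = yaml.safe_load(path.read_text()) or {}
    errors = []
    missing = [s for s in REQUIRED_SECTIONS if s not in raw]
    if missing:
        raise ConfigError([f"missing required section {s!r}" for s in missing])
    base = path.parent

    c = raw["costs"]
    try:
        costs = CostInputs(**{k: _spec_from(c[k], f"costs.{k}", errors)
                              for k in CostInputs().__dict__})
    except (KeyError, ValueError) as e:
        errors.append(f"costs: {e}")
        costs = CostInputs()

    u = raw["utilities"]
    try:
        baseline = {}
        for gender, bands in u["baseline"].items():
            for i, node in enumerate(bands):
                baseline[(gender, i)] = _spec_from(
                    node, f"utilities.baseline.{gender}[{i}]", errors)
        for key, spec in baseline.items():
            if not 0 <= spec.point <= 1:
                errors.append(f"utilities.baseline.{key}: value "
                              f"{spec.point} outside [0, 1]")
        utilities = UtilityInputs(
            baseline=baseline,
            disutility_t2d=_spec_from(u["disutility_t2d"],
                                      "utilities.disutility_t2d", errors),
            disutility_complications_weighted=_spec_from(
                u["disutility_complications_weighted"],
                "utilities.disutility_complications_weighted", errors))
    except (KeyError, ValueError) as e:
        errors.append(f"utilities: {e}")
        utilities = UtilityInputs()

    h = raw["hazards"]
    try:
        hazards = HazardInputs(
            intervention_hr=_spec_from(h["intervention_hr"],
                                       "hazards.intervention_hr", errors),
            intervention_effect_duration_years=int(
                h.get("intervention_effect_duration_years", 15)),
            t2d_mortality_hr_women=_spec_from(
                h["t2d_mortality_hr_women"],
                "hazards.t2d_mortality_hr_women", errors),
            t2d_mortality_hr_men=_spec_from(
                h["t2d_mortality_hr_men"],
                "hazards.t2d_mortality_hr_men", errors),
            complication_mortality_hr=_spec_from(
                h["complication_mortality_hr"],
                "hazards.complication_mortality_hr", errors))
    except (KeyError, ValueError) as e:
        errors.append(f"hazards: {e}")
        hazards = HazardInputs()

    e_ = raw["economics"]
    try:
        economics = EconomicSettings(
            discount_rate=float(e_.get("discount_rate", 0.03)),
            horizon_years=int(e_.get("horizon_years", 20)),
            wtp_threshold=float(e_.get("wtp_threshold", 50_000)),
            perspective=e_.get("perspective", "societal"))
    except ValueError as err:
        errors.append(f"economics: {err}")
        economics = EconomicSettings()

    cohort = None
    try:
        co = raw["cohort"]
        if "strata_csv" in co:
            df = pd.read_csv(base / co["strata_csv"])
            cohort = CohortDefinition(
                strata=tuple(Stratum(r.gender, int(r.entry_age),
                                     str(r.findrisc_stratum), int(r["count"]))
                             for _, r in df.iterrows()),
                reach_rate=float(co.get("reach_rate", 0.099)))
        else:
            cohort = build_reached_cohort(
                pd.read_csv(base / co["population_csv"]),
                pd.read_csv(base / co["visit_rate_csv"]),
                pd.read_csv(base / co["t2d_free_csv"]),
                float(co["reach_rate"]),
                pd.read_csv(base / co["findrisc_csv"]),
                age_group_width=int(co.get("age_group_width", 1)))
        if "total_reached" in co and cohort is not None:
            if cohort.total_reached != int(co["total_reached"]):
                errors.append(
                    f"cohort: reached total {cohort.total_reached} does not "
                    f"match declared total_reached {co['total_reached']}")
    except (KeyError, ValueError, FileNotFoundError) as err:
        errors.append(f"cohort: {err}")

    inc_fit = comp_fit = life = None
    try:
        sv = raw["survival"]
        dialect = sv.get("parameterization", "PH")
        inc_fit = load_coefficient_table(
            base / sv["incidence_coefficients_csv"],
            shape=float(sv["incidence_shape"]), parameterization=dialect,
            corr_matrix=(pd.read_csv(base / sv["incidence_correlation_csv"])
                         if "incidence_correlation_csv" in sv else None))
        comp_fit = load_coefficient_table(
            base / sv["complication_coefficients_csv"],
            shape=float(sv["complication_shape"]), parameterization=dialect,
            corr_matrix=(pd.read_csv(base / sv["complication_correlation_csv"])
                         if "complication_correlation_csv" in sv else None))
        life = LifeTable(pd.read_csv(base / sv["life_table_csv"]))
    except (KeyError, ValueError, FileNotFoundError) as err:
        errors.append(f"survival: {err}")

    if errors:
        raise ConfigError(errors)
    return ModelInputs(params=ParameterSet(costs=costs, utilities=utilities,
                                           hazards=hazards,
                                           economics=economics),
                       incidence_fit=inc_fit, complication_fit=comp_fit,
                       life_table=life, cohort=cohort)


def write_reference_config(out_dir, seed: int = 2021) -> Path:
    """Materialize the synthetic reference setup as YAML + CSV files.

    The survival coefficient CSVs written here are synthetic stand-ins for
    the study's restricted regression tables.
    """
    from .synthetic import reference_inputs

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = reference_inputs(seed=seed)

    for name, fit in (("incidence", inputs.incidence_fit),
                      ("complications", inputs.complication_fit)):
        names = fit.param_names
        cov = np.asarray(fit.covariance)
        se = np.sqrt(np.diag(cov))
        pd.DataFrame({"term": list(fit.coefficients),
                      "estimate": list(fit.coefficients.values()),
                      "se": se[:-1]}).to_csv(
            out / f"synthetic_{name}_coefficients.csv", index=False)
        with np.errstate(invalid="ignore"):
            corr = cov / np.outer(se, se)
        corr[np.isnan(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        pd.DataFrame(corr, columns=names).assign(term=names).set_index(
            "term").to_csv(out / f"synthetic_{name}_correlation.csv")
    inputs.life_table.table.to_csv(out / "synthetic_life_table.csv",
                                   index=False)
    inputs.cohort.to_frame().to_csv(out / "synthetic_cohort_strata.csv",
                                    index=False)

    def _dist(spec: DistributionSpec) -> dict:
        d = {"kind": spec.kind}
        for f_ in ("se", "alpha", "beta", "ci_low", "ci_high"):
            v = getattr(spec, f_)
            if math.isfinite(v):
                d[f_] = float(v)
        return d

    def _node(spec: DistributionSpec) -> dict:
        return {"value": float(spec.point), "distribution": _dist(spec)}

    p = inputs.params
    cfg = {
        "costs": {k: _node(getattr(p.costs, k))
                  for k in p.costs.__dict__},
        "utilities": {
            "baseline": {g: [_node(p.utilities.baseline[(g, i)])
                             for i in range(4)] for g in ("women", "men")},
            "disutility_t2d": _node(p.utilities.disutility_t2d),
            "disutility_complications_weighted":
                _node(p.utilities.disutility_complications_weighted)},
        "hazards": {
            "intervention_hr": _node(p.hazards.intervention_hr),
            "intervention_effect_duration_years":
                p.hazards.intervention_effect_duration_years,
            "t2d_mortality_hr_women": _node(p.hazards.t2d_mortality_hr_women),
            "t2d_mortality_hr_men": _node(p.hazards.t2d_mortality_hr_men),
            "complication_mortality_hr":
                _node(p.hazards.complication_mortality_hr)},
        "economics": {"discount_rate": p.economics.discount_rate,
                      "horizon_years": p.economics.horizon_years,
                      "wtp_threshold": p.economics.wtp_threshold,
                      "perspective": p.economics.perspective},
        "cohort": {"strata_csv": "synthetic_cohort_strata.csv",
                   "reach_rate": inputs.cohort.reach_rate,
                   "total_reached": inputs.cohort.total_reached},
        "survival": {
            "parameterization": "PH",
            "incidence_coefficients_csv":
                "synthetic_incidence_coefficients.csv",
            "incidence_correlation_csv":
                "synthetic_incidence_correlation.csv",
            "incidence_shape": float(inputs.incidence_fit.shape),
            "complication_coefficients_csv":
                "synthetic_complications_coefficients.csv",
            "complication_correlation_csv":
                "synthetic_complications_correlation.csv",
            "complication_shape": float(inputs.complication_fit.shape),
            "life_table_csv": "synthetic_life_table.csv"},
    }
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg_path
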
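"""Parametric survival models and their conversion to cycle probabilities.

T2D incidence and complication onset are modelled with Weibull proportional-
hazards (PH) regressions, S(t|x) = exp(−exp(x'β)·t^ρ), fitted by maximum
likelihood under right censoring.  An AFT (accelerated failure time) dialect
is supported for coefficient tables exported from software that reports the
AFT form; the two are exact reparameterizations of each other.

Survival functions are turned into annual transition probabilities through
conditional survival, 1 − S(t+1|x)/S(t|x), and literature hazard ratios act
on probabilities via the rate-scale identity 1 − (1−p)^HR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


class FitError(RuntimeError):
    """Raised when a survival regression cannot be fitted."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One right-censored time-to-event observation."""

    subject_id: int
    entry_age: float
    gender: str
    time: float
    event: int
    findrisc_stratum: str | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class WeibullFit:
    """A fitted (or loaded) Weibull regression.

    ``coefficients`` maps term name → estimate; ``covariance`` covers all
    coefficients plus ``log_shape`` as the final row/column (ordering given
    by ``param_names``).
    """

    parameterization: str  # "PH" or "AFT"
    shape: float
    coefficients: Mapping[str, float]
    covariance: np.ndarray | None = None
    loglik: float = float("nan")
    n: int = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        if self.parameterization not in {"PH", "AFT"}:
            raise ValueError("parameterization must be PH or AFT")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.covariance is not None:
            cov = np.asarray(self.covariance)
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-8:
                raise ValueError("covariance must be PSD")

    @property
    def param_names(self) -> list:
        return list(self.coefficients) + ["log_shape"]

    @property
    def k(self) -> int:
        return len(self.coefficients) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * math.log(self.n)

    def linear_predictor(self, covariates: Mapping[str, float]) -> float:
        """x'β with an implicit intercept term."""
        lp = self.coefficients.get("intercept", 0.0)
        for name, beta in self.coefficients.items():
            if name == "intercept":
                continue
            try:
                lp += beta * covariates[name]
            except KeyError:
                raise KeyError(f"covariate {name!r} missing") from None
        return lp


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting (PH form, analytic gradient and Hessian)
# ---------------------------------------------------------------------------

def _design(records: Sequence[SurvivalRecord],
            covariate_names: Sequence[str]) -> tuple:
    """Design matrix with leading intercept column."""
    rows = []
    for r in records:
        row = [1.0]
        for name in covariate_names:
            if name == "age":
                row.append(r.entry_age)
            elif name == "male":
                row.append(1.0 if r.gender == "men" else 0.0)
            elif name.startswith("findrisc:"):
                row.append(1.0 if r.findrisc_stratum == name.split(":", 1)[1]
                           else 0.0)
            else:
                raise ValueError(f"unknown covariate {name!r}")
        rows.append(row)
    X = np.asarray(rows)
    t = np.array([r.time for r in records])
    d = np.array([float(r.event) for r in records])
    return X, t, d


def _nll_grad_hess(theta, X, t, d, fixed_shape):
    beta = theta[:X.shape[1]]
    u = 0.0 if fixed_shape is not None else theta[-1]
    rho = fixed_shape if fixed_shape is not None else math.exp(u)
    logt = np.log(t)
    eta = X @ beta
    lam = np.exp(np.clip(eta + rho * logt, -700, 700))  # cumulative hazard
    ll = d @ (math.log(rho) + (rho - 1) * logt + eta) - lam.sum()

    g_beta = X.T @ (d - lam)
    rlt = rho * logt
    H_bb = -(X.T * lam) @ X
    if fixed_shape is not None:
        return -ll, -g_beta, -H_bb
    g_u = d @ (1.0 + rlt) - lam @ rlt
    grad = np.append(g_beta, g_u)
    H_bu = -X.T @ (lam * rlt)
    H_uu = d @ rlt - lam @ (rlt * (rlt + 1.0))
    H = np.zeros((len(theta), len(theta)))
    H[:-1, :-1] = H_bb
    H[:-1, -1] = H[-1, :-1] = H_bu
    H[-1, -1] = H_uu
    return -ll, -grad, -H


def _newton(theta0, X, t, d, fixed_shape, gtol, max_iter=200):
    """Safeguarded Newton minimization of the negative log-likelihood."""
    theta = np.array(theta0, dtype=float)
    nll, grad, hess = _nll_grad_hess(theta, X, t, d, fixed_shape)
    for _ in range(max_iter):
        if np.linalg.norm(grad, ord=np.inf) <= gtol * max(1.0, abs(nll)) / 10:
            break
        ridge = 0.0
        for _ in range(30):  # regularize until we get a descent direction
            try:
                step = np.linalg.solve(
                    hess + ridge * np.eye(len(theta)), grad)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and grad @ step > 0:
                break
            ridge = max(2 * ridge, 1e-8 * max(1.0, abs(np.diag(hess)).max()))
        else:  # pragma: no cover
            raise FitError("could not find a descent direction")
        alpha = 1.0
        for _ in range(60):  # backtracking line search
            cand = theta - alpha * step
            nll_c, grad_c, hess_c = _nll_grad_hess(cand, X, t, d, fixed_shape)
            if math.isfinite(nll_c) and nll_c <= nll - 1e-4 * alpha * (grad @ step):
                theta, nll, grad, hess = cand, nll_c, grad_c, hess_c
                break
            alpha *= 0.5
        else:
            break  # no further improvement possible at machine precision
    return theta


def fit_weibull(records: Sequence[SurvivalRecord],
                covariate_names: Sequence[str] = (),
                fixed_shape: float | None = None,
                gtol: float = 1e-6) -> WeibullFit:
    """Fit a Weibull PH regression by maximum likelihood.

    ``covariate_names`` may contain ``"age"``, ``"male"`` and
    ``"findrisc:<stratum>"`` indicator terms.  ``fixed_shape=1.0`` constrains
    the model to an exponential regression (used for AIC/BIC comparison).
    Raises :class:`FitError` on fewer than two events or non-convergence.
    """
    n_events = sum(r.event for r in records)
    if n_events < 2:
        raise FitError(f"need ≥ 2 events to fit, got {n_events}")
    X, t, d = _design(records, covariate_names)

    # warm start: exponential fit (concave in β) then full Newton
    x0 = np.zeros(X.shape[1])
    x0[0] = math.log(max(n_events / t.sum(), 1e-10))  # crude rate intercept
    x0 = _newton(x0, X, t, d, 1.0, gtol)
    if fixed_shape is None:
        x0 = np.append(x0, 0.0)
    theta = _newton(x0, X, t, d, fixed_shape, gtol)

    nll, grad, hess = _nll_grad_hess(theta, X, t, d, fixed_shape)
    if np.linalg.norm(grad, ord=np.inf) > gtol * max(1.0, abs(nll)):
        raise FitError(f"did not converge: |grad|={np.linalg.norm(grad):g}")

    names = ["intercept"] + list(covariate_names)
    coeffs = dict(zip(names, theta[:X.shape[1]]))
    if fixed_shape is not None:
        shape = fixed_shape
        cov_b = np.linalg.inv(hess)
        cov = np.zeros((len(names) + 1, len(names) + 1))
        cov[:-1, :-1] = cov_b  # log_shape fixed → zero variance row
    else:
        shape = math.exp(theta[-1])
        cov = np.linalg.inv(hess)
    cov = (cov + cov.T) / 2
    return WeibullFit(parameterization="PH", shape=shape, coefficients=coeffs,
                      covariance=cov, loglik=-nll, n=len(records),
                      n_events=int(n_events))


def select_model(candidate_fits: Sequence[WeibullFit]) -> WeibullFit:
    """Lowest AIC; ties broken by lowest BIC, then by fewest parameters."""
    if not candidate_fits:
        raise ValueError("no candidate fits")
    return min(candidate_fits, key=lambda f: (f.aic, f.bic, f.k))


def wald_test(fit: WeibullFit) -> tuple:
    """Joint Wald chi-square test of all non-intercept coefficients.

    Returns (chi2, df, p) with chi2 = β'Σ⁻¹β over the tested block.
    """
    if fit.covariance is None:
        raise ValueError("fit has no covariance")
    names = fit.param_names
    idx = [i for i, nm in enumerate(names)
           if nm not in ("intercept", "log_shape")]
    beta = np.array([fit.coefficients[names[i]] for i in idx])
    block = np.asarray(fit.covariance)[np.ix_(idx, idx)]
    try:
        chi2 = float(beta @ np.linalg.solve(block, beta))
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular covariance block: {e}") from None
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df)) if df else 1.0


# ---------------------------------------------------------------------------
# Survival → transition probabilities
# ---------------------------------------------------------------------------

def _log_cumhaz(fit: WeibullFit, covariates: Mapping[str, float],
                logt: float) -> float:
    lp = fit.linear_predictor(covariates)
    if fit.parameterization == "AFT":
        # S(t) = exp(−(t/exp(x'β))^ρ) ⇒ log Λ = ρ(log t − x'β)
        return fit.shape * (logt - lp)
    return lp + fit.shape * logt


def survival_at(fit: WeibullFit, covariates: Mapping[str, float],
                t: float) -> float:
    """S(t|x); S(0)=1 and non-increasing in t."""
    if t < 0:
        raise ValueError("t must be ≥ 0")
    if t == 0:
        return 1.0
    return math.exp(-math.exp(_log_cumhaz(fit, covariates, math.log(t))))


def annual_event_prob(fit: WeibullFit, covariates: Mapping[str, float],
                      cycle_start_t: float) -> float:
    """Probability of the event within [t, t+1) given event-free at t."""
    if cycle_start_t < 0:
        raise ValueError("cycle_start_t must be ≥ 0")
    s0 = survival_at(fit, covariates, cycle_start_t)
    s1 = survival_at(fit, covariates, cycle_start_t + 1.0)
    if s0 == 0.0:
        warnings.warn("survival already 0 at cycle start; event prob set to 1")
        return 1.0
    return min(1.0, max(0.0, 1.0 - s1 / s0))


def apply_hr_to_prob(p: float, hr: float) -> float:
    """Scale an annual probability by a hazard ratio: 1 − (1−p)^hr."""
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p == 1.0:
        return 1.0
    return -math.expm1(hr * math.log1p(-p))


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probabilities by age and gender.

    Ages beyond the last tabulated row reuse that row's probability.
    """

    table: pd.DataFrame  # columns: age, gender, qx

    def __post_init__(self) -> None:
        req = {"age", "gender", "qx"}
        if not req <= set(self.table.columns):
            raise ValueError(f"life table needs columns {sorted(req)}")
        if ((self.table.qx < 0) | (self.table.qx > 1)).any():
            raise ValueError("qx must lie in [0, 1]")

    def annual_death_prob(self, age: float, gender: str) -> float:
        sub = self.table[self.table.gender == gender].sort_values("age")
        if sub.empty:
            raise ValueError(f"no life-table rows for gender {gender!r}")
        a = min(int(age), int(sub.age.max()))
        row = sub[sub.age == a]
        if row.empty:
            raise ValueError(f"life table missing age {a} for {gender}")
        return float(row.qx.iloc[0])

    def qx_array(self, gender: str, max_age: int) -> np.ndarray:
        """Vector q[0..max_age], extending the last row beyond the table."""
        cache = self.__dict__.setdefault("_qx_cache", {})
        hit = cache.get(gender)
        if hit is not None and len(hit) > max_age:
            return hit[:max_age + 1]
        sub = self.table[self.table.gender == gender].sort_values("age")
        q = np.zeros(max_age + 1)
        ages = sub.age.to_numpy()
        vals = sub.qx.to_numpy()
        for a in range(max_age + 1):
            i = np.searchsorted(ages, a, side="right") - 1
            q[a] = vals[max(i, 0)]
        cache[gender] = q
        return q


_STATES = ("at_risk", "t2d", "t2d_complications")


def mortality_prob(life_table: LifeTable, age: float, gender: str, state: str,
                   hazards=None) -> float:
    """Annual death probability in a model state.

    At risk: life-table probability unchanged.  T2D: gender-specific excess
    mortality HR.  T2D with complications: additionally the complication
    mortality HR, stacked multiplicatively on the hazard scale.
    """
    if state == "dead":
        return 1.0
    if state not in _STATES:
        raise ValueError(f"unknown state {state!r}")
    q = life_table.annual_death_prob(age, gender)
    if state == "at_risk":
        return q
    from .parameters import HazardInputs
    hz = hazards if hazards is not None else HazardInputs()
    hr = hz.t2d_mortality_hr(gender).point
    if state == "t2d_complications":
        hr *= hz.complication_mortality_hr.point
    return min(1.0, apply_hr_to_prob(q, hr))


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.subject_id, r.entry_age, r.gender, r.findrisc_stratum,
          r.time, r.event) for r in records],
        columns=["subject_id", "age", "gender", "findrisc_stratum",
                 "time", "event"])


def records_from_frame(df: pd.DataFrame) -> list:
    return [SurvivalRecord(subject_id=int(r.subject_id), entry_age=float(r.age),
                           gender=str(r.gender), time=float(r.time),
                           event=int(r.event),
                           findrisc_stratum=(None if pd.isna(r.findrisc_stratum)
                                             else str(r.findrisc_stratum)))
            for r in df.itertuples(index=False)]


def load_coefficient_table(path, shape: float, parameterization: str,
                           corr_matrix: pd.DataFrame | None = None,
                           n: int = 0, n_events: int = 0) -> WeibullFit:
    """Load a (term, estimate, se) CSV as a WeibullFit.

    ``parameterization`` must be declared explicitly ("PH" or "AFT") — the
    coefficient coding of an external table is never guessed.  When a
    correlation matrix is supplied its rows/columns must match the terms
    (plus optionally ``log_shape``); covariance is rebuilt as D·R·D from the
    SE column.
    """
    df = pd.read_csv(path)
    coeffs = dict(zip(df.term, df.estimate.astype(float)))
    ses = df.se.astype(float).to_numpy()
    names = list(df.term) + ["log_shape"]
    se_full = np.append(ses, 0.0)
    if corr_matrix is not None:
        R = corr_matrix.loc[:, corr_matrix.columns != corr_matrix.columns[0]] \
            if corr_matrix.columns[0] in ("term", "Unnamed: 0") else corr_matrix
        R = np.asarray(R, dtype=float)
        if R.shape[0] == len(names) - 1:  # no shape row supplied
            R = np.pad(R, ((0, 1), (0, 1)))
            R[-1, -1] = 1.0
        cov = np.outer(se_full, se_full) * R
    else:
        cov = np.diag(se_full ** 2)
    return WeibullFit(parameterization=parameterization, shape=shape,
                      coefficients=coeffs, covariance=cov,
                      n=n, n_events=n_events)
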
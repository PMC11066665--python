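"""BMI-trajectory analysis: nested linear mixed models, likelihood-ratio
comparison, scenario predictions with 83% confidence bands, and decade
BMI-gain summaries.

The model ladder (all fit by maximum likelihood, so that likelihood-ratio
tests of fixed-effect structure are valid) is

1. *baseline* — fixed: intercept, sex, BMI polygenic score, 10 genotype
   PCs, smoking (ever/never), age and disease status; random: per-subject
   intercept and per-subject age slope;
2. *interaction* — adds disease status × age;
3. *treatment* — adds a quartic polynomial of accumulated antipsychotic
   treatment years (supply days up to each BMI measurement), entered as an
   orthogonalized polynomial basis of the age-27-centered data for
   numerical stability.

Scenario predictions are population level (random effects at zero); the
confidence band comes from the fixed-effect covariance through the linear
predictor, using the normal quantile at ``(1 + level)/2``.  Per the
non-overlap convention, two means differ at roughly the 5% level when
their 83% bands are disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .io import DAYS_PER_YEAR, PC_COLUMNS
from . import exposure as expo
from .io import smoking_ever_never

AGE_CENTER = 27.0  # years; the median onset age, also the scenario origin


class PolyBasis:
    """Orthogonalized degree-4 polynomial basis (no constant term) for the
    treatment-years variable.

    Columns are linear combinations of ``t, t², t³, t⁴`` fixed by a thin QR
    decomposition on the training values, so the basis vanishes at ``t = 0``
    and transforms new values consistently at prediction time.
    """

    degree = 4

    def __init__(self) -> None:
        self.scale_: float | None = None
        self.r_inv_: np.ndarray | None = None

    @staticmethod
    def _raw(t: np.ndarray, scale: float) -> np.ndarray:
        t = np.asarray(t, float) / scale
        return np.column_stack([t ** k for k in range(1, PolyBasis.degree + 1)])

    def fit(self, t: np.ndarray) -> "PolyBasis":
        t = np.asarray(t, float)
        if np.unique(t).size <= self.degree:
            raise ValueError("treatment-years variable has too few distinct "
                             "values for a quartic basis")
        self.scale_ = max(float(np.std(t)), 1e-8)
        v = self._raw(t, self.scale_)
        _, r = np.linalg.qr(v)
        self.r_inv_ = np.linalg.inv(r) * np.sqrt(len(t))
        return self

    def transform(self, t: np.ndarray) -> np.ndarray:
        if self.r_inv_ is None:
            raise RuntimeError("basis not fitted")
        return self._raw(t, self.scale_) @ self.r_inv_

    @property
    def columns(self) -> list[str]:
        return [f"tx{k}" for k in range(1, self.degree + 1)]


def trajectory_frame(persons: pd.DataFrame, measurements: pd.DataFrame,
                     prs: pd.DataFrame, dispensing: pd.DataFrame,
                     case_ids: set[str],
                     lookback_years: float = 2.0) -> pd.DataFrame:
    """Join BMI observations with covariates and look-back exposure into
    the long-format analysis frame (one row per BMI measurement)."""
    bmi = measurements[measurements["kind"] == "bmi"].copy()
    bmi["bmi"] = pd.to_numeric(bmi["value"])
    win = expo.derive_windowed(persons, dispensing, measurements,
                               lookback_years=lookback_years)
    bmi = bmi.reset_index(drop=True)
    win = win.reset_index(drop=True)
    df = pd.concat([bmi[["person_id", "measure_date", "bmi"]],
                    win[["pdc_window", "median_cpz_window_mg",
                         "ty_supply_to_anchor"]]], axis=1)
    p = persons.set_index("person_id")
    df = df[df["person_id"].isin(p.index)]
    df["age"] = [(m.toordinal() - p.loc[pid, "birth_date"].toordinal()) / DAYS_PER_YEAR
                 for pid, m in zip(df["person_id"], df["measure_date"])]
    df["age_c"] = df["age"] - AGE_CENTER
    df["sex_male"] = (df["person_id"].map(p["sex"]) == "male").astype(float)
    smoke = smoking_ever_never(measurements)
    df["smoking"] = df["person_id"].map(smoke).eq("ever").astype(float)
    df["case"] = df["person_id"].isin(case_ids).astype(float)
    df["case_age"] = df["case"] * df["age_c"]
    df["tx_years"] = df["ty_supply_to_anchor"].fillna(0.0)
    score_cols = ["BMI"] + list(PC_COLUMNS)
    df = df.merge(prs[["person_id"] + score_cols], on="person_id", how="inner")
    df = df.rename(columns={"BMI": "bmi_prs"})
    df["const"] = 1.0
    return df.reset_index(drop=True)


def ladder_specs(include_smoking: bool = True,
                 include_pcs: bool = True) -> dict[str, list[str]]:
    """The nested fixed-effect specifications of the model ladder."""
    base = ["const", "sex_male", "bmi_prs"]
    if include_pcs:
        base += list(PC_COLUMNS)
    if include_smoking:
        base += ["smoking"]
    base += ["age_c", "case"]
    return {
        "baseline": base,
        "interaction": base + ["case_age"],
        "treatment": base + ["case_age"] + [f"tx{k}" for k in range(1, 5)],
    }


@dataclass
class LMMFit:
    """Maximum-likelihood mixed-model fit (random intercept + age slope)."""

    name: str
    fixed_cols: list[str]
    fe_params: pd.Series
    cov_fe: pd.DataFrame
    cov_re: np.ndarray
    sigma2: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    poly: PolyBasis | None = None
    result: object = field(repr=False, default=None)

    def predict_mean(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, float) @ self.fe_params.to_numpy()

    def predict_se(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return np.sqrt(np.einsum("ij,jk,ik->i", x, self.cov_fe.to_numpy(), x))


def fit_lmm(df: pd.DataFrame, fixed_cols: list[str], name: str = "model",
            poly: PolyBasis | None = None,
            start: LMMFit | None = None,
            method: str | None = None) -> LMMFit:
    """Fit one mixed model by ML with per-subject random intercept and
    random age slope; on a singular random-effects covariance the model is
    refit with independent (diagonal) random effects and a warning.

    Optimisation starts from an OLS fit with a mostly-between-person
    variance split, or from a previously fitted (nested) model via
    ``start`` — this keeps the profiled-likelihood climb short and avoids
    the poor local solutions a cold start can produce.
    """
    endog = df["bmi"].to_numpy(float)
    exog = df[fixed_cols].to_numpy(float)
    exog_re = df[["const", "age_c"]].to_numpy(float)
    groups = df["person_id"].to_numpy()
    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)

    ols = sm.OLS(endog, exog).fit()
    if start is None:
        rv = float(ols.scale)
        cov0 = np.array([[0.7 * rv, 0.0], [0.0, 0.01]]) / (0.3 * rv)
        sp = MixedLMParams.from_components(
            fe_params=np.asarray(ols.params), cov_re=cov0)
    else:
        fe0 = np.asarray(ols.params, float).copy()
        for j, c in enumerate(fixed_cols):
            if c in start.fe_params.index:
                fe0[j] = float(start.fe_params[c])
        sp = MixedLMParams.from_components(fe_params=fe0, cov_re=start.cov_re)

    def _try_fit(free=None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kw = {"method": method} if method else {}
            return model.fit(reml=False, maxiter=500, free=free, disp=False,
                             start_params=sp, **kw)

    res = _try_fit()
    cov_re = np.asarray(res.cov_re, float)
    eig = np.linalg.eigvalsh(cov_re)
    if not res.converged or eig.min() <= 1e-10:
        warnings.warn(f"{name}: singular random-effects covariance; "
                      "refitting with diagonal structure")
        free = MixedLMParams.from_components(
            fe_params=np.ones(len(fixed_cols)), cov_re=np.eye(2))
        res = _try_fit(free=free)
        cov_re = np.asarray(res.cov_re, float)
    k = len(fixed_cols)
    fe = pd.Series(np.asarray(res.fe_params, float), index=fixed_cols)
    cov_fe = pd.DataFrame(np.asarray(res.cov_params())[:k, :k],
                          index=fixed_cols, columns=fixed_cols)
    return LMMFit(name=name, fixed_cols=list(fixed_cols), fe_params=fe,
                  cov_fe=cov_fe, cov_re=cov_re, sigma2=float(res.scale),
                  llf=float(res.llf), n_obs=len(df),
                  n_groups=int(pd.Series(groups).nunique()),
                  converged=bool(res.converged), poly=poly, result=res)


def fit_ladder(df: pd.DataFrame, specs: dict[str, list[str]] | None = None
               ) -> tuple[dict[str, LMMFit], pd.DataFrame]:
    """Fit the nested ladder and compare successive models by LRT.

    Treatment-years columns ``tx1..tx4`` are created here from an
    orthogonalized quartic basis fitted on the frame's ``tx_years``.
    """
    specs = specs or ladder_specs()
    df = df.copy()
    poly: PolyBasis | None = None
    need_tx = any(any(c.startswith("tx") for c in cols) for cols in specs.values())
    if need_tx:
        poly = PolyBasis().fit(df["tx_years"].to_numpy(float))
        tx = poly.transform(df["tx_years"].to_numpy(float))
        for j, c in enumerate(poly.columns):
            df[c] = tx[:, j]
    fits: dict[str, LMMFit] = {}
    rows = []
    prev: LMMFit | None = None
    for name, cols in specs.items():
        fit = fit_lmm(df, cols, name=name, poly=poly, start=prev)
        if prev is not None and fit.llf < prev.llf - 1e-8:
            # a nested model can never fit worse at the ML optimum; retry
            # with more robust optimisers and keep the best likelihood
            for method in ("powell", None):
                alt = fit_lmm(df, cols, name=name, poly=poly,
                              start=prev if method else None, method=method)
                if alt.llf > fit.llf:
                    fit = alt
                if fit.llf >= prev.llf - 1e-8:
                    break
        fits[name] = fit
        row = {"model": name, "n_fixed": len(cols), "llf": fit.llf}
        if prev is not None:
            lr = 2.0 * (fit.llf - prev.llf)
            dof = len(cols) - len(prev.fixed_cols)
            row.update({"lrt_chi2": lr, "lrt_df": dof,
                        "lrt_p": float(stats.chi2.sf(max(lr, 0.0), dof)),
                        "vs": prev.name})
        rows.append(row)
        prev = fit
    return fits, pd.DataFrame(rows)


@dataclass
class TrajectoryScenario:
    """A counterfactual person for population-level trajectory prediction."""

    group: str = "control"            # control | untreated_case | treated_case
    sex_male: bool = True
    smoking: bool = True
    bmi_prs_level: float = 0.0        # in SD units: -1, 0, +1
    treatment_days_per_year: int = 180
    start_age: float = 27.0
    horizon_years: float = 10.0
    age_step: float = 0.5

    def tx_years_at(self, ages: np.ndarray) -> np.ndarray:
        """Piecewise-linear treatment-year accrual from start_age."""
        if self.group != "treated_case":
            return np.zeros_like(ages, dtype=float)
        per_year = self.treatment_days_per_year / DAYS_PER_YEAR
        return np.maximum(ages - self.start_age, 0.0) * per_year


@dataclass
class TrajectoryPrediction:
    scenario: TrajectoryScenario
    ages: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    ci_level: float

    @property
    def decade_gain(self) -> float:
        return float(self.mean[-1] - self.mean[0])


def scenario_design(fit: LMMFit, scenario: TrajectoryScenario,
                    ages: np.ndarray) -> np.ndarray:
    """Fixed-effect design rows for a scenario on an age grid; PCs at zero,
    random effects at zero (population level)."""
    is_case = scenario.group in ("untreated_case", "treated_case")
    tx = scenario.tx_years_at(ages)
    needs_tx = any(c.startswith("tx") for c in fit.fixed_cols)
    if scenario.group == "treated_case" and not needs_tx:
        raise ValueError("scenario term 'tx_years' absent from model "
                         f"{fit.name!r}")
    values: dict[str, np.ndarray] = {
        "const": np.ones_like(ages),
        "sex_male": np.full_like(ages, float(scenario.sex_male)),
        "smoking": np.full_like(ages, float(scenario.smoking)),
        "bmi_prs": np.full_like(ages, scenario.bmi_prs_level),
        "age_c": ages - AGE_CENTER,
        "case": np.full_like(ages, float(is_case)),
        "case_age": float(is_case) * (ages - AGE_CENTER),
    }
    for c in PC_COLUMNS:
        values[c] = np.zeros_like(ages)
    if needs_tx:
        if fit.poly is None:
            raise ValueError("model has treatment terms but no stored basis")
        txb = fit.poly.transform(tx)
        for j, c in enumerate(fit.poly.columns):
            values[c] = txb[:, j]
    missing = [c for c in fit.fixed_cols if c not in values]
    if missing:
        raise ValueError("scenario term(s) absent: " + ", ".join(missing))
    return np.column_stack([values[c] for c in fit.fixed_cols])


def predict_trajectory(fit: LMMFit, scenario: TrajectoryScenario,
                       ci_level: float = 0.83) -> TrajectoryPrediction:
    """Population-level predicted BMI across ages with a fixed-effect
    confidence band at ``ci_level`` (83% by default, per the non-overlap
    comparison rule)."""
    n_steps = int(round(scenario.horizon_years / scenario.age_step))
    ages = scenario.start_age + scenario.age_step * np.arange(n_steps + 1)
    x = scenario_design(fit, scenario, ages)
    mean = fit.predict_mean(x)
    se = fit.predict_se(x)
    z = stats.norm.ppf((1.0 + ci_level) / 2.0)
    return TrajectoryPrediction(scenario=scenario, ages=ages, mean=mean,
                                lo=mean - z * se, hi=mean + z * se,
                                ci_level=ci_level)


def nonoverlap_test(pred_a: TrajectoryPrediction,
                    pred_b: TrajectoryPrediction) -> np.ndarray:
    """True at each age where the two confidence bands are disjoint."""
    if len(pred_a.ages) != len(pred_b.ages) or \
            not np.allclose(pred_a.ages, pred_b.ages):
        raise ValueError("age grids differ between predictions")
    return (pred_a.lo > pred_b.hi) | (pred_b.lo > pred_a.hi)


def dose_adherence_effects(df: pd.DataFrame,
                           include_pcs: bool = False) -> tuple[pd.DataFrame, LMMFit]:
    """Fixed effects of windowed treatment intensity on BMI among treated
    cases: standardized look-back median CPZ dose, look-back adherence,
    accumulated treatment years and BMI PRS (plus sex/smoking/age).

    Terms constant in the analysis set are dropped with a warning.
    """
    sub = df[(df["case"] == 1) & df["pdc_window"].notna()
             & df["median_cpz_window_mg"].notna()].copy()
    sub["cpz_std"] = (sub["median_cpz_window_mg"]
                      - sub["median_cpz_window_mg"].mean())
    sd = sub["median_cpz_window_mg"].std()
    if sd > 0:
        sub["cpz_std"] /= sd
    terms = ["const", "sex_male", "smoking", "age_c",
             "cpz_std", "pdc_window", "tx_years", "bmi_prs"]
    if include_pcs:
        terms += list(PC_COLUMNS)
    keep = []
    for t in terms:
        if t != "const" and sub[t].std() == 0:
            warnings.warn(f"term {t!r} constant in analysis set; dropped")
        else:
            keep.append(t)
    fit = fit_lmm(sub, keep, name="dose_adherence")
    table = pd.DataFrame({
        "estimate": fit.fe_params,
        "se": np.sqrt(np.diag(fit.cov_fe)),
    })
    table["z"] = table["estimate"] / table["se"]
    table["p"] = 2.0 * stats.norm.sf(np.abs(table["z"]))
    return table, fit
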
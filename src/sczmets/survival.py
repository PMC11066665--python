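"""Endpoint-specific time-to-event construction and Cox modelling.

Six metabolic endpoints are analysed: type-2 diabetes, hypercholesterolemia,
essential hypertension, coronary heart disease, cerebrovascular disease and
their union ("any metabolic disorder").  For each endpoint every matched
person contributes one record measured from the index date (case onset,
inherited by matched controls) to the first qualifying ICD-10 diagnosis,
death, or end of follow-up; persons already diagnosed on or before the
index date are excluded as prevalent, with full bookkeeping so that
``eligible + prevalent + missing covariates = cohort size``.

Cox proportional-hazards fits use the partial likelihood with Efron tie
handling (via lifelines).  Polygenic scores can be scanned in the same
forward-stepwise fashion as the case-control association, with the
6-endpoint Bonferroni family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .association import bonferroni_threshold
from .io import DAYS_PER_YEAR, PC_COLUMNS, PRS_TRAITS, bmi_who_category, \
    median_bmi, smoking_ever_never

#: default ICD-10 code-prefix sets per endpoint
ENDPOINTS: dict[str, tuple[str, ...]] = {
    "T2D": ("E11",),
    "hypercholesterolemia": ("E78.0",),
    "essential_hypertension": ("I10",),
    "CHD": tuple(f"I2{i}" for i in range(6)),            # I20-I25
    "CVD": tuple(f"I6{i}" for i in range(10)),           # I60-I69
}
ENDPOINTS["any_metabolic"] = tuple(
    sorted({c for name in ("T2D", "hypercholesterolemia",
                           "essential_hypertension", "CHD", "CVD")
            for c in ENDPOINTS[name]}))


class FitError(RuntimeError):
    pass


@dataclass
class SurvivalData:
    """Eligible records plus exclusion bookkeeping for one endpoint."""

    endpoint: str
    records: pd.DataFrame
    n_prevalent: int
    n_missing_covariates: int
    n_nonpositive_time: int

    @property
    def counts(self) -> dict:
        r = self.records
        return {
            "endpoint": self.endpoint,
            "eligible_cases": int((r["case"] == 1).sum()),
            "eligible_controls": int((r["case"] == 0).sum()),
            "events_cases": int(r.loc[r["case"] == 1, "event"].sum()),
            "events_controls": int(r.loc[r["case"] == 0, "event"].sum()),
            "prevalent_excluded": self.n_prevalent,
            "missing_covariates": self.n_missing_covariates,
            "nonpositive_time": self.n_nonpositive_time,
        }


def first_matching_diagnosis(diagnoses: pd.DataFrame,
                             prefixes: tuple[str, ...]) -> pd.Series:
    """Per-person date of the first diagnosis matching any code prefix."""
    if diagnoses.empty:
        return pd.Series(dtype="datetime64[ns]")
    hit = diagnoses[diagnoses["icd10"].astype(str).str.startswith(prefixes)]
    if hit.empty:
        return pd.Series(dtype="datetime64[ns]")
    return hit.groupby("person_id")["event_date"].min()


def build_survival(matched, diagnoses: pd.DataFrame, persons: pd.DataFrame,
                   endpoint: str,
                   measurements: pd.DataFrame | None = None,
                   prs: pd.DataFrame | None = None,
                   require_covariates: bool = False) -> SurvivalData:
    """One time-to-event record per eligible matched person.

    ``matched`` is a :class:`~sczmets.cohort.MatchedCohort`.  Event is the
    first diagnosis matching the endpoint's code prefixes strictly after
    the index date; persons with a matching code on or before index are
    prevalent and excluded.  With ``require_covariates`` persons lacking
    smoking or BMI information are also excluded (and counted).
    """
    prefixes = ENDPOINTS[endpoint]
    first_dx = first_matching_diagnosis(diagnoses, prefixes)
    idx = matched.index_dates()
    p = persons.set_index("person_id")
    case_ids = set(matched.case_ids)

    smoking = (smoking_ever_never(measurements)
               if measurements is not None else pd.Series(dtype=object))
    bmi = (median_bmi(measurements)
           if measurements is not None else pd.Series(dtype=float))

    rows, n_prev, n_miss, n_nonpos = [], 0, 0, 0
    for pid, index_date in idx.items():
        if pid not in p.index:
            continue
        fu = p.loc[pid, "followup_end"]
        dx = first_dx.get(pid, pd.NaT)
        if not pd.isna(dx) and dx <= index_date:
            n_prev += 1
            continue
        smoke = smoking.get(pid, None)
        med_bmi = bmi.get(pid, np.nan)
        if require_covariates and (smoke is None or np.isnan(med_bmi)):
            n_miss += 1
            continue
        event = (not pd.isna(dx)) and dx <= fu
        end = dx if event else fu
        t = (end.toordinal() - index_date.toordinal()) / DAYS_PER_YEAR
        if t <= 0:
            n_nonpos += 1
            continue
        rows.append({
            "person_id": pid, "case": int(pid in case_ids),
            "time": t, "event": int(event),
            "sex_male": float(p.loc[pid, "sex"] == "male"),
            "birth_year": float(p.loc[pid, "birth_date"].year),
            "smoking_ever": (float(smoke == "ever") if smoke is not None else np.nan),
            "bmi_category": (bmi_who_category(med_bmi)
                             if not np.isnan(med_bmi) else None),
        })
    records = pd.DataFrame(rows)
    if prs is not None and len(records):
        records = records.merge(
            prs[["person_id"] + list(PRS_TRAITS) + list(PC_COLUMNS)],
            on="person_id", how="left")
    return SurvivalData(endpoint=endpoint, records=records, n_prevalent=n_prev,
                        n_missing_covariates=n_miss, n_nonpositive_time=n_nonpos)


@dataclass
class CoxFit:
    summary: pd.DataFrame          # term -> coef, HR, CI, se, p
    n: int
    n_events: int
    model_terms: list[str]
    fitter: CoxPHFitter = field(repr=False, default=None)

    def hr(self, term: str) -> float:
        return float(np.exp(self.summary.loc[term, "coef"]))

    def hr_ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return (float(np.exp(row["coef"] - 1.959963984540054 * row["se"])),
                float(np.exp(row["coef"] + 1.959963984540054 * row["se"])))


def fit_cox(records: pd.DataFrame, terms: list[str]) -> CoxFit:
    """Efron-tie partial-likelihood Cox fit of ``time/event`` on ``terms``.

    Categorical ``bmi_category`` is expanded into dummies (reference:
    ``normal``).  Raises :class:`FitError` when a modelled group has no
    events or the optimiser fails.
    """
    df = records.copy()
    use: list[str] = []
    for t in terms:
        if t == "bmi_category":
            dummies = pd.get_dummies(df["bmi_category"], prefix="bmi", dtype=float)
            dummies = dummies.drop(columns=[c for c in ("bmi_normal",)
                                            if c in dummies.columns])
            keep = [c for c in dummies.columns if dummies[c].std() > 0]
            df = pd.concat([df, dummies[keep]], axis=1)
            use.extend(keep)
        else:
            df[t] = pd.to_numeric(df[t], errors="coerce")
            use.append(t)
    df = df.dropna(subset=use + ["time", "event"])
    if df["event"].sum() == 0:
        raise FitError("no events in the analysis set")
    if "case" in use:
        for grp, g in df.groupby("case"):
            if g["event"].sum() == 0:
                raise FitError(f"group case={grp} has zero events; fit refused")
    for t in use:
        if df[t].std() == 0:
            raise FitError(f"term {t!r} is constant in the analysis set")
    cph = CoxPHFitter()
    try:
        cph.fit(df[["time", "event"] + use], duration_col="time",
                event_col="event")
    except Exception as exc:
        raise FitError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"], "se": s["se(coef)"], "p": s["p"],
        "hr": np.exp(s["coef"]),
        "hr_lo": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
        "hr_hi": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
    })
    return CoxFit(summary=summary, n=len(df), n_events=int(df["event"].sum()),
                  model_terms=use, fitter=cph)


def cox_prs_stepwise(records: pd.DataFrame, base_terms: list[str],
                     candidates: tuple[str, ...] = PRS_TRAITS,
                     family_size: int = 6, alpha: float = 0.05
                     ) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Forward-stepwise PRS inclusion on top of a Cox model, with the
    endpoint-family Bonferroni entry threshold (``0.05/6`` by default).

    Returns ``(included, trace, marginal)``; the marginal table holds each
    candidate's covariate-adjusted single-score fit.
    """
    threshold = bonferroni_threshold(family_size, alpha)

    def term_fit(extra: list[str], cand: str) -> dict:
        try:
            fit = fit_cox(records, base_terms + extra + [cand])
            row = fit.summary.loc[cand]
            return {"term": cand, "estimate": float(row["coef"]),
                    "se": float(row["se"]), "p": float(row["p"]),
                    "hr": float(row["hr"]), "error": ""}
        except (FitError, KeyError) as exc:
            return {"term": cand, "estimate": np.nan, "se": np.nan,
                    "p": np.nan, "hr": np.nan, "error": str(exc)}

    marginal = pd.DataFrame([term_fit([], c) for c in candidates]).set_index("term")
    marginal["nominal_significant"] = marginal["p"] < alpha
    marginal["bonferroni_significant"] = marginal["p"] < threshold

    included: list[str] = []
    remaining = list(candidates)
    trace_rows = []
    step = 0
    while remaining:
        fits = [term_fit(included, c) for c in remaining]
        ok = [f for f in fits if np.isfinite(f["p"])]
        if not ok:
            break
        best = min(ok, key=lambda f: (f["p"], candidates.index(f["term"])))
        if best["p"] >= threshold:
            break
        step += 1
        included.append(best["term"])
        remaining.remove(best["term"])
        trace_rows.append({"step": step, "term": best["term"],
                           "p_at_entry": best["p"]})
    trace = pd.DataFrame(trace_rows, columns=["step", "term", "p_at_entry"])
    return included, trace, marginal


def adherence_survival(records: pd.DataFrame, profiles: pd.DataFrame,
                       term: str = "pdc_1year",
                       covariates: list[str] = ("sex_male", "birth_year"),
                       min_followup_years: float = 1.0) -> CoxFit:
    """Cox fit among treated cases only, with a first-year adherence metric
    as the exposure of interest."""
    cases = records[records["case"] == 1].merge(
        profiles[["person_id", term, "n_purchases"]], on="person_id")
    cases = cases[(cases["n_purchases"] > 0)
                  & cases[term].notna()
                  & (cases["time"] >= min_followup_years)]
    return fit_cox(cases, [term] + list(covariates))


def endpoint_table(matched, diagnoses, persons, measurements=None, prs=None,
                   endpoints: list[str] | None = None,
                   prs_stepwise: bool = False) -> pd.DataFrame:
    """Per-endpoint analysis summary shaped like a cohort results table:
    eligible N, incident events, HR (95% CI) for case status, and the PRSs
    surviving the 6-endpoint multiple-testing threshold when scanned."""
    rows = []
    for name in endpoints or list(ENDPOINTS):
        data = build_survival(matched, diagnoses, persons, name,
                              measurements=measurements, prs=prs)
        counts = data.counts
        try:
            fit = fit_cox(data.records, ["case", "sex_male", "birth_year"])
            hr, (lo, hi) = fit.hr("case"), fit.hr_ci("case")
            counts.update({"hr_case": hr, "hr_lo": lo, "hr_hi": hi,
                           "p_case": float(fit.summary.loc["case", "p"])})
        except FitError as exc:
            counts.update({"hr_case": np.nan, "hr_lo": np.nan,
                           "hr_hi": np.nan, "p_case": np.nan,
                           "fit_error": str(exc)})
            rows.append(counts)
            continue
        if prs_stepwise and prs is not None:
            included, _, marginal = cox_prs_stepwise(
                data.records, ["case", "sex_male", "birth_year"])
            counts["prs_surviving"] = ",".join(included)
            counts["prs_nominal"] = ",".join(
                marginal.index[marginal["nominal_significant"]])
        rows.append(counts)
    return pd.DataFrame(rows)
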
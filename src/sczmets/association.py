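"""Polygenic-score association: correlation structure, covariate-adjusted
marginal scans, and the forward-stepwise multivariate procedure.

Each candidate polygenic score is first modelled on its own against the
outcome (logistic for case status, linear for continuous outcomes such as
the median chlorpromazine-equivalent dose), always adjusted for the
baseline covariates (sex, birth year, 10 genotype PCs).  Scores are then
added incrementally to the baseline model, lowest Wald p-value first,
rescanning the remainder after each entry, until no candidate clears the
entry threshold (Bonferroni ``0.05/15`` for the 15-trait family by
default).  Wald tests are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import PC_COLUMNS, PRS_TRAITS

BASELINE_COVARIATES = ("sex_male", "birth_year") + PC_COLUMNS


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise entry/significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def odds_ratio_2x2(exposed_cases: int, unexposed_cases: int,
                   exposed_controls: int, unexposed_controls: int
                   ) -> tuple[float, tuple[float, float]]:
    """Unadjusted odds ratio with a 95% Wald CI from 2×2 counts."""
    t22 = sm.stats.Table2x2(np.array([[exposed_cases, unexposed_cases],
                                      [exposed_controls, unexposed_controls]]))
    return float(t22.oddsratio), tuple(t22.oddsratio_confint(0.05))


def prs_correlation(prs: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the 15 standardized scores."""
    if len(prs) < 3:
        raise ValueError("need at least 3 persons for a correlation matrix")
    cols = [t for t in PRS_TRAITS if t in prs.columns]
    x = prs[cols].astype(float)
    sd = x.std()
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError("constant PRS column(s): " + ", ".join(constant.index))
    return x.corr()


@dataclass
class StepwiseConfig:
    outcome_kind: str = "binary"                    # binary | continuous
    candidates: tuple[str, ...] = PRS_TRAITS
    baseline: tuple[str, ...] = BASELINE_COVARIATES
    alpha: float = 0.05
    family_size: int = len(PRS_TRAITS)

    @property
    def entry_threshold(self) -> float:
        return bonferroni_threshold(self.family_size, self.alpha)


@dataclass
class StepwiseResult:
    marginal: pd.DataFrame         # per-candidate covariate-adjusted fits
    trace: pd.DataFrame            # step, term, p_at_entry
    final_terms: list[str]
    final_model: pd.DataFrame      # coefficients of baseline + included PRSs
    config: StepwiseConfig = field(repr=False, default=None)


def _design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    x = data[terms].astype(float)
    return sm.add_constant(x, has_constant="add")


def _fit_term(outcome: np.ndarray, data: pd.DataFrame, terms: list[str],
              term: str, kind: str) -> dict:
    """Fit outcome ~ terms and report Wald statistics for ``term``."""
    x = _design(data, terms)
    try:
        if kind == "binary":
            res = sm.Logit(outcome, x).fit(disp=0, maxiter=200)
        else:
            res = sm.OLS(outcome, x).fit()
        if not np.isfinite(res.bse[term]) or res.bse[term] > 1e3:
            raise np.linalg.LinAlgError("unstable fit")
    except Exception as exc:  # separation, singularity, non-convergence
        return {"term": term, "estimate": np.nan, "se": np.nan, "p": np.nan,
                "error": type(exc).__name__}
    est, se, p = float(res.params[term]), float(res.bse[term]), float(res.pvalues[term])
    out = {"term": term, "estimate": est, "se": se, "p": p, "error": ""}
    if kind == "binary":
        out["or"] = float(np.exp(est))
        out["or_lo"] = float(np.exp(est - 1.959963984540054 * se))
        out["or_hi"] = float(np.exp(est + 1.959963984540054 * se))
    return out


def marginal_scan(outcome: np.ndarray, data: pd.DataFrame,
                  config: StepwiseConfig | None = None) -> pd.DataFrame:
    """One covariate-adjusted regression per candidate score.

    ``data`` must contain the candidate and baseline columns; failures
    (separation, singular fits) are recorded per candidate and the scan
    continues.
    """
    cfg = config or StepwiseConfig()
    rows = [_fit_term(outcome, data, list(cfg.baseline) + [c], c, cfg.outcome_kind)
            for c in cfg.candidates]
    df = pd.DataFrame(rows).set_index("term")
    df["nominal_significant"] = df["p"] < cfg.alpha
    df["bonferroni_significant"] = df["p"] < cfg.entry_threshold
    return df


def forward_stepwise(outcome: np.ndarray, data: pd.DataFrame,
                     config: StepwiseConfig | None = None) -> StepwiseResult:
    """Forward-stepwise inclusion of candidate scores over the baseline
    model; deterministic tie-break by trait-name order (the candidate tuple
    order).  An empty inclusion set is a valid result."""
    cfg = config or StepwiseConfig()
    marginal = marginal_scan(outcome, data, cfg)
    included: list[str] = []
    remaining = list(cfg.candidates)
    trace_rows = []
    step = 0
    while remaining:
        fits = [_fit_term(outcome, data,
                          list(cfg.baseline) + included + [c], c, cfg.outcome_kind)
                for c in remaining]
        ok = [f for f in fits if np.isfinite(f["p"])]
        if not ok:
            break
        best = min(ok, key=lambda f: (f["p"], cfg.candidates.index(f["term"])))
        if best["p"] >= cfg.entry_threshold:
            break
        step += 1
        included.append(best["term"])
        remaining.remove(best["term"])
        trace_rows.append({"step": step, "term": best["term"],
                           "p_at_entry": best["p"], "estimate": best["estimate"]})
    # final model coefficients
    x = _design(data, list(cfg.baseline) + included)
    if cfg.outcome_kind == "binary":
        res = sm.Logit(outcome, x).fit(disp=0, maxiter=200)
    else:
        res = sm.OLS(outcome, x).fit()
    final = pd.DataFrame({"estimate": res.params, "se": res.bse, "p": res.pvalues})
    trace = pd.DataFrame(trace_rows, columns=["step", "term", "p_at_entry",
                                              "estimate"])
    return StepwiseResult(marginal=marginal, trace=trace,
                          final_terms=included, final_model=final, config=cfg)


def association_frame(persons: pd.DataFrame, prs: pd.DataFrame,
                      case_ids: set[str] | None = None) -> pd.DataFrame:
    """Join persons with scores into one analysis frame with the canonical
    covariate encoding (``sex_male`` 0/1, continuous ``birth_year``)."""
    df = persons.merge(prs, on="person_id", how="inner")
    df["sex_male"] = (df["sex"] == "male").astype(float)
    df["birth_year"] = df["birth_date"].dt.year.astype(float)
    if case_ids is not None:
        df["case"] = df["person_id"].isin(case_ids).astype(int)
    return df
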
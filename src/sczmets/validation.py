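"""Independent oracles and parameter-recovery experiments.

This module holds the package's self-checks:

* a **day-grid brute-force oracle** for every coverage-based exposure
  metric.  It replays the dispensing conventions day by day (a FIFO supply
  queue for the stockpiling convention; per-day interval stamping without
  it), deliberately sharing no code with the interval arithmetic in
  :mod:`sczmets.exposure`, and must agree exactly;
* Monte-Carlo **parameter-recovery experiments** that generate data with
  known truth (Cox hazard ratios, logistic odds ratios, mixed-model fixed
  effects and scenario decade gains) and measure how well the analysis
  stages recover it;
* a Monte-Carlo check of the 83%-confidence-interval **non-overlap rule**;
* a greedy-vs-optimal benchmark for the birth-year matcher.

Everything is seeded and deterministic given its arguments.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import association, cohort, exposure, survival, synthetic, trajectory
from .io import ANTIPSYCHOTICS, DAYS_PER_YEAR, METABOLICALLY_ACTIVE


# ---------------------------------------------------------------------------
# day-grid oracle for exposure metrics


def daygrid_metrics(purchases: pd.DataFrame, followup_end,
                    cpz: dict[str, float], stockpile: bool = True,
                    batch_gap_days: int = 90,
                    anchor=None, lookback_years: float = 2.0) -> dict:
    """Brute-force exposure metrics from an explicit per-day array.

    Builds, day by day, which purchase supplies each calendar day (FIFO
    consumption under stockpiling; direct interval stamping otherwise), and
    derives every coverage metric by counting days.
    """
    rows = purchases.sort_values("purchase_date", kind="stable")
    horizon = pd.Timestamp(followup_end).toordinal()
    day0 = min(pd.Timestamp(d).toordinal() for d in rows["purchase_date"])
    span = max(horizon, max(pd.Timestamp(d).toordinal() + int(s)
                            for d, s in zip(rows["purchase_date"],
                                            rows["days_supplied"]))) - day0
    dose = np.zeros(span, float)
    active = np.zeros(span, bool)
    covered = np.zeros(span, bool)

    if stockpile:
        # FIFO: walk days; on a purchase day enqueue its supply, each day
        # consume one day from the front of the queue
        queue: list[list] = []  # [days_left, drug, mg/day]
        purchase_iter = [(pd.Timestamp(d).toordinal() - day0, str(drug), float(mg),
                          int(s))
                         for d, drug, mg, s in zip(rows["purchase_date"],
                                                   rows["drug_name"],
                                                   rows["daily_dose_mg"],
                                                   rows["days_supplied"])]
        pi = 0
        for day in range(span):
            while pi < len(purchase_iter) and purchase_iter[pi][0] == day:
                _, drug, mg, s = purchase_iter[pi]
                queue.append([s, drug, mg])
                pi += 1
            if day0 + day >= horizon:
                continue
            if queue:
                item = queue[0]
                covered[day] = True
                dose[day] += item[2] * cpz[item[1]]
                active[day] = item[1] in METABOLICALLY_ACTIVE
                item[0] -= 1
                if item[0] == 0:
                    queue.pop(0)
    else:
        for _, r in rows.iterrows():
            s = pd.Timestamp(r["purchase_date"]).toordinal() - day0
            for day in range(s, min(s + int(r["days_supplied"]),
                                    horizon - day0)):
                covered[day] = True
                dose[day] += float(r["daily_dose_mg"]) * cpz[str(r["drug_name"])]
                if str(r["drug_name"]) in METABOLICALLY_ACTIVE:
                    active[day] = True

    cov_idx = np.flatnonzero(covered)
    if cov_idx.size == 0:
        return {"covered_days": 0}
    fp = 0  # first purchase, relative day
    supply_end = int(cov_idx[-1]) + 1

    def count(lo: int, hi: int) -> int:
        lo, hi = max(lo, 0), min(hi, span)
        return int(covered[lo:hi].sum()) if hi > lo else 0

    def pdc(lo: int, hi: int) -> float | None:
        return count(lo, hi) / (hi - lo) if hi > lo else None

    horizon_rel = horizon - day0
    out = {
        "covered_days": int(cov_idx.size),
        "pdc_1year": pdc(fp, min(fp + 365, horizon_rel)),
        "pdc_lastyear": pdc(supply_end - 365, supply_end),
        "pdc_purchase": pdc(fp, supply_end),
        "pdc_followup": pdc(fp, horizon_rel),
        "ty_purchase": (supply_end - fp) / DAYS_PER_YEAR,
        "ty_supply": cov_idx.size / DAYS_PER_YEAR,
        "median_cpz_mg": float(np.median(dose[covered])),
        "active_share": float(active[covered].sum() / cov_idx.size),
    }
    if anchor is not None:
        a = pd.Timestamp(anchor).toordinal() - day0
        if a <= fp:
            out.update({"pdc_window": None, "median_cpz_window_mg": None,
                        "ty_supply_to_anchor": 0.0})
        else:
            lo = max(a - int(round(lookback_years * DAYS_PER_YEAR)), fp)
            wcov = covered[max(lo, 0):a]
            wdose = dose[max(lo, 0):a][wcov]
            out.update({
                "pdc_window": int(wcov.sum()) / (a - lo),
                "median_cpz_window_mg": (float(np.median(wdose))
                                         if wdose.size else None),
                "ty_supply_to_anchor": count(fp, a) / DAYS_PER_YEAR,
            })
    return out


def random_history(rng: np.random.Generator,
                   max_purchases: int = 30) -> tuple[pd.DataFrame, pd.Timestamp, pd.Timestamp]:
    """A random dispensing history designed to hit edge cases: duplicate
    dates, overlapping supplies, long gaps, truncation at follow-up."""
    n = int(rng.integers(1, max_purchases + 1))
    base = pd.Timestamp("2010-01-01").toordinal()
    days = np.sort(rng.integers(0, 2500, n))
    drugs = rng.choice(ANTIPSYCHOTICS, n)
    cpz = exposure.load_cpz_table()
    rows = pd.DataFrame({
        "person_id": "X",
        "purchase_date": [pd.Timestamp.fromordinal(base + int(d)) for d in days],
        "atc_code": "N05AX99",
        "drug_name": drugs,
        "daily_dose_mg": np.round(rng.uniform(5, 600, n), 1),
        "days_supplied": rng.integers(1, 91, n),
    })
    followup = pd.Timestamp.fromordinal(base + int(days.max())
                                        + int(rng.integers(30, 1200)))
    anchor = pd.Timestamp.fromordinal(base + int(rng.integers(-100, 2600)))
    return rows, followup, anchor


def _close(a, b, tol=1e-12) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return abs(a - b) <= tol * max(1.0, abs(a), abs(b))


def coverage_oracle_check(n_histories: int = 1000, seed: int = 0,
                          stockpile: bool = True) -> dict:
    """Compare every interval-arithmetic exposure metric against the
    day-grid oracle on random histories; returns agreement counts."""
    rng = np.random.default_rng(seed)
    cpz = exposure.load_cpz_table()
    keys = ("pdc_1year", "pdc_lastyear", "pdc_purchase", "pdc_followup",
            "ty_purchase", "ty_supply", "median_cpz_mg", "active_share",
            "pdc_window", "median_cpz_window_mg", "ty_supply_to_anchor")
    n_agree = 0
    mismatches: list[dict] = []
    for i in range(n_histories):
        rows, fu, anchor = random_history(rng)
        prof = exposure.treatment_profile(rows, fu, cpz=cpz,
                                          stockpile=stockpile)
        tl = exposure.build_timeline(rows, fu, stockpile=stockpile)
        w = exposure.windowed_exposure(tl, cpz, anchor)
        prof.update({"pdc_window": w.pdc_window,
                     "median_cpz_window_mg": w.median_cpz_window_mg,
                     "ty_supply_to_anchor": w.ty_supply_to_anchor})
        oracle = daygrid_metrics(rows, fu, cpz, stockpile=stockpile,
                                 anchor=anchor)
        bad = [k for k in keys if not _close(prof.get(k), oracle.get(k))]
        if bad:
            mismatches.append({"history": i, "keys": bad})
        else:
            n_agree += 1
    return {"n": n_histories, "n_agree": n_agree, "mismatches": mismatches}


# ---------------------------------------------------------------------------
# regression recovery experiments


def cox_hr_recovery(n_reps: int = 50, seed: int = 0, n_cases: int = 677,
                    n_controls: int = 2708, true_hr: float = 1.95) -> dict:
    """Cox estimates on exponential proportional-hazards cohorts with known
    hazard ratio: mean estimated HR and 95%-CI coverage of the truth."""
    rng = np.random.default_rng(seed)
    hrs, covered = [], 0
    for _ in range(n_reps):
        rec = synthetic.simulate_survival_records(
            n_cases, n_controls, true_hr=true_hr, rng=rng)
        fit = survival.fit_cox(rec, ["case"])
        hrs.append(fit.hr("case"))
        lo, hi = fit.hr_ci("case")
        covered += int(lo <= true_hr <= hi)
    return {"n_reps": n_reps, "mean_hr": float(np.mean(hrs)),
            "ci_coverage": covered / n_reps, "true_hr": true_hr}


def logistic_or_recovery(n_reps: int = 100, seed: int = 0,
                         n_cases: int = 677, n_controls: int = 2708,
                         true_or: float = 1.75) -> dict:
    """Marginal-scan logistic recovery of the SCZ-score odds ratio."""
    rng = np.random.default_rng(seed)
    ors = []
    cfg = association.StepwiseConfig(candidates=("SCZ",))
    for _ in range(n_reps):
        prs, case = synthetic.simulate_prs_case_control(
            n_cases, n_controls, log_or=math.log(true_or), rng=rng)
        data = prs.copy()
        data["sex_male"] = rng.integers(0, 2, len(data)).astype(float)
        data["birth_year"] = rng.integers(1970, 2000, len(data)).astype(float)
        scan = association.marginal_scan(case, data, cfg)
        ors.append(float(scan.loc["SCZ", "or"]))
    return {"n_reps": n_reps, "mean_or": float(np.mean(ors)),
            "true_or": true_or}


def _raw_tx_coefs(fit: trajectory.LMMFit) -> tuple[np.ndarray, np.ndarray]:
    """Map orthogonal-basis treatment coefficients back to raw per-year
    polynomial coefficients (with standard errors)."""
    cols = fit.poly.columns
    b = fit.fe_params[cols].to_numpy()
    cov = fit.cov_fe.loc[cols, cols].to_numpy()
    t = fit.poly.r_inv_ @ np.eye(len(cols))
    scale = np.array([fit.poly.scale_ ** k for k in range(1, len(cols) + 1)])
    m = (t / scale[:, None]).T  # raw_k = sum_j T[j,k]/scale_k * b_j
    raw = m.T @ b
    raw_se = np.sqrt(np.diag(m.T @ cov @ m))
    return raw, raw_se


def lmm_ladder_recovery(n_reps: int = 50, seed: int = 0, n_cases: int = 200,
                        alpha: float = 0.05) -> dict:
    """Closed-loop mixed-model check on generated BMI panels.

    For each replicate a cohort is generated with a true disease×age
    interaction and a true quartic treatment effect; the ladder is refit
    and we record how often the likelihood-ratio test selects each richer
    model and how often the generating fixed effects fall within ±2 SE of
    their estimates.
    """
    effect_map = {"const": "intercept", "sex_male": "male",
                  "smoking": "smoking", "bmi_prs": "bmi_prs",
                  "age_c": "age", "case": "case", "case_age": "case_age"}
    sel_inter, sel_treat, within, total = 0, 0, 0, 0
    for rep in range(n_reps):
        cfg = synthetic.GeneratorConfig(n_cases=n_cases, pool_factor=1.0,
                                        seed=seed + 1000 * rep)
        cfg.validate()
        sim = synthetic.simulate_cohort(cfg)
        t = sim.tables
        case_ids = set(sim.truth.loc[sim.truth["is_case"], "person_id"])
        frame = trajectory.trajectory_frame(t.persons, t.measurements, t.prs,
                                            t.dispensing, case_ids)
        fits, comp = trajectory.fit_ladder(frame)
        comp = comp.set_index("model")
        sel_inter += int(comp.loc["interaction", "lrt_p"] < alpha)
        sel_treat += int(comp.loc["treatment", "lrt_p"] < alpha)
        fit = fits["treatment"]
        eff = cfg.bmi_effects
        for col, name in effect_map.items():
            est = float(fit.fe_params[col])
            se = float(np.sqrt(fit.cov_fe.loc[col, col]))
            within += int(abs(est - eff[name]) <= 2 * se)
            total += 1
    return {"n_reps": n_reps,
            "interaction_selected": sel_inter / n_reps,
            "treatment_selected": sel_treat / n_reps,
            "fixed_effects_within_2se": within / total}


def true_decade_gain(effects: dict, days_per_year: int = 180,
                     horizon: float = 10.0) -> float:
    """Decade BMI gain implied by generating coefficients for a treated
    case accruing ``days_per_year`` of supply per year."""
    tx = horizon * days_per_year / DAYS_PER_YEAR
    quartic = (effects["tx1"] * tx + effects["tx2"] * tx ** 2
               + effects["tx3"] * tx ** 3 + effects["tx4"] * tx ** 4)
    return (effects["age"] + effects["case_age"]) * horizon + quartic


def decade_gain_recovery(n_reps: int = 8, seed: int = 0,
                         n_cases: int = 677) -> dict:
    """Generate full-size cohorts, refit the treatment model, and predict
    the 180-days-per-year treated-case scenario's decade gain."""
    gains = []
    scen = trajectory.TrajectoryScenario(group="treated_case",
                                         treatment_days_per_year=180)
    truth_gain = None
    for rep in range(n_reps):
        cfg = synthetic.GeneratorConfig(n_cases=n_cases, pool_factor=1.0,
                                        seed=seed + 7919 * rep)
        sim = synthetic.simulate_cohort(cfg)
        truth_gain = true_decade_gain(cfg.bmi_effects)
        t = sim.tables
        case_ids = set(sim.truth.loc[sim.truth["is_case"], "person_id"])
        frame = trajectory.trajectory_frame(t.persons, t.measurements, t.prs,
                                            t.dispensing, case_ids)
        specs = {"treatment": trajectory.ladder_specs()["treatment"]}
        fits, _ = trajectory.fit_ladder(frame, specs)
        pred = trajectory.predict_trajectory(fits["treatment"], scen)
        gains.append(pred.decade_gain)
    return {"n_reps": n_reps, "mean_gain": float(np.mean(gains)),
            "true_gain": float(truth_gain)}


def nonoverlap_null_rate(n_draws: int = 10000, seed: int = 0,
                         ci_level: float = 0.83) -> dict:
    """Monte-Carlo false-positive rate of the CI non-overlap rule for two
    independent equal-SE means under the null (≈5% at the 83% level)."""
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf((1.0 + ci_level) / 2.0)
    a = rng.standard_normal(n_draws)
    b = rng.standard_normal(n_draws)
    rate = float(np.mean(np.abs(a - b) > 2.0 * z))
    return {"n_draws": n_draws, "rate": rate, "z": float(z)}


def matching_benchmark(n_pools: int = 100, n_cases: int = 5, k: int = 4,
                       seed: int = 0) -> dict:
    """Greedy matcher vs optimal assignment on random small pools.

    Greedy nearest-neighbour is not guaranteed to reach the minimal total
    birth-year distance; each pool where it does not is reported.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    deviations = []
    for pool_i in range(n_pools):
        years = rng.integers(1975, 1996, n_cases)
        cases = pd.DataFrame({
            "person_id": [f"c{j}" for j in range(n_cases)],
            "sex": "female", "birth_year": years,
            "onset_date": pd.Timestamp("2015-06-01"),
        })
        n_cand = 3 * n_cases * k + int(rng.integers(0, 10))
        cand = pd.DataFrame({
            "person_id": [f"p{j}" for j in range(n_cand)],
            "sex": "female",
            "birth_year": rng.integers(1970, 2001, n_cand),
        })
        greedy = cohort.match_controls(cases, cand, k=k, seed=int(rng.integers(1 << 30)))
        g = greedy.total_distance()
        opt = cohort.optimal_total_distance(cases, cand, k=k)
        if g == opt:
            agree += 1
        else:
            deviations.append({"pool": pool_i, "greedy": g, "optimal": opt})
    return {"n_pools": n_pools, "n_agree": agree, "deviations": deviations}
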
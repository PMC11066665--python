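import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from sczmets import cohort, survival, synthetic


def efron_negloglik(beta, time, event, x):
    """Independent Efron-tie partial likelihood, written directly from the
    formula (one term per distinct event time)."""
    ll = 0.0
    theta = np.exp(beta * x)
    for ut in np.unique(time[event == 1]):
        d_mask = (time == ut) & (event == 1)
        risk = time >= ut
        m = int(d_mask.sum())
        sum_risk = theta[risk].sum()
        sum_d = theta[d_mask].sum()
        ll += beta * x[d_mask].sum()
        for ell in range(m):
            ll -= np.log(sum_risk - (ell / m) * sum_d)
    return -ll


# a tiny fixture with tied event times (synthetic; printed in full)
TINY = pd.DataFrame({
    "time":  [1.0, 1.0, 2.0, 3.0, 3.0, 4.0],
    "event": [1,   1,   0,   1,   1,   0],
    "case":  [1,   0,   1,   1,   0,   0],
})


def test_cox_matches_gridsearch_oracle_on_tiny_fixture():
    fit = survival.fit_cox(TINY, ["case"])
    res = minimize_scalar(
        efron_negloglik, bounds=(-5, 5), method="bounded",
        args=(TINY["time"].to_numpy(), TINY["event"].to_numpy(),
              TINY["case"].to_numpy(float)),
        options={"xatol": 1e-10})
    assert float(fit.summary.loc["case", "coef"]) == \
        pytest.approx(res.x, abs=1e-6)


def test_cox_matches_oracle_on_random_data():
    rng = np.random.default_rng(2)
    rec = synthetic.simulate_survival_records(40, 120, true_hr=2.2, rng=rng)
    rec["time"] = rec["time"].round(1)  # force ties
    rec = rec[rec["time"] > 0]
    fit = survival.fit_cox(rec, ["case"])
    res = minimize_scalar(
        efron_negloglik, bounds=(-5, 5), method="bounded",
        args=(rec["time"].to_numpy(), rec["event"].to_numpy(),
              rec["case"].to_numpy(float)), options={"xatol": 1e-10})
    assert float(fit.summary.loc["case", "coef"]) == \
        pytest.approx(res.x, abs=1e-5)


def _matched_fixture():
    persons = pd.DataFrame({
        "person_id": ["c1", "k1", "k2"],
        "sex": ["male"] * 3,
        "birth_date": pd.to_datetime(["1985-01-01"] * 3),
        "death_date": [pd.NaT] * 3,
        "followup_end": pd.to_datetime(["2023-03-31"] * 3),
    })
    pairs = pd.DataFrame({
        "case_id": ["c1", "c1"], "control_id": ["k1", "k2"],
        "birth_year_distance": [0, 0],
        "index_date": pd.to_datetime(["2012-01-01"] * 2),
    })
    return persons, cohort.MatchedCohort(pairs=pairs, k=2)


class TestBuildSurvival:
    def test_prevalent_case_excluded(self):
        persons, matched = _matched_fixture()
        diagnoses = pd.DataFrame({
            "person_id": ["c1"], "event_date": pd.to_datetime(["2011-06-01"]),
            "icd10": ["E11"]})
        data = survival.build_survival(matched, diagnoses, persons, "T2D")
        assert data.n_prevalent == 1
        assert set(data.records["person_id"]) == {"k1", "k2"}

    def test_no_matching_code_censored_at_followup(self):
        persons, matched = _matched_fixture()
        diagnoses = pd.DataFrame({
            "person_id": ["k1"], "event_date": pd.to_datetime(["2015-06-01"]),
            "icd10": ["I10"]})
        data = survival.build_survival(matched, diagnoses, persons, "T2D")
        rec = data.records.set_index("person_id")
        assert (rec["event"] == 0).all()
        assert rec.loc["c1", "time"] == pytest.approx(
            (pd.Timestamp("2023-03-31") - pd.Timestamp("2012-01-01")).days
            / 365.25)

    def test_event_after_index_counted(self):
        persons, matched = _matched_fixture()
        diagnoses = pd.DataFrame({
            "person_id": ["c1"], "event_date": pd.to_datetime(["2015-01-01"]),
            "icd10": ["E11.9"]})
        data = survival.build_survival(matched, diagnoses, persons, "T2D")
        rec = data.records.set_index("person_id")
        assert rec.loc["c1", "event"] == 1
        assert rec.loc["c1", "time"] == pytest.approx(3.0, abs=0.01)

    def test_bookkeeping_sums_to_cohort(self, small_cohort, small_matched):
        t = small_cohort.tables
        _, matched = small_matched
        n_persons = len(set(matched.case_ids) | set(matched.control_ids))
        for endpoint in ("T2D", "any_metabolic"):
            d = survival.build_survival(matched, t.diagnoses, t.persons,
                                        endpoint, measurements=t.measurements,
                                        require_covariates=True)
            total = (len(d.records) + d.n_prevalent
                     + d.n_missing_covariates + d.n_nonpositive_time)
            assert total == n_persons


class TestFitCox:
    def test_zero_events_in_group_refused(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4.0],
                           "event": [0, 0, 1, 1],
                           "case": [1, 1, 0, 0]})
        with pytest.raises(survival.FitError, match="case=1"):
            survival.fit_cox(df, ["case"])

    def test_constant_term_refused(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4.0], "event": [1, 0, 1, 0],
                           "case": [1, 1, 1, 1]})
        with pytest.raises(survival.FitError, match="constant"):
            survival.fit_cox(df, ["case"])

    def test_null_simulation_ci_coverage(self):
        rng = np.random.default_rng(3)
        cover = 0
        for _ in range(40):
            rec = synthetic.simulate_survival_records(150, 600, true_hr=1.0,
                                                      rng=rng)
            fit = survival.fit_cox(rec, ["case"])
            lo, hi = fit.hr_ci("case")
            cover += int(lo <= 1.0 <= hi)
        assert cover / 40 >= 0.85

    def test_monotone_censoring_reduces_events(self, small_cohort,
                                               small_matched):
        t = small_cohort.tables
        _, matched = small_matched
        d = survival.build_survival(matched, t.diagnoses, t.persons,
                                    "any_metabolic")
        full = int(d.records["event"].sum())
        trunc = d.records.copy()
        cut = trunc["time"].median()
        trunc["event"] = np.where(trunc["time"] <= cut, trunc["event"], 0)
        trunc["time"] = trunc["time"].clip(upper=cut)
        assert int(trunc["event"].sum()) <= full


class TestAdherence:
    def test_protective_adherence_sign_recovered(self):
        rng = np.random.default_rng(4)
        negative = 0
        for _ in range(20):
            n = 500
            pdc = rng.uniform(0, 1, n)
            rate = 0.05 * np.exp(-0.8 * pdc)
            t_event = rng.exponential(1.0 / rate)
            t_cens = rng.uniform(2, 12, n)
            rec = pd.DataFrame({
                "person_id": [f"c{i}" for i in range(n)],
                "case": 1,
                "time": np.minimum(t_event, t_cens),
                "event": (t_event <= t_cens).astype(int),
                "sex_male": rng.integers(0, 2, n).astype(float),
                "birth_year": rng.integers(1970, 2000, n).astype(float),
            })
            profiles = pd.DataFrame({
                "person_id": rec["person_id"], "pdc_1year": pdc,
                "n_purchases": 10})
            fit = survival.adherence_survival(rec, profiles)
            negative += int(fit.summary.loc["pdc_1year", "coef"] < 0)
        assert negative >= 19

    def test_constant_adherence_refused(self):
        rec = pd.DataFrame({
            "person_id": ["a", "b", "c", "d"], "case": 1,
            "time": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 0],
            "sex_male": [0.0, 1.0, 0.0, 1.0],
            "birth_year": [1980.0, 1985.0, 1990.0, 1981.0],
        })
        profiles = pd.DataFrame({"person_id": rec["person_id"],
                                 "pdc_1year": 0.5, "n_purchases": 5})
        with pytest.raises(survival.FitError):
            survival.adherence_survival(rec, profiles)


def test_endpoint_table_shape(small_cohort, small_matched):
    t = small_cohort.tables
    _, matched = small_matched
    tab = survival.endpoint_table(matched, t.diagnoses, t.persons,
                                  endpoints=["any_metabolic"])
    assert {"eligible_cases", "eligible_controls", "events_cases",
            "events_controls"} <= set(tab.columns)
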
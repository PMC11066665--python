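import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import erfinv

from sczmets import trajectory as traj
from sczmets.io import PC_COLUMNS


def _linear_frame(rng, n_subj=150, slope=0.15, resid=0.8):
    """Simple longitudinal frame: BMI linear in age, random intercepts."""
    rows = []
    for i in range(n_subj):
        u = rng.normal(0, 2.0)
        ages = np.sort(rng.uniform(20, 45, 4))
        for a in ages:
            rows.append({"person_id": f"s{i}", "bmi": 24 + slope * (a - 27)
                         + u + rng.normal(0, resid),
                         "age": a, "age_c": a - 27.0,
                         "sex_male": float(i % 2), "smoking": 0.0,
                         "bmi_prs": 0.0, "case": 0.0, "case_age": 0.0,
                         "tx_years": 0.0, "const": 1.0,
                         "pdc_window": np.nan,
                         "median_cpz_window_mg": np.nan})
    df = pd.DataFrame(rows)
    for c in PC_COLUMNS:
        df[c] = 0.0
    return df


@pytest.fixture(scope="module")
def linear_fit():
    rng = np.random.default_rng(0)
    df = _linear_frame(rng)
    specs = {"baseline": ["const", "sex_male", "age_c"]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits, _ = traj.fit_ladder(df, specs)
    return fits["baseline"]


class TestPolyBasis:
    def test_vanishes_at_zero(self):
        rng = np.random.default_rng(1)
        b = traj.PolyBasis().fit(rng.uniform(0, 8, 200))
        assert np.allclose(b.transform(np.array([0.0])), 0.0)

    def test_round_trips_a_quartic(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(0, 8, 300)
        b = traj.PolyBasis().fit(t)
        y = 1.06 * t - 0.16 * t ** 2 + 0.014 * t ** 3 - 0.00035 * t ** 4
        coef, *_ = np.linalg.lstsq(b.transform(t), y, rcond=None)
        assert np.allclose(b.transform(t) @ coef, y, atol=1e-8)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            traj.PolyBasis().fit(np.array([0.0, 1.0, 0.0, 1.0]))


class TestPrediction:
    def test_linear_slope_gives_decade_gain(self, linear_fit):
        scen = traj.TrajectoryScenario(group="control", sex_male=False,
                                       smoking=False)
        pred = traj.predict_trajectory(linear_fit, scen)
        assert pred.decade_gain == pytest.approx(
            10 * float(linear_fit.fe_params["age_c"]), rel=1e-9)
        assert pred.decade_gain == pytest.approx(1.5, abs=0.25)

    def test_decade_gain_invariant_to_grid_origin(self, linear_fit):
        a = traj.predict_trajectory(linear_fit, traj.TrajectoryScenario(
            group="control", start_age=27.0))
        b = traj.predict_trajectory(linear_fit, traj.TrajectoryScenario(
            group="control", start_age=32.0))
        assert a.decade_gain == pytest.approx(b.decade_gain, rel=1e-9)

    def test_band_halfwidth_uses_normal_quantile(self, linear_fit):
        scen = traj.TrajectoryScenario(group="control")
        pred = traj.predict_trajectory(linear_fit, scen, ci_level=0.83)
        x = traj.scenario_design(linear_fit, scen, pred.ages)
        se = linear_fit.predict_se(x)
        z_oracle = np.sqrt(2.0) * erfinv(0.83)  # ~1.372
        assert z_oracle == pytest.approx(1.3722, abs=1e-4)
        assert np.allclose((pred.hi - pred.lo) / 2.0, z_oracle * se)

    def test_band_widens_with_extrapolation(self, linear_fit):
        pred = traj.predict_trajectory(linear_fit, traj.TrajectoryScenario(
            group="control", start_age=27.0, horizon_years=25.0))
        half = pred.hi - pred.lo
        assert half[-1] > half[0]

    def test_treated_scenario_requires_treatment_terms(self, linear_fit):
        with pytest.raises(ValueError, match="tx"):
            traj.predict_trajectory(linear_fit, traj.TrajectoryScenario(
                group="treated_case"))


class TestNonoverlap:
    def _pred(self, mean, se, ages=None):
        ages = np.arange(27.0, 37.5, 0.5) if ages is None else ages
        m = np.full_like(ages, mean, dtype=float)
        z = 1.3722038089987263
        return traj.TrajectoryPrediction(
            scenario=traj.TrajectoryScenario(), ages=ages, mean=m,
            lo=m - z * se, hi=m + z * se, ci_level=0.83)

    def test_identical_predictions_never_disjoint(self):
        a, b = self._pred(24.0, 0.5), self._pred(24.0, 0.5)
        assert not traj.nonoverlap_test(a, b).any()

    def test_widely_separated_always_disjoint(self):
        a, b = self._pred(24.0, 0.5), self._pred(30.0, 0.5)
        assert traj.nonoverlap_test(a, b).all()

    def test_mismatched_grids_raise(self):
        a = self._pred(24.0, 0.5)
        b = self._pred(24.0, 0.5, ages=np.arange(30.0, 40.5, 0.5))
        with pytest.raises(ValueError, match="grid"):
            traj.nonoverlap_test(a, b)

    def test_null_rate_close_to_alpha(self):
        from sczmets.validation import nonoverlap_null_rate
        res = nonoverlap_null_rate(n_draws=10_000, seed=3)
        assert res["rate"] == pytest.approx(0.05, abs=0.02)


class TestLadder:
    def test_loglik_monotone_in_nesting(self, small_cohort):
        t = small_cohort.tables
        truth = small_cohort.truth
        case_ids = set(truth.loc[truth["is_case"], "person_id"])
        frame = traj.trajectory_frame(t.persons, t.measurements, t.prs,
                                      t.dispensing, case_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits, comp = traj.fit_ladder(frame)
        llf = comp["llf"].to_numpy()
        assert (np.diff(llf) >= -1e-6).all()
        assert (comp["lrt_p"].dropna() >= 0).all()

    def test_blup_prediction_beats_population_prediction(self, small_cohort):
        t = small_cohort.tables
        truth = small_cohort.truth
        case_ids = set(truth.loc[truth["is_case"], "person_id"])
        frame = traj.trajectory_frame(t.persons, t.measurements, t.prs,
                                      t.dispensing, case_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = traj.fit_lmm(frame, traj.ladder_specs()["baseline"])
        x = frame[fit.fixed_cols].to_numpy(float)
        pop = fit.predict_mean(x)
        re = fit.result.random_effects
        blup_adj = np.array([
            re[pid].iloc[0] + re[pid].iloc[1] * ac
            for pid, ac in zip(frame["person_id"], frame["age_c"])])
        resid_pop = frame["bmi"].to_numpy() - pop
        resid_blup = resid_pop - blup_adj
        assert (resid_blup ** 2).sum() < (resid_pop ** 2).sum()


def test_dose_adherence_effects_recovers_positive_signs(small_cohort):
    """Among treated cases, windowed dose/adherence/duration and BMI PRS
    all enter positively (as generated)."""
    rng = np.random.default_rng(12)
    n = 500
    rows = []
    for i in range(n):
        u = rng.normal(0, 2.0)
        pdc = rng.uniform(0.2, 1.0)
        cpz = rng.lognormal(np.log(200), 0.5)
        for k in range(3):
            age_c = rng.uniform(-5, 10)
            tx = max(0.1, age_c + 5) * pdc * 0.5
            bmi = (24 + 0.15 * age_c + 1.4 * pdc + 0.27 * tx
                   + 1.56 * rng.normal() * 0 + u + rng.normal(0, 1.0))
            rows.append({"person_id": f"c{i}", "bmi": bmi, "age_c": age_c,
                         "sex_male": float(i % 2), "smoking": 0.0,
                         "bmi_prs": 0.0, "case": 1.0,
                         "case_age": age_c, "tx_years": tx,
                         "pdc_window": pdc, "median_cpz_window_mg": cpz,
                         "const": 1.0})
    df = pd.DataFrame(rows)
    for c in PC_COLUMNS:
        df[c] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _ = traj.dose_adherence_effects(df)
    assert table.loc["pdc_window", "estimate"] > 0
    assert table.loc["tx_years", "estimate"] > 0


def test_dose_adherence_constant_term_dropped():
    rng = np.random.default_rng(13)
    rows = []
    for i in range(80):
        for _ in range(3):
            age_c = rng.uniform(-5, 10)
            rows.append({"person_id": f"c{i}", "bmi": 24 + rng.normal(),
                         "age_c": age_c, "sex_male": float(i % 2),
                         "smoking": 1.0,  # constant -> must be dropped
                         "bmi_prs": rng.normal(), "case": 1.0,
                         "case_age": age_c, "tx_years": rng.uniform(0, 5),
                         "pdc_window": rng.uniform(0, 1),
                         "median_cpz_window_mg": rng.lognormal(5, 0.4),
                         "const": 1.0})
    df = pd.DataFrame(rows)
    for c in PC_COLUMNS:
        df[c] = 0.0
    with pytest.warns(UserWarning, match="smoking"):
        table, _ = traj.dose_adherence_effects(df)
    assert "smoking" not in table.index
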
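import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sczmets import exposure as ex
from sczmets import validation as v
from conftest import purchases

FU = pd.Timestamp("2015-01-01")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 1500), st.integers(1, 90)),
                min_size=1, max_size=15))
def test_timeline_invariants_hold_for_any_history(spec):
    """Intervals are disjoint, sorted, >=1 day; with stockpiling and no
    truncation the covered days equal the supplied days."""
    tl = ex.build_timeline(purchases(spec), FU, stockpile=True)
    for (s1, e1), (s2, e2) in zip(tl.covered, tl.covered[1:]):
        assert e1 < s2
    assert all(e > s for s, e in tl.covered)
    horizon = FU.toordinal()
    if tl.supply_end < horizon:
        assert tl.covered_days == sum(s for _, s in spec)
    assert tl.supply_end <= horizon


class TestTimeline:
    def test_stockpile_shifts_overlap_forward(self, cpz):
        tl = ex.build_timeline(purchases([(0, 30), (10, 30)]), FU,
                               stockpile=True)
        base = pd.Timestamp("2010-01-01").toordinal()
        assert tl.covered == [(base, base + 60)]
        assert tl.covered_days == 60

    def test_no_stockpile_merges_overlap(self, cpz):
        tl = ex.build_timeline(purchases([(0, 30), (10, 30)]), FU,
                               stockpile=False)
        assert tl.covered_days == 40

    def test_truncated_at_followup(self):
        tl = ex.build_timeline(purchases([(0, 400)]),
                               pd.Timestamp("2010-01-01")
                               + pd.Timedelta(days=100))
        assert tl.covered_days == 100

    def test_total_days_equal_sum_supplied_without_truncation(self):
        rng = np.random.default_rng(4)
        spec = [(int(d), int(s)) for d, s in
                zip(np.sort(rng.integers(0, 600, 12)),
                    rng.integers(1, 60, 12))]
        tl = ex.build_timeline(purchases(spec), FU, stockpile=True)
        assert tl.covered_days == sum(s for _, s in spec)

    def test_empty_purchases_signal_never_treated(self):
        with pytest.raises(ex.NeverTreatedError):
            ex.build_timeline(purchases([]).iloc[0:0], FU)


class TestPDC:
    def test_single_purchase_first_year(self):
        tl = ex.build_timeline(purchases([(0, 30)]), FU)
        assert ex.compute_pdc(tl, "first_year", FU) == pytest.approx(30 / 365)

    def test_full_coverage_all_windows_one(self):
        spec = [(30 * i, 30) for i in range(37)]  # ~3y continuous
        fu = pd.Timestamp("2010-01-01") + pd.Timedelta(days=37 * 30)
        tl = ex.build_timeline(purchases(spec), fu)
        for w in ex.PDC_WINDOWS:
            assert ex.compute_pdc(tl, w, fu) == 1.0

    def test_mock_history_first_year(self):
        tl = ex.build_timeline(purchases([(0, 30), (40, 30), (100, 30)]), FU)
        assert ex.compute_pdc(tl, "first_year", FU) == pytest.approx(90 / 365)

    def test_followup_never_exceeds_purchase_span_pdc(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            rows, fu, _ = v.random_history(rng)
            tl = ex.build_timeline(rows, fu)
            p = ex.compute_pdc(tl, "purchase_span", fu)
            f = ex.compute_pdc(tl, "followup", fu)
            assert f <= p + 1e-12


class TestTreatmentLengths:
    def test_gap_free_coverage(self):
        spec = [(365 * i, 365) for i in range(2)]
        tl = ex.build_timeline(purchases(spec), FU)
        ty_p, ty_s = ex.treatment_lengths(tl)
        assert ty_p == ty_s == pytest.approx(730 / 365.25)

    def test_gap_splits_supply_from_span(self):
        tl = ex.build_timeline(purchases([(0, 365), (1095, 365)]), FU)
        ty_p, ty_s = ex.treatment_lengths(tl)
        assert ty_s == pytest.approx(730 / 365.25)
        assert ty_p == pytest.approx(1460 / 365.25)

    def test_supply_never_exceeds_span(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            rows, fu, _ = v.random_history(rng)
            ty_p, ty_s = ex.treatment_lengths(ex.build_timeline(rows, fu))
            assert ty_s <= ty_p + 1e-12


class TestDiscontinuation:
    def test_supply_end_far_before_followup(self):
        tl = ex.build_timeline(purchases([(0, 30)]), FU)
        fu = pd.Timestamp("2010-01-31") + pd.Timedelta(days=400)
        disc, years = ex.flag_discontinuation(tl, fu)
        assert disc and years == pytest.approx(30 / 365.25)

    def test_within_threshold_of_death(self):
        tl = ex.build_timeline(purchases([(0, 30)]), FU)
        death = pd.Timestamp("2010-01-31") + pd.Timedelta(days=100)
        disc, _ = ex.flag_discontinuation(tl, FU, death_date=death)
        assert not disc


class TestCPZDose:
    def test_chlorpromazine_anchor(self, cpz):
        tl = ex.build_timeline(purchases([(0, 30)]), FU)
        assert ex.median_cpz_dose(tl, cpz) == 100.0

    def test_two_batches_equal_days_average(self, cpz):
        spec = [(0, 30, "chlorpromazine", 150.0),
                (200, 30, "chlorpromazine", 250.0)]
        tl = ex.build_timeline(purchases(spec), FU)
        assert len(ex.batches(tl, 90)) == 2
        assert ex.median_cpz_dose(tl, cpz) == 200.0

    def test_invariant_to_splitting_a_purchase(self, cpz):
        whole = ex.build_timeline(purchases([(0, 60)]), FU)
        split = ex.build_timeline(purchases([(0, 30), (30, 30)]), FU)
        assert ex.median_cpz_dose(whole, cpz) == \
            ex.median_cpz_dose(split, cpz)

    def test_unknown_drug_raises(self, cpz):
        tl = ex.build_timeline(purchases([(0, 30)]), FU)
        with pytest.raises(KeyError, match="chlorpromazine"):
            ex.median_cpz_dose(tl, {"olanzapine": 20.0})


class TestActiveShare:
    def test_all_active(self, cpz):
        tl = ex.build_timeline(purchases([(0, 30, "olanzapine", 10.0)]), FU)
        assert ex.active_drug_share(tl) == 1.0

    def test_none_active(self):
        tl = ex.build_timeline(purchases([(0, 30, "haloperidol", 4.0)]), FU)
        assert ex.active_drug_share(tl) == 0.0

    def test_half_and_half(self):
        spec = [(0, 30, "quetiapine", 300.0), (60, 30, "haloperidol", 4.0)]
        tl = ex.build_timeline(purchases(spec), FU)
        assert ex.active_drug_share(tl) == 0.5


class TestWindowed:
    def test_anchor_before_first_purchase(self, cpz):
        tl = ex.build_timeline(purchases([(0, 30)]), FU)
        w = ex.windowed_exposure(tl, cpz, pd.Timestamp("2009-06-01"))
        assert w.pdc_window is None
        assert w.ty_supply_to_anchor == 0.0

    def test_full_coverage_in_lookback(self, cpz):
        spec = [(30 * i, 30) for i in range(37)]
        tl = ex.build_timeline(purchases(spec), FU)
        w = ex.windowed_exposure(tl, cpz, pd.Timestamp("2012-06-01"))
        assert w.pdc_window == 1.0


def test_profiles_zero_purchase_person(small_cohort):
    t = small_cohort.tables
    profiles = ex.derive_profiles(t.persons, t.dispensing)
    untreated = profiles[profiles["n_purchases"] == 0]
    assert len(untreated) > 0
    assert untreated["pdc_1year"].isna().all()
    assert (~untreated["discontinued"].astype(bool)).all()


def test_interval_metrics_match_daygrid_oracle():
    """Exact agreement with the day-by-day brute force, both conventions."""
    res = v.coverage_oracle_check(n_histories=150, seed=77, stockpile=True)
    assert res["n_agree"] == res["n"], res["mismatches"][:3]
    res = v.coverage_oracle_check(n_histories=60, seed=78, stockpile=False)
    assert res["n_agree"] == res["n"], res["mismatches"][:3]
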
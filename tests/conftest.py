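import pandas as pd
import pytest

from sczmets import cohort, exposure, synthetic


@pytest.fixture(scope="session")
def cpz():
    return exposure.load_cpz_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic extract shared across test modules."""
    cfg = synthetic.GeneratorConfig(n_cases=60, pool_factor=1.5, seed=314)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matched(small_cohort):
    t = small_cohort.tables
    cases, _ = cohort.identify_cases(t.persons, t.dispensing, t.diagnoses)
    pool = cohort.eligible_controls(t.persons, t.diagnoses, t.dispensing,
                                    set(cases["person_id"]))
    matched = cohort.match_controls(cases, pool, k=4, seed=9)
    return cases, matched


def purchases(spec, person_id="p1", drug="chlorpromazine", dose=100.0,
              start="2010-01-01"):
    """Build a dispensing frame from (day_offset, days_supplied) pairs, or
    (day_offset, days_supplied, drug, dose) tuples."""
    base = pd.Timestamp(start).toordinal()
    rows = []
    for item in spec:
        day, supply = item[0], item[1]
        d = item[2] if len(item) > 2 else drug
        mg = item[3] if len(item) > 3 else dose
        rows.append({"person_id": person_id,
                     "purchase_date": pd.Timestamp.fromordinal(base + day),
                     "atc_code": "N05AA01", "drug_name": d,
                     "daily_dose_mg": mg, "days_supplied": supply})
    return pd.DataFrame(rows)
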
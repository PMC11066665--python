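"""Synthetic biobank-extract generator.

The real analysis runs on access-restricted registry data, so this module
generates a full synthetic extract with the statistical structure the
downstream stages assume:

* ~677 schizophrenia-spectrum (SSD) cases with onset at age 15–40 after
  2006, 54% female, plus a birth-year/sex-compatible control candidate pool;
* correlated standardized polygenic scores (15 traits, 10 PCs); case status
  is tied to the SCZ score by a configurable log-odds-ratio via a mean-shift
  construction (cases' score vector is shifted by ``δ·R[:,SCZ]``, which
  makes the multivariate logistic coefficient on the SCZ score exactly
  ``δ`` and induces realistic shifts in correlated scores);
* dispensing histories with gaps, switching among the 20 recognised
  antipsychotics, stockpiling, and forced discontinuation;
* metabolic endpoint diagnoses from constant (memoryless) proportional
  hazards in age, so that hazards are equally proportional on the
  time-since-index scale used by the Cox models;
* BMI measurement panels generated from the longitudinal trajectory model
  (random intercept + random age slope, disease×age interaction, quartic
  polynomial in accumulated treatment years).

All latent quantities are returned in a truth table so parameter-recovery
tests can close the loop.  Identical ``(config, seed)`` give identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import DAYS_PER_YEAR, PC_COLUMNS, PRS_TRAITS, Tables
from . import exposure as expo

FREEZE_DATE = pd.Timestamp("2023-03-31")
REGISTRY_START = pd.Timestamp("2004-01-01")
ONSET_WINDOW = (pd.Timestamp("2007-01-01"), pd.Timestamp("2019-01-01"))

# ATC codes for the recognised antipsychotics (all N05A, never N05AN)
ATC_BY_DRUG = {
    "chlorpromazine": "N05AA01", "levomepromazine": "N05AA02",
    "fluphenazine": "N05AB02", "perphenazine": "N05AB03",
    "haloperidol": "N05AD01", "melperone": "N05AD03",
    "sertindole": "N05AE03", "ziprasidone": "N05AE04",
    "flupentixol": "N05AF01", "chlorprothixene": "N05AF03",
    "zuclopenthixol": "N05AF05", "sulpiride": "N05AL01",
    "amisulpride": "N05AL05", "clozapine": "N05AH02",
    "olanzapine": "N05AH03", "quetiapine": "N05AH04",
    "risperidone": "N05AX08", "aripiprazole": "N05AX12",
    "paliperidone": "N05AX13", "cariprazine": "N05AX15",
}

DRUG_WEIGHTS = {
    "olanzapine": 0.18, "quetiapine": 0.17, "risperidone": 0.13,
    "aripiprazole": 0.10, "clozapine": 0.09, "amisulpride": 0.06,
    "haloperidol": 0.06, "zuclopenthixol": 0.04, "perphenazine": 0.03,
    "flupentixol": 0.03, "chlorprothixene": 0.03, "levomepromazine": 0.02,
    "sulpiride": 0.02, "paliperidone": 0.025, "ziprasidone": 0.01,
    "cariprazine": 0.01, "chlorpromazine": 0.01, "melperone": 0.005,
    "sertindole": 0.005, "fluphenazine": 0.005,
}

#: generating fixed effects of the BMI trajectory model (kg/m² units;
#: age centered at 27 years; treatment years entered as a raw quartic)
DEFAULT_BMI_EFFECTS = {
    "intercept": 24.0,
    "male": 0.3,
    "smoking": -0.3,
    "bmi_prs": 1.2,          # per SD of BMI PRS
    "age": 0.15,             # BMI points per year of age (controls)
    "case": -0.6,            # case level offset at age 27
    "case_age": 0.03,        # extra slope for cases (untreated trajectory)
    "tx1": 1.06, "tx2": -0.16, "tx3": 0.014, "tx4": -0.00035,
    "sd_intercept": 3.8, "sd_slope": 0.07, "sd_resid": 1.3,
}

#: endpoint name -> (generated ICD-10 code, control events/person-year,
#:                   hazard ratio for SSD case status, PRS log-HRs)
DEFAULT_ENDPOINT_TRUTH = {
    "T2D": ("E11", 0.0005, 4.19, {"T2D": 0.30}),
    "hypercholesterolemia": ("E78.0", 0.0080, 1.43, {"nonHDL": 0.22, "LDL": 0.12}),
    "essential_hypertension": ("I10", 0.0064, 1.92, {"DBP": 0.25, "SBP": 0.10}),
    "CHD": ("I21", 0.0008, 3.35, {"nonHDL": 0.15}),
    "CVD": ("I63", 0.0010, 3.48, {}),
}

DEFAULT_DISPENSING = {
    "treated_fraction": 0.879,        # share of cases with >=1 purchase
    "first_purchase_delay_days": 90,  # uniform upper bound after onset
    "adherence_beta": (3.5, 1.9),     # person-level adherence ~ Beta
    "supply_days": ((30, 60, 90), (0.35, 0.35, 0.30)),
    "gap_lognorm_sigma": 0.25,        # multiplicative gap noise
    "switch_prob": 0.08,              # drug switch per purchase
    "discontinuation_prob": 0.41,     # forced early stop
    "disc_median_years": 2.1,         # lognormal median of stop time
    "disc_sigma": 0.8,
    "cpz_median_mg": 190.0,           # person-level CPZ-equiv target
    "cpz_sigma": 0.55,
}


def default_prs_correlation() -> pd.DataFrame:
    """Plausible 15×15 PRS correlation matrix with the trait clusters the
    score panel exhibits (blood pressure, lipids, glycaemic traits, and an
    adiposity/inflammation group; SCZ inversely related to BMI/CRP/T2D)."""
    pairs = {
        ("TC", "LDL"): 0.85, ("TC", "nonHDL"): 0.90, ("LDL", "nonHDL"): 0.90,
        ("TC", "HDL"): 0.10, ("HDL", "TG"): -0.35, ("HDL", "nonHDL"): -0.15,
        ("TG", "nonHDL"): 0.45, ("TG", "CRP"): 0.25, ("CRP", "BMI"): 0.40,
        ("CRP", "T2D"): 0.32, ("T2D", "BMI"): 0.45, ("T2D", "TG"): 0.30,
        ("T2D", "FG"): 0.30, ("T2D", "HbA1c"): 0.30, ("HbA1c", "RG"): 0.43,
        ("HbA1c", "FG"): 0.05, ("FG", "RG"): 0.30, ("SBP", "DBP"): 0.60,
        ("CHD", "LDL"): 0.30, ("CHD", "nonHDL"): 0.30, ("CHD", "SBP"): 0.20,
        ("CHD", "T2D"): 0.25, ("BMI", "TG"): 0.25, ("BMI", "HDL"): -0.30,
        ("BMI", "SBP"): 0.20, ("BMI", "DBP"): 0.20, ("SCZ", "BMI"): -0.20,
        ("SCZ", "CRP"): -0.15, ("SCZ", "T2D"): -0.10,
    }
    idx = {t: i for i, t in enumerate(PRS_TRAITS)}
    r = np.eye(len(PRS_TRAITS))
    for (a, b), v in pairs.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    # project onto the nearest well-conditioned correlation matrix
    # (eigenvalue floor + diagonal renormalization); the targeted pairwise
    # values move by < 0.005
    w, vec = np.linalg.eigh(r)
    r = vec @ np.diag(np.clip(w, 0.05, None)) @ vec.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=PRS_TRAITS, columns=PRS_TRAITS)


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic extract; defaults reproduce the
    target cohort shape (677 cases, 4 controls each, 54% female)."""

    n_cases: int = 677
    controls_per_case: int = 4
    pool_factor: float = 1.5          # candidate pool size per needed control
    fraction_female: float = 0.54
    prs_correlation: pd.DataFrame = field(default_factory=default_prs_correlation)
    scz_log_or: float = math.log(1.75)
    bmi_effects: dict = field(default_factory=lambda: dict(DEFAULT_BMI_EFFECTS))
    endpoints: dict = field(default_factory=lambda: dict(DEFAULT_ENDPOINT_TRUTH))
    dispensing: dict = field(default_factory=lambda: dict(DEFAULT_DISPENSING))
    onset_age_mean: float = 27.0
    onset_age_sd: float = 6.9
    # BMI visit process: most persons have few measurements; a minority of
    # frequent attenders have many, giving the heavy-tailed utilisation of
    # registry data (median stays ~3 obs, ~330-day median spacing)
    bmi_obs_poisson_mean: float = 1.8  # n_obs = 1 + Poisson(mean)
    bmi_frequent_fraction: float = 0.15
    bmi_obs_poisson_mean_frequent: float = 10.0
    bmi_gap_median_days: float = 330.0
    bmi_gap_sigma: float = 1.0
    smoking_ever_case: float = 0.603
    smoking_ever_control: float = 0.455
    smoking_missing: float = 0.07
    death_prob_case: float = 0.0192
    death_prob_control: float = 0.0018
    seed: int = 0

    def validate(self) -> None:
        r = np.asarray(self.prs_correlation, float)
        if r.shape != (len(PRS_TRAITS),) * 2 or not np.allclose(r, r.T):
            raise ConfigError("prs_correlation must be a symmetric 15x15 matrix")
        if not np.allclose(np.diag(r), 1.0):
            raise ConfigError("prs_correlation must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ConfigError("prs_correlation is not positive semidefinite")
        for p in (self.fraction_female, self.dispensing["treated_fraction"],
                  self.dispensing["discontinuation_prob"]):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Named substream so adding a stage never perturbs earlier draws."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


_STREAMS = {"persons": 0, "prs": 1, "dispensing": 2, "outcomes": 3,
            "measurements": 4, "smoking": 5}


def _truncnorm(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def simulate_dispensing(onset_day: int, followup_day: int, process: dict,
                        cpz: dict[str, float],
                        rng: np.random.Generator,
                        immediate: bool = False) -> list[dict]:
    """One case's purchase history (possibly empty is handled by caller).

    First purchase shortly after onset; inter-purchase gaps equal
    ``days_supplied / adherence`` with multiplicative log-normal noise; with
    the configured probability a forced discontinuation truncates the
    sequence more than a year before end of follow-up.
    """
    delay = 0 if immediate else int(rng.integers(0, process["first_purchase_delay_days"] + 1))
    first = onset_day + delay
    if first >= followup_day:
        return []
    a, b = process["adherence_beta"]
    adherence = float(rng.beta(a, b))
    adherence = max(adherence, 0.05)
    supplies, weights = process["supply_days"]
    drugs = list(DRUG_WEIGHTS)
    dw = np.array([DRUG_WEIGHTS[d] for d in drugs])
    dw = dw / dw.sum()
    drug = str(rng.choice(drugs, p=dw))
    cpz_target = float(rng.lognormal(math.log(process["cpz_median_mg"]),
                                     process["cpz_sigma"]))
    doses: dict[str, float] = {}

    if rng.random() < process["discontinuation_prob"]:
        stop = first + process["disc_median_years"] * DAYS_PER_YEAR * \
            float(rng.lognormal(0.0, process["disc_sigma"]))
        stop = min(stop, followup_day - 420)
        stop = max(stop, first + 1)
    else:
        stop = followup_day

    out: list[dict] = []
    t = float(first)
    while t < stop:
        if drug not in doses:
            doses[drug] = cpz_target * float(rng.lognormal(0.0, 0.15)) / cpz[drug]
        supply = int(rng.choice(supplies, p=weights))
        out.append({"purchase_day": int(round(t)), "drug_name": drug,
                    "atc_code": ATC_BY_DRUG[drug],
                    "daily_dose_mg": round(doses[drug], 2),
                    "days_supplied": supply})
        if rng.random() < process["switch_prob"]:
            drug = str(rng.choice(drugs, p=dw))
        gap = supply / adherence * float(rng.lognormal(0.0, process["gap_lognorm_sigma"]))
        t += max(gap, 1.0)
    return out


def _tx_quartic(tx: np.ndarray, eff: dict) -> np.ndarray:
    tx = np.asarray(tx, float)
    return (eff["tx1"] * tx + eff["tx2"] * tx ** 2
            + eff["tx3"] * tx ** 3 + eff["tx4"] * tx ** 4)


def bmi_mean(eff: dict, male, smoking, bmi_prs, age_c, case, tx_years) -> np.ndarray:
    """Population-level BMI mean of the generating trajectory model."""
    return (eff["intercept"] + eff["male"] * np.asarray(male, float)
            + eff["smoking"] * np.asarray(smoking, float)
            + eff["bmi_prs"] * np.asarray(bmi_prs, float)
            + eff["age"] * np.asarray(age_c, float)
            + eff["case"] * np.asarray(case, float)
            + eff["case_age"] * np.asarray(case, float) * np.asarray(age_c, float)
            + _tx_quartic(np.asarray(tx_years, float), eff))


@dataclass
class SyntheticCohort:
    """Generated tables plus the latent truth used to generate them."""

    tables: Tables
    truth: pd.DataFrame
    config: GeneratorConfig


def simulate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate the full synthetic extract (persons, dispensing, diagnoses,
    measurements, PRS) plus a per-person truth table."""
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    n_cases = cfg.n_cases
    n_pool = int(round(n_cases * cfg.controls_per_case * cfg.pool_factor))
    n_total = n_cases + n_pool
    cpz = expo.load_cpz_table()

    rng_p = _rng(cfg.seed, _STREAMS["persons"])
    rng_prs = _rng(cfg.seed, _STREAMS["prs"])
    rng_d = _rng(cfg.seed, _STREAMS["dispensing"])
    rng_o = _rng(cfg.seed, _STREAMS["outcomes"])
    rng_m = _rng(cfg.seed, _STREAMS["measurements"])
    rng_s = _rng(cfg.seed, _STREAMS["smoking"])

    # ---- cases: onset, sex, birth, death -------------------------------
    n_female = int(round(cfg.fraction_female * n_cases))
    case_sex = np.array(["female"] * n_female + ["male"] * (n_cases - n_female))
    rng_p.shuffle(case_sex)
    onset_age = _truncnorm(rng_p, cfg.onset_age_mean, cfg.onset_age_sd,
                           15.0, 40.0, n_cases)
    w0, w1 = ONSET_WINDOW
    onset_day = rng_p.integers(w0.toordinal(), w1.toordinal(), n_cases)
    birth_day = onset_day - np.round(onset_age * DAYS_PER_YEAR).astype(int)
    freeze = FREEZE_DATE.toordinal()
    death_day = np.full(n_total, -1, dtype=int)
    dies = rng_p.random(n_cases) < cfg.death_prob_case
    for i in np.where(dies)[0]:
        death_day[i] = int(rng_p.integers(onset_day[i] + 30, freeze))

    # ---- control pool: perturbed copies of random cases ----------------
    src = rng_p.integers(0, n_cases, n_pool) if n_cases else np.array([], int)
    jitter_y = rng_p.choice([-1, 0, 1], size=n_pool, p=[0.25, 0.5, 0.25])
    pool_birth = (birth_day[src] + jitter_y * 365
                  + rng_p.integers(-120, 121, n_pool)) if n_pool else np.array([], int)
    pool_sex = case_sex[src] if n_pool else np.array([], dtype=object)
    pool_index = (onset_day[src] + rng_p.integers(-180, 181, n_pool)) if n_pool \
        else np.array([], int)
    dies_c = rng_p.random(n_pool) < cfg.death_prob_control
    for j in np.where(dies_c)[0]:
        death_day[n_cases + j] = int(rng_p.integers(pool_index[j] + 30, freeze))

    ids = np.array([f"C{i:06d}" for i in range(1, n_cases + 1)]
                   + [f"P{j:06d}" for j in range(1, n_pool + 1)])
    is_case = np.r_[np.ones(n_cases, bool), np.zeros(n_pool, bool)]
    all_birth = np.r_[birth_day, pool_birth].astype(int) if n_total else np.array([], int)
    all_sex = np.r_[case_sex, pool_sex]
    all_index = np.r_[onset_day, pool_index].astype(int) if n_total else np.array([], int)
    followup = np.where(death_day > 0, death_day, freeze)

    persons = pd.DataFrame({
        "person_id": ids,
        "sex": all_sex,
        "birth_date": [pd.Timestamp.fromordinal(int(d)) for d in all_birth],
        "death_date": [pd.Timestamp.fromordinal(int(d)) if d > 0 else pd.NaT
                       for d in death_day],
        "followup_end": [pd.Timestamp.fromordinal(int(d)) for d in followup],
    })

    # ---- PRS: correlated scores; cases shifted along delta * R[:, SCZ] --
    r = np.asarray(cfg.prs_correlation, float)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(len(PRS_TRAITS)))
    z = rng_prs.standard_normal((n_total, len(PRS_TRAITS))) @ chol.T
    shift = cfg.scz_log_or * r[:, list(PRS_TRAITS).index("SCZ")]
    z[is_case] += shift
    pcs = rng_prs.standard_normal((n_total, len(PC_COLUMNS)))
    prs = pd.DataFrame(z, columns=list(PRS_TRAITS))
    prs.insert(0, "person_id", ids)
    for j, c in enumerate(PC_COLUMNS):
        prs[c] = pcs[:, j]

    # ---- dispensing (cases only) ----------------------------------------
    disp_rows: list[dict] = []
    treated = np.zeros(n_total, bool)
    onset_src = np.array([""] * n_total, dtype=object)
    for i in range(n_cases):
        t = rng_d.random() < cfg.dispensing["treated_fraction"]
        treated[i] = t
        src_rx = t and (rng_d.random() < 0.5)
        onset_src[i] = "prescription" if src_rx else "diagnosis"
        if t:
            hist = simulate_dispensing(int(onset_day[i]), int(followup[i]),
                                       cfg.dispensing, cpz, rng_d,
                                       immediate=src_rx)
            if not hist:
                treated[i] = False
                onset_src[i] = "diagnosis"
            for h in hist:
                disp_rows.append({"person_id": ids[i],
                                  "purchase_date": pd.Timestamp.fromordinal(h["purchase_day"]),
                                  "atc_code": h["atc_code"],
                                  "drug_name": h["drug_name"],
                                  "daily_dose_mg": h["daily_dose_mg"],
                                  "days_supplied": h["days_supplied"]})
        else:
            onset_src[i] = "diagnosis"
    dispensing = pd.DataFrame(
        disp_rows, columns=["person_id", "purchase_date", "atc_code",
                            "drug_name", "daily_dose_mg", "days_supplied"])

    # ---- diagnoses: SSD onset rows + metabolic endpoints ----------------
    diag_rows: list[dict] = []
    for i in range(n_cases):
        if onset_src[i] == "diagnosis":
            diag_rows.append({"person_id": ids[i],
                              "event_date": pd.Timestamp.fromordinal(int(onset_day[i])),
                              "icd10": "F20"})
        elif rng_o.random() < 0.9:  # prescription-first cases usually get a
            lag = int(rng_o.integers(0, 181))  # diagnosis code soon after
            d = min(int(onset_day[i]) + lag, int(followup[i]))
            diag_rows.append({"person_id": ids[i],
                              "event_date": pd.Timestamp.fromordinal(d),
                              "icd10": "F20"})

    trait_idx = {t: j for j, t in enumerate(PRS_TRAITS)}
    event_age: dict[str, np.ndarray] = {}
    for name, (code, h0, hr, prs_fx) in cfg.endpoints.items():
        lin = np.log(hr) * is_case.astype(float)
        for trait, beta in prs_fx.items():
            lin = lin + beta * z[:, trait_idx[trait]]
        rate = h0 * np.exp(lin)
        t_years = rng_o.exponential(1.0 / rate)
        age_evt = 15.0 + t_years  # constant hazard from age 15 (memoryless)
        event_age[name] = age_evt
        evt_day = all_birth + np.round(age_evt * DAYS_PER_YEAR).astype(int)
        for i in np.where(evt_day <= followup)[0]:
            diag_rows.append({"person_id": ids[i],
                              "event_date": pd.Timestamp.fromordinal(int(evt_day[i])),
                              "icd10": code})
    diagnoses = pd.DataFrame(
        diag_rows, columns=["person_id", "event_date", "icd10"])

    # ---- smoking ---------------------------------------------------------
    meas_rows: list[dict] = []
    smoke_ever = np.where(is_case,
                          rng_s.random(n_total) < cfg.smoking_ever_case,
                          rng_s.random(n_total) < cfg.smoking_ever_control)
    smoke_missing = rng_s.random(n_total) < cfg.smoking_missing
    for i in range(n_total):
        if smoke_missing[i]:
            continue
        d = min(all_index[i] + int(rng_s.integers(0, int(3.7 * 2 * 365))),
                int(followup[i]))
        meas_rows.append({"person_id": ids[i],
                          "measure_date": pd.Timestamp.fromordinal(d),
                          "kind": "smoking",
                          "value": "ever" if smoke_ever[i] else "never"})

    # ---- BMI panel from the trajectory truth -----------------------------
    eff = cfg.bmi_effects
    u = rng_m.normal(0.0, eff["sd_intercept"], n_total)
    v = rng_m.normal(0.0, eff["sd_slope"], n_total)
    bmi_prs = z[:, trait_idx["BMI"]]
    male = (all_sex == "male").astype(float)
    timelines: dict[str, expo.SupplyTimeline] = {}
    if len(dispensing):
        for pid, g in dispensing.groupby("person_id"):
            i = int(np.where(ids == pid)[0][0])
            timelines[pid] = expo.build_timeline(
                g, pd.Timestamp.fromordinal(int(followup[i])), stockpile=True)
    frequent = rng_m.random(n_total) < cfg.bmi_frequent_fraction
    n_obs_all = 1 + np.where(
        frequent,
        rng_m.poisson(cfg.bmi_obs_poisson_mean_frequent, n_total),
        rng_m.poisson(cfg.bmi_obs_poisson_mean, n_total))
    for i in range(n_total):
        t = all_index[i] + float(rng_m.integers(0, 721))
        tl = timelines.get(ids[i])
        for _ in range(int(n_obs_all[i])):
            if t > followup[i]:
                break
            day = int(round(t))
            age_c = (day - all_birth[i]) / DAYS_PER_YEAR - 27.0
            tx = (tl.covered_in(tl.first_purchase, day) / DAYS_PER_YEAR
                  if tl is not None else 0.0)
            mean = bmi_mean(eff, male[i], float(smoke_ever[i]), bmi_prs[i],
                            age_c, float(is_case[i]), tx)
            val = mean + u[i] + v[i] * age_c + rng_m.normal(0.0, eff["sd_resid"])
            val = float(np.clip(val, 12.0, 75.0))
            meas_rows.append({"person_id": ids[i],
                              "measure_date": pd.Timestamp.fromordinal(day),
                              "kind": "bmi", "value": round(val, 1)})
            t += cfg.bmi_gap_median_days * float(rng_m.lognormal(0.0, cfg.bmi_gap_sigma))
    measurements = pd.DataFrame(
        meas_rows, columns=["person_id", "measure_date", "kind", "value"])

    truth = pd.DataFrame({
        "person_id": ids,
        "is_case": is_case,
        "treated": treated,
        "onset_source": onset_src,
        "latent_index": [pd.Timestamp.fromordinal(int(d)) for d in all_index],
        "rand_intercept": u,
        "rand_slope": v,
        "smoking_ever": smoke_ever,
        "smoking_missing": smoke_missing,
        **{f"event_age_{n}": event_age[n] for n in cfg.endpoints},
    })

    tables = Tables(persons=persons, dispensing=dispensing,
                    diagnoses=diagnoses, measurements=measurements, prs=prs)
    return SyntheticCohort(tables=tables, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# focused simulators for parameter-recovery experiments


def simulate_survival_records(n_cases: int = 677, n_controls: int = 2708,
                              true_hr: float = 1.95,
                              baseline_rate: float = 0.012,
                              censor_years: tuple[float, float] = (2.0, 16.0),
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Exponential proportional-hazards time-to-event records for a matched
    cohort: event time ``~ Exp(h0·HR^case)`` with uniform administrative
    censoring, the design used for Cox recovery checks."""
    rng = rng or np.random.default_rng()
    n = n_cases + n_controls
    case = np.r_[np.ones(n_cases), np.zeros(n_controls)]
    rate = baseline_rate * np.power(true_hr, case)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(*censor_years, n)
    time = np.minimum(t_event, t_cens)
    return pd.DataFrame({"time": time, "event": (t_event <= t_cens).astype(int),
                         "case": case.astype(int)})


def simulate_prs_case_control(n_cases: int = 677, n_controls: int = 2708,
                              log_or: float = math.log(1.75),
                              prs_correlation: pd.DataFrame | None = None,
                              rng: np.random.Generator | None = None
                              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Correlated PRS table plus case indicator, with case status tied to
    the SCZ score at the configured log-odds-ratio (mean-shift construction,
    exact for unit-variance normal scores)."""
    rng = rng or np.random.default_rng()
    r = np.asarray(prs_correlation if prs_correlation is not None
                   else default_prs_correlation(), float)
    n = n_cases + n_controls
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(len(PRS_TRAITS)))
    z = rng.standard_normal((n, len(PRS_TRAITS))) @ chol.T
    case = np.r_[np.ones(n_cases), np.zeros(n_controls)].astype(int)
    z[case == 1] += log_or * r[:, list(PRS_TRAITS).index("SCZ")]
    prs = pd.DataFrame(z, columns=list(PRS_TRAITS))
    prs["person_id"] = [f"S{i:06d}" for i in range(n)]
    for j, c in enumerate(PC_COLUMNS):
        prs[c] = rng.standard_normal(n)
    return prs, case
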
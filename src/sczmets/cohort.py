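"""Case identification and matched-control selection.

A schizophrenia-spectrum (SSD) case is a person whose first qualifying
event — either a first antipsychotic dispensing (ATC ``N05A*``, lithium
excluded upstream) or a first SSD diagnosis (ICD-10 F20–F29) — falls at age
15–40 and strictly after a configurable buffer year (default 2006, i.e. two
years after the start of electronic registry coverage).

Each case then receives ``k`` controls (default 4) drawn without
replacement from a candidate pool purged of anyone with any mental or
behavioural disorder (ICD-10 ``F*``) or any antipsychotic dispensing,
matched exactly on sex and by greedy nearest neighbour on birth year.
Controls inherit their case's onset date as the index date used as the
time origin of the survival analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DAYS_PER_YEAR

SSD_PREFIXES = tuple(f"F2{i}" for i in range(10))  # F20..F29


def _age_years(birth, when) -> float:
    return (pd.Timestamp(when).toordinal() - pd.Timestamp(birth).toordinal()) / DAYS_PER_YEAR


def identify_cases(persons: pd.DataFrame, dispensing: pd.DataFrame,
                   diagnoses: pd.DataFrame,
                   min_age: float = 15.0, max_age: float = 40.0,
                   min_year: int = 2006) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Identify SSD cases by the earliest qualifying event.

    Returns ``(cases, exclusions)``.  ``cases`` has one row per qualifying
    person with onset date/source, age at onset and first purchase date;
    ``exclusions`` lists persons with a qualifying event falling outside the
    age window (``age_window``) or on/before the buffer year
    (``year_window``), with the earlier reason winning when both apply.
    """
    first_rx = (dispensing.groupby("person_id")["purchase_date"].min()
                if len(dispensing) else pd.Series(dtype="datetime64[ns]"))
    ssd = diagnoses[diagnoses["icd10"].astype(str).str.startswith(SSD_PREFIXES)]
    first_dx = (ssd.groupby("person_id")["event_date"].min()
                if len(ssd) else pd.Series(dtype="datetime64[ns]"))

    cases, excl = [], []
    for _, p in persons.iterrows():
        pid = p["person_id"]
        rx = first_rx.get(pid, pd.NaT)
        dx = first_dx.get(pid, pd.NaT)
        if pd.isna(rx) and pd.isna(dx):
            continue
        if pd.isna(dx) or (not pd.isna(rx) and rx <= dx):
            onset, source = rx, "prescription"
        else:
            onset, source = dx, "diagnosis"
        age = _age_years(p["birth_date"], onset)
        if not (min_age <= age <= max_age):
            excl.append({"person_id": pid, "reason": "age_window",
                         "onset_date": onset, "age_at_onset": age})
            continue
        if onset.year <= min_year:
            excl.append({"person_id": pid, "reason": "year_window",
                         "onset_date": onset, "age_at_onset": age})
            continue
        cases.append({"person_id": pid, "onset_date": onset,
                      "onset_source": source, "age_at_onset": age,
                      "first_purchase_date": rx if not pd.isna(rx) else pd.NaT,
                      "sex": p["sex"], "birth_year": p["birth_date"].year})
    case_cols = ["person_id", "onset_date", "onset_source", "age_at_onset",
                 "first_purchase_date", "sex", "birth_year"]
    excl_cols = ["person_id", "reason", "onset_date", "age_at_onset"]
    return (pd.DataFrame(cases, columns=case_cols),
            pd.DataFrame(excl, columns=excl_cols))


def eligible_controls(persons: pd.DataFrame, diagnoses: pd.DataFrame,
                      dispensing: pd.DataFrame,
                      case_ids: set[str] | None = None) -> pd.DataFrame:
    """Candidate pool: persons with no F* diagnosis ever, no antipsychotic
    dispensing ever, and not themselves cases."""
    f_any = set(diagnoses.loc[diagnoses["icd10"].astype(str).str.startswith("F"),
                              "person_id"]) if len(diagnoses) else set()
    rx_any = set(dispensing["person_id"]) if len(dispensing) else set()
    bad = f_any | rx_any | (case_ids or set())
    pool = persons[~persons["person_id"].isin(bad)].copy()
    pool["birth_year"] = pool["birth_date"].dt.year
    return pool


class PoolExhaustedError(RuntimeError):
    """Raised when some case cannot receive its full complement of controls."""

    def __init__(self, shortfalls: dict[str, int]):
        self.shortfalls = shortfalls
        msg = "; ".join(f"case {c}: {k} control(s) short"
                        for c, k in shortfalls.items())
        super().__init__(f"control pool exhausted — {msg}")


@dataclass
class MatchedCohort:
    """Case → controls mapping with index dates (case onset, inherited)."""

    pairs: pd.DataFrame  # case_id, control_id, birth_year_distance, index_date
    k: int

    @property
    def case_ids(self) -> list[str]:
        return list(dict.fromkeys(self.pairs["case_id"]))

    @property
    def control_ids(self) -> list[str]:
        return list(self.pairs["control_id"])

    def index_dates(self) -> pd.Series:
        """index_date per person (cases and controls)."""
        ctrl = self.pairs.set_index("control_id")["index_date"]
        case = self.pairs.drop_duplicates("case_id").set_index("case_id")["index_date"]
        return pd.concat([case, ctrl])

    def total_distance(self) -> int:
        return int(self.pairs["birth_year_distance"].sum())


def match_controls(cases: pd.DataFrame, candidates: pd.DataFrame,
                   k: int = 4, seed: int = 0) -> MatchedCohort:
    """Greedy nearest-neighbour matching without replacement.

    Exact on sex, nearest on |birth-year difference|.  Cases are processed
    in order of ascending exact-year candidate availability (scarcest
    first), then person_id; candidate ties at equal distance are broken by a
    seeded shuffle fixed once at pool construction.  Raises
    :class:`PoolExhaustedError` when any case cannot be given ``k`` controls.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    # tie-break rank: a seeded shuffle fixed once at pool construction
    perm = np.random.default_rng(seed).permutation(len(candidates))
    rank = {pid: int(r) for pid, r in zip(candidates["person_id"], perm)}

    # per (sex, birth_year) buckets ordered by tie-break rank; consumed from
    # the front
    buckets: dict[str, dict[int, list[tuple[int, str]]]] = {}
    span: dict[str, tuple[int, int]] = {}
    for s, g in candidates.groupby("sex"):
        by_year: dict[int, list[tuple[int, str]]] = {}
        for y, pid in zip(g["birth_year"].astype(int), g["person_id"]):
            by_year.setdefault(y, []).append((rank[pid], pid))
        for lst in by_year.values():
            lst.sort()
        buckets[s] = by_year
        span[s] = (min(by_year), max(by_year))
    heads: dict[str, dict[int, int]] = {s: {y: 0 for y in b}
                                        for s, b in buckets.items()}

    def take_nearest(sex: str, year: int):
        """Nearest unused candidate of this sex; distance ties across the
        two equidistant years broken by rank."""
        if sex not in buckets:
            return None
        lo, hi = span[sex]
        for d in range(0, max(year - lo, hi - year) + 1):
            best = None
            for y in ({year} if d == 0 else {year - d, year + d}):
                b = buckets[sex].get(y)
                if b is None:
                    continue
                h = heads[sex][y]
                if h < len(b) and (best is None or b[h] < best[0]):
                    best = (b[h], y)
            if best is not None:
                (r, pid), y = best
                heads[sex][y] += 1
                return d, pid
        return None

    # scarcity: cases with the fewest exact-birth-year candidates match first
    def scarcity(row) -> int:
        b = buckets.get(row["sex"], {})
        return len(b.get(int(row["birth_year"]), []))

    case_order = cases.assign(_scar=cases.apply(scarcity, axis=1)) \
        .sort_values(["_scar", "person_id"], kind="stable")

    # k round-robin passes: every case receives its nearest available
    # candidate once per pass (ratio-matching order)
    pairs = []
    shortfalls: dict[str, int] = {}
    for _pass in range(k):
        for _, c in case_order.iterrows():
            got = take_nearest(c["sex"], int(c["birth_year"]))
            if got is None:
                shortfalls[c["person_id"]] = \
                    shortfalls.get(c["person_id"], 0) + 1
                continue
            dist, pid = got
            pairs.append({"case_id": c["person_id"], "control_id": pid,
                          "birth_year_distance": dist,
                          "index_date": c["onset_date"]})
    if shortfalls:
        raise PoolExhaustedError(shortfalls)
    pairs_df = pd.DataFrame(
        pairs, columns=["case_id", "control_id", "birth_year_distance",
                        "index_date"])
    # restore the caller's case order for readability
    pos = {pid: i for i, pid in enumerate(cases["person_id"])}
    pairs_df = pairs_df.sort_values("case_id", key=lambda s: s.map(pos),
                                    kind="stable").reset_index(drop=True)
    return MatchedCohort(pairs=pairs_df, k=k)


def optimal_total_distance(cases: pd.DataFrame, candidates: pd.DataFrame,
                           k: int = 4) -> int:
    """Minimal achievable total |birth-year| distance for the same matching
    problem, via an optimal assignment (each case contributes ``k`` slots).

    Serves as the independent benchmark for the greedy matcher; greedy
    nearest-neighbour can exceed this optimum on adversarial pools.
    """
    from scipy.optimize import linear_sum_assignment

    total = 0
    for sex, cg in cases.groupby("sex"):
        cand = candidates[candidates["sex"] == sex]
        if len(cand) < k * len(cg):
            raise PoolExhaustedError({str(c): k for c in cg["person_id"]})
        cy = np.repeat(cg["birth_year"].to_numpy(int), k)
        ky = cand["birth_year"].to_numpy(int)
        cost = np.abs(cy[:, None] - ky[None, :])
        r, col = linear_sum_assignment(cost)
        total += int(cost[r, col].sum())
    return total
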
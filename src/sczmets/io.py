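"""Longitudinal data model: canonical schemas, validation, and CSV/TSV I/O.

The pipeline consumes five person-level tables drawn from a registry-style
biobank extract:

* ``persons`` — one row per participant (sex, birth date, death date,
  administrative end of follow-up).
* ``dispensing`` — drug-dispensing (pharmacy claims) rows for antipsychotics
  (ATC ``N05A*``, lithium excluded), with the dispensed agent, its daily dose
  in mg and the number of days supplied.
* ``diagnoses`` — dated ICD-10 diagnosis events.
* ``measurements`` — dated BMI values plus an ever/never smoking indicator.
* ``prs`` — per-person standardized polygenic scores for schizophrenia and
  14 metabolic-syndrome traits, plus 10 genotype principal components.

All tables are plain comma- or tab-separated files with a header and
ISO-8601 (``YYYY-MM-DD``) dates.  Validation is total: every input row is
either accepted into the typed collection or lands in a rejection report
with a reason code; the two counts always sum to the input size.

Conventions used throughout the package:

* day arithmetic uses half-open intervals ``[start, end)`` in whole days;
* "years" always means days / 365.25.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DAYS_PER_YEAR = 365.25

#: the 20 antipsychotic agents recognised by the pipeline
ANTIPSYCHOTICS = (
    "quetiapine", "olanzapine", "aripiprazole", "clozapine", "risperidone",
    "haloperidol", "amisulpride", "sertindole", "flupentixol", "perphenazine",
    "ziprasidone", "levomepromazine", "zuclopenthixol", "chlorprothixene",
    "sulpiride", "cariprazine", "melperone", "chlorpromazine", "fluphenazine",
    "paliperidone",
)

#: antipsychotics with the strongest metabolic side-effect profile
METABOLICALLY_ACTIVE = frozenset({"olanzapine", "clozapine", "quetiapine"})

#: the 15 polygenic-score traits, in canonical order
PRS_TRAITS = (
    "SCZ", "CHD", "TC", "LDL", "HDL", "nonHDL", "TG", "CRP",
    "HbA1c", "FG", "RG", "T2D", "BMI", "SBP", "DBP",
)
PC_COLUMNS = tuple(f"PC{i}" for i in range(1, 11))

ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]+)?$")
LITHIUM_ATC_PREFIX = "N05AN"

TABLE_NAMES = ("persons", "dispensing", "diagnoses", "measurements", "prs")

# canonical column sets; a schema_config may rename user columns onto these
CANONICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "persons": ("person_id", "sex", "birth_date", "death_date", "followup_end"),
    "dispensing": ("person_id", "purchase_date", "atc_code", "drug_name",
                   "daily_dose_mg", "days_supplied"),
    "diagnoses": ("person_id", "event_date", "icd10"),
    "measurements": ("person_id", "measure_date", "kind", "value"),
    "prs": ("person_id",) + PRS_TRAITS + PC_COLUMNS,
}

DATE_COLUMNS: dict[str, tuple[str, ...]] = {
    "persons": ("birth_date", "death_date", "followup_end"),
    "dispensing": ("purchase_date",),
    "diagnoses": ("event_date",),
    "measurements": ("measure_date",),
    "prs": (),
}


class SchemaError(ValueError):
    """A table is missing required columns or is otherwise unusable."""


@dataclass
class Tables:
    """The five validated canonical tables plus per-table rejection reports.

    ``rejects[name]`` is a DataFrame with the offending rows, the 1-based
    input ``line`` number and a ``reason`` code, so that
    ``len(table) + len(rejects) == rows read``.
    """

    persons: pd.DataFrame
    dispensing: pd.DataFrame
    diagnoses: pd.DataFrame
    measurements: pd.DataFrame
    prs: pd.DataFrame
    rejects: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __getitem__(self, name: str) -> pd.DataFrame:
        if name not in TABLE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _empty(table: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_COLUMNS[table]})
    for c in DATE_COLUMNS[table]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


def _reject_frame(df: pd.DataFrame, mask: pd.Series, reason: str,
                  sink: list[pd.DataFrame]) -> pd.DataFrame:
    """Move rows where ``mask`` holds into the rejection sink."""
    if mask.any():
        bad = df.loc[mask].copy()
        bad["reason"] = reason
        sink.append(bad)
    return df.loc[~mask]


def _parse_dates(df: pd.DataFrame, cols: tuple[str, ...], optional: tuple[str, ...],
                 sink: list[pd.DataFrame]) -> pd.DataFrame:
    for c in cols:
        raw = df[c].astype(object)
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        if c in optional:
            bad = parsed.isna() & ~blank
        else:
            bad = parsed.isna()
        df = df.assign(**{c: parsed})
        df = _reject_frame(df, bad, f"unparseable_date:{c}", sink)
    return df


def validate_persons(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    sink: list[pd.DataFrame] = []
    df = df.copy()
    df["line"] = range(2, len(df) + 2)  # 1-based, after header
    df = _parse_dates(df, DATE_COLUMNS["persons"], optional=("death_date",), sink=sink)
    df = _reject_frame(df, df["person_id"].isna(), "missing_person_id", sink)
    df = _reject_frame(df, ~df["sex"].isin(["female", "male"]), "bad_sex", sink)
    df = _reject_frame(df, ~(df["birth_date"] < df["followup_end"]),
                       "birth_after_followup", sink)
    dead = df["death_date"].notna()
    df = _reject_frame(df, dead & (df["death_date"] > df["followup_end"]),
                       "death_after_followup", sink)
    df = _reject_frame(df, df["person_id"].duplicated(keep="first"),
                       "duplicate_person", sink)
    rejects = pd.concat(sink, ignore_index=True) if sink else pd.DataFrame()
    return df.reset_index(drop=True), rejects


def validate_dispensing(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    sink: list[pd.DataFrame] = []
    df = df.copy()
    df["line"] = range(2, len(df) + 2)
    df = _parse_dates(df, DATE_COLUMNS["dispensing"], optional=(), sink=sink)
    df = _reject_frame(df, df["person_id"].isna(), "missing_person_id", sink)
    atc = df["atc_code"].astype(str)
    df = _reject_frame(df, ~atc.str.startswith("N05A"), "not_antipsychotic_atc", sink)
    df = _reject_frame(df, df["atc_code"].astype(str).str.startswith(LITHIUM_ATC_PREFIX),
                       "lithium_excluded", sink)
    df = _reject_frame(df, ~df["drug_name"].isin(ANTIPSYCHOTICS), "unknown_drug", sink)
    dose = pd.to_numeric(df["daily_dose_mg"], errors="coerce")
    df = df.assign(daily_dose_mg=dose)
    df = _reject_frame(df, ~(dose > 0), "non-positive dose", sink)
    supply = pd.to_numeric(df["days_supplied"], errors="coerce")
    df = df.assign(days_supplied=supply)
    df = _reject_frame(df, ~((supply > 0) & (supply == supply.round())),
                       "non-positive supply", sink)
    df = df.assign(days_supplied=df["days_supplied"].astype(int))
    rejects = pd.concat(sink, ignore_index=True) if sink else pd.DataFrame()
    return df.reset_index(drop=True), rejects


def validate_diagnoses(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    sink: list[pd.DataFrame] = []
    df = df.copy()
    df["line"] = range(2, len(df) + 2)
    df = _parse_dates(df, DATE_COLUMNS["diagnoses"], optional=(), sink=sink)
    df = _reject_frame(df, df["person_id"].isna(), "missing_person_id", sink)
    ok = df["icd10"].astype(str).str.match(ICD10_RE)
    df = _reject_frame(df, ~ok, "bad_icd10", sink)
    rejects = pd.concat(sink, ignore_index=True) if sink else pd.DataFrame()
    return df.reset_index(drop=True), rejects


def validate_measurements(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    sink: list[pd.DataFrame] = []
    df = df.copy()
    df["line"] = range(2, len(df) + 2)
    df = _parse_dates(df, DATE_COLUMNS["measurements"], optional=(), sink=sink)
    df = _reject_frame(df, df["person_id"].isna(), "missing_person_id", sink)
    df = _reject_frame(df, ~df["kind"].isin(["bmi", "smoking"]), "bad_kind", sink)
    is_bmi = df["kind"] == "bmi"
    bmi_val = pd.to_numeric(df["value"], errors="coerce")
    df = _reject_frame(df, is_bmi & ~((bmi_val > 10) & (bmi_val < 80)),
                       "bmi_out_of_range", sink)
    is_smoke = df["kind"] == "smoking"
    df = _reject_frame(df, is_smoke & ~df["value"].isin(["ever", "never"]),
                       "bad_smoking_value", sink)
    rejects = pd.concat(sink, ignore_index=True) if sink else pd.DataFrame()
    return df.reset_index(drop=True), rejects


def validate_prs(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    sink: list[pd.DataFrame] = []
    df = df.copy()
    df["line"] = range(2, len(df) + 2)
    df = _reject_frame(df, df["person_id"].isna(), "missing_person_id", sink)
    num_cols = list(PRS_TRAITS + PC_COLUMNS)
    for c in num_cols:
        df = df.assign(**{c: pd.to_numeric(df[c], errors="coerce")})
    bad = df[num_cols].isna().any(axis=1)
    df = _reject_frame(df, bad, "missing_score", sink)
    df = _reject_frame(df, df["person_id"].duplicated(keep="first"),
                       "duplicate_person", sink)
    rejects = pd.concat(sink, ignore_index=True) if sink else pd.DataFrame()
    return df.reset_index(drop=True), rejects


_VALIDATORS = {
    "persons": validate_persons,
    "dispensing": validate_dispensing,
    "diagnoses": validate_diagnoses,
    "measurements": validate_measurements,
    "prs": validate_prs,
}


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_table(path: str | Path, table: str,
               column_map: dict[str, str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read, rename (via ``column_map``: user name → canonical name) and
    validate one table.  Returns ``(accepted, rejects)``."""
    path = Path(path)
    if table not in TABLE_NAMES:
        raise SchemaError(f"unknown table {table!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=object,
                     keep_default_na=True, na_values=[""])
    if column_map:
        df = df.rename(columns=column_map)
    required = [c for c in CANONICAL_COLUMNS[table] if c != "death_date"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r}: missing required column(s) "
                          + ", ".join(missing))
    if table == "persons" and "death_date" not in df.columns:
        df["death_date"] = pd.NA
    if df.empty:
        return _empty(table), pd.DataFrame()
    return _VALIDATORS[table](df[list(CANONICAL_COLUMNS[table])].copy())


def read_tables(paths: dict[str, str | Path],
                schema_config: dict[str, dict[str, str]] | None = None) -> Tables:
    """Read every canonical table named in ``paths`` and validate it.

    ``schema_config`` optionally maps, per table, user column names to the
    canonical names.  Tables absent from ``paths`` come back empty.
    """
    frames: dict[str, pd.DataFrame] = {}
    rejects: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        if name in paths:
            cmap = (schema_config or {}).get(name)
            frames[name], rejects[name] = read_table(paths[name], name, cmap)
        else:
            frames[name], rejects[name] = _empty(name), pd.DataFrame()
    return Tables(**frames, rejects=rejects)


def write_table(df: pd.DataFrame, path: str | Path, table: str | None = None) -> Path:
    """Write a table as TSV with ISO dates; round-trip stable with
    :func:`read_table` for canonical tables."""
    path = Path(path)
    out = df.copy()
    out = out.drop(columns=[c for c in ("line",) if c in out.columns])
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out.to_csv(path, sep=sep, index=False)
    return path


def write_tables(tables: Tables, outdir: str | Path) -> dict[str, Path]:
    """Write all five tables (TSV) plus rejection reports into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in TABLE_NAMES:
        written[name] = write_table(tables[name], outdir / f"{name}.tsv", name)
        rej = tables.rejects.get(name)
        if rej is not None and len(rej):
            write_table(rej, outdir / f"{name}.rejects.tsv")
    return written


def smoking_ever_never(measurements: pd.DataFrame) -> pd.Series:
    """Reduce smoking measurements to one ever/never status per person.

    Any recorded "ever" wins over any number of "never" records.  Returns a
    Series indexed by person_id with values "ever"/"never"; persons without
    any smoking record are absent.
    """
    smoke = measurements[measurements["kind"] == "smoking"]
    if smoke.empty:
        return pd.Series(dtype=object)
    ever = smoke.groupby("person_id")["value"].apply(lambda v: (v == "ever").any())
    return ever.map({True: "ever", False: "never"})


def median_bmi(measurements: pd.DataFrame) -> pd.Series:
    """Per-person median BMI over all BMI measurements."""
    bmi = measurements[measurements["kind"] == "bmi"].copy()
    if bmi.empty:
        return pd.Series(dtype=float)
    bmi["value"] = pd.to_numeric(bmi["value"])
    return bmi.groupby("person_id")["value"].median()


def bmi_who_category(bmi: float) -> str:
    """WHO BMI range category used as a survival covariate."""
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    return "obese"
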
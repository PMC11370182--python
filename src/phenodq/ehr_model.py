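"""Canonical in-memory model for EHR cohort extracts.

A cohort is a pair of pandas tables — one row per patient, one row per coded
clinical event — plus an inclusive study window (default 2017-01-01 to
2019-12-31).  Three event streams are carried: diagnoses (ICD-10),
medications (RxNorm) and laboratory results (LOINC).  The module also owns
code-set matching semantics (exact or prefix, after dot-stripping
normalisation) and window filtering, and round-trips cohorts through plain
CSV files.

All transforms in this package treat event tables as immutable values and
return new tables; nothing mutates a cohort in place.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DX", "RX", "LAB", "DATA_TYPES", "CODE_SYSTEM_FOR",
    "DEFAULT_STUDY_WINDOW", "PATIENT_COLUMNS", "EVENT_COLUMNS",
    "SchemaError", "IntegrityError", "CodeSystemError", "ConfigError",
    "CodeSet", "Cohort", "normalize_code", "match_code", "match_code_array",
    "filter_window", "read_cohort", "write_cohort", "cohorts_equal",
]

DX = "DX"
RX = "RX"
LAB = "LAB"
DATA_TYPES = (DX, RX, LAB)

#: Each event stream carries exactly one terminology.
CODE_SYSTEM_FOR = {DX: "ICD10", RX: "RXNORM", LAB: "LOINC"}

DEFAULT_STUDY_WINDOW = (date(2017, 1, 1), date(2019, 12, 31))

PATIENT_COLUMNS = [
    "patient_id", "birth_year", "sex", "race", "ethnicity", "state",
    "inpatient_visits", "ed_visits",
]
EVENT_COLUMNS = [
    "patient_id", "data_type", "code_system", "code", "event_date",
    "setting", "value", "unit",
]

SEX_VALUES = ("female", "male", "other")
RACE_VALUES = ("white", "black", "asian", "other")
ETHNICITY_VALUES = ("hispanic", "non_hispanic", "other")
SETTING_VALUES = ("inpatient", "outpatient", "ed")


class SchemaError(ValueError):
    """A table is missing a required column or has an unparseable cell."""


class IntegrityError(ValueError):
    """Referential integrity between tables is broken."""


class CodeSystemError(ValueError):
    """A code was compared against a code set from a different terminology."""


class ConfigError(ValueError):
    """A configuration document is structurally invalid."""


_CODE_PATTERNS = {
    # Letter + two alphanumerics, optional dot, up to four more characters
    # ("E11", "E11.9", "C50.911").  Dotless child codes are accepted too.
    "ICD10": re.compile(r"^[A-Z][0-9][0-9A-Z]\.?[0-9A-Z]{0,4}$"),
    "RXNORM": re.compile(r"^[0-9]{1,8}$"),
    "LOINC": re.compile(r"^[0-9]{1,7}-[0-9]$"),
}


def normalize_code(code: str) -> str:
    """Canonical form used for all matching: uppercase, dots removed."""
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class CodeSet:
    """A named list of codes in one terminology, matched exactly or by prefix.

    Prefix matching operates on normalised (dot-stripped) codes, so the
    family code ``E11`` matches the child diagnosis ``E11.9``.
    """

    name: str
    code_system: str
    codes: frozenset
    match_mode: str = "exact"

    def __post_init__(self):
        if self.code_system not in _CODE_PATTERNS:
            raise ConfigError(f"unknown code system {self.code_system!r}")
        if self.match_mode not in ("exact", "prefix"):
            raise ConfigError(f"unknown match mode {self.match_mode!r}")
        pat = _CODE_PATTERNS[self.code_system]
        for c in self.codes:
            if not pat.match(str(c)):
                raise ConfigError(
                    f"code {c!r} is not syntactically valid {self.code_system}"
                )
        object.__setattr__(self, "codes", frozenset(str(c) for c in self.codes))

    @property
    def normalized(self) -> tuple:
        return tuple(sorted(normalize_code(c) for c in self.codes))


def match_code(code: str, code_set: CodeSet, code_system: str | None = None) -> bool:
    """Does ``code`` belong to ``code_set``?

    ``code_system``, when given, must equal the set's system; passing a code
    from another terminology is a usage error, never silently False.
    """
    if code_system is not None and code_system != code_set.code_system:
        raise CodeSystemError(
            f"cannot match {code_system} code against {code_set.code_system} set"
        )
    norm = normalize_code(code)
    targets = code_set.normalized
    if code_set.match_mode == "exact":
        return norm in targets
    return any(norm.startswith(t) for t in targets)


def match_code_array(codes: pd.Series, code_set: CodeSet) -> np.ndarray:
    """Vectorised :func:`match_code` over a series; matches unique codes once."""
    uniq = pd.unique(codes.astype(str))
    hits = {c: match_code(c, code_set) for c in uniq}
    return codes.astype(str).map(hits).to_numpy(dtype=bool)


@dataclass(frozen=True)
class Cohort:
    """Patients + events sharing patient identifiers, with a study window."""

    patients: pd.DataFrame
    events: pd.DataFrame
    study_window: tuple = DEFAULT_STUDY_WINDOW

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def with_events(self, events: pd.DataFrame) -> "Cohort":
        return Cohort(self.patients, events, self.study_window)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def validate_cohort(patients: pd.DataFrame, events: pd.DataFrame) -> None:
    """Raise if the two tables violate the model invariants."""
    _require_columns(patients, PATIENT_COLUMNS, "demographics")
    _require_columns(events, EVENT_COLUMNS, "events")
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise IntegrityError(f"duplicate patient_id {dup!r}")
    if len(events):
        known = set(patients["patient_id"])
        unknown = set(events["patient_id"]) - known
        if unknown:
            raise IntegrityError(
                f"events reference unknown patient_id(s): {sorted(unknown)[:5]}"
            )
        bad_sys = events.loc[
            events["code_system"] != events["data_type"].map(CODE_SYSTEM_FOR)
        ]
        if len(bad_sys):
            row = bad_sys.iloc[0]
            raise IntegrityError(
                f"data_type {row['data_type']} paired with code_system "
                f"{row['code_system']}"
            )


def _attach_event_ids(events: pd.DataFrame) -> pd.DataFrame:
    """Stable per-event identity used by the seeded perturbation operators."""
    events = events.reset_index(drop=True)
    events["event_id"] = np.arange(len(events), dtype=np.int64)
    return events


def read_cohort(demographics_path, events_path,
                study_window: tuple = DEFAULT_STUDY_WINDOW) -> Cohort:
    """Load a cohort from the two CSV extracts, validating as it goes.

    Raises :class:`SchemaError` for missing columns or unparseable dates
    (naming the offending row) and :class:`IntegrityError` for events that
    reference a patient absent from the demographics table.
    """
    patients = pd.read_csv(
        demographics_path,
        dtype={"patient_id": str, "sex": str, "race": str,
               "ethnicity": str, "state": str},
    )
    _require_columns(patients, PATIENT_COLUMNS, "demographics")
    patients = patients[PATIENT_COLUMNS].copy()
    for col in ("birth_year", "inpatient_visits", "ed_visits"):
        patients[col] = patients[col].astype(np.int64)

    try:
        events = pd.read_csv(
            events_path,
            dtype={"patient_id": str, "data_type": str, "code_system": str,
                   "code": str, "setting": str, "unit": str},
        )
    except pd.errors.EmptyDataError:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    _require_columns(events, EVENT_COLUMNS, "events")
    events = events[EVENT_COLUMNS].copy()
    parsed = pd.to_datetime(events["event_date"], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & events["event_date"].notna()
    if bad.any():
        rownum = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise SchemaError(
            f"unparseable event_date {events.loc[bad.idxmax(), 'event_date']!r} "
            f"at row {rownum} of events CSV"
        )
    events["event_date"] = parsed
    events["value"] = pd.to_numeric(events["value"], errors="coerce")
    for col in ("setting", "unit"):
        events[col] = events[col].fillna("")
    validate_cohort(patients, events)
    return Cohort(patients, _attach_event_ids(events), study_window)


def write_cohort(cohort: Cohort, out_dir) -> tuple:
    """Write ``demographics.csv`` and ``events.csv``; inverse of read_cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo_path = out / "demographics.csv"
    events_path = out / "events.csv"
    cohort.patients[PATIENT_COLUMNS].to_csv(demo_path, index=False)
    ev = cohort.events[EVENT_COLUMNS].copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"]).dt.strftime("%Y-%m-%d")
    ev.to_csv(events_path, index=False)
    return demo_path, events_path


def cohorts_equal(a: Cohort, b: Cohort) -> bool:
    """Field-for-field equality on the declared columns (event ids ignored)."""
    try:
        pd.testing.assert_frame_equal(
            a.patients[PATIENT_COLUMNS].reset_index(drop=True),
            b.patients[PATIENT_COLUMNS].reset_index(drop=True),
        )
        pd.testing.assert_frame_equal(
            a.events[EVENT_COLUMNS].reset_index(drop=True),
            b.events[EVENT_COLUMNS].reset_index(drop=True),
        )
    except AssertionError:
        return False
    return a.study_window == b.study_window


def filter_window(events: pd.DataFrame, window: tuple) -> pd.DataFrame:
    """Events with dates inside the closed interval ``window``; order kept."""
    lo, hi = window
    if lo > hi:
        raise ValueError(f"inverted window {lo}..{hi}")
    if not len(events):
        return events.copy()
    d = pd.to_datetime(events["event_date"])
    mask = (d >= pd.Timestamp(lo)) & (d <= pd.Timestamp(hi))
    return events.loc[mask].copy()
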
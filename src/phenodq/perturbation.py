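"""Seeded, nested, composable data-quality defect operators.

Three defect families act on event tables and never touch demographics:

* incompleteness — uniform-at-random event deletion per data type;
* inaccuracy — random code replacement (diagnosis/medication), deterministic
  multiplicative scaling of laboratory values, and US→UK unit conversion
  (glucose mg/dL→mmol/L, HbA1c NGSP %→IFCC mmol/mol);
* timeliness — uniform forward date shifts; attrition arises because the
  fixed study window then excludes late events.

Random selection uses a counter-based scheme: each event's uniforms are a
pure hash of (seed, event_id, role), so the selected set at fraction f1 is a
subset of the set at f2 >= f1 under the same seed.  This makes retention
curves exactly monotone along a drop grid, not just in expectation, and
requires no stored masks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ehr_model import DX, RX, LAB, DATA_TYPES, LAB as _LAB, Cohort, ConfigError

__all__ = [
    "PerturbationSpec", "DROP_GRID", "REPLACE_GRID", "SCALE_GRID",
    "SHIFT_GRID", "DEFAULT_UNIT_RULES", "event_uniforms", "drop_events",
    "replace_codes", "scale_lab_values", "corrupt_units", "shift_dates",
    "apply", "observed_code_pools",
]

#: "10% increments, 0% to 100%"
DROP_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))
REPLACE_GRID = DROP_GRID
#: "2% incremental change from -100% to +10%" (56 points)
SCALE_GRID = tuple(np.round(np.arange(-1.00, 0.101, 0.02), 2))
#: "date shifts at increments of 30 to 365 days"
SHIFT_GRID = (0, 30, 60, 90, 120, 150, 180, 210, 240, 270, 300, 330, 360, 365)

#: US→UK laboratory reporting: value' = scale * value + offset.
#: Glucose mg/dL → mmol/L (molar mass 180.16 g/mol); HbA1c NGSP % → IFCC
#: mmol/mol via the master equation 10.93 * NGSP - 23.50.
DEFAULT_UNIT_RULES = (
    {"codes": ("2345-7", "1558-6"), "from_unit": "mg/dL", "to_unit": "mmol/L",
     "scale": 1.0 / 18.016, "offset": 0.0},
    {"codes": ("55454-3", "4548-4"), "from_unit": "%", "to_unit": "mmol/mol",
     "scale": 10.93, "offset": -23.50},
)

_ROLE_DROP, _ROLE_SELECT, _ROLE_CHOICE = 0, 1, 2


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finaliser; uint64 in, well-mixed uint64 out.

    Relies on modular uint64 arithmetic, hence the local errstate."""
    x = np.asarray(x, dtype=np.uint64).copy()
    with np.errstate(over="ignore"):
        x ^= x >> np.uint64(33)
        x *= np.uint64(0xFF51AFD7ED558CCD)
        x ^= x >> np.uint64(33)
        x *= np.uint64(0xC4CEB9FE1A85EC53)
        x ^= x >> np.uint64(33)
    return x


def event_uniforms(event_ids: np.ndarray, seed: int, role: int) -> np.ndarray:
    """Stable uniform(0,1) per event for one role under one seed."""
    ids = np.asarray(event_ids, dtype=np.uint64)
    with np.errstate(over="ignore"):
        base = _mix64(np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
                      + np.uint64(role + 1))
        keyed = ids + np.uint64(0x9E3779B97F4A7C15) ^ base
    return _mix64(keyed) / np.float64(2**64)


def _require_event_ids(events: pd.DataFrame) -> np.ndarray:
    if "event_id" not in events.columns:
        raise ConfigError("events table lacks event_id; load or generate "
                          "cohorts through this package first")
    return events["event_id"].to_numpy()


def _check_fraction(fraction: float) -> None:
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"fraction {fraction} outside [0, 1]")


def drop_events(events: pd.DataFrame, data_types: Iterable, fraction: float,
                seed: int) -> pd.DataFrame:
    """Remove targeted events whose drop-uniform falls below ``fraction``."""
    _check_fraction(fraction)
    if not len(events) or fraction == 0.0:
        return events.copy()
    targeted = events["data_type"].isin(set(data_types)).to_numpy()
    u = event_uniforms(_require_event_ids(events), seed, _ROLE_DROP)
    keep = ~(targeted & (u < fraction))
    return events.loc[keep].copy()


def observed_code_pools(events: pd.DataFrame) -> dict:
    """Distinct codes per data type in the table — the default replacement
    vocabulary ('including T2D and non-T2D codes')."""
    return {t: tuple(sorted(events.loc[events["data_type"] == t, "code"]
                            .unique()))
            for t in DATA_TYPES}


def replace_codes(events: pd.DataFrame, data_types: Iterable, fraction: float,
                  pools: Mapping, seed: int) -> pd.DataFrame:
    """Replace selected events' codes with a different code from the pool.

    The replacement is drawn uniformly from the pool *excluding* the event's
    current code, so a replaced event never keeps its code.  Selection and
    choice are both stable per (seed, event), so grid points nest and a given
    event receives the same new code at every fraction that selects it.
    """
    _check_fraction(fraction)
    out = events.copy()
    if not len(events) or fraction == 0.0:
        return out
    ids = _require_event_ids(events)
    u_sel = event_uniforms(ids, seed, _ROLE_SELECT)
    u_choice = event_uniforms(ids, seed, _ROLE_CHOICE)
    codes = out["code"].to_numpy(dtype=object)
    for dtype in set(data_types):
        pool = np.asarray(pools[dtype], dtype=object)
        if len(pool) < 2:
            raise ConfigError(f"replacement pool for {dtype} needs >= 2 codes")
        sel = ((out["data_type"] == dtype).to_numpy()
               & (u_sel < fraction))
        if not sel.any():
            continue
        cur = codes[sel]
        in_pool = np.isin(cur, pool)
        npool = len(pool)
        # current code in pool: draw over the other npool-1 codes by index
        # trick (collision with the current code maps to the last element).
        j = np.floor(u_choice[sel] * (npool - 1)).astype(int)
        j = np.minimum(j, npool - 2)
        cand = pool[j]
        cand = np.where(cand == cur, pool[npool - 1], cand)
        # current code absent: draw uniformly over the whole pool.
        j_all = np.minimum(np.floor(u_choice[sel] * npool).astype(int),
                           npool - 1)
        cand = np.where(in_pool, cand, pool[j_all])
        codes[sel] = cand
    out["code"] = codes
    return out


def scale_lab_values(events: pd.DataFrame, delta: float) -> pd.DataFrame:
    """Every laboratory value v becomes v * (1 + delta); deterministic."""
    if not -1.0 - 1e-12 <= delta <= 0.10 + 1e-12:
        raise ConfigError(f"lab value delta {delta} outside [-1.0, +0.10]")
    out = events.copy()
    if not len(out):
        return out
    is_lab = (out["data_type"] == _LAB).to_numpy()
    vals = out["value"].to_numpy(dtype=float, copy=True)
    vals[is_lab] = vals[is_lab] * (1.0 + delta)
    out["value"] = vals
    return out


def corrupt_units(events: pd.DataFrame,
                  rules: Sequence = DEFAULT_UNIT_RULES) -> pd.DataFrame:
    """Relabel and transform laboratory results per the conversion rules.

    Events whose (code, unit) match no rule pass through unchanged."""
    out = events.copy()
    if not len(out):
        return out
    vals = out["value"].to_numpy(dtype=float, copy=True)
    units = out["unit"].to_numpy(dtype=object, copy=True)
    is_lab = (out["data_type"] == _LAB).to_numpy()
    for rule in rules:
        if rule["scale"] == 0:
            raise ConfigError("unit conversion rule with zero scale")
        hit = (is_lab
               & out["code"].isin(set(rule["codes"])).to_numpy()
               & (units == rule["from_unit"]))
        vals[hit] = vals[hit] * rule["scale"] + rule["offset"]
        units[hit] = rule["to_unit"]
    out["value"] = vals
    out["unit"] = units
    return out


def shift_dates(events: pd.DataFrame, days: int,
                data_types: Iterable = DATA_TYPES) -> pd.DataFrame:
    """Advance targeted events' dates by exactly ``days`` calendar days."""
    if days < 0:
        raise ConfigError("date shifts are forward only (days >= 0)")
    out = events.copy()
    if not len(out) or days == 0:
        return out
    targeted = out["data_type"].isin(set(data_types)).to_numpy()
    dates = out["event_date"].to_numpy(dtype="datetime64[ns]", copy=True)
    dates[targeted] = dates[targeted] + np.timedelta64(days, "D")
    out["event_date"] = dates
    return out


_KINDS = ("drop", "replace_code", "scale_lab_value", "corrupt_units",
          "shift_dates", "compound")

_SHIFT_LEVELS = frozenset({0, 365} | {30 * k for k in range(1, 13)})


@dataclass(frozen=True)
class PerturbationSpec:
    """Declarative description of one induced defect (or a composition)."""

    kind: str
    data_types: tuple = DATA_TYPES
    level: float = 0.0
    seed: int = 0
    children: tuple = ()
    pools: Mapping | None = None        # replace_code only; default observed
    unit_rules: Sequence = DEFAULT_UNIT_RULES

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown perturbation kind {self.kind!r}")
        bad = set(self.data_types) - set(DATA_TYPES)
        if bad:
            raise ConfigError(f"unknown data types {sorted(bad)}")
        if self.kind in ("drop", "replace_code"):
            _check_fraction(self.level)
        elif self.kind == "scale_lab_value":
            if not -1.0 - 1e-12 <= self.level <= 0.10 + 1e-12:
                raise ConfigError("scale level outside [-1.0, +0.10]")
        elif self.kind == "shift_dates":
            if int(self.level) not in _SHIFT_LEVELS:
                raise ConfigError(
                    "shift level must lie on the 30-day grid or be 365")
        elif self.kind == "compound":
            for child in self.children:
                if not isinstance(child, PerturbationSpec):
                    raise ConfigError("compound children must be specs")


def apply(spec: PerturbationSpec, cohort: Cohort) -> Cohort:
    """Dispatch a spec against a cohort; the patients table is never touched."""
    events = cohort.events
    if spec.kind == "compound":
        out = cohort
        for child in spec.children:
            out = apply(child, out)
        return out
    if spec.kind == "drop":
        events = drop_events(events, spec.data_types, spec.level, spec.seed)
    elif spec.kind == "replace_code":
        pools = spec.pools if spec.pools is not None else observed_code_pools(events)
        events = replace_codes(events, spec.data_types, spec.level, pools,
                               spec.seed)
    elif spec.kind == "scale_lab_value":
        events = scale_lab_values(events, spec.level)
    elif spec.kind == "corrupt_units":
        events = corrupt_units(events, spec.unit_rules)
    elif spec.kind == "shift_dates":
        events = shift_dates(events, int(spec.level), spec.data_types)
    return cohort.with_events(events)
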
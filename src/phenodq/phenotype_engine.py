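"""Declarative computable-phenotype language and evaluator.

A *criterion* is a lower-bound count of coded events matching a code set,
optionally restricted by care setting, a value predicate (laboratory
results), distinct calendar days, and a maximum span (``window_days``)
within which the qualifying events must fall.  A *pathway* is a conjunction
of criteria; a *definition* is a disjunction of pathways, optionally with a
trailing reference period anchored to the study-window end.

The five shipped type-2-diabetes definitions (CCW, DDC, SUPREME-DM, eMERGE,
JHU) are YAML configs under ``definitions/``; structural constraints that are
intrinsic to each definition (e.g. CCW is diagnosis-only with a 2-year
reference period; eMERGE has no diagnosis-only, medication-only or
medication+laboratory-only pathway) are enforced at compile time, so a
mis-edited config fails loudly rather than silently changing the science.

A patient's *evidence profile* is the union of data types over all satisfied
pathways — the data types that actually identified the patient, not the data
types merely present in their record.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ehr_model import (
    DX, RX, LAB, DATA_TYPES, SETTING_VALUES,
    CodeSet, Cohort, ConfigError, match_code_array,
)

__all__ = [
    "ValuePredicate", "Criterion", "Pathway", "PhenotypeDefinition",
    "IdentificationResult", "PHENOTYPE_NAMES", "STRATA",
    "load_code_sets", "compile_definition", "load_definition",
    "load_all_definitions", "evaluate_criterion", "evaluate_phenotype",
    "data_type_stratum", "reference_window",
]

PHENOTYPE_NAMES = ("CCW", "DDC", "SUPREME_DM", "EMERGE", "JHU")

#: The 7 non-empty data-type combinations, in canonical order.
STRATA = ("DX", "RX", "LAB", "DX+RX", "DX+LAB", "RX+LAB", "DX+RX+LAB")

_OPS = {
    "ge": np.greater_equal,
    "gt": np.greater,
    "le": np.less_equal,
    "lt": np.less,
}


@dataclass(frozen=True)
class ValuePredicate:
    """Comparison applied to laboratory result values.

    A result only satisfies the predicate when its unit string equals
    ``unit`` exactly — there is no automatic unit conversion, which is what
    makes unit corruption a detectable data-quality defect.
    """

    op: str
    threshold: float
    unit: str

    def __post_init__(self):
        if self.op not in _OPS:
            raise ConfigError(f"unknown predicate op {self.op!r}")


@dataclass(frozen=True)
class Criterion:
    data_type: str
    code_set: CodeSet
    min_count: int = 1
    distinct_days: bool = False
    setting: str | None = None
    window_days: int | None = None
    predicate: ValuePredicate | None = None

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise ConfigError(f"unknown data_type {self.data_type!r}")
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if self.predicate is not None and self.data_type != LAB:
            raise ConfigError("value predicates apply to LAB criteria only")
        if self.window_days is not None and self.min_count < 2:
            raise ConfigError("window_days requires min_count >= 2")
        if self.setting is not None and self.setting not in SETTING_VALUES:
            raise ConfigError(f"unknown setting {self.setting!r}")


@dataclass(frozen=True)
class Pathway:
    name: str
    criteria: tuple

    def __post_init__(self):
        if not self.criteria:
            raise ConfigError(f"pathway {self.name!r} has no criteria")

    @property
    def data_types(self) -> frozenset:
        return frozenset(c.data_type for c in self.criteria)


@dataclass(frozen=True)
class PhenotypeDefinition:
    name: str
    pathways: tuple
    reference_period_days: int | None = None


@dataclass(frozen=True)
class IdentificationResult:
    """Identified patient set plus per-patient evidence profiles."""

    phenotype: str
    identified: frozenset
    evidence_profile: Mapping  # patient_id -> frozenset of data types

    @property
    def n_identified(self) -> int:
        return len(self.identified)


# ---------------------------------------------------------------------------
# Config compilation

def _parse_code_sets(raw: Mapping) -> dict:
    out = {}
    for name, spec in raw.items():
        out[name] = CodeSet(
            name=name,
            code_system=spec["code_system"],
            codes=frozenset(str(c) for c in spec["codes"]),
            match_mode=spec.get("match_mode", "exact"),
        )
    return out


@lru_cache(maxsize=1)
def load_code_sets() -> dict:
    """The shipped shared code sets (T2D diagnosis/medication/lab panels)."""
    with resources.files("phenodq.definitions").joinpath("code_sets.yaml").open() as fh:
        return _parse_code_sets(yaml.safe_load(fh))


def _structural_check(defn: PhenotypeDefinition) -> None:
    """Per-name invariants that are intrinsic to each published definition."""
    unions = [p.data_types for p in defn.pathways]
    if defn.name == "CCW":
        if any(c.data_type != DX for p in defn.pathways for c in p.criteria):
            raise ConfigError("CCW admits diagnosis criteria only")
        if defn.reference_period_days != 730:
            raise ConfigError("CCW requires a 730-day reference period")
    elif defn.name == "JHU":
        if len(defn.pathways) != 3 or any(len(p.criteria) != 1 for p in defn.pathways):
            raise ConfigError("JHU must be three single-criterion pathways")
        if set(map(frozenset, unions)) != {frozenset({DX}), frozenset({RX}),
                                           frozenset({LAB})}:
            raise ConfigError("JHU pathways must cover DX, RX and LAB singly")
    elif defn.name == "EMERGE":
        forbidden = {frozenset({DX}), frozenset({RX}), frozenset({RX, LAB})}
        bad = [p.name for p in defn.pathways if p.data_types in forbidden]
        if bad:
            raise ConfigError(
                f"eMERGE forbids DX-only, RX-only and RX+LAB-only pathways: {bad}"
            )
    elif defn.name == "SUPREME_DM":
        bad = [p.name for p in defn.pathways if p.data_types == frozenset({RX})]
        if bad:
            raise ConfigError(f"SUPREME-DM forbids RX-only pathways: {bad}")


def compile_definition(config: Mapping, code_sets: Mapping | None = None
                       ) -> PhenotypeDefinition:
    """Validate a config document into a :class:`PhenotypeDefinition`.

    ``code_sets`` resolves named references; inline sets may be supplied
    under the config's own ``code_sets`` key.  Unknown references and
    structural violations raise :class:`ConfigError`.
    """
    resolved = dict(load_code_sets() if code_sets is None else code_sets)
    if "code_sets" in config:
        resolved.update(_parse_code_sets(config["code_sets"]))
    name = config["name"]
    if name not in PHENOTYPE_NAMES:
        raise ConfigError(f"unknown phenotype name {name!r}")
    pathways = []
    for p in config["pathways"]:
        criteria = []
        for c in p["criteria"]:
            ref = c["code_set"]
            if ref not in resolved:
                raise ConfigError(f"unresolved code set reference {ref!r}")
            pred = None
            if c.get("predicate"):
                pr = c["predicate"]
                pred = ValuePredicate(pr["op"], float(pr["threshold"]), pr["unit"])
            criteria.append(Criterion(
                data_type=c["data_type"],
                code_set=resolved[ref],
                min_count=int(c.get("min_count", 1)),
                distinct_days=bool(c.get("distinct_days", False)),
                setting=c.get("setting"),
                window_days=c.get("window_days"),
                predicate=pred,
            ))
        pathways.append(Pathway(p["name"], tuple(criteria)))
    defn = PhenotypeDefinition(
        name=name,
        pathways=tuple(pathways),
        reference_period_days=config.get("reference_period_days"),
    )
    _structural_check(defn)
    return defn


_DEFN_FILES = {"CCW": "ccw.yaml", "DDC": "ddc.yaml", "SUPREME_DM": "supreme_dm.yaml",
               "EMERGE": "emerge.yaml", "JHU": "jhu.yaml"}


@lru_cache(maxsize=None)
def load_definition(name: str) -> PhenotypeDefinition:
    if name not in _DEFN_FILES:
        raise ConfigError(f"unknown phenotype name {name!r}")
    with resources.files("phenodq.definitions").joinpath(_DEFN_FILES[name]).open() as fh:
        return compile_definition(yaml.safe_load(fh))


def load_all_definitions() -> tuple:
    return tuple(load_definition(n) for n in PHENOTYPE_NAMES)


# ---------------------------------------------------------------------------
# Evaluation

def reference_window(defn: PhenotypeDefinition, study_window: tuple) -> tuple:
    """Definition's reference period: the trailing N days of the window."""
    lo, hi = study_window
    if defn.reference_period_days is None:
        return (lo, hi)
    start = hi - timedelta(days=defn.reference_period_days - 1)
    return (max(lo, start), hi)


def _satisfying_patients(events: pd.DataFrame, criterion: Criterion,
                         window: tuple) -> pd.Index:
    """Patients whose events satisfy one criterion (vectorised)."""
    if not len(events):
        return pd.Index([], name="patient_id")
    mask = (events["data_type"] == criterion.data_type).to_numpy()
    if mask.any():
        d = events["event_date"].to_numpy(dtype="datetime64[ns]")
        lo, hi = window
        mask &= (d >= np.datetime64(pd.Timestamp(lo)))
        mask &= (d <= np.datetime64(pd.Timestamp(hi)))
    if criterion.setting is not None and mask.any():
        mask &= (events["setting"] == criterion.setting).to_numpy()
    if mask.any():
        sub_match = match_code_array(events.loc[mask, "code"], criterion.code_set)
        idx = np.flatnonzero(mask)
        mask = np.zeros(len(events), dtype=bool)
        mask[idx[sub_match]] = True
    if criterion.predicate is not None and mask.any():
        pr = criterion.predicate
        vals = events["value"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            mask &= _OPS[pr.op](vals, pr.threshold)
        mask &= (events["unit"] == pr.unit).to_numpy()

    qual = events.loc[mask, ["patient_id", "event_date"]]
    if not len(qual):
        return pd.Index([], name="patient_id")
    if criterion.distinct_days:
        counts = qual.groupby("patient_id")["event_date"].nunique()
    else:
        counts = qual.groupby("patient_id").size()
    ok = counts.index[counts >= criterion.min_count]
    if criterion.window_days is None or not len(ok):
        return pd.Index(ok, name="patient_id")

    # window_days: need min_count qualifying events (distinct days if so
    # flagged) within some span of window_days calendar days.
    k = criterion.min_count
    q = qual[qual["patient_id"].isin(ok)]
    if criterion.distinct_days:
        q = q.drop_duplicates(["patient_id", "event_date"])
    q = q.sort_values(["patient_id", "event_date"])
    earlier = q.groupby("patient_id")["event_date"].shift(k - 1)
    span_ok = (q["event_date"] - earlier).dt.days <= (criterion.window_days - 1)
    hits = q.loc[span_ok.fillna(False), "patient_id"].unique()
    return pd.Index(hits, name="patient_id")


def evaluate_criterion(criterion: Criterion, patient_events: pd.DataFrame,
                       window: tuple) -> bool:
    """Does one patient's event table satisfy the criterion in ``window``?"""
    if len(patient_events) and patient_events["patient_id"].nunique() > 1:
        raise ValueError("patient_events must belong to a single patient")
    return len(_satisfying_patients(patient_events, criterion, window)) > 0


_BIT = {DX: 1, RX: 2, LAB: 4}
_BITS_TO_STRATUM = {
    sum(_BIT[t] for t in s.split("+")): s for s in STRATA
}


def evaluate_phenotype(defn: PhenotypeDefinition, cohort: Cohort
                       ) -> IdentificationResult:
    """Apply one definition to a whole cohort.

    A patient is identified iff at least one pathway has all its criteria
    satisfied on events restricted to the definition's reference period; the
    evidence profile is the union of the satisfied pathways' data types.
    """
    window = reference_window(defn, cohort.study_window)
    events = cohort.events
    profile_bits = pd.Series(0, index=pd.Index(cohort.patients["patient_id"],
                                               name="patient_id"), dtype=np.int64)
    crit_cache: dict = {}
    for pathway in defn.pathways:
        sat: pd.Index | None = None
        for criterion in pathway.criteria:
            key = id(criterion)
            if key not in crit_cache:
                crit_cache[key] = _satisfying_patients(events, criterion, window)
            hits = crit_cache[key]
            sat = hits if sat is None else sat.intersection(hits)
            if not len(sat):
                break
        if sat is not None and len(sat):
            bits = sum(_BIT[t] for t in pathway.data_types)
            profile_bits.loc[sat] |= bits
    hit = profile_bits[profile_bits > 0]
    profile = {
        pid: frozenset(t for t in DATA_TYPES if b & _BIT[t])
        for pid, b in hit.items()
    }
    return IdentificationResult(
        phenotype=defn.name,
        identified=frozenset(hit.index),
        evidence_profile=profile,
    )


def data_type_stratum(result: IdentificationResult) -> dict:
    """Partition the identified set into the 7 data-type strata."""
    counts = {s: 0 for s in STRATA}
    for types in result.evidence_profile.values():
        bits = sum(_BIT[t] for t in types)
        counts[_BITS_TO_STRATUM[bits]] += 1
    return counts
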
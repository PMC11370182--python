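"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: matching is a
per-event linear scan, counting is done with Python sets, and span
constraints are checked by exhaustive enumeration over date combinations.
"""
from datetime import timedelta
from itertools import combinations

import pandas as pd

from phenodq.ehr_model import normalize_code


def naive_match(code, code_set):
    norm = code.strip().upper().replace(".", "")
    listed = [c.strip().upper().replace(".", "") for c in code_set.codes]
    if code_set.match_mode == "exact":
        return any(norm == c for c in listed)
    return any(norm.startswith(c) for c in listed)


def _criterion_ok(criterion, events, window):
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    qualifying = []
    for ev in events:
        if ev["data_type"] != criterion.data_type:
            continue
        d = pd.Timestamp(ev["event_date"])
        if not (lo <= d <= hi):
            continue
        if criterion.setting is not None and ev["setting"] != criterion.setting:
            continue
        if not naive_match(ev["code"], criterion.code_set):
            continue
        if criterion.predicate is not None:
            pr = criterion.predicate
            v = ev["value"]
            if pd.isna(v) or ev["unit"] != pr.unit:
                continue
            ok = {"ge": v >= pr.threshold, "gt": v > pr.threshold,
                  "le": v <= pr.threshold, "lt": v < pr.threshold}[pr.op]
            if not ok:
                continue
        qualifying.append(d)

    k = criterion.min_count
    dates = sorted(set(qualifying)) if criterion.distinct_days else sorted(qualifying)
    if len(dates) < k:
        return False
    if criterion.window_days is None:
        return True
    for combo in combinations(dates, k):
        if (max(combo) - min(combo)).days <= criterion.window_days - 1:
            return True
    return False


def oracle_reference_window(defn, study_window):
    lo, hi = study_window
    if defn.reference_period_days is None:
        return (lo, hi)
    start = hi - timedelta(days=defn.reference_period_days - 1)
    return (max(lo, start), hi)


def oracle_evaluate(defn, cohort):
    """Per-patient pure-Python evaluation; returns (identified, profiles)."""
    window = oracle_reference_window(defn, cohort.study_window)
    by_patient = {}
    for ev in cohort.events.to_dict("records"):
        by_patient.setdefault(ev["patient_id"], []).append(ev)
    identified = set()
    profiles = {}
    for pid in cohort.patients["patient_id"]:
        events = by_patient.get(pid, [])
        types = set()
        for pathway in defn.pathways:
            if all(_criterion_ok(c, events, window) for c in pathway.criteria):
                types |= {c.data_type for c in pathway.criteria}
        if types:
            identified.add(pid)
            profiles[pid] = frozenset(types)
    return identified, profiles
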
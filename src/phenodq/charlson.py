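"""Charlson comorbidity index over ICD-10 diagnosis events.

The index is a weighted sum over 17 comorbidity categories: a category
contributes its weight once if the patient has at least one diagnosis code in
it, regardless of how many matching codes occur.  The shipped category map is
the Quan ICD-10 coding algorithm with the original Charlson weights
(1/2/3/6); it lives in ``data/charlson_icd10.yaml`` and can be replaced.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .ehr_model import DX, normalize_code

__all__ = ["CharlsonCategory", "load_default_map", "code_category",
           "charlson_index", "charlson_scores"]

VALID_WEIGHTS = (1, 2, 3, 6)


@dataclass(frozen=True)
class CharlsonCategory:
    name: str
    weight: int
    prefixes: tuple


@lru_cache(maxsize=1)
def load_default_map() -> tuple:
    """The shipped Quan ICD-10 map as a tuple of categories."""
    with resources.files("phenodq.data").joinpath("charlson_icd10.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    cats = []
    for c in raw["categories"]:
        if c["weight"] not in VALID_WEIGHTS:
            raise ValueError(f"invalid Charlson weight {c['weight']}")
        cats.append(CharlsonCategory(
            c["name"], int(c["weight"]),
            tuple(normalize_code(p) for p in c["prefixes"]),
        ))
    return tuple(cats)


def code_category(code: str, cmap: tuple | None = None) -> CharlsonCategory | None:
    """Category a single ICD-10 code falls into, or None.

    Prefix lists are disjoint, so at most one category can match.
    """
    cmap = cmap or load_default_map()
    norm = normalize_code(code)
    for cat in cmap:
        if any(norm.startswith(p) for p in cat.prefixes):
            return cat
    return None


def charlson_index(dx_events: pd.DataFrame, cmap: tuple | None = None) -> int:
    """Score one patient's diagnosis events; each category counted once."""
    cmap = cmap or load_default_map()
    if not len(dx_events):
        return 0
    codes = dx_events.loc[dx_events["data_type"] == DX, "code"]
    seen = set()
    for code in codes:
        cat = code_category(code, cmap)
        if cat is not None:
            seen.add(cat)
    return sum(c.weight for c in seen)


def charlson_scores(events: pd.DataFrame, patient_ids: pd.Series,
                    cmap: tuple | None = None) -> pd.Series:
    """Vectorised per-patient scores for a whole cohort.

    Returns a Series indexed by every id in ``patient_ids`` (patients with no
    scoring diagnosis get 0).  Unique codes are classified once, which keeps
    this linear in the number of distinct codes rather than events.
    """
    cmap = cmap or load_default_map()
    index = pd.Index(patient_ids, name="patient_id")
    scores = pd.Series(0, index=index, dtype=np.int64)
    dx = events.loc[events["data_type"] == DX, ["patient_id", "code"]]
    if not len(dx):
        return scores
    uniq = pd.unique(dx["code"])
    cat_of = {}
    weight_of = {}
    for code in uniq:
        cat = code_category(code, cmap)
        if cat is not None:
            cat_of[code] = cat.name
            weight_of[cat.name] = cat.weight
    dx = dx.assign(category=dx["code"].map(cat_of)).dropna(subset=["category"])
    if not len(dx):
        return scores
    per_cat = dx.drop_duplicates(["patient_id", "category"])
    per_cat = per_cat.assign(weight=per_cat["category"].map(weight_of))
    summed = per_cat.groupby("patient_id")["weight"].sum()
    scores.loc[summed.index] = summed.astype(np.int64)
    return scores
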
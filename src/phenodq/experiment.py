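"""Perturbation grids, retention curves, overlap partitions and reports.

``run_grid`` drives one data-quality axis: for every (target data type,
level, replicate seed) it perturbs the cohort, re-applies every phenotype
definition, and records the identified count and two retention fractions —
one against the same seed's level-0 baseline (identical to the unperturbed
evaluation by the level-0 identity property) and one against the whole
cohort denominator.  Stochastic axes default to 5 replicate seeds;
deterministic axes (laboratory value scaling, date shifting) run once.

``overlap_partition`` computes exact counts over the 2^5 - 1 disjoint
membership regions of the five identified sets; ``characteristics``
reproduces a study-style descriptive table for any patient subset.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import perturbation as pt
from .charlson import charlson_index, charlson_scores, load_default_map
from .ehr_model import DX, RX, LAB, DATA_TYPES, Cohort, ConfigError
from .phenotype_engine import (
    IdentificationResult, PhenotypeDefinition, STRATA,
    data_type_stratum, evaluate_phenotype,
)

__all__ = [
    "AXES", "GridResult", "OverlapPartition", "run_grid",
    "overlap_partition", "charlson_index", "charlson_scores",
    "characteristics", "export_report", "strata_table",
]

AXES = ("incompleteness", "inaccuracy", "timeliness",
        "compound_incompleteness", "compound_inaccuracy",
        "compound_timeliness")

GRID_COLUMNS = ["phenotype", "data_type_target", "level", "replicate_seed",
                "n_identified", "retention_fraction", "retention_of_cohort"]


@dataclass(frozen=True)
class GridResult:
    axis: str
    rows: pd.DataFrame  # GRID_COLUMNS


@dataclass(frozen=True)
class OverlapPartition:
    """Counts over every non-empty subset of phenotype names.

    ``counts[frozenset({...})]`` is the number of patients identified by
    exactly that subset of phenotypes and no others; regions are disjoint
    and sum to the union of the identified sets.
    """

    counts: Mapping
    denominator_n: int

    @property
    def union_n(self) -> int:
        return sum(self.counts.values())

    @property
    def intersection_n(self) -> int:
        all_names = frozenset().union(*self.counts.keys()) if self.counts else frozenset()
        return self.counts.get(all_names, 0) if all_names else 0


def _identity_level(axis: str) -> float:
    return 0.0


def _spec_for(axis: str, target: str, level: float, seed: int,
              pools: Mapping | None) -> pt.PerturbationSpec:
    if axis in ("incompleteness", "compound_incompleteness"):
        types = DATA_TYPES if axis.startswith("compound") else (target,)
        return pt.PerturbationSpec("drop", types, level, seed)
    if axis == "inaccuracy":
        if target == LAB:
            return pt.PerturbationSpec("scale_lab_value", (LAB,), level, seed)
        return pt.PerturbationSpec("replace_code", (target,), level, seed,
                                   pools=pools)
    if axis == "compound_inaccuracy":
        # Diagnosis and medication codes are replaced; laboratory codes are
        # never replaced (their values are manipulated on their own axis).
        return pt.PerturbationSpec("replace_code", (DX, RX), level, seed,
                                   pools=pools)
    if axis in ("timeliness", "compound_timeliness"):
        types = DATA_TYPES if axis.startswith("compound") else (target,)
        return pt.PerturbationSpec("shift_dates", types, level, seed)
    raise ConfigError(f"unknown axis {axis!r}")


def _default_levels(axis: str, target: str) -> tuple:
    if axis in ("incompleteness", "compound_incompleteness",
                "compound_inaccuracy"):
        return pt.DROP_GRID
    if axis == "inaccuracy":
        return pt.SCALE_GRID if target == LAB else pt.REPLACE_GRID
    return pt.SHIFT_GRID


def _deterministic(axis: str, target: str) -> bool:
    if axis in ("timeliness", "compound_timeliness"):
        return True
    return axis == "inaccuracy" and target == LAB


def run_grid(cohort: Cohort, definitions: Sequence, axis: str,
             levels: Sequence | None = None,
             data_type_targets: Sequence | None = None,
             seeds: Sequence = (1, 2, 3, 4, 5),
             pools: Mapping | None = None) -> GridResult:
    """Sweep one data-quality axis and tabulate per-phenotype retention.

    The identity level (0) must be on the grid; it anchors each replicate's
    retention baseline.  Compound axes ignore ``data_type_targets`` and hit
    all three streams simultaneously.
    """
    if axis not in AXES:
        raise ConfigError(f"unknown axis {axis!r}; expected one of {AXES}")
    if axis.startswith("compound"):
        targets = ("ALL",)
    elif data_type_targets is None:
        targets = DATA_TYPES if axis != "inaccuracy" else (DX, RX, LAB)
    else:
        targets = tuple(data_type_targets)
    if pools is None:
        pools = pt.observed_code_pools(cohort.events)

    names = [d.name for d in definitions]
    rows = []
    for target in targets:
        lv = tuple(levels) if levels is not None else _default_levels(axis, target)
        if not any(np.isclose(l, _identity_level(axis)) for l in lv):
            raise ConfigError(f"levels for axis {axis!r} must include 0")
        seed_list = (seeds[0],) if _deterministic(axis, target) else tuple(seeds)
        for seed in seed_list:
            baselines = {}
            for level in lv:
                spec = _spec_for(axis, target, level, seed, pools)
                perturbed = pt.apply(spec, cohort)
                for defn in definitions:
                    res = evaluate_phenotype(defn, perturbed)
                    n = res.n_identified
                    if np.isclose(level, _identity_level(axis)):
                        baselines[defn.name] = n
                    base = baselines.get(defn.name)
                    rows.append({
                        "phenotype": defn.name,
                        "data_type_target": target,
                        "level": level,
                        "replicate_seed": seed,
                        "n_identified": n,
                        "retention_fraction": (n / base) if base else np.nan,
                        "retention_of_cohort": n / cohort.n_patients,
                    })
    if len(set(names)) != len(names):
        raise ConfigError("duplicate phenotype names in definitions")
    return GridResult(axis=axis, rows=pd.DataFrame(rows, columns=GRID_COLUMNS))


def overlap_partition(results: Sequence, denominator_n: int
                      ) -> OverlapPartition:
    """Exact disjoint region counts over the identified sets."""
    names = [r.phenotype for r in results]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate phenotype names: {names}")
    membership: dict = {}
    for r in results:
        for pid in r.identified:
            membership.setdefault(pid, set()).add(r.phenotype)
    counts: dict = {}
    for pid, s in membership.items():
        key = frozenset(s)
        counts[key] = counts.get(key, 0) + 1
    return OverlapPartition(counts=counts, denominator_n=denominator_n)


def partition_table(partition: OverlapPartition,
                    names: Sequence) -> pd.DataFrame:
    """All 2^k - 1 regions as a tidy table (zeros included)."""
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(sorted(names), r):
            key = frozenset(combo)
            rows.append({
                "region": "+".join(combo),
                "n_phenotypes": r,
                "count": partition.counts.get(key, 0),
            })
    return pd.DataFrame(rows)


def strata_table(results: Sequence) -> pd.DataFrame:
    """Per-phenotype data-type strata, one row per phenotype."""
    rows = []
    for r in results:
        row = {"phenotype": r.phenotype, "n_identified": r.n_identified}
        row.update(data_type_stratum(r))
        rows.append(row)
    return pd.DataFrame(rows, columns=["phenotype", "n_identified", *STRATA])


def characteristics(cohort: Cohort, subset: Iterable) -> pd.DataFrame:
    """Study-style descriptive table for a patient subset.

    Rows: age mean/SD/median, categorical counts and percentages (sex, race,
    ethnicity, state), visit means/SDs, Charlson mean/SD/median.  An empty
    subset yields NaN statistics flagged by an ``empty`` attribute row.
    """
    subset = set(subset)
    unknown = subset - set(cohort.patients["patient_id"])
    if unknown:
        raise ValueError(f"subset contains unknown patients: {sorted(unknown)[:5]}")
    pats = cohort.patients[cohort.patients["patient_id"].isin(subset)]
    rows = []

    def add(block, stat, value):
        rows.append({"characteristic": block, "statistic": stat,
                     "value": float(value) if value == value else np.nan})

    n = len(pats)
    add("n", "count", n)
    if n:
        age = 2017 - pats["birth_year"]
        add("age", "mean", age.mean())
        add("age", "sd", age.std(ddof=1) if n > 1 else 0.0)
        add("age", "median", age.median())
        for block, col in (("sex", "sex"), ("race", "race"),
                           ("ethnicity", "ethnicity"), ("state", "state")):
            vc = pats[col].value_counts()
            for cat, cnt in vc.items():
                add(f"{block}:{cat}", "count", cnt)
                add(f"{block}:{cat}", "percent", 100.0 * cnt / n)
        for col in ("inpatient_visits", "ed_visits"):
            add(col, "mean", pats[col].mean())
            add(col, "sd", pats[col].std(ddof=1) if n > 1 else 0.0)
        cci = charlson_scores(
            cohort.events[cohort.events["patient_id"].isin(subset)],
            pats["patient_id"])
        add("charlson", "mean", cci.mean())
        add("charlson", "sd", cci.std(ddof=1) if n > 1 else 0.0)
        add("charlson", "median", cci.median())
    df = pd.DataFrame(rows, columns=["characteristic", "statistic", "value"])
    df.attrs["empty"] = (n == 0)
    return df


def export_report(grids: Sequence, partitions: Sequence,
                  out_dir, phenotype_names: Sequence | None = None,
                  figures: bool = False) -> list:
    """Write tidy CSV analogues of the study figures; optional line charts.

    File naming is deterministic; reruns on identical inputs are
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for grid in grids:
        path = out / f"retention_{grid.axis}.csv"
        grid.rows.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
        if figures:
            written.append(_retention_figure(grid, out))
    for i, part in enumerate(partitions):
        names = (sorted(frozenset().union(*part.counts.keys()))
                 if part.counts else list(phenotype_names or []))
        path = out / f"overlap_partition_{i}.csv"
        partition_table(part, names).to_csv(path, index=False)
        written.append(path)
    return written


def _retention_figure(grid: GridResult, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    df = grid.rows
    for target in df["data_type_target"].unique():
        sub = df[df["data_type_target"] == target]
        agg = (sub.groupby(["phenotype", "level"])["retention_fraction"]
               .mean().reset_index())
        for name, g in agg.groupby("phenotype"):
            label = name if len(df["data_type_target"].unique()) == 1 \
                else f"{name} ({target})"
            ax.plot(g["level"], 100 * g["retention_fraction"],
                    marker="o", ms=3, label=label)
    ax.set_xlabel(f"{grid.axis} level")
    ax.set_ylabel("% of baseline population identified")
    ax.set_ylim(bottom=0)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = out / f"retention_{grid.axis}.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
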
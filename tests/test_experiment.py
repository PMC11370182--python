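from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from phenodq.charlson import charlson_index, charlson_scores, code_category, load_default_map
from phenodq.ehr_model import Cohort, ConfigError
from phenodq.experiment import (
    characteristics, export_report, overlap_partition, partition_table,
    run_grid, strata_table,
)
from phenodq.phenotype_engine import IdentificationResult, evaluate_phenotype
from phenodq.synthetic_cohort import default_profile, generate_cohort
from conftest import make_cohort, make_events

from oracle import oracle_evaluate


class TestCharlson:
    def test_empty_events_score_zero(self):
        ev = make_events([])
        assert charlson_index(ev) == 0

    def test_mi_plus_uncomplicated_diabetes(self):
        ev = make_events([("P1", "DX", "I21.9", "2018-01-01"),
                          ("P1", "DX", "E11.9", "2018-02-01")])
        assert charlson_index(ev) == 2

    def test_metastatic_category_counted_once(self):
        ev = make_events([("P1", "DX", "C78.0", "2018-01-01"),
                          ("P1", "DX", "C78.1", "2018-02-01")])
        assert charlson_index(ev) == 6

    def test_weights_are_charlson_weights(self):
        cmap = load_default_map()
        assert {c.weight for c in cmap} <= {1, 2, 3, 6}
        assert len(cmap) == 17

    def test_category_prefixes_disjoint(self):
        cmap = load_default_map()
        for i, a in enumerate(cmap):
            for b in cmap[i + 1:]:
                for pa in a.prefixes:
                    for pb in b.prefixes:
                        assert not (pa.startswith(pb) or pb.startswith(pa)), \
                            (a.name, b.name, pa, pb)

    def test_vectorised_scores_agree_with_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        codes = ["I21.9", "I50.9", "E11.9", "E10.21", "C78.0", "C50.9",
                 "B20", "N18.3", "I10", "Z00.00", "K74.60", "J44.9"]
        rows = []
        pids = [f"P{i}" for i in range(1000)]
        for pid in pids:
            for _ in range(rng.integers(0, 6)):
                rows.append((pid, "DX", rng.choice(codes), "2018-01-01"))
        ev = make_events(rows)
        vec = charlson_scores(ev, pd.Series(pids))
        for pid in pids:
            sub = ev[ev["patient_id"] == pid]
            assert vec.loc[pid] == charlson_index(sub), pid


class TestOverlapPartition:
    def _result(self, name, ids):
        return IdentificationResult(name, frozenset(ids),
                                    {i: frozenset({"DX"}) for i in ids})

    def test_identical_sets_collapse_to_full_intersection(self):
        ids = {f"P{i}" for i in range(40)}
        results = [self._result(n, ids)
                   for n in ("CCW", "DDC", "SUPREME_DM", "EMERGE", "JHU")]
        part = overlap_partition(results, denominator_n=100)
        key = frozenset({"CCW", "DDC", "SUPREME_DM", "EMERGE", "JHU"})
        assert part.counts == {key: 40}
        assert part.union_n == 40 and part.intersection_n == 40

    def test_disjoint_sets_populate_only_singletons(self):
        results = [self._result(n, {f"{n}-{i}" for i in range(3)})
                   for n in ("CCW", "DDC", "JHU")]
        part = overlap_partition(results, denominator_n=50)
        assert all(len(k) == 1 for k in part.counts)
        assert part.union_n == 9

    def test_region_counts_sum_to_union(self, mid_cohort, definitions):
        results = [evaluate_phenotype(d, mid_cohort) for d in definitions]
        part = overlap_partition(results, mid_cohort.n_patients)
        union = set().union(*(r.identified for r in results))
        assert part.union_n == len(union) <= mid_cohort.n_patients
        table = partition_table(part, [d.name for d in definitions])
        assert len(table) == 31
        assert table["count"].sum() == len(union)

    def test_duplicate_names_rejected(self):
        r = self._result("CCW", {"P1"})
        with pytest.raises(ValueError):
            overlap_partition([r, r], 10)


class TestRunGrid:
    def test_level_zero_retention_is_one_everywhere(self, small_cohort, definitions):
        grid = run_grid(small_cohort, definitions, "incompleteness",
                        levels=[0.0, 0.5], data_type_targets=["DX"],
                        seeds=[1])
        base = grid.rows[grid.rows["level"] == 0.0]
        assert (base["retention_fraction"] == 1.0).all()

    def test_ccw_zero_at_full_dx_incompleteness(self, small_cohort, definitions):
        grid = run_grid(small_cohort, definitions, "incompleteness",
                        levels=[0.0, 1.0], data_type_targets=["DX"], seeds=[1])
        row = grid.rows[(grid.rows["phenotype"] == "CCW")
                        & (grid.rows["level"] == 1.0)]
        assert (row["n_identified"] == 0).all()
        others = grid.rows[(grid.rows["phenotype"] != "CCW")
                           & (grid.rows["level"] == 1.0)]
        assert (others["n_identified"] > 0).all()

    def test_compound_full_drop_zeroes_every_phenotype(self, small_cohort, definitions):
        grid = run_grid(small_cohort, definitions, "compound_incompleteness",
                        levels=[0.0, 1.0], seeds=[1])
        final = grid.rows[grid.rows["level"] == 1.0]
        assert (final["n_identified"] == 0).all()

    def test_retention_monotone_along_full_drop_grid(self, small_cohort, definitions):
        grid = run_grid(small_cohort, definitions, "incompleteness",
                        seeds=[1, 2])
        for (name, target, seed), g in grid.rows.groupby(
                ["phenotype", "data_type_target", "replicate_seed"]):
            g = g.sort_values("level")
            assert (np.diff(g["n_identified"]) <= 0).all(), (name, target, seed)

    def test_ccw_invariant_to_rx_and_lab_perturbation(self, small_cohort, definitions):
        for axis, targets in (("incompleteness", ["RX", "LAB"]),
                              ("inaccuracy", ["LAB"])):
            grid = run_grid(small_cohort, definitions, axis,
                            data_type_targets=targets, seeds=[1])
            ccw = grid.rows[grid.rows["phenotype"] == "CCW"]
            assert ccw["n_identified"].nunique() == 1

    def test_scale_axis_only_moves_lab_backed_phenotypes(self, small_cohort, definitions):
        grid = run_grid(small_cohort, definitions, "inaccuracy",
                        levels=[0.0, -1.0], data_type_targets=["LAB"],
                        seeds=[1])
        full = grid.rows[grid.rows["level"] == -1.0]
        ccw = full[full["phenotype"] == "CCW"]
        assert (ccw["retention_fraction"] == 1.0).all()
        ddc = full[full["phenotype"] == "DDC"]
        assert (ddc["retention_fraction"] < 1.0).all()

    def test_missing_identity_level_rejected(self, small_cohort, definitions):
        with pytest.raises(ConfigError):
            run_grid(small_cohort, definitions, "incompleteness",
                     levels=[0.1, 0.5], data_type_targets=["DX"], seeds=[1])

    def test_timeliness_matches_per_patient_recomputation(self, definitions):
        cohort = generate_cohort(default_profile(300), seed=41)
        grid = run_grid(cohort, definitions, "timeliness",
                        levels=[0, 180, 365], data_type_targets=["DX"],
                        seeds=[1])
        from phenodq.perturbation import PerturbationSpec, apply
        for days in (0, 180, 365):
            shifted = apply(PerturbationSpec("shift_dates", ("DX",), days),
                            cohort)
            for defn in definitions:
                expected, _ = oracle_evaluate(defn, shifted)
                row = grid.rows[(grid.rows["phenotype"] == defn.name)
                                & (grid.rows["level"] == days)]
                assert int(row["n_identified"].iloc[0]) == len(expected), \
                    (defn.name, days)


class TestCharacteristics:
    def test_single_patient_statistics(self):
        c = make_cohort(["P1", "P2"], [])
        df = characteristics(c, {"P1"})
        by = df.set_index(["characteristic", "statistic"])["value"]
        assert by[("age", "mean")] == by[("age", "median")] == 57.0
        assert by[("age", "sd")] == 0.0
        assert not df.attrs["empty"]

    def test_percentages_sum_to_100_per_block(self, small_cohort):
        subset = set(small_cohort.patients["patient_id"][:200])
        df = characteristics(small_cohort, subset)
        for block in ("sex", "race", "ethnicity", "state"):
            pct = df[(df["characteristic"].str.startswith(f"{block}:"))
                     & (df["statistic"] == "percent")]["value"].sum()
            assert pct == pytest.approx(100.0, abs=1e-9)

    def test_full_cohort_mean_age_recovers_target(self, mid_cohort):
        subset = set(mid_cohort.patients["patient_id"])
        df = characteristics(mid_cohort, subset)
        by = df.set_index(["characteristic", "statistic"])["value"]
        n = mid_cohort.n_patients
        assert abs(by[("age", "mean")] - 62.4) < 3 * 15.4 / np.sqrt(n)

    def test_empty_subset_flagged(self, small_cohort):
        df = characteristics(small_cohort, set())
        assert df.attrs["empty"]

    def test_unknown_patient_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            characteristics(small_cohort, {"NOPE"})


class TestExportReport:
    def test_row_counts_and_determinism(self, tmp_path, small_cohort, definitions):
        grid = run_grid(small_cohort, definitions[:2], "incompleteness",
                        levels=[0.0, 0.5, 1.0], data_type_targets=["DX"],
                        seeds=[1])
        results = [evaluate_phenotype(d, small_cohort) for d in definitions]
        part = overlap_partition(results, small_cohort.n_patients)
        out1 = export_report([grid], [part], tmp_path / "a")
        out2 = export_report([grid], [part], tmp_path / "b")
        ret = pd.read_csv(tmp_path / "a" / "retention_incompleteness.csv")
        assert len(ret) == 2 * 3  # 2 phenotypes x 3 levels
        assert (tmp_path / "a" / "overlap_partition_0.csv").exists()
        for f1, f2 in zip(sorted(out1), sorted(out2)):
            assert f1.read_bytes() == f2.read_bytes()

    def test_empty_partitions_is_fine(self, tmp_path, small_cohort, definitions):
        grid = run_grid(small_cohort, definitions[:1], "incompleteness",
                        levels=[0.0], data_type_targets=["DX"], seeds=[1])
        written = export_report([grid], [], tmp_path)
        assert all("partition" not in p.name for p in written)

    def test_strata_table_shape(self, small_cohort, definitions):
        results = [evaluate_phenotype(d, small_cohort) for d in definitions]
        tbl = strata_table(results)
        assert len(tbl) == 5
        assert (tbl[list(tbl.columns[2:])].sum(axis=1)
                == tbl["n_identified"]).all()
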
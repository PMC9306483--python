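"""Exposure-activity ratios, their aggregates, and the endpoint-mixture screen."""

import math

import numpy as np
import pandas as pd
import pytest

import sedsieve as sv
from sedsieve.ear_screen import (
    acc_to_ug_per_L,
    aggregate_ear,
    annotate,
    compute_ear,
    flag_chemicals,
    priority_endpoints,
    required_site_count,
)

from conftest import make_measurements, make_registry


def make_acc(rows):
    """rows: (chemical_id, endpoint_id, acc_value, acc_unit, excluded)."""
    df = pd.DataFrame(
        rows, columns=["chemical_id", "endpoint_id", "acc_value", "acc_unit", "excluded"]
    )
    df["gene_symbol"] = "ESR1"
    df["exclusion_reason"] = np.where(df["excluded"], "flagged", "")
    return sv.tables_io.validate_acc(df)


def simple_porewater(rows):
    """rows: (site_id, chemical_id, c_pw, status)."""
    return pd.DataFrame(
        rows, columns=["site_id", "chemical_id", "c_pw_ug_L", "status"]
    )


class TestAccConversion:
    def test_micromolar_times_molecular_weight(self):
        reg = make_registry([{"chemical_id": "x", "mw_g_mol": 228.29}])
        acc = make_acc([("x", "e1", 1.0, "micromolar", False)])
        out = acc_to_ug_per_L(acc, reg)
        assert out.loc[0, "acc_ug_L"] == pytest.approx(228.29)

    def test_half_micromolar(self):
        reg = make_registry([{"chemical_id": "x", "mw_g_mol": 100.0}])
        acc = make_acc([("x", "e1", 0.5, "micromolar", False)])
        assert acc_to_ug_per_L(acc, reg).loc[0, "acc_ug_L"] == pytest.approx(50.0)

    def test_ug_per_L_passes_through(self):
        reg = make_registry([{"chemical_id": "x"}])
        acc = make_acc([("x", "e1", 7.25, "ug_L", False)])
        assert acc_to_ug_per_L(acc, reg).loc[0, "acc_ug_L"] == 7.25

    def test_micromolar_without_mw_dropped(self):
        reg = make_registry([{"chemical_id": "x", "mw_g_mol": np.nan}])
        acc = make_acc(
            [("x", "e1", 1.0, "micromolar", False), ("x", "e2", 3.0, "ug_L", False)]
        )
        out = acc_to_ug_per_L(acc, reg)
        assert list(out["endpoint_id"]) == ["e2"]


class TestComputeEar:
    def test_unit_ratio(self):
        reg = make_registry([{"chemical_id": "x"}])
        pw = simple_porewater([("s1", "x", 1.0, "ok")])
        acc = make_acc([("x", "e1", 1.0, "ug_L", False)])
        ear = compute_ear(pw, acc, reg)
        assert ear.loc[0, "ear"] == 1.0

    def test_excluded_rows_never_contribute(self):
        reg = make_registry([{"chemical_id": "x"}])
        pw = simple_porewater([("s1", "x", 5.0, "ok")])
        with_excluded = make_acc(
            [("x", "e1", 1.0, "ug_L", False), ("x", "e2", 1.0, "ug_L", True)]
        )
        without = make_acc([("x", "e1", 1.0, "ug_L", False)])
        pd.testing.assert_frame_equal(
            compute_ear(pw, with_excluded, reg), compute_ear(pw, without, reg)
        )

    def test_brute_force_on_small_cube(self):
        reg = make_registry(
            [{"chemical_id": "a", "mw_g_mol": 100.0}, {"chemical_id": "b", "mw_g_mol": 200.0}]
        )
        pw = simple_porewater(
            [
                ("s1", "a", 2.0, "ok"),
                ("s1", "b", 3.0, "ok"),
                ("s2", "a", 0.0, "censored"),
                ("s2", "b", 7.0, "ok"),
            ]
        )
        acc = make_acc(
            [
                ("a", "e1", 4.0, "ug_L", False),
                ("a", "e2", 0.05, "micromolar", False),  # 5 µg/L
                ("b", "e1", 6.0, "ug_L", False),
                ("b", "e2", 0.01, "micromolar", False),  # 2 µg/L
            ]
        )
        ear = compute_ear(pw, acc, reg).set_index(["site_id", "chemical_id", "endpoint_id"])
        expected = {
            ("s1", "a", "e1"): 0.5,
            ("s1", "a", "e2"): 0.4,
            ("s1", "b", "e1"): 0.5,
            ("s1", "b", "e2"): 1.5,
            ("s2", "a", "e1"): 0.0,
            ("s2", "a", "e2"): 0.0,
            ("s2", "b", "e1"): 7 / 6,
            ("s2", "b", "e2"): 3.5,
        }
        assert len(ear) == len(expected)
        for key, value in expected.items():
            assert ear.loc[key, "ear"] == pytest.approx(value)

    def test_non_ok_porewater_absent(self):
        reg = make_registry([{"chemical_id": "x"}])
        pw = simple_porewater([("s1", "x", np.nan, "no_koc")])
        acc = make_acc([("x", "e1", 1.0, "ug_L", False)])
        assert compute_ear(pw, acc, reg).empty


class TestAggregateEar:
    def _ear(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "chemical_id", "endpoint_id", "ear"])

    def test_max_over_endpoints(self):
        reg = make_registry([{"chemical_id": "a"}])
        agg = aggregate_ear(self._ear([("s1", "a", "e1", 0.2), ("s1", "a", "e2", 0.5)]), reg)
        assert agg["ear_max"].set_index(["site_id", "chemical_id"]).loc[("s1", "a"), "ear_max"] == 0.5

    def test_endpoint_additivity(self):
        reg = make_registry([{"chemical_id": "a"}, {"chemical_id": "b"}])
        agg = aggregate_ear(self._ear([("s1", "a", "e1", 0.3), ("s1", "b", "e1", 0.4)]), reg)
        ep = agg["ear_endpoint"].set_index(["site_id", "endpoint_id"])
        assert ep.loc[("s1", "e1"), "ear_endpoint"] == pytest.approx(0.7)

    def test_class_sums_partition_sample(self, default_study, default_results):
        agg = default_results.ear_aggregates
        np.testing.assert_allclose(
            agg["ear_class"].sum(axis=1), agg["ear_sample"], rtol=1e-12
        )

    def test_ear_max_bounded_by_endpoint_sum_per_chemical(self, default_results):
        ear = default_results.ear
        per_chem_sum = ear.groupby(["site_id", "chemical_id"])["ear"].sum()
        per_chem_max = ear.groupby(["site_id", "chemical_id"])["ear"].max()
        assert (per_chem_max <= per_chem_sum + 1e-15).all()


class TestFlagChemicals:
    def test_threshold_is_strict(self):
        ear_max = pd.DataFrame(
            {
                "site_id": ["s1", "s1", "s1"],
                "chemical_id": ["a", "b", "c"],
                "ear_max": [0.001, 0.0011, 0.0001],
            }
        )
        out = flag_chemicals(ear_max, 0.001)
        assert list(out["chemical_id"]) == ["b"]
        assert out.loc[0, "n_sites_exceeding"] == 1


class TestPriorityEndpoints:
    def test_prevalence_count_for_the_emulated_study(self):
        assert required_site_count(0.2, 71) == 14

    def test_small_study_floor_is_one(self):
        assert required_site_count(0.2, 3) == 1

    def test_endpoint_below_count_not_retained(self):
        rows = [(f"s{i}", "e1", 0.5) for i in range(13)]
        ep = pd.DataFrame(rows, columns=["site_id", "endpoint_id", "ear_endpoint"])
        ear = pd.DataFrame(columns=["site_id", "chemical_id", "endpoint_id", "ear"])
        summary, _ = priority_endpoints(ear, ep, n_sites=71)
        assert summary.empty

    @staticmethod
    def brute_force(ear_rows, n_sites, site_thr=0.1, prev=0.2, member_thr=0.001, major_thr=0.01):
        """Exhaustive enumeration over endpoints, sites and chemicals."""
        needed = max(1, math.floor(prev * n_sites))
        sums = {}
        for site, chem, endpoint, ear in ear_rows:
            sums[(site, endpoint)] = sums.get((site, endpoint), 0.0) + ear
        endpoints = {e for _, e in sums}
        retained = {}
        for endpoint in endpoints:
            exceeding = {s for (s, e), v in sums.items() if e == endpoint and v > site_thr}
            if len(exceeding) >= needed:
                retained[endpoint] = len(exceeding)
        members = {}
        for endpoint in retained:
            members[endpoint] = sorted(
                {
                    chem
                    for site, chem, e, ear in ear_rows
                    if e == endpoint and ear >= member_thr
                }
            )
        majors = {}
        for endpoint in retained:
            counts = {}
            for site, chem, e, ear in ear_rows:
                if e == endpoint and ear >= major_thr:
                    counts.setdefault(chem, set()).add(site)
            majors[endpoint] = sorted(c for c, s in counts.items() if len(s) >= needed)
        return retained, members, majors

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_sites = int(rng.integers(2, 7))
            n_chems = int(rng.integers(1, 6))
            n_eps = int(rng.integers(1, 6))
            rows = [
                (f"s{s}", f"c{c}", f"e{e}", float(rng.lognormal(-3, 2)))
                for s in range(n_sites)
                for c in range(n_chems)
                for e in range(n_eps)
                if rng.random() < 0.7
            ]
            ear = pd.DataFrame(rows, columns=["site_id", "chemical_id", "endpoint_id", "ear"])
            ep = (
                ear.groupby(["site_id", "endpoint_id"], as_index=False)["ear"]
                .sum()
                .rename(columns={"ear": "ear_endpoint"})
            )
            summary, membership = priority_endpoints(ear, ep, n_sites)
            retained, members, majors = self.brute_force(rows, n_sites)
            assert set(summary["endpoint_id"]) == set(retained)
            for _, row in summary.iterrows():
                e = row["endpoint_id"]
                assert row["n_sites_exceeding"] == retained[e]
                got_members = row["member_chemicals"].split(";") if row["member_chemicals"] else []
                assert got_members == members[e]
                got_majors = row["major_contributors"].split(";") if row["major_contributors"] else []
                assert got_majors == majors[e]


class TestAnnotate:
    def _report(self, endpoints):
        return pd.DataFrame(
            {
                "endpoint_id": endpoints,
                "n_sites_exceeding": [1] * len(endpoints),
                "member_chemicals": [""] * len(endpoints),
                "major_contributors": [""] * len(endpoints),
            }
        )

    def _map(self):
        return sv.tables_io.validate_aop_map(
            pd.DataFrame(
                {
                    "endpoint_id": ["e1"],
                    "gene_symbol": ["ESR1"],
                    "aop_ids": ["AOP:25;AOP:29"],
                    "annotation": ["estrogen receptor agonism"],
                }
            )
        )

    def test_mapped_endpoint_gets_both_aops(self):
        out = annotate(self._report(["e1"]), self._map())
        assert out.loc[0, "aop_ids"] == "AOP:25;AOP:29"
        assert out.loc[0, "gene_symbol"] == "ESR1"

    def test_unmapped_endpoint_retained_with_empty_annotation(self):
        out = annotate(self._report(["e1", "e9"]), self._map())
        assert len(out) == 2
        row = out.set_index("endpoint_id").loc["e9"]
        assert row["aop_ids"] == "" and row["gene_symbol"] == ""

    def test_cardinality_preserved(self, default_results, default_study):
        report = default_results.priority_endpoint_summary
        assert len(report) == report["endpoint_id"].nunique()
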
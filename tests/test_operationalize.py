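"""Cohort operationalization: birth counting, identification, linkage, funnel."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import pearson_chi2, welch_statistic
from conftest import make_path_network
from obstaccess.operationalize import (
    HospitalRecord,
    apply_exclusions,
    build_closure_cohort,
    categorize_density,
    categorize_fertility,
    chi_squared_test,
    cohort_frame,
    count_live_births,
    descriptive_table,
    identify_obstetric_sites,
    min_interfacility_time,
    welch_t_test,
)


def make_record(
    site_id="S1",
    departments=("2400",),
    procedures=None,
    teaching="no",
    ownership="public",
    facility_type="acute",
    year=2014,
    node=0,
    area="A1",
    whole_hospital_closed=False,
):
    return HospitalRecord(
        site_id=site_id,
        year=year,
        location=node,
        postal_area=area,
        departments=frozenset(departments),
        procedures=procedures if procedures is not None else {"9-262.0": 100},
        ownership=ownership,
        teaching=teaching,
        whole_hospital_closed=whole_hospital_closed,
        facility_type=facility_type,
    )


AREAS = {"A1": (300.0, 1.45), "A2": (80.0, 1.2), "A3": (1500.0, 1.7)}


class TestLiveBirthCounting:
    @pytest.mark.parametrize(
        "procedures, expected",
        [
            ({"9-262.0": 300, "9-262.1": 100}, 400),
            ({"5-740": 250}, 0),  # caesarean code is not a live-birth code
            ({"9-262": 10, "9-262.x": 1, "9-262.y": 2}, 13),
            ({"9-262.0": 0}, 0),
            ({}, 0),
            ({"9-262.0": 50, "5-740": 20, "9-262.y": 5}, 55),
        ],
    )
    def test_counts_only_listed_codes(self, procedures, expected):
        assert count_live_births(make_record(procedures=procedures)) == expected

    def test_malformed_code_warns_and_is_excluded(self):
        rec = make_record(procedures={"9-262.0": 10, "not a code!!": 99})
        with pytest.warns(UserWarning, match="malformed"):
            assert count_live_births(rec) == 10


class TestSiteIdentification:
    def test_department_and_birth_rules(self):
        gyn_no_births = make_record("G1", procedures={"5-740": 120})
        obstetrics_with_births = make_record("O1", procedures={"9-262.0": 10})
        pediatrics_only = make_record("P1", departments=("1000",), procedures={"9-262.0": 5})
        rehab = make_record("R1", facility_type="rehabilitation")
        day_care = make_record("D1", facility_type="day_care")
        kept = identify_obstetric_sites(
            [gyn_no_births, obstetrics_with_births, pediatrics_only, rehab, day_care]
        )
        assert [r.site_id for r in kept] == ["O1"]

    def test_empty_registry_is_not_an_error(self):
        assert identify_obstetric_sites([]) == []


class TestCategorizers:
    @pytest.mark.parametrize(
        "density, expected",
        [
            (50, "low"),
            (100, "low"),
            (100.001, "medium"),
            (300, "medium"),
            (750, "medium"),  # the printed rule's 500-1000 gap goes to medium
            (1000, "medium"),
            (1000.001, "high"),
            (1500, "high"),
            (0, "low"),
        ],
    )
    def test_density_cutpoints(self, density, expected):
        assert categorize_density(density) == expected

    def test_density_rejects_negative(self):
        with pytest.raises(ValueError):
            categorize_density(-1.0)

    @pytest.mark.parametrize(
        "rate, expected",
        [(1.3, "low"), (1.2, "low"), (1.45, "medium"), (1.6, "medium"), (1.61, "high")],
    )
    def test_fertility_cutpoints(self, rate, expected):
        assert categorize_fertility(rate) == expected

    @pytest.mark.parametrize("rate", [0.0, -0.5, math.nan])
    def test_fertility_rejects_nonpositive(self, rate):
        with pytest.raises(ValueError):
            categorize_fertility(rate)


class TestMinInterfacilityTime:
    def test_two_sites_single_edge_symmetric(self):
        net = make_path_network([12.0])
        times = min_interfacility_time(net, {"a": 0, "b": 1})
        assert times == {"a": 12.0, "b": 12.0}

    def test_path_graph_three_sites(self):
        # A-(5)-B-(7)-C: nearest-other times are A:5, B:5, C:7.
        net = make_path_network([5.0, 7.0])
        times = min_interfacility_time(net, {"A": 0, "B": 1, "C": 2})
        assert times == {"A": 5.0, "B": 5.0, "C": 7.0}

    def test_single_site_infinite_with_warning(self):
        net = make_path_network([5.0])
        with pytest.warns(UserWarning, match="single obstetric site"):
            times = min_interfacility_time(net, {"only": 0})
        assert math.isinf(times["only"])

    def test_sites_only_on_intermediate_nodes(self):
        # A-(1)-x-(2)-B-(10)-C: A and B are 3 apart through a non-site node.
        net = make_path_network([1.0, 2.0, 10.0])
        times = min_interfacility_time(net, {"A": 0, "B": 2, "C": 3})
        assert times == {"A": 3.0, "B": 3.0, "C": 10.0}

    def test_matches_pairwise_dijkstra_on_random_graphs(self, rng):
        import networkx as nx

        from _oracles import random_connected_graph
        from obstaccess.network import RoadNetwork

        for trial in range(10):
            g = random_connected_graph(rng, int(rng.integers(4, 12)))
            for n in g.nodes:
                g.nodes[n]["x"] = float(n)
                g.nodes[n]["y"] = 0.0
            net = RoadNetwork(g)
            k = int(rng.integers(2, g.number_of_nodes() + 1))
            site_nodes = {
                f"s{i}": int(n)
                for i, n in enumerate(rng.choice(list(g.nodes), size=k, replace=False))
            }
            got = min_interfacility_time(net, site_nodes)
            for sid, node in site_nodes.items():
                expected = min(
                    nx.shortest_path_length(g, node, other, weight="time")
                    for osid, other in site_nodes.items()
                    if osid != sid
                )
                assert got[sid] == pytest.approx(expected, abs=1e-9)

    def test_colocated_sites_are_zero_minutes_apart(self):
        net = make_path_network([5.0])
        times = min_interfacility_time(net, {"a": 0, "b": 0, "c": 1})
        assert times["a"] == 0.0 and times["b"] == 0.0
        assert times["c"] == 5.0


class TestClosureCohort:
    def _registries(self):
        base = [
            make_record("H1", node=0, area="A1"),
            make_record("H2", node=1, area="A2", departments=("2400", "1000")),
            make_record("H3", node=2, area="A3"),
        ]
        follow = [make_record("H1", node=0, area="A1", year=2019)]
        # H2 loses obstetrics but stays open; H3 vanishes entirely.
        follow_full = follow + [
            make_record("H2", node=1, area="A2", year=2019, departments=("0100",), procedures={})
        ]
        return base, follow, follow_full

    def test_closure_and_total_closure_flags(self):
        base, follow, follow_full = self._registries()
        net = make_path_network([5.0, 7.0])
        cohort = build_closure_cohort(
            base, follow, AREAS, network=net, followup_full_registry=follow_full
        )
        by_id = {r.site_id: r for r in cohort}
        assert not by_id["H1"].closed_by_followup
        assert by_id["H2"].closed_by_followup and not by_id["H2"].total_hospital_closure
        assert by_id["H3"].closed_by_followup and by_id["H3"].total_hospital_closure

    def test_whole_closure_flag_alone_marks_total(self):
        base = [make_record("H1", node=0), make_record("H2", node=1, area="A2")]
        follow = [make_record("H1", node=0, year=2019)]
        follow_full = follow + [
            make_record(
                "H2", node=1, area="A2", year=2019, departments=("0100",),
                procedures={}, whole_hospital_closed=True,
            )
        ]
        cohort = build_closure_cohort(
            base, follow, AREAS, network=make_path_network([3.0]),
            followup_full_registry=follow_full,
        )
        h2 = next(r for r in cohort if r.site_id == "H2")
        assert h2.closed_by_followup and h2.total_hospital_closure

    def test_identical_registries_mean_no_closures(self):
        base, _, _ = self._registries()
        cohort = build_closure_cohort(base, base, AREAS, network=make_path_network([5.0, 7.0]))
        assert sum(r.closed_by_followup for r in cohort) == 0

    def test_duplicate_site_id_fails(self):
        base = [make_record("H1", node=0), make_record("H1", node=1)]
        with pytest.raises(ValueError, match="duplicate site_id"):
            build_closure_cohort(base, base, AREAS)

    def test_missing_area_attributes_fail_with_site_name(self):
        base = [make_record("H1", node=0, area="NOWHERE"), make_record("H2", node=1)]
        with pytest.raises(ValueError, match="H1"):
            build_closure_cohort(base, base, AREAS, network=make_path_network([2.0]))

    def test_rerun_is_bit_identical(self):
        base, follow, follow_full = self._registries()
        net = make_path_network([5.0, 7.0])
        a = build_closure_cohort(base, follow, AREAS, network=net,
                                 followup_full_registry=follow_full)
        b = build_closure_cohort(base, follow, AREAS, network=net,
                                 followup_full_registry=follow_full)
        assert cohort_frame(a).equals(cohort_frame(b))


class TestExclusions:
    def _cohort(self):
        base = [
            make_record("U1", teaching="university", node=0),
            make_record("N1", node=1, area="A2"),
            make_record("N2", node=2, area="A3"),
        ]
        return build_closure_cohort(base, base, AREAS, network=make_path_network([4.0, 6.0]))

    def test_university_rows_removed(self):
        kept, log = apply_exclusions(self._cohort())
        assert {r.site_id for r in kept} == {"N1", "N2"}
        assert log == {
            "input_rows": 3,
            "excluded_university": 1,
            "excluded_total_closure": 0,
            "regression_rows": 2,
        }

    def test_no_exclusions_is_identity(self):
        cohort = [r for r in self._cohort() if r.teaching != "university"]
        kept, log = apply_exclusions(cohort)
        assert kept == cohort and log["regression_rows"] == len(cohort)

    def test_all_university_warns_and_returns_empty(self):
        cohort = [r for r in self._cohort() if r.teaching == "university"]
        with pytest.warns(UserWarning, match="every cohort row"):
            kept, _ = apply_exclusions(cohort)
        assert kept == []


class TestDescriptiveStatistics:
    def test_identical_samples_welch(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_uniform_contingency_table(self):
        stat, p, reliable = chi_squared_test(np.array([[10, 10], [10, 10]]))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0) and reliable

    def test_welch_matches_textbook_formula(self):
        a = [4.2, 5.1, 6.3, 5.9, 4.8]
        b = [3.1, 4.4, 3.9, 5.2, 4.0]
        t_ours, _ = welch_t_test(a, b)
        t_oracle, _ = welch_statistic(a, b)
        assert t_ours == pytest.approx(t_oracle, abs=1e-6)

    def test_chi2_matches_textbook_formula(self):
        table = np.array([[12, 30, 18], [25, 22, 13]], float)
        stat, _, reliable = chi_squared_test(table)
        assert reliable
        assert stat == pytest.approx(pearson_chi2(table), abs=1e-6)

    def test_zero_expected_count_flagged_unreliable(self):
        stat, p, reliable = chi_squared_test(np.array([[5, 0], [7, 0]], float))
        assert not reliable

    def test_table_layout(self):
        df_a = pd.DataFrame(
            {
                "live_births": [100, 200, 300],
                "min_interfacility_time": [5.0, 10.0, 20.0],
                "ownership": ["public", "private", "public"],
                "has_pediatrics": [True, False, True],
                "teaching": ["no", "yes", "no"],
                "density_category": ["low", "high", "medium"],
            }
        )
        df_b = df_a.copy()
        out = descriptive_table(df_a, df_b)
        assert set(out["kind"]) == {"continuous", "categorical"}
        cont = out[out["kind"] == "continuous"]
        assert np.allclose(cont["p_value"], 1.0)
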
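"""Co-selection networks: construction, from-scratch centralities versus
exhaustive and networkx oracles, density and complexity associations."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ipcnet import (
    ROSTER_NAMES,
    ResponseTable,
    betweenness_centrality,
    build_all_networks,
    build_network,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    density_vs_complexity,
    export_edge_list,
    export_graphml,
    network_density,
    preprocess,
    quintile_cases,
    simulate_cohort,
)
from ipcnet.network import CoSelectionNetwork


def _net(edges, nodes=None):
    """Ad-hoc network over integer-named nodes for centrality tests."""
    nodes = tuple(nodes) if nodes is not None else tuple(
        sorted({v for e in edges for v in e})
    )
    counts = {v: 1 for e in edges for v in e}  # only endpoints ever selected
    weights = {tuple(sorted(e)): 1 for e in edges}
    return CoSelectionNetwork(
        case_id=0, n_responders=1, selection_counts=counts,
        edge_weights=weights, nodes=nodes,
    )


def _records(study_design, selections_by_respondent, case_id=82):
    rows = []
    for rid, sels in selections_by_respondent.items():
        rows.append({"respondent_id": rid, "case_id": case_id, "perceived": 50.0,
                     "inclination": 50.0, "meeting": 2 if sels else 1,
                     "selections": ";".join(sels)})
    return ResponseTable(records=pd.DataFrame(rows), design=study_design)


def brute_force_betweenness(net: CoSelectionNetwork) -> dict:
    """Exhaustive oracle: enumerate every shortest path between every pair
    and split credit equally among paths."""
    adj = net.adjacency()
    nodes = list(net.nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS distance
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            continue
        paths = []

        def extend(path):
            v = path[-1]
            if v == t:
                paths.append(path)
                return
            for w in adj[v]:
                if dist.get(w, -1) == dist[v] + 1:
                    extend(path + [w])

        extend([s])
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


class TestBuildNetwork:
    def test_complete_agreement_triangle(self, study_design):
        table = _records(study_design, {
            "a": ["parent", "paediatric nurse", "paediatrician"],
            "b": ["parent", "paediatric nurse", "paediatrician"],
            "c": ["parent", "paediatric nurse", "paediatrician"],
        })
        net = build_network(table, 82)
        assert net.n_responders == 3
        assert net.n_edges == 3
        assert all(w == 3 for w in net.edge_weights.values())
        props = net.selection_proportions
        assert props["parent"] == 1.0 and props["dietician"] == 0.0

    def test_disjoint_singletons_give_no_edges(self, study_design):
        table = _records(study_design, {"a": ["parent"], "b": ["dietician"]})
        net = build_network(table, 82)
        assert net.n_edges == 0
        assert all(d == 0 for d in degree_centrality(net).values())

    def test_cooccurrence_definition(self, study_design):
        table = _records(study_design, {
            "a": ["parent", "paediatrician"],
            "b": ["paediatrician", "dietician"],
        })
        net = build_network(table, 82)
        assert set(net.edge_weights) == {
            ("paediatrician", "parent"), ("dietician", "paediatrician")
        }

    def test_only_meeting_records_contribute(self, study_design):
        table = _records(study_design, {"a": ["parent", "paediatrician"], "b": []})
        net = build_network(table, 82)
        assert net.n_responders == 1

    def test_zero_responders_flagged_empty(self, study_design):
        table = _records(study_design, {"a": []})
        net = build_network(table, 82)
        assert net.n_responders == 0 and net.n_edges == 0
        assert math.isnan(net.selection_proportions["parent"])

    def test_edge_threshold(self, study_design):
        table = _records(study_design, {
            "a": ["parent", "paediatrician"],
            "b": ["parent", "paediatrician"],
            "c": ["parent", "dietician"],
        })
        net = build_network(table, 82, edge_threshold=2)
        assert set(net.edge_weights) == {("paediatrician", "parent")}

    def test_network_validation(self):
        with pytest.raises(ValueError, match="self-edge"):
            CoSelectionNetwork(case_id=0, n_responders=1,
                               selection_counts={"parent": 1},
                               edge_weights={("parent", "parent"): 1})
        with pytest.raises(ValueError, match="exceeds"):
            CoSelectionNetwork(case_id=0, n_responders=2,
                               selection_counts={"parent": 1, "dietician": 2},
                               edge_weights={("dietician", "parent"): 2})


class TestCentralities:
    def test_star_degrees(self):
        net = _net([(0, 1), (0, 2), (0, 3)])
        dc = degree_centrality(net)
        assert dc[0] == 3 and dc[1] == dc[2] == dc[3] == 1

    def test_path_betweenness_and_closeness(self):
        net = _net([("a", "b"), ("b", "c")])
        bc = betweenness_centrality(net)
        assert bc == {"a": 0.0, "b": 1.0, "c": 0.0}
        cc = closeness_centrality(net)
        assert cc["a"] == pytest.approx(1 / 3)
        assert cc["b"] == pytest.approx(1 / 2)

    def test_four_cycle_betweenness(self):
        net = _net([(0, 1), (1, 2), (2, 3), (3, 0)])
        bc = betweenness_centrality(net)
        assert all(v == pytest.approx(0.5) for v in bc.values())

    def test_isolated_member_has_undefined_closeness(self):
        net = _net([(0, 1)], nodes=(0, 1, 2))
        cc = closeness_centrality(net)
        assert math.isnan(cc[2])
        assert degree_centrality(net)[2] == 0

    def test_hub_on_connected_fifteen_node_graph(self):
        # member adjacent to all 14 others: distance 1 to everyone -> 1/14
        edges = [("parent", m) for m in ROSTER_NAMES if m != "parent"]
        net = _net(edges, nodes=ROSTER_NAMES)
        assert closeness_centrality(net)["parent"] == pytest.approx(1 / 14)

    def test_brandes_equals_brute_force_and_networkx(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 9))
            p = float(rng.uniform(0.15, 0.8))
            edges = [(i, j) for i, j in itertools.combinations(range(n), 2)
                     if rng.random() < p]
            net = _net(edges, nodes=tuple(range(n)))
            ours = betweenness_centrality(net)
            brute = brute_force_betweenness(net)
            for v in net.nodes:
                assert ours[v] == pytest.approx(brute[v], abs=1e-9)
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            g.add_edges_from(edges)
            ref = nx.betweenness_centrality(g, normalized=False)
            for v in net.nodes:
                assert ours[v] == pytest.approx(ref[v], abs=1e-9)

    def test_closeness_matches_networkx_per_component(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            edges = [(i, j) for i, j in itertools.combinations(range(n), 2)
                     if rng.random() < 0.4]
            net = _net(edges, nodes=tuple(range(n)))
            ours = closeness_centrality(net)
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            g.add_edges_from(edges)
            # networkx reports (reachable)/(n-1) * (reachable/sum d); undo to 1/sum d
            for v in net.nodes:
                reach = [u for u in net.nodes
                         if u != v and nx.has_path(g, v, u)]
                if not reach:
                    assert math.isnan(ours[v])
                else:
                    total = sum(nx.shortest_path_length(g, v, u) for u in reach)
                    assert ours[v] == pytest.approx(1.0 / total)

    def test_degree_sum_is_twice_edge_count(self, cohort):
        for net in build_all_networks(cohort).values():
            assert sum(degree_centrality(net).values()) == 2 * net.n_edges


class TestDensity:
    def test_complete_roster_graph(self):
        edges = list(itertools.combinations(ROSTER_NAMES, 2))
        net = _net(edges, nodes=ROSTER_NAMES)
        assert network_density(net).density == pytest.approx(1.0)

    def test_triangle_on_full_roster_base(self):
        net = _net([("parent", "paediatric nurse"),
                    ("paediatric nurse", "paediatrician"),
                    ("parent", "paediatrician")], nodes=ROSTER_NAMES)
        rec = network_density(net)
        assert rec.density == pytest.approx(2 * 3 / (15 * 14))
        observed = network_density(net, node_base="observed")
        assert observed.density == pytest.approx(1.0)
        assert observed.n_nodes == 3

    def test_empty_network_density_zero(self):
        net = _net([], nodes=ROSTER_NAMES)
        assert network_density(net).density == 0.0

    def test_adding_an_edge_increases_density(self):
        a = _net([("parent", "dietician")], nodes=ROSTER_NAMES)
        b = _net([("parent", "dietician"), ("dietician", "psychologist")],
                 nodes=ROSTER_NAMES)
        assert network_density(b).density > network_density(a).density

    def test_single_node_base_rejected(self):
        net = _net([], nodes=("parent",))
        with pytest.raises(ValueError, match="fewer than 2"):
            network_density(net)


class TestComplexityAssociations:
    def test_positive_selection_slopes_give_positive_taus(
        self, study_design, default_params
    ):
        table = simulate_cohort(study_design, 110, default_params, seed=21)
        proc = preprocess(table)
        nets = build_all_networks(table)
        taus = density_vs_complexity(nets, study_design, proc)
        assert all(res.tau > 0 for res in taus.values())

    def test_flat_selection_slopes_give_weak_taus(self, study_design, default_params):
        from ipcnet import MemberPropensity
        flat = {m: MemberPropensity(p.a, 0.0)
                for m, p in default_params.member_propensities.items()}
        params = default_params.replace(
            member_propensities=flat,
            meeting_intercept_mean=1.0, meeting_slope_mean=0.0, meeting_slope_sd=0.0,
        )
        taus = []
        for seed in range(8):
            table = simulate_cohort(study_design, 110, params, seed=100 + seed)
            proc = preprocess(table)
            taus.append(density_vs_complexity(
                build_all_networks(table), study_design, proc
            )["density~sum"].tau)
        assert abs(np.mean(taus)) < 0.25


class TestDisplayCases:
    def test_quintile_cases_match_published_selection(self, study_design):
        assert quintile_cases(study_design) == (82, 21, 60, 201, 153)

    def test_centrality_table_shape(self, cohort, study_design):
        nets = {cid: build_network(cohort, cid) for cid in quintile_cases(study_design)}
        table = centrality_table(nets)
        assert len(table) == 5 * 16  # 15 members + summary row per case
        members = table[table["member"] != "median (IQR)"]
        assert set(members["member"]) == set(ROSTER_NAMES)
        assert members["DC"].between(0, 14).all()

    def test_degree_spread_narrows_with_complexity(self, study_design, default_params):
        table = simulate_cohort(study_design, 110, default_params, seed=33)
        low = build_network(table, 82)
        high = build_network(table, 153)
        dc_low = np.array(list(degree_centrality(low).values()))
        dc_high = np.array(list(degree_centrality(high).values()))
        assert dc_low.max() - dc_low.min() > dc_high.max() - dc_high.min()
        assert dc_high.min() > dc_low.min()


class TestExports:
    def test_edge_list_round_trip(self, tmp_path, cohort):
        net = build_network(cohort, 153)
        path = tmp_path / "edges.csv"
        export_edge_list(net, path)
        loaded = pd.read_csv(path)
        assert len(loaded) == net.n_edges
        back = {tuple(sorted((r.member_a, r.member_b))): r.weight
                for r in loaded.itertuples()}
        assert back == net.edge_weights

    def test_graphml_preserves_attributes(self, tmp_path, cohort):
        net = build_network(cohort, 153)
        path = tmp_path / "net.graphml"
        export_graphml(net, path)
        g = nx.read_graphml(path)
        assert set(g.nodes) == set(ROSTER_NAMES)
        for m in net.nodes:
            assert g.nodes[m]["selection_count"] == net.selection_counts.get(m, 0)
        for (u, v), w in net.edge_weights.items():
            assert g.edges[u, v]["weight"] == w
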
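"""Co-selection networks of interprofessional-team members.

For each case, respondents who indicated the need for a team meeting chose
roster members who should "certainly be present".  The co-selection network
for a case has the 15 roster members as nodes; node weight is the
proportion of those responders selecting the member, and an edge joins two
members iff at least one responder selected both, weighted by the number of
such responders.

Individual importance is quantified on the binarized (edge-presence) graph:

* degree centrality (DC): number of distinct co-occurrence partners;
* betweenness centrality (BC): unnormalized shortest-path betweenness
  (fractional counting over multiple shortest paths, endpoints excluded),
  computed with Brandes' dependency-accumulation algorithm;
* closeness centrality (CC): 1 / (sum of shortest-path distances to the
  other members of the node's connected component); undefined (NaN) for
  isolated members.

Team cohesion is network density 2E / (N(N-1)) with N the full 15-member
roster by default (the observed-member base is available as an option).

All centralities and density are authored here; networkx is used in the
test suite as an independent cross-check and for GraphML export only.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SELECTION_SEP, ResponseTable
from .roster import ROSTER_NAMES
from .stats import KendallResult, kendall_tau_b


@dataclass(frozen=True)
class CoSelectionNetwork:
    """Per-case roster graph: selection counts/proportions on nodes,
    co-selection counts on edges."""

    case_id: int
    n_responders: int
    selection_counts: dict[str, int]
    edge_weights: dict[tuple[str, str], int]  # keys sorted pairs, weight >= threshold
    nodes: tuple[str, ...] = field(default=ROSTER_NAMES)

    def __post_init__(self) -> None:
        for (u, v), w in self.edge_weights.items():
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            if (u, v) != tuple(sorted((u, v))):
                raise ValueError(f"edge key {(u, v)} not in sorted order")
            cap = min(self.selection_counts.get(u, 0), self.selection_counts.get(v, 0))
            if w > cap:
                raise ValueError(f"edge weight {w} exceeds endpoint selection counts for {(u, v)}")

    @property
    def selection_proportions(self) -> dict[str, float]:
        if self.n_responders == 0:
            return {m: float("nan") for m in self.nodes}
        return {m: self.selection_counts.get(m, 0) / self.n_responders for m in self.nodes}

    @property
    def n_edges(self) -> int:
        return len(self.edge_weights)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {m: set() for m in self.nodes}
        for u, v in self.edge_weights:
            adj[u].add(v)
            adj[v].add(u)
        return adj


def build_network(
    table: ResponseTable, case_id: int, *, edge_threshold: int = 1
) -> CoSelectionNetwork:
    """Build the co-selection network of one case from questionnaire records.

    Only records with meeting = 2 contribute.  An edge is kept when its
    co-selection count reaches ``edge_threshold`` (default 1).
    """
    if case_id not in table.design.case_ids:
        raise ValueError(f"case {case_id} is not in the design")
    if edge_threshold < 1:
        raise ValueError("edge_threshold must be >= 1")
    recs = table.records
    recs = recs[(recs["case_id"] == case_id) & (recs["meeting"] == 2)]
    counts: dict[str, int] = {}
    weights: dict[tuple[str, str], int] = {}
    roster = set(ROSTER_NAMES)
    for sel in recs["selections"].fillna(""):
        names = [m for m in str(sel).split(SELECTION_SEP) if m] if sel else []
        unknown = set(names) - roster
        if unknown:
            raise ValueError(f"selections contain non-roster members: {sorted(unknown)}")
        for m in names:
            counts[m] = counts.get(m, 0) + 1
        for u, v in itertools.combinations(sorted(set(names)), 2):
            weights[(u, v)] = weights.get((u, v), 0) + 1
    weights = {e: w for e, w in weights.items() if w >= edge_threshold}
    return CoSelectionNetwork(
        case_id=case_id,
        n_responders=len(recs),
        selection_counts=counts,
        edge_weights=weights,
    )


def degree_centrality(net: CoSelectionNetwork) -> dict[str, int]:
    """Distinct co-occurrence partners per member (edge presence, not weight)."""
    return {m: len(nbrs) for m, nbrs in net.adjacency().items()}


def _bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def betweenness_centrality(net: CoSelectionNetwork) -> dict[str, float]:
    """Unnormalized shortest-path betweenness by Brandes' algorithm.

    Single-source BFS builds the shortest-path DAG and path counts; the
    dependency accumulation sums each node's fractional share of shortest
    paths between all other pairs.  On an undirected graph every pair is
    visited from both endpoints, so the accumulated total is halved.
    """
    adj = net.adjacency()
    bc = {v: 0.0 for v in net.nodes}
    for s in net.nodes:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in net.nodes}
        sigma = {v: 0.0 for v in net.nodes}
        sigma[s] = 1.0
        dist = {v: -1 for v in net.nodes}
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = {v: 0.0 for v in net.nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return {v: x / 2.0 for v, x in bc.items()}


def closeness_centrality(net: CoSelectionNetwork) -> dict[str, float]:
    """Unnormalized closeness 1 / sum(distances), restricted to the member's
    connected component; NaN for isolated members."""
    adj = net.adjacency()
    cc = {}
    for v in net.nodes:
        dist = _bfs_distances(adj, v)
        total = sum(dist.values())  # d(v, v) = 0 contributes nothing
        cc[v] = 1.0 / total if total > 0 else float("nan")
    return cc


@dataclass(frozen=True)
class DensityRecord:
    case_id: int
    density: float
    n_edges: int
    n_nodes: int


def network_density(net: CoSelectionNetwork, node_base: str = "full_roster") -> DensityRecord:
    """Cohesion as 2E / (N(N-1)).

    ``node_base="full_roster"`` (default) uses all 15 roster members as N;
    ``"observed"`` uses only members selected at least once.
    """
    if node_base == "full_roster":
        n = len(net.nodes)
    elif node_base == "observed":
        n = sum(1 for m in net.nodes if net.selection_counts.get(m, 0) > 0)
    else:
        raise ValueError(f"node_base must be 'full_roster' or 'observed', got {node_base!r}")
    if n < 2:
        raise ValueError(f"density undefined for fewer than 2 nodes (N={n})")
    e = net.n_edges
    return DensityRecord(
        case_id=net.case_id, density=2.0 * e / (n * (n - 1)), n_edges=e, n_nodes=n
    )


def build_all_networks(
    table: ResponseTable, *, edge_threshold: int = 1
) -> dict[int, CoSelectionNetwork]:
    """One co-selection network per design case."""
    return {
        cid: build_network(table, cid, edge_threshold=edge_threshold)
        for cid in table.design.case_ids
    }


def density_vs_complexity(
    networks: dict[int, CoSelectionNetwork],
    design,
    processed: pd.DataFrame,
    *,
    node_base: str = "full_roster",
) -> dict[str, KendallResult]:
    """Kendall tau-b of per-case network density against modelled sum score,
    modelled product score and case-averaged MC perceived complexity."""
    if len(networks) < 3:
        raise ValueError("need at least 3 case networks")
    frame = design.to_frame().set_index("case_id")
    cids = [cid for cid in design.case_ids if cid in networks]
    dens = [network_density(networks[c], node_base).density for c in cids]
    perceived = processed.groupby("case_id")["mc_perceived"].mean()
    return {
        "density~sum": kendall_tau_b(frame.loc[cids, "sum_score"], dens),
        "density~product": kendall_tau_b(frame.loc[cids, "product_score"], dens),
        "density~perceived": kendall_tau_b(perceived.reindex(cids), dens),
    }


def quintile_cases(design) -> tuple[int, ...]:
    """The five display cases at the minimum, lower quartile, median, upper
    quartile and maximum of modelled complexity (sum score; product score
    then case id break ties), distinct by construction on a strictly ordered
    design."""
    frame = (
        design.to_frame()
        .sort_values(["sum_score", "product_score", "case_id"])
        .reset_index(drop=True)
    )
    n = len(frame)
    idx = sorted({0, round((n - 1) * 0.25), round((n - 1) * 0.5), round((n - 1) * 0.75), n - 1})
    cids = tuple(int(frame.loc[i, "case_id"]) for i in idx)
    if len(cids) < 5:
        raise ValueError("design too small for five distinct quintile cases")
    return cids


def centrality_table(networks: dict[int, CoSelectionNetwork]) -> pd.DataFrame:
    """DC/BC/CC per roster member per case, long format, with per-case
    median and IQR appended as summary rows (member = "median (IQR)")."""
    rows = []
    for cid, net in networks.items():
        dc = degree_centrality(net)
        bc = betweenness_centrality(net)
        cc = closeness_centrality(net)
        for m in net.nodes:
            rows.append({"case_id": cid, "member": m, "DC": dc[m], "BC": bc[m], "CC": cc[m]})
        per = pd.DataFrame({"DC": dc, "BC": bc, "CC": cc})
        med = per.median()
        iqr = per.quantile(0.75) - per.quantile(0.25)
        rows.append(
            {
                "case_id": cid, "member": "median (IQR)",
                "DC": f"{med['DC']:g} ({iqr['DC']:g})",
                "BC": f"{med['BC']:.3f} ({iqr['BC']:.3f})",
                "CC": f"{med['CC']:.3f} ({iqr['CC']:.3f})",
            }
        )
    return pd.DataFrame(rows)


def export_edge_list(net: CoSelectionNetwork, path: str | Path) -> None:
    """Edge-list CSV: member_a, member_b, weight."""
    rows = [
        {"member_a": u, "member_b": v, "weight": w}
        for (u, v), w in sorted(net.edge_weights.items())
    ]
    pd.DataFrame(rows, columns=["member_a", "member_b", "weight"]).to_csv(path, index=False)


def export_graphml(net: CoSelectionNetwork, path: str | Path) -> None:
    """GraphML with node attributes selection_count and selection_proportion
    and edge attribute weight."""
    import networkx as nx

    g = nx.Graph()
    props = net.selection_proportions
    for m in net.nodes:
        g.add_node(
            m,
            selection_count=int(net.selection_counts.get(m, 0)),
            selection_proportion=float(props[m]),
        )
    for (u, v), w in net.edge_weights.items():
        g.add_edge(u, v, weight=int(w))
    nx.write_graphml(g, path)
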
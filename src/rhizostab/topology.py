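"""Node- and network-level topology: degree, closeness, modularity, hubs.

Closeness centrality uses the component-scaled (Wasserman-Faust)
convention so its values are comparable network-wide even when the
co-occurrence graph is disconnected, which keeps the field's hub
threshold (closeness > 0.25) meaningful.  Module detection is Louvain
modularity maximisation with a fixed seed and sorted node order for
stable tie-breaking; relative modularity compares the observed
modularity with degree-preserving rewired (Maslov-Sneppen) null graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("rhizostab")


@dataclass
class TopologyReport:
    """Per-node and network-level topological descriptors."""

    nodes: pd.DataFrame  # index node; degree, closeness, module, kingdom, is_hub
    n_nodes: int
    n_edges: int
    average_degree: float
    modularity: float
    relative_modularity: float | None
    rand_modularity_mean: float | None
    rand_modularity_sd: float | None
    hubs: list[str]

    def write(self, node_path: str | Path, summary_path: str | Path) -> None:
        self.nodes.to_csv(node_path, sep="\t", index_label="node")
        pd.DataFrame(
            {
                "n_nodes": [self.n_nodes],
                "n_edges": [self.n_edges],
                "average_degree": [self.average_degree],
                "modularity": [self.modularity],
                "relative_modularity": [self.relative_modularity],
                "rand_modularity_mean": [self.rand_modularity_mean],
                "rand_modularity_sd": [self.rand_modularity_sd],
                "n_hubs": [len(self.hubs)],
            }
        ).to_csv(summary_path, sep="\t", index=False)


def degree_and_closeness(net: nx.Graph, convention: str = "wf") -> pd.DataFrame:
    """Per-node degree and closeness centrality.

    ``convention="wf"`` (default) scales closeness of node v by
    (n_v - 1)/(N - 1) where n_v is v's component size, so isolated nodes
    get 0 and values stay in [0, 1]; ``convention="component"`` uses the
    unscaled within-component closeness.
    """
    if net.number_of_nodes() < 1:
        raise ValueError("network has no nodes")
    if convention == "wf":
        closeness = nx.closeness_centrality(net, wf_improved=True)
    elif convention == "component":
        closeness = nx.closeness_centrality(net, wf_improved=False)
    else:
        raise ValueError(f"unknown closeness convention {convention!r}")
    degree = dict(net.degree())
    return pd.DataFrame(
        {"degree": pd.Series(degree), "closeness": pd.Series(closeness)}
    ).loc[list(net.nodes())]


def detect_modules(net: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Louvain module assignment and its Newman-Girvan modularity.

    Deterministic given ``seed``: the graph is rebuilt with sorted node
    order before the heuristic runs.
    """
    if net.number_of_edges() == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    h = nx.Graph()
    h.add_nodes_from(sorted(net.nodes()))
    h.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges()))
    communities = nx.community.louvain_communities(h, seed=seed)
    modularity = nx.community.modularity(h, communities)
    assignment = {
        node: idx for idx, comm in enumerate(communities) for node in comm
    }
    return assignment, float(modularity)


def relative_modularity(
    net: nx.Graph, n_random: int = 100, seed: int = 0
) -> tuple[float, float, float]:
    """RM = (M_obs - mean(M_rand)) / mean(M_rand) against a rewired null.

    Null graphs are degree-preserving Maslov-Sneppen double-edge-swap
    randomisations (10 * |E| swaps each).  When rewiring is impossible
    (e.g. a star), an Erdos-Renyi G(n, E) null with the same node and
    edge count is used instead, with a log message.  Returns
    (RM, mean(M_rand), sd(M_rand)).
    """
    if net.number_of_edges() < 2:
        raise ValueError("relative modularity needs >= 2 edges")
    _, m_obs = detect_modules(net, seed=seed)
    rng = np.random.default_rng(seed)
    m_rand = []
    for r in range(n_random):
        h = nx.Graph()
        h.add_nodes_from(sorted(net.nodes()))
        h.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges()))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            nx.double_edge_swap(
                h,
                nswap=10 * net.number_of_edges(),
                max_tries=200 * net.number_of_edges() + 100,
                seed=sub_seed,
            )
        except nx.NetworkXException:
            logger.warning(
                "relative_modularity: degree-preserving rewiring impossible; "
                "falling back to an Erdos-Renyi null with matched n, E"
            )
            h = nx.gnm_random_graph(
                net.number_of_nodes(), net.number_of_edges(), seed=sub_seed
            )
            if h.number_of_edges() == 0:
                continue
        _, m = detect_modules(h, seed=sub_seed)
        m_rand.append(m)
    mean = float(np.mean(m_rand))
    sd = float(np.std(m_rand, ddof=1)) if len(m_rand) > 1 else 0.0
    if mean == 0:
        raise ValueError("null modularity mean is 0; RM undefined")
    return (m_obs - mean) / mean, mean, sd


def find_network_hubs(
    report: pd.DataFrame | "TopologyReport",
    closeness_min: float = 0.25,
    degree_min: float = 40,
) -> list[str]:
    """Nodes with closeness > ``closeness_min`` AND degree > ``degree_min``.

    Both comparisons are strict, so a node sitting exactly on a
    threshold is not a hub.
    """
    df = report.nodes if isinstance(report, TopologyReport) else report
    mask = (df["closeness"] > closeness_min) & (df["degree"] > degree_min)
    return df.index[mask].tolist()


def topology_report(
    net: nx.Graph,
    seed: int = 0,
    n_random: int = 100,
    closeness_min: float = 0.25,
    degree_min: float = 40,
    with_relative_modularity: bool = True,
) -> TopologyReport:
    """Assemble the full per-network topology report."""
    nodes = degree_and_closeness(net)
    if net.number_of_edges() > 0:
        assignment, modularity = detect_modules(net, seed=seed)
        nodes["module"] = pd.Series(assignment)
    else:
        modularity = float("nan")
        nodes["module"] = 0
    if "kingdom" in next(iter(net.nodes(data=True)), (None, {}))[1]:
        nodes["kingdom"] = pd.Series(dict(net.nodes(data="kingdom")))
    rm = rm_mean = rm_sd = None
    if with_relative_modularity and net.number_of_edges() >= 2:
        rm, rm_mean, rm_sd = relative_modularity(net, n_random=n_random, seed=seed)
    hubs = find_network_hubs(nodes, closeness_min, degree_min)
    nodes["is_hub"] = nodes.index.isin(hubs)
    n, e = net.number_of_nodes(), net.number_of_edges()
    return TopologyReport(
        nodes=nodes,
        n_nodes=n,
        n_edges=e,
        average_degree=(2.0 * e / n) if n else 0.0,
        modularity=modularity,
        relative_modularity=rm,
        rand_modularity_mean=rm_mean,
        rand_modularity_sd=rm_sd,
        hubs=hubs,
    )
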
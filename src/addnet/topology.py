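"""Degree/betweenness analysis and hub/bridge filtering.

Hubs are drug nodes whose degree strictly exceeds a cutoff (default 3);
bridging nodes are any nodes whose normalized betweenness centrality
strictly exceeds a cutoff (default 0.04). Betweenness is normalized by
(n-1)(n-2)/2 with n the total node count of the graph, pairs in
different components contributing zero — the NetworkAnalyzer convention.
Retaining hubs and bridges and inducing the surrounding subgraph yields
the candidate subnetwork; its non-addictive drugs are the repurposing
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

Node = tuple[str, str]


@dataclass
class TopologyReport:
    """Per-node degree/betweenness with hub/bridge flags and the cutoffs used."""

    degree: dict[Node, int]
    betweenness: dict[Node, float]
    degree_cutoff: float = 3
    betweenness_cutoff: float = 0.04
    is_hub: dict[Node, bool] = field(default_factory=dict)
    is_bridge: dict[Node, bool] = field(default_factory=dict)
    powerlaw_slope: float | None = None
    powerlaw_r: float | None = None


def compute_degrees(net: nx.Graph) -> dict[Node, int]:
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    return dict(net.degree())


def compute_betweenness(net: nx.Graph, normalized: bool = True) -> dict[Node, float]:
    """Betweenness centrality of every node; all zeros for n < 3."""
    if net.number_of_nodes() < 3:
        return {node: 0.0 for node in net.nodes}
    return nx.betweenness_centrality(net, normalized=normalized)


def fit_degree_distribution(drug_degrees: list[int] | np.ndarray) -> tuple[float, float]:
    """Least-squares fit of log10(count) on log10(k) over degrees k >= 1.

    Returns ``(slope, r)``. A power-law degree distribution shows up as a
    negative slope with |r| close to 1. Raises ``ValueError`` when fewer
    than 3 distinct positive degrees are present (no line to fit).
    """
    ks, counts = np.unique(np.asarray(drug_degrees, dtype=int), return_counts=True)
    mask = ks >= 1
    ks, counts = ks[mask], counts[mask]
    if len(ks) < 3:
        raise ValueError("need at least 3 distinct positive degrees to fit a power law")
    x = np.log10(ks)
    y = np.log10(counts)
    slope, _intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    return float(slope), r


def classify_nodes(
    net: nx.Graph,
    degree: dict[Node, int],
    betweenness: dict[Node, float],
    degree_cutoff: float = 3,
    betweenness_cutoff: float = 0.04,
) -> TopologyReport:
    """Flag hubs (drug nodes, k strictly > cutoff) and bridges (any node,
    C_B strictly > cutoff)."""
    is_hub = {
        node: (node[0] == "drug" and degree.get(node, 0) > degree_cutoff) for node in net.nodes
    }
    is_bridge = {node: betweenness.get(node, 0.0) > betweenness_cutoff for node in net.nodes}
    return TopologyReport(
        degree=degree,
        betweenness=betweenness,
        degree_cutoff=degree_cutoff,
        betweenness_cutoff=betweenness_cutoff,
        is_hub=is_hub,
        is_bridge=is_bridge,
    )


def analyze(net: nx.Graph, degree_cutoff: float = 3, betweenness_cutoff: float = 0.04) -> TopologyReport:
    """Full topology pass: degrees, betweenness, flags, power-law fit."""
    degree = compute_degrees(net)
    betw = compute_betweenness(net)
    report = classify_nodes(net, degree, betw, degree_cutoff, betweenness_cutoff)
    drug_degrees = [k for node, k in degree.items() if node[0] == "drug"]
    try:
        report.powerlaw_slope, report.powerlaw_r = fit_degree_distribution(drug_degrees)
    except ValueError:
        pass
    return report


def extract_candidate_subnetwork(
    net: nx.Graph, report: TopologyReport
) -> tuple[nx.Graph, list[str]]:
    """Induce the hub/bridge subnetwork and list candidate drugs.

    Retained drugs: hub OR bridge. Retained targets: bridge targets plus
    targets adjacent to a retained drug. Isolated retained nodes are
    dropped. Candidates are the retained non-addictive drugs ordered by
    degree (desc), betweenness (desc), then id.
    """
    retained_drugs = {
        node
        for node in net.nodes
        if node[0] == "drug" and (report.is_hub.get(node) or report.is_bridge.get(node))
    }
    if not retained_drugs:
        return nx.Graph(), []
    retained_targets = {
        node
        for node in net.nodes
        if node[0] == "target"
        and (report.is_bridge.get(node) or any(nb in retained_drugs for nb in net.neighbors(node)))
    }
    sub = net.subgraph(retained_drugs | retained_targets).copy()
    sub.remove_nodes_from([n for n, d in sub.degree() if d == 0])
    candidates = sorted(
        (node for node in retained_drugs if not net.nodes[node].get("addictive", False)),
        key=lambda n: (-report.degree.get(n, 0), -report.betweenness.get(n, 0.0), n[1]),
    )
    return sub, [node[1] for node in candidates]


def suggest_cutoff(values: list[float] | np.ndarray, min_tail: int = 3) -> float:
    """Advisory cutoff from a two-segment fit of the log-log survival curve.

    Sorts the positive values, computes the empirical survival fraction,
    and picks the breakpoint that minimises total squared error of two
    straight-line fits in log-log space. Returns the value at the
    breakpoint; degree/betweenness defaults should be preferred when the
    curve is short or noisy.
    """
    vals = np.sort(np.asarray([v for v in values if v > 0], dtype=float))
    n = len(vals)
    if n < 2 * min_tail:
        raise ValueError("too few positive values for a two-segment fit")
    surv = 1.0 - np.arange(n) / n
    x, y = np.log10(vals), np.log10(surv)
    best_err, best_break = np.inf, min_tail
    for b in range(min_tail, n - min_tail):
        err = 0.0
        for xi, yi in ((x[:b], y[:b]), (x[b:], y[b:])):
            if len(np.unique(xi)) < 2:
                continue
            coeff = np.polyfit(xi, yi, 1)
            err += float(np.sum((np.polyval(coeff, xi) - yi) ** 2))
        if err < best_err:
            best_err, best_break = err, b
    return float(vals[best_break])


def write_topology_report(report: TopologyReport, net: nx.Graph, path: str | Path) -> None:
    """TSV with one row per node: id, class, degree, betweenness, flags."""
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("node\tnode_class\tdegree\tbetweenness\tis_hub\tis_bridge\n")
        for node in sorted(net.nodes):
            handle.write(
                f"{node[1]}\t{node[0]}\t{report.degree.get(node, 0)}\t"
                f"{report.betweenness.get(node, 0.0):.6g}\t"
                f"{int(bool(report.is_hub.get(node)))}\t"
                f"{int(bool(report.is_bridge.get(node)))}\n"
            )
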
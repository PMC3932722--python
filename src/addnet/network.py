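"""Bipartite drug-target network construction.

Networks are undirected simple :class:`networkx.Graph` objects. Node
identity is the pair ``(node_class, identifier)`` with ``node_class`` in
``{"drug", "target"}``, which prevents a drug name from colliding with a
gene symbol. Drug nodes carry a boolean ``addictive`` attribute; edges
carry ``edge_class`` in ``{"drug_target", "drug_enzyme", "ppi"}`` (the
latter two occur only in drug-centric ego networks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .records import DrugRecord, IntegrityError

logger = logging.getLogger(__name__)


def drug_node(drug_id: str) -> tuple[str, str]:
    return ("drug", drug_id)


def target_node(gene_symbol: str) -> tuple[str, str]:
    return ("target", gene_symbol)


@dataclass(frozen=True)
class NetSummary:
    """Class-aware node and edge accounting for a bipartite network."""

    n_nodes: int
    n_drugs_addictive: int
    n_drugs_nonaddictive: int
    n_targets: int
    n_edges: int
    n_edges_addictive_side: int
    n_edges_nonaddictive_side: int

    def __post_init__(self) -> None:
        if self.n_nodes != self.n_drugs_addictive + self.n_drugs_nonaddictive + self.n_targets:
            raise IntegrityError("node class counts do not sum to the node total")


def build_addictive_network(addictive_drugs: Iterable[DrugRecord]) -> nx.Graph:
    """Bipartite network of addictive drugs and their targets.

    A drug connects to a target iff the target is a known target of the
    drug. Drugs with no targets cannot form edges and are left out of the
    graph (they remain in the dataset).
    """
    drugs = list(addictive_drugs)
    if not drugs:
        raise ValueError("no addictive drugs supplied")
    net = nx.Graph()
    skipped = 0
    for drug in drugs:
        if not drug.targets:
            skipped += 1
            continue
        dn = drug_node(drug.drug_id)
        net.add_node(dn, node_class="drug", addictive=True, name=drug.name)
        for gene in drug.targets:
            tn = target_node(gene)
            net.add_node(tn, node_class="target", addictive=False)
            net.add_edge(dn, tn, edge_class="drug_target")
    if skipped:
        logger.info("build_addictive_network: %d zero-target drugs excluded", skipped)
    return net


def addictive_target_set(net: nx.Graph) -> set[str]:
    return {node[1] for node in net.nodes if node[0] == "target"}


def expand_network(addictive_net: nx.Graph, all_drugs: Iterable[DrugRecord]) -> nx.Graph:
    """Add non-addictive drugs sharing at least one target with the core.

    A pool drug enters the network iff it shares >= 1 target with an
    addictive drug, and only its edges to addictive-drug targets are
    added — its other targets do not become nodes, so the target side of
    the network is unchanged. Returns a new graph; the input is untouched.
    """
    net = addictive_net.copy()
    core_targets = addictive_target_set(addictive_net)
    for drug in all_drugs:
        if drug.is_addictive:
            continue
        shared = drug.targets & core_targets
        if not shared:
            continue
        dn = drug_node(drug.drug_id)
        net.add_node(dn, node_class="drug", addictive=False, name=drug.name)
        for gene in shared:
            net.add_edge(dn, target_node(gene), edge_class="drug_target")
    return net


def summarize(net: nx.Graph) -> NetSummary:
    """Count nodes and edges by class; totals always reconcile."""
    n_add = n_non = n_targets = 0
    for node, data in net.nodes(data=True):
        if node[0] == "drug":
            if data.get("addictive", False):
                n_add += 1
            else:
                n_non += 1
        else:
            n_targets += 1
    e_add = e_non = 0
    for u, v, data in net.edges(data=True):
        drug_end = u if u[0] == "drug" else v
        if net.nodes[drug_end].get("addictive", False) and drug_end[0] == "drug":
            e_add += 1
        else:
            e_non += 1
    return NetSummary(
        n_nodes=net.number_of_nodes(),
        n_drugs_addictive=n_add,
        n_drugs_nonaddictive=n_non,
        n_targets=n_targets,
        n_edges=net.number_of_edges(),
        n_edges_addictive_side=e_add,
        n_edges_nonaddictive_side=e_non,
    )


def build_ego_network(
    drug_id: str,
    targets: Iterable[str],
    enzymes: Iterable[str],
    ppi_edges: Iterable[tuple[str, str]],
) -> nx.Graph:
    """Drug-centric network: the drug, its targets and metabolising
    enzymes, and protein-protein interactions among/around them.

    Protein nodes are deduplicated across roles (a protein may be both an
    enzyme and a PPI endpoint); parallel edges collapse.
    """
    targets = set(targets)
    enzymes = set(enzymes)
    if drug_id in targets or drug_id in enzymes:
        raise IntegrityError(f"drug {drug_id!r} listed among its own proteins")
    net = nx.Graph()
    dn = drug_node(drug_id)
    net.add_node(dn, node_class="drug", addictive=False)
    for gene in targets:
        net.add_node(target_node(gene), node_class="target", addictive=False, role="target")
        net.add_edge(dn, target_node(gene), edge_class="drug_target")
    for gene in enzymes:
        net.add_node(target_node(gene), node_class="target", addictive=False, role="enzyme")
        net.add_edge(dn, target_node(gene), edge_class="drug_enzyme")
    for p, q in ppi_edges:
        for gene in (p, q):
            if gene == drug_id:
                raise IntegrityError("PPI edges cannot involve the drug")
            if target_node(gene) not in net:
                net.add_node(target_node(gene), node_class="target", addictive=False, role="ppi")
        net.add_edge(target_node(p), target_node(q), edge_class="ppi")
    return net
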
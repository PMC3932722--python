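"""End-to-end pipeline: networks -> topology -> screens -> reports.

Order of operations: build the addictive drug-target network, expand it
with the non-addictive pool, run the topology pass (degrees,
betweenness, hub/bridge flags, power-law diagnostic), extract the
candidate subnetwork, then evaluate candidates with the three screens
(pathway enrichment of addictive targets, ATC class comparison,
literature co-occurrence restricted to the candidates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import data_io, network, screens, topology
from .records import DrugRecord, GeneSetCollection, LiteratureCountTable


@dataclass
class PipelineConfig:
    degree_cutoff: float = 3
    betweenness_cutoff: float = 0.04
    enrich_adj_p: float = 0.01
    enrich_min_genes: int = 5
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.degree_cutoff < 0 or self.betweenness_cutoff < 0:
            raise ValueError("cutoffs must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PipelineResult:
    addictive_net: nx.Graph
    expanded_net: nx.Graph
    addictive_summary: network.NetSummary
    expanded_summary: network.NetSummary
    report: topology.TopologyReport
    subnetwork: nx.Graph
    subnetwork_summary: network.NetSummary | None
    candidates: list[str]
    enrichment: list[screens.EnrichmentResult]
    atc: screens.AtcComparison
    cooccurrence: list[screens.CooccurrenceRecord]
    candidate_report: screens.CandidateReport
    config: PipelineConfig = field(default_factory=PipelineConfig)


def run_pipeline(
    drugs: list[DrugRecord],
    gene_sets: GeneSetCollection | None,
    literature: LiteratureCountTable | None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis over in-memory records.

    ``drugs`` holds both addictive and non-addictive records,
    distinguished by their category. Gene sets and literature counts are
    optional; the corresponding screens are skipped when absent.
    """
    config = config or PipelineConfig()
    config.validate()
    addictive = [d for d in drugs if d.is_addictive]
    nonaddictive = [d for d in drugs if not d.is_addictive]

    addictive_net = network.build_addictive_network(addictive)
    expanded = network.expand_network(addictive_net, nonaddictive)
    report = topology.analyze(
        expanded, degree_cutoff=config.degree_cutoff, betweenness_cutoff=config.betweenness_cutoff
    )
    subnet, candidates = topology.extract_candidate_subnetwork(expanded, report)

    query_genes = set().union(*(d.targets for d in addictive)) if addictive else set()
    enrichment: list[screens.EnrichmentResult] = []
    if gene_sets is not None and len(gene_sets) and query_genes:
        enrichment = screens.enrich(query_genes, gene_sets)

    in_network_ids = {n[1] for n in expanded.nodes if n[0] == "drug"}
    atc = screens.compare_atc(
        [d for d in addictive if d.drug_id in in_network_ids],
        [d for d in nonaddictive if d.drug_id in in_network_ids],
    )

    cooc: list[screens.CooccurrenceRecord] = []
    if literature is not None and literature.rows:
        candidate_set = set(candidates)
        restricted = LiteratureCountTable(
            corpus_total=literature.corpus_total,
            rows=[r for r in literature.rows if r.drug_id in candidate_set],
        )
        if restricted.rows:
            cooc = screens.literature_screen(restricted, alpha=config.alpha)

    candidate_report = screens.rank_candidates(
        candidates, cooc, degree=report.degree, betweenness=report.betweenness
    )
    return PipelineResult(
        addictive_net=addictive_net,
        expanded_net=expanded,
        addictive_summary=network.summarize(addictive_net),
        expanded_summary=network.summarize(expanded),
        report=report,
        subnetwork=subnet,
        subnetwork_summary=network.summarize(subnet) if subnet.number_of_nodes() else None,
        candidates=candidates,
        enrichment=enrichment,
        atc=atc,
        cooccurrence=cooc,
        candidate_report=candidate_report,
        config=config,
    )


def _summary_dict(s: network.NetSummary | None) -> dict | None:
    if s is None:
        return None
    return {
        "n_nodes": s.n_nodes,
        "n_drugs_addictive": s.n_drugs_addictive,
        "n_drugs_nonaddictive": s.n_drugs_nonaddictive,
        "n_targets": s.n_targets,
        "n_edges": s.n_edges,
        "n_edges_addictive_side": s.n_edges_addictive_side,
        "n_edges_nonaddictive_side": s.n_edges_nonaddictive_side,
    }


def write_outputs(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write every report to ``out_dir``; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def path(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    data_io.export_network(result.addictive_net, path("addictive_network.edges.tsv"), "edge-tsv")
    data_io.export_network(result.expanded_net, path("expanded_network.edges.tsv"), "edge-tsv")
    data_io.export_network(result.expanded_net, path("expanded_network.sif"), "sif")
    if result.subnetwork.number_of_nodes():
        data_io.export_network(result.subnetwork, path("candidate_subnetwork.edges.tsv"), "edge-tsv")
    topology.write_topology_report(result.report, result.expanded_net, path("topology.tsv"))
    if result.enrichment:
        screens.write_enrichment_tsv(result.enrichment, path("enrichment.tsv"))
    screens.write_atc_tsv_report(result.atc, path("atc_comparison.tsv"))
    if result.cooccurrence:
        screens.write_cooccurrence_tsv(result.cooccurrence, path("literature_screen.tsv"))
    screens.write_candidate_tsv(result.candidate_report, path("candidates.tsv"))

    summary = {
        "config": {
            "degree_cutoff": result.config.degree_cutoff,
            "betweenness_cutoff": result.config.betweenness_cutoff,
            "enrich_adj_p": result.config.enrich_adj_p,
            "enrich_min_genes": result.config.enrich_min_genes,
            "alpha": result.config.alpha,
            "seed": result.config.seed,
        },
        "addictive_network": _summary_dict(result.addictive_summary),
        "expanded_network": _summary_dict(result.expanded_summary),
        "candidate_subnetwork": _summary_dict(result.subnetwork_summary),
        "n_candidates": len(result.candidates),
        "n_significant_candidates": result.candidate_report.n_significant,
        "pct_significant_candidates": round(result.candidate_report.pct_significant, 2),
        "n_enriched_sets": sum(r.passes_filters for r in result.enrichment),
        "powerlaw_slope": result.report.powerlaw_slope,
        "powerlaw_r": result.report.powerlaw_r,
    }
    with path("summary.json").open("w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2)
        handle.write("\n")
    return written
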
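"""Candidate-evaluation screens.

Three independent lines of evidence about drugs in the network:

* :func:`enrich` — hypergeometric over-representation of a gene list in
  named gene sets, Benjamini-Hochberg adjusted; a set "passes" when the
  adjusted p is below 0.01 and it contains at least 5 query genes.
* :func:`compare_atc` — per anatomical main group (ATC level 1), a
  Fisher's exact comparison of the proportion of addictive vs
  non-addictive drugs carrying that classification.
* :func:`literature_screen` — per drug, a Fisher's exact test of
  drug/keyword co-occurrence counts against a literature corpus total,
  Bonferroni-corrected over the drugs tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .records import DrugRecord, LiteratureCountTable
from .stats import (
    ContingencyTable2x2,
    bh_adjust,
    bonferroni_adjust,
    fisher_exact,
    hypergeom_sf,
)

logger = logging.getLogger(__name__)

ENRICH_ADJ_P = 0.01
ENRICH_MIN_GENES = 5


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    adj_p: float = math.nan

    @property
    def passes_filters(self) -> bool:
        return self.adj_p < ENRICH_ADJ_P and self.overlap >= ENRICH_MIN_GENES

    @property
    def pct_of_query(self) -> float:
        """Percentage of query genes contained in this set."""
        return 100.0 * self.overlap / self.query_size


def enrich(query_genes, gene_sets, universe_genes=None) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of ``query_genes`` in each gene set.

    The universe defaults to all genes appearing in the collection; the
    query and every set are intersected with it before testing. The BH
    family is all tested sets. Results come back sorted by adjusted p,
    ties broken by set id.
    """
    universe = set(universe_genes) if universe_genes is not None else gene_sets.universe()
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes) & universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    results = []
    for set_id in sorted(gene_sets.sets):
        members = gene_sets.sets[set_id] & universe
        k = len(members & query)
        p = hypergeom_sf(k, len(universe), len(members), len(query)) if members else 1.0
        results.append(
            EnrichmentResult(
                set_id=set_id,
                overlap=k,
                set_size=len(members),
                query_size=len(query),
                universe_size=len(universe),
                p=p,
            )
        )
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    results.sort(key=lambda r: (r.adj_p, r.set_id))
    return results


@dataclass
class AtcCategoryRow:
    category: str
    n_addictive: int
    n_nonaddictive: int
    addictive_total: int
    nonaddictive_total: int
    p: float

    @property
    def prop_addictive(self) -> float:
        return self.n_addictive / self.addictive_total

    @property
    def prop_nonaddictive(self) -> float:
        return self.n_nonaddictive / self.nonaddictive_total


@dataclass
class AtcComparison:
    """Per level-1 category counts/proportions with a Fisher p each.

    Denominators are the drugs carrying at least one ATC code in each
    group; a drug contributes to every category it is classified under.
    """

    rows: list[AtcCategoryRow]
    addictive_total: int
    nonaddictive_total: int


def compare_atc(
    addictive: Iterable[DrugRecord],
    nonaddictive: Iterable[DrugRecord],
    sidedness: str = "two_sided",
) -> AtcComparison:
    """Compare anatomical main group membership between drug groups.

    Drugs without any ATC code are excluded from both denominators.
    Each category's 2x2 is [in-category vs not] x [addictive vs not].
    """
    add_coded = [d for d in addictive if d.atc_codes]
    non_coded = [d for d in nonaddictive if d.atc_codes]
    categories = set()
    for d in add_coded + non_coded:
        categories |= d.atc_level1()
    rows = []
    for cat in sorted(categories):
        a_in = sum(1 for d in add_coded if cat in d.atc_level1())
        n_in = sum(1 for d in non_coded if cat in d.atc_level1())
        if a_in == 0 and n_in == 0:
            logger.info("compare_atc: category %s absent from both groups, skipped", cat)
            continue
        table = ContingencyTable2x2(
            a=a_in, b=len(add_coded) - a_in, c=n_in, d=len(non_coded) - n_in
        )
        rows.append(
            AtcCategoryRow(
                category=cat,
                n_addictive=a_in,
                n_nonaddictive=n_in,
                addictive_total=len(add_coded),
                nonaddictive_total=len(non_coded),
                p=fisher_exact(table, sidedness=sidedness),
            )
        )
    return AtcComparison(
        rows=rows, addictive_total=len(add_coded), nonaddictive_total=len(non_coded)
    )


@dataclass
class CooccurrenceRecord:
    drug_id: str
    n_drug: int
    n_keyword: int
    n_both: int
    corpus_total: int
    p: float
    adj_p: float = math.nan

    @property
    def expected(self) -> float:
        return self.n_drug * self.n_keyword / self.corpus_total

    @property
    def obs_exp_ratio(self) -> float:
        exp = self.expected
        if exp == 0:
            return math.inf if self.n_both > 0 else 0.0
        return self.n_both / exp

    @property
    def significant(self) -> bool:
        return self.adj_p < 0.05


def literature_screen(
    counts: LiteratureCountTable, alpha: float = 0.05
) -> list[CooccurrenceRecord]:
    """Per-drug Fisher test of drug/keyword co-occurrence.

    The 2x2 for each drug is ``[[n_both, n_drug - n_both],
    [n_keyword - n_both, rest of corpus]]``. Bonferroni family size is
    the number of rows actually tested; rows violating the count
    invariants are rejected with a logged report and do not enter the
    family. Output is sorted by observed/expected ratio, descending
    (strongest over-representation first).
    """
    records = []
    for row in counts.rows:
        try:
            row.validate(counts.corpus_total)
        except Exception as exc:
            logger.warning("literature_screen: rejecting row %s: %s", row.drug_id, exc)
            continue
        table = ContingencyTable2x2(
            a=row.n_both,
            b=row.n_drug - row.n_both,
            c=row.n_keyword - row.n_both,
            d=counts.corpus_total - row.n_drug - row.n_keyword + row.n_both,
        )
        records.append(
            CooccurrenceRecord(
                drug_id=row.drug_id,
                n_drug=row.n_drug,
                n_keyword=row.n_keyword,
                n_both=row.n_both,
                corpus_total=counts.corpus_total,
                p=fisher_exact(table, sidedness="greater"),
            )
        )
    adj = bonferroni_adjust([r.p for r in records])
    for r, a in zip(records, adj):
        r.adj_p = float(a)
    records.sort(key=lambda r: (-r.obs_exp_ratio, r.drug_id))
    return records


@dataclass
class RankedCandidate:
    drug_id: str
    degree: int
    betweenness: float
    n_both: int
    expected: float
    obs_exp_ratio: float
    p: float
    adj_p: float
    significant: bool


@dataclass
class CandidateReport:
    rows: list[RankedCandidate]

    @property
    def n_candidates(self) -> int:
        return len(self.rows)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.rows)

    @property
    def pct_significant(self) -> float:
        return 100.0 * self.n_significant / self.n_candidates if self.rows else 0.0

    def summary_line(self) -> str:
        return (
            f"{self.n_significant} of {self.n_candidates} candidate drugs "
            f"({self.pct_significant:.2f}%) significantly co-occur with "
            "addiction keywords in the literature"
        )


def rank_candidates(
    candidates: Sequence[str],
    cooccurrence: Sequence[CooccurrenceRecord],
    degree: dict | None = None,
    betweenness: dict | None = None,
) -> CandidateReport:
    """Join topology-derived candidates with their literature evidence.

    Candidates missing from the co-occurrence table get zero counts and
    p = 1 (no literature evidence). Rows keep the candidate order given.
    """
    by_id = {r.drug_id: r for r in cooccurrence}
    degree = degree or {}
    betweenness = betweenness or {}
    rows = []
    for drug_id in candidates:
        rec = by_id.get(drug_id)
        node = ("drug", drug_id)
        if rec is None:
            rows.append(
                RankedCandidate(
                    drug_id=drug_id,
                    degree=degree.get(node, 0),
                    betweenness=betweenness.get(node, 0.0),
                    n_both=0,
                    expected=0.0,
                    obs_exp_ratio=0.0,
                    p=1.0,
                    adj_p=1.0,
                    significant=False,
                )
            )
        else:
            rows.append(
                RankedCandidate(
                    drug_id=drug_id,
                    degree=degree.get(node, 0),
                    betweenness=betweenness.get(node, 0.0),
                    n_both=rec.n_both,
                    expected=rec.expected,
                    obs_exp_ratio=rec.obs_exp_ratio,
                    p=rec.p,
                    adj_p=rec.adj_p,
                    significant=rec.significant,
                )
            )
    return CandidateReport(rows=rows)


# ---------------------------------------------------------------------------
# TSV reports


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("set_id\toverlap\tset_size\tquery_size\tuniverse_size\tp\tadj_p\tpasses\n")
        for r in results:
            handle.write(
                f"{r.set_id}\t{r.overlap}\t{r.set_size}\t{r.query_size}\t"
                f"{r.universe_size}\t{r.p:.6g}\t{r.adj_p:.6g}\t{int(r.passes_filters)}\n"
            )


def write_atc_tsv_report(comparison: AtcComparison, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(
            "category\tn_addictive\taddictive_total\tprop_addictive\t"
            "n_nonaddictive\tnonaddictive_total\tprop_nonaddictive\tp\n"
        )
        for r in comparison.rows:
            handle.write(
                f"{r.category}\t{r.n_addictive}\t{r.addictive_total}\t"
                f"{r.prop_addictive:.4f}\t{r.n_nonaddictive}\t{r.nonaddictive_total}\t"
                f"{r.prop_nonaddictive:.4f}\t{r.p:.6g}\n"
            )


def write_cooccurrence_tsv(records: list[CooccurrenceRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("drug_id\tn_drug\tn_keyword\tn_both\texpected\tobs_exp_ratio\tp\tadj_p\tsignificant\n")
        for r in records:
            handle.write(
                f"{r.drug_id}\t{r.n_drug}\t{r.n_keyword}\t{r.n_both}\t"
                f"{r.expected:.4f}\t{r.obs_exp_ratio:.4f}\t{r.p:.6g}\t"
                f"{r.adj_p:.6g}\t{int(r.significant)}\n"
            )


def write_candidate_tsv(report: CandidateReport, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(
            "drug_id\tdegree\tbetweenness\tn_both\texpected\tobs_exp_ratio\tp\tadj_p\tsignificant\n"
        )
        for r in report.rows:
            handle.write(
                f"{r.drug_id}\t{r.degree}\t{r.betweenness:.6g}\t{r.n_both}\t"
                f"{r.expected:.4f}\t{r.obs_exp_ratio:.4f}\t{r.p:.6g}\t"
                f"{r.adj_p:.6g}\t{int(r.significant)}\n"
            )
        handle.write(f"# {report.summary_line()}\n")
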
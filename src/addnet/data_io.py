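"""Readers and writers for every on-disk representation.

Supported formats:

* drug-target tables — TSV with columns ``drug_id, name, groups,
  nida_category, targets`` (``groups`` and ``targets`` are
  semicolon-separated; ``targets`` may be empty);
* a simplified drug XML dialect — ``<drugs>`` containing ``<drug id=...
  nida_category=...>`` elements with ``<name>``, ``<group>`` and
  ``<target gene=...>`` children (a deliberately small schema, not the
  full DrugBank one);
* GMT gene-set files (set id, description, member genes, tab-separated);
* ATC assignments — TSV with columns ``drug_id, atc_codes``;
* literature count tables — TSV with columns ``drug_id, n_drug,
  n_keyword, n_both`` and an optional ``# corpus_total = N`` comment;
* network exports: SIF, GraphML and a self-describing edge TSV that
  round-trips through :func:`read_edge_tsv`.

All files are UTF-8 with LF line endings.
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources
from pathlib import Path

import networkx as nx
from lxml import etree

from .records import (
    KNOWN_GROUPS,
    PUBMED_2012_TOTAL,
    DrugRecord,
    FormatError,
    GeneSetCollection,
    IntegrityError,
    LiteratureCountRow,
    LiteratureCountTable,
    TargetRecord,
)

_DRUG_TSV_COLUMNS = ("drug_id", "name", "groups", "nida_category", "targets")


def _split_multi(raw: str) -> set[str]:
    return {tok.strip() for tok in raw.split(";") if tok.strip()}


# ---------------------------------------------------------------------------
# drug-target tables


def read_drug_target_tsv(path: str | Path) -> tuple[list[DrugRecord], list[TargetRecord]]:
    """Read a drug-target TSV into drug records plus deduplicated targets.

    Raises :class:`FormatError` naming any missing column and
    :class:`IntegrityError` on duplicate drug ids.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for col in _DRUG_TSV_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        drugs: list[DrugRecord] = []
        seen_ids: set[str] = set()
        gene_symbols: set[str] = set()
        for row in reader:
            drug_id = row["drug_id"].strip()
            if drug_id in seen_ids:
                raise IntegrityError(f"{path}: duplicate drug_id {drug_id!r}")
            seen_ids.add(drug_id)
            targets = _split_multi(row["targets"] or "")
            gene_symbols |= targets
            drugs.append(
                DrugRecord(
                    drug_id=drug_id,
                    name=row["name"].strip(),
                    groups=_split_multi(row["groups"] or ""),
                    nida_category=(row["nida_category"] or "none").strip(),
                    targets=targets,
                )
            )
    target_records = [TargetRecord(gene_symbol=g) for g in sorted(gene_symbols)]
    return drugs, target_records


def write_drug_target_tsv(drugs: list[DrugRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_DRUG_TSV_COLUMNS)
        for drug in drugs:
            writer.writerow(
                [
                    drug.drug_id,
                    drug.name,
                    ";".join(sorted(drug.groups)),
                    drug.nida_category,
                    ";".join(sorted(drug.targets)),
                ]
            )


# ---------------------------------------------------------------------------
# simplified drug XML dialect


def read_drug_xml(path: str | Path) -> list[DrugRecord]:
    """Read the simplified drug XML dialect.

    Unknown group tokens are kept verbatim with a warning; malformed XML
    raises :class:`FormatError` carrying the parser's line number.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: malformed XML at line {exc.lineno}: {exc.msg}") from exc
    drugs: list[DrugRecord] = []
    seen: set[str] = set()
    for elem in tree.getroot().iter("drug"):
        drug_id = elem.get("id", "").strip()
        if not drug_id:
            raise FormatError(f"{path}: <drug> element without id attribute")
        if drug_id in seen:
            raise IntegrityError(f"{path}: duplicate drug id {drug_id!r}")
        seen.add(drug_id)
        name_elem = elem.find("name")
        groups: set[str] = set()
        for group_elem in elem.iter("group"):
            token = (group_elem.text or "").strip()
            if token and token not in KNOWN_GROUPS:
                warnings.warn(f"unknown group token {token!r} for {drug_id}", stacklevel=2)
            if token:
                groups.add(token)
        targets = {t.get("gene", "").strip() for t in elem.iter("target")}
        targets.discard("")
        drugs.append(
            DrugRecord(
                drug_id=drug_id,
                name=(name_elem.text or "").strip() if name_elem is not None else "",
                groups=groups,
                nida_category=elem.get("nida_category", "none"),
                targets=targets,
            )
        )
    return drugs


def write_drug_xml(drugs: list[DrugRecord], path: str | Path) -> None:
    root = etree.Element("drugs")
    for drug in drugs:
        elem = etree.SubElement(root, "drug", id=drug.drug_id, nida_category=drug.nida_category)
        etree.SubElement(elem, "name").text = drug.name
        for group in sorted(drug.groups):
            etree.SubElement(elem, "group").text = group
        for gene in sorted(drug.targets):
            etree.SubElement(elem, "target", gene=gene)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    collection = GeneSetCollection()
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, description, *genes = fields
            genes = [g for g in genes if g]
            collection.add(set_id, set(genes), description)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for set_id in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[set_id]))
            handle.write(f"{set_id}\t{collection.descriptions.get(set_id, '')}\t{genes}\n")


# ---------------------------------------------------------------------------
# ATC assignments and literature counts


def read_atc_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read ``drug_id -> set of ATC codes`` from a two-column TSV."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for col in ("drug_id", "atc_codes"):
            if col not in (reader.fieldnames or []):
                raise FormatError(f"{path}: missing required column {col!r}")
        for row in reader:
            out[row["drug_id"].strip()] = _split_multi(row["atc_codes"] or "")
    return out


def write_atc_tsv(codes: dict[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("drug_id\tatc_codes\n")
        for drug_id in sorted(codes):
            handle.write(f"{drug_id}\t{';'.join(sorted(codes[drug_id]))}\n")


def read_literature_counts_tsv(path: str | Path) -> LiteratureCountTable:
    path = Path(path)
    corpus_total = PUBMED_2012_TOTAL
    rows: list[LiteratureCountRow] = []
    with path.open(encoding="utf-8") as handle:
        data_lines = []
        for line in handle:
            stripped = line.strip()
            if stripped.startswith("#"):
                key, _, value = stripped.lstrip("#").partition("=")
                if key.strip() == "corpus_total":
                    corpus_total = int(value.strip())
                continue
            if stripped:
                data_lines.append(line)
    reader = csv.DictReader(data_lines, delimiter="\t")
    for col in ("drug_id", "n_drug", "n_keyword", "n_both"):
        if col not in (reader.fieldnames or []):
            raise FormatError(f"{path}: missing required column {col!r}")
    for row in reader:
        rows.append(
            LiteratureCountRow(
                drug_id=row["drug_id"].strip(),
                n_drug=int(row["n_drug"]),
                n_keyword=int(row["n_keyword"]),
                n_both=int(row["n_both"]),
            )
        )
    table = LiteratureCountTable(corpus_total=corpus_total, rows=rows)
    table.validate()
    return table


def write_literature_counts_tsv(table: LiteratureCountTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(f"# corpus_total = {table.corpus_total}\n")
        handle.write("drug_id\tn_drug\tn_keyword\tn_both\n")
        for row in table.rows:
            handle.write(f"{row.drug_id}\t{row.n_drug}\t{row.n_keyword}\t{row.n_both}\n")


# ---------------------------------------------------------------------------
# network exports

EXPORT_FORMATS = ("sif", "graphml", "edge-tsv")


def export_network(net: nx.Graph, path: str | Path, format: str = "edge-tsv") -> None:
    """Write a network in SIF, GraphML or the round-trippable edge TSV.

    Node identity in the graph is the pair ``(node_class, identifier)``;
    SIF and GraphML flatten it to ``class:identifier`` strings.
    """
    fmt = format.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {format!r}; choose from {EXPORT_FORMATS}")
    if net.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    path = Path(path)
    if fmt == "sif":
        with path.open("w", encoding="utf-8") as handle:
            for u, v, data in sorted(net.edges(data=True)):
                relation = data.get("edge_class", "drug_target")
                handle.write(f"{u[1]}\t{relation}\t{v[1]}\n")
    elif fmt == "graphml":
        flat = nx.Graph()
        for node, data in net.nodes(data=True):
            flat.add_node(
                f"{node[0]}:{node[1]}",
                node_class=node[0],
                addictive=bool(data.get("addictive", False)),
            )
        for u, v, data in net.edges(data=True):
            flat.add_edge(
                f"{u[0]}:{u[1]}",
                f"{v[0]}:{v[1]}",
                edge_class=data.get("edge_class", "drug_target"),
            )
        nx.write_graphml(flat, str(path))
    else:
        with path.open("w", encoding="utf-8") as handle:
            handle.write(
                "source_class\tsource\tsource_addictive\t"
                "target_class\ttarget\ttarget_addictive\tedge_class\n"
            )
            for u, v, data in sorted(net.edges(data=True)):
                handle.write(
                    "\t".join(
                        [
                            u[0],
                            str(u[1]),
                            str(int(bool(net.nodes[u].get("addictive", False)))),
                            v[0],
                            str(v[1]),
                            str(int(bool(net.nodes[v].get("addictive", False)))),
                            data.get("edge_class", "drug_target"),
                        ]
                    )
                    + "\n"
                )


def read_edge_tsv(path: str | Path) -> nx.Graph:
    """Reconstruct a network written by :func:`export_network` as edge TSV."""
    path = Path(path)
    net = nx.Graph()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            u = (row["source_class"], row["source"])
            v = (row["target_class"], row["target"])
            net.add_node(u, node_class=u[0], addictive=bool(int(row["source_addictive"])))
            net.add_node(v, node_class=v[0], addictive=bool(int(row["target_addictive"])))
            net.add_edge(u, v, edge_class=row["edge_class"])
    return net


# ---------------------------------------------------------------------------
# packaged reference table


def load_addictive_drug_table() -> list[DrugRecord]:
    """The packaged table of 44 NIDA-listed addictive drugs.

    Records carry declared target counts (``target_count``) but no target
    identities; the target gene lists live in supplementary data that is
    not reproduced here.
    """
    text = (
        resources.files("addnet.data").joinpath("nida_addictive_drugs.tsv").read_text("utf-8")
    )
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    records = []
    for row in reader:
        records.append(
            DrugRecord(
                drug_id=row["drug_id"],
                name=row["name"],
                groups=_split_multi(row["groups"]),
                nida_category=row["nida_category"],
                target_count=int(row["target_count"]),
            )
        )
    if len(records) != 44:
        raise IntegrityError("packaged addictive-drug table must contain 44 records")
    return records
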
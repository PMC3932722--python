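"""File format round-trips and the packaged addictive-drug table."""

import warnings
from collections import Counter

import networkx as nx
import pytest

from addnet import data_io
from addnet.records import FormatError, GeneSetCollection, IntegrityError
from conftest import make_drug


def write_tsv(path, rows, header="drug_id\tname\tgroups\tnida_category\ttargets"):
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestDrugTargetTsv:
    def test_reads_rows_and_deduplicates_targets(self, tmp_path):
        path = write_tsv(
            tmp_path / "drugs.tsv",
            [
                "D1\tdrug one\tapproved\tdepressants\tOPRM1;GABRA1",
                "D2\tdrug two\tapproved;illicit\tnone\tOPRM1",
            ],
        )
        drugs, targets = data_io.read_drug_target_tsv(path)
        assert [d.drug_id for d in drugs] == ["D1", "D2"]
        assert sum(1 for t in targets if t.gene_symbol == "OPRM1") == 1
        assert {t.gene_symbol for t in targets} == {"OPRM1", "GABRA1"}

    def test_header_only_file_yields_empty_lists(self, tmp_path):
        drugs, targets = data_io.read_drug_target_tsv(write_tsv(tmp_path / "e.tsv", []))
        assert drugs == [] and targets == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = write_tsv(tmp_path / "bad.tsv", [], header="drug_id\tname\tgroups\tnida_category")
        with pytest.raises(FormatError, match="targets"):
            data_io.read_drug_target_tsv(path)

    def test_duplicate_drug_id_is_integrity_error(self, tmp_path):
        path = write_tsv(
            tmp_path / "dup.tsv",
            ["D1\ta\tapproved\tnone\tX", "D1\tb\tapproved\tnone\tY"],
        )
        with pytest.raises(IntegrityError, match="D1"):
            data_io.read_drug_target_tsv(path)

    def test_full_dataset_roundtrip(self, tmp_path, default_dataset):
        _config, addictive, pool, _targets = default_dataset
        path = tmp_path / "all.tsv"
        data_io.write_drug_target_tsv(addictive + pool, path)
        back, _ = data_io.read_drug_target_tsv(path)
        assert len(back) == len(addictive) + len(pool)
        assert sum(1 for d in back if d.is_addictive) == len(addictive)
        by_id = {d.drug_id: d for d in back}
        for original in addictive + pool:
            assert by_id[original.drug_id].targets == original.targets
            assert by_id[original.drug_id].groups == original.groups


class TestDrugXml:
    def test_single_drug_with_two_targets(self, tmp_path):
        path = tmp_path / "one.xml"
        path.write_text(
            '<drugs><drug id="D1" nida_category="stimulants"><name>d</name>'
            '<group>approved</group><target gene="A"/><target gene="B"/></drug></drugs>'
        )
        (record,) = data_io.read_drug_xml(path)
        assert record.targets == {"A", "B"} and record.nida_category == "stimulants"

    def test_drug_without_targets_has_empty_set(self, tmp_path):
        path = tmp_path / "none.xml"
        path.write_text('<drugs><drug id="D1"><name>d</name></drug></drugs>')
        (record,) = data_io.read_drug_xml(path)
        assert record.targets == set()

    def test_xml_tsv_roundtrip_equivalence(self, tmp_path, default_dataset):
        _config, addictive, _pool, _targets = default_dataset
        tsv, xml = tmp_path / "d.tsv", tmp_path / "d.xml"
        data_io.write_drug_target_tsv(addictive, tsv)
        data_io.write_drug_xml(addictive, xml)
        from_tsv, _ = data_io.read_drug_target_tsv(tsv)
        from_xml = data_io.read_drug_xml(xml)
        key = lambda d: d.drug_id
        for a, b in zip(sorted(from_tsv, key=key), sorted(from_xml, key=key)):
            assert (a.drug_id, a.name, a.groups, a.nida_category, a.targets) == (
                b.drug_id, b.name, b.groups, b.nida_category, b.targets
            )

    def test_malformed_xml_reports_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<drugs>\n<drug id='D1'>\n</drugs>")
        with pytest.raises(FormatError, match="line"):
            data_io.read_drug_xml(path)

    def test_unknown_group_token_kept_with_warning(self, tmp_path):
        path = tmp_path / "odd.xml"
        path.write_text(
            '<drugs><drug id="D1"><name>d</name><group>vet_approved</group></drug></drugs>'
        )
        with pytest.warns(UserWarning, match="vet_approved"):
            (record,) = data_io.read_drug_xml(path)
        assert "vet_approved" in record.groups


class TestGmt:
    def test_minimal_line(self, tmp_path):
        path = tmp_path / "a.gmt"
        path.write_text("P1\tdesc\tA\tB\n")
        collection = data_io.read_gmt(path)
        assert collection.sets == {"P1": {"A", "B"}}

    def test_roundtrip_identity(self, tmp_path):
        collection = GeneSetCollection()
        for i in range(5):
            collection.add(f"S{i}", {f"G{i}", f"G{i + 1}", "COMMON"}, f"set {i}")
        path = tmp_path / "b.gmt"
        data_io.write_gmt(collection, path)
        assert data_io.read_gmt(path) == collection

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("P1\tdesc\tA\nP2\tonly-two-fields\n")
        with pytest.raises(FormatError, match=":2"):
            data_io.read_gmt(path)

    def test_duplicate_set_id_is_integrity_error(self, tmp_path):
        path = tmp_path / "d.gmt"
        path.write_text("P1\tx\tA\nP1\ty\tB\n")
        with pytest.raises(IntegrityError):
            data_io.read_gmt(path)


class TestNetworkExport:
    @staticmethod
    def toy_net():
        net = nx.Graph()
        net.add_node(("drug", "D1"), node_class="drug", addictive=True)
        net.add_node(("drug", "D2"), node_class="drug", addictive=False)
        net.add_node(("target", "G1"), node_class="target", addictive=False)
        net.add_edge(("drug", "D1"), ("target", "G1"), edge_class="drug_target")
        net.add_edge(("drug", "D2"), ("target", "G1"), edge_class="drug_target")
        return net

    def test_sif_has_one_line_per_edge(self, tmp_path):
        path = tmp_path / "net.sif"
        data_io.export_network(self.toy_net(), path, "sif")
        assert len(path.read_text().strip().splitlines()) == 2

    def test_edge_tsv_roundtrip(self, tmp_path):
        net = self.toy_net()
        path = tmp_path / "net.tsv"
        data_io.export_network(net, path, "edge-tsv")
        back = data_io.read_edge_tsv(path)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in net.edges}
        assert back.nodes[("drug", "D1")]["addictive"] is True
        assert back.nodes[("drug", "D2")]["addictive"] is False

    def test_graphml_written_with_attributes(self, tmp_path):
        path = tmp_path / "net.graphml"
        data_io.export_network(self.toy_net(), path, "graphml")
        flat = nx.read_graphml(path)
        assert flat.nodes["drug:D1"]["node_class"] == "drug"
        assert flat.number_of_edges() == 2

    def test_empty_graph_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            data_io.export_network(nx.Graph(), tmp_path / "x.sif", "sif")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            data_io.export_network(self.toy_net(), tmp_path / "x", "gexf")


class TestPackagedTable:
    def test_counts_by_category_and_group(self):
        records = data_io.load_addictive_drug_table()
        assert len(records) == 44
        assert sum(1 for r in records if r.n_targets > 0) == 41
        categories = Counter(r.nida_category for r in records)
        assert categories == {
            "depressants": 12,
            "dissociative anesthetics": 2,
            "hallucinogens": 1,
            "opioids and morphine derivatives": 10,
            "stimulants": 6,
            "other compounds": 13,
        }
        assert sum(1 for r in records if "approved" in r.groups) == 39
        # the per-record table lists 23 illicit drugs
        assert sum(1 for r in records if "illicit" in r.groups) == 23
        assert sum(1 for r in records if "withdrawn" in r.groups) == 3
        assert sum(1 for r in records if "experimental" in r.groups) == 3

    def test_ids_are_wellformed_and_unique(self):
        records = data_io.load_addictive_drug_table()
        ids = [r.drug_id for r in records]
        assert len(set(ids)) == 44
        assert all(i.startswith("DB") and i[2:].isdigit() and len(i) == 7 for i in ids)
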
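import numpy as np
import pytest

from dppn.network_io import (
    InteractionRecord,
    apply_id_mapping,
    filter_interactions,
    load_annotations,
    read_annotation_map,
    read_edge_list,
    read_interactions,
    write_annotations,
    write_edge_list,
)
from dppn.virtual_expansion import multiplicity_summary


def rec(a, b, ta=9606, tb=9606, t="MI:0915"):
    return InteractionRecord(a, b, ta, tb, t)


class TestFilterInteractions:
    def test_four_criteria_hand_example(self):
        records = [
            rec("A", "B"),
            rec("B", "A"),  # duplicate under endpoint reordering
            rec("A", "A"),  # self-interaction
            rec("A", "C", t="MI:0403"),  # non-physical type
            rec("A", "D", tb=10090),  # human-mouse
        ]
        net = filter_interactions(records)
        assert net.edges == {("A", "B")}
        assert net.provenance["removed_taxon"] == 1
        assert net.provenance["removed_self"] == 1
        assert net.provenance["removed_type"] == 1
        assert net.provenance["removed_duplicate"] == 1

    def test_empty_input_gives_empty_network(self):
        net = filter_interactions([])
        assert net.nodes == [] and net.edges == set()

    def test_duplicate_collapse_across_types(self):
        net = filter_interactions([rec("A", "B", t="MI:0915"), rec("A", "B", t="MI:0407")])
        assert net.edges == {("A", "B")}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        records = [
            rec(f"P{rng.integers(20)}", f"P{rng.integers(20)}",
                ta=int(rng.choice([9606, 10090])),
                t=str(rng.choice(["MI:0915", "MI:0407", "MI:0403"])))
            for _ in range(200)
        ]
        once = filter_interactions(records)
        again = filter_interactions(
            [rec(u, v) for u, v in once.edges]
        )
        assert again.edges == once.edges

    def test_removal_bookkeeping_conserves_records(self):
        rng = np.random.default_rng(1)
        records = [
            rec(f"P{rng.integers(15)}", f"P{rng.integers(15)}",
                tb=int(rng.choice([9606, 7227])),
                t=str(rng.choice(["MI:0915", "MI:0407", "MI:0914"])))
            for _ in range(300)
        ]
        net = filter_interactions(records)
        p = net.provenance
        removed = (p["removed_taxon"] + p["removed_self"]
                   + p["removed_type"] + p["removed_duplicate"])
        assert p["input_records"] == p["kept_edges"] + removed

    def test_malformed_record_rejected(self):
        with pytest.raises(ValueError):
            rec("", "B")
        with pytest.raises(ValueError):
            rec("A", "B", ta=-1)


class TestLoadAnnotations:
    def test_evidence_and_vocabulary_filter(self):
        rows = [
            ("P1", "GO:0005634", "IDA"),
            ("P1", "GO:0005829", "IEA"),
            ("P2", "GO:0005739", "HDA"),
        ]
        assert load_annotations(rows) == {"P1": {"Nucleus"}, "P2": {"Mitochondrion"}}

    def test_all_non_experimental_evidence_gives_empty_map(self):
        rows = [("P1", "GO:0005634", "IEA"), ("P2", "GO:0005739", "ISS")]
        assert load_annotations(rows) == {}

    def test_out_of_vocabulary_term_dropped(self):
        # extracellular region is not one of the 12 modeled compartments
        assert load_annotations([("P1", "GO:0005576", "IDA")]) == {}

    def test_multiplicity_matches_brute_force_groupby(self):
        rng = np.random.default_rng(2)
        gos = ["GO:0005634", "GO:0005829", "GO:0005739", "GO:0005886"]
        rows = [
            (f"P{rng.integers(30)}", str(rng.choice(gos)),
             str(rng.choice(["IDA", "HDA", "IEA"])))
            for _ in range(400)
        ]
        amap = load_annotations(rows)
        expected: dict[str, set] = {}
        for p, go, ev in rows:
            if ev in ("IDA", "HDA"):
                expected.setdefault(p, set()).add(go)
        expected_counts = sorted(len(v) for v in expected.values())
        got = multiplicity_summary(amap)
        assert sorted(
            k for k, n in got.counts.items() for _ in range(n)
        ) == expected_counts


class TestIdMapping:
    def test_only_one_to_one_mappings_kept(self, triangle):
        mapping = {"A": "X", "B": "X", "C": "Z"}  # A and B collide on X
        mapped = apply_id_mapping(triangle, mapping)
        assert mapped.nodes == ["Z"]
        assert mapped.edges == set()

    def test_clean_mapping_renames_edges(self, triangle):
        mapped = apply_id_mapping(triangle, {"A": "X", "B": "Y", "C": "Z"})
        assert mapped.edges == {("X", "Y"), ("X", "Z"), ("Y", "Z")}


class TestFileRoundTrips:
    def test_edge_list_round_trip(self, tmp_path, k4):
        path = tmp_path / "edges.tsv"
        write_edge_list(k4, path)
        assert read_edge_list(path).edges == k4.edges

    def test_annotation_round_trip(self, tmp_path):
        amap = {"P1": {"Nucleus", "Cytosol"}, "P2": {"Mitochondrion"}}
        path = tmp_path / "ann.tsv"
        write_annotations(amap, path)
        assert read_annotation_map(path) == amap

    def test_read_interactions_minimal_tsv(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\t9606\t9606\tMI:0915\nA\tC\t9606\t9606\tMI:0407\n")
        records = read_interactions(path)
        assert len(records) == 2
        assert records[0].interactor_b == "B"
        net = filter_interactions(records)
        assert net.edges == {("A", "B"), ("A", "C")}
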
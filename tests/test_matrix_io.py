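"""Reading, validating, and re-serializing multi-condition matrices."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhibnet.errors import ConflictError, ConsistencyError, MatrixFormatError
from inhibnet.matrix_io import (
    InhibitionTensor,
    StrainSet,
    condition_slice,
    network_to_tensor,
    read_strain_metadata,
    read_tensor,
    union_network,
    write_long,
    write_sif,
    write_wide,
)

from conftest import random_tensor, strain_ids, tensor_from_arrays


class TestContainers:
    def test_strain_set_rejects_duplicates_and_partial_phylum(self):
        with pytest.raises(ConsistencyError, match="duplicate"):
            StrainSet(("A", "B", "A"))
        with pytest.raises(ConsistencyError, match="phylum"):
            StrainSet(("A", "B"), phylum={"A": "Firmicutes"})

    def test_tensor_rejects_nonbinary_entry_naming_cell(self):
        data = np.zeros((1, 3, 3), dtype=np.int64)
        data[0, 0, 1] = 2
        with pytest.raises(MatrixFormatError, match="S01.*S02"):
            tensor_from_arrays(data)

    def test_tensor_rejects_self_inhibition(self):
        data = np.zeros((2, 3, 3), dtype=np.uint8)
        data[1, 2, 2] = 1
        with pytest.raises(MatrixFormatError, match="diagonal"):
            tensor_from_arrays(data)

    def test_tensor_rejects_duplicate_conditions(self):
        data = np.zeros((2, 2, 2), dtype=np.uint8)
        with pytest.raises(ConsistencyError, match="condition"):
            InhibitionTensor(StrainSet(("A", "B")), ("c1", "c1"), data)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_wide_round_trip_is_exact(self, tmp_path, seed):
        tensor = random_tensor(np.random.default_rng(seed), n=6, k=3)
        paths = write_wide(tensor, tmp_path)
        back = read_tensor(paths, format="wide")
        assert back.strains.ids == tensor.strains.ids
        assert back.conditions == tensor.conditions
        assert np.array_equal(back.data, tensor.data)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_long_round_trip_with_declared_strains(self, tmp_path, seed):
        tensor = random_tensor(np.random.default_rng(seed), n=5, k=2)
        path = write_long(tensor, tmp_path / "edges.tsv")
        # one sparse file holding all conditions, filtered per pass
        back = read_tensor(
            {c: path for c in tensor.conditions}, format="long",
            strains=tensor.strains.ids,
        )
        assert back.strains.ids == tensor.strains.ids
        assert back.conditions == tensor.conditions
        assert np.array_equal(back.data, tensor.data)

    def test_long_per_condition_files_round_trip(self, tmp_path):
        tensor = random_tensor(np.random.default_rng(11), n=5, k=3)
        paths = {}
        for ci, c in enumerate(tensor.conditions):
            sub = tensor_from_arrays(tensor.data[ci:ci + 1], (c,))
            paths[c] = write_long(sub, tmp_path / f"{c}.tsv")
        back = read_tensor(paths, format="long", strains=tensor.strains.ids)
        assert np.array_equal(back.data, tensor.data)
        assert back.conditions == tensor.conditions

    def test_union_idempotent_through_long_reserialization(self, tmp_path):
        tensor = random_tensor(np.random.default_rng(5), n=6, k=3)
        net = union_network(tensor)
        back = union_network(network_to_tensor(net))
        assert back.edges == net.edges


class TestReaders:
    def test_wide_shape_propagation(self, tmp_path):
        tensor = random_tensor(np.random.default_rng(0), n=21, k=3)
        paths = write_wide(tensor, tmp_path)
        back = read_tensor(paths)
        assert back.n_species == 21 and back.n_conditions == 3

    def test_wide_strain_order_taken_from_first_file(self, tmp_path):
        (tmp_path / "c1.tsv").write_text(
            "\tB\tA\nB\t0\t1\nA\t0\t0\n", encoding="utf-8")
        (tmp_path / "c2.tsv").write_text(
            "\tA\tB\nA\t0\t0\nB\t1\t0\n", encoding="utf-8")
        tensor = read_tensor({"c1": tmp_path / "c1.tsv",
                              "c2": tmp_path / "c2.tsv"})
        assert tensor.strains.ids == ("B", "A")
        # c2 records B->A; in canonical (B, A) order that is cell [0, 1]
        assert tensor.matrix("c2")[0, 1] == 1
        assert tensor.matrix("c2")[1, 0] == 0

    def test_wide_nonbinary_value_names_labels(self, tmp_path):
        (tmp_path / "c1.tsv").write_text(
            "\tA\tB\nA\t0\t2\nB\t0\t0\n", encoding="utf-8")
        with pytest.raises(MatrixFormatError, match="'A'.*'B'"):
            read_tensor({"c1": tmp_path / "c1.tsv"})

    def test_wide_mismatched_strain_sets_lists_difference(self, tmp_path):
        (tmp_path / "c1.tsv").write_text(
            "\tA\tB\nA\t0\t1\nB\t0\t0\n", encoding="utf-8")
        (tmp_path / "c2.tsv").write_text(
            "\tA\tC\nA\t0\t1\nC\t0\t0\n", encoding="utf-8")
        with pytest.raises(ConsistencyError) as err:
            read_tensor({"c1": tmp_path / "c1.tsv",
                         "c2": tmp_path / "c2.tsv"})
        assert "B" in str(err.value) and "C" in str(err.value)

    def test_long_single_positive_row(self, tmp_path):
        (tmp_path / "m1.tsv").write_text(
            "producer\treceiver\tcondition\tvalue\nA\tB\tmedium1\t1\n",
            encoding="utf-8")
        tensor = read_tensor({"medium1": tmp_path / "m1.tsv"},
                             format="long", strains=("A", "B", "C"))
        assert tensor.data.sum() == 1
        assert tensor.matrix("medium1")[0, 1] == 1

    def test_long_missing_cells_default_zero_with_warning(self, tmp_path,
                                                          caplog):
        (tmp_path / "m1.tsv").write_text(
            "producer\treceiver\tvalue\nA\tB\t1\n", encoding="utf-8")
        with caplog.at_level("WARNING", logger="inhibnet.matrix_io"):
            read_tensor({"m1": tmp_path / "m1.tsv"}, format="long",
                        strains=("A", "B", "C"))
        assert "8 unspecified cells" in caplog.text  # 9 cells - 1 given

    def test_long_conflicting_duplicates_raise(self, tmp_path):
        (tmp_path / "m1.tsv").write_text(
            "producer\treceiver\tvalue\nA\tB\t1\nA\tB\t0\n",
            encoding="utf-8")
        with pytest.raises(ConflictError, match="A.*B"):
            read_tensor({"m1": tmp_path / "m1.tsv"}, format="long",
                        strains=("A", "B"))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.tsv"):
            read_tensor({"c1": tmp_path / "nope.tsv"})

    def test_strain_metadata(self, tmp_path):
        (tmp_path / "meta.tsv").write_text(
            "strain\tphylum\nA\tFirmicutes\nB\tBacteroidetes\n",
            encoding="utf-8")
        assert read_strain_metadata(tmp_path / "meta.tsv") == {
            "A": "Firmicutes", "B": "Bacteroidetes"}


class TestNetworks:
    def test_union_merges_supports_into_one_edge(self):
        data = np.zeros((3, 3, 3), dtype=np.uint8)
        data[:, 0, 1] = 1  # A->B in all three conditions
        data[0, 1, 2] = 1  # B->C in the first only
        net = union_network(tensor_from_arrays(data))
        assert net.n_edges == 2
        ids = strain_ids(3)
        assert net.support(ids[0], ids[1]) == frozenset(("c1", "c2", "c3"))
        assert net.support(ids[1], ids[2]) == frozenset(("c1",))

    def test_union_of_all_zero_tensor_is_empty(self):
        net = union_network(tensor_from_arrays(np.zeros((2, 4, 4))))
        assert net.n_edges == 0

    def test_condition_slice_singleton_support_and_lookup_error(self):
        data = np.zeros((2, 3, 3), dtype=np.uint8)
        data[1, 0, 2] = 1
        tensor = tensor_from_arrays(data)
        sliced = condition_slice(tensor, "c2")
        assert sliced.n_edges == 1
        assert all(s == frozenset(("c2",)) for s in sliced.edges.values())
        assert condition_slice(tensor, "c1").n_edges == 0
        with pytest.raises(KeyError, match="c9"):
            condition_slice(tensor, "c9")

    @pytest.mark.parametrize("seed", range(5))
    def test_slices_partition_the_detections(self, seed):
        tensor = random_tensor(np.random.default_rng(seed), n=7, k=3)
        union = union_network(tensor)
        slice_edges = sum(
            condition_slice(tensor, c).n_edges for c in tensor.conditions)
        assert slice_edges == int(tensor.data.sum())
        assert union.n_edges <= slice_edges
        multi = sum(1 for s in union.edges.values() if len(s) >= 2)
        assert (union.n_edges == slice_edges) == (multi == 0)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    n=st.integers(2, 7),
    k=st.integers(1, 4),
    seed=st.integers(0, 2 ** 16),
)
def test_round_trip_property_any_shape(tmp_path_factory, n, k, seed):
    """Write-then-read reproduces entries, strain order, and condition
    order exactly, for arbitrary shapes and densities (both formats)."""
    tmp = tmp_path_factory.mktemp("rt")
    rng = np.random.default_rng(seed)
    tensor = random_tensor(rng, n=n, k=k,
                           density=float(rng.uniform(0.0, 0.6)))
    wide_back = read_tensor(write_wide(tensor, tmp / f"w{seed}"))
    assert wide_back.strains.ids == tensor.strains.ids
    assert wide_back.conditions == tensor.conditions
    assert np.array_equal(wide_back.data, tensor.data)
    long_path = write_long(tensor, tmp / f"l{seed}.tsv")
    long_back = read_tensor({c: long_path for c in tensor.conditions},
                            format="long", strains=tensor.strains.ids)
    assert np.array_equal(long_back.data, tensor.data)


def test_sif_export_format(tmp_path):
    data = np.zeros((1, 3, 3), dtype=np.uint8)
    data[0, 0, 1] = 1
    net = union_network(tensor_from_arrays(data))
    path = write_sif(net, tmp_path / "net.sif")
    assert path.read_text() == "S01\tinhibits\tS02\n"
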
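"""Matrix loading, dual-route feature assignment and cumuCC properties."""

import math

import numpy as np
import pytest

from resconn.features import (
    CorrelationMatrix,
    assign_hash,
    assign_materialized,
    cumucc,
    load_correlation_matrix,
)
from resconn.graphs import (
    complete_unipartite,
    enumerate_pairs,
    make_cross,
    make_memconp,
    make_patch,
)
from tests.conftest import random_matrix


class TestCorrelationMatrix:
    def test_symmetric_access_and_default(self):
        m = CorrelationMatrix(4, {(1, 3): 0.7, (2, 4): 0.2})
        assert m.value(3, 1) == 0.7
        assert m.value(4, 2) == 0.2
        assert m.value(1, 2) == 0.0
        assert m.value(2, 2) == 0.0

    def test_out_of_range_rejected(self):
        m = CorrelationMatrix(4)
        with pytest.raises(ValueError):
            m.value(0, 1)
        with pytest.raises(ValueError):
            m.set(1, 5, 0.3)


class TestMatrixLoader:
    def test_freecontact_dialect(self, tmp_path):
        path = tmp_path / "scores"
        path.write_text("1 A 3 G 0.7\n2 A 4 V 0.2\n")
        m = load_correlation_matrix(path, L=4)
        assert m.value(3, 1) == 0.7
        assert m.value(4, 2) == 0.2
        assert m.value(1, 2) == 0.0

    def test_three_column_dialect(self, tmp_path):
        path = tmp_path / "scores"
        path.write_text("1 2 0.5\n3 4 -0.25\n")
        m = load_correlation_matrix(path, L=4)
        assert m.value(1, 2) == 0.5
        assert m.value(4, 3) == -0.25

    def test_score_column_selection(self, tmp_path):
        path = tmp_path / "scores"
        path.write_text("1 A 2 C 0.1 0.9\n")
        m = load_correlation_matrix(path, L=2, score_column=1)
        assert m.value(1, 2) == 0.9

    def test_empty_file_gives_zero_matrix(self, tmp_path):
        path = tmp_path / "scores"
        path.write_text("")
        m = load_correlation_matrix(path, L=5)
        assert len(m) == 0
        assert m.value(2, 5) == 0.0

    def test_duplicate_pair_last_wins(self, tmp_path, caplog):
        path = tmp_path / "scores"
        path.write_text("1 2 0.5\n2 1 0.8\n")
        with caplog.at_level("WARNING"):
            m = load_correlation_matrix(path, L=3)
        assert m.value(1, 2) == 0.8
        assert any("duplicate" in r.message for r in caplog.records)

    @pytest.mark.parametrize("row", ["0 1 0.5", "1 6 0.5", "1 1 0.5", "1 2 abc"])
    def test_malformed_rows_rejected(self, tmp_path, row):
        path = tmp_path / "scores"
        path.write_text(row + "\n")
        with pytest.raises(ValueError):
            load_correlation_matrix(path, L=5)


ALL_GRAPHS = [
    ("patch1", make_patch(1), 0), ("patch2", make_patch(2), 0),
    ("patch3", make_patch(3), 0), ("memconp", make_memconp(), 0),
    ("cross1", make_cross(1), 0), ("cross2", make_cross(2), 0),
    ("cross3", make_cross(3), 0),
    ("loc1", complete_unipartite(1), 1), ("loc2", complete_unipartite(2), 2),
    ("loc3", complete_unipartite(3), 3),
]


class TestAssignment:
    def test_single_pair_direct_lookup(self):
        m = CorrelationMatrix(5, {(2, 4): 0.9})
        table = assign_hash([(2, 4)], make_cross(0), m)
        assert table.values.tolist() == [[0.9]]

    def test_boundary_columns_take_placeholder(self):
        m = random_matrix(np.random.default_rng(0), 4)
        table = assign_hash([(1, 3)], make_patch(1), m, placeholder_value=-7.0)
        cl_offsets = make_patch(1).offsets
        for k, (a, b) in enumerate(cl_offsets):
            if 1 + a < 1 or 3 + b > 4:
                assert table.values[0, k] == -7.0

    def test_empty_centers(self):
        m = CorrelationMatrix(5)
        table = assign_materialized([], make_patch(1), m)
        assert table.shape == (0, 9)

    def test_locrrc_column_count(self):
        m = random_matrix(np.random.default_rng(1), 10)
        table = assign_materialized([5], complete_unipartite(1), m, w=1)
        assert table.shape == (1, 6)

    def test_dimension_error(self):
        m = CorrelationMatrix(5)
        with pytest.raises(ValueError):
            assign_hash([(2, 8)], make_patch(1), m)

    @pytest.mark.parametrize("name,graph,w", ALL_GRAPHS)
    def test_hash_equals_materialized(self, name, graph, w, rng):
        """Defining property: the direct route reproduces the materialized
        3D-object route element-wise."""
        L = int(rng.integers(20, 81))
        m = random_matrix(rng, L)
        if w:
            centers = list(rng.integers(1, L + 1, size=10))
        else:
            pairs = enumerate_pairs(L, 1)
            centers = [pairs[k] for k in rng.choice(len(pairs), size=10, replace=False)]
        a = assign_hash(centers, graph, m, w=w)
        b = assign_materialized(centers, graph, m, w=w)
        np.testing.assert_array_equal(a.values, b.values)

    def test_center_permutation_permutes_rows(self, rng):
        L = 30
        m = random_matrix(rng, L)
        centers = enumerate_pairs(L, 5)[:12]
        perm = list(rng.permutation(len(centers)))
        a = assign_hash(centers, make_patch(2), m)
        b = assign_hash([centers[k] for k in perm], make_patch(2), m)
        np.testing.assert_array_equal(a.values[perm], b.values)

    def test_lookup_count_linear_in_centers(self, rng):
        """Operation-count analogue of the linear-time claim: lookups grow
        exactly linearly with the number of centers for a fixed template."""
        L = 60
        graph = make_patch(2)
        # interior, well-separated pairs: every connection then costs
        # exactly one lookup
        pairs = [(p, q) for p, q in enumerate_pairs(L, 5)
                 if p > 2 and q <= L - 2]
        sizes = [50, 100, 200, 400]
        counts = []
        for n in sizes:
            m = random_matrix(np.random.default_rng(3), L)
            assign_hash(pairs[:n], graph, m)
            counts.append(m.lookups)
        slopes = np.diff(np.log(counts)) / np.diff(np.log(sizes))
        np.testing.assert_allclose(slopes, 1.0, atol=1e-12)

    def test_tsv_roundtrip(self, tmp_path, rng):
        import pandas as pd
        m = random_matrix(rng, 20)
        table = assign_hash(enumerate_pairs(20, 8)[:5], make_cross(1), m)
        out = tmp_path / "features.tsv"
        table.to_tsv(out)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns[:2]) == ["p", "q"]
        assert df.shape == (5, 2 + 5)


class TestCumuCC:
    def test_hand_worked_l4_example(self, small_matrix):
        """k=2 selects pairs (1,2) and (1,3); CC = [7, 4, 3, 0]; c is the
        mean over all six pairs (10.5 / 6 = 1.75)."""
        res = cumucc(small_matrix, ratio=0.5)
        assert res.k_used == 2
        assert res.c == pytest.approx(1.75)
        np.testing.assert_allclose(res.scores * res.c, [7.0, 4.0, 3.0, 0.0])

    def test_brute_force_all_pairs(self, small_matrix):
        """ratio large enough to select all six pairs: CC_R is the full
        row sum of the matrix."""
        res = cumucc(small_matrix, ratio=10)
        assert res.k_used == 6
        row_sums = [4 + 3 + 0.5, 4 + 2 + 0.5, 3 + 2 + 0.5, 1.5]
        np.testing.assert_allclose(res.scores * res.c, row_sums)

    def test_constant_matrix_closed_form(self):
        """With all pairs equal to v, c = v and each score counts the
        selected pairs containing the residue."""
        L = 6
        m = CorrelationMatrix(L, {(i, j): 2.5 for i in range(1, L + 1)
                                  for j in range(i + 1, L + 1)})
        res = cumucc(m, ratio=1.0)
        assert res.c == pytest.approx(2.5)
        # ties broken ascending (i,j): the 6 selected pairs are (1,2)..(1,6),(2,3)
        np.testing.assert_allclose(res.scores, [5, 2, 2, 1, 1, 1])

    def test_sum_rule(self, rng):
        """Sum of CC_R over residues is twice the selected-score total."""
        L = 25
        m = random_matrix(rng, L)
        res = cumucc(m, ratio=2.0)
        stored = dict(m.items())
        ranked = sorted(stored.items(), key=lambda kv: (-kv[1], kv[0]))
        top = sum(v for _, v in ranked[:res.k_used])
        assert np.sum(res.scores) * res.c == pytest.approx(2 * top)

    def test_positive_scale_invariance(self, rng):
        L = 15
        m = random_matrix(rng, L)
        scaled = CorrelationMatrix(L, {ij: 3.7 * v for ij, v in m.items()})
        a = cumucc(m, ratio=1.5)
        b = cumucc(scaled, ratio=1.5)
        np.testing.assert_allclose(a.scores, b.scores, rtol=1e-12)
        assert a.k_used == b.k_used

    def test_k_capped_at_pair_count(self, small_matrix):
        assert cumucc(small_matrix, ratio=100).k_used == 6

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cumucc(CorrelationMatrix(5), ratio=1.0)

    def test_nonpositive_ratio_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            cumucc(small_matrix, ratio=0.0)

    def test_per_residue_variant(self, small_matrix):
        """Opt-in variant: each residue sums its own k highest partners."""
        res = cumucc(small_matrix, ratio=0.5, per_residue=True)  # k = 2
        np.testing.assert_allclose(res.scores * res.c, [7.0, 6.0, 5.0, 1.0])
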
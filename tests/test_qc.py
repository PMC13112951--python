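import io

import numpy as np
import pytest

from seqgnped.ideal import cumulative_ideal
from seqgnped.qc import (
    PatternSpace,
    QcMatrix,
    build_collapsed_classes,
    dichotomize_scores,
    read_qc_matrix,
    undichotomize_scores,
    write_qc_matrix,
)


class TestQcMatrix:
    def test_bundled_matrix_structure(self, qc21):
        assert qc21.n_items == 21
        assert qc21.n_attributes == 5
        assert list(qc21.max_scores) == [2] * 13 + [3] * 3 + [1] * 5
        assert qc21.n_categories == 40
        assert qc21.complete

    def test_non_binary_entry_rejected(self):
        csv = "item,cat,A1,A2\n1,1,1,2\n"
        with pytest.raises(ValueError, match="binary"):
            read_qc_matrix(io.StringIO(csv))

    def test_category_gap_rejected(self):
        csv = "item,cat,A1,A2\n1,1,1,0\n1,3,0,1\n"
        with pytest.raises(ValueError, match="1..S_j"):
            read_qc_matrix(io.StringIO(csv))

    def test_duplicate_item_cat_rejected(self):
        csv = "item,cat,A1\n1,1,1\n1,1,1\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_qc_matrix(io.StringIO(csv))

    def test_zero_row_warns_but_loads(self):
        csv = "item,cat,A1,A2\n1,1,0,0\n2,1,1,1\n"
        with pytest.warns(UserWarning, match="all-zero"):
            qc = read_qc_matrix(io.StringIO(csv))
        assert qc.n_items == 2

    def test_incomplete_attribute_coverage_warns(self):
        csv = "item,cat,A1,A2\n1,1,1,0\n"
        with pytest.warns(UserWarning, match="incomplete"):
            qc = read_qc_matrix(io.StringIO(csv))
        assert not qc.complete

    def test_roundtrip(self, qc21, tmp_path):
        path = tmp_path / "qc.csv"
        write_qc_matrix(qc21, path)
        back = read_qc_matrix(path)
        assert np.array_equal(back.q, qc21.q)
        assert np.array_equal(back.item_of_row, qc21.item_of_row)
        assert np.array_equal(back.cat_of_row, qc21.cat_of_row)


class TestPatternSpace:
    def test_canonical_order_msb_first(self):
        ps = PatternSpace(3)
        pats = ps.patterns
        assert pats.shape == (8, 3)
        assert list(pats[0]) == [0, 0, 0]
        assert list(pats[1]) == [0, 0, 1]  # attribute 1 is the MSB
        assert list(pats[4]) == [1, 0, 0]
        # each pattern appears exactly once
        assert len({tuple(p) for p in pats}) == 8

    def test_index_roundtrip(self):
        ps = PatternSpace(4)
        for m, p in enumerate(ps.patterns):
            assert ps.index_of(p) == m

    def test_capacity_guard(self):
        with pytest.raises(ValueError):
            PatternSpace(20)


class TestDichotomize:
    @pytest.mark.parametrize(
        "score,expected",
        [(0, [0, 0, 0]), (1, [1, 0, 0]), (2, [1, 1, 0]), (3, [1, 1, 1])],
    )
    def test_threshold_rule(self, score, expected):
        qc = QcMatrix.from_arrays([[[1, 0], [0, 1], [1, 1]]])
        Y = dichotomize_scores(np.array([[score]]), qc)
        assert list(Y[0]) == expected

    def test_out_of_range_score_named(self, qc21):
        X = np.zeros((3, 21), dtype=int)
        X[1, 16] = 2  # item 17 is dichotomous
        with pytest.raises(ValueError, match=r"X\[1,16\]"):
            dichotomize_scores(X, qc21)

    def test_monotone_and_invertible(self, qc21):
        rng = np.random.default_rng(42)
        X = rng.integers(0, qc21.max_scores[None, :] + 1, size=(50, 21))
        Y = dichotomize_scores(X, qc21)
        # non-increasing within each item's categories
        for j in range(qc21.n_items):
            rows = qc21.item_rows(j)
            assert (np.diff(Y[:, rows], axis=1) <= 0).all()
        assert np.array_equal(undichotomize_scores(Y, qc21), X)


class TestCollapsedClasses:
    def test_two_attribute_category_collapses_unused(self):
        # K=3, single category requiring attributes 1 and 2
        qc = QcMatrix.from_arrays([[[1, 1, 0]]])
        ps = PatternSpace(3)
        idx = build_collapsed_classes(qc, ps)
        assert idx.n_classes[0] == 4
        lab = idx.class_of_pattern[0]
        pats = ps.patterns
        i000 = ps.index_of([0, 0, 0])
        i001 = ps.index_of([0, 0, 1])
        i100 = ps.index_of([1, 0, 0])
        assert lab[i000] == lab[i001]
        assert lab[i000] != lab[i100]

    def test_second_category_uses_cumulative_attribute_set(self):
        # relevant set at h=2 is the union {1,2}: 4 singleton classes
        qc = QcMatrix.from_arrays([[[1, 0], [0, 1]]])
        ps = PatternSpace(2)
        idx = build_collapsed_classes(qc, ps)
        assert idx.n_classes[1] == 4
        assert len(set(idx.class_of_pattern[1])) == 4

    def test_full_q_vector_gives_injective_mapping(self):
        qc = QcMatrix.from_arrays([[[1, 1, 1]]])
        idx = build_collapsed_classes(qc, PatternSpace(3))
        assert len(set(idx.class_of_pattern[0])) == 8

    def test_classes_constant_in_cumulative_ideals(self, random_qc):
        # brute force: patterns sharing a class share (eta_c, eta_d) at that cell
        rng = np.random.default_rng(7)
        for _ in range(10):
            qc = random_qc(rng)
            ps = PatternSpace(qc.n_attributes)
            idx = build_collapsed_classes(qc, ps)
            for c in range(qc.n_categories):
                j, h = qc.item_of_row[c], qc.cat_of_row[c]
                cats = list(qc.q[qc.item_rows(j)])
                seen = {}
                for m, alpha in enumerate(ps.patterns):
                    key = idx.class_of_pattern[c, m]
                    val = (
                        cumulative_ideal(alpha, cats, h, "conjunctive"),
                        cumulative_ideal(alpha, cats, h, "disjunctive"),
                    )
                    assert seen.setdefault(key, val) == val
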
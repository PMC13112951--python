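import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqgnped.qc import QcMatrix
from seqgnped.simulate import (
    generate_seq_dina,
    generate_seq_gdina,
    misspecify_q,
    reduce_polytomous_proportion,
    reduce_polytomous_qc,
    sample_profiles_higher_order,
    sample_profiles_uniform,
    sequential_response_probability,
)


class TestProfileSampling:
    def test_uniform_marginal_rate(self):
        alpha = sample_profiles_uniform(10_000, 1, seed=1)
        assert abs(alpha.mean() - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_uniform_patterns_equiprobable(self):
        from scipy.stats import chisquare

        alpha = sample_profiles_uniform(100_000, 5, seed=2)
        codes = alpha @ (1 << np.arange(4, -1, -1))
        _, p = chisquare(np.bincount(codes, minlength=32))
        assert p > 0.01

    def test_seed_determinism(self):
        a = sample_profiles_uniform(100, 4, seed=3)
        b = sample_profiles_uniform(100, 4, seed=3)
        assert np.array_equal(a, b)

    def test_higher_order_difficulty_grid(self):
        _, params = sample_profiles_higher_order(10, 5, seed=4)
        assert np.allclose(params.lambda0, [-1.5, -0.75, 0.0, 0.75, 1.5])
        assert ((params.lambda1 >= 1) & (params.lambda1 <= 2)).all()

    def test_higher_order_mastery_decreases_with_difficulty(self):
        alpha, params = sample_profiles_higher_order(50_000, 5, seed=5)
        rates = alpha.mean(axis=0)
        # lambda0 increases across attributes, so mastery rates must decrease
        assert (np.diff(rates) < 0).all()


class TestSequentialResponseProbability:
    @pytest.mark.parametrize(
        "S,expected",
        [
            ((0.8, 0.6), (0.2, 0.32, 0.48)),
            ((1.0, 1.0), (0.0, 0.0, 1.0)),
            ((0.0, 0.3), (1.0, 0.0, 0.0)),
        ],
    )
    def test_direct_cases(self, S, expected):
        assert sequential_response_probability(S) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_sums_to_one(self, S):
        assert sequential_response_probability(S).sum() == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sequential_response_probability([0.5, 1.2])


class TestSeqDina:
    def test_full_mastery_score_distribution(self):
        # 2-category item, full masterer: P(X=2)=1-s, P(0)=P(1)=s/2
        qc = QcMatrix.from_arrays([[[1, 0], [0, 1]]])
        alpha = np.ones((100_000, 2), dtype=int)
        X = generate_seq_dina(alpha, qc, s=0.05, seed=6)
        freq = np.bincount(X[:, 0], minlength=3) / len(X)
        tol = 4 * np.sqrt(0.05 / 100_000)
        assert abs(freq[2] - 0.95) < tol
        assert abs(freq[0] - 0.025) < tol
        assert abs(freq[1] - 0.025) < tol

    def test_zero_slip_is_deterministic_depth(self):
        qc = QcMatrix.from_arrays([[[1, 0], [0, 1]], [[0, 1]]])
        alpha = np.array([[1, 0], [1, 1], [0, 0]])
        X = generate_seq_dina(alpha, qc, s=0.0, seed=7)
        assert list(X[0]) == [1, 0]  # passes step 1 only; fails item 2
        assert list(X[1]) == [2, 1]
        assert list(X[2]) == [0, 0]

    def test_seed_determinism(self, qc21):
        alpha = sample_profiles_uniform(50, 5, seed=8)
        assert np.array_equal(
            generate_seq_dina(alpha, qc21, 0.1, seed=9),
            generate_seq_dina(alpha, qc21, 0.1, seed=9),
        )


class TestSeqGdina:
    def test_links_are_balanced(self, qc21):
        alpha = sample_profiles_uniform(5, 5, seed=10)
        links = [
            generate_seq_gdina(alpha, qc21, 0.05, seed=s, return_params=True)[1]["link"]
            for s in range(200)
        ]
        rate = np.mean(np.concatenate(links))
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / (200 * 21))

    def test_boundary_mastery_matches_seq_dina_distribution(self):
        # full- and zero-mastery examinees see the same score law in both schemes
        qc = QcMatrix.from_arrays([[[1, 1], [1, 0]]])
        alpha_full = np.ones((100_000, 2), dtype=int)
        Xg = generate_seq_gdina(alpha_full, qc, 0.1, seed=11)
        Xd = generate_seq_dina(alpha_full, qc, 0.1, seed=12)
        fg = np.bincount(Xg[:, 0], minlength=3) / len(Xg)
        fd = np.bincount(Xd[:, 0], minlength=3) / len(Xd)
        assert np.allclose(fg, fd, atol=0.01)

    def test_zero_slip_full_mastery_tops_out(self, qc21):
        alpha = np.ones((20, 5), dtype=int)
        X = generate_seq_gdina(alpha, qc21, s=0.0, seed=13)
        assert np.array_equal(X, np.tile(qc21.max_scores, (20, 1)))

    def test_seed_determinism(self, qc21):
        alpha = sample_profiles_uniform(30, 5, seed=14)
        assert np.array_equal(
            generate_seq_gdina(alpha, qc21, 0.1, seed=15),
            generate_seq_gdina(alpha, qc21, 0.1, seed=15),
        )


class TestMisspecifyQ:
    def test_rate_zero_identity(self, qc21):
        out = misspecify_q(qc21, 0.0, seed=16)
        assert np.array_equal(out.q, qc21.q)

    def test_altered_row_count_and_constraints(self, qc21):
        out = misspecify_q(qc21, 0.1, seed=17)
        diff_rows = np.flatnonzero((out.q != qc21.q).any(axis=1))
        assert len(diff_rows) == 4  # ceil(0.1 * 40)
        for c in diff_rows:
            hamming = int(np.abs(out.q[c] - qc21.q[c]).sum())
            assert 1 <= hamming <= 3
            assert out.q[c].sum() > 0

    def test_seed_determinism(self, qc21):
        a = misspecify_q(qc21, 0.2, seed=18)
        b = misspecify_q(qc21, 0.2, seed=18)
        assert np.array_equal(a.q, b.q)


class TestPolytomousReduction:
    def test_target_75_is_identity(self, qc21):
        rng_scores = np.random.default_rng(19)
        X = rng_scores.integers(0, qc21.max_scores[None, :] + 1, size=(10, 21))
        out_qc, out_X = reduce_polytomous_proportion(qc21, X, 75, seed=20)
        assert out_qc is qc21
        assert np.array_equal(out_X, X)

    def test_converted_item_gets_union_q_and_max_rule(self, qc21):
        rng = np.random.default_rng(21)
        X = rng.integers(0, qc21.max_scores[None, :] + 1, size=(200, 21))
        out_qc, out_X = reduce_polytomous_proportion(qc21, X, 25, seed=22)
        assert (out_qc.max_scores >= 2).sum() == 6  # 16 - 10 converted
        converted = np.flatnonzero((qc21.max_scores >= 2) & (out_qc.max_scores == 1))
        assert len(converted) == 10
        for j in converted:
            union = qc21.q[qc21.item_rows(j)].max(axis=0)
            assert np.array_equal(out_qc.q[out_qc.item_rows(j)[0]], union)
            assert np.array_equal(out_X[:, j], (X[:, j] == qc21.max_scores[j]).astype(int))

    def test_qc_only_reduction_matches_counts(self, qc21):
        out = reduce_polytomous_qc(qc21, 50, seed=23)
        assert (out.max_scores >= 2).sum() == 11
        assert out.n_items == 21

    def test_too_many_conversions_rejected(self):
        qc = QcMatrix.from_arrays([[[1, 0], [0, 1]], [[1, 1]]])
        with pytest.raises(ValueError, match="cannot convert"):
            reduce_polytomous_qc(qc, 25, seed=24)

    def test_invalid_target_rejected(self, qc21):
        with pytest.raises(ValueError, match="75, 50, 25"):
            reduce_polytomous_qc(qc21, 60, seed=25)
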
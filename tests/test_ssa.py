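import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradsig import (
    ExpressionProfile,
    decompose,
    diagonal_average,
    embed,
    extract_signal_ssa,
    reconstruct_group,
    rmse,
    sdd_curve,
    w_correlation,
    w_correlation_weights,
)


def _exp_profile(A=10.0, lam=20.0, n=61):
    x = np.arange(float(n))
    return ExpressionProfile("exp", x, sdd_curve(A, lam, x), "simulated_truth")


class TestEmbed:
    def test_lagged_vectors_definition(self):
        X = embed([1, 2, 3, 4], 2)
        np.testing.assert_array_equal(X.values, [[1, 2, 3], [2, 3, 4]])

    def test_shape_is_L_by_K(self):
        X = embed(np.arange(5.0), 3)
        assert X.values.shape == (3, 3)
        assert X.K == 3

    def test_hankel_structure(self):
        X = embed(np.random.default_rng(0).normal(size=12), 5).values
        for i in range(4):
            np.testing.assert_array_equal(X[i + 1, :-1], X[i, 1:])

    def test_geometric_series_has_rank_one(self):
        y = 3.0 * 0.9 ** np.arange(50)
        s = np.linalg.svd(embed(y, 25).values, compute_uv=False)
        assert s[1] < 1e-10 * s[0]

    @pytest.mark.parametrize("L", [1, 0, 12, 20])
    def test_window_length_bounds(self, L):
        with pytest.raises(ValueError):
            embed(np.arange(12.0), L)


class TestDecompose:
    def test_constant_series_single_component(self):
        dec = decompose(embed(np.full(10, 4.0), 4))
        assert dec.rank_d == 1

    def test_elementary_matrices_sum_to_X(self):
        X = embed(np.random.default_rng(1).normal(size=14), 6)
        dec = decompose(X)
        total = (dec.left_vectors * dec.singular_values) @ dec.right_vectors.T
        np.testing.assert_allclose(total, X.values, atol=1e-10)

    def test_singular_values_match_eigendecomposition_oracle(self):
        X = embed(np.random.default_rng(2).normal(size=13), 6)
        dec = decompose(X)
        eigvals = np.linalg.eigvalsh(X.values @ X.values.T)[::-1]
        np.testing.assert_allclose(dec.singular_values**2, eigvals, atol=1e-8)

    def test_left_vectors_orthonormal(self):
        dec = decompose(embed(np.random.default_rng(3).normal(size=30), 12))
        gram = dec.left_vectors.T @ dec.left_vectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_nonfinite_rejected(self):
        X = embed(np.arange(8.0), 3)
        bad = X.values.copy()
        bad[0, 0] = np.nan
        from gradsig import TrajectoryMatrix

        with pytest.raises(ValueError):
            decompose(TrajectoryMatrix(bad, 3, 8))


class TestReconstruct:
    def test_antidiagonal_means(self):
        np.testing.assert_allclose(diagonal_average([[1, 2], [3, 4]]), [1, 2.5, 4])

    def test_full_group_returns_series(self):
        y = np.random.default_rng(4).normal(size=25)
        X = embed(y, 10)
        dec = decompose(X)
        back = reconstruct_group(dec, X, range(1, dec.rank_d + 1))
        np.testing.assert_allclose(back, y, atol=1e-10)

    def test_first_eigentriple_recovers_noiseless_exponential(self):
        p = _exp_profile()
        X = embed(p.intensities, 30)
        dec = decompose(X)
        back = reconstruct_group(dec, X, [1])
        assert np.max(np.abs(back - p.intensities)) < 1e-8

    def test_partition_additivity(self):
        y = np.random.default_rng(5).normal(size=30)
        X = embed(y, 12)
        dec = decompose(X)
        d = dec.rank_d
        part1 = reconstruct_group(dec, X, range(1, d // 2 + 1))
        part2 = reconstruct_group(dec, X, range(d // 2 + 1, d + 1))
        np.testing.assert_allclose(part1 + part2, y, atol=1e-9)

    @pytest.mark.parametrize("group", [[], [0], [99]])
    def test_bad_groups_rejected(self, group):
        X = embed(np.arange(10.0), 4)
        with pytest.raises(ValueError):
            reconstruct_group(decompose(X), X, group)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_sum_of_m_exponentials_needs_m_components(self, m):
        rates = [0.95, 0.8, 0.6][:m]
        i = np.arange(60.0)
        y = sum((j + 1) * r**i for j, r in enumerate(rates))
        X = embed(y, 30)
        dec = decompose(X)
        assert dec.rank_d == m
        back = reconstruct_group(dec, X, range(1, m + 1))
        np.testing.assert_allclose(back, y, atol=1e-7)


class TestExtractSignal:
    def test_noiseless_exponential_residual_negligible(self):
        e = extract_signal_ssa(_exp_profile(), n_components=1)
        assert np.max(np.abs(e.residual)) < 1e-8

    def test_full_rank_reconstruction_leaves_no_residual(self, noisy_replicate):
        _, noisy = noisy_replicate
        from gradsig import embed as _embed, decompose as _dec

        rank = _dec(_embed(noisy.intensities, 50)).rank_d
        e = extract_signal_ssa(noisy, 50, n_components=rank)
        assert np.max(np.abs(e.residual)) < 1e-8

    def test_smoothing_beats_raw_observations(self, noisy_replicate):
        truth, noisy = noisy_replicate
        e = extract_signal_ssa(noisy)
        assert rmse(e.signal, truth.intensities) < rmse(noisy.intensities, truth.intensities)

    def test_signal_plus_residual_is_observed(self, noisy_replicate):
        _, noisy = noisy_replicate
        e = extract_signal_ssa(noisy)
        np.testing.assert_allclose(e.signal + e.residual, noisy.intensities, atol=1e-10)


class TestWCorrelation:
    def test_self_correlation_is_one(self):
        y = np.random.default_rng(6).normal(size=20)
        assert w_correlation(y, y, 8) == pytest.approx(1.0)

    def test_antisymmetry(self):
        y = np.random.default_rng(7).normal(size=20)
        assert w_correlation(y, -y, 8) == pytest.approx(-1.0)

    def test_weights_small_case_by_enumeration(self):
        np.testing.assert_array_equal(w_correlation_weights(4, 2), [1, 2, 2, 1])

    @given(n=st.integers(5, 40), data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_weights_match_brute_force_count(self, n, data):
        L = data.draw(st.integers(2, n - 1))
        K = n - L + 1
        counts = np.zeros(n)
        for l in range(1, L + 1):
            for k in range(1, K + 1):
                counts[l + k - 2] += 1
        np.testing.assert_array_equal(w_correlation_weights(n, L), counts)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=15), rng.normal(size=15)
        assert w_correlation(a, b, 6) == pytest.approx(w_correlation(b, a, 6))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            w_correlation(np.zeros(10), np.ones(10), 4)

    def test_signal_noise_separability_on_default_fixture(self, noisy_replicate):
        _, noisy = noisy_replicate
        e = extract_signal_ssa(noisy)
        L = e.meta["window_length_L"]
        assert abs(w_correlation(e.signal, e.residual, L)) < 0.1
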
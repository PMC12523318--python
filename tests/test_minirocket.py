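"""MiniROCKET unit and oracle tests.

The independent oracle is a naive dilated-convolution + bias-threshold
counter that never touches the optimized shift-sum code path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from murmurkit.minirocket import (
    FeatureMap,
    KernelBank,
    build_kernel_bank,
    convolve,
    dilation_schedule,
    enumerate_kernels,
    fit_biases,
    transform,
)


def naive_transform(X: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Brute-force PPV features, one trace position at a time."""
    N, C, L = X.shape
    out = np.zeros((N, bank.n_features))
    for f in range(bank.n_features):
        w = bank.weights[bank.kernel_idx[f]]
        d = int(bank.dilation[f])
        n_pos = L - 8 * d
        for n in range(N):
            if bank.mv_mode == "per_channel":
                x = X[n, int(bank.channel[f])]
                trace = np.array(
                    [sum(w[j] * x[i + j * d] for j in range(9)) for i in range(n_pos)]
                )
            else:
                trace = np.zeros(n_pos)
                for c in np.flatnonzero(bank.subsets[f]):
                    x = X[n, c]
                    trace += np.array(
                        [sum(w[j] * x[i + j * d] for j in range(9)) for i in range(n_pos)]
                    )
            out[n, f] = np.mean(trace > bank.bias[f])
    return out


class TestEnumerateKernels:
    def test_exactly_84(self):
        assert enumerate_kernels().shape == (84, 9)

    def test_weights_and_zero_sum(self):
        k = enumerate_kernels()
        assert set(np.unique(k)) == {-1.0, 2.0}
        assert np.all((k == 2.0).sum(axis=1) == 3)
        assert np.all((k == -1.0).sum(axis=1) == 6)
        assert np.all(k.sum(axis=1) == 0)

    def test_lexicographic_first(self):
        np.testing.assert_array_equal(
            enumerate_kernels()[0], [2, 2, 2, -1, -1, -1, -1, -1, -1])


class TestDilationSchedule:
    def test_minimal_input_single_dilation(self):
        assert [d for d, _ in dilation_schedule(9, 84)] == [1]

    def test_target_10000_gives_9996(self):
        sched = dilation_schedule(1000, 10_000)
        assert 84 * sum(s for _, s in sched) == 9996

    def test_all_spans_feasible(self):
        for L in (9, 50, 200, 1000):
            for d, _ in dilation_schedule(L, 840):
                assert 8 * d + 1 <= L

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dilation_schedule(8, 100)


class TestConvolve:
    def test_constant_input_zero_trace(self):
        k = enumerate_kernels()[17]
        trace = convolve(np.full(50, 3.7), k, dilation=2)
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)

    def test_linear_ramp_constant_trace(self):
        k = enumerate_kernels()[30]
        expected = sum(k[j] * j for j in range(9))
        trace = convolve(np.arange(40, dtype=float), k, dilation=1)
        np.testing.assert_allclose(trace, expected)

    def test_impulse_against_sliding_dot_oracle(self):
        k = enumerate_kernels()[5]
        x = np.zeros(21)
        x[10] = 1.0
        trace = convolve(x, k, dilation=1)
        oracle = [np.dot(k, x[i : i + 9]) for i in range(len(x) - 8)]
        np.testing.assert_allclose(trace, oracle)

    def test_span_exceeding_sequence_rejected(self):
        with pytest.raises(ValueError, match="span"):
            convolve(np.zeros(16), enumerate_kernels()[0], dilation=2)


class TestFitBiases:
    def test_median_of_single_group(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1, 4, 64)).astype(np.float32)
        bank = build_kernel_bank(64, n_features=84, seed=0)
        fitted = fit_biases(X, bank, seed=0)
        f = int(np.argmin(np.abs(bank.quantile - 0.5)))
        trace = convolve(
            X[0, int(bank.channel[f])].astype(np.float64),
            bank.weights[bank.kernel_idx[f]], int(bank.dilation[f]))
        q = np.quantile(trace, bank.quantile[f], method="inverted_cdf")
        np.testing.assert_allclose(fitted.bias[f], q, rtol=1e-5, atol=1e-5)

    def test_duplicating_training_groups_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 4, 64)).astype(np.float32)
        bank = build_kernel_bank(64, n_features=336, seed=1)
        once = fit_biases(X, bank, seed=0)
        doubled = fit_biases(np.concatenate([X, X]), bank, seed=0)
        np.testing.assert_allclose(once.bias, doubled.bias)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 4, 64)).astype(np.float32)
        bank = build_kernel_bank(64, n_features=336, seed=1)
        a = fit_biases(X, bank, seed=3, max_sample=16)
        b = fit_biases(X, bank, seed=3, max_sample=16)
        np.testing.assert_array_equal(a.bias, b.bias)

    def test_empty_training_set_rejected(self):
        bank = build_kernel_bank(64, n_features=84)
        with pytest.raises(ValueError, match="empty"):
            fit_biases(np.empty((0, 4, 64), dtype=np.float32), bank)


class TestTransform:
    def _fitted(self, X, n_features=336, mv_mode="per_channel", seed=0):
        bank = build_kernel_bank(X.shape[2], n_features=n_features,
                                 mv_mode=mv_mode, seed=seed)
        return fit_biases(X, bank, seed=seed)

    def test_unfitted_bank_rejected(self):
        bank = build_kernel_bank(64, n_features=84)
        with pytest.raises(ValueError, match="biases"):
            transform(np.zeros((1, 4, 64), dtype=np.float32), bank)

    def test_extreme_biases_give_zero_and_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((3, 4, 64)).astype(np.float32)
        bank = self._fitted(X, n_features=84)
        lo = bank.bias - 1e6
        hi = bank.bias + 1e6
        from dataclasses import replace
        assert np.all(transform(X, replace(bank, bias=hi)).values == 0.0)
        assert np.all(transform(X, replace(bank, bias=lo)).values == 1.0)

    def test_values_in_unit_interval_and_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 4, 100)).astype(np.float32)
        bank = self._fitted(X)
        a, b = transform(X, bank), transform(X, bank)
        assert np.all((a.values >= 0) & (a.values <= 1))
        np.testing.assert_array_equal(a.values, b.values)

    def test_constant_offset_invariance(self):
        """Zero-sum kernels: adding a constant to the input changes nothing.

        Integer-valued inputs make every operation exact in float64, so
        the invariance is checked bit-for-bit.
        """
        rng = np.random.default_rng(5)
        X = rng.integers(-10, 10, size=(6, 4, 80)).astype(np.float64)
        bank = self._fitted(X)
        base = transform(X, bank)
        shifted = transform(X + 4.0, bank)
        np.testing.assert_array_equal(base.values, shifted.values)

    @pytest.mark.parametrize("mv_mode", ["per_channel", "subset_sum"])
    def test_oracle_equivalence(self, mv_mode):
        """Optimized transform equals naive counting to 1e-9 (both modes).

        Biases come from an independent training sample and the data are
        integer-valued, so threshold comparisons never sit on a rounding
        knife edge in either code path.
        """
        rng = np.random.default_rng(6)
        train = rng.integers(-10, 10, size=(8, 4, 200)).astype(np.float64)
        X = rng.integers(-10, 10, size=(10, 4, 200)).astype(np.float64)
        bank = build_kernel_bank(200, n_features=500, mv_mode=mv_mode, seed=7)
        bank = fit_biases(train, bank, seed=7)
        fast = transform(X, bank).values
        slow = naive_transform(X, bank)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_train_transform_layout_stable(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((12, 4, 64)).astype(np.float32)
        bank = self._fitted(X, n_features=168)
        fm_train = transform(X[:8], bank)
        fm_test = transform(X[8:], bank)
        assert fm_train.values.shape[1] == fm_test.values.shape[1] == bank.n_features
        assert [f["feature"] for f in fm_train.feature_ids[:3]] == [0, 1, 2]

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_feature_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        X = (10 * rng.standard_normal((3, 4, 40))).astype(np.float32)
        bank = build_kernel_bank(40, n_features=84, seed=seed)
        fm = transform(X, fit_biases(X, bank, seed=seed))
        assert np.all((fm.values >= 0) & (fm.values <= 1))
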
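"""Multivariate MiniROCKET: fixed dilated kernels with PPV pooling.

The transform convolves every input sequence with a fixed bank of 1x9
kernels whose weights are -1 or +2 with exactly three +2 entries, so
every kernel sums to zero (constant inputs produce all-zero traces and
adding a constant to the input changes nothing).  There are C(9,3) = 84
such kernels.  Each (kernel, dilation, bias) combination yields one
feature: the proportion of positions where the bias-shifted convolution
trace is positive (PPV pooling), a number in [0, 1].

Biases are data-driven: quantiles of convolution traces computed on a
seeded sample of training groups, at low-discrepancy quantile levels.
The quantile uses the inverted-CDF definition, which is exactly
invariant under duplicating every training group.  A literal
uniform-random bias mode is available for fidelity comparisons.

Multivariate handling over the four valve channels:

* ``per_channel`` (default) — each feature reads one channel; features
  are split evenly across the 4 channels and concatenated.
* ``subset_sum`` — each feature sums the traces of a seeded channel
  subset (size 1-4) before pooling.

The 10,000-feature target is realized as the nearest feasible multiple
of 84 (9,996 at the default settings); the effective count is recorded
on the bank.  Convolution is valid-mode: a kernel with dilation d spans
8d+1 samples and its trace has L - 8d positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .embed import EmbeddingArray

__all__ = [
    "KernelBank",
    "FeatureMap",
    "enumerate_kernels",
    "dilation_schedule",
    "convolve",
    "build_kernel_bank",
    "fit_biases",
    "transform",
]

KERNEL_LEN = 9
N_KERNELS = 84
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0

DEFAULT_N_FEATURES = 10_000
DEFAULT_BIAS_SAMPLE = 32


def enumerate_kernels() -> np.ndarray:
    """All 84 length-9 weight vectors with three +2 and six -1 entries.

    Ordered lexicographically by the positions of the +2 weights, so the
    first kernel has +2 at positions (0, 1, 2).  Every row sums to zero.
    """
    kernels = np.full((N_KERNELS, KERNEL_LEN), -1.0)
    for row, pos in enumerate(itertools.combinations(range(KERNEL_LEN), 3)):
        kernels[row, list(pos)] = 2.0
    return kernels


def _plus_positions() -> np.ndarray:
    return np.array(list(itertools.combinations(range(KERNEL_LEN), 3)), dtype=np.int64)


def dilation_schedule(input_length: int, n_features_target: int = DEFAULT_N_FEATURES,
                      n_kernels: int = N_KERNELS) -> list:
    """Powers-of-two dilations with per-dilation feature-slot allocations.

    A dilation d is feasible while the dilated span 8d+1 fits the input.
    The per-kernel slot budget floor(target / 84) is spread as evenly as
    possible across feasible dilations (earlier dilations absorb the
    remainder).  Returns [(dilation, slots_per_kernel), ...].
    """
    if input_length < KERNEL_LEN:
        raise ValueError(f"input length {input_length} too short for a 1x{KERNEL_LEN} kernel")
    dilations = []
    d = 1
    while 8 * d + 1 <= input_length:
        dilations.append(d)
        d *= 2
    slots = n_features_target // n_kernels
    if slots < 1:
        raise ValueError("feature target below one slot per kernel")
    base, rem = divmod(slots, len(dilations))
    return [(dil, base + (1 if i < rem else 0)) for i, dil in enumerate(dilations)]


def convolve(sequence: np.ndarray, kernel: np.ndarray, dilation: int) -> np.ndarray:
    """Valid-mode dilated convolution: trace[i] = sum_j w[j] * x[i + j*d]."""
    x = np.asarray(sequence, dtype=np.float64)
    span = (KERNEL_LEN - 1) * dilation + 1
    if span > len(x):
        raise ValueError(f"dilated span {span} exceeds sequence length {len(x)}")
    n_pos = len(x) - (KERNEL_LEN - 1) * dilation
    trace = np.zeros(n_pos)
    for j, w in enumerate(kernel):
        trace += w * x[j * dilation : j * dilation + n_pos]
    return trace


@dataclass
class KernelBank:
    """The enumerated kernels plus the per-feature wiring and fitted biases."""

    weights: np.ndarray          # (84, 9)
    kernel_idx: np.ndarray       # (F,) which of the 84 kernels
    dilation: np.ndarray         # (F,)
    channel: np.ndarray          # (F,) channel read in per_channel mode
    subsets: np.ndarray          # (F, n_channels) bool, used in subset_sum mode
    quantile: np.ndarray         # (F,) bias quantile level in (0, 1)
    input_length: int
    n_channels: int
    mv_mode: str = "per_channel"
    bias_mode: str = "quantile"
    seed: int = 0
    bias: np.ndarray | None = None   # (F,) set by fit_biases

    @property
    def n_features(self) -> int:
        return len(self.kernel_idx)

    @property
    def fitted(self) -> bool:
        return self.bias is not None

    def feature_ids(self) -> list:
        """Stable per-column identifiers tying features to their wiring."""
        ids = []
        for f in range(self.n_features):
            channels = (
                (int(self.channel[f]),)
                if self.mv_mode == "per_channel"
                else tuple(np.flatnonzero(self.subsets[f]))
            )
            ids.append(
                {
                    "feature": f,
                    "kernel": int(self.kernel_idx[f]),
                    "dilation": int(self.dilation[f]),
                    "channels": channels,
                    "quantile": float(self.quantile[f]),
                    "bias": float(self.bias[f]) if self.fitted else None,
                }
            )
        return ids


@dataclass
class FeatureMap:
    """PPV feature matrix (groups x features), all entries in [0, 1]."""

    values: np.ndarray
    feature_ids: list = field(default_factory=list)


def build_kernel_bank(
    input_length: int,
    n_features: int = DEFAULT_N_FEATURES,
    n_channels: int = 4,
    mv_mode: str = "per_channel",
    bias_mode: str = "quantile",
    seed: int = 0,
) -> KernelBank:
    """Wire up the feature layout (kernels x dilations x bias slots).

    The effective feature count is the largest multiple of 84 not
    exceeding ``n_features``.  Quantile levels follow the golden-ratio
    low-discrepancy sequence within each (kernel, dilation) slot block.
    """
    if mv_mode not in ("per_channel", "subset_sum"):
        raise ValueError(f"unknown mv_mode {mv_mode!r}")
    schedule = dilation_schedule(input_length, n_features)
    rng = np.random.default_rng(seed)
    kernel_idx, dilation, channel, quantile, subsets = [], [], [], [], []
    position = 0
    for k in range(N_KERNELS):
        for dil, slots in schedule:
            for j in range(slots):
                kernel_idx.append(k)
                dilation.append(dil)
                quantile.append(((j + 1) * _GOLDEN) % 1.0)
                channel.append(position % n_channels)
                size = int(rng.integers(1, n_channels + 1))
                members = rng.choice(n_channels, size=size, replace=False)
                mask = np.zeros(n_channels, dtype=bool)
                mask[members] = True
                subsets.append(mask)
                position += 1
    return KernelBank(
        weights=enumerate_kernels(),
        kernel_idx=np.asarray(kernel_idx, dtype=np.int64),
        dilation=np.asarray(dilation, dtype=np.int64),
        channel=np.asarray(channel, dtype=np.int64),
        subsets=np.asarray(subsets, dtype=bool),
        quantile=np.asarray(quantile, dtype=np.float64),
        input_length=input_length,
        n_channels=n_channels,
        mv_mode=mv_mode,
        bias_mode=bias_mode,
        seed=seed,
    )


def _as_values(data) -> np.ndarray:
    # float32 inputs stay float32 (the pipeline's memory-lean path);
    # anything else is promoted to float64 for exact-arithmetic checks
    x = data.values if isinstance(data, EmbeddingArray) else np.asarray(data)
    if x.ndim != 3:
        raise ValueError("expected a (groups, channels, length) array")
    dtype = np.float32 if x.dtype == np.float32 else np.float64
    return np.ascontiguousarray(x, dtype=dtype)


def _kernel_trace(shifts, A, plus_pos):
    # weights are -1 everywhere and +2 at three positions: w.x = 3*sum_plus - sum_all
    return 3.0 * (shifts[plus_pos[0]] + shifts[plus_pos[1]] + shifts[plus_pos[2]]) - A


def fit_biases(
    train,
    bank: KernelBank,
    seed: int = 0,
    max_sample: int = DEFAULT_BIAS_SAMPLE,
) -> KernelBank:
    """Fit one bias per feature from training-trace quantiles.

    Traces are computed on a seeded sample of at most ``max_sample``
    training groups (all of them when the training set is small).  In
    ``quantile`` mode the bias is the inverted-CDF quantile of the
    pooled trace at the feature's level; in ``uniform_random`` mode it
    is drawn uniformly between the pooled trace's min and max.
    """
    X = _as_values(train)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_sample:
        sample = np.sort(rng.choice(X.shape[0], size=max_sample, replace=False))
        X = X[sample]
    plus = _plus_positions()
    biases = np.empty(bank.n_features, dtype=np.float64)
    L = X.shape[2]
    for d in np.unique(bank.dilation):
        P = L - (KERNEL_LEN - 1) * d
        if P <= 0:
            raise ValueError(f"input length {L} too short for dilation {d}")
        shifts = [X[:, :, j * d : j * d + P] for j in range(KERNEL_LEN)]
        A = np.sum(shifts, axis=0)
        in_d = bank.dilation == d
        for k in np.unique(bank.kernel_idx[in_d]):
            fidx = np.flatnonzero(in_d & (bank.kernel_idx == k))
            T = _kernel_trace(shifts, A, plus[k])  # (S, C, P)
            if bank.mv_mode == "per_channel":
                for c in np.unique(bank.channel[fidx]):
                    sub = fidx[bank.channel[fidx] == c]
                    pooled = T[:, c, :].ravel()
                    biases[sub] = _draw_biases(pooled, bank, sub, rng)
            else:
                for f in fidx:
                    pooled = T[:, bank.subsets[f], :].sum(axis=1).ravel()
                    biases[f] = _draw_biases(pooled, bank, np.array([f]), rng)[0]
    return replace(bank, bias=biases)


def _draw_biases(pooled: np.ndarray, bank: KernelBank, fidx: np.ndarray, rng) -> np.ndarray:
    if bank.bias_mode == "quantile":
        return np.quantile(pooled, bank.quantile[fidx], method="inverted_cdf")
    lo, hi = float(pooled.min()), float(pooled.max())
    return rng.uniform(lo, hi, size=len(fidx))


def transform(data, bank: KernelBank, batch_size: int = 256) -> FeatureMap:
    """PPV features: per feature, the fraction of trace positions above bias."""
    if not bank.fitted:
        raise ValueError("kernel bank has no fitted biases; call fit_biases first")
    X = _as_values(data)
    N, C, L = X.shape
    if L != bank.input_length:
        raise ValueError(f"sequence length {L} != bank input length {bank.input_length}")
    out = np.empty((N, bank.n_features), dtype=X.dtype)
    plus = _plus_positions()
    for start in range(0, N, batch_size):
        Xb = X[start : start + batch_size]
        for d in np.unique(bank.dilation):
            P = L - (KERNEL_LEN - 1) * d
            shifts = [Xb[:, :, j * d : j * d + P] for j in range(KERNEL_LEN)]
            A = np.sum(shifts, axis=0)
            in_d = bank.dilation == d
            for k in np.unique(bank.kernel_idx[in_d]):
                fidx = np.flatnonzero(in_d & (bank.kernel_idx == k))
                T = _kernel_trace(shifts, A, plus[k])  # (B, C, P)
                b = bank.bias[fidx]
                if bank.mv_mode == "per_channel":
                    Tc = T[:, bank.channel[fidx], :]   # (B, m, P)
                else:
                    Tc = np.einsum("bcp,mc->bmp", T, bank.subsets[fidx].astype(X.dtype))
                out[start : start + batch_size, fidx] = (
                    Tc > b[None, :, None]
                ).mean(axis=2, dtype=X.dtype)
    return FeatureMap(values=out, feature_ids=bank.feature_ids())
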
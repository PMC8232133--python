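"""Parameterized fully-convolutional architecture for CC-ECG classification.

The network consumes a raw 10 s single-lead strip (1250 samples, µV, no
normalization) and emits the probability pSh of a shockable rhythm.  It is
a stack of N convolutional blocks — valid-padding 1D convolution (F_i
filters, kernel K_i), ReLU, max-pooling of size 2, dropout 0.3 — followed
by global max-pooling (GMP) over time and a single sigmoid unit:

    pSh = sigmoid( sum_f w_f * GMP_f + b )

Two closed forms govern the architecture:

* shape calculus — block i maps temporal length L to L - K_i + 1 after the
  valid convolution, then floor((L - K_i + 1) / 2) after pooling;
* parameter count — Params = sum_i F_i (K_i F_{i-1} + 1) + (F_N + 1),
  with F_0 = 1 for the single-lead input.

The model itself (forward pass, backpropagation) is implemented here in
numpy; gradients are exact and checked against finite differences in the
test suite.  Dropout is active only during training (inverted scaling so
test-time activations need no rescaling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InvalidParameterError, ShapeInfeasibleError
from .metrics import STRIP_SAMPLES

GRID_N = (2, 3, 4, 5, 6, 7)
GRID_F = (5, 10, 15, 20, 25, 30, 40, 50)
GRID_K = (5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 85, 100)
POOL_SIZE = 2
DROPOUT_RATE = 0.3
PARAMS_CAP = 250_000
INIT_RANGE = 0.05   # random-uniform kernel initializer half-range


@dataclass(frozen=True)
class HPConfig:
    """One candidate architecture: depth plus per-block filters and kernels."""

    n_blocks: int
    filters: Tuple[int, ...]
    kernels: Tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))
        object.__setattr__(self, "kernels", tuple(int(k) for k in self.kernels))
        if self.n_blocks not in GRID_N:
            raise InvalidParameterError(f"n_blocks must be in {GRID_N}")
        if len(self.filters) != self.n_blocks or len(self.kernels) != self.n_blocks:
            raise InvalidParameterError("filters/kernels length must equal n_blocks")
        if any(f not in GRID_F for f in self.filters):
            raise InvalidParameterError(f"filters must come from {GRID_F}")
        if any(k not in GRID_K for k in self.kernels):
            raise InvalidParameterError(f"kernels must come from {GRID_K}")

    def is_valid(self, input_len: int = STRIP_SAMPLES) -> bool:
        """Full candidate validity: trends, shape feasibility, parameter cap."""
        from .search import validate_trend  # local import to avoid a cycle

        if not (validate_trend(self.filters) and validate_trend(self.kernels)):
            return False
        try:
            shape_trace(self, input_len)
        except ShapeInfeasibleError:
            return False
        return count_params(self) <= PARAMS_CAP


@dataclass(frozen=True)
class ShapeTrace:
    """Per-block temporal lengths under valid padding and pool size 2."""

    input_len: int
    conv_lens: Tuple[int, ...]
    pool_lens: Tuple[int, ...]
    filters: Tuple[int, ...]

    @property
    def gmp_len(self) -> int:
        return self.filters[-1]


def shape_trace(hp: HPConfig, input_len: int = STRIP_SAMPLES) -> ShapeTrace:
    """Temporal shape of every block output for a given input length.

    Raises :class:`ShapeInfeasibleError` if any convolution would need a
    kernel longer than its input (output length below one sample).
    """
    conv_lens, pool_lens = [], []
    length = input_len
    for k in hp.kernels:
        conv = length - k + 1
        if conv < 1:
            raise ShapeInfeasibleError(
                f"kernel {k} cannot be applied to length {length}"
            )
        pool = conv // POOL_SIZE   # non-overlapping windows, remainder dropped
        if pool < 1:
            raise ShapeInfeasibleError(f"pooling empties a length-{conv} output")
        conv_lens.append(conv)
        pool_lens.append(pool)
        length = pool
    return ShapeTrace(
        input_len=input_len,
        conv_lens=tuple(conv_lens),
        pool_lens=tuple(pool_lens),
        filters=hp.filters,
    )


def count_params(hp: HPConfig) -> int:
    """Exact trainable-parameter count.

    Params = sum_i F_i (K_i F_{i-1} + 1) + (F_N + 1), with F_0 = 1 for the
    single-lead input; the trailing term is the dense classifier.
    """
    total = 0
    f_prev = 1
    for f, k in zip(hp.filters, hp.kernels):
        total += f * (k * f_prev + 1)
        f_prev = f
    return total + (hp.filters[-1] + 1)


def block_param_counts(hp: HPConfig) -> List[int]:
    """Per-block parameter counts plus the dense layer, in network order."""
    counts = []
    f_prev = 1
    for f, k in zip(hp.filters, hp.kernels):
        counts.append(f * (k * f_prev + 1))
        f_prev = f
    counts.append(hp.filters[-1] + 1)
    return counts


def cnn3_preset() -> HPConfig:
    """The selected three-block network (5@10, 25@20, 50@20).

    The published architecture table lists the first kernel as 5, but its
    own parameter count (55) and the printed shape chain
    1250 -> 1241 -> 620 -> 601 -> 300 -> 281 -> 140 are consistent only
    with a first kernel of 10; the internally consistent reading is used.
    """
    return HPConfig(n_blocks=3, filters=(5, 25, 50), kernels=(10, 20, 20))


# ---------------------------------------------------------------------------
# numpy model
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1D convolution: x (B, L, C), w (K, C, F) -> (B, L-K+1, F).

    Two BLAS-backed strategies: for few input channels an im2col buffer
    followed by a single matrix product (the tap dimension is too thin for
    efficient per-tap products), otherwise K tap-wise matrix products with
    no buffer materialization.
    """
    k_size, n_ch, _ = w.shape
    l_out = x.shape[1] - k_size + 1
    if n_ch <= 16:
        wins = sliding_window_view(x, k_size, axis=1)       # (B, Lout, C, K)
        col = np.ascontiguousarray(wins.transpose(0, 1, 3, 2))
        out = col.reshape(-1, k_size * n_ch) @ w.reshape(k_size * n_ch, -1)
        out = out.reshape(x.shape[0], l_out, w.shape[2])
    else:
        out = x[:, :l_out, :] @ w[0]
        for k in range(1, k_size):
            out += x[:, k: k + l_out, :] @ w[k]
    return out + b


class ConvNet:
    """Trainable fully-convolutional classifier (the model handle).

    Weights are float32; the forward pass can cache intermediates for
    backpropagation and expose per-layer activations for inspection.
    """

    def __init__(self, hp: HPConfig, init_seed: int = 0,
                 input_len: int = STRIP_SAMPLES, dtype=np.float32):
        self.hp = hp
        self.input_len = input_len
        self.trace = shape_trace(hp, input_len)   # raises if infeasible
        self.init_seed = int(init_seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(self.init_seed)
        self.conv_w: List[np.ndarray] = []
        self.conv_b: List[np.ndarray] = []
        f_prev = 1
        for f, k in zip(hp.filters, hp.kernels):
            self.conv_w.append(
                rng.uniform(-INIT_RANGE, INIT_RANGE, size=(k, f_prev, f)).astype(self.dtype)
            )
            self.conv_b.append(np.zeros(f, dtype=self.dtype))
            f_prev = f
        self.dense_w = rng.uniform(-INIT_RANGE, INIT_RANGE, size=f_prev).astype(self.dtype)
        self.dense_b = np.zeros(1, dtype=self.dtype)

    # -- introspection ------------------------------------------------------

    @property
    def parameters(self) -> List[np.ndarray]:
        params = []
        for w, b in zip(self.conv_w, self.conv_b):
            params.extend([w, b])
        params.extend([self.dense_w, self.dense_b])
        return params

    @property
    def num_params(self) -> int:
        """Trainable parameter count by introspection over weight arrays."""
        return int(sum(p.size for p in self.parameters))

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        own = self.parameters
        if len(own) != len(weights):
            raise InvalidParameterError("weight list length mismatch")
        for dst, src in zip(own, weights):
            if dst.shape != np.shape(src):
                raise InvalidParameterError("weight shape mismatch")
            dst[...] = src

    # -- forward ------------------------------------------------------------

    def _coerce(self, x) -> np.ndarray:
        x = np.asarray(getattr(x, "samples", x), dtype=self.dtype)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.input_len:
            raise InvalidParameterError(
                f"expected input length {self.input_len}, got {x.shape[1]}"
            )
        return x

    def forward(self, x, training: bool = False,
                dropout_rng: Optional[np.random.Generator] = None,
                cache: Optional[dict] = None) -> np.ndarray:
        """Probability pSh for a batch; caches intermediates when asked."""
        a = self._coerce(x)
        store = cache if cache is not None else None
        if store is not None:
            store["inputs"] = [a]
            store["relu_mask"] = []
            store["pool_arg"] = []
            store["drop_mask"] = []
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            z = _conv_forward(a, w, b)
            relu_mask = z > 0
            a = np.where(relu_mask, z, 0.0).astype(self.dtype)
            n_pool = a.shape[1] // POOL_SIZE
            trimmed = a[:, : n_pool * POOL_SIZE].reshape(
                a.shape[0], n_pool, POOL_SIZE, a.shape[2]
            )
            if store is not None:
                arg = trimmed.argmax(axis=2)
                a = np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :]
            else:
                a = trimmed.max(axis=2)
            if training:
                if dropout_rng is None:
                    dropout_rng = np.random.default_rng(0)
                keep = (dropout_rng.random(a.shape) >= DROPOUT_RATE)
                a = a * keep / (1.0 - DROPOUT_RATE)
                a = a.astype(self.dtype)
                if store is not None:
                    store["drop_mask"].append(keep)
            elif store is not None:
                store["drop_mask"].append(None)
            if store is not None:
                store["relu_mask"].append(relu_mask)
                store["pool_arg"].append(arg)
                store["inputs"].append(a)
        if store is not None:
            gmp_arg = a.argmax(axis=1)                      # (B, F_N)
            gmp = np.take_along_axis(a, gmp_arg[:, None, :], axis=1)[:, 0, :]
            store["gmp_arg"] = gmp_arg
        else:
            gmp = a.max(axis=1)
        z = gmp @ self.dense_w + self.dense_b[0]
        p = _sigmoid(z.astype(np.float64))
        if store is not None:
            store["gmp"] = gmp
            store["p"] = p
        return p

    def predict_proba(self, x) -> np.ndarray:
        return self.forward(x, training=False)

    def gmp_features(self, x) -> np.ndarray:
        """GMP feature matrix (B, F_N) at inference (dropout inactive)."""
        cache: dict = {}
        self.forward(x, training=False, cache=cache)
        return cache["gmp"]

    def layer_activations(self, x) -> dict:
        """Per-layer activations of a single strip, for inspection.

        Returns conv outputs (post-ReLU) and pooled outputs per block plus
        the GMP vector; shapes follow :func:`shape_trace`.
        """
        a = self._coerce(x)
        out = {"conv": [], "pool": []}
        for w, b in zip(self.conv_w, self.conv_b):
            z = _conv_forward(a, w, b)
            a = np.maximum(z, 0.0)
            out["conv"].append(a[0].copy())
            n_pool = a.shape[1] // POOL_SIZE
            trimmed = a[:, : n_pool * POOL_SIZE].reshape(
                a.shape[0], n_pool, POOL_SIZE, a.shape[2]
            )
            a = trimmed.max(axis=2)
            out["pool"].append(a[0].copy())
        out["gmp"] = a.max(axis=1)[0]
        return out

    # -- backward -----------------------------------------------------------

    def loss_and_gradients(self, x, y,
                           dropout_rng: Optional[np.random.Generator] = None,
                           training: bool = True):
        """Mean binary cross-entropy and exact gradients for one batch."""
        cache: dict = {}
        p = self.forward(x, training=training, dropout_rng=dropout_rng, cache=cache)
        y = np.asarray(y, dtype=np.float64)
        batch = y.shape[0]
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

        dz = ((p - y) / batch).astype(self.dtype)           # (B,)
        gmp = cache["gmp"]
        d_dense_w = gmp.T @ dz
        d_dense_b = np.array([dz.sum()], dtype=self.dtype)
        d_gmp = dz[:, None] * self.dense_w[None, :]          # (B, F_N)

        # scatter GMP gradient back to the final pooled map
        last = cache["inputs"][-1]
        da = np.zeros_like(last)
        np.put_along_axis(da, cache["gmp_arg"][:, None, :], d_gmp[:, None, :], axis=1)

        grads: List[np.ndarray] = []
        for i in reversed(range(self.hp.n_blocks)):
            keep = cache["drop_mask"][i]
            if keep is not None:
                da = da * keep / (1.0 - DROPOUT_RATE)
            relu_mask = cache["relu_mask"][i]
            conv_len = relu_mask.shape[1]
            n_pool = conv_len // POOL_SIZE
            d_trim = np.zeros(
                (da.shape[0], n_pool, POOL_SIZE, da.shape[2]), dtype=self.dtype
            )
            np.put_along_axis(
                d_trim, cache["pool_arg"][i][:, :, None, :], da[:, :, None, :], axis=2
            )
            dz_conv = np.zeros(relu_mask.shape, dtype=self.dtype)
            dz_conv[:, : n_pool * POOL_SIZE] = d_trim.reshape(
                da.shape[0], n_pool * POOL_SIZE, da.shape[2]
            )
            dz_conv *= relu_mask

            x_in = cache["inputs"][i]
            w = self.conv_w[i]
            k_size, n_ch, n_filt = w.shape
            l_out = dz_conv.shape[1]
            dz_flat = dz_conv.reshape(-1, n_filt)
            db = dz_conv.sum(axis=(0, 1))
            if n_ch <= 16:
                # mirror the forward im2col strategy for thin channels
                wins = sliding_window_view(x_in, k_size, axis=1)
                col = np.ascontiguousarray(wins.transpose(0, 1, 3, 2))
                col = col.reshape(-1, k_size * n_ch)
                dw = (col.T @ dz_flat).reshape(k_size, n_ch, n_filt)
                if i > 0:
                    dcol = dz_flat @ w.reshape(k_size * n_ch, n_filt).T
                    dcol = dcol.reshape(x_in.shape[0], l_out, k_size, n_ch)
                    da = np.zeros_like(x_in)
                    for k in range(k_size):
                        da[:, k: k + l_out, :] += dcol[:, :, k, :]
            else:
                dw = np.empty_like(w)                        # (K, C, F)
                for k in range(k_size):
                    taps = x_in[:, k: k + l_out, :].reshape(-1, n_ch)
                    dw[k] = taps.T @ dz_flat
                if i > 0:  # propagate into the previous block's pooled output
                    da = np.zeros_like(x_in)
                    for k in range(k_size):
                        da[:, k: k + l_out, :] += dz_conv @ w[k].T
            grads.insert(0, db.astype(self.dtype))
            grads.insert(0, dw.astype(self.dtype))
        grads.extend([d_dense_w.astype(self.dtype), d_dense_b])
        return loss, grads, p


def build_model(hp: HPConfig, init_seed: int = 0) -> ConvNet:
    """Build a trainable model; raises :class:`ShapeInfeasibleError` if the
    configuration shrinks the temporal axis below one sample."""
    return ConvNet(hp, init_seed=init_seed)


def classify(model: ConvNet, strips, pthr: float) -> np.ndarray:
    """Per-strip shock advisory: 'Sh' iff pSh >= pthr (boundary inclusive)."""
    if not 0.0 < pthr < 1.0:
        raise InvalidParameterError("pthr must lie strictly inside (0, 1)")
    if hasattr(strips, "waveforms"):
        x = strips.waveforms()
    else:
        x = strips
    p = model.predict_proba(x)
    return np.where(p >= pthr, "Sh", "NSh")


def gmp_filter_order(model: ConvNet) -> np.ndarray:
    """Permutation of final-block filters by ascending classifier weight.

    Negative-weight filters (supporting the non-shockable decision) come
    first, positive-weight filters (supporting shock) last.
    """
    return np.argsort(model.dense_w, kind="stable")


def extract_gmp_features(model: ConvNet, strip) -> Tuple[np.ndarray, np.ndarray]:
    """GMP feature vector of one strip plus the weight-sorted filter order."""
    features = model.gmp_features(strip)[0]
    return features, gmp_filter_order(model)
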
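"""LeNet-style convolutional patch classifier, implemented on numpy.

The network maps a whitened 80x80 single-channel patch to a two-class
softmax posterior:

    conv 64@5x5 (valid) -> ReLU -> maxpool 3x3 stride 3
    conv 32@5x5 (valid) -> ReLU -> maxpool 3x3 stride 3
    flatten (7*7*32 = 1568) -> dense 32 -> ReLU -> dropout
    dense 2 -> softmax

Spatial trace 80 -> 76 -> 25 -> 21 -> 7; 103,170 trainable parameters
(1,664 + 51,232 + 50,208 + 66).  Convolutions are evaluated as im2col
matrix products so the heavy lifting runs through BLAS; backpropagation and
the Adam optimizer are written out explicitly.  Everything is seeded, so a
fixed seed reproduces a training run bit-identically on one thread.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from numba import njit


@njit(cache=True)
def _pool_fwd_nb(x, p, out, arg):
    """Non-overlapping p*p max pooling with argmax offsets, into buffers."""
    n, h, w, c = x.shape
    oh = (h - p) // p + 1
    ow = (w - p) // p + 1
    for ni in range(n):
        for oi in range(oh):
            for oj in range(ow):
                for ci in range(c):
                    best = np.float32(-3.4e38)
                    bk = 0
                    for di in range(p):
                        for dj in range(p):
                            v = x[ni, oi * p + di, oj * p + dj, ci]
                            if v > best:
                                best = v
                                bk = di * p + dj
                    out[ni, oi, oj, ci] = best
                    arg[ni, oi, oj, ci] = bk


@njit(cache=True)
def _pool_bwd_nb(dy, arg, p, dx):
    """Scatter each pooled gradient to its argmax position (dx fully written)."""
    n, h, w, c = dx.shape
    oh = (h - p) // p + 1
    ow = (w - p) // p + 1
    for ni in range(n):
        for oi in range(oh):
            for di in range(p):
                for oj in range(ow):
                    for dj in range(p):
                        bk = di * p + dj
                        for ci in range(c):
                            if arg[ni, oi, oj, ci] == bk:
                                dx[ni, oi * p + di, oj * p + dj, ci] = dy[ni, oi, oj, ci]
                            else:
                                dx[ni, oi * p + di, oj * p + dj, ci] = 0.0
        # rows/cols beyond the pooled region receive no gradient
        for hi in range(oh * p, h):
            for wi in range(w):
                for ci in range(c):
                    dx[ni, hi, wi, ci] = 0.0
        for hi in range(oh * p):
            for wi in range(ow * p, w):
                for ci in range(c):
                    dx[ni, hi, wi, ci] = 0.0


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyperparameters of the patch classifier."""

    input_size: int = 80
    conv1_filters: int = 64
    conv2_filters: int = 32
    kernel: int = 5
    pool: int = 3
    pool_stride: int = 3
    dense_units: int = 32
    n_classes: int = 2
    dropout_rate: float = 0.5

    def feature_shapes(self) -> list[tuple[int, int, int]]:
        """Spatial trace (H, W, C) after each conv / pool stage."""
        s = self.input_size
        shapes = []
        for filters in (self.conv1_filters, self.conv2_filters):
            s = s - self.kernel + 1
            if s <= 0:
                raise ValueError("input too small for the layer trace")
            shapes.append((s, s, filters))
            s = (s - self.pool) // self.pool_stride + 1
            if s <= 0:
                raise ValueError("input too small for the layer trace")
            shapes.append((s, s, filters))
        return shapes

    @property
    def flat_units(self) -> int:
        h, w, c = self.feature_shapes()[-1]
        return h * w * c


@dataclass
class TrainConfig:
    """Optimization settings for training from scratch."""

    learning_rate: float = 0.001
    max_epochs: int = 60
    batch_size: int = 256
    rng_seed: int = 0
    plateau_patience: int | None = 8
    plateau_min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class PatchNet:
    """Trainable two-class CNN over 80x80 whitened patches."""

    def __init__(self, spec: NetSpec = NetSpec(), rng_seed: int = 0):
        spec.feature_shapes()  # validates the layer trace
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        k, c1, c2 = spec.kernel, spec.conv1_filters, spec.conv2_filters
        self.params = {
            "W1": _he(rng, (k * k * 1, c1), k * k * 1),
            "b1": np.zeros(c1, dtype=np.float32),
            "W2": _he(rng, (k * k * c1, c2), k * k * c1),
            "b2": np.zeros(c2, dtype=np.float32),
            "W3": _he(rng, (spec.flat_units, spec.dense_units), spec.flat_units),
            "b3": np.zeros(spec.dense_units, dtype=np.float32),
            "W4": _he(rng, (spec.dense_units, spec.n_classes), spec.dense_units),
            "b4": np.zeros(spec.n_classes, dtype=np.float32),
        }
        self._ws: dict = {}  # reusable per-batch work buffers

    # ---- workspace -----------------------------------------------------
    # Large per-batch buffers are reused across steps: fresh page-faulting
    # allocations of >100 MB arrays dominate the step time otherwise.

    def _buf(self, name: str, shape, dtype=np.float32) -> np.ndarray:
        key = (name, shape, np.dtype(dtype).str)
        ws = self._ws
        if key not in ws:
            ws[key] = np.empty(shape, dtype=dtype)
        return ws[key]

    # ---- layer helpers -------------------------------------------------

    def _im2col_1ch(self, x: np.ndarray, k: int) -> np.ndarray:
        """(N, H, W, 1) -> (k*k, N*(H-k+1)*(W-k+1)) column buffer.

        Kernel-position-major layout keeps each of the k*k slice copies
        contiguous, and the conv GEMM reads it as a plain transpose.
        """
        n, h, w, c = x.shape
        assert c == 1, "first conv expects single-channel input"
        oh, ow = h - k + 1, w - k + 1
        cols = self._buf("cols1", (k * k, n, oh, ow))
        x2 = x[..., 0]
        for i in range(k):
            for j in range(k):
                cols[i * k + j] = x2[:, i : i + oh, j : j + ow]
        return cols.reshape(k * k, n * oh * ow)

    def _pool_fwd(self, x: np.ndarray, tag: str):
        """Non-overlapping max pooling; returns output and argmax offsets."""
        p, s = self.spec.pool, self.spec.pool_stride
        assert p == s, "non-overlapping pooling assumed"
        n, h, w, c = x.shape
        oh, ow = (h - p) // s + 1, (w - p) // s + 1
        out = self._buf(f"{tag}.out", (n, oh, ow, c))
        arg = self._buf(f"{tag}.arg", (n, oh, ow, c), np.int8)
        _pool_fwd_nb(x, p, out, arg)
        return out, arg

    def _pool_bwd(self, dy: np.ndarray, arg: np.ndarray, x_shape, tag: str) -> np.ndarray:
        """Route the gradient to each block's (first) maximum position."""
        dx = self._buf(f"{tag}.dx", x_shape)
        _pool_bwd_nb(np.ascontiguousarray(dy, dtype=np.float32), arg,
                     self.spec.pool, dx)
        return dx

    def _conv2_shift(self, p1: np.ndarray, i: int, j: int, hz: int, wz: int) -> np.ndarray:
        """Contiguous copy of the (i, j)-shifted window of p1, reused buffer."""
        n, _, _, c = p1.shape
        block = self._buf("blk", (n, hz, wz, c))
        block[:] = p1[:, i : i + hz, j : j + wz, :]
        return block

    # ---- forward / backward -------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, rng=None):
        """Return class probabilities (N, 2); caches activations if training.

        Probabilities are returned in a reused buffer: copy them if they
        must survive the next call.
        """
        spec, P = self.spec, self.params
        k = spec.kernel
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] != spec.input_size or x.shape[2] != spec.input_size:
            raise ValueError(
                f"expected {spec.input_size}x{spec.input_size} patches, got "
                f"{x.shape[1]}x{x.shape[2]}"
            )
        x = np.ascontiguousarray(x, dtype=np.float32)

        n = x.shape[0]
        o1 = spec.input_size - k + 1
        c1f, c2f = spec.conv1_filters, spec.conv2_filters
        cols1 = self._im2col_1ch(x, k)
        z1f = self._buf("z1f", (n * o1 * o1, c1f))
        np.matmul(cols1.T, P["W1"], out=z1f)
        z1f += P["b1"]
        a1 = self._buf("a1", (n, o1, o1, c1f))
        np.maximum(z1f.reshape(a1.shape), 0.0, out=a1)
        p1, arg1 = self._pool_fwd(a1, "p1")

        # conv2 as k*k shifted GEMMs over p1 (avoids a large im2col buffer)
        W2v = P["W2"].reshape(c1f, k, k, c2f)
        hz = p1.shape[1] - k + 1
        wz = p1.shape[2] - k + 1
        z2 = self._buf("z2", (n, hz, wz, c2f))
        z2f = z2.reshape(-1, c2f)
        z2f[:] = P["b2"]
        tmp = self._buf("tmp2", (n * hz * wz, c2f))
        for i in range(k):
            for j in range(k):
                block = self._conv2_shift(p1, i, j, hz, wz)
                np.matmul(block.reshape(-1, c1f),
                          np.ascontiguousarray(W2v[:, i, j, :]), out=tmp)
                z2f += tmp
        a2 = self._buf("a2", z2.shape)
        np.maximum(z2, 0.0, out=a2)
        p2, arg2 = self._pool_fwd(a2, "p2")

        flat = p2.reshape(n, -1)
        z3 = flat @ P["W3"] + P["b3"]
        a3 = np.maximum(z3, 0.0)
        if train and spec.dropout_rate > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            keep = (rng.random(a3.shape) >= spec.dropout_rate).astype(np.float32)
            d3 = a3 * keep / (1.0 - spec.dropout_rate)
        else:
            keep = None
            d3 = a3
        logits = d3 @ P["W4"] + P["b4"]
        logits = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache = None
        if train:
            cache = dict(
                cols1=cols1, a1=a1, arg1=arg1, p1=p1,
                arg2=arg2, z2=z2, p2=p2,
                flat=flat, z3=z3, keep=keep, d3=d3,
            )
        return probs, cache

    def backward(self, probs: np.ndarray, y: np.ndarray, cache) -> dict:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        spec, P = self.spec, self.params
        n = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads = {}
        grads["W4"] = cache["d3"].T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dd3 = dlogits @ P["W4"].T
        if cache["keep"] is not None:
            dd3 = dd3 * cache["keep"] / (1.0 - spec.dropout_rate)
        da3 = dd3 * (cache["z3"] > 0)
        grads["W3"] = cache["flat"].T @ da3
        grads["b3"] = da3.sum(axis=0)
        dflat = da3 @ P["W3"].T

        z2 = cache["z2"]
        hz, wz = z2.shape[1], z2.shape[2]
        oh = (hz - spec.pool) // spec.pool_stride + 1
        dp2 = dflat.reshape(n, oh, oh, spec.conv2_filters)
        da2 = self._pool_bwd(dp2, cache["arg2"], z2.shape, "p2")
        da2 *= z2 > 0
        da2_flat = da2.reshape(-1, spec.conv2_filters)
        grads["b2"] = da2_flat.sum(axis=0)

        # conv2 weight gradient and input gradient via the same k*k shifts
        k = spec.kernel
        c1f, c2f = spec.conv1_filters, spec.conv2_filters
        W2v = P["W2"].reshape(c1f, k, k, c2f)
        dW2v = np.zeros_like(W2v)
        p1 = cache["p1"]
        dp1 = self._buf("dp1", p1.shape)
        dp1[:] = 0.0
        tmp = self._buf("tmp1", (n * hz * wz, c1f))
        for i in range(k):
            for j in range(k):
                block = self._conv2_shift(p1, i, j, hz, wz)
                dW2v[:, i, j, :] = block.reshape(-1, c1f).T @ da2_flat
                np.matmul(da2_flat, np.ascontiguousarray(W2v[:, i, j, :]).T, out=tmp)
                dp1[:, i : i + hz, j : j + wz, :] += tmp.reshape(n, hz, wz, c1f)
        grads["W2"] = dW2v.reshape(P["W2"].shape)

        a1 = cache["a1"]
        da1 = self._pool_bwd(dp1, cache["arg1"], a1.shape, "p1")
        da1 *= a1 > 0
        da1_flat = da1.reshape(-1, spec.conv1_filters)
        grads["W1"] = cache["cols1"] @ da1_flat
        grads["b1"] = da1_flat.sum(axis=0)
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic inference probabilities, (N, 2)."""
        outs = []
        for i in range(0, len(x), batch_size):
            probs, _ = self.forward(x[i : i + batch_size], train=False)
            outs.append(probs.copy())
        return np.concatenate(outs) if outs else np.zeros((0, self.spec.n_classes))


def build_net(spec: NetSpec = NetSpec(), rng_seed: int = 0) -> PatchNet:
    """Instantiate the patch classifier with seeded He initialization."""
    return PatchNet(spec, rng_seed=rng_seed)


def count_parameters(net: PatchNet) -> int:
    """Total trainable weight and bias count."""
    return int(sum(p.size for p in net.params.values()))


def layer_parameter_counts(spec: NetSpec = NetSpec()) -> dict[str, int]:
    """Closed-form per-layer parameter arithmetic (weights + biases)."""
    k = spec.kernel
    return {
        "conv1": (k * k * 1 + 1) * spec.conv1_filters,
        "conv2": (k * k * spec.conv1_filters + 1) * spec.conv2_filters,
        "dense1": (spec.flat_units + 1) * spec.dense_units,
        "dense2": (spec.dense_units + 1) * spec.n_classes,
    }


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for key, g in grads.items():
            g = np.asarray(g, dtype=np.float32)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            params[key] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


def _stack_patches(patches) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.pixels for p in patches]).astype(np.float32)[..., None]
    y = np.array([1 if p.label == "carcinogenic" else 0 for p in patches], dtype=np.int64)
    return X, y


def train_patch_classifier(
    patches, config: TrainConfig = TrainConfig(), spec: NetSpec = NetSpec()
) -> tuple[PatchNet, dict]:
    """Train the patch CNN from scratch on labeled whitened patches.

    Returns the trained network and a history dict with per-epoch mean
    training cross-entropy and accuracy.  Cross-entropy is minimized with
    Adam at the configured initial learning rate; training stops early when
    the loss plateaus.
    """
    X, y = _stack_patches(patches)
    if len(np.unique(y)) < 2:
        raise ValueError("training patches must contain both classes")
    net = build_net(spec, rng_seed=config.rng_seed)
    opt = _Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.rng_seed + 1)
    history = {"loss": [], "accuracy": []}
    best, stale = np.inf, 0
    n = len(X)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = X[idx], y[idx]
            probs, cache = net.forward(xb, train=True, rng=rng)
            eps = 1e-12
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + eps))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {_epoch}, step {i // config.batch_size}"
                )
            losses.append(float(loss) * len(yb))
            correct += int((probs.argmax(axis=1) == yb).sum())
            grads = net.backward(probs, yb, cache)
            opt.step(net.params, grads)
        epoch_loss = float(np.sum(losses) / n)
        history["loss"].append(epoch_loss)
        history["accuracy"].append(correct / n)
        if config.plateau_patience is not None:
            if epoch_loss < best - config.plateau_min_delta:
                best, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= config.plateau_patience:
                    break
    return net, history


def predict_patch_probabilities(net: PatchNet, patches) -> list[float]:
    """Posterior probability of class carcinogenic for each patch, in order."""
    if not patches:
        return []
    size = net.spec.input_size
    for p in patches:
        if p.pixels.shape != (size, size):
            raise ValueError(f"patch shape {p.pixels.shape} != ({size}, {size})")
    X = np.stack([p.pixels for p in patches]).astype(np.float32)[..., None]
    return net.predict_proba(X)[:, 1].astype(float).tolist()


def write_training_log(history: dict, path: str | Path) -> None:
    """Write the per-epoch training history as CSV (epoch, loss, accuracy)."""
    lines = ["epoch,loss,accuracy"]
    for i, (loss, acc) in enumerate(zip(history["loss"], history["accuracy"])):
        lines.append(f"{i},{loss:.6f},{acc:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_net(net: PatchNet, path: str | Path) -> None:
    """Save weights (.npz) plus a JSON sidecar with the architecture spec."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **net.params)
    path.with_suffix(".json").write_text(json.dumps(asdict(net.spec), indent=1))


def load_net(path: str | Path) -> PatchNet:
    path = Path(path)
    spec = NetSpec(**json.loads(path.with_suffix(".json").read_text()))
    net = PatchNet(spec)
    with np.load(path.with_suffix(".npz")) as data:
        net.params = {k: data[k].copy() for k in data.files}
    return net
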
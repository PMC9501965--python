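"""The A-net encoder-decoder and its boundary-weighted loss.

A-net is a U-net variant in which every valid convolution is replaced by
a same (zero-padded) convolution, so encoder and decoder feature maps at
matching levels have identical spatial size and skip connections
concatenate without cropping; the output therefore matches the input size.
Each block is two 3x3 convolutions, each followed by batch normalization
and ReLU; 2x2 max pooling halves the resolution on the way down and 2x2
stride-2 transposed convolutions double it on the way up.  A 1x1
convolution maps to M class channels, read out by a pixel-wise softmax

    P_i(x) = exp(a_i(x)) / sum_j exp(a_j(x))

and trained with boundary-weighted cross-entropy

    E = -sum_x w(x) log P_{g(x)}(x),

where the precomputed weight map w gives extra mass to pixels near label
boundaries so the network learns to separate thin adjacent structures.

The network is implemented directly on numpy (forward and backward passes
written out, Adam updates), sized for CPU training on small tiles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "AnetConfig",
    "TrainConfig",
    "WeightMap",
    "Anet",
    "feature_shape",
    "pixel_softmax",
    "weighted_cross_entropy",
    "softmax_ce_with_grad",
    "compute_weight_map",
    "forward",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
]

_DT = np.float32


@dataclass(frozen=True)
class AnetConfig:
    """Architecture hyperparameters.

    depth encoder blocks (default 4), first block with base_channels
    channels (default 64, doubling per level so depth 4 gives a
    1024-channel bottleneck), M output classes (default 2: filament vs
    background).  Input side must be divisible by 2**depth.
    """

    depth: int = 4
    base_channels: int = 64
    classes: int = 2
    in_channels: int = 1

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.classes < 2:
            raise ValueError("classes must be >= 2")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults match the reference regime:
    Adam, minibatch 1; epochs up to 200)."""

    epochs: int = 200
    batch_size: int = 1
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size != 1:
            raise ValueError("only minibatch size 1 is supported")


@dataclass
class WeightMap:
    """Per-pixel loss weights over the label domain."""

    omega: np.ndarray
    ground_truth: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=np.float64)
        self.ground_truth = np.asarray(self.ground_truth)
        if self.omega.shape != self.ground_truth.shape:
            raise ValueError("omega and ground_truth shapes must match")
        if (self.omega < 0).any():
            raise ValueError("omega must be nonnegative")


def feature_shape(input_side: int, depth: int) -> int:
    """Spatial side of the bottleneck feature map: input_side / 2**depth."""
    if input_side % 2**depth:
        raise ValueError(f"input side {input_side} not divisible by 2**{depth}")
    return input_side // 2**depth


def pixel_softmax(activations: np.ndarray) -> np.ndarray:
    """Pixel-wise softmax over the leading class axis, stabilized by
    max-subtraction; probabilities sum to 1 at every pixel."""
    a = np.asarray(activations, dtype=np.float64)
    if a.ndim != 3 or a.shape[0] < 2:
        raise ValueError("activations must be (M, H, W) with M >= 2")
    shifted = a - a.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=0, keepdims=True)


def weighted_cross_entropy(P: np.ndarray, weight_map: WeightMap) -> float:
    """E = -sum_x w(x) log P_{g(x)}(x); zero iff the true-class probability
    is 1 wherever w > 0, and linear in w."""
    P = np.asarray(P, dtype=np.float64)
    g = weight_map.ground_truth.astype(int)
    if P.shape[1:] != g.shape:
        raise ValueError("probability map and ground truth shapes must match")
    rows, cols = np.indices(g.shape)
    pg = np.clip(P[g, rows, cols], 1e-300, None)
    return float(-(weight_map.omega * np.log(pg)).sum())


def softmax_ce_with_grad(logits: np.ndarray, weight_map: WeightMap):
    """Loss and its gradient w.r.t. the class activations:
    dE/da_i(x) = w(x) (P_i(x) - [i == g(x)])."""
    a = np.asarray(logits, dtype=np.float64)
    g = weight_map.ground_truth.astype(int)
    shifted = a - a.max(axis=0, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=0, keepdims=True))
    logp = shifted - logz
    rows, cols = np.indices(g.shape)
    loss = float(-(weight_map.omega * logp[g, rows, cols]).sum())
    P = np.exp(logp)
    grad = P.copy()
    grad[g, rows, cols] -= 1.0
    grad *= weight_map.omega[None]
    return loss, grad


def compute_weight_map(label: np.ndarray, w0: float = 10.0,
                       sigma: float = 5.0) -> WeightMap:
    """Boundary-emphasis weight map, computed once per label.

    w(x) = w_class(g(x)) + w0 * exp(-d(x)^2 / (2 sigma^2)), with d the
    Euclidean distance to the nearest foreground/background boundary pixel
    and w_class the inverse-frequency class balance N / (M * N_c).  A
    uniform label has no boundary, so w reduces to the class term.
    """
    g = (np.asarray(label) > 0).astype(np.uint8)
    n = g.size
    w_class = np.empty(g.shape, dtype=np.float64)
    for c in (0, 1):
        nc = int((g == c).sum())
        w_class[g == c] = n / (2.0 * nc) if nc else 0.0
    # boundary: pixels with a 4-neighbor of the opposite class
    diff = np.zeros(g.shape, dtype=bool)
    diff[:-1, :] |= g[:-1, :] != g[1:, :]
    diff[1:, :] |= g[1:, :] != g[:-1, :]
    diff[:, :-1] |= g[:, :-1] != g[:, 1:]
    diff[:, 1:] |= g[:, 1:] != g[:, :-1]
    if diff.any():
        d = ndimage.distance_transform_edt(~diff)
        omega = w_class + w0 * np.exp(-(d**2) / (2.0 * sigma**2))
    else:
        omega = w_class
    return WeightMap(omega=omega, ground_truth=g)


# --------------------------------------------------------------------------
# layers


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value):
        self.value = value.astype(_DT)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    cin, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad))) if pad else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    return np.ascontiguousarray(
        win.transpose(1, 2, 0, 3, 4).reshape(h * w, cin * k * k)
    )


class _Conv:
    """Same-padded 2D convolution (k odd), stride 1, via im2col + GEMM."""

    def __init__(self, cin, cout, k, rng):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = _Param(rng.normal(0.0, std, (cout, cin * k * k)))
        self.b = _Param(np.zeros(cout))
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2

    def forward(self, x, training):
        self._shape = x.shape
        cols = _im2col(x, self.k, self.pad)
        if training:
            self._cols = cols
        y = cols @ self.w.value.T + self.b.value
        h, w = x.shape[1:]
        return np.ascontiguousarray(y.reshape(h, w, self.cout).transpose(2, 0, 1))

    def backward(self, gy):
        h, w = self._shape[1:]
        g = gy.transpose(1, 2, 0).reshape(h * w, self.cout)
        self.w.grad += (g.T @ self._cols).astype(_DT)
        self.b.grad += g.sum(axis=0).astype(_DT)
        # input gradient: convolve gy with the flipped, transposed kernel
        wt = self.w.value.reshape(self.cout, self.cin, self.k, self.k)
        wflip = wt.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        gcols = _im2col(gy, self.k, self.pad)
        gx = gcols @ wflip.reshape(self.cin, -1).T
        self._cols = None
        return np.ascontiguousarray(gx.reshape(h, w, self.cin).transpose(2, 0, 1))

    def params(self):
        return [self.w, self.b]


class _BatchNorm:
    """Per-channel normalization over the spatial extent (single-sample
    training: statistics are the H*W spatial moments)."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = _Param(np.ones(c))
        self.beta = _Param(np.zeros(c))
        self.run_mean = np.zeros(c, dtype=_DT)
        self.run_var = np.ones(c, dtype=_DT)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.run_mean = ((1 - self.momentum) * self.run_mean
                             + self.momentum * mu).astype(_DT)
            self.run_var = ((1 - self.momentum) * self.run_var
                            + self.momentum * var).astype(_DT)
        else:
            mu, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv[:, None, None]
        if training:
            self._xhat, self._inv = xhat, inv
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, gy):
        xhat, inv = self._xhat, self._inv
        n = gy.shape[1] * gy.shape[2]
        self.gamma.grad += (gy * xhat).sum(axis=(1, 2)).astype(_DT)
        self.beta.grad += gy.sum(axis=(1, 2)).astype(_DT)
        gxhat = gy * self.gamma.value[:, None, None]
        s1 = gxhat.sum(axis=(1, 2), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(1, 2), keepdims=True)
        gx = (inv[:, None, None] / n) * (n * gxhat - s1 - xhat * s2)
        self._xhat = self._inv = None
        return gx.astype(_DT)

    def params(self):
        return [self.gamma, self.beta]


class _ReLU:
    def forward(self, x, training):
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, gy):
        gx = gy * self._mask
        self._mask = None
        return gx

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x, training):
        c, h, w = x.shape
        v = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
        v = v.reshape(c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        if training:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        c, h, w = self._shape
        flat = np.zeros((c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(flat, self._idx[..., None], gy[..., None], axis=-1)
        gx = flat.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4)
        self._idx = None
        return np.ascontiguousarray(gx.reshape(c, h, w))

    def params(self):
        return []


class _ConvT2:
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin, cout, rng):
        std = np.sqrt(2.0 / (cin * 4))
        self.w = _Param(rng.normal(0.0, std, (cin, cout, 2, 2)))
        self.b = _Param(np.zeros(cout))
        self.cin, self.cout = cin, cout

    def forward(self, x, training):
        if training:
            self._x = x
        y = np.einsum("chw,cokl->ohkwl", x, self.w.value, optimize=True)
        c, h, w = x.shape
        return y.reshape(self.cout, 2 * h, 2 * w) + self.b.value[:, None, None]

    def backward(self, gy):
        o, h2, w2 = gy.shape
        gr = gy.reshape(o, h2 // 2, 2, w2 // 2, 2)
        gx = np.einsum("ohkwl,cokl->chw", gr, self.w.value, optimize=True)
        self.w.grad += np.einsum("chw,ohkwl->cokl", self._x, gr,
                                 optimize=True).astype(_DT)
        self.b.grad += gy.sum(axis=(1, 2)).astype(_DT)
        self._x = None
        return gx.astype(_DT)

    def params(self):
        return [self.w, self.b]


class _ConvBlock:
    """conv3x3 -> BN -> ReLU, twice."""

    def __init__(self, cin, cout, rng):
        self.layers = [
            _Conv(cin, cout, 3, rng), _BatchNorm(cout), _ReLU(),
            _Conv(cout, cout, 3, rng), _BatchNorm(cout), _ReLU(),
        ]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy

    def params(self):
        return [p for l in self.layers for p in l.params()]


class Anet:
    """The all-same-convolution encoder-decoder network."""

    def __init__(self, config: AnetConfig, seed: int = 0,
                 rng: np.random.Generator | None = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(seed)
        d, b = config.depth, config.base_channels
        self.enc = []
        cin = config.in_channels
        for k in range(d):
            cout = b * 2**k
            self.enc.append(_ConvBlock(cin, cout, rng))
            cin = cout
        self.pools = [_MaxPool2() for _ in range(d)]
        self.bottleneck = _ConvBlock(cin, b * 2**d, rng)
        cin = b * 2**d
        self.ups, self.dec = [], []
        for k in reversed(range(d)):
            cout = b * 2**k
            self.ups.append(_ConvT2(cin, cout, rng))
            self.dec.append(_ConvBlock(2 * cout, cout, rng))
            cin = cout
        self.out = _Conv(cin, config.classes, 1, rng)

    # -- passes -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(C_in, H, W) -> class activations (M, H, W); H, W preserved."""
        x = np.asarray(x, dtype=_DT)
        if x.ndim == 2:
            x = x[None]
        side = x.shape[1]
        if side % 2**self.config.depth or x.shape[2] % 2**self.config.depth:
            raise ValueError(
                f"input side {x.shape[1:]} not divisible by 2**{self.config.depth}"
            )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._split = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            # same-conv property: encoder map has identical spatial size,
            # so the skip concatenates without cropping
            x = np.concatenate([skip, x], axis=0)
            self._split.append(skip.shape[0])
            x = dec.forward(x, training)
        return self.out.forward(x, training)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.out.backward(grad_logits.astype(_DT))
        skip_grads = []
        for dec, up, nskip in zip(reversed(self.dec), reversed(self.ups),
                                  reversed(self._split)):
            g = dec.backward(g)
            skip_grads.append(g[:nskip])
            g = up.backward(g[nskip:])
        g = self.bottleneck.backward(g)
        for blk, pool, sg in zip(reversed(self.enc), reversed(self.pools),
                                 reversed(skip_grads)):
            g = pool.backward(g)
            g = blk.backward(g + sg)

    # -- parameters -------------------------------------------------------
    def params(self):
        out = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for up, dec in zip(self.ups, self.dec):
            out += up.params() + dec.params()
        out += self.out.params()
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    def state_arrays(self) -> list:
        arrs = [p.value.copy() for p in self.params()]
        for bn in self._bn_layers():
            arrs += [bn.run_mean.copy(), bn.run_var.copy()]
        return arrs

    def load_state_arrays(self, arrs: list) -> None:
        ps = self.params()
        for p, a in zip(ps, arrs[: len(ps)]):
            p.value[...] = a
        rest = arrs[len(ps):]
        for i, bn in enumerate(self._bn_layers()):
            bn.run_mean[...] = rest[2 * i]
            bn.run_var[...] = rest[2 * i + 1]

    def _bn_layers(self):
        blocks = self.enc + [self.bottleneck] + self.dec
        return [l for blk in blocks for l in blk.layers
                if isinstance(l, _BatchNorm)]


def forward(model: Anet, img: np.ndarray) -> np.ndarray:
    """Inference pass: per-class probability map, same spatial size."""
    logits = model.forward(img, training=False)
    return pixel_softmax(logits.astype(np.float64))


# --------------------------------------------------------------------------
# training


def _standardize(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float64)
    return ((a - a.mean()) / (a.std() + 1e-8)).astype(_DT)


class _Adam:
    def __init__(self, params, cfg: TrainConfig):
        self.params, self.cfg, self.t = params, cfg, 0

    def step(self):
        self.t += 1
        c = self.cfg
        bc1 = 1 - c.beta1**self.t
        bc2 = 1 - c.beta2**self.t
        for p in self.params:
            p.m = c.beta1 * p.m + (1 - c.beta1) * p.grad
            p.v = c.beta2 * p.v + (1 - c.beta2) * p.grad**2
            p.value -= (c.lr * (p.m / bc1)
                        / (np.sqrt(p.v / bc2) + c.adam_eps)).astype(_DT)


@dataclass
class TrainResult:
    model: Anet
    history: list
    best_epoch: int


def _loss_of(model, x, wm, training):
    logits = model.forward(x, training=training)
    loss, grad = softmax_ce_with_grad(logits, wm)
    return loss / wm.omega.size, grad


def train(pairs: list, config: AnetConfig, train_cfg: TrainConfig,
          val_pairs: list | None = None, log=None) -> TrainResult:
    """Train on (image, binary label) pairs with minibatch 1 and Adam.

    Weight maps are computed once per label in advance; images are
    standardized per tile.  Fully deterministic for a fixed seed (one
    global RNG drives initialization and data order).  The best state by
    validation loss (training loss if no validation set) is restored into
    the returned model.  NaN loss aborts with a diagnostic.
    """
    if not pairs:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(train_cfg.seed)
    model = Anet(config, rng=rng)

    def prep(ps):
        return [(_standardize(img.pixels if hasattr(img, "pixels") else img),
                 compute_weight_map(lab)) for img, lab in ps]

    tr = prep(pairs)
    va = prep(val_pairs) if val_pairs else None
    opt = _Adam(model.params(), train_cfg)
    history, best = [], (np.inf, 0, model.state_arrays())
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(tr))
        total = 0.0
        for i in order:
            x, wm = tr[i]
            model.zero_grad()
            loss, grad = _loss_of(model, x, wm, training=True)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, sample {i}"
                )
            model.backward(grad)
            opt.step()
            total += loss
        train_loss = total / len(tr)
        if va:
            sel_loss = float(np.mean([_loss_of(model, x, wm, False)[0]
                                      for x, wm in va]))
        else:
            sel_loss = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": sel_loss if va else None})
        if log is not None:
            log(history[-1])
        if sel_loss < best[0]:
            best = (sel_loss, epoch, model.state_arrays())
    if train_cfg.epochs:
        model.load_state_arrays(best[2])
    return TrainResult(model=model, history=history, best_epoch=best[1])


def predict_proba(model: Anet, img) -> np.ndarray:
    """Standardize an image tile and return the (M, H, W) probability map."""
    arr = img.pixels if hasattr(img, "pixels") else np.asarray(img)
    return forward(model, _standardize(arr))


def save_model(path, model: Anet) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrs = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrs)


def load_model(path) -> Anet:
    data = np.load(path, allow_pickle=False)
    config = AnetConfig(**json.loads(str(data["config"])))
    model = Anet(config, seed=0)
    n = len(model.state_arrays())
    model.load_state_arrays([data[f"arr_{i}"] for i in range(n)])
    return model
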
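"""Encoder-decoder BiLSTM backbone and shape-preserving session-calibrator.

The backbone is a classifier shaped like a symmetric autoencoder: an
encoder (two BiLSTM layers, then two fully connected layers ending in a
4-unit *bottleneck*) and a mirrored decoder (two fully connected layers,
then two BiLSTM layers driven by the bottleneck repeated across the 24
time steps), topped by a softmax classification head.  It is not a true
autoencoder — there is no reconstruction objective — but the bottleneck
activations give a 4-dimensional latent representation of each window.

The calibrator is a small time-distributed channel mixer (8 -> hidden ->
8, shared across the 24 time steps) placed in front of the backbone.  It
preserves the 8x24 window shape and models exactly the physical
session-to-session distortions of an armband: per-channel gain, offset
and electrode rotation (channel mixing).

Both networks are implemented directly on numpy arrays with hand-written
reverse-mode gradients; the LSTM time loops are numba-compiled.  All
parameters are float32.  A model whose ``frozen`` flag is set is skipped
entirely by the optimizer, so its parameters stay bitwise unchanged
through any number of training steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "ModelConfig",
    "BackboneModel",
    "CalibratorModel",
    "AdamOptimizer",
    "build_backbone",
    "build_calibrator",
    "forward",
    "softmax_cross_entropy",
    "save_checkpoint",
    "load_checkpoint",
]

F32 = np.float32


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults sized for CPU training)."""

    n_channels: int = 8
    win_len: int = 24
    n_classes: int = 11
    bilstm_layers: int = 2
    bilstm_hidden: int = 64       # units per direction
    fc_layers: int = 2
    fc_hidden: int = 32
    bottleneck_dim: int = 4
    dropout: float = 0.25
    calibrator_hidden: int = 16

    def validate(self) -> None:
        ok = (
            self.n_channels >= 1 and self.win_len >= 1 and self.n_classes >= 2
            and self.bilstm_layers >= 1 and self.bilstm_hidden >= 1
            and self.fc_layers >= 1 and self.fc_hidden >= 1
            and self.bottleneck_dim >= 1 and 0.0 <= self.dropout < 1.0
            and self.calibrator_hidden >= 1
        )
        if not ok:
            raise ValueError(f"invalid architecture: {self}")


# ---------------------------------------------------------------------------
# numba LSTM kernels
# ---------------------------------------------------------------------------

_C0 = np.float32(10395.0)
_C1 = np.float32(1260.0)
_C2 = np.float32(21.0)
_C3 = np.float32(4725.0)
_C4 = np.float32(210.0)
_CLIP = np.float32(4.9)
_HALF = np.float32(0.5)


@njit(inline="always")
def _ftanh(x):  # pragma: no cover
    # Branchless all-float32 Pade (7,6) rational tanh on the clamped
    # argument (|error| < 1e-3; SIMD-friendly).  The clamp saturates at
    # ~0.99906, not 1.0, so saturated units keep a nonzero gradient.
    xc = min(max(x, -_CLIP), _CLIP)
    x2 = xc * xc
    return (xc * (_C0 + x2 * (_C1 + x2 * _C2))
            / (_C0 + x2 * (_C3 + x2 * (_C4 + x2))))


@njit(inline="always")
def _fsigm(x):  # pragma: no cover
    return _HALF + _HALF * _ftanh(_HALF * x)


@njit(cache=True, fastmath=True)
def _lstm_fwd(zx, wh):  # pragma: no cover - exercised via LSTM layer tests
    """Run one LSTM direction.  zx: (T, B, 4H) input pre-activations.

    Gate math is fused into scalar loops with rational tanh/sigmoid
    approximations to avoid per-step temporaries and libm calls.
    """
    T, B, H4 = zx.shape
    H = H4 // 4
    h = np.zeros((T, B, H), dtype=zx.dtype)
    gi = np.empty((T, B, H), dtype=zx.dtype)
    gf = np.empty((T, B, H), dtype=zx.dtype)
    gg = np.empty((T, B, H), dtype=zx.dtype)
    go = np.empty((T, B, H), dtype=zx.dtype)
    cc = np.empty((T, B, H), dtype=zx.dtype)
    tc = np.empty((T, B, H), dtype=zx.dtype)
    h_prev = np.zeros((B, H), dtype=zx.dtype)
    c_prev = np.zeros((B, H), dtype=zx.dtype)
    one = zx.dtype.type(1.0)
    for t in range(T):
        a = zx[t] + np.dot(h_prev, wh)
        for b in range(B):
            for j in range(H):
                it = _fsigm(a[b, j])
                ft = _fsigm(a[b, H + j])
                gt = _ftanh(a[b, 2 * H + j])
                ot = _fsigm(a[b, 3 * H + j])
                ct = ft * c_prev[b, j] + it * gt
                tct = _ftanh(ct)
                gi[t, b, j] = it
                gf[t, b, j] = ft
                gg[t, b, j] = gt
                go[t, b, j] = ot
                cc[t, b, j] = ct
                tc[t, b, j] = tct
                h[t, b, j] = ot * tct
        h_prev = h[t]
        c_prev = cc[t]
    return h, gi, gf, gg, go, cc, tc


@njit(cache=True, fastmath=True)
def _lstm_bwd(dh_up, gi, gf, gg, go, cc, tc, wh_t):  # pragma: no cover
    """BPTT for one direction; returns gate pre-activation grads (T, B, 4H)."""
    T, B, H = dh_up.shape
    dz = np.empty((T, B, 4 * H), dtype=dh_up.dtype)
    dh_next = np.zeros((B, H), dtype=dh_up.dtype)
    dc_next = np.zeros((B, H), dtype=dh_up.dtype)
    da = np.empty((B, 4 * H), dtype=dh_up.dtype)
    one = dh_up.dtype.type(1.0)
    zero = dh_up.dtype.type(0.0)
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(H):
                dh = dh_up[t, b, j] + dh_next[b, j]
                tcv = tc[t, b, j]
                dc = dc_next[b, j] + dh * go[t, b, j] * (one - tcv * tcv)
                cp = cc[t - 1, b, j] if t > 0 else zero
                iv, fv, gv, ov = gi[t, b, j], gf[t, b, j], gg[t, b, j], go[t, b, j]
                da[b, j] = dc * gv * iv * (one - iv)
                da[b, H + j] = dc * cp * fv * (one - fv)
                da[b, 2 * H + j] = dc * iv * (one - gv * gv)
                da[b, 3 * H + j] = dh * tcv * ov * (one - ov)
                dc_next[b, j] = dc * fv
        dz[t] = da
        dh_next = np.dot(da, wh_t)
    return dz


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _uniform(rng: np.random.Generator, shape, k: float) -> np.ndarray:
    return rng.uniform(-k, k, size=shape).astype(F32)


class _LSTMDir:
    """One LSTM direction; gate order i, f, g, o; forget bias +1."""

    def __init__(self, prefix: str, d_in: int, hidden: int, reverse: bool):
        self.prefix, self.d_in, self.h, self.reverse = prefix, d_in, hidden, reverse
        self.names = [f"{prefix}.wx", f"{prefix}.wh", f"{prefix}.b"]

    def init(self, params: dict, rng: np.random.Generator) -> None:
        k = 1.0 / np.sqrt(self.h)
        params[f"{self.prefix}.wx"] = _uniform(rng, (self.d_in, 4 * self.h), k)
        params[f"{self.prefix}.wh"] = _uniform(rng, (self.h, 4 * self.h), k)
        b = _uniform(rng, (4 * self.h,), k)
        b[self.h:2 * self.h] += 1.0  # forget-gate bias
        params[f"{self.prefix}.b"] = b

    def forward(self, P: dict, x: np.ndarray):
        # x: (T, B, D) -> h: (T, B, H) in original time order
        xs = x[::-1] if self.reverse else x
        T, B, D = xs.shape
        zx = (xs.reshape(T * B, D) @ P[f"{self.prefix}.wx"]
              + P[f"{self.prefix}.b"]).reshape(T, B, 4 * self.h)
        h, gi, gf, gg, go, cc, tc = _lstm_fwd(np.ascontiguousarray(zx),
                                              P[f"{self.prefix}.wh"])
        out = h[::-1] if self.reverse else h
        cache = (xs, h, gi, gf, gg, go, cc, tc)
        return out, cache

    def backward(self, P: dict, G: dict, d_out: np.ndarray, cache):
        xs, h, gi, gf, gg, go, cc, tc = cache
        d_up = d_out[::-1] if self.reverse else d_out
        wh = P[f"{self.prefix}.wh"]
        dz = _lstm_bwd(np.ascontiguousarray(d_up), gi, gf, gg, go, cc, tc,
                       np.ascontiguousarray(wh.T))
        T, B, H = d_up.shape
        dz_flat = dz.reshape(T * B, 4 * H)
        if G is not None:
            h_prev = np.concatenate([np.zeros((1, B, H), dtype=F32), h[:-1]], axis=0)
            G[f"{self.prefix}.wh"] += h_prev.reshape(T * B, H).T @ dz_flat
            G[f"{self.prefix}.wx"] += xs.reshape(T * B, self.d_in).T @ dz_flat
            G[f"{self.prefix}.b"] += dz_flat.sum(axis=0)
        dx = (dz_flat @ P[f"{self.prefix}.wx"].T).reshape(T, B, self.d_in)
        return dx[::-1] if self.reverse else dx


class _BiLSTM:
    """Bidirectional LSTM layer: (T, B, D) -> (T, B, 2H)."""

    def __init__(self, prefix: str, d_in: int, hidden: int):
        self.prefix, self.d_in, self.h = prefix, d_in, hidden
        self.fwd = _LSTMDir(f"{prefix}.fwd", d_in, hidden, reverse=False)
        self.bwd = _LSTMDir(f"{prefix}.bwd", d_in, hidden, reverse=True)
        self.names = self.fwd.names + self.bwd.names

    def init(self, params, rng):
        self.fwd.init(params, rng)
        self.bwd.init(params, rng)

    def forward(self, P, x):
        hf, cf = self.fwd.forward(P, x)
        hb, cb = self.bwd.forward(P, x)
        return np.concatenate([hf, hb], axis=2), (cf, cb)

    def backward(self, P, G, d_out, cache):
        cf, cb = cache
        h = self.h
        dxf = self.fwd.backward(P, G, np.ascontiguousarray(d_out[:, :, :h]), cf)
        dxb = self.bwd.backward(P, G, np.ascontiguousarray(d_out[:, :, h:]), cb)
        return dxf + dxb

    def structure(self) -> tuple:
        return ("bilstm", self.d_in, self.h)


class _Linear:
    def __init__(self, prefix: str, d_in: int, d_out: int):
        self.prefix, self.d_in, self.d_out = prefix, d_in, d_out
        self.names = [f"{prefix}.w", f"{prefix}.b"]

    def init(self, params, rng):
        k = 1.0 / np.sqrt(self.d_in)
        params[f"{self.prefix}.w"] = _uniform(rng, (self.d_in, self.d_out), k)
        params[f"{self.prefix}.b"] = _uniform(rng, (self.d_out,), k)

    def forward(self, P, x):
        return x @ P[f"{self.prefix}.w"] + P[f"{self.prefix}.b"], x

    def backward(self, P, G, d_out, cache):
        x = cache
        if G is not None:
            G[f"{self.prefix}.w"] += x.T @ d_out
            G[f"{self.prefix}.b"] += d_out.sum(axis=0)
        return d_out @ P[f"{self.prefix}.w"].T

    def structure(self) -> tuple:
        return ("fc", self.d_in, self.d_out)


_LEAK = F32(0.01)


def _lrelu(z):
    return np.where(z > 0, z, _LEAK * z)


def _dlrelu(z):
    return np.where(z > 0, F32(1.0), _LEAK)


def _dropout(x, rate, rng, train):
    if not train or rate <= 0:
        return x, None
    mask = (rng.random(x.shape) >= rate).astype(F32) / F32(1.0 - rate)
    return x * mask, mask


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class _Model:
    """Named float32 parameter collection with a freeze flag."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.frozen: bool = False

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def clone(self):
        """Deep copy (parameters and metadata); freeze flag reset."""
        import copy

        other = copy.copy(self)
        other.params = self.copy_params()
        other.frozen = False
        return other


class BackboneModel(_Model):
    """Session-agnostic encoder-decoder BiLSTM classifier.

    ``forward`` maps a batch of 8x24 windows to (class probabilities,
    4-unit bottleneck activations).  ``input_scale`` is a single scalar
    set from the training windows so raw millivolt amplitudes enter the
    recurrent layers at unit order of magnitude.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        super().__init__(config)
        c = config
        H, F = c.bilstm_hidden, c.fc_hidden
        self.enc_lstm = [
            _BiLSTM(f"enc.lstm{i}", c.n_channels if i == 0 else 2 * H, H)
            for i in range(c.bilstm_layers)
        ]
        enc_fc_sizes = [2 * H] + [F] * (c.fc_layers - 1) + [c.bottleneck_dim]
        self.enc_fc = [
            _Linear(f"enc.fc{i}", enc_fc_sizes[i], enc_fc_sizes[i + 1])
            for i in range(c.fc_layers)
        ]
        dec_fc_sizes = list(reversed(enc_fc_sizes))
        self.dec_fc = [
            _Linear(f"dec.fc{i}", dec_fc_sizes[i], dec_fc_sizes[i + 1])
            for i in range(c.fc_layers)
        ]
        self.dec_lstm = [
            _BiLSTM(f"dec.lstm{i}", 2 * H, H) for i in range(c.bilstm_layers)
        ]
        self.head = _Linear("head", 2 * H, c.n_classes)
        rng = np.random.default_rng(seed)
        for layer in (*self.enc_lstm, *self.enc_fc, *self.dec_fc,
                      *self.dec_lstm, self.head):
            layer.init(self.params, rng)
        self.input_scale: float = 1.0
        self.class_labels: list[str] = []

    # -- structure ----------------------------------------------------------

    def encoder_structure(self) -> list[tuple]:
        return [l.structure() for l in (*self.enc_lstm, *self.enc_fc)]

    def decoder_structure(self) -> list[tuple]:
        return [l.structure() for l in (*self.dec_fc, *self.dec_lstm)]

    def fit_input_scale(self, windows: np.ndarray, target_std: float = 3.0) -> None:
        """Set the scalar input gain from training windows.

        Inputs are standardized to a standard deviation of ~3 so the
        first recurrent layer's gates operate across their responsive
        range, which lets the cell state accumulate amplitude (variance)
        information quickly.
        """
        sd = float(np.std(windows))
        self.input_scale = target_std / sd if sd > 0 else 1.0

    # -- forward / backward -------------------------------------------------

    @staticmethod
    def _pool(seq: np.ndarray, h: int) -> np.ndarray:
        # final recurrent state of each direction: forward at t=T-1,
        # backward at t=0 (its last processed step)
        return np.concatenate([seq[-1, :, :h], seq[0, :, h:]], axis=1)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                prescaled: bool = False):
        """x: (B, 8, 24) -> (probs (B, K), bottleneck (B, 4), cache).

        ``prescaled=True`` means ``input_scale`` has already been
        applied upstream (it must be, whenever a calibrator sits in
        front of the backbone, so the calibrator operates at unit
        signal scale).
        """
        c = self.config
        if x.ndim != 3 or x.shape[1:] != (c.n_channels, c.win_len):
            raise ValueError(f"bad window: expected (B, {c.n_channels}, {c.win_len}), got {x.shape}")
        if train and rng is None:
            rng = np.random.default_rng(0)
        P = self.params
        cache: dict = {"train": train}
        xs = x if prescaled else x * F32(self.input_scale)
        h = np.ascontiguousarray(xs.transpose(2, 0, 1).astype(F32))
        T, B = c.win_len, x.shape[0]

        for i, layer in enumerate(self.enc_lstm):
            h, cc = layer.forward(P, h)
            h, mask = _dropout(h, c.dropout, rng, train)
            cache[f"enc.lstm{i}"] = (cc, mask)
        feat = self._pool(h, c.bilstm_hidden)
        cache["enc.seq_shape"] = h.shape

        a = feat
        for i, layer in enumerate(self.enc_fc[:-1]):
            z, cc = layer.forward(P, a)
            r = _lrelu(z)
            r, mask = _dropout(r, c.dropout, rng, train)
            cache[f"enc.fc{i}"] = (cc, z, mask)
            a = r
        z, cc = self.enc_fc[-1].forward(P, a)
        bott = np.tanh(z)
        cache["enc.bott"] = (cc, bott)

        a = bott
        for i, layer in enumerate(self.dec_fc):
            z, cc = layer.forward(P, a)
            r = _lrelu(z)
            if i < len(self.dec_fc) - 1:
                r, mask = _dropout(r, c.dropout, rng, train)
            else:
                mask = None
            cache[f"dec.fc{i}"] = (cc, z, mask)
            a = r

        hseq = np.broadcast_to(a[None, :, :], (T, B, a.shape[1])).astype(F32)
        hd = np.ascontiguousarray(hseq)
        for i, layer in enumerate(self.dec_lstm):
            hd, cc = layer.forward(P, hd)
            if i < len(self.dec_lstm) - 1:
                hd, mask = _dropout(hd, c.dropout, rng, train)
            else:
                mask = None
            cache[f"dec.lstm{i}"] = (cc, mask)
        dfeat = self._pool(hd, c.bilstm_hidden)
        cache["dec.seq_shape"] = hd.shape

        logits, cc = self.head.forward(P, dfeat)
        cache["head"] = cc
        probs = _softmax(logits)
        cache["logits"] = logits
        return probs, bott, cache

    def backward(self, G: dict, d_logits: np.ndarray, cache: dict) -> np.ndarray:
        """Backprop from logit grads; returns grad w.r.t. the raw input (B, 8, 24)."""
        c = self.config
        P = self.params
        H = c.bilstm_hidden
        d_dfeat = self.head.backward(P, G, d_logits, cache["head"])

        T, B, _ = cache["dec.seq_shape"]
        d_hd = np.zeros((T, B, 2 * H), dtype=F32)
        d_hd[-1, :, :H] += d_dfeat[:, :H]
        d_hd[0, :, H:] += d_dfeat[:, H:]
        for i in reversed(range(len(self.dec_lstm))):
            cc, mask = cache[f"dec.lstm{i}"]
            if mask is not None:
                d_hd = d_hd * mask
            d_hd = self.dec_lstm[i].backward(P, G, d_hd, cc)
        d_a = d_hd.sum(axis=0)  # undo broadcast across time

        for i in reversed(range(len(self.dec_fc))):
            cc, z, mask = cache[f"dec.fc{i}"]
            if mask is not None:
                d_a = d_a * mask
            d_a = self.dec_fc[i].backward(P, G, d_a * _dlrelu(z), cc)

        cc, bott = cache["enc.bott"]
        d_z = d_a * (1.0 - bott * bott)
        d_a = self.enc_fc[-1].backward(P, G, d_z, cc)
        for i in reversed(range(len(self.enc_fc) - 1)):
            cc, z, mask = cache[f"enc.fc{i}"]
            if mask is not None:
                d_a = d_a * mask
            d_a = self.enc_fc[i].backward(P, G, d_a * _dlrelu(z), cc)

        T, B, _ = cache["enc.seq_shape"]
        d_h = np.zeros((T, B, 2 * H), dtype=F32)
        d_h[-1, :, :H] += d_a[:, :H]
        d_h[0, :, H:] += d_a[:, H:]
        for i in reversed(range(len(self.enc_lstm))):
            cc, mask = cache[f"enc.lstm{i}"]
            if mask is not None:
                d_h = d_h * mask
            d_h = self.enc_lstm[i].backward(P, G, d_h, cc)
        # (T, B, C) -> (B, C, T); grad w.r.t. the (scaled) input as passed in
        return d_h.transpose(1, 2, 0)


class CalibratorModel(_Model):
    """Per-session front end: residual time-distributed channel mixer.

    ``y_t = x_t + W2 leaky(W1 x_t + b1) + b2`` applied at each of the 24
    time steps (weights shared across time).  The residual form keeps
    the map anchored to the identity: the session correction is learned
    as a perturbation, matching the physics of armband re-donning (gain,
    offset, electrode rotation are all near-identity channel maps), and
    a partially trained calibrator can never collapse the signal.

    ``init="identity"`` zeroes the output layer so the initial transform
    is exactly the identity; ``init="random"`` starts from a small
    random correction.
    """

    def __init__(self, config: ModelConfig, seed: int = 0, init: str = "identity"):
        config.validate()
        super().__init__(config)
        c = config
        self.l1 = _Linear("cal.fc0", c.n_channels, c.calibrator_hidden)
        self.l2 = _Linear("cal.fc1", c.calibrator_hidden, c.n_channels)
        rng = np.random.default_rng(seed)
        self.l1.init(self.params, rng)
        self.l2.init(self.params, rng)
        if init == "identity":
            self.params["cal.fc1.w"] = np.zeros_like(self.params["cal.fc1.w"])
            self.params["cal.fc1.b"] = np.zeros_like(self.params["cal.fc1.b"])
        elif init == "random":
            self.params["cal.fc1.w"] *= F32(0.1)
            self.params["cal.fc1.b"] *= F32(0.1)
        else:
            raise ValueError(f"unknown calibrator init {init!r}")

    def forward(self, x: np.ndarray):
        """x: (B, 8, 24) -> (y (B, 8, 24), cache); shape-preserving."""
        c = self.config
        if x.ndim != 3 or x.shape[1:] != (c.n_channels, c.win_len):
            raise ValueError(f"bad window: got {x.shape}")
        B = x.shape[0]
        flat = x.transpose(0, 2, 1).reshape(B * c.win_len, c.n_channels).astype(F32)
        z1, c1 = self.l1.forward(self.params, flat)
        r1 = _lrelu(z1)
        y, c2 = self.l2.forward(self.params, r1)
        out = (flat + y).reshape(B, c.win_len, c.n_channels).transpose(0, 2, 1)
        return out, (c1, z1, c2, B)

    def backward(self, G: dict, d_out: np.ndarray, cache) -> np.ndarray:
        c1, z1, c2, B = cache
        c = self.config
        d_flat = d_out.transpose(0, 2, 1).reshape(B * c.win_len, c.n_channels).astype(F32)
        d_r1 = self.l2.backward(self.params, G, d_flat, c2)
        d_x = d_flat + self.l1.backward(self.params, G, d_r1 * _dlrelu(z1), c1)
        return d_x.reshape(B, c.win_len, c.n_channels).transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# loss / optimizer / public ops
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross entropy and the gradient w.r.t. the logits."""
    probs = _softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.maximum(probs[np.arange(n), y], 1e-12))))
    d = probs.copy()
    d[np.arange(n), y] -= 1.0
    return loss, (d / n).astype(F32)


class AdamOptimizer:
    """Adam over one or more models; frozen models are skipped entirely."""

    def __init__(self, models: list[_Model], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.models = models
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = [
            {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in m.params.items()}
            for m in models
        ]

    def step(self, grads: list[dict]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for m, st, G in zip(self.models, self.state, grads):
            if m.frozen or G is None:
                continue
            for k, v in m.params.items():
                g = G[k]
                mom, vel = st[k]
                mom *= self.b1
                mom += (1 - self.b1) * g
                vel *= self.b2
                vel += (1 - self.b2) * g * g
                v -= F32(self.lr) * (mom / bc1) / (np.sqrt(vel / bc2) + self.eps)


def build_backbone(config: ModelConfig, seed: int = 0) -> BackboneModel:
    """Seeded, reproducible backbone construction."""
    return BackboneModel(config, seed=seed)


def build_calibrator(config: ModelConfig, seed: int = 0,
                     init: str = "identity") -> CalibratorModel:
    """Seeded calibrator; ``init`` is "identity" (pass-through) or "random"."""
    return CalibratorModel(config, seed=seed, init=init)


def forward(
    backbone: BackboneModel,
    calibrator: CalibratorModel | None,
    windows: np.ndarray,
):
    """Inference pass: (B, 8, 24) -> (class probabilities, bottleneck).

    Dropout is disabled; the calibrator (when given) is applied in front
    of the backbone.
    """
    x = np.asarray(windows, dtype=F32)
    if x.ndim == 2:
        x = x[None]
    x = x * F32(backbone.input_scale)
    if calibrator is not None:
        x, _ = calibrator.forward(x)
    probs, bott, _ = backbone.forward(x, train=False, prescaled=True)
    return probs, bott


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, backbone: BackboneModel,
                    calibrators: dict[str, CalibratorModel] | None = None) -> None:
    """Single-file archive of named parameter arrays plus the ModelConfig."""
    arrays = {f"backbone/{k}": v for k, v in backbone.params.items()}
    calibrators = calibrators or {}
    for sid, cal in calibrators.items():
        for k, v in cal.params.items():
            arrays[f"calibrator/{sid}/{k}"] = v
    meta = {
        "config": asdict(backbone.config),
        "input_scale": backbone.input_scale,
        "class_labels": backbone.class_labels,
        "calibrator_ids": sorted(calibrators),
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`."""
    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = ModelConfig(**meta["config"])
    backbone = BackboneModel(cfg, seed=0)
    for k in backbone.params:
        backbone.params[k] = data[f"backbone/{k}"]
    backbone.input_scale = float(meta["input_scale"])
    backbone.class_labels = list(meta["class_labels"])
    calibrators: dict[str, CalibratorModel] = {}
    for sid in meta["calibrator_ids"]:
        cal = CalibratorModel(cfg, seed=0, init="identity")
        for k in cal.params:
            cal.params[k] = data[f"calibrator/{sid}/{k}"]
        calibrators[sid] = cal
    return backbone, calibrators
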
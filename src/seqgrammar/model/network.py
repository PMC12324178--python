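"""The CNN-BiLSTM encoder network with explicit forward/backward passes.

Architecture: token embedding -> stack of same-padded Conv1D+ReLU layers ->
stack of bidirectional LSTM layers (masked recurrence, so padded positions
never influence real ones) -> time-distributed dense layer producing
per-base emission scores.  The softmax head turns emissions into per-base
label probabilities; the CRF head (see :mod:`seqgrammar.model.crf`) scores
whole label paths on top of the same emissions.

All parameters live in a flat ``name -> float32 array`` dict; ``forward``
returns emissions plus a cache, ``backward`` returns a matching gradient
dict.  Written against NumPy's BLAS-backed matmul; per-timestep work is
batched so the Python-level loop runs once per position, not per read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_layers`` is a tuple of (filters, kernel_size); ``lstm_layers`` a
    tuple of per-layer hidden units (per direction).  ``n_labels`` counts
    the pad class (id 0), the terminal-flank class and the layout elements.
    """

    n_labels: int
    embed_dim: int = 8
    conv_layers: tuple[tuple[int, int], ...] = ((48, 7),)
    lstm_layers: tuple[int, ...] = (32,)
    dropout: float = 0.1
    head: str = "softmax"  # or "crf"
    vocab_size: int = 6  # pad + ACGTN

    def __post_init__(self) -> None:
        if self.head not in ("softmax", "crf"):
            raise ValueError(f"unknown head {self.head!r}")
        if not self.conv_layers or not self.lstm_layers:
            raise ValueError("need at least one conv and one lstm layer")
        if self.n_labels < 2:
            raise ValueError("n_labels must cover pad plus real labels")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["conv_layers"] = tuple(tuple(x) for x in d["conv_layers"])
        d["lstm_layers"] = tuple(d["lstm_layers"])
        return cls(**d)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Network:
    """Trainable encoder: tokens -> per-base emission scores."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        p["embed"] = (0.1 * rng.standard_normal((config.vocab_size, config.embed_dim))).astype(
            np.float32
        )
        d_in = config.embed_dim
        for li, (filters, kernel) in enumerate(config.conv_layers):
            p[f"conv{li}_W"] = _glorot(rng, (kernel * d_in, filters))
            p[f"conv{li}_b"] = np.zeros(filters, dtype=np.float32)
            d_in = filters
        for li, units in enumerate(config.lstm_layers):
            for direction in ("f", "b"):
                p[f"lstm{li}{direction}_W"] = _glorot(rng, (d_in, 4 * units))
                p[f"lstm{li}{direction}_U"] = _glorot(rng, (units, 4 * units))
                b = np.zeros(4 * units, dtype=np.float32)
                b[units : 2 * units] = 1.0  # forget-gate bias
                p[f"lstm{li}{direction}_b"] = b
            d_in = 2 * units
        p["dense_W"] = _glorot(rng, (d_in, config.n_labels))
        p["dense_b"] = np.zeros(config.n_labels, dtype=np.float32)
        if config.head == "crf":
            p["crf_T"] = np.zeros((config.n_labels, config.n_labels), dtype=np.float32)
            p["crf_start"] = np.zeros(config.n_labels, dtype=np.float32)
            p["crf_end"] = np.zeros(config.n_labels, dtype=np.float32)
        self.params = p

    # ------------------------------------------------------------------ #

    def forward(
        self,
        tokens: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        need_cache: bool = True,
    ) -> tuple[np.ndarray, dict]:
        """Emissions (B, T, n_labels) plus the cache needed by backward.

        ``need_cache=False`` (inference) skips storing intermediates.
        """
        cfg = self.config
        p = self.params
        maskf = mask.astype(p["embed"].dtype)
        cache: dict = {"tokens": tokens, "maskf": maskf, "train": train, "drop": []}
        mask3 = maskf[:, :, None]
        x = p["embed"][tokens] * mask3  # (B, T, D); pads contribute exact zeros
        cache["embed_in"] = tokens
        cache["convs"] = []
        for li, (filters, kernel) in enumerate(cfg.conv_layers):
            x, c = self._conv_forward(
                x, p[f"conv{li}_W"], p[f"conv{li}_b"], kernel, need_cache
            )
            cache["convs"].append(c)
            x = self._dropout(x, cache, train, rng) * mask3
        cache["lstms"] = []
        for li, units in enumerate(cfg.lstm_layers):
            outs = []
            lcache = {}
            for direction in ("f", "b"):
                h, c = self._lstm_forward(
                    x,
                    p[f"lstm{li}{direction}_W"],
                    p[f"lstm{li}{direction}_U"],
                    p[f"lstm{li}{direction}_b"],
                    maskf,
                    reverse=(direction == "b"),
                    need_cache=need_cache,
                )
                outs.append(h)
                lcache[direction] = c
            lcache["input"] = x
            cache["lstms"].append(lcache)
            x = np.concatenate(outs, axis=2)
            x = self._dropout(x, cache, train, rng)
        cache["dense_in"] = x
        emissions = x @ p["dense_W"] + p["dense_b"]
        return emissions, cache

    def backward(self, cache: dict, d_emissions: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        grads: dict[str, np.ndarray] = {}
        x = cache["dense_in"]
        B, T, _ = x.shape
        grads["dense_W"] = x.reshape(B * T, -1).T @ d_emissions.reshape(B * T, -1)
        grads["dense_b"] = d_emissions.sum(axis=(0, 1))
        dx = d_emissions @ p["dense_W"].T
        drop_iter = iter(reversed(cache["drop"]))
        for li in reversed(range(len(cfg.lstm_layers))):
            dx = self._dropout_backward(dx, drop_iter)
            units = cfg.lstm_layers[li]
            lcache = cache["lstms"][li]
            dxf, dxb = dx[:, :, :units], dx[:, :, units:]
            d_in = np.zeros_like(lcache["input"])
            for direction, dh_out in (("f", dxf), ("b", dxb)):
                dW, dU, db, dxi = self._lstm_backward(
                    lcache[direction],
                    p[f"lstm{li}{direction}_U"],
                    p[f"lstm{li}{direction}_W"],
                    dh_out,
                    cache["maskf"],
                )
                grads[f"lstm{li}{direction}_W"] = dW
                grads[f"lstm{li}{direction}_U"] = dU
                grads[f"lstm{li}{direction}_b"] = db
                d_in += dxi
            dx = d_in
        mask3 = cache["maskf"][:, :, None]
        for li in reversed(range(len(cfg.conv_layers))):
            dx = self._dropout_backward(dx * mask3, drop_iter)
            filters, kernel = cfg.conv_layers[li]
            dW, db, dx = self._conv_backward(
                cache["convs"][li], p[f"conv{li}_W"], kernel, dx
            )
            grads[f"conv{li}_W"] = dW
            grads[f"conv{li}_b"] = db
        dembed = np.zeros_like(p["embed"])
        np.add.at(dembed, cache["embed_in"], dx * mask3)
        grads["embed"] = dembed
        return grads

    # ------------------------------------------------------------------ #

    def _dropout(self, x, cache, train, rng):
        rate = self.config.dropout
        if not train or rate <= 0.0:
            cache["drop"].append(None)
            return x
        if rng is None:
            rng = np.random.default_rng()
        keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)
        cache["drop"].append(keep)
        return x * keep

    @staticmethod
    def _dropout_backward(dx, drop_iter):
        keep = next(drop_iter)
        return dx if keep is None else dx * keep

    @staticmethod
    def _conv_forward(x, W, b, kernel, need_cache=True):
        B, T, D = x.shape
        pad = kernel // 2
        xp = np.zeros((B, T + kernel - 1, D), dtype=x.dtype)
        xp[:, pad : pad + T] = x
        cols = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
        # cols: (B, T, D, kernel) -> (B*T, kernel*D)
        cols = cols.transpose(0, 1, 3, 2).reshape(B * T, kernel * D)
        pre = cols @ W + b
        out = np.maximum(pre, 0.0)
        if not need_cache:
            return out.reshape(B, T, -1), None
        return out.reshape(B, T, -1), {"cols": cols, "relu": pre > 0, "shape": (B, T, D)}

    @staticmethod
    def _conv_backward(cache, W, kernel, dy):
        B, T, D = cache["shape"]
        F = W.shape[1]
        dpre = dy.reshape(B * T, F) * cache["relu"]
        dW = cache["cols"].T @ dpre
        db = dpre.sum(axis=0)
        dcols = (dpre @ W.T).reshape(B, T, kernel, D)
        pad = kernel // 2
        dxp = np.zeros((B, T + kernel - 1, D), dtype=dy.dtype)
        for j in range(kernel):
            dxp[:, j : j + T] += dcols[:, :, j]
        return dW, db, dxp[:, pad : pad + T]

    @staticmethod
    def _lstm_forward(x, W, U, b, maskf, reverse, need_cache=True):
        # Time-major (T, B, .) storage so every per-timestep slice is a
        # contiguous block; gate layout in z is [i | f | o | g] so one
        # (vectorized) sigmoid covers a contiguous (B, 3H) block.
        B, T, D = x.shape
        H = U.shape[0]
        gates = np.ascontiguousarray(
            ((x.reshape(B * T, D) @ W + b).reshape(B, T, 4 * H)).transpose(1, 0, 2)
        )
        dt = x.dtype
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        zbuf = np.empty((B, 4 * H), dtype=dt)
        if need_cache:
            tanh_c = np.empty((T, B, H), dtype=dt)
            c_prev = np.empty((T, B, H), dtype=dt)
            h_prev = np.empty((T, B, H), dtype=dt)
        out = np.empty((T, B, H), dtype=dt)
        mask_t = np.ascontiguousarray(maskf.T)
        steps = range(T - 1, -1, -1) if reverse else range(T)
        fully_real = bool(maskf.all())
        for t in steps:
            z = gates[t]
            np.matmul(h, U, out=zbuf)
            z += zbuf
            zs = z[:, : 3 * H]
            np.negative(zs, out=zs)
            np.exp(zs, out=zs)
            zs += 1.0
            np.reciprocal(zs, out=zs)  # sigmoid(i,f,o) in place
            g = np.tanh(z[:, 3 * H :], out=z[:, 3 * H :])
            i = z[:, :H]
            f = z[:, H : 2 * H]
            o = z[:, 2 * H : 3 * H]
            if need_cache:
                c_prev[t] = c
                h_prev[t] = h
            c_new = f * c
            c_new += i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if fully_real:
                h, c = h_new, c_new
            else:
                m = mask_t[t, :, None]
                h = m * h_new + (1.0 - m) * h
                c = m * c_new + (1.0 - m) * c
            if need_cache:
                tanh_c[t] = tc
            out[t] = h
        out_bt = np.ascontiguousarray(out.transpose(1, 0, 2))
        if not need_cache:
            return out_bt, None
        cache = {
            "x": x,
            "gates": gates,
            "tanh_c": tanh_c,
            "c_prev": c_prev,
            "h_prev": h_prev,
            "mask_t": mask_t,
            "reverse": reverse,
        }
        return out_bt, cache

    @staticmethod
    def _lstm_backward(cache, U, W, dh_out, maskf):
        from seqgrammar.model._recurrence import lstm_backward_kernel

        x = cache["x"]
        B, T, D = x.shape
        H = U.shape[0]
        dh_out_t = np.ascontiguousarray(dh_out.transpose(1, 0, 2))
        dxp, dU = lstm_backward_kernel(
            cache["gates"],
            cache["tanh_c"],
            cache["c_prev"],
            cache["h_prev"],
            U,
            cache["mask_t"],
            dh_out_t,
            cache["reverse"],
        )
        dxp_bt = np.ascontiguousarray(dxp.transpose(1, 0, 2)).reshape(B * T, 4 * H)
        dW = x.reshape(B * T, D).T @ dxp_bt
        db = dxp_bt.sum(axis=0)
        dx = (dxp_bt @ W.T).reshape(B, T, D)
        return dW, dU, db, dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax_cross_entropy(
    emissions: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Masked per-token cross-entropy.

    Returns (mean loss over real positions, d_emissions, probabilities).
    Padded positions contribute nothing to loss or gradient.
    """
    m = emissions.max(axis=2, keepdims=True)
    ex = np.exp(emissions - m)
    probs = ex / ex.sum(axis=2, keepdims=True)
    n_real = int(mask.sum())
    B, T, L = emissions.shape
    idx_b, idx_t = np.nonzero(mask)
    gold = labels[idx_b, idx_t]
    logp = np.log(probs[idx_b, idx_t, gold] + 1e-12)
    loss = float(-logp.sum() / max(n_real, 1))
    d = probs.copy()
    d[idx_b, idx_t, gold] -= 1.0
    d *= mask[:, :, None] / max(n_real, 1)
    return loss, d, probs
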
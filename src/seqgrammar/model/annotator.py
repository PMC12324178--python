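"""High-level trainable annotator: fit on labeled reads, predict label paths."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from seqgrammar.model.encoding import encode_sequence, pad_batch
from seqgrammar.model.network import ModelConfig, Network, softmax_cross_entropy
from seqgrammar.model.crf import crf_nll, crf_decode


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam).

    ``batch_tokens`` bounds batch memory as batch_size x max_len; reads are
    length-sorted first so padding waste stays small.  ``loss`` is derived
    from the model head when left as ``auto``.
    """

    learning_rate: float = 3e-3
    lr_decay: float = 1.0  # multiplicative per-epoch decay
    epochs: int = 2
    batch_tokens: int = 65536
    batch_size: int | None = None
    seed: int = 0
    clip_norm: float = 5.0
    loss: str = "auto"  # categorical_cross_entropy | crf_negative_log_likelihood


class SequenceAnnotator:
    """Per-base structural labeler over a fixed label schema.

    Wraps the CNN-BiLSTM :class:`Network` with either a softmax head
    (per-base probabilities; confidences available) or a CRF head
    (joint path decoding via Viterbi).
    """

    def __init__(self, config: ModelConfig, label_schema: Sequence[str], seed: int = 0):
        if config.n_labels != len(label_schema):
            raise ValueError(
                f"n_labels={config.n_labels} != schema size {len(label_schema)}"
            )
        self.config = config
        self.label_schema = tuple(label_schema)
        self.net = Network(config, seed=seed)
        self.history: list[dict] = []

    # ------------------------------------------------------------------ #

    def fit(self, reads: Sequence, train_config: TrainConfig | None = None) -> list[dict]:
        """Train on labeled reads; returns per-epoch loss/accuracy history.

        ``reads`` holds objects with ``sequence`` and per-base ``labels``
        attributes (e.g. :class:`~seqgrammar.simulate.SimulatedRead`) or
        ``(tokens, labels)`` array pairs.
        """
        tcfg = train_config or TrainConfig()
        expected = (
            "crf_negative_log_likelihood"
            if self.config.head == "crf"
            else "categorical_cross_entropy"
        )
        if tcfg.loss not in ("auto", expected):
            raise ValueError(f"loss {tcfg.loss!r} inconsistent with {self.config.head} head")
        data = [self._coerce(r) for r in reads]
        for tokens, labels in data:
            if labels.max(initial=0) >= self.config.n_labels:
                raise ValueError("label id out of range for model schema")
        data.sort(key=lambda d: len(d[0]))
        batches = self._make_batches(data, tcfg)
        rng = np.random.default_rng(tcfg.seed)
        opt = _Adam(self.net.params, tcfg.learning_rate)
        for epoch in range(tcfg.epochs):
            opt.lr = tcfg.learning_rate * tcfg.lr_decay**epoch
            order = rng.permutation(len(batches))
            tot_loss = tot_correct = tot_tokens = 0.0
            for bi in order:
                toks, labs = batches[bi]
                batch = pad_batch(toks)
                labels = np.zeros_like(batch.tokens)
                for i, l in enumerate(labs):
                    labels[i, : len(l)] = l
                loss, n_tok, n_corr = self._train_step(batch, labels, opt, rng, tcfg)
                tot_loss += loss * n_tok
                tot_tokens += n_tok
                tot_correct += n_corr
            self.history.append(
                {
                    "epoch": len(self.history),
                    "loss": tot_loss / max(tot_tokens, 1),
                    "accuracy": tot_correct / max(tot_tokens, 1),
                }
            )
        return self.history

    def _train_step(self, batch, labels, opt, rng, tcfg):
        emissions, cache = self.net.forward(
            batch.tokens, batch.mask, train=True, rng=rng
        )
        n_tok = int(batch.mask.sum())
        if self.config.head == "softmax":
            loss, d_em, probs = softmax_cross_entropy(emissions, labels, batch.mask)
            pred = probs.argmax(axis=2)
        else:
            p = self.net.params
            loss, head_grads = crf_nll(
                emissions, p["crf_T"], p["crf_start"], p["crf_end"],
                labels, batch.lengths,
            )
            d_em = head_grads["emissions"]
            pred = emissions.argmax(axis=2)  # proxy accuracy; decoding is Viterbi
        n_corr = int(((pred == labels) & batch.mask).sum())
        grads = self.net.backward(cache, d_em)
        if self.config.head == "crf":
            grads["crf_T"] = head_grads["crf_T"]
            grads["crf_start"] = head_grads["crf_start"]
            grads["crf_end"] = head_grads["crf_end"]
        _clip_global_norm(grads, tcfg.clip_norm)
        opt.step(grads)
        return loss, n_tok, n_corr

    @staticmethod
    def _coerce(r) -> tuple[np.ndarray, np.ndarray]:
        if hasattr(r, "sequence"):
            return encode_sequence(r.sequence), np.asarray(r.labels, dtype=np.int64)
        tokens, labels = r
        return np.asarray(tokens), np.asarray(labels, dtype=np.int64)

    @staticmethod
    def _make_batches(data, tcfg: TrainConfig):
        # data is length-sorted; bound the padded batch area
        # (batch_size x longest member) by batch_tokens
        batches = []
        i = 0
        while i < len(data):
            if tcfg.batch_size is not None:
                n = tcfg.batch_size
            else:
                n = _greedy_batch_size(
                    [len(t) for t, _ in data[i:]], tcfg.batch_tokens
                )
            chunk = data[i : i + n]
            batches.append(([t for t, _ in chunk], [l for _, l in chunk]))
            i += n
        return batches

    # ------------------------------------------------------------------ #

    def predict(
        self,
        sequences: Sequence[str],
        token_budget: int = 300_000,
    ) -> list[tuple[np.ndarray, np.ndarray | None]]:
        """Label every base of each read.

        Returns, per input read, ``(label_ids, confidence)`` where
        confidence is the per-base max softmax probability (``None`` for the
        CRF head, which decodes jointly).  Batch size follows the dynamic
        scaling rule ``max(1, token_budget // mean_length)``; results are
        exactly independent of the batching because the recurrence is
        masked.
        """
        if len(sequences) == 0:
            return []
        encoded = [encode_sequence(s) for s in sequences]
        lengths = [len(e) for e in encoded]
        order = np.argsort(lengths, kind="stable")
        out: list = [None] * len(sequences)
        i = 0
        while i < len(order):
            bsz = _greedy_batch_size([lengths[j] for j in order[i:]], token_budget)
            idx = order[i : i + bsz]
            i += bsz
            batch = pad_batch([encoded[j] for j in idx])
            emissions, _ = self.net.forward(
                batch.tokens, batch.mask, train=False, need_cache=False
            )
            if self.config.head == "softmax":
                m = emissions.max(axis=2, keepdims=True)
                ex = np.exp(emissions - m)
                probs = ex / ex.sum(axis=2, keepdims=True)
                pred = probs.argmax(axis=2)
                conf = probs.max(axis=2)
                for row, j in enumerate(idx):
                    n = batch.lengths[row]
                    out[j] = (pred[row, :n].astype(np.int64), conf[row, :n].copy())
            else:
                p = self.net.params
                paths = crf_decode(
                    emissions, p["crf_T"], p["crf_start"], p["crf_end"], batch.lengths
                )
                for row, j in enumerate(idx):
                    out[j] = (paths[row], None)
        return out

    def warm_start_from(self, other: "SequenceAnnotator") -> None:
        """Copy shared encoder weights from a trained sibling model.

        Used by the hybrid recipe: the CRF variant starts from the fast
        softmax model's encoder and only needs a short fine-tuning pass to
        learn its transition parameters.
        """
        for k, v in other.net.params.items():
            if k in self.net.params and self.net.params[k].shape == v.shape:
                self.net.params[k] = v.copy()

    # ------------------------------------------------------------------ #

    def save(self, directory: str | Path) -> None:
        """Checkpoint: weights + architecture + label binarizer."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.net.params)
        (d / "config.json").write_text(self.config.to_json())
        (d / "labels.json").write_text(json.dumps(list(self.label_schema)))

    @classmethod
    def load(cls, directory: str | Path) -> "SequenceAnnotator":
        d = Path(directory)
        config = ModelConfig.from_json((d / "config.json").read_text())
        schema = json.loads((d / "labels.json").read_text())
        obj = cls(config, schema)
        with np.load(d / "weights.npz") as z:
            obj.net.params = {k: z[k] for k in z.files}
        return obj


def predict_labels(
    annotator: SequenceAnnotator,
    store,
    chunk_size: int = 300_000,
    token_budget: int = 300_000,
) -> dict[str, tuple[np.ndarray, np.ndarray | None]]:
    """Annotate every read of a :class:`~seqgrammar.preprocess.BinStore`.

    Reads are pulled bin by bin in chunks of ``chunk_size`` reads; inference
    batch size inside a chunk follows the dynamic token-budget rule.
    """
    results: dict[str, tuple[np.ndarray, np.ndarray | None]] = {}
    for bin_id in store.bin_ids():
        table = store.read_bin(bin_id)
        ids, seqs = table["read_id"], table["sequence"]
        for i in range(0, len(ids), chunk_size):
            chunk = list(seqs[i : i + chunk_size])
            preds = annotator.predict(chunk, token_budget=token_budget)
            for rid, pred in zip(ids[i : i + chunk_size], preds):
                results[rid] = pred
    return results


def _greedy_batch_size(sorted_lengths: Sequence[int], token_budget: int) -> int:
    """Largest n with n * sorted_lengths[n-1] <= token_budget (min 1)."""
    n = 1
    while n < len(sorted_lengths) and (n + 1) * sorted_lengths[n] <= token_budget:
        n += 1
    return n


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.astype(self.params[k].dtype)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_global_norm(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale
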
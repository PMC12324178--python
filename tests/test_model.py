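import itertools

import numpy as np
import pytest

import seqgrammar as sg
from seqgrammar.model import (
    ModelConfig,
    Network,
    SequenceAnnotator,
    TrainConfig,
    crf_decode,
    crf_nll,
    encode_sequence,
    pad_batch,
)
from seqgrammar.model.encoding import EncodingError
from seqgrammar.model.network import softmax_cross_entropy
from seqgrammar.simulate import simulate_reads


def toy_config(head="softmax", n_labels=5, dropout=0.0):
    return ModelConfig(
        n_labels=n_labels,
        embed_dim=3,
        conv_layers=((4, 3),),
        lstm_layers=(3,),
        dropout=dropout,
        head=head,
    )


def random_batch(rng, B=3, T=7, n_labels=5):
    lengths = np.sort(rng.integers(2, T + 1, size=B))[::-1]
    lengths[0] = T
    mask = np.arange(T)[None, :] < lengths[:, None]
    tokens = rng.integers(1, 6, size=(B, T)) * mask
    labels = rng.integers(1, n_labels, size=(B, T)) * mask
    return tokens, labels, mask, lengths


# ---------------------------------------------------------------- encoding


def test_encode_sequence_mapping():
    assert encode_sequence("ACGTN").tolist() == [1, 2, 3, 4, 5]
    assert encode_sequence("").tolist() == []
    assert encode_sequence("acgt").tolist() == [1, 2, 3, 4]
    with pytest.raises(EncodingError, match="position 2"):
        encode_sequence("ACXGT")


def test_pad_batch_round_trip():
    rng = np.random.default_rng(0)
    seqs = [rng.integers(1, 6, size=n) for n in rng.integers(1, 40, size=64)]
    batch = pad_batch(seqs)
    assert batch.tokens.shape[1] == max(len(s) for s in seqs)
    assert ((batch.tokens == 0) == ~batch.mask).all()
    for orig, rec in zip(seqs, batch.unpad()):
        assert np.array_equal(orig, rec)
    with pytest.raises(ValueError):
        pad_batch([])


def test_pad_batch_no_padding_when_equal_lengths():
    batch = pad_batch([np.ones(5, dtype=int)] * 3)
    assert batch.mask.all()


# ---------------------------------------------------------------- network


def test_output_shape_and_softmax_normalization():
    rng = np.random.default_rng(1)
    net = Network(toy_config(), seed=0)
    tokens, labels, mask, _ = random_batch(rng, B=4, T=9)
    em, _ = net.forward(tokens, mask)
    assert em.shape == (4, 9, 5)
    _, _, probs = softmax_cross_entropy(em, labels, mask)
    assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-5)


@pytest.mark.parametrize("head", ["softmax", "crf"])
def test_gradients_match_finite_differences(head):
    """Analytic backward equals central finite differences (float64)."""
    rng = np.random.default_rng(0)
    net = Network(toy_config(head), seed=1)
    for k in net.params:
        net.params[k] = net.params[k].astype(np.float64)
    tokens, labels, mask, lengths = random_batch(rng)

    def loss_fn():
        em, cache = net.forward(tokens, mask)
        if head == "softmax":
            loss, d_em, _ = softmax_cross_entropy(em, labels, mask)
            return loss, d_em, None, cache
        p = net.params
        loss, g = crf_nll(em, p["crf_T"], p["crf_start"], p["crf_end"], labels, lengths)
        return loss, g["emissions"], g, cache

    loss, d_em, head_grads, cache = loss_fn()
    grads = net.backward(cache, d_em)
    if head_grads:
        grads.update({k: head_grads[k] for k in ("crf_T", "crf_start", "crf_end")})
    eps = 1e-6
    for k, p in net.params.items():
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss_fn()[0]
            p[idx] = orig - eps
            lm = loss_fn()[0]
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - grads[k][idx]) <= 1e-3 * max(1.0, abs(num)), k


def test_padding_does_not_change_loss():
    """Extending every read with extra pad columns leaves the loss intact."""
    rng = np.random.default_rng(3)
    tokens, labels, mask, lengths = random_batch(rng, B=4, T=6)
    for head in ("softmax", "crf"):
        net = Network(toy_config(head), seed=2)
        pad = np.zeros((4, 5), dtype=tokens.dtype)
        tokens2 = np.hstack([tokens, pad])
        labels2 = np.hstack([labels, pad])
        mask2 = np.hstack([mask, pad.astype(bool)])
        em1, _ = net.forward(tokens, mask)
        em2, _ = net.forward(tokens2, mask2)
        if head == "softmax":
            l1 = softmax_cross_entropy(em1, labels, mask)[0]
            l2 = softmax_cross_entropy(em2, labels2, mask2)[0]
        else:
            p = net.params
            l1 = crf_nll(em1, p["crf_T"], p["crf_start"], p["crf_end"], labels, lengths)[0]
            l2 = crf_nll(em2, p["crf_T"], p["crf_start"], p["crf_end"], labels2, lengths)[0]
        assert np.isclose(l1, l2, rtol=1e-5)


# ---------------------------------------------------------------- CRF


def test_viterbi_equals_exhaustive_enumeration():
    rng = np.random.default_rng(2)
    for _ in range(25):
        L = int(rng.integers(2, 5))
        T = int(rng.integers(1, 9))
        em = rng.standard_normal((1, T, L))
        tr = rng.standard_normal((L, L))
        st, en = rng.standard_normal(L), rng.standard_normal(L)
        got = tuple(crf_decode(em, tr, st, en, np.array([T]))[0])
        best, best_score = None, -np.inf
        for y in itertools.product(range(L), repeat=T):
            s = st[y[0]] + en[y[-1]] + sum(em[0, t, y[t]] for t in range(T))
            s += sum(tr[y[t - 1], y[t]] for t in range(1, T))
            if s > best_score:
                best_score, best = s, y
        assert got == best


def test_viterbi_respects_forbidden_transition():
    rng = np.random.default_rng(4)
    tr = np.zeros((2, 2))
    tr[1, 0] = -1e6  # forbid B -> A
    em = rng.standard_normal((8, 8, 2))
    for path in crf_decode(em, tr, np.zeros(2), np.zeros(2), np.full(8, 8)):
        s = "".join("AB"[i] for i in path)
        assert "BA" not in s


def test_crf_nll_decreases_partition_consistency():
    """NLL of the best path is bounded below by 0 and finite."""
    rng = np.random.default_rng(5)
    em = rng.standard_normal((2, 6, 3))
    tr = rng.standard_normal((3, 3))
    st, en = rng.standard_normal(3), rng.standard_normal(3)
    lengths = np.array([6, 4])
    labels = rng.integers(0, 3, size=(2, 6))
    loss, grads = crf_nll(em, tr, st, en, labels, lengths)
    assert np.isfinite(loss) and loss > 0
    assert grads["emissions"].shape == em.shape
    # marginal-minus-onehot gradients sum to ~0 per token row
    assert np.allclose(grads["emissions"][0].sum(axis=1), 0.0, atol=1e-8)


# ---------------------------------------------------------------- training


@pytest.fixture(scope="module")
def tiny_reads(layout, whitelist):
    cfg = sg.SimulationConfig(
        layout=layout,
        n_reads=40,
        whitelist=whitelist,
        seed=44,
        error_rates=sg.ErrorRates.zero(),
        insert_length_range=(30, 60),
        flank_length_range=(0, 10),
    )
    return simulate_reads(cfg)


def test_history_bookkeeping(layout, tiny_reads):
    schema = layout.label_schema
    model = SequenceAnnotator(toy_config(n_labels=len(schema)), schema, seed=0)
    hist = model.fit(tiny_reads[:10], TrainConfig(epochs=1, seed=0))
    assert len(hist) == 1
    assert set(hist[0]) == {"epoch", "loss", "accuracy"}


def test_learnability_on_error_free_reads(layout, tiny_reads):
    """A small model reaches >0.99 per-base training accuracy on clean reads."""
    schema = layout.label_schema
    cfg = ModelConfig(
        n_labels=len(schema), embed_dim=8, conv_layers=((24, 5),),
        lstm_layers=(24,), dropout=0.0,
    )
    model = SequenceAnnotator(cfg, schema, seed=0)
    model.fit(
        tiny_reads,
        TrainConfig(
            epochs=60, learning_rate=0.01, lr_decay=0.96, seed=0, batch_tokens=1024
        ),
    )
    preds = model.predict([r.sequence for r in tiny_reads])
    acc = np.mean(
        np.concatenate([lab == r.labels for r, (lab, _) in zip(tiny_reads, preds)])
    )
    assert acc > 0.99


def test_same_seed_training_is_deterministic(layout, tiny_reads):
    schema = layout.label_schema
    losses = []
    for _ in range(2):
        model = SequenceAnnotator(toy_config(n_labels=len(schema)), schema, seed=3)
        hist = model.fit(tiny_reads[:20], TrainConfig(epochs=2, seed=7))
        losses.append(hist[-1]["loss"])
    assert losses[0] == losses[1]


def test_label_out_of_range_rejected(layout):
    schema = layout.label_schema
    model = SequenceAnnotator(toy_config(n_labels=len(schema)), schema, seed=0)
    bad = [(np.array([1, 2, 3]), np.array([1, 2, 99]))]
    with pytest.raises(ValueError, match="label id"):
        model.fit(bad, TrainConfig(epochs=1))


def test_loss_head_consistency_enforced(layout):
    schema = layout.label_schema
    model = SequenceAnnotator(toy_config(n_labels=len(schema)), schema, seed=0)
    with pytest.raises(ValueError, match="inconsistent"):
        model.fit([], TrainConfig(loss="crf_negative_log_likelihood"))


# ---------------------------------------------------------------- predict


@pytest.mark.parametrize("head", ["softmax", "crf"])
def test_prediction_invariant_to_batching(layout, tiny_reads, head):
    schema = layout.label_schema
    model = SequenceAnnotator(toy_config(head, n_labels=len(schema)), schema, seed=1)
    seqs = [r.sequence for r in tiny_reads[:30]]
    one_by_one = model.predict(seqs, token_budget=1)  # forces batch size 1
    big = model.predict(seqs, token_budget=300_000)
    for (l1, c1), (l2, c2) in zip(one_by_one, big):
        assert np.array_equal(l1, l2)
        if c1 is not None:
            assert np.allclose(c1, c2, atol=1e-5)
    assert all(len(l) == len(s) for (l, _), s in zip(big, seqs))


def test_checkpoint_round_trip(tmp_path, layout, tiny_reads):
    schema = layout.label_schema
    model = SequenceAnnotator(toy_config(n_labels=len(schema)), schema, seed=2)
    model.fit(tiny_reads[:10], TrainConfig(epochs=1, seed=0))
    model.save(tmp_path / "ckpt")
    clone = SequenceAnnotator.load(tmp_path / "ckpt")
    assert clone.label_schema == model.label_schema
    seqs = [r.sequence for r in tiny_reads[:5]]
    for (l1, _), (l2, _) in zip(model.predict(seqs), clone.predict(seqs)):
        assert np.array_equal(l1, l2)
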
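"""Linear-chain CRF head: negative log-likelihood and Viterbi decoding.

The CRF scores a label path y for a read of length n as

    score(y) = start[y_1] + sum_t em[t, y_t] + sum_t T[y_{t-1}, y_t] + end[y_n]

where ``em`` are the encoder's per-base emission scores and ``T`` the
learned label-transition matrix.  Training minimises the negative
log-likelihood ``logZ - score(gold)``; gradients come from forward-backward
marginals.  Decoding returns the maximum-scoring path (Viterbi).
"""

from __future__ import annotations

import numpy as np


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore"):  # -inf rows (inactive sequences) stay -inf
        out = m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))
    return np.where(np.isnan(out), -np.inf, out).squeeze(axis)


def crf_nll(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    labels: np.ndarray,
    lengths: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean per-token CRF negative log-likelihood and its gradients.

    Returns ``(loss, grads)`` with grads keyed ``emissions``, ``crf_T``,
    ``crf_start``, ``crf_end``.  Positions at or beyond each read's length
    are ignored entirely.
    """
    em = emissions.astype(np.float64)
    T_mat = transitions.astype(np.float64)
    B, T, L = em.shape
    lengths = np.asarray(lengths)
    n_tokens = int(lengths.sum())
    norm = 1.0 / max(n_tokens, 1)

    # forward pass (alphas)
    alphas = np.empty((B, T, L))
    alphas[:, 0] = start + em[:, 0]
    for t in range(1, T):
        prev = alphas[:, t - 1]
        a = _logsumexp(prev[:, :, None] + T_mat[None], axis=1) + em[:, t]
        active = (t < lengths)[:, None]
        alphas[:, t] = np.where(active, a, prev)
    last = alphas[np.arange(B), lengths - 1]
    logZ = _logsumexp(last + end, axis=1)

    # gold path score
    bidx = np.arange(B)
    gold_em = np.zeros(B)
    gold_tr = np.zeros(B)
    for t in range(T):
        active = t < lengths
        gold_em[active] += em[bidx[active], t, labels[active, t]]
        if t >= 1:
            act = t < lengths
            gold_tr[act] += T_mat[labels[act, t - 1], labels[act, t]]
    gold = start[labels[:, 0]] + gold_em + gold_tr + end[labels[bidx, lengths - 1]]
    loss = float(((logZ - gold) * norm).sum())

    # backward recursion (betas), stored for vectorized gradient assembly
    betas = np.empty((B, T, L))
    beta = np.full((B, L), -np.inf)
    for t in range(T - 1, -1, -1):
        is_last = lengths - 1 == t
        if is_last.any():
            beta[is_last] = end
        betas[:, t] = beta
        if t > 0:
            active = t < lengths
            nb = _logsumexp(T_mat[None] + (em[:, t] + beta)[:, None, :], axis=2)
            beta = np.where(active[:, None], nb, beta)

    active_bt = np.arange(T)[None, :] < lengths[:, None]  # (B, T)
    # token marginals
    marg = np.exp(alphas + betas - logZ[:, None, None])
    marg[~active_bt] = 0.0
    d_em = marg.copy()
    d_em[bidx[:, None], np.arange(T)[None, :], labels] -= active_bt

    # pairwise marginals: xi_t(i,j) = exp(alpha_{t-1,i}) T'(i,j) exp(em_t+beta_t,j)
    # factorizes, so the sum over (b, t) is a single matmul after per-(b,t)
    # max-shifting for numerical safety
    pair_active = active_bt[:, 1:]  # positions t >= 1 with a predecessor
    a_prev = alphas[:, :-1]
    q_next = em[:, 1:] + betas[:, 1:]
    u = a_prev.max(axis=2)
    v = q_next.max(axis=2)
    v = np.where(np.isfinite(v), v, 0.0)  # inactive positions: beta is -inf
    P = np.exp(a_prev - u[:, :, None])
    with np.errstate(invalid="ignore"):
        Q = np.exp(q_next - v[:, :, None])
    Q = np.nan_to_num(Q, nan=0.0, posinf=0.0)
    scale = np.exp(u + v - logZ[:, None])
    scale[~pair_active] = 0.0
    Q *= scale[:, :, None]
    N = B * (T - 1)
    d_T = np.exp(T_mat) * (P.reshape(N, L).T @ Q.reshape(N, L))
    np.subtract.at(
        d_T,
        (labels[:, :-1][pair_active], labels[:, 1:][pair_active]),
        1.0,
    )
    d_start = marg[:, 0].sum(axis=0)
    np.subtract.at(d_start, labels[:, 0], 1.0)
    marg_last = np.exp(last + end - logZ[:, None])
    d_end = marg_last.sum(axis=0)
    np.subtract.at(d_end, labels[bidx, lengths - 1], 1.0)

    grads = {
        "emissions": (d_em * norm).astype(emissions.dtype),
        "crf_T": (d_T * norm).astype(transitions.dtype),
        "crf_start": (d_start * norm).astype(start.dtype),
        "crf_end": (d_end * norm).astype(end.dtype),
    }
    return loss, grads


def crf_decode(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    lengths: np.ndarray,
) -> list[np.ndarray]:
    """Maximum-scoring label path per read (Viterbi)."""
    em = emissions.astype(np.float64)
    T_mat = transitions.astype(np.float64)
    B, T, L = em.shape
    lengths = np.asarray(lengths)
    delta = start + em[:, 0]
    back = np.zeros((B, T, L), dtype=np.int16)
    deltas = np.empty((B, T, L))
    deltas[:, 0] = delta
    for t in range(1, T):
        scores = deltas[:, t - 1][:, :, None] + T_mat[None]
        back[:, t] = scores.argmax(axis=1)
        best = np.take_along_axis(scores, back[:, t][:, None, :], axis=1).squeeze(1)
        nd = best + em[:, t]
        active = (t < lengths)[:, None]
        deltas[:, t] = np.where(active, nd, deltas[:, t - 1])
    paths: list[np.ndarray] = []
    for b in range(B):
        n = int(lengths[b])
        final = deltas[b, n - 1] + end
        y = np.empty(n, dtype=np.int64)
        y[-1] = int(final.argmax())
        for t in range(n - 1, 0, -1):
            y[t - 1] = back[b, t, y[t]]
        paths.append(y)
    return paths
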
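"""Numba kernels for skip-gram negative sampling and frozen-output
paragraph-vector (PV-DBOW) training.

Single-threaded by design: determinism for a given seed is part of the
module contract, so no hogwild parallelism.  Randomness comes from an
explicit splitmix64 stream carried through the loops.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=True, inline="always")
def _next_u64(state):
    state = state + _SPLITMIX_GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=True, inline="always")
def _next_uniform(state):
    state, z = _next_u64(state)
    return state, (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _sample_cum(cum, u):
    """Index i with cum[i-1] <= u < cum[i] by binary search."""
    lo, hi = 0, len(cum) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[mid] <= u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x > 12.0:
        return 1.0
    if x < -12.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def sgns_train(data, offsets, w_in, w_out, cum, window, negatives, lr0, lr_min, epochs, seed):
    """Skip-gram with negative sampling over pre-indexed sentences.

    data: int32 token ids, concatenated sentences; offsets: int64 sentence
    boundaries; w_in/w_out: (n, k) float32, updated in place; cum: cumulative
    noise distribution (unigram^0.75).  Linear learning-rate decay lr0 ->
    lr_min over all epochs; per-position dynamic window in 1..window.
    """
    k = w_in.shape[1]
    state = np.uint64(seed) * np.uint64(2654435761) + np.uint64(0x1234ABCD)
    total = np.float64(epochs) * len(data)
    done = 0.0
    grad = np.empty(k, dtype=np.float32)
    for _ep in range(epochs):
        for s in range(len(offsets) - 1):
            start, end = offsets[s], offsets[s + 1]
            for i in range(start, end):
                lr = lr0 * (1.0 - done / total)
                if lr < lr_min:
                    lr = lr_min
                done += 1.0
                center = data[i]
                state, z = _next_u64(state)
                b = 1 + np.int64(z % np.uint64(window))
                lo = i - b
                if lo < start:
                    lo = start
                hi = i + b + 1
                if hi > end:
                    hi = end
                for j in range(lo, hi):
                    if j == i:
                        continue
                    target = data[j]
                    for q in range(k):
                        grad[q] = 0.0
                    for neg in range(negatives + 1):
                        if neg == 0:
                            out = target
                            label = 1.0
                        else:
                            state, u = _next_uniform(state)
                            out = _sample_cum(cum, u)
                            if out == target:
                                continue
                            label = 0.0
                        dot = 0.0
                        for q in range(k):
                            dot += w_in[center, q] * w_out[out, q]
                        g = (label - _sigmoid(dot)) * lr
                        for q in range(k):
                            grad[q] += g * w_out[out, q]
                            w_out[out, q] += g * w_in[center, q]
                    for q in range(k):
                        w_in[center, q] += grad[q]


@njit(cache=True)
def dbow_fit_docs(data, offsets, w_out, d_mat, cum, negatives, lr0, lr_min, epochs, seed):
    """Frozen-output PV-DBOW: optimise each document vector to predict its
    own tokens against negative-sampled noise; w_out never changes.

    Each document is fitted independently from its own seeded stream, so
    training documents and unseen documents go through the identical
    procedure.  d_mat rows are updated in place.
    """
    k = w_out.shape[1]
    m = len(offsets) - 1
    for s in range(m):
        start, end = offsets[s], offsets[s + 1]
        if end <= start:
            continue  # degenerate: no in-vocabulary tokens, row left at zero
        # pass the raw (seed, doc) state through the mixer once so that
        # consecutive documents get decorrelated streams — raw splitmix
        # states that differ by one gamma produce shifted copies of the
        # same sequence, which would correlate neighbouring documents
        state = (np.uint64(seed) + np.uint64(s)) * np.uint64(0x9E3779B97F4A7C15) + np.uint64(7)
        state, z = _next_u64(state)
        state = z
        # small deterministic random init, scale 0.5/k as in word2vec
        for q in range(k):
            state, u = _next_uniform(state)
            d_mat[s, q] = np.float32((u - 0.5) / k)
        total = np.float64(epochs) * (end - start)
        done = 0.0
        for _ep in range(epochs):
            for i in range(start, end):
                lr = lr0 * (1.0 - done / total)
                if lr < lr_min:
                    lr = lr_min
                done += 1.0
                target = data[i]
                for neg in range(negatives + 1):
                    if neg == 0:
                        out = target
                        label = 1.0
                    else:
                        state, u = _next_uniform(state)
                        out = _sample_cum(cum, u)
                        if out == target:
                            continue
                        label = 0.0
                    dot = 0.0
                    for q in range(k):
                        dot += d_mat[s, q] * w_out[out, q]
                    g = (label - _sigmoid(dot)) * lr
                    for q in range(k):
                        d_mat[s, q] += g * w_out[out, q]
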
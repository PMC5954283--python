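"""Numba kernels for paragraph-vector SGD with hierarchical softmax.

All kernels are single-threaded and iterate contexts in a fixed order, so a
run is bit-reproducible given the same inputs.  The predictive feature for a
context is the concatenation ``h = (w_1, ..., w_m, x_doc)`` of the m context
word vectors and the document vector; each internal tree node carries an
(m+1)*d parameter vector scored against h by a sigmoid.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_EXP = 30.0


@njit(cache=True, fastmath=True)
def _sigmoid(z):
    if z > MAX_EXP:
        return 1.0
    if z < -MAX_EXP:
        return 0.0
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True, fastmath=True)
def hsm_train_epoch(
    tokens,        # int32[total]  flat token stream, UNK == 0
    offsets,       # int64[S+1]    sentence boundaries into tokens
    doc_index,     # int32[S]      row of doc_vec for each sentence
    order,         # int64[S]      sentence visit order this epoch
    word_vec,      # float64[V, d]
    doc_vec,       # float64[N, d]
    node_vec,      # float64[V-1, (m+1)d]
    code_offsets,  # int64[V+1]    per-token path boundaries
    code_bits,     # uint8[...]    branch bit per path node
    code_points,   # int32[...]    internal node id per path node
    m,             # context window length
    d,             # embedding dimension
    lr0, lr1,      # linear learning-rate schedule endpoints
    ctx_done,      # contexts consumed before this epoch (for the schedule)
    ctx_total,     # total contexts across all epochs
):
    hdim = (m + 1) * d
    h = np.empty(hdim, dtype=np.float64)
    neu1e = np.empty(hdim, dtype=np.float64)
    processed = 0
    for si in range(order.shape[0]):
        sent = order[si]
        start = offsets[sent]
        stop = offsets[sent + 1]
        T = stop - start
        di = doc_index[sent]
        for t in range(T - m):
            frac = (ctx_done + processed) / ctx_total
            lr = lr0 + (lr1 - lr0) * frac
            processed += 1
            target = tokens[start + t + m]
            if target == 0:  # UNK is never a prediction target
                continue
            # assemble h = (context word vectors, doc vector)
            for a in range(m):
                w = tokens[start + t + a]
                base = a * d
                for c in range(d):
                    h[base + c] = word_vec[w, c]
            base = m * d
            for c in range(d):
                h[base + c] = doc_vec[di, c]
            for c in range(hdim):
                neu1e[c] = 0.0
            for j in range(code_offsets[target], code_offsets[target + 1]):
                pt = code_points[j]
                bit = code_bits[j]
                z = 0.0
                for c in range(hdim):
                    z += node_vec[pt, c] * h[c]
                g = (bit - _sigmoid(z)) * lr
                for c in range(hdim):
                    neu1e[c] += g * node_vec[pt, c]
                    node_vec[pt, c] += g * h[c]
            for a in range(m):
                w = tokens[start + t + a]
                base = a * d
                for c in range(d):
                    word_vec[w, c] += neu1e[base + c]
            base = m * d
            for c in range(d):
                doc_vec[di, c] += neu1e[base + c]
    return processed


@njit(cache=True, fastmath=True)
def hsm_objective(
    tokens, offsets, doc_index,
    word_vec, doc_vec, node_vec,
    code_offsets, code_bits, code_points,
    m, d,
):
    """Objective value: sum over sentences of the mean context log-probability."""
    hdim = (m + 1) * d
    h = np.empty(hdim, dtype=np.float64)
    total = 0.0
    n_sent = 0
    for sent in range(offsets.shape[0] - 1):
        start = offsets[sent]
        stop = offsets[sent + 1]
        T = stop - start
        if T <= m:
            continue
        di = doc_index[sent]
        sent_lp = 0.0
        n_ctx = 0
        for t in range(T - m):
            target = tokens[start + t + m]
            if target == 0:
                continue
            for a in range(m):
                w = tokens[start + t + a]
                base = a * d
                for c in range(d):
                    h[base + c] = word_vec[w, c]
            base = m * d
            for c in range(d):
                h[base + c] = doc_vec[di, c]
            lp = 0.0
            for j in range(code_offsets[target], code_offsets[target + 1]):
                pt = code_points[j]
                z = 0.0
                for c in range(hdim):
                    z += node_vec[pt, c] * h[c]
                if code_bits[j] == 0:
                    z = -z
                # log sigmoid(z), clipped for stability
                if z > MAX_EXP:
                    pass
                elif z < -MAX_EXP:
                    lp += z
                else:
                    lp += -np.log1p(np.exp(-z))
            sent_lp += lp
            n_ctx += 1
        if n_ctx > 0:
            total += sent_lp / n_ctx
            n_sent += 1
    return total, n_sent


@njit(cache=True, fastmath=True)
def hsm_infer_epoch(
    tokens,        # int32[T] one sentence
    word_vec, node_vec,
    dvec,          # float64[d] the vector being inferred (updated in place)
    code_offsets, code_bits, code_points,
    m, d, lr0, lr1, ctx_done, ctx_total,
):
    """One SGD pass over a single sentence updating only the doc vector."""
    hdim = (m + 1) * d
    h = np.empty(hdim, dtype=np.float64)
    T = tokens.shape[0]
    processed = 0
    for t in range(T - m):
        frac = (ctx_done + processed) / ctx_total
        lr = lr0 + (lr1 - lr0) * frac
        processed += 1
        target = tokens[t + m]
        if target == 0:
            continue
        for a in range(m):
            w = tokens[t + a]
            base = a * d
            for c in range(d):
                h[base + c] = word_vec[w, c]
        base = m * d
        for c in range(d):
            h[base + c] = dvec[c]
        grad_doc = np.zeros(d, dtype=np.float64)
        for j in range(code_offsets[target], code_offsets[target + 1]):
            pt = code_points[j]
            z = 0.0
            for c in range(hdim):
                z += node_vec[pt, c] * h[c]
            g = (code_bits[j] - _sigmoid(z)) * lr
            for c in range(d):
                grad_doc[c] += g * node_vec[pt, base + c]
        for c in range(d):
            dvec[c] += grad_doc[c]
    return processed
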
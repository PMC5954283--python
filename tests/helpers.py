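"""Test-only helpers: brute-force oracles and the k-mer-count baseline."""

import collections

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from epipair.classifier import f1_score


def brute_force_windows(seq: str, k: int, s: int) -> list[str]:
    """Enumerate all window start positions 0, s, 2s, ... <= L - k."""
    out = []
    pos = 0
    while pos + k <= len(seq):
        out.append(seq[pos : pos + k])
        pos += s
    return out


def reference_huffman_lengths(counts: dict[str, int]) -> dict[str, int]:
    """Two-queue Huffman construction, independent of the package's heap code.

    Returns a code length per symbol; total weighted length is unique across
    optimal prefix codes even when individual lengths differ under ties.
    """
    leaves = sorted(counts.items(), key=lambda kv: kv[1])
    q1 = [(w, [sym]) for sym, w in leaves]
    q2: list[tuple[int, list[str]]] = []
    depth = {sym: 0 for sym in counts}
    while len(q1) + len(q2) > 1:
        picks = []
        for _ in range(2):
            if q1 and (not q2 or q1[0][0] <= q2[0][0]):
                picks.append(q1.pop(0))
            else:
                picks.append(q2.pop(0))
        (w1, s1), (w2, s2) = picks
        for sym in s1 + s2:
            depth[sym] += 1
        q2.append((w1 + w2, s1 + s2))
    return depth


def kmer_count_features(records, k=6):
    """Raw k-mer count vector per record over the union vocabulary."""
    counters = [
        collections.Counter(r.seq[i : i + k] for i in range(len(r.seq) - k + 1))
        for r in records
    ]
    kmers = sorted(set().union(*[set(c) for c in counters]))
    index = {km: i for i, km in enumerate(kmers)}
    out = {}
    for rec, counter in zip(records, counters):
        v = np.zeros(len(kmers))
        for km, n in counter.items():
            v[index[km]] = n
        out[rec.id] = v
    return out


def count_baseline_f1(enhancers, promoters, dataset, k=6, cv_seed=1):
    """The simple 6-mer-count logistic baseline used to calibrate the generator."""
    emap = kmer_count_features(enhancers, k)
    pmap = kmer_count_features(promoters, k)
    X = np.vstack(
        [np.concatenate([emap[p.enh_id], pmap[p.prom_id]]) for p in dataset.pairs]
    )
    y = dataset.labels
    pred = cross_val_predict(
        LogisticRegression(max_iter=5000), X, y,
        cv=StratifiedKFold(10, shuffle=True, random_state=cv_seed),
    )
    return f1_score(pred, y)
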
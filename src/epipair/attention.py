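"""Attention weighting of k-mers against their sequence embedding.

The importance of word t in sequence i is the softmax-normalised dot product
between the document vector x_i and the token's word vector:

    alpha_{it} = exp(x_i . w_{c_{i,t}}) / sum_j exp(x_i . w_{c_{i,j}})

with the denominator running over the tokens of sentence i only.  High-weight
k-mers are candidate motifs and can be exported as FASTA for downstream
enrichment tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import KmerSentence
from .embedding import EmbeddingModel


@dataclass
class AttentionProfile:
    doc_id: str
    kmers: list[str]
    weights: np.ndarray  # (T,), positive, sums to 1

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.weights))

    @property
    def max_weight(self) -> float:
        return float(self.weights[self.argmax])


def attention_weights(
    model: EmbeddingModel,
    sentence: KmerSentence,
    doc_vector: Optional[np.ndarray] = None,
) -> AttentionProfile:
    """Compute the per-token softmax importance profile of one sentence.

    ``doc_vector`` overrides the trained vector, e.g. one produced by
    :func:`epipair.embedding.infer_vector` for an unseen sequence.
    """
    if sentence.T == 0:
        raise ValueError(f"sentence {sentence.doc_id!r} has no tokens")
    if doc_vector is None:
        x = model.embed(sentence.doc_id)
    else:
        x = np.asarray(doc_vector, dtype=np.float64)
    if sentence.tokens is None:
        sentence.tokens = model.vocab.encode(sentence)
    z = model.word_vec[sentence.tokens.astype(np.int64)] @ x
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    return AttentionProfile(doc_id=sentence.doc_id, kmers=list(sentence.kmers), weights=w)


def top_kmers(
    profiles: Iterable[AttentionProfile],
    per_sequence_n: int = 1,
    doc_ids: Optional[set] = None,
) -> list[tuple[str, str, float]]:
    """Per sequence, the n highest-weight distinct k-mers as (kmer, doc_id, weight).

    ``doc_ids`` restricts the selection, e.g. to sequences participating in
    positive pairs.  Ties are broken by first occurrence; a k-mer occurring
    several times in one sentence is reported once, at its highest weight.
    """
    if per_sequence_n < 1:
        raise ValueError("per_sequence_n must be >= 1")
    selection: list[tuple[str, str, float]] = []
    for prof in profiles:
        if doc_ids is not None and prof.doc_id not in doc_ids:
            continue
        best: dict[str, tuple[float, int]] = {}
        for pos, (km, w) in enumerate(zip(prof.kmers, prof.weights)):
            cur = best.get(km)
            if cur is None or w > cur[0]:
                best[km] = (float(w), pos if cur is None else cur[1])
        ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[1][1]))
        for km, (w, _pos) in ranked[:per_sequence_n]:
            selection.append((km, prof.doc_id, w))
    return selection


def export_kmers_fasta(selection: Sequence[tuple[str, str, float]], path) -> None:
    """Write selected k-mers as FASTA with headers ``<doc_id>|rank<r>|w=<weight>``."""
    if not selection:
        raise ValueError("empty selection: nothing to export")
    ranks: dict[str, int] = {}
    with open(path, "w") as fh:
        for km, doc_id, w in selection:
            ranks[doc_id] = ranks.get(doc_id, 0) + 1
            fh.write(f">{doc_id}|rank{ranks[doc_id]}|w={w:.6g}\n{km}\n")


def profiles_to_tsv(profiles: Iterable[AttentionProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("doc_id\tposition\tkmer\tweight\n")
        for prof in profiles:
            for pos, (km, w) in enumerate(zip(prof.kmers, prof.weights)):
                fh.write(f"{prof.doc_id}\t{pos}\t{km}\t{w:.6g}\n")
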
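"""Distributed-memory paragraph embeddings for k-mer sentences.

Each sequence (document) and each k-mer word is mapped to a vector in R^d.
Training slides an m-word context along every sentence and predicts the next
word from the concatenation ``h = (w_1, ..., w_m, x_doc)`` of the context
word vectors and the document vector, so ``h`` lives in R^{(m+1)d}.  The
document vector is shared across all contexts of its own sentence, while
word vectors are shared corpus-wide.  After training, the document vectors
are the fixed-length sequence embedding features.

Two interchangeable output layers satisfy the same probability contract:

* ``exact`` — a dense softmax ``y = b + U h`` over the vocabulary, feasible
  only for small vocabularies; kept as a reference backend.
* ``hsm`` (default) — hierarchical softmax over a binary Huffman tree built
  from corpus word frequencies, where a leaf's probability is the product of
  branch sigmoids along its root path.
"""

from __future__ import annotations

import heapq
import io
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import KmerSentence, VALID_BASES
from . import _sgd

log = logging.getLogger(__name__)

UNK_TOKEN = "<UNK>"
UNK_INDEX = 0


class Vocabulary:
    """Bijection between observed k-mer words and dense indices.

    Index 0 is the reserved UNK word, the target-excluded sink for windows
    containing ambiguous bases.  Real words occupy indices ``1 .. V`` in
    lexicographic order so vocabulary construction is order-independent.
    """

    def __init__(self, tokens: Sequence[str], counts: Sequence[int]):
        self.tokens: list[str] = [UNK_TOKEN] + list(tokens)
        self.counts = np.asarray([0] + list(counts), dtype=np.int64)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_words(self) -> int:
        """Number of real (non-UNK) words."""
        return len(self.tokens) - 1

    def lookup(self, kmer: str) -> int:
        return self.index.get(kmer, UNK_INDEX)

    def encode(self, sentence: KmerSentence) -> np.ndarray:
        idx = np.fromiter(
            (self.index.get(km, UNK_INDEX) for km in sentence.kmers),
            dtype=np.int32,
            count=len(sentence.kmers),
        )
        return idx


def build_vocabulary(sentences: Iterable[KmerSentence]) -> Vocabulary:
    """Count every valid k-mer in the corpus and assign dense indices."""
    counts: dict[str, int] = {}
    n_tokens = 0
    for sent in sentences:
        for km in sent.kmers:
            n_tokens += 1
            if set(km) <= VALID_BASES:
                counts[km] = counts.get(km, 0) + 1
    if n_tokens == 0:
        raise ValueError("empty corpus: no tokens observed")
    tokens = sorted(counts)
    return Vocabulary(tokens, [counts[t] for t in tokens])


def encode_corpus(sentences: Sequence[KmerSentence], vocab: Vocabulary) -> None:
    for sent in sentences:
        sent.tokens = vocab.encode(sent)


# ---------------------------------------------------------------------------
# Huffman tree
# ---------------------------------------------------------------------------

@dataclass
class HuffmanTree:
    """Binary Huffman code over the vocabulary's real words.

    ``codes[i]`` / ``points[i]`` give, for vocabulary index i, the branch
    bits and internal-node ids along the root path; UNK (index 0) has an
    empty path and is never predicted.
    """

    codes: list[np.ndarray]
    points: list[np.ndarray]
    n_internal: int

    def code_length(self, index: int) -> int:
        return len(self.codes[index])

    def kraft_sum(self) -> float:
        return float(sum(2.0 ** -len(c) for c in self.codes[1:]))

    def flat_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        offsets = np.zeros(len(self.codes) + 1, dtype=np.int64)
        for i, c in enumerate(self.codes):
            offsets[i + 1] = offsets[i] + len(c)
        bits = np.concatenate([c for c in self.codes]).astype(np.uint8) \
            if offsets[-1] else np.zeros(0, dtype=np.uint8)
        pts = np.concatenate([p for p in self.points]).astype(np.int32) \
            if offsets[-1] else np.zeros(0, dtype=np.int32)
        return offsets, bits, pts


def build_huffman(vocab: Vocabulary) -> HuffmanTree:
    """Build the frequency-sorted binary Huffman tree over real words.

    Ties in the merge queue are broken by the lexicographically smallest
    token contained in each subtree, so the tree is reproducible.
    """
    V = vocab.n_words
    if V < 2:
        raise ValueError(f"need at least 2 vocabulary words for a Huffman tree, got {V}")
    # heap entries: (count, tie_key, node_id); leaves are vocab indices 1..V,
    # internal nodes are numbered from 0 as they are created.
    heap: list[tuple[int, str, int]] = [
        (int(vocab.counts[i]), vocab.tokens[i], i) for i in range(1, V + 1)
    ]
    heapq.heapify(heap)
    children: dict[int, tuple[int, int]] = {}  # internal id -> (left, right)
    n_internal = 0
    # internal nodes are tagged with ids >= V+1 in the heap, remapped below
    while len(heap) > 1:
        c0, k0, n0 = heapq.heappop(heap)
        c1, k1, n1 = heapq.heappop(heap)
        internal_id = n_internal
        n_internal += 1
        children[internal_id] = (n0, n1)
        heapq.heappush(heap, (c0 + c1, min(k0, k1), V + 1 + internal_id))
    root = heap[0][2]

    codes: list[np.ndarray] = [np.zeros(0, dtype=np.uint8)] * (V + 1)
    points: list[np.ndarray] = [np.zeros(0, dtype=np.int32)] * (V + 1)

    stack = [(root, [], [])]
    while stack:
        node, bits, path = stack.pop()
        if node <= V:  # leaf: vocabulary index
            codes[node] = np.array(bits, dtype=np.uint8)
            points[node] = np.array(path, dtype=np.int32)
            continue
        internal = node - (V + 1)
        left, right = children[internal]
        stack.append((left, bits + [0], path + [internal]))
        stack.append((right, bits + [1], path + [internal]))
    return HuffmanTree(codes=codes, points=points, n_internal=n_internal)


# ---------------------------------------------------------------------------
# Model and training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyper-parameters of the embedding stage.

    The defaults are the setting used throughout: k = 6, stride 1, context
    window m = 20, embedding dimension d = 100.  Epoch count and learning
    rates are exposed because no canonical values exist for them; the
    learning rate decays linearly from ``lr0`` to ``lr1`` across all updates.
    """

    k: int = 6
    s: int = 1
    m: int = 20
    d: int = 100
    epochs: int = 20
    lr0: float = 0.025
    lr1: float = 1e-4
    seed: int = 1
    backend: str = "hsm"  # "hsm" or "exact"

    def __post_init__(self) -> None:
        for name in ("k", "s", "m", "d", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lr0 <= 0 or self.lr1 <= 0:
            raise ValueError("learning rates must be positive")
        if self.backend not in ("hsm", "exact"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class EmbeddingModel:
    """Trained word vectors, document vectors and output-layer parameters."""

    vocab: Vocabulary
    config: TrainConfig
    word_vec: np.ndarray                 # (V+1, d) including the UNK row
    doc_vec: np.ndarray                  # (N, d)
    doc_ids: list[str]
    tree: Optional[HuffmanTree] = None   # hsm backend
    U: Optional[np.ndarray] = None       # exact backend: (V, (m+1)d)
    b: Optional[np.ndarray] = None       # exact backend: (V,)
    doc_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_index:
            self.doc_index = {d: i for i, d in enumerate(self.doc_ids)}

    @property
    def d(self) -> int:
        return self.word_vec.shape[1]

    def embed(self, doc_id: str) -> np.ndarray:
        """Return the trained document vector for a training-corpus sequence."""
        if doc_id not in self.doc_index:
            raise KeyError(
                f"doc id {doc_id!r} was not in the training corpus; "
                "use infer_vector for unseen sequences"
            )
        return self.doc_vec[self.doc_index[doc_id]].copy()

    # -- probability contract -------------------------------------------------

    def next_word_probability(
        self, context_tokens: Sequence[int], doc_id: str
    ) -> np.ndarray:
        """Distribution over the vocabulary for the word following a context.

        Returned array is aligned to vocabulary indices; the UNK entry is 0
        and real-word entries sum to 1.
        """
        m, d = self.config.m, self.d
        if len(context_tokens) != m:
            raise ValueError(f"context length {len(context_tokens)} != m = {m}")
        if doc_id not in self.doc_index:
            raise KeyError(f"unknown doc id {doc_id!r}")
        ctx = np.asarray(context_tokens, dtype=np.int64)
        h = np.concatenate(
            [self.word_vec[ctx].ravel(), self.doc_vec[self.doc_index[doc_id]]]
        )
        V = self.vocab.n_words
        probs = np.zeros(V + 1, dtype=np.float64)
        if self.config.backend == "exact":
            y = self.b + self.U @ h
            y -= y.max()
            e = np.exp(y)
            probs[1:] = e / e.sum()
        else:
            node_z = self._node_vec @ h  # (V-1,) one sigmoid argument per node
            for i in range(1, V + 1):
                bits = self.tree.codes[i]
                pts = self.tree.points[i]
                z = node_z[pts] * np.where(bits == 1, 1.0, -1.0)
                z = np.clip(z, -_sgd.MAX_EXP, _sgd.MAX_EXP)
                probs[i] = float(np.exp(-np.logaddexp(0.0, -z).sum()))
        return probs

    # node parameter matrix, present only for the hsm backend
    _node_vec: Optional[np.ndarray] = None

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Write a lossless, byte-deterministic model container."""
        meta = {
            "format": "epipair-model",
            "version": 1,
            "backend": self.config.backend,
            "config": asdict(self.config),
            "tokens": self.vocab.tokens[1:],
            "counts": [int(c) for c in self.vocab.counts[1:]],
            "doc_ids": self.doc_ids,
            "arrays": ["word_vec", "doc_vec"]
            + (["node_vec"] if self.tree is not None else [])
            + (["U", "b"] if self.U is not None else []),
        }
        with open(path, "wb") as fh:
            fh.write(b"#epipair-model-v1\n")
            fh.write(json.dumps(meta, sort_keys=True).encode() + b"\n")
            for name in meta["arrays"]:
                arr = {"word_vec": self.word_vec, "doc_vec": self.doc_vec,
                       "node_vec": self._node_vec, "U": self.U, "b": self.b}[name]
                np.lib.format.write_array(fh, np.ascontiguousarray(arr), version=(1, 0))

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        with open(path, "rb") as fh:
            magic = fh.readline()
            if magic.strip() != b"#epipair-model-v1":
                raise ValueError(f"{path}: not an epipair model file")
            meta = json.loads(fh.readline())
            arrays = {name: np.lib.format.read_array(fh) for name in meta["arrays"]}
        vocab = Vocabulary(meta["tokens"], meta["counts"])
        config = TrainConfig(**meta["config"])
        model = cls(
            vocab=vocab,
            config=config,
            word_vec=arrays["word_vec"],
            doc_vec=arrays["doc_vec"],
            doc_ids=list(meta["doc_ids"]),
            U=arrays.get("U"),
            b=arrays.get("b"),
        )
        if "node_vec" in arrays:
            model.tree = build_huffman(vocab)
            model._node_vec = arrays["node_vec"]
        return model


def _corpus_arrays(sentences: Sequence[KmerSentence], m: int):
    """Flatten trainable sentences (T > m) into contiguous kernel inputs."""
    usable = [s for s in sentences if s.tokens is not None and s.T > m]
    skipped = [s for s in sentences if s.tokens is None or s.T <= m]
    if skipped:
        warnings.warn(
            f"{len(skipped)} sentence(s) with T <= m = {m} contribute no "
            "contexts and were skipped"
        )
    if not usable:
        raise ValueError(
            f"no sentence has more than m = {m} tokens; lower m or provide longer sequences"
        )
    offsets = np.zeros(len(usable) + 1, dtype=np.int64)
    for i, s in enumerate(usable):
        offsets[i + 1] = offsets[i] + s.T
    tokens = np.concatenate([s.tokens for s in usable]).astype(np.int32)
    return usable, tokens, offsets


def train(
    sentences: Sequence[KmerSentence],
    config: TrainConfig,
    vocab: Optional[Vocabulary] = None,
) -> EmbeddingModel:
    """Train word, document and output-layer parameters by SGD.

    Contexts are visited in sliding-window order within each sentence;
    sentence order is reshuffled every epoch from the seeded generator.
    Single-threaded and bit-reproducible for a fixed seed.
    """
    if vocab is None:
        vocab = build_vocabulary(sentences)
    for s in sentences:
        if s.tokens is None:
            s.tokens = vocab.encode(s)
    m, d = config.m, config.d
    usable, tokens, offsets = _corpus_arrays(sentences, m)
    doc_ids = [s.doc_id for s in usable]
    if len(set(doc_ids)) != len(doc_ids):
        raise ValueError("duplicate doc ids in training corpus")
    n_sent = len(usable)
    doc_index = np.arange(n_sent, dtype=np.int32)

    rng = np.random.default_rng(config.seed)
    V = vocab.n_words
    scale = 0.5 / d
    word_vec = rng.uniform(-scale, scale, size=(V + 1, d))
    doc_vec = rng.uniform(-scale, scale, size=(n_sent, d))

    model = EmbeddingModel(
        vocab=vocab, config=config, word_vec=word_vec, doc_vec=doc_vec,
        doc_ids=doc_ids,
    )

    ctx_per_epoch = int(sum(s.T - m for s in usable))
    ctx_total = ctx_per_epoch * config.epochs

    if config.backend == "hsm":
        tree = build_huffman(vocab)
        model.tree = tree
        node_vec = np.zeros((tree.n_internal, (m + 1) * d))
        model._node_vec = node_vec
        code_offsets, code_bits, code_points = tree.flat_arrays()
        done = 0
        for epoch in range(config.epochs):
            order = rng.permutation(n_sent).astype(np.int64)
            done += _sgd.hsm_train_epoch(
                tokens, offsets, doc_index, order,
                word_vec, doc_vec, node_vec,
                code_offsets, code_bits, code_points,
                m, d, config.lr0, config.lr1, done, ctx_total,
            )
        log.info("hsm training done: %d sentences, V=%d, %d contexts/epoch, %d epochs",
                 n_sent, V, ctx_per_epoch, config.epochs)
    else:
        U = np.zeros((V, (m + 1) * d))
        bvec = np.zeros(V)
        model.U, model.b = U, bvec
        done = 0
        for epoch in range(config.epochs):
            order = rng.permutation(n_sent)
            for sent in order:
                st, sp = offsets[sent], offsets[sent + 1]
                for t in range(sp - st - m):
                    lr = config.lr0 + (config.lr1 - config.lr0) * (done / ctx_total)
                    done += 1
                    target = tokens[st + t + m]
                    if target == UNK_INDEX:
                        continue
                    ctx = tokens[st + t : st + t + m].astype(np.int64)
                    h = np.concatenate([word_vec[ctx].ravel(), doc_vec[sent]])
                    y = bvec + U @ h
                    y -= y.max()
                    p = np.exp(y)
                    p /= p.sum()
                    grad_y = -p
                    grad_y[target - 1] += 1.0  # U rows cover real words only
                    grad_h = U.T @ grad_y
                    U += lr * np.outer(grad_y, h)
                    bvec += lr * grad_y
                    for a in range(m):
                        word_vec[ctx[a]] += lr * grad_h[a * d : (a + 1) * d]
                    doc_vec[sent] += lr * grad_h[m * d :]
        log.info("exact-softmax training done: %d sentences, V=%d", n_sent, V)
    return model


def objective(model: EmbeddingModel, sentences: Sequence[KmerSentence]) -> float:
    """Sum over sentences of the mean next-word log-probability."""
    m, d = model.config.m, model.d
    if model.config.backend == "hsm":
        usable, tokens, offsets = _corpus_arrays(sentences, m)
        doc_index = np.array(
            [model.doc_index[s.doc_id] for s in usable], dtype=np.int32
        )
        code_offsets, code_bits, code_points = model.tree.flat_arrays()
        total, n = _sgd.hsm_objective(
            tokens, offsets, doc_index,
            model.word_vec, model.doc_vec, model._node_vec,
            code_offsets, code_bits, code_points, m, d,
        )
        return float(total)
    total = 0.0
    for s in sentences:
        if s.T <= m:
            continue
        lps = []
        for t in range(s.T - m):
            target = int(s.tokens[t + m])
            if target == UNK_INDEX:
                continue
            p = model.next_word_probability(s.tokens[t : t + m], s.doc_id)
            lps.append(np.log(p[target]))
        if lps:
            total += float(np.mean(lps))
    return total


def infer_vector(
    model: EmbeddingModel,
    sentence: KmerSentence,
    epochs: int = 20,
    lr0: float = 0.025,
    lr1: float = 1e-4,
    seed: int = 1,
) -> np.ndarray:
    """Infer a document vector for an unseen sentence.

    Word vectors and output-layer parameters stay frozen; only a fresh doc
    vector is optimised on the training objective.  ``epochs=0`` returns the
    random initialisation.
    """
    if model.config.backend != "hsm":
        raise NotImplementedError("inference is implemented for the hsm backend")
    m, d = model.config.m, model.d
    if sentence.tokens is None:
        sentence.tokens = model.vocab.encode(sentence)
    if sentence.T <= m:
        raise ValueError(f"sentence has T = {sentence.T} <= m = {m}; cannot infer")
    rng = np.random.default_rng(seed)
    dvec = rng.uniform(-0.5 / d, 0.5 / d, size=d)
    if epochs == 0:
        return dvec
    tokens = sentence.tokens.astype(np.int32)
    code_offsets, code_bits, code_points = model.tree.flat_arrays()
    ctx_total = (sentence.T - m) * epochs
    done = 0
    for _ in range(epochs):
        done += _sgd.hsm_infer_epoch(
            tokens, model.word_vec, model._node_vec, dvec,
            code_offsets, code_bits, code_points,
            m, d, lr0, lr1, done, ctx_total,
        )
    return dvec
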
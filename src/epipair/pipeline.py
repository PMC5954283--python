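"""End-to-end synthetic-study pipeline: simulate -> embed -> cross-validate.

The package-wide defaults (k = 6, s = 1, m = 20, d = 100; GBRT with
learning rate 1e-3, 4000 trees, depth 25) describe the full-corpus setting.
The synthetic study bundled with the package runs on a much smaller corpus
(400 sequences per role, ~200 kb of sequence), and uses correspondingly
smaller models, chosen once and fixed:

* classification: k = 3, m = 1, d = 12 — a 64-word vocabulary is densely
  observed at this corpus size, giving stable paragraph vectors;
* attention / motif analysis: k = 6 — motif-length words are needed for
  per-k-mer importance to be interpretable;
* GBRT: learning rate 0.1, 300 trees, depth 3 — sized to 400 pairs.

See docs/methods.md for the reasoning behind these scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classifier import CVReport, GBRTConfig, assemble_features, cross_validate
from .corpus import PairDataset, SequenceRecord, tokenize
from .embedding import EmbeddingModel, TrainConfig, train
from .synth import GroundTruth, SyntheticSpec, generate_all

#: tokenization length for the synthetic classification study
STUDY_CLASSIFY_K = 3
#: tokenization length for the synthetic attention study
STUDY_ATTENTION_K = 6


def study_train_config(role: str, k: int = STUDY_CLASSIFY_K, seed: int = 11) -> TrainConfig:
    """Embedding hyper-parameters used for the bundled synthetic study.

    Promoter sentences are roughly twice as long as enhancer sentences, so
    they see twice the SGD updates per epoch and get half the epochs.
    """
    epochs = 25 if role == "enhancer" else 12
    return TrainConfig(k=k, s=1, m=1, d=12, epochs=epochs, lr0=0.05, seed=seed)


def study_gbrt_config(seed: int = 1) -> GBRTConfig:
    return GBRTConfig(learning_rate=0.1, n_trees=300, depth=3, seed=seed)


@dataclass
class StudyResult:
    spec: SyntheticSpec
    enhancers: list[SequenceRecord]
    promoters: list[SequenceRecord]
    dataset: PairDataset
    truth: GroundTruth
    enh_model: EmbeddingModel
    prom_model: EmbeddingModel
    features: np.ndarray
    report: CVReport


def train_role_model(
    records: Sequence[SequenceRecord], role: str, k: int, seed: int
) -> EmbeddingModel:
    config = study_train_config(role, k=k, seed=seed)
    sentences = [tokenize(r, config.k, config.s) for r in records]
    return train(sentences, config)


def run_study(
    spec: Optional[SyntheticSpec] = None,
    seed: int = 1,
    n_folds: int = 10,
    k: int = STUDY_CLASSIFY_K,
) -> StudyResult:
    """Run the full synthetic pipeline and cross-validate the classifier.

    ``seed`` controls the embedding initialisation/ordering, the fold split
    and the GBRT; the corpus itself is fixed by ``spec.seed``.
    """
    if spec is None:
        spec = SyntheticSpec(seed=seed)
    enhancers, promoters, dataset, truth = generate_all(spec)
    enh_model = train_role_model(enhancers, "enhancer", k, seed=seed + 10)
    prom_model = train_role_model(promoters, "promoter", k, seed=seed + 11)
    features = assemble_features(dataset, enh_model, prom_model)
    report = cross_validate(
        dataset, features, study_gbrt_config(seed=seed), n_folds=n_folds, seed=seed
    )
    return StudyResult(
        spec=spec, enhancers=enhancers, promoters=promoters, dataset=dataset,
        truth=truth, enh_model=enh_model, prom_model=prom_model,
        features=features, report=report,
    )
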
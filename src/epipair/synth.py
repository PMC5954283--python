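"""Synthetic enhancer-promoter corpora with known ground truth.

The generator plants position-weight-matrix motifs into i.i.d. background
sequence and defines interactions by motif compatibility: every sequence
carries one of two regulatory "programs" (tag A or B), realised through a
role- and tag-specific PWM inserted in several copies.  An enhancer-promoter
pair whose tags match interacts with high probability, a mismatched pair
with low probability, so the label carries irreducible noise like real
interaction data.  Sequences get coordinates on a virtual chromosome;
candidate pairs closer than 10 kb are discarded and negatives are sampled
distance-matched to the positives across quantile bins, one negative per
positive.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .corpus import Pair, PairDataset, SequenceRecord, load_fasta, load_pairs, write_fasta

BASES = np.array(["A", "C", "G", "T"])


def consensus_pwm(consensus: str, p: float = 0.9) -> np.ndarray:
    """PWM giving the consensus base probability ``p`` at every position."""
    pwm = np.full((len(consensus), 4), (1.0 - p) / 3.0)
    for i, base in enumerate(consensus):
        pwm[i, "ACGT".index(base)] = p
    return pwm


# Tag-specific motif consensi, one per (role, tag).
DEFAULT_MOTIFS = {
    ("enhancer", "A"): "GATAAGGCTA",
    ("enhancer", "B"): "CCGGTAACGT",
    ("promoter", "A"): "TTGACGTCAT",
    ("promoter", "B"): "AGGCATTCGA",
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    n_enhancers: int = 400
    n_promoters: int = 400
    enh_length: tuple[int, int] = (250, 600)      # uniform range, bp
    prom_length: tuple[int, int] = (600, 1000)    # uniform range, bp
    motif_consensus: dict = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    consensus_p: float = 0.9          # per-position consensus probability
    insertion_prob: float = 1.0       # probability a sequence receives its motif
    # motif copies per sequence, per role; promoters are longer, so they get
    # proportionally more copies to keep motif density comparable
    enh_copies: int = 18
    prom_copies: int = 24
    # interaction probability per (enhancer tag, promoter tag) combination;
    # the A-program pair is the compatible one, everything else is background
    pairing_rule: dict = field(default_factory=lambda: {
        ("A", "A"): 0.9,
        ("A", "B"): 0.05,
        ("B", "A"): 0.05,
        ("B", "B"): 0.05,
    })
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    chrom_length: int = 50_000_000
    min_distance: int = 10_000        # pairs closer than this are discarded
    max_distance: int = 2_000_000
    n_bins: int = 5                   # distance bins for negative matching
    negatives_per_positive: int = 1
    n_positives: int = 200
    seed: int = 1

    def __post_init__(self) -> None:
        for prob in (self.consensus_p, self.insertion_prob,
                     *self.pairing_rule.values()):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")

    def pwm(self, role: str, tag: str) -> np.ndarray:
        return consensus_pwm(self.motif_consensus[(role, tag)], self.consensus_p)


@dataclass
class GroundTruth:
    """What the generator planted: tags, motif positions, coordinates."""

    tags: dict[str, str] = field(default_factory=dict)
    plants: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    coords: dict[str, int] = field(default_factory=dict)

    def update(self, other: "GroundTruth") -> None:
        self.tags.update(other.tags)
        self.plants.update(other.plants)
        self.coords.update(other.coords)


def _sample_pwm(pwm: np.ndarray, rng: np.random.Generator) -> str:
    idx = [rng.choice(4, p=pwm[i]) for i in range(pwm.shape[0])]
    return "".join(BASES[idx])


def generate_sequences(
    spec: SyntheticSpec, role: str, seed: Optional[int] = None
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Sample one role's corpus: background, planted motifs, coordinates."""
    if role == "enhancer":
        n, (lo, hi), copies = spec.n_enhancers, spec.enh_length, spec.enh_copies
    elif role == "promoter":
        n, (lo, hi), copies = spec.n_promoters, spec.prom_length, spec.prom_copies
    else:
        raise ValueError(f"unknown role {role!r}")
    motif_len = max(len(spec.motif_consensus[(role, t)]) for t in ("A", "B"))
    if motif_len > lo:
        raise ValueError(
            f"motif length {motif_len} exceeds minimum sequence length {lo}"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[SequenceRecord] = []
    truth = GroundTruth()
    background = np.asarray(spec.background)
    for i in range(n):
        doc_id = f"{role.upper()}_{i}"
        L = int(rng.integers(lo, hi + 1))
        seq = rng.choice(BASES, size=L, p=background)
        tag = "A" if rng.random() < 0.5 else "B"
        plants: list[tuple[str, int, int]] = []
        if rng.random() < spec.insertion_prob:
            pwm = spec.pwm(role, tag)
            mlen = pwm.shape[0]
            motif_name = f"{role}_{tag}"
            occupied: list[tuple[int, int]] = []
            attempts = 0
            while len(plants) < copies and attempts < 400:
                attempts += 1
                start = int(rng.integers(0, L - mlen + 1))
                if any(start < e and start + mlen > s for s, e in occupied):
                    continue
                instance = _sample_pwm(pwm, rng)
                seq[start : start + mlen] = list(instance)
                occupied.append((start, start + mlen))
                plants.append((motif_name, start, start + mlen))
        records.append(SequenceRecord(id=doc_id, role=role, seq="".join(seq)))
        truth.tags[doc_id] = tag
        truth.plants[doc_id] = plants
        truth.coords[doc_id] = int(rng.integers(0, spec.chrom_length))
    return records, truth


def generate_pairs(
    spec: SyntheticSpec,
    enhancers: list[SequenceRecord],
    promoters: list[SequenceRecord],
    truth: GroundTruth,
    seed: Optional[int] = None,
) -> PairDataset:
    """Draw labelled pairs with distance-binned negative matching.

    Positives are candidate pairs that interact under the tag-compatibility
    rule; negatives are non-interacting candidates subsampled so the
    per-bin distance histogram matches the positives, one negative per
    positive.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    enh_ids = [r.id for r in enhancers]
    prom_ids = [r.id for r in promoters]
    e_coord = np.array([truth.coords[i] for i in enh_ids])
    p_coord = np.array([truth.coords[i] for i in prom_ids])
    dist = np.abs(e_coord[:, None] - p_coord[None, :])
    ei, pi = np.nonzero((dist >= spec.min_distance) & (dist <= spec.max_distance))
    order = rng.permutation(len(ei))
    ei, pi = ei[order], pi[order]

    positives: list[tuple[str, str, int]] = []
    neg_pool: list[tuple[str, str, int]] = []
    want_neg_pool = spec.n_positives * spec.negatives_per_positive * 20
    for e_idx, p_idx in zip(ei, pi):
        enh_id, prom_id = enh_ids[e_idx], prom_ids[p_idx]
        p_int = spec.pairing_rule[(truth.tags[enh_id], truth.tags[prom_id])]
        interact = rng.random() < p_int
        d = int(dist[e_idx, p_idx])
        if interact and len(positives) < spec.n_positives:
            positives.append((enh_id, prom_id, d))
        elif not interact and len(neg_pool) < want_neg_pool:
            neg_pool.append((enh_id, prom_id, d))
        if len(positives) >= spec.n_positives and len(neg_pool) >= want_neg_pool:
            break
    if not positives:
        raise ValueError("pairing rule produced zero positive pairs")

    pos_d = np.array([d for _, _, d in positives], dtype=float)
    edges = np.quantile(pos_d, np.linspace(0, 1, spec.n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf

    def bin_of(d: float) -> int:
        return int(np.searchsorted(edges, d, side="right") - 1)

    pos_bins = np.array([bin_of(d) for d in pos_d])
    neg_by_bin: dict[int, list[tuple[str, str, int]]] = {b: [] for b in range(spec.n_bins)}
    for item in neg_pool:
        neg_by_bin[bin_of(item[2])].append(item)
    negatives: list[tuple[str, str, int]] = []
    for b in range(spec.n_bins):
        need = int(np.sum(pos_bins == b)) * spec.negatives_per_positive
        avail = neg_by_bin[b]
        if len(avail) < need:
            raise ValueError(
                f"distance bin {b}: only {len(avail)} candidate negatives for "
                f"{need} required; generate a larger corpus"
            )
        take = rng.choice(len(avail), size=need, replace=False)
        negatives.extend(avail[t] for t in take)

    pairs = [Pair(e, p, 1, d) for e, p, d in positives] + [
        Pair(e, p, 0, d) for e, p, d in negatives
    ]
    shuffle = rng.permutation(len(pairs))
    return PairDataset(pairs=[pairs[i] for i in shuffle])


def generate_all(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[SequenceRecord], PairDataset, GroundTruth]:
    """Full fixture: both corpora plus a labelled pair table."""
    enhancers, truth_e = generate_sequences(spec, "enhancer", seed=spec.seed)
    promoters, truth_p = generate_sequences(spec, "promoter", seed=spec.seed + 100_003)
    truth = GroundTruth()
    truth.update(truth_e)
    truth.update(truth_p)
    dataset = generate_pairs(spec, enhancers, promoters, truth)
    return enhancers, promoters, dataset, truth


def write_fixture(
    dataset: PairDataset,
    enhancers: list[SequenceRecord],
    promoters: list[SequenceRecord],
    truth: GroundTruth,
    outdir,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "enhancers": outdir / "enhancers.fa",
        "promoters": outdir / "promoters.fa",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    write_fasta(enhancers, paths["enhancers"])
    write_fasta(promoters, paths["promoters"])
    dataset.write_tsv(paths["pairs"])
    with open(paths["truth"], "w") as fh:
        fh.write("doc_id\ttag\tcoord\tmotif\tstart\tend\n")
        for rec in list(enhancers) + list(promoters):
            plants = truth.plants.get(rec.id, [])
            base = f"{rec.id}\t{truth.tags[rec.id]}\t{truth.coords[rec.id]}"
            if not plants:
                fh.write(f"{base}\t.\t-1\t-1\n")
            for motif, start, end in plants:
                fh.write(f"{base}\t{motif}\t{start}\t{end}\n")
    return paths


def load_ground_truth(path) -> GroundTruth:
    truth = GroundTruth()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            doc_id, tag, coord, motif, start, end = line.rstrip("\n").split("\t")
            truth.tags[doc_id] = tag
            truth.coords[doc_id] = int(coord)
            truth.plants.setdefault(doc_id, [])
            if motif != ".":
                truth.plants[doc_id].append((motif, int(start), int(end)))
    return truth


def load_fixture(indir) -> tuple[list[SequenceRecord], list[SequenceRecord], PairDataset, GroundTruth]:
    indir = Path(indir)
    enhancers = load_fasta(indir / "enhancers.fa", role="enhancer")
    promoters = load_fasta(indir / "promoters.fa", role="promoter")
    dataset = load_pairs(indir / "pairs.tsv", enhancers, promoters)
    truth = load_ground_truth(indir / "ground_truth.tsv")
    return enhancers, promoters, dataset, truth
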
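"""Sequence corpus handling: FASTA/BED input and k-mer sentence construction.

A DNA sequence is treated as a *sentence* whose words are its overlapping
k-mers, enumerated left to right with a fixed stride ``s``.  A sequence of
length ``L`` therefore yields ``floor((L - k) / s) + 1`` tokens; trailing
bases that do not complete a window are dropped.  Each sequence carries a
unique document id (``ENHANCER_i`` / ``PROMOTER_i`` when synthesised) so the
embedding stage can attach a paragraph vector to it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
ROLES = ("enhancer", "promoter")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One enhancer or promoter sequence with a corpus-unique id."""

    id: str
    role: str
    seq: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class KmerSentence:
    """A sequence rendered as an ordered list of k-mer words.

    ``kmers`` holds the literal window strings (including windows with
    ambiguous bases); ``tokens`` holds vocabulary indices once a
    :class:`~epipair.embedding.Vocabulary` has encoded the sentence, with
    windows containing non-ACGT characters mapped to the reserved UNK index.
    """

    doc_id: str
    kmers: list[str]
    k: int
    s: int
    tokens: Optional[np.ndarray] = None

    @property
    def T(self) -> int:
        return len(self.kmers)

    def __len__(self) -> int:
        return len(self.kmers)


def tokenize(record: SequenceRecord, k: int, s: int, vocab=None) -> KmerSentence:
    """Split a sequence into k-mer words using a sliding window with stride s.

    Returns ``floor((L - k)/s) + 1`` windows for ``L >= k``; shorter
    sequences give an empty sentence (with a warning) rather than an error.
    If ``vocab`` is given the sentence is also encoded to token indices.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if s < 1:
        raise ValueError(f"stride must be >= 1, got {s}")
    seq = record.seq
    L = len(seq)
    if L < k:
        warnings.warn(
            f"sequence {record.id!r} shorter than k ({L} < {k}); empty sentence",
            stacklevel=2,
        )
        kmers: list[str] = []
    else:
        kmers = [seq[i : i + k] for i in range(0, L - k + 1, s)]
    sentence = KmerSentence(doc_id=record.id, kmers=kmers, k=k, s=s)
    if vocab is not None:
        sentence.tokens = vocab.encode(sentence)
    return sentence


# ---------------------------------------------------------------------------
# FASTA / BED / pair-table I/O
# ---------------------------------------------------------------------------

def load_fasta(path, role: str = "enhancer") -> list[SequenceRecord]:
    """Read a FASTA file into records; ids are headers up to first whitespace."""
    from Bio import SeqIO

    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ValueError(f"{path}: line 1 is not a FASTA header: {first[:40]!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(id=entry.id, role=role, seq=str(entry.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i : i + 80] + "\n")


def extract_from_genome(genome_fasta, bed_path, role: str) -> list[SequenceRecord]:
    """Extract BED intervals (0-based half-open) from a genome FASTA.

    The BED name column, when present, supplies the record id; otherwise ids
    are synthesised as ``<ROLE>_<i>``.  A minus in the strand column yields
    the reverse complement.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if chrom not in genome:
                raise ValueError(f"{bed_path}:{lineno}: unknown chromosome {chrom!r}")
            chrom_len = len(genome[chrom])
            if start < 0 or end > chrom_len or start >= end:
                raise ValueError(
                    f"{bed_path}:{lineno}: interval {chrom}:{start}-{end} outside "
                    f"chromosome bounds [0, {chrom_len})"
                )
            name = cols[3] if len(cols) >= 4 and cols[3] not in (".", "") else None
            strand = cols[5] if len(cols) >= 6 else "+"
            seq = genome[chrom][start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            rec_id = name if name is not None else f"{role.upper()}_{len(records)}"
            if rec_id in seen:
                raise ValueError(f"{bed_path}:{lineno}: duplicate id {rec_id!r}")
            seen.add(rec_id)
            records.append(SequenceRecord(id=rec_id, role=role, seq=seq))
    return records


@dataclass
class Pair:
    enh_id: str
    prom_id: str
    label: int
    distance: Optional[int] = None


@dataclass
class PairDataset:
    """Labelled enhancer-promoter pairs, optionally with per-pair features."""

    pairs: list[Pair] = field(default_factory=list)
    external_features: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=np.int64)

    @property
    def distances(self) -> Optional[np.ndarray]:
        if any(p.distance is None for p in self.pairs):
            return None
        return np.array([p.distance for p in self.pairs], dtype=np.int64)

    def set_external_features(self, features: np.ndarray) -> None:
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[0] != len(self.pairs):
            raise ValueError(
                f"external feature table has {features.shape[0] if features.ndim == 2 else '?'} "
                f"rows, expected {len(self.pairs)}"
            )
        if not np.all(np.isfinite(features)):
            raise ValueError("external features contain non-finite values")
        self.external_features = features

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            has_dist = all(p.distance is not None for p in self.pairs)
            header = ["enh_id", "prom_id", "label"] + (["distance"] if has_dist else [])
            fh.write("\t".join(header) + "\n")
            for p in self.pairs:
                row = [p.enh_id, p.prom_id, str(p.label)]
                if has_dist:
                    row.append(str(p.distance))
                fh.write("\t".join(row) + "\n")


def load_pairs(
    path,
    enhancers: Sequence[SequenceRecord],
    promoters: Sequence[SequenceRecord],
) -> PairDataset:
    """Read a tab-separated pair table (enh_id, prom_id, label[, distance])."""
    enh_ids = {r.id for r in enhancers}
    prom_ids = {r.id for r in promoters}
    pairs: list[Pair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] == "enh_id":
                continue
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            enh_id, prom_id, label_s = cols[0], cols[1], cols[2]
            if enh_id not in enh_ids:
                raise ValueError(f"{path}:{lineno}: unresolvable enhancer id {enh_id!r}")
            if prom_id not in prom_ids:
                raise ValueError(f"{path}:{lineno}: unresolvable promoter id {prom_id!r}")
            if label_s not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: non-binary label {label_s!r}")
            distance = int(cols[3]) if len(cols) >= 4 and cols[3] != "" else None
            pairs.append(Pair(enh_id, prom_id, int(label_s), distance))
    dataset = PairDataset(pairs=pairs)
    n_pos = int(dataset.labels.sum())
    log.info("loaded %d pairs (%d positive, %d negative) from %s",
             len(pairs), n_pos, len(pairs) - n_pos, path)
    return dataset
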
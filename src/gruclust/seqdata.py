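"""Sequence datasets: I/O, the 4:1 split protocol, and synthetic two-class data.

DNA sequences live in two-column tables (``sequence,label``) with binary
class labels; unlabelled tables carry the sequence column only.  The
synthetic generator emulates a two-class ChIP-seq-derived benchmark by
planting a class-specific consensus motif (or position weight matrix) into
i.i.d. background sequence with a tunable insertion probability, so class
separability can be dialled from chance level to near-perfect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence as TypingSequence, Union

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class SequenceParseError(ValueError):
    """Raised when a sequence file or record violates the format contract."""


@dataclass
class SequenceRecord:
    """One DNA sequence with an optional binary class label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None:
            self.label = int(self.label)
            if self.label not in (0, 1):
                raise SequenceParseError(
                    f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
                )
        if len(self.sequence) < 1:
            raise SequenceParseError(f"record {self.id!r}: empty sequence")


def normalize_sequence(seq: str, *, record_id: str = "?", policy: str = "strict") -> str:
    """Upper-case ``seq`` and enforce the alphabet policy.

    ``strict`` (default) rejects anything outside A/C/G/T; ``allow_n``
    additionally admits ``N``, which downstream tokenization maps to the
    unknown token.
    """
    seq = seq.strip().upper()
    allowed = set(ALPHABET) | ({"N"} if policy == "allow_n" else set())
    for pos, base in enumerate(seq):
        if base not in allowed:
            raise SequenceParseError(
                f"record {record_id!r}: base {base!r} at position {pos} is outside "
                f"the {'A/C/G/T/N' if policy == 'allow_n' else 'A/C/G/T'} alphabet"
            )
    return seq


def _looks_like_header(fields: list[str], has_labels: bool) -> bool:
    # A header row has non-DNA content in the sequence column; a row whose
    # label column holds a literal 0/1 is data even then (and will be
    # rejected with a proper parse error if the sequence is malformed).
    probe = fields[0].strip().upper()
    non_dna = not probe or any(ch not in set(ALPHABET) | {"N"} for ch in probe)
    if has_labels and len(fields) > 1 and fields[1].strip() in ("0", "1"):
        return False
    return non_dna


def read_sequence_csv(
    path: Union[str, Path],
    has_labels: bool = True,
    *,
    alphabet_policy: str = "strict",
) -> list[SequenceRecord]:
    """Read a one/two-column sequence CSV into records, preserving file order.

    Column layout is ``sequence[,label]``; an optional header row is
    auto-detected by non-ACGT content in the first column.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        rows = [row for row in reader if row and any(f.strip() for f in row)]
    if rows and _looks_like_header(rows[0], has_labels):
        rows = rows[1:]
    for i, row in enumerate(rows):
        rid = f"row{i}"
        seq = normalize_sequence(row[0], record_id=rid, policy=alphabet_policy)
        label: Optional[int] = None
        if has_labels:
            if len(row) < 2:
                raise SequenceParseError(f"row {i}: expected a label column")
            raw = row[1].strip()
            if raw not in ("0", "1"):
                raise SequenceParseError(
                    f"row {i}: malformed label {raw!r} (must be 0 or 1)"
                )
            label = int(raw)
        records.append(SequenceRecord(id=rid, sequence=seq, label=label))
    return records


def write_sequence_csv(
    records: TypingSequence[SequenceRecord],
    path: Union[str, Path],
    *,
    include_labels: bool = True,
    header: bool = True,
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow(["sequence", "label"] if include_labels else ["sequence"])
        for rec in records:
            if include_labels:
                if rec.label is None:
                    raise SequenceParseError(f"record {rec.id!r} has no label to write")
                writer.writerow([rec.sequence, rec.label])
            else:
                writer.writerow([rec.sequence])


def read_fasta(path: Union[str, Path], *, alphabet_policy: str = "strict") -> list[SequenceRecord]:
    """Read FASTA; a header suffix ``|label=<0|1>`` carries the class label."""
    from Bio import SeqIO

    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        label: Optional[int] = None
        rid = entry.id
        if "|label=" in entry.description:
            tail = entry.description.rsplit("|label=", 1)[1].strip()
            if tail not in ("0", "1"):
                raise SequenceParseError(f"record {rid!r}: malformed label {tail!r}")
            label = int(tail)
            rid = rid.rsplit("|label=", 1)[0]
        seq = normalize_sequence(str(entry.seq), record_id=rid, policy=alphabet_policy)
        records.append(SequenceRecord(id=rid, sequence=seq, label=label))
    return records


def write_fasta(
    records: TypingSequence[SequenceRecord],
    path: Union[str, Path],
    *,
    include_labels: bool = True,
) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            head = rec.id
            if include_labels and rec.label is not None:
                head = f"{head}|label={rec.label}"
            fh.write(f">{head}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Split protocol
# ---------------------------------------------------------------------------

Ratio = tuple[int, int]


@dataclass
class DatasetSplit:
    """Learning/validation/test partition of a labelled dataset.

    ``test_unlabelled`` holds the test records with their labels stripped
    (they are predicted, not trained on); the true labels are retained
    out-of-band in ``test_labels`` so the prediction can be scored afterwards.
    """

    train: list[SequenceRecord]
    validation: list[SequenceRecord]
    test_unlabelled: list[SequenceRecord]
    test_labels: np.ndarray
    learn_test_ratio: Ratio = (4, 1)
    train_val_ratio: Ratio = (4, 1)
    seed: int = 0


def _stratified_partition(
    records: list[SequenceRecord], ratio: Ratio, rng: np.random.Generator
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split into (major, minor) parts of exact global sizes per ``ratio``.

    Stratified by label: each class contributes proportionally, with the
    minor part taking the floor and largest fractional remainders breaking
    the rounding.
    """
    big, small = ratio
    n = len(records)
    n_minor = (n * small) // (big + small)
    by_class: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(int(rec.label), []).append(i)  # type: ignore[arg-type]
    quota: dict[int, int] = {}
    fractions = []
    for cls in sorted(by_class):
        exact = len(by_class[cls]) * n_minor / n if n else 0.0
        quota[cls] = int(np.floor(exact))
        fractions.append((exact - quota[cls], cls))
    short = n_minor - sum(quota.values())
    for _, cls in sorted(fractions, reverse=True)[:short]:
        quota[cls] += 1
    minor_idx: set[int] = set()
    for cls, idx in sorted(by_class.items()):
        order = rng.permutation(len(idx))
        minor_idx.update(idx[j] for j in order[: quota[cls]])
    major = [records[i] for i in range(n) if i not in minor_idx]
    minor = [records[i] for i in range(n) if i in minor_idx]
    return major, minor


def stratified_split(
    records: TypingSequence[SequenceRecord],
    ratio: Ratio = (4, 1),
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """One stratified two-way split at exact global sizes.

    16,000 labelled records at 4:1 yield exactly 12,800 and 3,200.
    """
    records = list(records)
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabelled; the split needs labels")
    if any(r <= 0 for r in ratio):
        raise ValueError("split ratios must be positive")
    if len(records) < 2:
        raise ValueError("cannot split fewer than 2 records into two parts")
    return _stratified_partition(records, ratio, np.random.default_rng(seed))


def split_dataset(
    records: TypingSequence[SequenceRecord],
    learn_test_ratio: Ratio = (4, 1),
    train_val_ratio: Ratio = (4, 1),
    seed: int = 0,
) -> DatasetSplit:
    """Two-stage stratified split: learn:test, then train:validation.

    With the default 4:1 / 4:1 ratios, 20,000 labelled records split into
    16,000 learning and 4,000 test sequences, and the learning part into
    12,800 training and 3,200 validation sequences.  Deterministic for a
    fixed seed; the three parts are disjoint and exhaustive.
    """
    records = list(records)
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabelled; the split needs labels")
    if any(r <= 0 for ratio in (learn_test_ratio, train_val_ratio) for r in ratio):
        raise ValueError("split ratios must be positive")
    if len(records) < 3:
        raise ValueError(f"cannot split {len(records)} records into three parts")
    rng = np.random.default_rng(seed)
    learn, test = _stratified_partition(records, learn_test_ratio, rng)
    train, validation = _stratified_partition(learn, train_val_ratio, rng)
    test_labels = np.array([rec.label for rec in test], dtype=np.int64)
    test_unlabelled = [
        SequenceRecord(id=rec.id, sequence=rec.sequence, label=None) for rec in test
    ]
    return DatasetSplit(
        train=train,
        validation=validation,
        test_unlabelled=test_unlabelled,
        test_labels=test_labels,
        learn_test_ratio=learn_test_ratio,
        train_val_ratio=train_val_ratio,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic two-class data
# ---------------------------------------------------------------------------

Motif = Union[str, np.ndarray]

#: Default class motifs: a GATA-like and a C/EBP-like 8-mer (Hamming
#: distance 7) whose dimer compositions are nearly disjoint, so the classes
#: are separable under overlapping 2-mer tokenization.
DEFAULT_MOTIF_CLASS0 = "AGATAAGA"
DEFAULT_MOTIF_CLASS1 = "TTGCGCAA"


@dataclass
class SyntheticConfig:
    """Parameters of the motif-planted two-class generator.

    Each class-``c`` sequence is drawn i.i.d. from ``background_composition``
    and, with probability ``insertion_prob``, has its class motif written at
    a uniformly random position.  A motif is either a consensus string or a
    position weight matrix of shape ``(width, 4)`` with rows over (A,C,G,T).
    """

    n_per_class: int = 2000
    seq_length: int = 100
    motif_class0: Motif = DEFAULT_MOTIF_CLASS0
    motif_class1: Motif = DEFAULT_MOTIF_CLASS1
    insertion_prob: Union[float, tuple[float, float]] = 0.9
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("background_composition must be 4 probabilities summing to 1")
        for p in self.insertion_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"insertion_prob {p} outside [0, 1]")
        for motif in (self.motif_class0, self.motif_class1):
            if _motif_width(motif) > self.seq_length:
                raise ValueError("motif longer than seq_length")
        if self.n_per_class < 1 or self.seq_length < 1:
            raise ValueError("n_per_class and seq_length must be positive")

    @property
    def insertion_probs(self) -> tuple[float, float]:
        p = self.insertion_prob
        return (float(p), float(p)) if np.isscalar(p) else (float(p[0]), float(p[1]))


def _motif_width(motif: Motif) -> int:
    if isinstance(motif, str):
        return len(motif)
    arr = np.asarray(motif, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("PWM motif must have shape (width, 4)")
    return arr.shape[0]


def _sample_motif(motif: Motif, rng: np.random.Generator) -> str:
    if isinstance(motif, str):
        return normalize_sequence(motif, record_id="motif")
    pwm = np.asarray(motif, dtype=float)
    pwm = pwm / pwm.sum(axis=1, keepdims=True)
    return "".join(ALPHABET[rng.choice(4, p=row)] for row in pwm)


def generate_synthetic(config: SyntheticConfig) -> list[SequenceRecord]:
    """Generate ``2 * n_per_class`` labelled records (class 0 first).

    Byte-identical across runs for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    comp = np.asarray(config.background_composition, dtype=float)
    records: list[SequenceRecord] = []
    bases = np.array(list(ALPHABET))
    for cls, motif, p_insert in zip(
        (0, 1), (config.motif_class0, config.motif_class1), config.insertion_probs
    ):
        width = _motif_width(motif)
        background = rng.choice(4, size=(config.n_per_class, config.seq_length), p=comp)
        insert = rng.random(config.n_per_class) < p_insert
        positions = rng.integers(0, config.seq_length - width + 1, size=config.n_per_class)
        for i in range(config.n_per_class):
            row = bases[background[i]]
            if insert[i]:
                planted = _sample_motif(motif, rng)
                start = positions[i]
                row[start : start + width] = list(planted)
            records.append(
                SequenceRecord(id=f"c{cls}_{i:05d}", sequence="".join(row), label=cls)
            )
    return records
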
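"""Overlapping k-mer tokenization of DNA sequences.

A sequence is split into its overlapping length-``k`` windows (stride 1 by
default, duplicates retained), a corpus-derived vocabulary maps each k-mer
to a positive integer id, and datasets are encoded as post-padded integer
matrices ready for the recurrent backbone.  Id 0 is reserved for padding
and, under the permissive policy, for unknown k-mers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .seqdata import SequenceRecord

PAD_ID = 0


class TokenizationError(ValueError):
    """Raised when a k-mer cannot be mapped under the strict policy."""


@dataclass
class KmerizerConfig:
    k: int = 2
    stride: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 8:
            raise ValueError(f"k must be in [1, 8], got {self.k}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")


def kmerize(
    sequence: str,
    k: int = 2,
    stride: int = 1,
    *,
    strict: bool = True,
) -> list[str]:
    """Split ``sequence`` into its ordered, lower-cased k-mer windows.

    With stride 1 this yields the ``len(sequence) - k + 1`` overlapping
    windows, duplicates retained — e.g. ``"CCTCCCGAGAGA"`` with ``k=2``
    gives ``cc ct tc cc cc cg ga ag ga ag ga``.  A sequence shorter than
    ``k`` raises under the default strict flag and yields ``[]`` otherwise.
    """
    KmerizerConfig(k=k, stride=stride)
    seq = sequence.lower()
    if len(seq) < k:
        if strict:
            raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
        return []
    return [seq[i : i + k] for i in range(0, len(seq) - k + 1, stride)]


@dataclass
class Vocabulary:
    """Bijection between observed k-mers and contiguous ids 1..V.

    Id 0 never maps to a k-mer: it is the padding id and, under the
    permissive tokenization policy, the unknown id.
    """

    k: int
    index_of: dict[str, int]
    ordering: str = "frequency_desc"

    def __post_init__(self) -> None:
        ids = sorted(self.index_of.values())
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("vocabulary ids must be contiguous 1..V")
        if len(self.index_of) > 4**self.k:
            raise ValueError(f"more than 4^{self.k} k-mers in vocabulary")
        for kmer in self.index_of:
            if len(kmer) != self.k or kmer != kmer.lower():
                raise ValueError(f"bad vocabulary key {kmer!r}")

    def __len__(self) -> int:
        return len(self.index_of)

    def __getitem__(self, kmer: str) -> int:
        return self.index_of[kmer]

    @property
    def kmer_of(self) -> dict[int, str]:
        """Inverse mapping id -> k-mer."""
        return {i: s for s, i in self.index_of.items()}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int], ordering: str = "custom") -> "Vocabulary":
        keys = list(mapping)
        if not keys:
            raise ValueError("empty vocabulary mapping")
        k = len(keys[0])
        return cls(k=k, index_of={s.lower(): int(i) for s, i in mapping.items()}, ordering=ordering)

    def save(self, path: Union[str, Path]) -> None:
        """Write a two-column ``kmer<TAB>id`` table in id order."""
        with Path(path).open("w") as fh:
            fh.write(f"# k={self.k}\tordering={self.ordering}\n")
            for kmer, idx in sorted(self.index_of.items(), key=lambda kv: kv[1]):
                fh.write(f"{kmer}\t{idx}\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Vocabulary":
        index_of: dict[str, int] = {}
        k = None
        ordering = "frequency_desc"
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    meta = dict(f.split("=", 1) for f in line[1:].split() if "=" in f)
                    k = int(meta.get("k", 0)) or None
                    ordering = meta.get("ordering", ordering)
                    continue
                if line:
                    kmer, idx = line.split("\t")
                    index_of[kmer] = int(idx)
        if k is None:
            k = len(next(iter(index_of)))
        return cls(k=k, index_of=index_of, ordering=ordering)


def build_vocabulary(
    corpus: Iterable[Union[str, SequenceRecord]],
    k: int = 2,
    stride: int = 1,
    ordering: str = "frequency_desc",
) -> Vocabulary:
    """Build a vocabulary of every distinct k-mer observed in ``corpus``.

    ``frequency_desc`` (default) ranks by corpus count, ties lexicographic;
    ``lexicographic`` sorts keys, which is reproducible without a corpus.
    """
    counts: Counter[str] = Counter()
    n_seqs = 0
    for item in corpus:
        seq = item.sequence if isinstance(item, SequenceRecord) else item
        counts.update(kmerize(seq, k=k, stride=stride))
        n_seqs += 1
    if n_seqs == 0:
        raise ValueError("empty corpus")
    if ordering == "frequency_desc":
        ranked = sorted(counts, key=lambda s: (-counts[s], s))
    elif ordering == "lexicographic":
        ranked = sorted(counts)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    return Vocabulary(k=k, index_of={s: i + 1 for i, s in enumerate(ranked)}, ordering=ordering)


def tokenize(
    sequence: str,
    vocab: Vocabulary,
    stride: int = 1,
    *,
    unknown: str = "error",
) -> list[int]:
    """Map a sequence through :func:`kmerize` and the vocabulary.

    ``unknown='error'`` (default) raises on a k-mer absent from the
    vocabulary; ``unknown='zero'`` emits the unknown id 0.
    """
    out: list[int] = []
    for pos, kmer in enumerate(kmerize(sequence, k=vocab.k, stride=stride)):
        idx = vocab.index_of.get(kmer)
        if idx is None:
            if unknown == "error":
                raise TokenizationError(
                    f"k-mer {kmer!r} at position {pos} is not in the vocabulary"
                )
            idx = PAD_ID
        out.append(idx)
    return out


@dataclass
class TokenizedDataset:
    """Padded token matrix plus per-row true lengths and optional labels."""

    tokens: np.ndarray  # (n, max_len) int32, post-padded with 0
    lengths: np.ndarray  # (n,) int32
    labels: Optional[np.ndarray]  # (n,) int8 or None
    vocab: Vocabulary
    ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.tokens.shape[0]


def encode_dataset(
    records: Sequence[SequenceRecord],
    vocab: Vocabulary,
    stride: int = 1,
    *,
    unknown: str = "error",
) -> TokenizedDataset:
    """Tokenize records into a post-padded integer matrix.

    Rows are padded with 0 to the longest tokenized length in the
    collection; the label vector (if every record is labelled) stays
    aligned with the rows.
    """
    token_lists: list[list[int]] = []
    for rec in records:
        try:
            token_lists.append(tokenize(rec.sequence, vocab, stride=stride, unknown=unknown))
        except (TokenizationError, ValueError) as exc:
            raise TokenizationError(f"record {rec.id!r}: {exc}") from exc
    lengths = np.array([len(t) for t in token_lists], dtype=np.int32)
    width = int(lengths.max()) if len(lengths) else 0
    tokens = np.zeros((len(token_lists), width), dtype=np.int32)
    for i, toks in enumerate(token_lists):
        tokens[i, : len(toks)] = toks
    labels_list = [rec.label for rec in records]
    labels = (
        np.array(labels_list, dtype=np.int8)
        if labels_list and all(l is not None for l in labels_list)
        else None
    )
    return TokenizedDataset(
        tokens=tokens,
        lengths=lengths,
        labels=labels,
        vocab=vocab,
        ids=[rec.id for rec in records],
    )


class KmerVectorizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer: DNA strings -> padded token matrices.

    Parameters
    ----------
    k : window length (overlapping windows, stride 1 by default).
    stride : step between windows.
    ordering : ``frequency_desc`` or ``lexicographic`` id assignment.
    unknown : ``error`` (strict) or ``zero`` (map unseen k-mers to id 0).
    """

    def __init__(self, k: int = 2, stride: int = 1, ordering: str = "frequency_desc",
                 unknown: str = "error"):
        self.k = k
        self.stride = stride
        self.ordering = ordering
        self.unknown = unknown

    @staticmethod
    def _sequences(X) -> list[str]:
        return [x.sequence if isinstance(x, SequenceRecord) else str(x) for x in X]

    def fit(self, X, y=None) -> "KmerVectorizer":
        self.vocabulary_ = build_vocabulary(
            self._sequences(X), k=self.k, stride=self.stride, ordering=self.ordering
        )
        return self

    def transform(self, X) -> np.ndarray:
        records = [
            x if isinstance(x, SequenceRecord) else SequenceRecord(id=f"x{i}", sequence=str(x))
            for i, x in enumerate(X)
        ]
        return self.encode(records).tokens

    def encode(self, records: Sequence[SequenceRecord]) -> TokenizedDataset:
        """Like :meth:`transform` but returning lengths/labels/ids as well."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "vocabulary_")
        return encode_dataset(
            records, self.vocabulary_, stride=self.stride, unknown=self.unknown
        )
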
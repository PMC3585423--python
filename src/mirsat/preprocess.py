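"""Pre-alignment processing of small RNA-seq reads.

A raw small-RNA library sequenced for a fixed number of cycles reads through
the short insert into the ligated 3' adapter.  Before any quantification the
reads therefore have to be (i) quality-checked, (ii) 3'-adapter clipped,
(iii) filtered for a minimum insert length, and (iv) collapsed to unique
sequences with multiplicities.  This module implements that pipeline stage.

Adapter clipping is exact-prefix based: a read is clipped at the leftmost
exact occurrence of the first ``min_overlap`` bases of the adapter.  Reads
that begin with the adapter carry no insert at all (adapter dimers) and are
discarded; reads in which no adapter seed occurs are retained unclipped.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_MIN_LEN = 18
DEFAULT_MIN_OVERLAP = 8
QC_MIN_MEAN_QUALITY = 28.0

_VALID_BASES = set("ACGTN")


@dataclass
class ReadRecord:
    """A single sequencing read: identifier, bases and phred+33 qualities."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )

    @property
    def phred_scores(self) -> np.ndarray:
        return np.frombuffer(self.quality.encode("ascii"), dtype=np.uint8).astype(int) - 33

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ClipReport:
    """Read-accounting for one pass of adapter clipping + length filtering.

    ``n_input == n_adapter_only + n_too_short + n_retained``; unclipped reads
    are retained and additionally counted in ``n_unclipped``.
    """

    n_input: int = 0
    n_adapter_only: int = 0
    n_too_short: int = 0
    n_unclipped: int = 0
    n_retained: int = 0

    def validate(self) -> None:
        if self.n_input != self.n_adapter_only + self.n_too_short + self.n_retained:
            raise ValueError(f"inconsistent clip report: {self}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


@dataclass
class QCReport:
    """Per-position mean quality, read-length histogram and a pass flag.

    The library passes QC iff the mean phred score at every cycle is at
    least Q28 (inclusive).
    """

    n_reads: int
    per_position_mean: np.ndarray
    length_histogram: dict[int, int]
    passed: bool
    failing_positions: list[int] = field(default_factory=list)


@dataclass
class CollapsedReadSet:
    """Unique sequences with multiplicities, in canonical order.

    Canonical order is descending multiplicity, ties broken lexicographically
    by sequence, so two collapses of permuted inputs compare equal.
    """

    sequences: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.sequences) != len(self.counts):
            raise ValueError("sequences and counts must have equal length")
        if np.any(self.counts <= 0):
            raise ValueError("multiplicities must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def items(self) -> Iterator[tuple[str, int]]:
        return zip(self.sequences, (int(c) for c in self.counts))

    def __len__(self) -> int:
        return len(self.sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CollapsedReadSet):
            return NotImplemented
        return self.sequences == other.sequences and np.array_equal(self.counts, other.counts)

    def to_fasta(self, path: str | Path) -> None:
        """Write in the ``>seqN_xCOUNT`` dialect used by collapsed-read mappers."""
        with open(path, "w") as fh:
            for i, (seq, count) in enumerate(self.items()):
                fh.write(f">seq{i}_x{count}\n{seq}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load a phred+33 FASTQ file into memory."""
    with open(path) as fh:
        return [ReadRecord(title.split()[0], seq, qual)
                for title, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def qc_summary(reads: Sequence[ReadRecord], min_mean_quality: float = QC_MIN_MEAN_QUALITY) -> QCReport:
    """Summarise per-cycle quality and read lengths; flag libraries below Q28.

    Raises ``ValueError`` naming the offending record if any read has
    mismatched sequence/quality lengths (checked on construction, re-checked
    here for records built by other code paths).
    """
    if not reads:
        return QCReport(0, np.array([]), {}, True, [])
    max_len = 0
    for r in reads:
        if len(r.sequence) != len(r.quality):
            raise ValueError(f"read {r.id!r}: sequence/quality length mismatch")
        max_len = max(max_len, len(r))
    qsum = np.zeros(max_len)
    qn = np.zeros(max_len, dtype=np.int64)
    lengths: Counter[int] = Counter()
    for r in reads:
        scores = r.phred_scores
        qsum[: len(scores)] += scores
        qn[: len(scores)] += 1
        lengths[len(r)] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(qn > 0, qsum / np.maximum(qn, 1), np.nan)
    failing = [int(i) for i in np.nonzero(means < min_mean_quality)[0]]
    return QCReport(
        n_reads=len(reads),
        per_position_mean=means,
        length_histogram=dict(sorted(lengths.items())),
        passed=not failing,
        failing_positions=failing,
    )


ClipStatus = Literal["clipped", "adapter_only", "unclipped"]


def clip_adapter(
    read: ReadRecord,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[ClipStatus, ReadRecord]:
    """Clip a read at the leftmost exact occurrence of the adapter seed.

    The seed is the first ``min_overlap`` bases of the adapter; ``N`` bases in
    the read never match it.  A seed at position 0 means the read is an
    adapter dimer (``adapter_only``); no seed at all (including a terminal
    partial adapter shorter than the seed) leaves the read ``unclipped`` but
    retained.  Quality strings are truncated in lockstep with the sequence.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require 1 <= min_overlap <= len(adapter)")
    pos = read.sequence.find(adapter[:min_overlap])
    if pos == 0:
        return "adapter_only", ReadRecord(read.id, "", "")
    if pos < 0:
        return "unclipped", read
    return "clipped", ReadRecord(read.id, read.sequence[:pos], read.quality[:pos])


def filter_length(
    reads: Iterable[ReadRecord], min_len: int = DEFAULT_MIN_LEN
) -> tuple[list[ReadRecord], int]:
    """Drop reads shorter than ``min_len``; return survivors and the drop count."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept, dropped = [], 0
    for r in reads:
        if len(r) >= min_len:
            kept.append(r)
        else:
            dropped += 1
    return kept, dropped


def preprocess_reads(
    reads: Sequence[ReadRecord],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[list[ReadRecord], ClipReport]:
    """Full pre-alignment filter: clip, drop dimers, enforce minimum length.

    Returns the post-clipped read set together with a :class:`ClipReport`
    whose counts conserve the input total.
    """
    report = ClipReport(n_input=len(reads))
    retained: list[ReadRecord] = []
    for r in reads:
        status, clipped = clip_adapter(r, adapter=adapter, min_overlap=min_overlap)
        if status == "adapter_only":
            report.n_adapter_only += 1
            continue
        if status == "unclipped":
            report.n_unclipped += 1
        if len(clipped) >= min_len:
            retained.append(clipped)
        else:
            report.n_too_short += 1
    report.n_retained = len(retained)
    report.validate()
    return retained, report


def collapse_reads(reads: Iterable[ReadRecord | str]) -> CollapsedReadSet:
    """Collapse identical sequences into (sequence, multiplicity) pairs."""
    counter: Counter[str] = Counter(
        r.sequence if isinstance(r, ReadRecord) else r for r in reads
    )
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if not ordered:
        return CollapsedReadSet((), np.array([], dtype=np.int64))
    seqs, counts = zip(*ordered)
    return CollapsedReadSet(tuple(seqs), np.array(counts, dtype=np.int64))
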
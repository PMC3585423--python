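"""Assignment of post-clipped reads to mature miRNAs and count generation.

Reads are matched to the mature reference with a single-substitution (SNV)
tolerance and a bounded 3' length window, reflecting how short-read miRNA
quantifiers behave: the 5' end of a mature miRNA is the anchor (it is
templated by Drosha/Dicer processing and rarely varies), while the 3' end is
frequently trimmed or extended (isomiRs).  A read whose 5' anchor matches a
mature sequence but whose 3' end falls outside the tolerance is tallied in a
separate "others" (isomiR) ledger and is *not* counted as mapped.  Reads
matching neither the mature reference nor the structured-ncRNA / repeat
decoy references are unclassified.

Matching is a 5'-anchored Hamming comparison rather than full local
alignment: with a global one-substitution budget, no indels inside the
insert, and a reference whose sequences are well separated, the two are
equivalent, and the anchored comparison is deterministic and fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import CollapsedReadSet, ReadRecord, collapse_reads

logger = logging.getLogger(__name__)

DEFAULT_MAX_SNV = 1
DEFAULT_THREE_PRIME_WINDOW = 2
_ANCHOR_LEN = 16  # 5' anchor length used for the isomiR ("others") test

ASSIGN_CATEGORIES = ("mature", "others_isomir", "ncrna", "repeat", "unclassified")


@dataclass(frozen=True)
class Assignment:
    """Where one (unique) sequence went during alignment."""

    sequence: str
    category: str
    ids: tuple[str, ...]          # candidate ids (mature) or single decoy id
    n_mismatches: int             # substitutions of the best match (-1 if none)
    three_prime_offset: int       # len(read) - len(reference) of the best match


@dataclass
class CountTable:
    """Counts per (miRNA, sample) with per-sample mapped library sizes.

    ``library_sizes`` defaults to the column sums of ``counts`` (the mapped
    totals); the separate ``others`` table keeps the per-miRNA isomiR
    tallies out of the mapped counts.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None
    others: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            raise ValueError("library_sizes must cover every sample column")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="miRNA")


@dataclass
class CompositionReport:
    """Breakdown of post-clipped reads into assignment categories.

    ``fractions`` sum to one over post-clipped reads.  The mature-mapped
    fraction excludes the isomiR "others" reads, which are reported as their
    own category.
    """

    counts: dict[str, int]
    fractions: dict[str, float] = field(init=False)
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.counts.values())
        denom = max(self.total, 1)
        self.fractions = {k: v / denom for k, v in self.counts.items()}


class ReadAligner:
    """Vectorised 5'-anchored matcher with an assignment cache.

    Compares each query against every reference over their common 5' prefix,
    counting substitutions; a mature hit needs at most ``max_snv``
    substitutions and an absolute 3' length offset of at most
    ``three_prime_window``.  Queries failing only the 3'/substitution
    tolerance but matching a 5' anchor (<= 1 substitution in the first 16 nt)
    are isomiR "others"; remaining queries are tested against the ncRNA and
    repeat decoy references with the mature tolerance, and fall through to
    "unclassified".
    """

    def __init__(
        self,
        ref,
        ncrna: Sequence[tuple[str, str]] = (),
        repeat: Sequence[tuple[str, str]] = (),
        max_snv: int = DEFAULT_MAX_SNV,
        three_prime_window: int = DEFAULT_THREE_PRIME_WINDOW,
    ) -> None:
        if len(ref) == 0:
            raise ValueError("empty mature reference")
        self.ref = ref
        self.max_snv = int(max_snv)
        self.window = int(three_prime_window)
        self._mature = self._pack(list(zip(ref.ids, ref.sequences)))
        self._decoys = [("ncrna", self._pack(list(ncrna))), ("repeat", self._pack(list(repeat)))]
        self._cache: dict[str, Assignment] = {}

    @staticmethod
    def _pack(entries: list[tuple[str, str]]):
        if not entries:
            return None
        ids = np.array([e[0] for e in entries])
        lens = np.array([len(e[1]) for e in entries])
        width = int(lens.max())
        mat = np.full((len(entries), width), 255, dtype=np.uint8)
        for i, (_, seq) in enumerate(entries):
            mat[i, : len(seq)] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return ids, lens, mat

    def _match_block(self, pack, block: np.ndarray, lengths: np.ndarray):
        """Mismatch counts over the common prefix, anchor mismatches, offsets."""
        ids, rlens, rmat = pack
        width = rmat.shape[1]
        neq = block[:, None, :width] != rmat[None, :, :]
        cums = np.cumsum(neq, axis=2)
        ov = np.minimum(lengths[:, None], rlens[None, :])
        mism = np.take_along_axis(cums, (ov - 1)[:, :, None], axis=2)[:, :, 0]
        anchor = np.minimum(_ANCHOR_LEN, ov)
        amism = np.take_along_axis(cums, (anchor - 1)[:, :, None], axis=2)[:, :, 0]
        offs = lengths[:, None] - rlens[None, :]
        return ids, mism, amism, offs

    def assign(self, sequences: Iterable[str], chunk: int = 512) -> list[Assignment]:
        """Assign each sequence (cached across calls)."""
        sequences = list(sequences)
        todo = sorted({s for s in sequences if s not in self._cache})
        for start in range(0, len(todo), chunk):
            self._assign_chunk(todo[start:start + chunk])
        return [self._cache[s] for s in sequences]

    def assign_one(self, sequence: str) -> Assignment:
        return self.assign([sequence])[0]

    def _assign_chunk(self, seqs: list[str]) -> None:
        if not seqs:
            return
        width = max(self._mature[2].shape[1],
                    max((p[2].shape[1] for _, p in self._decoys if p is not None),
                        default=0))
        lengths = np.array([len(s) for s in seqs])
        block = np.zeros((len(seqs), width), dtype=np.uint8)
        for i, s in enumerate(seqs):
            enc = np.frombuffer(s[:width].encode("ascii"), dtype=np.uint8)
            block[i, : len(enc)] = enc

        ids, mism, amism, offs = self._match_block(self._mature, block, lengths)
        mature_ok = (np.abs(offs) <= self.window) & (mism <= self.max_snv)
        anchor_ok = amism <= 1
        decoy_hits = []
        for cat, pack in self._decoys:
            if pack is None:
                decoy_hits.append((cat, None))
                continue
            dids, dmism, _, doffs = self._match_block(pack, block, lengths)
            decoy_hits.append((cat, (dids, (np.abs(doffs) <= self.window) & (dmism <= self.max_snv), dmism, doffs)))

        for i, s in enumerate(seqs):
            hit = np.nonzero(mature_ok[i])[0]
            if hit.size:
                order = sorted(hit, key=lambda j: (mism[i, j], abs(offs[i, j]), ids[j]))
                best = order[0]
                self._cache[s] = Assignment(
                    s, "mature", tuple(ids[j] for j in order),
                    int(mism[i, best]), int(offs[i, best]))
                continue
            anc = np.nonzero(anchor_ok[i])[0]
            if anc.size:
                best = min(anc, key=lambda j: (amism[i, j], abs(offs[i, j]), ids[j]))
                self._cache[s] = Assignment(
                    s, "others_isomir", (ids[best],),
                    int(amism[i, best]), int(offs[i, best]))
                continue
            for cat, payload in decoy_hits:
                if payload is None:
                    continue
                dids, dok, dmism, doffs = payload
                dhit = np.nonzero(dok[i])[0]
                if dhit.size:
                    best = min(dhit, key=lambda j: (dmism[i, j], abs(doffs[i, j]), dids[j]))
                    self._cache[s] = Assignment(
                        s, cat, (dids[best],), int(dmism[i, best]), int(doffs[i, best]))
                    break
            else:
                self._cache[s] = Assignment(s, "unclassified", (), -1, 0)


def align_read(
    sequence: str,
    ref,
    ncrna: Sequence[tuple[str, str]] = (),
    repeat: Sequence[tuple[str, str]] = (),
    max_snv: int = DEFAULT_MAX_SNV,
    three_prime_window: int = DEFAULT_THREE_PRIME_WINDOW,
) -> Assignment:
    """One-shot assignment of a single sequence (builds a throwaway aligner)."""
    aligner = ReadAligner(ref, ncrna=ncrna, repeat=repeat, max_snv=max_snv,
                          three_prime_window=three_prime_window)
    return aligner.assign_one(sequence)


def resolve_multimappers(
    assignments: Iterable[tuple[tuple[str, ...], float]],
    policy: str = "uniform",
    all_ids: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> pd.Series:
    """Distribute (candidate-ids, weight) pairs to per-miRNA counts.

    discard
        reads with more than one candidate contribute nothing.
    uniform
        a read with k candidates contributes 1/k to each.
    em
        expectation-maximisation: shared reads are allocated proportionally
        to current abundance estimates, iterated to a fixed point (max
        absolute change < ``tol`` or ``max_iter`` sweeps).  A connected
        component with no uniquely mapping reads has no usable gradient and
        falls back to uniform allocation (logged).

    Total allocated mass is conserved for uniform and em.
    """
    if policy not in ("discard", "uniform", "em"):
        raise ValueError(f"unknown multimapper policy {policy!r}")
    items = [(tuple(ids), float(w)) for ids, w in assignments]
    for ids, _ in items:
        if not ids:
            raise ValueError("every assignment must list at least one candidate id")
    universe: list[str] = list(all_ids) if all_ids is not None else sorted(
        {i for ids, _ in items for i in ids})
    out = pd.Series(0.0, index=universe)

    if policy == "discard":
        for ids, w in items:
            if len(ids) == 1:
                out[ids[0]] += w
        return out
    if policy == "uniform":
        for ids, w in items:
            share = w / len(ids)
            for i in ids:
                out[i] += share
        return out

    # EM: operate per connected component of the id-sharing graph
    index = {mid: j for j, mid in enumerate(universe)}
    parent = list(range(len(universe)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ids, _ in items:
        r = find(index[ids[0]])
        for other in ids[1:]:
            parent[find(index[other])] = r

    unique_mass = np.zeros(len(universe))
    comp_has_unique: dict[int, bool] = {}
    for ids, w in items:
        if len(ids) == 1:
            unique_mass[index[ids[0]]] += w
    for ids, _ in items:
        root = find(index[ids[0]])
        comp_has_unique.setdefault(root, False)
    for j in range(len(universe)):
        root = find(j)
        if root in comp_has_unique and unique_mass[j] > 0:
            comp_has_unique[root] = True

    est = unique_mass.copy()
    shared = [(np.array([index[i] for i in ids]), w) for ids, w in items if len(ids) > 1]
    bad_components = {root for root, has in comp_has_unique.items() if not has}
    if bad_components:
        logger.warning(
            "EM fallback to uniform in %d component(s) with no uniquely mapping reads",
            len(bad_components))
    # initialise shared mass uniformly so zero-abundance starts can move
    alloc = est.copy()
    for idxs, w in shared:
        alloc[idxs] += w / len(idxs)
    for _ in range(max_iter):
        new = unique_mass.copy()
        for idxs, w in shared:
            if find(int(idxs[0])) in bad_components:
                new[idxs] += w / len(idxs)
                continue
            probs = alloc[idxs]
            total = probs.sum()
            if total <= 0:
                new[idxs] += w / len(idxs)
            else:
                new[idxs] += w * probs / total
        delta = np.abs(new - alloc).max()
        alloc = new
        if delta < tol:
            break
    return pd.Series(alloc, index=universe)


def compute_rpm(counts: pd.Series | Mapping[str, float], library_size: float) -> pd.Series:
    """Reads-per-million: count / mapped total * 1e6."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    s = pd.Series(counts, dtype=float)
    return s / float(library_size) * 1e6


def detection_set(counts: pd.Series | Mapping[str, float], threshold: float = 1) -> set[str]:
    """miRNA ids detected with at least ``threshold`` counts."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    s = pd.Series(counts, dtype=float)
    return set(s.index[s >= threshold])


def composition_breakdown(
    assignments: Iterable[tuple[Assignment, float]]
) -> CompositionReport:
    """Category breakdown over (assignment, multiplicity) pairs."""
    counts = {cat: 0 for cat in ASSIGN_CATEGORIES}
    for a, w in assignments:
        counts[a.category] += int(w)
    return CompositionReport(counts)


@dataclass
class QuantResult:
    """Quantification of one post-clipped library."""

    counts: pd.Series                 # mapped counts per miRNA (full reference index)
    others: pd.Series                 # isomiR "others" tallies per miRNA
    composition: CompositionReport
    mapped_total: float
    assignments: pd.DataFrame         # unique sequence, multiplicity, category, ids

    def rpm(self) -> pd.Series:
        return compute_rpm(self.counts, self.mapped_total)


def quantify(
    reads: CollapsedReadSet | Sequence[ReadRecord],
    ref,
    decoys=None,
    max_snv: int = DEFAULT_MAX_SNV,
    three_prime_window: int = DEFAULT_THREE_PRIME_WINDOW,
    policy: str = "uniform",
    aligner: ReadAligner | None = None,
) -> QuantResult:
    """Quantify a post-clipped library against a mature reference.

    ``decoys`` (any object with ``ncrna`` / ``repeat`` attributes of
    (id, sequence) pairs) enables classification of the non-miRNA read
    classes; without them unmatched reads are simply unclassified.  Passing
    a pre-built ``aligner`` re-uses its cache across calls — the per-read
    assignment is independent of the surrounding library, so quantifying a
    subsample through a shared aligner is exact, not an approximation.
    """
    pool = reads if isinstance(reads, CollapsedReadSet) else collapse_reads(reads)
    if aligner is None:
        aligner = ReadAligner(
            ref,
            ncrna=getattr(decoys, "ncrna", ()) if decoys is not None else (),
            repeat=getattr(decoys, "repeat", ()) if decoys is not None else (),
            max_snv=max_snv,
            three_prime_window=three_prime_window,
        )
    assigns = aligner.assign(pool.sequences)
    pairs = list(zip(assigns, (float(c) for c in pool.counts)))

    mature_items = [(a.ids, w) for a, w in pairs if a.category == "mature"]
    counts = resolve_multimappers(mature_items, policy=policy, all_ids=list(aligner.ref.ids))
    others = pd.Series(0.0, index=list(aligner.ref.ids))
    for a, w in pairs:
        if a.category == "others_isomir":
            others[a.ids[0]] += w
    composition = composition_breakdown(pairs)
    table = pd.DataFrame({
        "sequence": [a.sequence for a, _ in pairs],
        "multiplicity": [int(w) for _, w in pairs],
        "category": [a.category for a, _ in pairs],
        "ids": [",".join(a.ids) for a, _ in pairs],
        "n_mismatches": [a.n_mismatches for a, _ in pairs],
        "three_prime_offset": [a.three_prime_offset for a, _ in pairs],
    })
    return QuantResult(counts, others, composition, float(counts.sum()), table)
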
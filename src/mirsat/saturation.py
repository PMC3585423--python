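"""Depth-of-coverage analyses: detection saturation and correlation adequacy.

Two resampling procedures answer the practical question "how deep do I need
to sequence this sample type?":

* a *detection curve* subsamples the post-clipped read pool at increasing
  depths, quantifies each subsample, and counts the miRNAs detected with at
  least 1, 3, 5, 10 and 50 reads — the number of *newly* detected miRNAs
  per depth increment shrinks as the library saturates;
* a *correlation curve* subsamples the mapped reads at increasing depths and
  reports the Spearman rank correlation between each subsampled expression
  profile and the full-depth profile — once the correlation plateaus,
  additional depth no longer changes the ranking of miRNAs.

Subsampling is uniform without replacement at the individual-read level
(multivariate hypergeometric), which preserves the library's abundance
distribution.  Within one seeded run the subsamples are nested (the depth-d
sample is a subset of every deeper sample), so "new detections" are
well-defined and non-negative; independent draws are available via
:func:`subsample_reads`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import CollapsedReadSet
from .quantify import ReadAligner, detection_set, resolve_multimappers

DEFAULT_THRESHOLDS = (1, 3, 5, 10, 50)


@dataclass
class SaturationResult:
    """Detected and newly detected miRNA counts per depth and threshold."""

    depths: list[int]
    detected: pd.DataFrame        # index depth, columns threshold
    new_detected: pd.DataFrame    # first row equals the first depth's detected
    seed: int


@dataclass
class CorrelationResult:
    """Spearman rho of the subsampled profile against the full profile."""

    depths: list[int]
    rho: pd.Series                # index depth
    seed: int


class _NestedSampler:
    """Nested without-replacement subsampler over a multiset of items.

    A single seeded permutation of the expanded pool is drawn once; the
    depth-n subsample is its first n elements, so shallower subsamples are
    subsets of deeper ones and each is marginally a uniform simple random
    sample (multivariate hypergeometric counts).
    """

    def __init__(self, counts: np.ndarray, seed: int) -> None:
        self.counts = np.asarray(counts, dtype=np.int64)
        self.total = int(self.counts.sum())
        rng = np.random.default_rng(seed)
        self._perm = rng.permutation(np.repeat(np.arange(len(self.counts)), self.counts))

    def counts_at(self, n: int) -> np.ndarray:
        if not 0 <= n <= self.total:
            raise ValueError(f"subsample size {n} outside [0, {self.total}]")
        return np.bincount(self._perm[:n], minlength=len(self.counts))


def subsample_reads(pool: CollapsedReadSet, n: int, seed: int = 0) -> CollapsedReadSet:
    """Draw ``n`` reads uniformly without replacement from a collapsed pool."""
    sampler = _NestedSampler(pool.counts, seed)
    sub = sampler.counts_at(n)
    keep = sub > 0
    seqs = tuple(s for s, k in zip(pool.sequences, keep) if k)
    return CollapsedReadSet(seqs, sub[keep])


def detection_curve(
    pool: CollapsedReadSet,
    aligner: ReadAligner,
    start: int = 500_000,
    step: int = 1_000_000,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    seed: int = 0,
    policy: str = "uniform",
    nested: bool = True,
) -> SaturationResult:
    """Detection-saturation curve over a post-clipped read pool.

    Starting at ``start`` reads and adding ``step`` reads per increment (up
    to the pool total, which is always included as the final depth), each
    subsample is quantified through ``aligner`` and the number of miRNAs
    with at least t counts is recorded for every threshold t.  With
    ``nested=True`` (default) subsamples are cumulative; otherwise each
    depth is an independent draw (new-detection counts may then be
    negative and are reported as raw differences).
    """
    if pool.total < start:
        raise ValueError(f"pool of {pool.total} reads is smaller than start={start}")
    thresholds = sorted(thresholds)
    depths = list(range(start, pool.total + 1, step))
    if depths[-1] != pool.total:
        depths.append(pool.total)

    assigns = aligner.assign(pool.sequences)
    all_ids = list(aligner.ref.ids)
    sampler = _NestedSampler(pool.counts, seed)
    detected = pd.DataFrame(index=depths, columns=thresholds, dtype=int)
    for di, depth in enumerate(depths):
        sub = (sampler.counts_at(depth) if nested
               else _NestedSampler(pool.counts, seed + 7919 * (di + 1)).counts_at(depth))
        items = [(a.ids, float(c)) for a, c in zip(assigns, sub)
                 if c > 0 and a.category == "mature"]
        counts = resolve_multimappers(items, policy=policy, all_ids=all_ids)
        for t in thresholds:
            detected.loc[depth, t] = len(detection_set(counts, t))
    detected = detected.astype(int)
    new = detected.diff()
    new.iloc[0] = detected.iloc[0]
    return SaturationResult(depths, detected, new.astype(int), seed)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises ``ValueError`` for unequal lengths, fewer than two points, or a
    constant vector (for which the rank correlation is undefined) rather
    than returning NaN silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation is undefined for a constant vector")
    return float(scipy.stats.spearmanr(x, y).statistic)


def correlation_curve(
    mapped_counts: pd.Series | Mapping[Hashable, int],
    step: int = 100_000,
    max_depth: int | None = None,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation-adequacy curve over a mapped-read pool.

    ``mapped_counts`` is the full-depth per-miRNA mapped-read multiset.  At
    each depth (multiples of ``step`` up to ``max_depth``, default the full
    pool) the nested subsample's profile is correlated (Spearman) with the
    ``max_depth`` profile over the miRNAs detected at ``max_depth``, with
    zeros imputed for miRNAs missing from the subsample.  The final depth is
    always ``max_depth`` itself, where rho is exactly 1.
    """
    full = pd.Series(mapped_counts, dtype=np.int64)
    total = int(full.sum())
    if max_depth is None:
        max_depth = total
    if max_depth > total:
        raise ValueError(f"max_depth {max_depth} exceeds pool total {total}")
    if step > max_depth:
        raise ValueError("step must not exceed max_depth")
    depths = list(range(step, max_depth + 1, step))
    if depths[-1] != max_depth:
        depths.append(max_depth)
    sampler = _NestedSampler(full.to_numpy(), seed)
    reference = sampler.counts_at(max_depth)
    support = reference > 0
    ref_profile = reference[support]
    rhos = []
    for depth in depths:
        sub = sampler.counts_at(depth)[support]
        if depth == max_depth:
            rhos.append(1.0)    # identical profiles by construction
        else:
            rhos.append(spearman_rho(sub, ref_profile))
    return CorrelationResult(depths, pd.Series(rhos, index=depths), seed)


def detection_overlap(sets: Mapping[str, Iterable[Hashable]]) -> dict[tuple[str, ...], int]:
    """Partition counts for 2 or 3 named detection sets (Venn regions).

    Returns a mapping from the sorted tuple of set names an id belongs to
    (exactly) to the number of such ids; region counts sum to the union size.
    """
    named = {name: set(s) for name, s in sets.items()}
    if not 2 <= len(named) <= 3:
        raise ValueError("detection_overlap supports exactly 2 or 3 sets")
    names = sorted(named)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        from itertools import combinations

        for combo in combinations(names, r):
            inside = set.intersection(*(named[n] for n in combo))
            outside = set.union(*(named[n] for n in names if n not in combo), set())
            regions[combo] = len(inside - outside)
    return regions
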
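"""Synthetic small RNA-seq libraries with a per-read ground-truth ledger.

Real miRNA-seq libraries are a mixture of read categories: inserts from
mature miRNAs (with 3' isomiR variation and occasional base-call errors),
structured non-coding RNA fragments (rRNA/tRNA/snoRNA families), repeat
elements, unclassifiable sequence, and insert-free adapter dimers.  Only a
fraction of the reads that survive preprocessing map to mature miRNAs —
around 68% for skeletal muscle and around 21% for blood plasma — and the
per-miRNA abundance distribution has a long right tail, so detection of new
miRNAs saturates slowly with sequencing depth.

This module generates FASTQ libraries with exactly that structure and emits
a ledger recording each read's true category, source miRNA and edits, so
that every downstream stage (clipping, quantification, saturation analysis,
differential expression) can be validated against known truth.

Layout of every simulated read (``read_length`` cycles, default 50):

    insert + 3' adapter + random padding        (miRNA / decoy categories)
    adapter + random padding                    (adapter dimers)

Composition profiles are parameterised so that the category fractions among
*post-clipped* reads (dimers removed) match the stated targets; the
adapter-dimer fraction applies to raw reads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_ADAPTER, ReadRecord
from .quantify import CountTable

_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

MIN_MATURE_LEN = 18
MAX_MATURE_LEN = 25
#: minimum 5'-prefix Hamming distance enforced between distinct reference
#: sequences (and between decoys and references) so that single-substitution
#: matching is unambiguous by construction
MIN_REFERENCE_SEPARATION = 3
_DECOY_SEPARATION = 4
_PREFIX = 18  # separation is enforced on the first 18 nt (the minimum insert)

CATEGORIES = ("mirna", "ncrna", "repeat", "unclassified", "adapter_dimer")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# references and decoys
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatureReference:
    """A set of mature miRNA sequences (ids unique, 18-25 nt, ACGT)."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("reference ids must be unique")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("duplicate mature sequences in reference")
        for mid, seq in self.entries:
            if not seq or set(seq) - set(_BASES):
                raise ValueError(f"{mid}: sequence must be non-empty over ACGT")
            if not MIN_MATURE_LEN <= len(seq) <= MAX_MATURE_LEN:
                raise ValueError(
                    f"{mid}: mature length {len(seq)} outside "
                    f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
                )

    @property
    def entries(self) -> Iterator[tuple[str, str]]:
        return zip(self.ids, self.sequences)

    def __len__(self) -> int:
        return len(self.ids)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for mid, seq in self.entries:
                fh.write(f">{mid}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MatureReference":
        """Load mature sequences, normalising RNA (U) to DNA (T) alphabet."""
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper().replace("U", "T"))
        return cls(tuple(ids), tuple(seqs))


def build_reference(
    n_mirnas: int,
    length_range: tuple[int, int] = (20, 24),
    seed: int = 0,
    min_distance: int = MIN_REFERENCE_SEPARATION,
    max_tries_per_entry: int = 500,
) -> MatureReference:
    """Draw ``n_mirnas`` random mature sequences with guaranteed separation.

    Every pair of accepted sequences differs by at least ``min_distance``
    substitutions over their common 5' prefix, so assignment with a
    single-SNV tolerance is unambiguous by construction.  Raises
    ``ValueError`` if the requested separation cannot be achieved within the
    per-entry rejection budget (no silent retry loop).
    """
    lo, hi = length_range
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if not (MIN_MATURE_LEN <= lo <= hi <= MAX_MATURE_LEN):
        raise ValueError(f"length_range must lie within [{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    prefix_mat = np.empty((0, _PREFIX), dtype=np.uint8)
    while len(accepted) < n_mirnas:
        for attempt in itertools.count():
            if attempt >= max_tries_per_entry:
                raise ValueError(
                    f"cannot place sequence {len(accepted) + 1}/{n_mirnas} at "
                    f"pairwise distance >= {min_distance} within "
                    f"{max_tries_per_entry} tries; relax the separation or "
                    f"widen the length range"
                )
            length = int(rng.integers(lo, hi + 1))
            cand = "".join(_BASES[b] for b in rng.integers(0, 4, length))
            cand_pref = _encode(cand[:_PREFIX])
            if prefix_mat.size and int((prefix_mat != cand_pref).sum(axis=1).min()) < min_distance:
                continue
            accepted.append(cand)
            prefix_mat = np.vstack([prefix_mat, cand_pref])
            break
    width = len(str(n_mirnas))
    ids = tuple(f"syn-miR-{i + 1:0{width}d}" for i in range(n_mirnas))
    return MatureReference(ids, tuple(accepted))


@dataclass(frozen=True)
class DecoyPools:
    """Category-specific decoy sequences for the non-miRNA read classes.

    Each decoy is kept at 5'-prefix Hamming distance >= 4 from every mature
    sequence and from decoys of the other pools, so the true category of a
    simulated read (even one carrying a sequencing error) is unambiguous.
    The ``unclassified`` pool is deliberately *not* part of any reference
    handed to the quantifier — that is what makes those reads unclassifiable.
    """

    ncrna: tuple[tuple[str, str], ...]
    repeat: tuple[tuple[str, str], ...]
    unclassified: tuple[tuple[str, str], ...]

    def pool(self, category: str) -> tuple[tuple[str, str], ...]:
        return getattr(self, category)


def build_decoys(
    ref: MatureReference,
    n_ncrna: int = 150,
    n_repeat: int = 60,
    n_unclassified: int = 300,
    length_range: tuple[int, int] = (19, 24),
    seed: int = 0,
) -> DecoyPools:
    """Generate the three decoy pools for a given mature reference."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    taken = np.array([_encode(s[:_PREFIX]) for s in ref.sequences], dtype=np.uint8)
    pools: dict[str, list[tuple[str, str]]] = {}
    for label, n_pool in (("ncRNA", n_ncrna), ("repeat", n_repeat), ("unk", n_unclassified)):
        entries: list[tuple[str, str]] = []
        while len(entries) < n_pool:
            for attempt in itertools.count():
                if attempt >= 1000:  # astronomically unlikely for random 18-mers
                    raise ValueError("cannot separate decoy pools from the reference")
                length = int(rng.integers(lo, hi + 1))
                cand = "".join(_BASES[b] for b in rng.integers(0, 4, length))
                pref = _encode(cand[:_PREFIX])
                if int((taken != pref).sum(axis=1).min()) < _DECOY_SEPARATION:
                    continue
                entries.append((f"{label}-{len(entries) + 1:04d}", cand))
                taken = np.vstack([taken, pref])
                break
        pools[label] = entries
    return DecoyPools(tuple(pools["ncRNA"]), tuple(pools["repeat"]), tuple(pools["unk"]))


# ---------------------------------------------------------------------------
# abundances and composition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbundanceProfile:
    """Relative abundance per miRNA id; weights sum to one."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if vals.size == 0:
            raise ValueError("abundance profile must be non-empty")
        if np.any(vals < 0):
            raise ValueError("abundance weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {vals.sum()}, expected 1")

    def aligned_to(self, ref: MatureReference) -> np.ndarray:
        """Weight vector in reference order; ids must be a subset of the reference."""
        missing = set(self.weights) - set(ref.ids)
        if missing:
            raise ValueError(f"profile ids absent from reference: {sorted(missing)[:5]}")
        return np.array([self.weights.get(mid, 0.0) for mid in ref.ids])


def simulate_abundances(
    ref: MatureReference,
    shape: float = 3.0,
    seed: int = 0,
    law: str = "lognormal",
) -> AbundanceProfile:
    """Draw a long-tailed abundance profile over the reference.

    ``law='lognormal'`` (default) draws weights proportional to
    ``exp(shape * Z)`` with standard-normal Z; ``shape`` is the log-scale
    sigma.  The default sigma of 3.0 produces the strongly skewed profiles
    typical of tissue small-RNA libraries, where a handful of miRNAs carry
    most of the reads and a large tail sits near the detection limit.
    ``law='powerlaw'`` assigns weight proportional to ``rank**-shape`` over a
    random permutation of the ids.
    """
    if shape <= 0:
        raise ValueError("shape must be > 0")
    n = len(ref)
    rng = np.random.default_rng(seed)
    if law == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=shape, size=n)
    elif law == "powerlaw":
        ranks = rng.permutation(n) + 1
        raw = ranks.astype(float) ** -shape
    else:
        raise ValueError(f"unknown abundance law {law!r}")
    w = raw / raw.sum()
    return AbundanceProfile(dict(zip(ref.ids, w)))


@dataclass(frozen=True)
class CompositionProfile:
    """Fractions of raw reads per category; the five fields sum to one.

    ``f_adapter_dimer`` is the insert-free dimer fraction of raw reads; the
    other four fields are scaled so that, conditional on not being a dimer
    (i.e. among post-clipped reads), the category fractions equal the
    stated targets — see :meth:`muscle_like` and :meth:`plasma_like`.
    """

    f_mirna: float
    f_ncrna: float
    f_repeat: float
    f_unclassified: float
    f_adapter_dimer: float

    def __post_init__(self) -> None:
        for f in self.as_tuple():
            if not 0.0 <= f <= 1.0:
                raise ValueError("composition fractions must lie in [0, 1]")
        if abs(sum(self.as_tuple()) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.f_mirna, self.f_ncrna, self.f_repeat,
                self.f_unclassified, self.f_adapter_dimer)

    def postclip_fractions(self) -> dict[str, float]:
        """Category fractions among reads that survive dimer removal."""
        rest = 1.0 - self.f_adapter_dimer
        return {
            "mirna": self.f_mirna / rest,
            "ncrna": self.f_ncrna / rest,
            "repeat": self.f_repeat / rest,
            "unclassified": self.f_unclassified / rest,
        }

    @classmethod
    def from_postclip(
        cls, mirna: float, ncrna: float, repeat: float, adapter_dimer: float
    ) -> "CompositionProfile":
        unclassified = 1.0 - mirna - ncrna - repeat
        if unclassified < 0:
            raise ValueError("post-clip fractions exceed 1")
        scale = 1.0 - adapter_dimer
        return cls(mirna * scale, ncrna * scale, repeat * scale,
                   unclassified * scale, adapter_dimer)

    @classmethod
    def muscle_like(cls, adapter_dimer: float = 0.05) -> "CompositionProfile":
        """Skeletal-muscle-like library: 68% miRNA, 7% ncRNA, 3% repeat
        among post-clipped reads, small dimer contamination."""
        return cls.from_postclip(0.68, 0.07, 0.03, adapter_dimer)

    @classmethod
    def plasma_like(cls, adapter_dimer: float = 0.10) -> "CompositionProfile":
        """Blood-plasma-like library: 21% miRNA, 25% ncRNA, 0.21% repeat
        among post-clipped reads, heavier dimer contamination."""
        return cls.from_postclip(0.21, 0.25, 0.0021, adapter_dimer)


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Per-library simulation settings.

    isomir_rate
        probability that a miRNA read carries a 3' edit (trim of 1-3 nt,
        bounded so the insert stays >= 18 nt, or extension of 1-5 random nt).
    snv_rate
        probability that a read carries one substitution (a base-call error).
    low_quality_tail
        number of final cycles written at Q20 instead of Q35, for testing
        the QC gate; 0 (default) writes constant Q35.
    """

    n_reads: int
    adapter: str = DEFAULT_ADAPTER
    isomir_rate: float = 0.05
    snv_rate: float = 0.02
    read_length: int = 50
    seed: int = 0
    low_quality_tail: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        for r in (self.isomir_rate, self.snv_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.read_length < MIN_MATURE_LEN + 1:
            raise ValueError(
                f"read_length {self.read_length} shorter than the shortest "
                f"insert + 1 ({MIN_MATURE_LEN + 1})"
            )


@dataclass
class SimulatedLibrary:
    """One simulated FASTQ library plus its per-read truth ledger.

    The ledger has one row per read: ``read_id``, true ``category``,
    ``source_id`` (miRNA or decoy id, '.' for dimers), ``edits`` (';'-joined
    ``trim:N`` / ``ext:N:BASES`` / ``snv:POS:X>Y`` tokens, '.' if none) and
    the true post-clip ``insert`` sequence.
    """

    reads: list[ReadRecord]
    ledger: pd.DataFrame
    decoys: DecoyPools

    def write(self, fastq_path: str | Path, ledger_path: str | Path | None = None) -> None:
        from .preprocess import write_fastq

        write_fastq(self.reads, fastq_path)
        if ledger_path is not None:
            self.ledger.to_csv(ledger_path, sep="\t", index=False)


def _library_rng(seed: int, stream: int = 0) -> np.random.Generator:
    """Per-library substream: the global seed fans out via SeedSequence keys."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _quality_string(cfg: SimConfig) -> str:
    high = chr(35 + 33)
    if cfg.low_quality_tail <= 0:
        return high * cfg.read_length
    tail = min(cfg.low_quality_tail, cfg.read_length)
    return high * (cfg.read_length - tail) + chr(20 + 33) * tail


def _materialize(
    rng: np.random.Generator,
    ref: MatureReference,
    decoys: DecoyPools,
    cfg: SimConfig,
    cat_codes: np.ndarray,
    mir_idx: np.ndarray,
    read_prefix: str = "read",
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Assemble reads from pre-drawn categories and miRNA assignments.

    ``cat_codes`` indexes :data:`CATEGORIES`; ``mir_idx`` lists the source
    miRNA for the miRNA-category reads in order of appearance.
    """
    n = len(cat_codes)
    L = cfg.read_length
    qual = _quality_string(cfg)
    mat_seqs = ref.sequences
    mat_ids = ref.ids
    pools = {1: decoys.ncrna, 2: decoys.repeat, 3: decoys.unclassified}

    # pre-draw all randomness in a fixed order (seed => byte-identical output)
    n_mir = int((cat_codes == 0).sum())
    u_iso = rng.random(n_mir) < cfg.isomir_rate
    etype = rng.integers(0, 2, n_mir)          # 0 = trim, 1 = extend
    trim_u = rng.random(n_mir)                 # scaled to the per-miRNA trim cap
    ext_amt = rng.integers(1, 6, n_mir)
    ext_bases = rng.integers(0, 4, (n_mir, 5))
    u_snv = rng.random(n) < cfg.snv_rate
    snv_u = rng.random(n)
    snv_shift = rng.integers(1, 4, n)
    decoy_pick = rng.random(n)
    pad_pool = _BASE_ARR[rng.integers(0, 4, n * 36 + 64)].tobytes().decode()

    reads: list[ReadRecord] = []
    rows: list[tuple[str, str, str, str, str]] = []
    adapter = cfg.adapter
    base_index = {b: i for i, b in enumerate(_BASES)}
    k = 0       # miRNA-read cursor
    p = 0       # padding-pool cursor
    for i in range(n):
        code = int(cat_codes[i])
        cat = CATEGORIES[code]
        edits: list[str] = []
        if code == 0:
            j = int(mir_idx[k])
            insert = mat_seqs[j]
            source = mat_ids[j]
            if u_iso[k]:
                cap = min(3, len(insert) - MIN_MATURE_LEN)
                if etype[k] == 0 and cap > 0:
                    amt = 1 + int(trim_u[k] * cap)
                    insert = insert[:-amt]
                    edits.append(f"trim:{amt}")
                else:
                    amt = int(ext_amt[k])
                    ext = "".join(_BASES[b] for b in ext_bases[k, :amt])
                    insert = insert + ext
                    edits.append(f"ext:{amt}:{ext}")
            k += 1
        elif code == 4:
            insert = ""
            source = "."
        else:
            pool = pools[code]
            source, insert = pool[int(decoy_pick[i] * len(pool))]
        if insert and u_snv[i]:
            pos = int(snv_u[i] * len(insert))
            old = insert[pos]
            new = _BASES[(base_index[old] + int(snv_shift[i])) % 4]
            insert = insert[:pos] + new + insert[pos + 1:]
            edits.append(f"snv:{pos}:{old}>{new}")
        body = insert + adapter
        if len(body) < L:
            need = L - len(body)
            body += pad_pool[p:p + need]
            p += need
        seq = body[:L]
        rid = f"{read_prefix}{i:07d}"
        reads.append(ReadRecord(rid, seq, qual))
        rows.append((rid, cat, source, ";".join(edits) or ".", insert))
    ledger = pd.DataFrame(rows, columns=["read_id", "category", "source_id", "edits", "insert"])
    return reads, ledger


def simulate_library(
    ref: MatureReference,
    profile: AbundanceProfile,
    comp: CompositionProfile,
    cfg: SimConfig,
    decoys: DecoyPools | None = None,
    rng: np.random.Generator | None = None,
    read_prefix: str = "read",
) -> SimulatedLibrary:
    """Simulate one library of exactly ``cfg.n_reads`` reads.

    Categories are drawn i.i.d. from ``comp``; miRNA reads draw their source
    from ``profile`` and may carry a 3' isomiR edit and/or one substitution;
    decoy-category reads draw from category-specific pools kept well apart
    from the reference; adapter-dimer reads start with the adapter at
    position 0.  Passing ``decoys`` explicitly lets several libraries (and
    the quantifier) share the same pools; otherwise pools are derived
    deterministically from ``cfg.seed``.
    """
    weights = profile.aligned_to(ref)
    if decoys is None:
        decoys = build_decoys(ref, seed=cfg.seed + 10_007)
    if rng is None:
        rng = _library_rng(cfg.seed)
    n = cfg.n_reads
    cat_codes = rng.choice(len(CATEGORIES), size=n, p=list(comp.as_tuple()))
    n_mir = int((cat_codes == 0).sum())
    mir_idx = rng.choice(len(ref), size=n_mir, p=weights) if n_mir else np.array([], dtype=int)
    reads, ledger = _materialize(rng, ref, decoys, cfg, cat_codes, mir_idx, read_prefix)
    return SimulatedLibrary(reads, ledger, decoys)


# ---------------------------------------------------------------------------
# two-group experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentTruth:
    """Design truth for a two-group experiment.

    ``log2_fc`` maps miRNA id -> injected log2 fold change (group 2 relative
    to group 1); miRNAs absent from the map are true nulls (log2FC = 0).
    ``dispersion`` is the negative-binomial dispersion phi of the
    gamma-mixed-Poisson replicate noise; 0 degenerates to Poisson.
    """

    n_per_group: int = 9
    log2_fc: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _group_weights(
    ref: MatureReference, baseline: AbundanceProfile, truth: ExperimentTruth
) -> tuple[np.ndarray, np.ndarray]:
    w1 = baseline.aligned_to(ref)
    missing = set(truth.log2_fc) - set(ref.ids)
    if missing:
        raise ValueError(f"fold change on miRNAs absent from reference: {sorted(missing)[:5]}")
    support = {mid for mid, w in zip(ref.ids, w1) if w > 0}
    dead = set(truth.log2_fc) - support
    if dead:
        raise ValueError(f"fold change on miRNAs absent from baseline: {sorted(dead)[:5]}")
    fc = np.array([2.0 ** truth.log2_fc.get(mid, 0.0) for mid in ref.ids])
    w2 = w1 * fc
    return w1, w2 / w2.sum()


def _nb_counts(rng: np.random.Generator, lam: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-mixed Poisson draws: mean ``lam``, variance ``lam + phi*lam**2``."""
    if phi <= 0:
        return rng.poisson(lam)
    mix = rng.gamma(shape=1.0 / phi, scale=phi, size=lam.shape)
    return rng.poisson(lam * mix)


@dataclass
class SimulatedExperiment:
    """2 x n simulated libraries plus the injected-truth table."""

    libraries: dict[str, SimulatedLibrary]
    groups: dict[str, str]            # sample name -> group label
    truth: ExperimentTruth
    truth_table: pd.DataFrame         # miRNA, log2_fc, weight_group1/2, is_de
    decoys: DecoyPools


def simulate_experiment(
    ref: MatureReference,
    baseline: AbundanceProfile,
    truth: ExperimentTruth,
    comp: CompositionProfile,
    cfg: SimConfig,
    decoys: DecoyPools | None = None,
    group_names: tuple[str, str] = ("group1", "group2"),
) -> SimulatedExperiment:
    """Simulate a two-group experiment of ``2 * truth.n_per_group`` libraries.

    Group 2's expected abundance of miRNA i is the baseline scaled by
    ``2**log2_fc[i]`` and renormalised.  Per-library per-miRNA read counts
    are gamma-mixed Poisson with dispersion ``truth.dispersion``; the
    non-miRNA categories are Poisson around their composition expectations.
    Each library gets its own seed substream fanned out from ``cfg.seed``.
    """
    w1, w2 = _group_weights(ref, baseline, truth)
    if decoys is None:
        decoys = build_decoys(ref, seed=cfg.seed + 10_007)
    lam_mir = cfg.n_reads * comp.f_mirna
    other_codes = [1, 2, 3, 4]
    other_lams = np.array([comp.f_ncrna, comp.f_repeat, comp.f_unclassified,
                           comp.f_adapter_dimer]) * cfg.n_reads

    libraries: dict[str, SimulatedLibrary] = {}
    groups: dict[str, str] = {}
    for li in range(2 * truth.n_per_group):
        g = li // truth.n_per_group
        sample = f"{group_names[g]}_{li % truth.n_per_group + 1}"
        rng = _library_rng(cfg.seed, stream=li + 1)
        w = w1 if g == 0 else w2
        mir_counts = _nb_counts(rng, lam_mir * w, truth.dispersion)
        other_counts = rng.poisson(other_lams)
        cat_codes = np.concatenate(
            [np.zeros(mir_counts.sum(), dtype=int)]
            + [np.full(c, code, dtype=int) for code, c in zip(other_codes, other_counts)]
        )
        cat_codes = rng.permutation(cat_codes)
        mir_idx = rng.permutation(np.repeat(np.arange(len(ref)), mir_counts))
        reads, ledger = _materialize(rng, ref, decoys, cfg, cat_codes, mir_idx,
                                     read_prefix=f"{sample}:read")
        libraries[sample] = SimulatedLibrary(reads, ledger, decoys)
        groups[sample] = group_names[g]
    truth_table = pd.DataFrame({
        "miRNA": ref.ids,
        "log2_fc": [truth.log2_fc.get(mid, 0.0) for mid in ref.ids],
        "weight_group1": w1,
        "weight_group2": w2,
    })
    truth_table["is_de"] = truth_table["log2_fc"] != 0.0
    return SimulatedExperiment(libraries, groups, truth, truth_table, decoys)


def simulate_count_experiment(
    ref: MatureReference,
    baseline: AbundanceProfile,
    truth: ExperimentTruth,
    mean_mapped_reads: int = 100_000,
    seed: int = 0,
    group_names: tuple[str, str] = ("group1", "group2"),
) -> tuple[CountTable, list[str]]:
    """Directly simulate the mapped count table of a two-group experiment.

    Skips read materialisation and quantification: per-sample per-miRNA
    counts are drawn from the same gamma-mixed Poisson model that
    :func:`simulate_experiment` uses for the miRNA category, with expected
    library depth ``mean_mapped_reads``.  Returns the count table and the
    per-sample group labels (in column order).
    """
    w1, w2 = _group_weights(ref, baseline, truth)
    rng = np.random.default_rng(seed)
    cols, labels = {}, []
    for li in range(2 * truth.n_per_group):
        g = li // truth.n_per_group
        sample = f"{group_names[g]}_{li % truth.n_per_group + 1}"
        w = w1 if g == 0 else w2
        cols[sample] = _nb_counts(rng, mean_mapped_reads * w, truth.dispersion)
        labels.append(group_names[g])
    counts = pd.DataFrame(cols, index=list(ref.ids))
    return CountTable(counts), labels
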
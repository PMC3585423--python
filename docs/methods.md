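# Methods

This note documents the models behind `mirsat`, the defaults that matter,
what the simulator does and does not emulate, and the numerical choices
made where several conventions exist.

## The synthetic-library model

A simulated library is a multinomial mixture of five read categories:
mature-miRNA inserts, structured-ncRNA decoys, repeat decoys, unclassified
decoys, and insert-free adapter dimers. Every non-dimer read is laid out as
`insert + 3' adapter + random padding`, truncated to the read length
(default 50 cycles), so preprocessing sees realistic adapter read-through;
dimer reads start with the adapter at cycle 0. Qualities are constant Q35
(`low_quality_tail` degrades the final cycles to Q20 for QC testing).

**Composition.** The muscle-like and plasma-like profiles encode the
category mix observed in tissue versus cell-free libraries: among reads
that survive dimer removal, muscle is 68% miRNA / 7% structured ncRNA /
3% repeat / 22% unclassified, and plasma is 21% / 25% / 0.21% / 53.79%.
Because published composition figures are quoted over *post-clipped* reads,
the constructors scale the four insert categories by (1 − dimer fraction)
so those post-clip percentages hold exactly in expectation. The dimer
fraction itself is a library-prep property no composition figure pins
down; the defaults (5% muscle, 10% plasma — dimers are worse when input
RNA is scarce) are engineering choices, stated here once.

**Abundances.** Per-miRNA weights are drawn log-normally with σ = 3.0
(configurable; a rank-power law is available via `law="powerlaw"`).
Tissue miRNA profiles are extremely skewed — a handful of miRNAs carry the
majority of reads while a large tail sits near the detection limit — and
σ = 3.0 reproduces that regime: across seeds, the top 10 of 300 miRNAs
hold > 50% of the mass while ≥ 20% of miRNAs fall below 1/(10·n). This
long tail is what makes detection saturate slowly with depth.

**Edits.** With probability `isomir_rate` (default 0.05) a miRNA read
carries a 3' edit: a trim of 1–3 nt (capped so the insert stays ≥ 18 nt
and survives the length filter) or an extension of 1–5 random nt, equally
likely. With probability `snv_rate` (default 0.02) any read carries one
substitution at a uniform position. Edits of ≤ 2 nt stay inside the
quantifier's counting window; larger ones land in the isomiR "others"
ledger, which is why a 5% isomiR rate yields an "others" fraction of
roughly 1–2% of post-clipped reads — inside the 1–12% band reported for
real muscle libraries, and the reason the recovered mature fraction sits
~1.4 points below the nominal 68%.

**Separation guarantees.** Reference sequences are rejection-sampled so
every pair differs at ≥ 3 positions over the common 5' prefix, making
single-SNV assignment unambiguous by construction; decoys keep a prefix
distance ≥ 4 from all matures and from each other's pools, so even a
decoy read carrying a simulated SNV cannot fall within the mature
tolerance. The unclassified pool is never handed to the quantifier —
that is what makes those reads unclassifiable. Impossible separation
requests fail loudly rather than looping.

**Experiments.** Two-group designs default to 9 replicates per group.
Group 2's expected abundances are the baseline scaled by 2^log2FC and
renormalised; per-library per-miRNA counts are gamma-mixed Poisson with
dispersion φ (Var = μ + φμ²; φ = 0 is Poisson). One global seed fans out
to per-library substreams through `numpy` `SeedSequence` spawn keys, so a
fixed configuration is byte-identical on rerun.
`simulate_count_experiment` draws the mapped count table directly from the
same model, skipping read materialisation, for statistical studies where
the FASTQ round-trip adds nothing.

**What the simulator does not emulate:** indels and multi-error reads,
position-dependent or motif-dependent base-call error, ligation bias,
PCR duplicates, instrument artifacts (phasing, cluster density), hairpin
precursors, and genuine cross-mapping families of near-identical miRNAs
(references are well separated by design). Tests passing on this
generator therefore certify the pipeline's logic and calibration under a
clean mixture model, not its behaviour on adversarial real data — in
particular, real multi-mapping is far heavier than the simulated domain's.

## Preprocessing

Clipping searches for the leftmost exact occurrence of the adapter's
first `min_overlap` = 8 bases; `N` never matches. Exact-seed matching is
used deliberately: mismatch-tolerant clipper behaviour differs between
tool versions, whereas the exact rule is reproducible and sufficient when
errors are single substitutions (an errored seed simply shifts the match
into the following adapter copy or leaves the read unclipped). A seed at
position 0 marks an adapter dimer (removed); no seed leaves the read
retained and flagged unclipped — retention is the conservative choice, and
the quantifier classifies such reads on their own merits. The accounting
invariant `input = adapter_only + too_short + retained` is enforced on
every run. By chance ~0.03% of inserts contain the 8-mer seed internally
and are over-clipped; this is inherent to seed-based clipping and is why
ledger-consistency tests exclude those reads.

## Quantification

Matching is 5'-anchored Hamming comparison over the common prefix with a
global budget of `max_snv` = 1 substitution and a 3' offset window of
±2 nt. This replaces full local alignment on purpose: with a
one-substitution budget, no indels inside inserts, and a separated
reference, anchored comparison is equivalent on the simulated domain,
deterministic, and vectorisable. The mature/others boundary at ±2 nt is
configurable because published quantifiers display the "others" ledger
without stating their numeric tolerance. A read is "others" when some
mature anchor matches with ≤ 1 mismatch in the first 16 nt but the full
tolerance fails; the tally is attributed to the best-anchored miRNA.
Reference FASTA input normalises U to T on load.

Multi-mapper policy defaults to `uniform` (deterministic); `em` iterates
expected allocation proportional to current abundance estimates to a
fixed point (tolerance 1e-8, cap 500 sweeps), falling back to uniform
inside connected components with no uniquely mapping reads (logged), and
`discard` drops shared reads. Uniform and EM conserve total mapped mass.
Counts stay fractional through quantification and are rounded half-to-even
only at the differential-expression boundary, where the exact test needs
integers.

## Saturation and correlation

Subsampling draws reads (not miRNAs) uniformly without replacement, so
each subsample's per-sequence counts are multivariate hypergeometric and
the library's abundance distribution is preserved. One seeded permutation
per run makes the depth-d subsample a subset of every deeper one
("nested"); nesting is what makes per-increment new-detection counts
well-defined and non-negative, and an independent-draw mode exists behind
a flag. Detection curves default to a 500,000-read start and million-read
increments with thresholds {1, 3, 5, 10, 50}; the final pool depth is
always included. The correlation curve compares each nested subsample
against the full-depth profile over the miRNAs detected at full depth,
imputing zeros for the subsample (support choice documented because the
alternative union/intersection supports change tie handling); rank
correlation makes counts-vs-RPM irrelevant at fixed depth. Rho at full
depth is exactly 1 by construction, and the constant-vector case raises
instead of returning NaN. Tests and examples run these analyses at
2–3.5 M-read pool sizes with 250–400 k-read steps, which preserves every
qualitative property of the deeper defaults.

## Differential expression

TMM factors follow the classic recipe: reference sample = the one whose
upper-quartile of scaled counts is closest to the mean upper quartile;
genes zero in either sample excluded; 30% two-sided trim on M, 5% on A;
inverse-asymptotic-variance weights; factors rescaled to geometric mean 1.
Median-of-ratios size factors take the per-sample linear-space median of
ratios to the gene-wise geometric mean over all-nonzero genes.

The common dispersion is a pooled method-of-moments estimator: counts are
scaled to the geometric mean N₀ of effective library sizes, and
φ̂ = max(0, Σ(s² − m) / Σ m²) over (gene, group) cells with positive mean
and ≥ 2 replicates. It recovers injected dispersions within ±0.05 at the
300-gene, 9 + 9 scale and degenerates cleanly to 0 on Poisson data; a
design with no replicated group raises, since φ is then unidentifiable.

The exact test scales both groups to N₀, rounds half-to-even, conditions
on each miRNA's total t, and uses the fact that with a common dispersion
and equal pseudo-sizes the group-A sum given t has a distribution free of
the mean (negative-binomial conditional; binomial when φ = 0). The
two-sided p sums the probabilities of all outcomes no more probable than
the observed one — the minimum-likelihood convention, fixed here because
conventions differ. log2FC = log2(mean₂ + 0.5) − log2(mean₁ + 0.5) on
normalised means; the 0.5 pseudo-count guarantees finiteness at zeros and
exact antisymmetry under group swap, and is never used in testing.
Equalising to the geometric mean makes p-values invariant to rescaling
any one library *up to* the common N₀ drift of c^(1/m) plus integer
rounding; the tests assert that form of the invariance.

`run_differential_expression` optionally drops miRNAs with mean raw count
below `min_mean_count` (pipeline default 5) before testing: under the
long-tailed abundance law a large share of miRNAs have expected counts
near zero, where the conditional test is so discrete that no outcome can
reach p ≤ 0.05; filtering them is standard practice and keeps the FDR
adjustment from being diluted by uninformative features. BH adjustment is
the step-up procedure (delegated to statsmodels), flags at α = 0.05.
A Welch (default) or pooled two-sample t test is provided for validating
count summaries against external measurements; the degenerate
zero-variance, equal-means case returns p = 1 by convention rather than
NaN.

## Known limitations

Single common dispersion (no tagwise/trended shrinkage) makes the test
anticonservative for genes far more variable than the pool; two-group
designs only; the anchored matcher does not model indels or 5' isomiRs;
saturation analysis does not extrapolate beyond the observed pool
(no Chao-type richness estimation); and calibration statements are
established on the simulator's clean mixture model, as discussed above.
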
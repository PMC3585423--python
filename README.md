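# mirsat

Small RNA-seq analysis for mature miRNA profiling: adapter preprocessing,
SNV-tolerant quantification with isomiR accounting, depth-of-coverage
saturation and correlation-adequacy analysis, and count-based two-group
differential expression — together with a synthetic-library generator that
emits a per-read ground-truth ledger, so every stage can be validated
against known truth.

## Who this is for

Groups planning or analysing miRNA sequencing experiments face a set of
recurring questions before any biology happens: what fraction of reads will
actually map to mature miRNAs for a given sample type (tissue libraries
commonly reach ~68%, cell-free plasma ~21%, with the rest going to
structured ncRNA, repeats, unclassifiable sequence and adapter dimers);
how many reads are needed before miRNA detection saturates; whether a
cheap, shallow library already represents the sample's expression ranking;
and how to call differential expression from overdispersed counts with FDR
control. `mirsat` packages those analyses as a plain Python library with a
thin `mirsat` CLI on top, and — because public raw data for this design is
scarce — a simulator that reproduces the statistical structure of real
libraries (mixed read categories, long-tailed abundances, 3' isomiRs,
single-base call errors, adapter read-through) with every read's truth
recorded.

## The methods in brief

* **Preprocessing.** Reads are clipped at the leftmost exact occurrence of
  the 3' adapter seed (`TGGAATTCTCGGGTGCCAAGG`, first 8 nt); reads that
  begin with the adapter are insert-free dimers and are removed; clipped
  reads shorter than 18 nt are removed; survivors are collapsed to unique
  sequences with multiplicities. QC passes when every cycle's mean quality
  is ≥ Q28.
* **Quantification.** A read maps to a mature miRNA when a 5'-anchored
  comparison finds at most one substitution (SNV) and a 3' length offset
  within ±2 nt. Reads matching a 5' anchor but violating the 3'/SNV
  tolerance are isomiR "others": tallied per miRNA, never counted as
  mapped. Multi-mapping reads are split uniformly, discarded, or
  redistributed by EM, by choice. RPM_i = count_i / mapped_total × 10⁶.
* **Saturation.** Nested subsampling without replacement (multivariate
  hypergeometric) of the post-clipped pool, quantified at each depth, with
  detected-miRNA counts at thresholds {1, 3, 5, 10, 50} and per-increment
  new detections; and Spearman rank correlation of subsampled mapped
  profiles against the full-depth profile.
* **Differential expression.** TMM (doubly trimmed, inverse-variance
  weighted mean of M-values) or median-of-ratios normalisation; pooled
  method-of-moments common NB dispersion φ (Var = μ + φμ²); a conditional
  exact test on group sums at equalised library sizes (exactly binomial at
  φ = 0); Benjamini–Hochberg FDR at 0.05.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/02_quantify_composition.py` simulates a 50,000-read muscle-like
library, preprocesses and quantifies it:

```
library composition (fraction of post-clipped reads):
  mature         66.56%
  ncrna           6.96%
  others_isomir   1.36%
  repeat          3.02%
  unclassified   22.10%
mapped reads: 31591; isomiR 'others' reads: 645 (not counted as mapped)

top miRNAs by RPM (reads per million mapped):
  syn-miR-232         306416 RPM  (9680 reads)
  syn-miR-292         152037 RPM  (4803 reads)
  syn-miR-106          93159 RPM  (2943 reads)
```

The mature-mapped fraction recovers the muscle-like 68% target (minus the
~1.4% of miRNA reads whose 3' isomiR edits fall outside the counting
window — exactly the "others" behaviour real quantifiers show), the decoy
categories land on their 7%/3% targets, and the RPM column is the mapped
counts rescaled to a million. The other examples cover simulation and
preprocessing accounting (`01`), saturation and correlation curves (`03`),
and differential expression with injected fold changes (`04`), e.g.:

```
significant at BH-FDR 0.05 (4 miRNAs):
             log2_fc  p_value  p_adjusted  significant
syn-miR-256  -2.1832      0.0         0.0         True
syn-miR-231   2.0835      0.0         0.0         True
...
true positives: 4/4; false positives: 0
```

The same stages are scriptable from the shell:

```sh
mirsat simulate --profile muscle --n-reads 100000 --seed 1 --out sim/
mirsat preprocess sim/sample.fastq --out-fastq clipped.fastq --report clip.json
mirsat quantify sim/reference.fasta clipped.fastq --out-prefix sample
mirsat diffexp counts.tsv groups.tsv --norm tmm --out de.tsv
```

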
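# Methods

## Problem and model

At START, the G1 commitment point of the budding-yeast cell cycle, the
transcription factors MBF (Mbp1–Swi6) and SBF (Swi4–Swi6) activate the
G1/S regulon downstream of the cyclin Cln3.  Given a candidate list of
Cln3-responsive genes, the pipeline decides for each gene whether it is a
target of MBF, of SBF, of both, or of neither, by integrating nine
heterogeneous classifiers per factor:

1. wild-type induction peak time (categories 20/40/60/80 min),
2. wild-type log2 value at 20 min,
3. max(wt series) / max(*mbp1Δ* series) (Mbp1 only),
4. Pearson correlation of wt and *mbp1Δ* profiles (Mbp1 only in the
   "methods-text" preset; see Presets),
5. mean wt value at 40 and 60 min (Swi4 only),
6. max(wt at 20/40 min) / max(*swi4Δ* series) (Swi4 only),
7. induction upon Cln3 overexpression,
8. response upon Clb2 overexpression,
9. cell-cycle expression peak time (percent of cycle),

plus a consensus-motif classifier (MCB `ACGCGT` within 200 bp upstream of
the TSS for Mbp1; SCB `CRCGAA` within 400 bp for Swi4) and a binding
classifier summarizing four genome-wide ChIP-chip studies (none / one /
more than one study; for Swi4, a sole detection by the Swi4-rich study is
its own category because that study's SBF calls are the most reliable).

Scoring is naive additive.  Continuous classifiers are discretized into
four bins delimited by averaged order statistics: three random sets of 40
genes are drawn from the candidate list, each set is sorted within the
classifier, and the 10th/20th/30th ranked values are averaged across sets
to give the cuts (half-open bins, upper boundary inclusive).  Categorical
classifiers use their categories as bins.  Each (classifier, bin) receives

    LLS = ln( P(bin | positive) / P(bin | negative) )

with frequencies taken from training control sets, and a gene's score is
the sum of its nine bin weights.

## Controls, benchmarks, and cutoff selection

Training positives are genes called targets by *both* of two prior
classifications, excluding dual-regulated genes and targets of other
cell-cycle TFs, topped up from top-ranked single-study calls to 40 genes
for Mbp1 and 32 for Swi4; negatives merge five random draws of the same
size from unannotated genes.  Held-out evaluation uses two positive
benchmarks per factor (40 genes each: 10 dual-regulated + 30 single-TF
literature targets, disjoint from the training positives) and a negative
benchmark merging two draws of 40 (hence somewhat fewer than 80 genes
after de-duplication).

Sensitivity, specificity, precision, accuracy and the Matthews
correlation coefficient (MCC) are computed at every rank of the scored
list against each positive benchmark and combined across the two
benchmarks by geometric mean.  MCC is signed, so its geometric mean is
taken on the shifted scale (MCC+1)/2 and mapped back; the rate metrics
are combined directly.  The cutoff is the rank maximizing combined MCC
among ranks with accuracy ≥ 80%, precision ≥ 80% and specificity ≥ 90%
(ties resolved toward the larger, more sensitive rank).  If no rank is
feasible, the unconstrained MCC argmax is returned with a warning flag.
An alternative constraint preset ("materials-text": specificity and
precision ≥ 80%) is available.

## Numerical and design choices

- **Binning boundary rule.** bin1 = (−∞, t1], bin2 = (t1, t2],
  bin3 = (t2, t3], bin4 = (t3, ∞).  With degenerate thresholds
  (t1 = t2 = t3) every value lands in bin 1.
- **Smoothing.** P(bin|class) = (n + c)/(N + c·k) with pseudocount
  c = 0.5 by default and k the classifier's declared bin count; this
  keeps every weight finite regardless of control composition without
  materially distorting well-populated bins.  With c = 0, a bin
  unobserved in both classes carries weight 0, and a one-sided zero is an
  error.  N counts control genes with non-missing evidence for that
  classifier.
- **Missing evidence** contributes weight 0 (neutral), never exclusion:
  all candidates are scored even with undetermined cell-cycle peaks or
  absent mutant profiles.
- **Ratio features** on log2 data are unstable near zero; the denominator
  is floored at ε = 0.1 (configurable) before dividing — deterministic
  and monotone in the numerator.
- **cc_peak** is treated as continuous and binned by the random-subset
  procedure; this choice is recorded in artifact provenance headers.
- **Ranking ties** (equal total score) break lexicographically by
  systematic name, so outputs are platform-independent.
- **Motif coordinates.** Promoter position 1 is the base immediately
  upstream of the TSS; a match is counted when its entire span lies
  within positions 1..window, and "position" of an occurrence is its
  5'-most (most upstream) base.  Scanning is single-strand by design (a
  both-strands flag exists but defaults off).  The classifier uses the
  full MCB `ACGCGT`; the positional reporting analyses use the core
  `ACGCG`, matching how the two analyses are usually phrased; both are
  configurable.
- **Geometric-mean MCC shift.** The geometric mean of a signed quantity
  is ill-defined for negative values; the (m+1)/2 shift is the minimal
  monotone transform onto [0,1] and is inverted after combination.

## Presets

The Swi4 classifier roster is ambiguous between two readings of the
published score-matrix layout, so both ship, each with exactly nine
classifiers: `methods-text` (default) gives Swi4 {peak time, value at
20', 40–60' average, swi4Δ ratio, motif, binding, Cln3, Clb2, cc peak};
`file2-layout` replaces the 20' value with the wt/mbp1Δ correlation,
mirroring a score-matrix layout in which the correlation column is not
factor-specific.  Mbp1 is identical in both.

## Synthetic data

The generator reproduces the study design so the whole pipeline runs
with no external data: 445 candidates with 111 MBF and 94 SBF planted
targets (36 shared).  Defaults not fixed by the design were chosen once
as realistic for log2 microarray induction data:

- **Expression**: 4-point rise–peak–fall profiles (relative shape 1.0 /
  0.45 / 0.15 / 0.05 by distance from the peak timepoint), peak drawn
  from {20, 40, 60} min with probabilities 0.30/0.55/0.15, amplitude
  log-normal (median 2.0 log2 units, σ = 0.35), Gaussian noise
  sd = 0.25 on every value.  Attenuation: 1.0 in wild type; 0.15 in the
  cognate single deletion; 0.5 for shared targets in either single
  deletion; 0.05 in *swi6Δ* and *swi4Δ mbp1Δ*; 0 in the no-induction
  control and for all non-targets.
- **Binding**: per-study sensitivities 0.30–0.70 with the Swi4-rich
  study at 0.70 for Swi4 and the multi-condition study at 0.70 for Mbp1;
  false-positive rate 0.03 everywhere.
- **Promoters**: 1,000 bp, GC 0.38.  A proximal MCB is planted within
  200 bp for 65% of MBF targets vs 4.5% of background; a proximal SCB
  within 400 bp for 78% of SBF targets vs 33% of background; additional
  distal sites appear at rate 0.30 each so positional summaries have
  realistic far-zone mass.
- **Cell-cycle peaks**: MBF targets ~ N(20, 5) percent (unimodal early);
  SBF targets an equal mixture of N(25, 5) and N(40, 5) (bimodal);
  non-targets uniform, with 30% not cell-cycle regulated (missing peak)
  and 8% of targets undetermined.
- **Overexpression**: Cln3 response N(1.5, 0.5) for targets vs N(0, 0.4)
  background; Clb2 N(−0.5, 0.4) vs N(0, 0.4); 5% missing.
- **Prior literature**: two pseudo-classifications derived from truth
  with 10% label dropout and 15% non-target padding stand in for the two
  prior published target lists, so training controls and benchmarks are
  imperfect in the same way real literature-derived sets are.  Priors
  must be supersets of the truth lists or the benchmark construction
  (30 single-TF genes disjoint from 32 training positives for Swi4)
  becomes infeasible — hence the padding.  Training negatives exclude
  planted targets of the same factor by construction; benchmark
  negatives are drawn only from un-annotated genes and may therefore
  hide a dropped true target, as acknowledged for the real data.

What the generator does **not** emulate: array-level noise structure
(spatial artifacts, dye bias), correlated classifier errors (each
evidence channel errs independently here, which flatters a naive
additive model), stress-responsive confounders in the candidate list,
and promoter sequence composition beyond i.i.d. background with planted
consensus sites.  Passing recovery tests therefore shows the machinery
is correct and well-calibrated under the assumed structure, not that the
biological error rates of the original datasets are reproduced.

## Determinism and problem sizes

All sampling flows from one seed through `numpy.random.SeedSequence`
children in a fixed order (0 dataset, 1 controls/benchmarks, 2 binning),
so repeated runs are byte-identical and individual stages can be
replayed.  The test suite and the acceptance script use the default
445-gene design; seed sweeps use 20 replicate runs, which keeps the full
analysis under a minute on one CPU while leaving binomial sampling error
well inside the tested tolerances.

## Known limitations

- The nine-classifier naive sum ignores dependence between evidence
  channels (e.g. motif presence and binding calls are correlated in real
  promoters); weights are per-classifier marginals by design.
- Cutoff selection assumes the benchmark negatives are mostly correct;
  heavily contaminated benchmarks would bias the cutoff upward.
- Divergent-pair truth labels and functional class maps are consumed as
  input tables; the package does not curate them.
- Real-data mode expects the TSV/FASTA conventions described in the I/O
  module; spreadsheet-based supplementary layouts must be exported to
  TSV first.
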
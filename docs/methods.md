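# Methods

`consilience` implements two validation-centred consensus frameworks — one
for miRNA-target interaction (MTI) prediction, one for conformer-ensemble
virtual screening — plus the differential-expression and annotation filters
used to place candidate genes in a tissue context. This note records the
models, the tunable parameters, the numerical choices made where the design
was genuinely open, and what the synthetic generators do and do not emulate.

## Validation metrics

All validation reduces a strategy to a positive-prediction set scored
against a truth set of known-true and known-false items:

    ACC = 100 · (TP + TN) / (TP + FP + TN + FN)
    PPV = 100 · TP / (TP + FP)
    FPR = 100 · FP / (FP + TN)

PPV is reported as undefined (`None` in memory, `NA` in TSV, `null` in
JSON) when a strategy makes no positive call (TP + FP = 0), and FPR is
undefined when the truth set has no negatives. We deliberately do not coerce
undefined values to 0 or 100: a strategy with no positive calls can still
post the best accuracy, and treating its PPV as 0 would misorder strategy
comparisons. Undefined values sort last and are never flagged as winners.
Predicted items outside the truth universe are dropped with a logged
warning — evaluation is restricted to the labelled test set. Percentages
are rendered to 3 decimals in all outputs.

Ranked screens are summarised by the rank AUC

    AUC = 1 − (1 / (N_act · N_dec)) · Σ_i N_dec_better(i),

the probability that a random active outranks a random decoy. Ties credit
1/2 (the Mann–Whitney convention; no tie rule is published for this
statistic, so the standard one is used). `auc_rank` is computed from
average ranks; the ROC curve is built independently over all score
thresholds and its trapezoidal area agrees with the rank formula to 1e-9,
which the tests assert on random instances and by exhaustive all-pairs
enumeration for up to 8 scores per class.

## MTI consensus model

Per-program reliability thresholds:

| program      | rule                                   | reading |
|--------------|----------------------------------------|---------|
| microT-style | miTG score > 0.7                       | strict, as published |
| miRanda-style| mirSVR score ≤ −0.1                    | inclusive, as published |
| TargetScan-style | context+ score ≥ −1.67, ≥ 1 conserved site, optional P_CT floor | see below |

Two open points are resolved as explicit options. The published context+
rule reads "−1.67 or higher", although more negative context+ scores
conventionally mean stronger repression; the literal reading is the default
(`contextplus_direction="literal-paper"`) and the conventional one is
available as `"strong-repression"`. No P_CT threshold is published
("appropriate" value), so the default applies no P_CT filter and `pct_min`
makes it explicit when wanted.

The consensus model is the intersection of the per-program reliable sets
with already-known interactions subtracted. Validation builds disjoint
truth sets from two resources: pairs whose protein went **up** (log fold
change strictly > 0) under the miRNA's over-expression are known-false
(up-regulation contradicts targeting), and pairs with direct functional
evidence (reporter-gene-assay class codes, configurable) are known-true. A
pair qualifying for both is kept as true — direct experimental evidence
overrides a single proteomic fold change — and removed from the false set
with a logged count; some disjointness rule is required for the confusion
matrix to be well defined, and this is the package's own choice. miRNA
names are lower-cased and gene symbols upper-cased before any set
operation; no alias resolution is attempted.

The seven strategies compared are the three single programs, three pairwise
intersections and the triple intersection ("the model"). Because the triple
intersection is contained in every other strategy's positive set, its FP
count is provably minimal; the tests assert this on random instances.

## Ensemble screening model

Conformers exist only as columns of a (compound × conformer) score table
with a primary ("grid") and secondary ("re-rank") score per cell, lower =
better (a direction flag exists for higher-is-better reuse). Two-phase
ranking orders compounds by secondary score, then compounds lacking one by
primary score, then failed compounds, with lexicographic id tie-breaks for
determinism.

Numerical choices:

* **Top-fraction rounding is ceil** — `top 10%` of n compounds means
  ceil(0.1·n). No rounding rule is published; ceil guarantees a non-empty
  positive set for any n ≥ 1. A small epsilon guards the binary
  representation of q·n (so 0.3 · 10 counts as 3, not 4).
* **Failed docking**: a compound with no scores for a conformer ranks last
  there, still counts in the ranked length, and can never enter that
  conformer's top set. A failed docking is treated as evidence against
  binding, not as missing data; whether the original study excluded such
  compounds from denominators is unknowable from the published counts.
* **Valid conformers** must beat the reference structure *strictly on all
  three metrics simultaneously* (higher ACC, higher PPV, lower FPR) at the
  operative cutoff (default 10%); candidates with undefined PPV never
  qualify. The reference is always retained.
* **k-of-N consensus uses at-least-k semantics**, so hit sets are nested in
  k and FP/FPR are non-increasing in k by construction; "hits exactly k
  conformers" would not nest. k = N reproduces the all-valid-conformer
  model.

## Differential expression (SAM-style)

Raw intensities are log2-transformed and **median-centred per sample** —
the minimal assumption-free normalisation; the source protocol says only
"normalized". The per-gene statistic is

    d_i = (mean_2 − mean_1) / (s_i + s0)

with s_i the pooled standard error of the mean difference and **s0 the
median of all s_i** — a common simplification of SAM's quantile search for
the fudge constant, which is out of scope. The permutation null re-draws
the two-class labels: all C(n, n1) distinct assignments are enumerated when
there are at most `n_perm` of them (70 for a 4+4 design), otherwise
`n_perm` (default 200) are sampled from the given seed. Per-permutation s_i
are recomputed but s0 stays fixed at the observed value so the statistic's
scale is comparable across permutations. The FDR at a threshold delta is
the median over permutations of the null exceedance count divided by the
observed exceedance count; delta is searched on the exact grid of observed
|d| values (no plot-controller discretisation) and the smallest delta
meeting the bound (default 5%) is chosen. Flagged genes must additionally
change ≥ `min_fold` (default 2.0) in either direction. If no delta meets
the bound the significant set is empty with a logged notice — a legitimate
outcome on null data, not an error.

Context filtering intersects a candidate gene set with the union of the
differential gene sets (idempotent, monotone). Annotation terms are kept
when the raw hypergeometric upper-tail p is < 0.05 **and** fold enrichment
(k/n)/(K/N) is ≥ 2.0; no multiple-testing correction is applied beyond this
two-criterion rule, matching the filtering convention this pipeline
reproduces (an EASE-style adjusted p is not implemented).

## Synthetic generators

One seed drives independent sub-streams per generator
(`numpy.random.SeedSequence` spawn keys), so outputs are byte-identical
given the same configuration.

* **MTI tables**: each program's pass indicator comes from thresholding a
  Gaussian with a shared latent factor (`rho` = between-program
  correlation); a pair passes program p with probability sensitivity_p
  (true pairs) or 1 − specificity_p (false pairs). Scores are monotone
  piecewise maps of the Gaussian quantile, so threshold crossing matches
  the target probabilities exactly. With rho = 0 the triple intersection's
  sensitivity is s³ and FPR (1−p)³, which the tests verify within 3
  binomial standard errors at 2000 + 2000 pairs.
* **Docking scores**: secondary = μ_class + λ·z_compound + √(1−λ²)·ε with
  unit marginal variance; μ_active = Δ ≤ 0, μ_decoy = 0. Between-conformer
  score correlation is λ² and single-conformer AUC is Φ(|Δ|/√2) (verified
  within 3 Hanley–McNeil standard errors). The primary score adds
  independent noise (default sd 1.0), making the grid phase a weaker ranker
  than the re-rank phase, as a two-phase procedure presumes. Cells fail
  with probability φ, but every compound keeps ≥ 1 scored conformer.
  Default sizes mirror the study scale: 39 actives, 1448 decoys, 26
  conformers; defaults Δ = −1.0, λ = 0.5, φ = 0 are desk-scale choices
  giving a realistic mid-0.7 single-conformer AUC.
* **Expression**: baseline 8.0 log2 units + Gaussian noise (sd 0.25), a
  planted log2 effect of 2.0 in the first `n_de` genes of the treated
  class; 4 + 4 samples, 500 genes, 20 planted by default — the regime in
  which a 2-fold floor and 5% FDR are both attainable.
* **Annotations**: each universe gene belongs to one of 20 terms uniformly
  (universe 1000); the 50-gene study set is drawn without replacement with
  sampling weight 10 on the planted term's genes. The realised fold
  enrichment is attenuated below the weight by finite sampling (≈ 7–9),
  still far above the 2.0 floor.

What the generators do **not** emulate: docking-energy physics or
pose-level structure, miRNA seed-match biology, probe-level microarray
artefacts, and correlated annotation terms (real GO terms overlap; the
generated terms partition the universe). Passing tests therefore show that
the consensus, selection and filtering logic is correct under the stated
statistical models — not that the published external resources would be
reproduced.

## Problem sizes and determinism

The test suite runs the generators at the documented defaults
(39/1448 × 26, 2000 + 2000 pairs, 500 × 8 expression) and smaller toys for
exhaustive enumeration; everything is seeded, and hypothesis-based property
tests run derandomised. `scripts/acceptance.py` re-runs every stage from
scratch at those scales from a single `--seed` in well under a minute on
one CPU.

## Known limitations

* No alias/accession resolution in interaction integration — symbol-level
  dedup only.
* No bootstrap confidence intervals on AUC; no multi-class metrics.
* The SAM s0 is the median-s simplification, not the original quantile
  search; on very low-variance data the two can pick different constants.
* The published four-conformer screening metrics cannot be reconciled with
  integer confusion counts over exactly 39 + 1448 compounds (some compounds
  evidently failed docking there); this package makes its failed-docking
  rule explicit rather than guessing the original denominator.
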
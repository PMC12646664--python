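# Methods

## Model and procedure

The pipeline treats signature refinement as a per-gene screening problem.
Given a cohort of normalized log-scale expression with binary class labels
(control vs case, e.g. healthy vs IBD) and a parent signature whose genes
carry a cluster tag (reactive or tolerant), each parent gene is evaluated
as a single-gene monotone classifier:

- **AUC** — the Mann–Whitney pair statistic, computed from average ranks:
  `(Σ ranks_case − n₁(n₁+1)/2) / (n₁n₀)`. Ties contribute one half per
  pair; values above 0.5 mean case-high expression. This identity is the
  implementation; an independent brute-force pair count is the test
  oracle.
- **Accuracy** — `max(AUC, 1−AUC)`, so a strongly down-regulated gene is
  as good a classifier as an up-regulated one.
- **Direction** — up_in_case when AUC > 0.5, down_in_case when AUC < 0.5.
  An AUC of exactly 0.5 (within 1e-12) gives no regulation call and the
  gene can never be selected.
- **Dichotomization** — the expression vector is sorted and every split
  into a low and a high segment is scored by the summed squared error
  around the two segment means; the threshold is the midpoint of the two
  means at the best split. Squared-error ties are broken toward the more
  balanced split, then the smaller split index; a 1e-9 relative tolerance
  absorbs floating-point summation differences between algebraically
  equal splits. A median split is available as a configuration fallback.
- **Fisher exact test** — two-sided, on the (above / below-or-equal
  threshold) × class table. When every sample falls on one side of the
  threshold the table is uninformative and p is reported as 1 with a
  warning.

A gene is **selected** when accuracy ≥ `auc_min` (default 0.7) and Fisher
p ≤ `p_max` (default 0.05). Selection gates on raw p values by default;
Benjamini–Hochberg adjustment is available (`fdr=True`) but off, since
the procedure is defined on raw p. Selected genes are partitioned purely
by parent-cluster identity: reactive → iColAM, tolerant → niColAM. When a
selected gene's observed direction contradicts its cluster's expected
movement (reactive up in case, tolerant down), it keeps its cluster
assignment and is flagged `direction_conflict` in the audit table — the
partition is by cluster identity, and the conflict is surfaced rather
than silently resolved. Parent genes absent from the cohort are listed as
unscored, never dropped silently.

Single-gene classification here is deliberate: with one gene and no
held-out protocol, the ROC-AUC of the raw expression *is* the classifier,
and no cross-validation is performed. Composite-score classification of a
cohort uses the same AUC engine on the score, which coincides with
thresholded accuracy at perfect separation.

## Composite scores and temporal profiling

A sample's composite score for a gene set is the mean rank percentile of
member genes: per gene, samples are ranked (average ranks on ties) and
mapped to `(rank−1)/(n−1) ∈ [0,1]`; the per-gene percentiles are
averaged. Consequences used by the tests: a single-gene set's score is
that gene's percentile; any strictly monotone per-gene transform of the
matrix leaves scores unchanged; scores are bounded in [0, 1]. The iColAM
and niColAM scores are always reported separately, never combined into a
difference score; each set is internally unidirectional, so the score is
direction-less within a set. A weighted mean (e.g. weight = per-gene
accuracy) is available behind a parameter. Coverage — the fraction of set
genes found in the cohort — is always reported, with a warning below 0.5.

Cohort classification reports the score AUC, accuracy, a Welch two-sample
two-sided t test on raw scores, and the higher-scoring class; constant
scores yield AUC 0.5 and p 1 with a `degenerate_scores` flag. At three
samples per class (the smallest real design) a warning is emitted but the
computation proceeds.

Temporal profiling takes per-phase cohorts that share a control arm,
concatenates them on the common genes (shared control samples counted
once), and scores the combined matrix once so every phase sits on the
same rank scale — rank percentiles are cohort-relative, so scoring phases
separately would make their means incomparable. Per phase it reports the
mean score, a seeded percentile bootstrap CI (default 1000 resamples,
90%), and a Welch p against the control phase; the trend call per set is
the non-control phase of maximum mean score, with the control mean as the
reference baseline.

## Candidate prioritization

Three evidence layers, applied as sequential filters and ranked
lexicographically (not as a weighted sum, because the screening logic
applies them in order):

1. **Interactome overlay** — pure set algebra between the signature and
   named interactor lists. A gene in exactly one list is a *unique*
   (list-specific) interactor; genes in several lists are reported but
   non-specific. Order-independent and idempotent.
2. **Functional screen** — per-gene reporter activity relative to the
   stimulated control (= 1.0); enhancement = activity − 1, flagged when
   ≥ 0.75 (inclusive: a gene exactly on the 75% line counts). The
   control-equals-1 convention is assumed for input tables.
3. **Correlation panel** — per cohort and target, a Pearson (default) or
   Spearman coefficient with n and p; cohorts missing either gene or with
   fewer than three samples are skipped with a logged reason. The meta
   summary per target is the median r, the fraction of cohorts with
   r > 0, and a two-sided binomial sign-consistency p — a pooled r across
   heterogeneous platforms would not be meaningful, so consistency of
   sign is the cross-cohort statistic. The ranking key for this layer is
   the smallest sign-consistency p across targets.

Only candidates passing at least one layer enter the ranking; the full
evidence table is returned alongside so users can re-rank. Residual ties
are broken alphabetically and flagged.

## The synthetic-data generator

The generator emulates the statistical shape of the real inputs — not
their biology. Case/control cohorts are Gaussian on the log2 scale:
per-gene baselines uniform in [4, 12] log2 units, i.i.d. noise with
`noise_sd` (default 1.0), and planted genes shifted in cases by
`effect_size × noise_sd`, so `effect_size` is Cohen's d. With
`noise_sd = 0` the shift is `effect_size` log2 units directly, giving the
degenerate perfect-separation case. Ground truth (gene, cluster,
direction, shift) is emitted alongside every cohort so tests never
re-derive it. Default group sizes are 20/20 (comfortable) with n = 3 per
arm explicitly supported, mirroring the smallest real designs. Seeds are
mandatory; identical design + seed reproduces bit-identical output.

Time courses share one control arm across phases (default control, acute,
chronic, recovery; n = 6 per phase, a typical public-repository arm size)
and shift each planted gene set by a per-phase profile in log2 units; a
peak shift of 2.0 with unit noise represents a strong but realistic
colitis-course effect. Interactome lists plant one candidate unique to
the second list with configurable sizes and overlap; screen tables put
non-enhancers at activity 1.0 and enhancers at 1 + enhancement with small
Gaussian noise (sd 0.02). Correlation cohorts plant a target correlation
r via `candidate = r·z_target + √(1−r²)·noise` per cohort.

What the simulator does **not** model: count over-dispersion,
library-size or batch effects, probe-level microarray structure,
cross-gene correlation beyond the planted modules, or read-level
sequencing noise. Passing tests therefore demonstrate that the
statistical machinery behaves as specified under clean planted structure,
not that any particular biological dataset will yield a particular
signature. Real-data normalization and multi-probe collapsing are left to
the user, upstream of this package.

## Numerical and interface conventions

- Gene symbols are compared case-insensitively (upper-cased), original
  casing preserved for display; duplicate ids after canonicalization are
  rejected with the offenders named. Cross-species mapping uses an
  explicit table when given, else the naive case convention (ALL-CAPS ↔
  Title-case), and reports how every symbol was mapped.
- Genes with missing values are dropped on read (with a logged count),
  not imputed: rank and threshold statistics downstream are sensitive to
  imputation.
- Matrices are TSV by default with the delimiter sniffed (CSV accepted);
  the first column is the gene id regardless of its header. Readers
  return genes and samples in canonical order, so reading is
  order-insensitive; round trips reproduce content up to that ordering.
- Welch p values that are undefined (zero variance in both groups) are
  reported as 1 with a flag rather than NaN.
- The `all` pipeline writes a manifest (config echo, seed, package
  version, output checksums) without timestamps, so two runs with the
  same seed are byte-identical across every output file including the
  manifest.

## Problem sizes used by the acceptance script

The from-scratch measurements use: 30 planted genes at d = 3 among 300
nulls at n = 20/20 for recovery; 100 null genes at n = 10/10 with 200
label permutations vs 200 independent simulations for calibration
(counts binned to expected ≥ 5 before the chi-square); a 20-gene module
at d = 4 for composite accuracy; 100 replicate time courses for the
trend-call rate; 20 synthetic worlds (each with a 21-cohort correlation
panel) for prioritization; and two full pipeline runs for determinism.
These sizes keep each measurement well-powered while running in well
under a minute apiece on one CPU.

## Known limitations

- The refinement gate's false-positive behaviour at very small n is
  granular: with n = 3/3 only a handful of AUC values exist, so the
  0.7/0.05 gate is coarse (warned, not forbidden).
- The step threshold is a two-segment fit; multimodal expression with
  more than two regimes is collapsed to its best binary split.
- The sign-consistency meta-analysis treats cohorts as exchangeable votes
  and ignores cohort size beyond the per-cohort p values reported in the
  records table.
- The composite score weights member genes equally by default; a gene
  absent from a cohort simply drops out of the mean (tracked via
  coverage), which can shift scores when coverage differs across cohorts
  being compared informally.
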
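# colam

A toolkit for deriving, scoring, and mining **colon-associated macrophage
(ColAM) gene signatures** from bulk transcriptomics.

Intestinal macrophages balance two antagonistic programs: reactive
("accelerator", inflammatory) and tolerant ("brake", noninflammatory)
states. `colam` implements the computational workflow that refines a broad
macrophage reactivity/tolerance signature into colon-specific inflammatory
(**iColAM**) and noninflammatory (**niColAM**) gene sets on a labeled
case/control cohort, scores any cohort with those sets, profiles when each
population emerges across colitis phases, and prioritizes candidate
effector genes — the procedure that singles out a NOD2-coupled regulator
such as GIV/*CCDC88A*. It is aimed at computational biologists who have a
parent gene signature with cluster labels and labeled expression cohorts,
and want a reproducible, testable version of this screening pipeline.

## The statistics at the core

**Per-gene refinement.** Each parent gene *g* is a single-gene classifier
of case vs control. Its ROC-AUC is the Mann–Whitney pair statistic

> AUC(g) = ( #{case > control pairs} + ½·#{ties} ) / (n₁·n₀),

computed from average ranks; classification accuracy is max(AUC, 1−AUC)
and the regulation call is *up in case* when AUC > 0.5, *down* when
AUC < 0.5. Expression is dichotomized at a step-fit threshold — the split
of the sorted vector minimizing the two-segment squared error, with the
threshold at the midpoint of the segment means — and a two-sided Fisher
exact test is run on the (above/below threshold) × class table. A gene is
**selected** when accuracy ≥ 0.7 and Fisher p ≤ 0.05; selected genes are
partitioned by parent cluster into the iColAM (reactive) and niColAM
(tolerant) sets.

**Composite scoring.** A sample's score for a gene set is the mean rank
percentile of the member genes, a value in [0, 1] invariant to any
per-gene monotone normalization. Cohorts are classified by the score's
ROC-AUC plus a Welch two-sample t test; time courses sharing a control arm
are scored on a common rank scale and each set's trend is called as the
phase of maximum mean score, with seeded bootstrap confidence intervals.

**Prioritization.** Candidates inside a signature are ranked
lexicographically over three evidence layers: (1) a unique hit in exactly
one interactome list, (2) a functional-screen enhancement of reporter
activity ≥ 75% over the stimulated control (activity ≥ 1.75 relative
units, inclusive), (3) sign-consistent correlation with a target sensor
across independent cohorts (binomial sign-consistency p).

A first-class synthetic-data module generates all of these inputs with
planted, known ground truth, so the whole pipeline is testable without any
external download.

## Worked example

Run the whole chain — simulate a synthetic world, refine, score,
prioritize — with one command:

```sh
colam all --out demo --seed 42
```

```
pipeline complete: 16 iColAM / 17 niColAM genes; top candidate CCDC88A
```

The synthetic world plants 30 true signature genes (effect size d = 3,
n = 20/20) among 300 nulls, so refinement recovers the planted genes plus
a couple of borderline nulls. `demo/refine/gene_stats.tsv` holds the
per-gene audit table:

```
gene     cluster   auc     accuracy direction   threshold    fisher_p
SIGR000  reactive  0.995   0.995    up_in_case  10.719       5.82e-08
SIGR001  reactive  0.9775  0.9775   up_in_case  6.418        5.82e-08
```

`demo/score/classification.tsv` shows both composite scores separating
the classes perfectly (accuracy = 1; the iColAM score is high in cases,
the niColAM-planted direction mirrors it):

```
cohort    set               auc  accuracy  welch_p    direction
world_42  world_42_iColAM   1    1         1.97e-29   case_high
world_42  world_42_niColAM  0    1         3.07e-27   control_high
```

and `demo/prioritize/ranking.tsv` places the planted candidate first — it
is the only signature gene unique to the NOD2 interactor list, is a
screen enhancer at +90%, and correlates with NOD2 across all 21 synthetic
cohorts (sign-consistency p ≈ 1e-6):

```
rank  gene     signature_set  unique_to         enhancement  screen_flagged  sign_p
1     CCDC88A  niColAM        NOD2_interactors  0.898        True            9.5e-07
2     SIGR000  iColAM                           0.494        False           1
```

Each stage is also available separately (`colam simulate`, `refine`,
`score`, `phases`, `prioritize`) on your own TSV/GMT files; see
`colam <cmd> --help`. Every run writes a `manifest.json` with the config,
seed and output checksums, and re-running with the same seed reproduces
every file byte for byte.

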
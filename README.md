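# irgpi — rank-based immune gene-pair index for immunotherapy response

`irgpi` builds, applies and evaluates weighted gene-pair signatures that
predict immune-checkpoint-inhibitor (ICI) response and survival from bulk
tumor transcriptomes. It is aimed at translational researchers who want to
pool expression cohorts profiled on different platforms: every statistic in
the pipeline consumes only the *within-sample rank order* of genes, so
cohorts can be merged with no normalization at all.

## The method

For a gene pair `A|B`, a sample scores

    score(A|B, s) = 1  if  expr(A, s) > expr(B, s),  else 0 ,

and a signature assigns each sample the index

    IRGPI(s) = Σ_i score_i(s) · β_i ,

with coefficients β from multivariate Cox proportional-hazards regression.
Higher index ⇒ higher hazard ⇒ predicted non-responder (SD/PD); the
low-index group is the predicted CR/PR group.

Discovery proceeds: shared (immune) gene universe → all canonical pairs →
removal of near-constant pairs (same score in >80% of any cohort's
samples) → per-pair log-rank screening against overall survival with
Benjamini–Hochberg control (candidates at FDR < 0.001) → lasso-penalized
Cox selection with cross-validated penalty, then an unpenalized refit.
Evaluation covers ROC with the maximum-Youden cutoff, confusion metrics,
Kaplan–Meier/log-rank comparison, a Breslow-ties Cox hazard ratio, an
exhaustive OS-driven cutpoint scan for cohorts without response labels,
and fixed-effect inverse-variance meta-analysis (I² heterogeneity) across
cohorts. A published 31-pair melanoma signature is bundled for scoring
without refitting, and ssGSEA-style gene-set scoring plus Wilcoxon group
comparisons characterize the tumor microenvironment of the resulting
groups. A seeded synthetic-cohort generator with a planted pair signature
makes every stage testable without downloads; see `docs/methods.md` for
the full model and its assumptions.

## Worked example

Discovery on a simulated three-cohort study (41/28/51 samples, three
different expression "platforms", ten planted pairs at the strong-signal
condition):

```python
import pandas as pd
from irgpi import (SimulationConfig, generate, intersect_genes,
                   enumerate_candidate_pairs, filter_constant_pairs_streaming,
                   compute_pair_indicators, concat_indicator_matrices,
                   screen_pairs, select_candidates, FitConfig, fit_signature,
                   score_cohort_from_expression, roc_and_youden,
                   classify_and_confuse, compare_survival)

bundle = generate(SimulationConfig(seed=7, n_genes=60, n_samples=(41, 28, 51)))
cohorts = bundle.cohorts
clinical = [r for c in cohorts for r in c.clinical]

genes = intersect_genes(cohorts)
pairs = enumerate_candidate_pairs(genes)
kept = filter_constant_pairs_streaming([c.expression for c in cohorts], pairs)
meta = concat_indicator_matrices(
    [compute_pair_indicators(c.expression, kept) for c in cohorts])
result = screen_pairs(meta, clinical, endpoint="os")
candidates = select_candidates(result, fdr_threshold=0.001)
model = fit_signature(meta.subset_pairs([p.label for p in candidates]),
                      clinical, FitConfig(seed=1))

scores = pd.concat(
    [score_cohort_from_expression(c.expression, model).scores for c in cohorts])
labels = bundle.truth.responder.loc[scores.index]
roc = roc_and_youden(scores, labels)
confusion = classify_and_confuse(scores, roc.youden_cutoff, labels)
comp = compare_survival(scores, clinical, roc.youden_cutoff)
```

which prints (exact output of this script):

```
pairs enumerated   : 1770
pairs after filter : 1038
candidates (q<.001): 475
signature size     : 21 pairs
AUC                : 0.934
Youden cutoff      : -0.017
sens/spec/accuracy : 100.0% / 87.9% / 93.3%
log-rank p         : 4.29e-34
median OS low/high : 133.6 / 0.1 months
```

The fitted 21-pair signature separates simulated responders from
non-responders (AUC 0.93) and splits survival sharply — the extreme median
gap reflects the generator's strong-signal condition, under which the
planted index spans hazard ratios far larger than any real cohort would
show. Scoring the same cohorts after arbitrary per-sample monotone
transformations of expression reproduces these numbers bit-for-bit; that
invariance is the point of the method.

The same workflow is available from the shell (`simulate`, `build`,
`score`, `evaluate`, `cutpoint`, `ssgsea`, `compare`, `export-signature`),
each subcommand writing TSV outputs plus a `manifest.json` with input
checksums and seeds:

```sh
irgpi simulate --seed 7 --outdir bundle/
irgpi build -e bundle/synth1_expression.tsv -c bundle/synth1_clinical.tsv \
            -e bundle/synth2_expression.tsv -c bundle/synth2_clinical.tsv \
            -e bundle/synth3_expression.tsv -c bundle/synth3_clinical.tsv \
            --seed 1 --outdir build/
irgpi score --expression cohort_expression.tsv --signature bundled --outdir scored/
irgpi evaluate -s scored/scores.tsv -c cohort_clinical.tsv --outdir eval/
```

Scoring with `--signature bundled` uses the packaged 31-pair melanoma
model; expression tables lacking any of its 53 gene symbols either error
(default) or drop the affected pairs with a prominent warning that the
resulting scores are not comparable to published cutoffs.

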
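# prognosig

Evaluation machinery for **prognostic gene-expression signatures**.

Given (a) a genes × cancer-types matrix of prognostic *z*-scores — each
entry measuring how strongly one gene's expression associates with patient
outcome in one cancer type, plus a pan-cancer Stouffer meta-*z* column — and
(b) a collection of candidate gene signatures (GMT), `prognosig` answers two
questions:

1. **Is a signature enriched in poor-outcome genes?** A preranked
   enrichment engine ranks genes by *z* (or meta-*z*), walks a running sum
   that rewards signature members and penalises non-members, and reports the
   enrichment score (ES), the permutation-normalised NES, a family-wise
   error rate from the permutation distribution of the maximum NES across
   all tested sets, and three leading-edge metrics — *tag* (sensitivity),
   *list* (false-negative-rate analogue) and *signal* (enrichment
   strength). Competing signatures are ranked by the mean of their four
   metric ranks, and per-cancer-type runs count how many types a signature
   covers.
2. **Does the signature actually stratify survival?** For each expression
   cohort with (time, event) follow-up, every sample is classified
   high-/low-risk by leave-one-out nearest-centroid classification against
   the deceased and surviving centroids of the *other* samples, and the
   groups are compared with the Kaplan–Meier estimator, the log-rank test
   and an O/E hazard ratio. A subsampling module reruns the whole chain on
   thousands of death-rate-matched sub-cohorts (75%/50% of the cohort) to
   measure how robust the prognostic call is to cohort size.

A synthetic-data module generates every input the pipeline consumes — null
or planted-module *z*-matrices, random gene-set collections, and
proportional-hazards expression cohorts with configurable hazard ratio,
expression shift and censoring — so the full analysis is testable without
any external resource.

## The statistics in brief

For a ranked list of $N$ genes and a set with $N_h$ members present, the
running sum adds $|z_i|^p / \sum_{\text{hits}} |z|^p$ at each member and
subtracts $1/(N-N_h)$ otherwise; ES is the maximum absolute deviation from
zero. NES = ES / mean(|same-sign permutation ES|); the FWER *p* of a set is
the add-one-corrected fraction of gene-relabelling permutations whose most
extreme same-sign NES across **all** sets reaches the observed NES. With
peak position $k$: tag = (members at rank ≤ k)/$N_h$, list = $k/N$,
signal = tag·(1−list)·$N/(N-N_h)$.

The log-rank statistic accumulates, over distinct event times, the high-risk
group's observed minus hypergeometric-expected deaths over the summed
variances ($\chi^2$, 1 df), and the hazard ratio is
$(O_h/E_h)/(O_l/E_l)$.

## Worked example

```python
import prognosig as pg
from prognosig.enrichment import EnrichmentRunConfig

# a z-score matrix with a 50-gene poor-outcome module planted at +3z in 5 types
module = pg.PlantedModule(tuple(range(50)), 3.0, ("T1", "T2", "T3", "T4", "T5"))
matrix = pg.generate_zscore_matrix(pg.ZScoreSimConfig(
    n_genes=2000, cancer_types=("T1", "T2", "T3", "T4", "T5"),
    planted_modules=(module,), seed=42))
universe = list(matrix.gene_ids)
coll = pg.generate_geneset_collection(
    50, (25, 100), universe, planted={"MITOSIS_MODULE": universe[:50]}, seed=7)

res = pg.PrerankedGSEA(matrix, coll,
                       config=EnrichmentRunConfig(n_permutations=1000, seed=1)).fit()
print(res.summary(top=5))
```

```
Preranked enrichment results
============================================================
ranking column:     meta_z
ranked genes (N):   2000
sets scored:        51  (filtered out: 0 below 25 known genes)
permutations:       1000 (seed 1, p = 1.0)
significant (FWER < 0.05): 1

                n_known     ES    NES  p_fwer    tag   list  signal
set_name
MITOSIS_MODULE       50 1.0000 3.1728  0.0010 1.0000 0.0250  1.0000
RANDOM_0050          67 0.4381 1.4454  0.8332 0.2985 0.1845  0.2519
...
```

The planted module attains ES = 1.0 (all 50 members sit at the very top of
the meta-*z* ranking), NES 3.17, FWER *p* = 0.001 (the floor for 1,000
permutations), perfect sensitivity (tag = 1.0) and a narrow leading edge
(list = 0.025); no random set comes close.

```python
cohort = pg.generate_survival_cohort(pg.CohortSimConfig(
    n_samples=250, n_genes=300, signature_indices=tuple(range(60)),
    hazard_ratio=2.5, expression_shift=1.0, censor_rate=0.3, seed=11))
signature = [f"G{i+1:06d}" for i in range(60)]
fit = pg.SignatureSurvivalModel(cohort, signature).fit()
print(fit.summary())
```

```
Signature survival stratification
============================================================
cohort:            cohort (n = 250)
signature genes:   60 present
death rate:        0.740
eligible:          True
risk groups:       high = 135, low = 115
log-rank chi2:     25.8088
log-rank p:        3.77e-07
hazard ratio (O/E): 2.0651
observed events:   high = 110, low = 75
expected events:   high = 76.83, low = 108.17
```

The LOOCV classifier recovers the planted high-hazard group (planted
HR = 2.5; the O/E estimate of 2.07 is attenuated by classification noise and
censoring) and the survival difference is decisive. `fit.plot_km()` draws
the two Kaplan–Meier curves; `fit.robustness(...)` reruns the chain on
death-rate-matched sub-cohorts.

## Command line

```bash
prognosig simulate --n-genes 2000 --module-size 50 --cohort-n 250 --out demo/
prognosig enrich --scores demo/scores.tsv --gmt demo/sets.gmt \
    --perms 1000 --seed 17 --out results.tsv
prognosig rank-signatures --results results.tsv --out leaderboard.tsv
prognosig coverage --scores demo/scores.tsv --gmt demo/sets.gmt \
    --signature PLANTED_SIG --out coverage.tsv
prognosig survival-screen --expr demo/cohort_expr.tsv \
    --clinical demo/cohort_clinical.tsv --signature demo/signature.txt --out screen.tsv
prognosig robustness --expr demo/cohort_expr.tsv --clinical demo/cohort_clinical.tsv \
    --signature demo/signature.txt --trials 10000 --seed 17 --out robust.tsv
prognosig pipeline config.yaml --out out/
```

`pipeline` runs the whole analysis from a YAML config and writes every
report plus a JSON manifest (config snapshot, input digests, seeds) that
makes the run byte-reproducible.

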
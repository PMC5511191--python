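# Methods

This note records the models, conventions and numerical choices behind
`prognosig`, and what the synthetic-data experiments do and do not
demonstrate.

## Prognostic z-scores and the meta-z

The input substrate is a genes × cancer-types matrix of signed *z*-scores:
positive means higher expression associates with poorer outcome in that
type (this package's sign convention throughout). The pan-cancer `meta_z`
column combines the per-type columns with the unweighted Stouffer rule,
meta-z = Σ z_j / √k over k types, which is exactly N(0,1) when the columns
are independent standard normals. A weighted variant
(Σ w_j z_j / √Σ w_j²) is available via `ZScoreSimConfig.meta_weights` for
resources that weight studies by sample size; the default is unweighted
because per-type sample sizes are not part of this package's inputs.

## Preranked enrichment

**Ranking.** Genes are sorted by decreasing score; ties break by gene label
(stable lexicographic) so rankings are identical across platforms. Genes
with a missing score in the chosen column are excluded and reported.

**Running sum and ES.** For a list of N genes and a set with N_h members
present ("known genes"), a hit at rank i adds |z_i|^p / Σ_hits |z|^p and a
miss subtracts 1/(N−N_h). The ES is the running-sum value of maximum
absolute deviation from zero, first occurrence on exact ties. The weight
exponent defaults to p = 1 (score-weighted hits); p = 0 gives the
unweighted statistic and both are first-class. Numerically, the curve is
computed as (cumulative hit weight)/(total hit weight) minus (miss
count)/(N−N_h) — divisions of exact partial sums rather than accumulated
per-step increments — so ES = ±1.0 exactly for extreme placements and the
curve never leaves [−1, 1] even at the last bit. A vectorised path
evaluates only the candidate extremes (at hits and just before hits) with
bit-identical arithmetic; the test suite verifies exact agreement with the
full scan and with an exact-rational oracle.

**Permutation null, NES, FWER.** Without phenotype labels the only
available null is gene relabelling: a random set of equal size. For the
FWER, one label permutation per trial is shared by *all* sets, so null
enrichment of different sets is correlated within a trial exactly as the
family-wise maximum statistic requires. NES = ES / mean(|same-sign null
ES|), computed per set; a set with no same-sign nulls has undefined NES and
is excluded from rankings. The FWER p of a positive-NES set is the add-one
fraction (1+b)/(1+B) of permutations whose maximum positive NES across all
sets reaches it; negative NES mirror against the minima. p-values therefore
live in [1/(B+1), 1] and each sign is controlled at its nominal level
separately (the convention of the max-statistic construction); on fully
null data the two-sided family-wise false-positive rate measured over 40
replicates is ≈ 0.075 at α = 0.05 per tail.

**Leading edge.** With peak position k (1-based): tag = (set members at
rank ≤ k)/N_h, list = k/N, signal = tag·(1−list)·N/(N−N_h), and the
leading-edge genes are the members at rank ≤ k; for negative ES the mirror
definitions from the bottom of the list apply. When the set spans the
entire ranking (N_h = N) the signal ratio is 0/0 and is defined as 0.
Sets with fewer than 25 known genes are excluded before scoring (inflated
scores for tiny sets); the filter count is logged and reported.

**Signature leaderboard.** Among sets significant at FWER < α, each of
NES/tag/signal is ranked descending and list ascending (low list = purer
enrichment); ties get min-rank (competition ranking); the mean of the four
ranks orders the leaderboard. Per-type coverage flags each cancer type
where a signature's FWER p < α, and types are split into high/low
outcome-gene content at ≥ 10 genes with Benjamini–Hochberg Q < 0.05
(two-sided p from z).

## Survival arm

**Eligibility.** A cohort enters the analysis with ≥ 50 annotated cases,
≥ 25 signature genes measured and a death rate inside [0.10, 0.90]
(endpoints pass; only strictly more extreme rates fail). Failures are
reported, never raised.

**LOOCV nearest-centroid classification.** For each sample, the per-gene
means of the deceased (event = 1) and surviving (event = 0) *other*
samples over the signature genes form two centroids. Expression is
z-scored per gene within the training remainder, refit at every fold so
the held-out sample never leaks into the standardisation. The sample is
labelled high-risk when nearer to the deceased centroid; ties go to
low-risk. The default metric is Euclidean distance on the z-scored
profiles, with 1−Pearson and 1−Spearman selectable. Euclidean was chosen
over correlation because z-scoring already removes per-gene scale, while a
correlation across signature genes is additionally invariant to any shift
common to the whole signature — and a co-regulated module's most
informative component is often exactly that shared shift. On the Euclidean
path the comparison uses squared distance minus g/m_k (g genes, m_k
training class size): an unbiased estimate of the squared distance to the
class *mean*, which removes the systematic bias a held-out sample's own
class-size reduction would otherwise introduce.

**Kaplan–Meier, log-rank, hazard ratio.** The survival curve is the
product-limit estimator over distinct event times (censorings leave the
risk set after their time); with no censoring it equals the empirical
survival function exactly. The two-group log-rank test accumulates
observed minus hypergeometric-expected high-risk deaths over the summed
hypergeometric variances; χ² has 1 df. The hazard ratio is the O/E
estimate (O_h/E_h)/(O_l/E_l) — closed-form and deterministic; a Cox fit is
deliberately out of scope. The cohort-size analysis compares, across a
collection of screened datasets, the sizes of significant versus
non-significant ones with a two-sided Wilcoxon rank-sum test (exact for
combined n ≤ 20 without ties, otherwise normal approximation with tie
correction).

**Subsampling robustness.** From a cohort that is significant at full size
and has ≥ 200 samples, sub-cohorts of 75% and 50% size are drawn uniformly
without replacement and accepted only if their death rate is within ±10
percentage points (absolute) of the full cohort's; the band is
configurable. Sampling continues until the configured number of *accepted*
trials (default 10,000), with a total draw budget of 100 draws per trial;
exhausted trials are counted as rejected. Each accepted sub-cohort reruns
the full LOOCV + log-rank chain; the report gives the per-fraction share
of significant trials and p quantiles. The expectation that the 75%
fraction retains significance at least as often as the 50% fraction is
reported, not enforced.

## Synthetic data: what it emulates and what it does not

`generate_zscore_matrix` draws per-type scores N(0, σ²) and adds planted
module shifts; overlapping modules with conflicting shifts on the same
(gene, type) cell are rejected. `generate_survival_cohort` draws a latent
high-risk group (Bernoulli), shifts the signature genes' expression in that
group — per-gene magnitudes vary uniformly over 0.5–1.5× the configured
mean shift, as genes of a real module respond with different strengths —
and draws exponential event times with a multiplicative hazard (so the
configured hazard ratio is the estimand of the survival arm under
proportional hazards). Censoring times are uniform on (0, τ) with τ solved
(Brent) so the expected censored fraction equals `censor_rate` under the
two-group exponential mixture; this keeps censoring independent of event
times, as the log-rank test assumes. A `follow_up_horizon` cap can
additionally administratively censor long follow-up (default effectively
unbounded). All generators are pure functions of their configuration
including the seed.

Not emulated: microarray platform artefacts, probe-to-gene mapping, batch
effects, non-proportional hazards, competing risks, or per-dataset endpoint
heterogeneity. Passing tests therefore demonstrate the correctness and
calibration of the machinery under its stated model, not performance on any
real resource.

## Study conditions used by the packaged experiments

The acceptance script and tests run at desk scale, as the package's own
choice of problem sizes: enrichment calibration/recovery on 10⁴ genes ×
5 types with 100–200 sets and 1,000 permutations over 10–20 replicates;
survival recovery at n = 250, planted HR 2.5, 1-SD mean shift, 30%
censoring, 20 replicates; null calibration at planted HR 1 over 200–500
replicates; subsampling on an n = 400 cohort with 1,000 accepted trials
per fraction. The subsampling demonstration cohort uses 70% censoring
(death rate ≈ 0.28, typical of relapse endpoints): the point of that
experiment is the *loss of power* under subsampling, which is measurable
only when the event count is moderate — at a 65% death rate both fractions
sit at power ≈ 1.0 and the ordering degenerates to a tie.

## Known limitations

- **Optimism of same-cohort evaluation.** The LOOCV labels are functions
  of the cohort's own outcome vector (centroids are outcome-group means),
  so the downstream log-rank test on the *same* cohort is mildly
  anticonservative under a global null even with the distance-bias
  correction (measured ≈ 0.086 rejection at nominal 0.05, n = 250, 60-gene
  signature, 1,000 replicates): cross-sample label correlations with the
  event pattern remain. This is a property of the evaluation design, not of
  the implementation — labels built from expression alone are exactly
  calibrated (0.048). Independent validation cohorts are the remedy in
  practice.
- FWER is controlled per sign at its nominal level; a two-sided family
  interpretation roughly doubles the rate.
- The O/E hazard ratio is a consistent but crude estimator; for small event
  counts it is noisy and can be 0/∞ when one group has no events.
- FDR q-values are not computed (FWER is the significance criterion); a
  Benjamini–Hochberg extension over the null NES matrix would be
  straightforward.
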
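# Methods

This note documents the models behind `gipipe`, the calibrated defaults of
the synthetic cohort generator, the numerical conventions that affect
results, and what the synthetic tests do and do not establish about real
data.

## Classification model

Each signature (TP53 functional status, HRD status, global immune class) is a
nearest-centroid classifier. For a sample vector *x* restricted to the genes
shared with the centroid set, the similarity to each class centroid is
computed with the set's declared metric and the sample takes the argmax class
(argmin distance for Euclidean, reported as negative distance so argmax
semantics are uniform).

* **Metric.** Spearman rank correlation is the default: rank similarity is
  invariant to any strictly monotone transform of a sample, which is what
  lets centroids trained on one platform be applied to another and makes the
  (unknown) log base of the input irrelevant. Pearson and Euclidean are
  selectable per centroid set.
* **Missingness.** Similarities use each sample's observed genes; a sample
  observing fewer than `min_gene_fraction` (default 0.5) of the centroid
  genes is called `missing`. The default is a judgement call — there is no
  established convention for per-sample missingness in centroid classifiers —
  and is exposed as a parameter.
* **Ties.** Exact similarity ties go to the first tied class in the centroid
  set's declared class order, with `tie_flag` set. Ties are measure-zero for
  continuous expression but arise with degenerate inputs; deterministic,
  auditable tie-breaking matters more than the choice itself. Class order is
  therefore part of a `CentroidSet`'s identity and round-trips through
  serialization.
* **Training.** Centroids are per-class per-gene means. When
  `genes_per_class` is finite, genes are ranked by a one-way ANOVA F
  statistic across classes and the top genes retained; since the F ranking is
  shared across classes, the per-class union equals the global top-k. No
  PAM-style shrinkage is applied: plain class means after gene selection.

## The AGI composite

AGI = TP53 Mut-like OR HRD+. The OR is evaluated with three-valued logic:
one positive disjunct is decisive regardless of the other slot; NGI requires
both calls negative; every remaining combination (a negative or missing call
paired with a missing call) is `indeterminate`, because the missing slot
could still have made the tumor AGI. The full 9-entry truth table is tested
exhaustively.

## Immune scores and dichotomization

A cell-type score is the median of the type's marker genes within a sample
(median, not mean, so a single extreme marker cannot dominate a small panel).
The default panel has 48 genes: 10 cell types (B, T, CD8 T, Th, Treg, Tfh,
NK, eosinophil, neutrophil, macrophage), a cytotoxic panel, adaptive/innate
composites (unions of their member types), the 48-gene overall-immune
composite, and single-gene PD-L1 (*CD274*) and CD8 (*CD8A*) scores. A score
is missing for a sample observing fewer than half its panel genes.

Low/High categories cut at the cohort third quartile, with three fixed
conventions (each flips calls at the boundary if changed, so they are pinned
and documented):

1. Q3 is the 0.75 quantile under linear interpolation (`numpy` default).
2. High means strictly greater than Q3; a value exactly at Q3 is Low, which
   also makes the all-constant cohort well-defined (everyone Low).
3. Q3 is computed over the full analysis cohort, pooled across ER strata.
   Pooling is the only convention under which the High fraction can differ
   between ER strata, which is the behaviour the pipeline is designed to
   surface; when cohorts from different platforms are combined, cutoffs
   should be computed per cohort (the caller controls this by scoring
   cohorts separately).

## Association statistics

**RFD.** The relative frequency difference between exposure groups is the
coefficient of the exposure indicator in a binomial GLM with identity link,
×100 (percentage points), with Wald 95% CIs. With no covariates and a binary
exposure this is exactly the difference in observed proportions (verified to
1e-8 in tests). Identity-link binomial likelihoods are not guaranteed to be
maximizable inside the feasible region; a fit that fails to iterate to
convergence, produces non-finite estimates, or drives any fitted probability
out of (0, 1) is reported as a non-converged `DNC` record. A least-squares
linear-probability fallback with robust SEs exists behind an explicit
argument but is never substituted silently — non-convergence is a reportable
state, not an error to be papered over. A constant outcome is reported as
`degenerate outcome`. Multi-level outcomes (the three immune classes) are
handled as separate binary models per class against the Immune-Quiet
referent. Age enters linearly in years and race as an indicator.

**Differential scores.** Per score, an OLS fit of
`score ~ group + covariates`; the group coefficient is the adjusted mean
difference in expression units. Benjamini–Hochberg correction is applied
across the family of scores tested within one contrast (not the union of
contrasts): families are per-contrast because each contrast is interpreted
as its own panel of results.

**Welch t.** Two-sided, Satterthwaite degrees of freedom; requires two
observations with variance in at least one group.

## Recurrence analysis

Samples are excluded, with per-reason counts returned and logged, if they
are stage IV at diagnosis, AGI-indeterminate, missing ER, or missing
follow-up. Follow-up is administratively censored at 5 years; no event can
survive past the horizon in any report. Within each AGI stratum:

* Kaplan–Meier product-limit curves per immune class and the k-sample
  log-rank test (k−1 df). The NGI stratum is reported even when
  underpowered; an absent or single-class stratum yields an explicit skip
  reason rather than silence.
* Cox proportional-hazards models with Efron tie handling (preferable to
  Breslow when event times are coarsely recorded), crude and adjusted for
  age (linear), race (indicator), stage (indicators, stage I referent) and
  ER status (indicator), with Adaptive-Enriched as the immune-class
  referent. Monotone likelihoods (an indicator level with all or no events)
  are flagged `unstable` rather than suppressed.
* Proportionality: each covariate in turn gets a covariate × log(time)
  interaction refit as a time-varying covariate via counting-process
  expansion at the distinct event times, and the interaction's Wald p is
  reported. log(time) is the default time scale; the expansion is quadratic
  in the number of events, so the check is a flag (off by default) intended
  for cohort-scale models.

The hand-rolled partial-likelihood score test at β = 0
(`score_test_at_zero`) exists to expose the classical identity with the
log-rank statistic on tie-free two-group data; tests assert agreement to
1e-6 against an independent log-rank implementation.

## Synthetic cohort generator

The generator emulates the statistical skeleton of a diverse, ER-stratified
breast-cancer cohort with RNA-based instability calls and 5-year recurrence
follow-up. Defaults are calibrated once, in one place, and are not tuning
knobs:

| parameter | default | provenance |
|---|---|---|
| `n_samples` | 1942 | emulated cohort size |
| `p_er_negative` | 0.368 | 714 ER− of 1942 |
| P(TP53 Mut-like \| ER−/ER+) | 0.857 / 0.236 | cohort prevalences |
| P(HRD+ \| ER−/ER+) | 0.835 / 0.224 | cohort prevalences |
| P(AGI \| ER−) | 0.926 | cohort prevalence; implies positive TP53/HRD dependence |
| P(AGI \| ER+) | derived (0.407) | independence of the ER+ margins (see below) |
| immune mix \| AGI | 0.466 / 0.311 / 0.223 | AGI-stratum class counts (328/219/157) |
| immune mix \| NGI | 0.093 / 0.577 / 0.330 | solved from the mixture identity (see below) |
| `baseline_hazard` | 0.026 /year | 12.2% 5-year recurrence in the adaptive AGI referent (40/328) |
| `hr_by_class` | 1.0 / 1.79 / 1.65 | adjusted recurrence hazard ratios within AGI |
| `admin_censor` | 5 years | complete 5-year follow-up |
| `censor_uniform_max` | None | no random censoring by default (follow-up is complete) |
| `centroid_shift`, `marker_elevation` | 1.0 log-units | chosen as a clearly-detectable targeted-panel effect size |
| `noise_sd` | 0.5 log-units | per-gene technical + biological noise; gives near-perfect but not exact label recovery |
| gene blocks | 25 TP53 + 25 HRD + 48 immune + 402 noise = 500 | targeted NanoString-scale panel |

Details and deliberate choices:

* **TP53 × HRD joint law.** The two margins plus the AGI probability pin the
  2×2 joint per ER stratum (P(both) = P(T)+P(H)−P(AGI)). Among ER-negatives
  the calibrated AGI rate (0.926) is *below* the independence value (0.976),
  i.e. the two signatures co-occur more than independence predicts; the
  generator honors that dependence. For ER-positives the published AGI cell
  is internally inconsistent with its own missing-data accounting, so no
  default is taken from it: P(AGI | ER+) defaults to the independence value,
  with the dependence still configurable.
* **NGI immune mix.** Not printed anywhere; the default solves
  overall = P(class|AGI)·P(AGI) + P(class|NGI)·P(NGI) using the full-cohort
  class margins. The solved mix is innate-heavy, which means the generator
  does not emulate the positive innate-class association with instability
  seen in the motivating data — a known limitation, acceptable because no
  test depends on that direction.
* **Expression model.** Per-gene baselines are N(6, 1), drawn from a
  `genome_seed` separate from the cohort seed so the generating centroids
  are a deterministic function of the configuration. Class effects are
  *patterns*, not uniform shifts — half of a signature block up, half down —
  because a uniform shift would leave within-block ranks unchanged and be
  invisible to rank-based classification. Immune classes elevate their
  marker blocks (adaptive markers + CD274 for Adaptive-Enriched, innate
  markers for Innate-Enriched). Genes are conditionally independent given
  class: no gene–gene correlation, batch effects, or library-size structure.
* **Recurrence.** Event times are exponential (the simplest
  proportional-hazards law; a Weibull shape is exposed) with hazard
  `baseline_hazard × hr_by_class[class]` applied **only when the sample is
  AGI** — the generator's encoding of effect modification. Observed time is
  the minimum of event time, optional uniform censoring, and the 5-year
  administrative horizon.
* **Demographics.** Age ~ N(50, 11) clipped to 20–74; race Bernoulli(0.52
  Black); stage multinomial (4% stage IV). Both are independent of the
  latent labels by default, so crude and adjusted estimates coincide up to
  Monte-Carlo error; a single `confounding` knob links race to immune class
  and to hazard so that tests can make them diverge deliberately.

**What passing tests show — and don't.** Synthetic cohorts establish that
every stage computes what it claims (oracle equivalences), that estimators
recover generating parameters, and that the stratified contrast emerges
under the calibrated conditions. They do not establish classifier accuracy
on real platforms (real signature genes are correlated and drifted across
platforms), the realism of the marker panels, or calibration of the immune
scores against ground-truth cell fractions.

## Problem sizes used in checks

Marginal-prevalence checks use n = 5,000 (3 binomial SDs); the Cox recovery
check uses one n = 4,000 event-rich cohort (~70% events, giving a ~±9%
Monte-Carlo 95% interval on the hazard ratio); the stratified-contrast check
uses 100 replicates at n = 1,200; type-I error checks use 1,000 (Welch) and
500 (log-rank) null replicates. These sizes keep each property's Monte-Carlo
error comfortably below the margin it is tested against.

## Known limitations

* Identity-link binomial fitting inherits statsmodels' IRLS behaviour;
  borderline-feasible models may be reported DNC where a constrained
  optimizer would converge. This is deliberate (DNC is a first-class,
  reportable state) but means DNC rates are implementation-relative.
* The proportionality check refits one interaction at a time; global tests
  (all interactions jointly) are not provided.
* `cross_tabulate` supports the two denominator policies (full column vs
  observed-only) that published summary tables mix; more exotic policies
  (e.g. per-block custom denominators) must be composed by the caller.
* The generator's recurrence law has no frailty or non-proportional
  component, so the proportionality check should be unremarkable on
  synthetic data; it earns its keep only on real cohorts.
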
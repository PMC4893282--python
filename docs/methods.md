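# Methods

## The model

`seqthresh` fits a **sequential threshold model** — a discrete-time survival
model on the probit (liability) scale — to censored time-to-event outcomes,
with genome-wide SNPs entering through a Bayesian LASSO. Follow-up time is
partitioned by an `IntervalGrid` into K intervals; a patient reaches
interval k only by surviving intervals 1..k−1 event-free. Given that
interval k was reached, the probability of surviving it is

    Pr(survive k | reached k) = Φ(γ_k − η_i),    η_i = x_i'β + w_i'a,

where Φ is the standard normal CDF, γ_k an interval-specific cutoff,
x_i the encoded clinico-pathological covariates with effects β, and w_i the
centred SNP dosages with effects a. The residual standard deviation of the
latent liability is fixed at 1 — the probit scale is only identified up to
location/scale, and fixing σ²_e = 1 resolves the scale. Larger η means
higher event risk. The cutoffs are *unordered*: each γ_k is a free
interval-specific threshold, not a monotone sequence.

### Person-interval expansion and censoring

`expand` turns each patient into binary person-interval records. An event
in interval k* yields records for intervals 1..k* with outcomes
0,…,0,1. A censored patient contributes one 0-outcome record per *fully
survived* interval; the interval containing the censoring time is dropped,
because the patient's exposure there is incomplete and treating unobserved
exposure as survival would bias the interval hazards. A time exactly on an
interval's upper boundary counts that interval as fully survived.

One consequence: the final, open-ended interval [b_{K−1}, ∞) can never be
fully survived, so it carries only event records. Its cutoff is therefore
informed by events alone, and under a perfectly flat prior its full
conditional can become improper (the chain drifts). For this reason the
cutoffs get a weakly informative N(0, 100) prior by default
(`gamma_prior_var`; `inf` restores the flat prior). Where data inform a
cutoff, a variance-100 prior is numerically indistinguishable from flat;
where they do not, it keeps the chain bounded. Predictions depend only on
η and are unaffected by the last cutoff.

### Gibbs sampler

`fit` runs probit data augmentation (Albert–Chib): per record, a latent
liability is drawn from a unit-variance normal centred at η_i, truncated
below/above γ_k by the record's outcome (scipy's truncated-normal sampler,
stable in far tails). The cutoffs are updated as interval-specific
intercepts from their normal full conditionals; β is drawn jointly from
its conjugate multivariate normal (independent N(0, 10⁶) priors by
default — effectively flat); SNP effects are updated by single-site Gibbs
in fixed marker order under the Park–Casella hierarchy

    a_j ~ N(0, τ²_j),  τ²_j ~ Exp(λ²/2),  λ² ~ Gamma(0.1, 0.1),

with 1/τ²_j drawn from its inverse-Gaussian conditional and λ² from its
Gamma conditional. Defaults: 20 000 iterations, 5 000 burn-in, thinning 10
(conventional; every analysis in the test-suite and the acceptance script
uses shorter, explicitly stated chains sized to the problem). Runs are
bit-reproducible under a fixed seed. Genotypes are centred, not
standardised: the per-marker variances τ²_j already adapt the shrinkage
scale per marker, and centring removes intercept confounding.

Correctness of the sampler is established by three independent oracles in
the test-suite: (i) the probit block against a 2-D quadrature of the exact
(γ, β) posterior; (ii) the LASSO block against a 2-D numerical-integration
posterior over (effect, τ²); (iii) a joint-distribution (Geweke-style)
test in which the full kernel, alternated with data regeneration, must
preserve the prior marginals of γ, β, λ² and Σa². For the Geweke test the
generator is matched exactly to the kernel's observation model by adding a
dump interval in which all survivors are censored — otherwise the
drop-partial-interval convention makes the final interval's survival trial
unobservable and the comparison invalid.

## Evaluation

Cross-validation is stratified by event status with a seed-deterministic,
row-order-independent fold assignment (patients are sorted by id within
each stratum before the seeded shuffle; training subsets are fitted in
id-sorted order so results are invariant to cohort row permutations).
Defaults: 10 folds; 2 folds for small-event analyses. Two statistics per
fold, computed at the patient level from the posterior-mean predictor
η̂ on the held-out patients:

* **AUC** against the ever-event indicator (rank-based; equals the
  normalised Mann–Whitney U, ties counted half);
* **R²_probit** = var(η̂)/(var(η̂) + 1) — the proportion of liability
  variance attributable to the predictors in the test set (sample
  variance, n−1 denominator).

The SNP-only model's mean cross-validated R²_probit is reported as the
heritability estimate ĥ² for the outcome (a lower-bound-style estimate: a
whole-sample variant is available via `heritability_whole_sample`).
`decompose_cpp_prediction` measures how much of the covariate-based
prediction is itself predictable from the genome: η̂ from the
covariate-only model is regressed on the SNPs with a *linear* Bayesian
LASSO whose residual variance is free (drawn from its inverse-gamma
conditional), and var(pred)/(var(pred) + σ̂²) is computed on held-out
patients under the same fold scheme.

### A caveat on R²_probit with many markers

R²_probit measures the **variance** of the test-set predictions, not their
accuracy. When the number of markers approaches or exceeds the number of
person-interval records, the posterior places substantial mass on
noise-aligned effect vectors: the binary records can be nearly separated,
posterior-mean effects do not shrink to zero, and the held-out predictions
carry large variance even when no marker has any true effect (AUC stays at
0.5 — discrimination is unaffected). In that regime R²_probit, and hence
ĥ², is inflated, and the whole liability scale (β, γ) stretches with it.
This is a property of the model/statistic combination, verified against
independent posterior computations (quadrature and an ensemble-MCMC run on
the exact marginalised posterior), not a sampler artefact. It also offers
a mechanistic reading of the phenomenon, observed in applications of this
methodology, that adding markers to a covariate model can *decrease* its
R²_probit. Interpret R²_probit-based heritability only when the record
count comfortably exceeds the (pruned) marker count, and read AUC as the
primary discrimination measure otherwise.

## Marker quality control

`filter_markers` removes, in order: sex-chromosome markers (label set
configurable, default {X, Y, XY, 23, 24, 25}), markers with call rate
< 0.95, markers with MAF < 0.02 (MAF from non-missing calls as
min(p, 1−p), p = mean dosage/2). `ld_prune` then applies greedy pruning at
r² < 0.2 (squared Pearson correlation of dosages, pairwise-complete):
markers are visited in order of increasing missingness so that of any
correlated pair the better-genotyped marker survives; an optional window
bounds the comparisons. The greedy visit order makes the result
deterministic and reproducible; a brute-force pairwise oracle checks it on
small instances. A user-supplied force-include list can re-add markers
after pruning. Missing genotypes are imputed per marker: `mode` (default;
ties to the lower dosage), `mean_rounded`, or `forest` (a per-marker
random-forest classifier on the most correlated neighbouring markers,
seeded). Mode is the default because imputation is a pre-processing
convenience here, not part of the contributed method; the forest option
exists for users who want neighbour-informed fills.

## Synthetic cohorts

`simulate_cohort` emulates the kind of cohort the model targets: N = 822
patients by default; six prognosticator-like covariates (binary stage,
grade, multiplicity, size and a rare carcinoma-in-situ indicator with
prevalences 0.35/0.30/0.40/0.25/0.05, plus standardised age); biallelic
SNPs with MAF uniform on [0.02, 0.5] in LD blocks of 10 markers (latent
Gaussian copula, within-block correlation 0.6 — strong enough that the
r² < 0.2 pruning stage actually removes markers); Hardy–Weinberg dosages
from two thresholded latent haplotypes. Two presets fix the outcome
structure: recurrence-like (K = 9 intervals, target marginal event
fraction 0.33, ĥ² preset 1%) and progression-like (K = 4, event fraction
0.09, ĥ² preset 0.1%). The default genomic scale (5 000 markers; 2 000 in
the acceptance script) is a desk-scale stand-in for a genome-wide panel;
the generator does not emulate realistic genome-wide LD maps, population
stratification, or genotyping error beyond uniform missingness — so
passing tests demonstrate statistical correctness of the machinery, not
performance on real array data.

Outcomes are generated in the model's own generative direction: per
interval, a still-followed patient is first censored with an independent
per-interval probability (default 0.02, emulating loss to follow-up),
otherwise has the event with probability 1 − Φ(γ_k − η); survivors of all
K intervals are administratively censored at the end of the study. With
the preset event fractions this yields the heavy (> 50%) right-censoring
the model is designed for. The constant baseline cutoff is solved
numerically (Brent) so the marginal event fraction at η = 0 matches the
preset; the systematic part of the liability is centred (the model absorbs
location into the cutoffs), so realised event fractions exceed the target
only by the mild convexity effect of liability variance (~0.35 realised
vs 0.33 target at default signal strengths). True SNP effects are drawn
for a chosen number of causal markers and scaled against the *empirical*
genotype variance so the realised liability-scale SNP variance fraction
equals the requested h² exactly per realisation. Missingness is injected
only after outcomes are generated — it is a measurement artefact, not part
of the disease process.

## Numerical and design choices

* Grid construction from data (`build_grid_from_survival`) places interior
  boundaries at event-time quantiles, splitting events as evenly as
  possible — the reproducible analogue of choosing cut-points from a
  survival curve; an explicit boundary list overrides it. Tied quantiles
  (e.g. heavily discretised times) raise an error suggesting a smaller K.
* Records of censored patients with time 0 vanish entirely (logged).
* Zero-variance markers: dropped with a warning in LD pruning; effect
  pinned at 0 in the sampler.
* Truncation regions of negligible mass (|γ − η| > 8) rely on scipy's
  tail-stable truncated-normal sampler; draws are always finite.
* Inverse-Gaussian draws for 1/τ² clamp the conditional mean to
  [1e-10, 1e8] purely to avoid overflow at machine-zero effects.
* Collinear covariate encodings are rejected before sampling, naming the
  offending columns.
* Fold seeds and any seed derived from a user seed come from numpy's
  `SeedSequence`, kept below 2³¹.

## Known limitations

* R²_probit/ĥ² inflation in the marker-saturated regime (see above).
* The final interval's cutoff is weakly identified by construction.
* No competing risks (death from other causes is censoring), no
  time-varying covariates, no epistasis; single-chain execution.
* The LD-pruning greedy order is a heuristic; it guarantees r² < r2_max
  among retained in-window pairs, not a maximum-size retained set.
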
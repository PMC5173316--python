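# Methods

This package implements a hybrid clinical prognosis pipeline for binary
5-year breast-cancer-recurrence prediction on mixed-scale
clinicopathologic tabular data, together with the synthetic cohort
machinery needed to exercise it without access to registry data.

## Cohort model

A patient is described by 21 features: nine interval-scale (diagnosis
age, nodal ratio NR, menarche age, pregnancy count, tumor size TS in
cm, Ki67 %, involved and dissected axillary node counts, chemotherapy
count), eleven nominal/binary (family history, multifocality, ER, PR,
p53, surgery type, HER2, cathepsin-D, hormone therapy, radiotherapy,
molecular subtype) and one ordinal (histological grade 1–4). The
outcome is recurrence within five years of diagnosis (positive class).

Two features are *derived*, never independent: NR = involved/dissected
nodes, and the molecular subtype from ER/PR/HER2/Ki67 with the 14%
Ki67 proliferation cutoff (luminal A/B, HER2-positive luminal B,
non-luminal HER2-positive, triple negative). Loading a CSV drops
incomplete records (counted) and excludes patients flagged with primary
metastasis, since stage-IV disease at registry nearly guarantees the
outcome and would leak it.

Clinical discretization uses literature cut points: age at 40 years,
NR at 0.25, TS at the 2 cm/5 cm T-stage boundaries. The age rule as
usually quoted ("under 40" vs "over 40") leaves 40 itself unassigned;
we place it in the older, lower-risk group, consistent with the
under-40 risk-group convention. NR and TS boundaries are left-closed
(0.25 and 2.0 fall in the lower bin). Discretization is idempotent and
purely a priori (fixed thresholds), so applying it before splitting
cannot leak test information.

## Synthetic cohort generator

The generator emulates the *marginal* structure of the study cohort:
per-outcome-class mean/sd/min/max for each interval feature, per-class
category frequencies for each nominal feature and grade, prevalence
0.193, and a pooled Pearson correlation of 0.56 between involved and
dissected node counts. Outcomes are Bernoulli(prevalence); interval
features are truncated normal per class; node counts are drawn jointly
through a Gaussian copula, rounded, and constrained to
involved <= dissected; NR and subtype are recomputed from their parent
features so internal consistency always holds. Everything is
deterministic under a seed.

Two numerical points deserve note:

* The tabulated mean/sd are treated as **moments of the truncated
  law**, not as the location/scale of the underlying normal: the
  two-moment inverse problem is solved per feature and class. For the
  recurrent-class involved-node count (mean 6.6, sd 7.3 on [0, 39]) no
  truncated normal attains the target sd — a decreasing density on a
  lower-bounded support caps the sd near the mean — so the mean is
  matched exactly and the sd as closely as the family allows. Real
  node counts are zero-inflated and overdispersed; emulating that was
  deliberately out of scope (the generator's job is structural).
* Rounding and the involved <= dissected constraint perturb the node
  moments and the attained correlation, so the effective marginal
  targets and the latent copula correlation are calibrated by a short
  deterministic fixed-point simulation (10 iterations of 20 000 draws
  per class, internal fixed seed, cached). At n = 5000 every per-class
  mean lands within 3 sd/sqrt(n) of its target and the pooled node
  correlation within ±0.01 of 0.56.

What the generator does **not** emulate: conditional dependence between
features within an outcome class (beyond the node pair), skewness and
zero-inflation, and any subtype marginal (subtype is derived, so its
frequencies are whatever the marker marginals imply — more
HER2-positive luminal B than the study reports, since independent
marker draws meet more often than correlated real markers do). Passing
tests on synthetic cohorts therefore validate the *mechanics* of every
stage, not clinical performance on real data; see "Known limitations".

## Statistical feature selection

Each feature is tested univariately against the outcome at alpha = 0.05,
two-sided, no multiplicity correction — the filter is deliberately
liberal because the embedded selection refines it:

* interval: Lilliefors-corrected Kolmogorov–Smirnov normality check in
  each class (plain KS with estimated mean/sd is anti-conservative);
  both classes normal at 0.05 routes to the equal-variance two-sample
  t-test, anything else to Wilcoxon–Mann–Whitney (midranks, tie-corrected
  normal approximation);
* ordinal: always Mann–Whitney on rank codes;
* nominal: Pearson chi-square without continuity correction on the
  k x 2 table; if any expected cell is below 5 the p-value comes from a
  seeded Monte-Carlo permutation null (10^4 multivariate-hypergeometric
  draws with fixed margins), which keeps small-cell features (e.g.
  radiotherapy at 98–99% positive) honest.

A constant column in the current split is reported as non-discriminative
(p = 1, flagged) rather than an error: small training splits routinely
make near-constant binary features exactly constant.

## Decision tree, weighting, bagging

The classifier is a from-scratch C4.5-style entropy tree: interval
splits on midpoint thresholds chosen by gain ratio among candidates
with at least average information gain (the standard C4.5 guard against
split-information inflation), multiway categorical splits, growth until
purity, no admissible split, or fewer than 2 x min_leaf rows
(min_leaf = 2), then bottom-up pessimistic pruning with the binomial
upper-confidence-bound error at confidence 0.25.

Feature importance enters through a transform: a 0/1 inclusion mask
over categorical features and a weight in [0, 1] per interval feature.
Because thresholds are order statistics, multiplying feature *values*
by a weight would be a no-op for a tree; the weight instead multiplies
the feature's split **score** (weight x gain ratio). Weight 0 is then
exactly feature removal (verified as a test invariant), and
intermediate weights down-rank a feature in split competition. This is
an interpretation — value-weighting is only meaningful for the
scale-sensitive SVM/MLP variants, where weights multiply standardized
values instead.

Bagging is plain Breiman: 10 bootstrap resamples of size n with
replacement (a single-class resample is redrawn once), one
grown-and-pruned tree per resample, unweighted majority vote. A 5–5
tie predicts recurrence: in a prognosis setting a false negative is
the costlier error. Unseen categories at prediction time route to the
child with the larger training mass. A balanced XOR is a known blind
spot of any greedy entropy grower (every single feature has exactly
zero gain); uneven XOR samples are solved exactly.

## Particle swarm optimization

Star-topology PSO over [0, 1]^d: the categorical block decodes by
rounding at 0.5 (binary PSO), the interval block passes through as
weights. Velocity update v' = w v + c1 r1 (pbest − x) + c2 r2 (gbest − x)
with per-component U(0,1) draws, clamp at vmax; position x' = x + v'
clamped to the unit box. Defaults follow the study: c1 = c2 = 2,
w0 = 1.00 damped by 0.99 per iteration, 20 particles, 100 iterations,
vmax = 4. Initialization (positions U(0,1), velocities U(−1,1)) and
the early-stop rule (no global-best improvement above 1e-4 for 20
iterations) fill gaps the study leaves open; the convergence tests that
demand reaching a known optimum disable the early stop, mirroring the
max-iterations-only termination used for convergence plots.

Fitness is the training-set F-score of the bagged tree refitted under
the decoded transform — resubstitution, exactly as the study's
objective, with an optional out-of-bag mode (off by default) for the
overfitting-aware. All fitness calls within one optimization share a
single bootstrap seed so particles compete on identical resamples, and
the whole trajectory is reproducible from one seed. A degenerate
all-zero transform scores 0.

## Validation battery

From a 2x2 confusion matrix (positives = recurrence): Se, Sp, Acc, Pr,
F-score, alpha = 1−Sp, beta = 1−Se, the two-point balanced-accuracy
AUC = (Se+Sp)/2 (no threshold sweep — the ensemble vote has no
threshold), LR+ = Se/(1−Sp), LR− = (1−Se)/Sp, DOR = LR+/LR−, Matthews
correlation, discriminant power DP = sqrt(3)/pi x log10(DOR), and
Cohen's kappa. The DP logarithm is base 10: reproducing the published
DP = 1.28 from DOR = 208.9 forces it (natural log gives 2.95), and a
test asserts this. Zero denominators propagate as inf/NaN with
explicit flags — no Haldane-style corrections.

Qualitative bands operate on unrounded values: DP poor/limited/fair/good
at 1/2/3; AUC excellent/very good/good at 0.9/0.8/0.7; kappa excellent
above 0.75, fair-to-good from 0.40, poor below. The clinical
reliability verdict requires Se >= 80% (power), Sp >= 95% (type I
error <= 5%) and FDR = 1−Pr <= 5%, with the LR rules (LR+ > 10,
LR− < 0.1, conservative DOR > 100) reported individually.

Classifier pairs are compared with the continuity-corrected McNemar
statistic z = (|x−y|−1)/sqrt(x+y) on the discordant misclassification
counts, signed by which classifier errs more, significant at |z| > 1.96;
when significant the higher-DP classifier is called superior. With
x = y the corrected statistic is symmetric in the pair (−1/sqrt(x+y)),
so antisymmetry holds only for x != y.

## Pipeline, scenarios, comparators

Holdout: stratified 70/30 (579 -> 405/174), stratification because
unstratified folds at 19.3% prevalence are unstable. All data-dependent
stages — filter selection, PSO, tree fitting — see only training rows
(asserted by a mutation test). Four-fold stratified CV re-runs the
entire pipeline inside each fold by default (a flag reuses the holdout
transform instead). Ablations share the split seed so McNemar operates
on paired predictions: `no_pso` feeds filter-selected features straight
into the bag; `svm_pso`/`mlp_pso` put an RBF-SVM (hyperparameters from
a one-off 5-fold grid search over C = 2^-5..2^15, gamma = 2^-15..2^3 in
octave-squared steps, fixed during the swarm) or a 10-unit
single-hidden-layer sigmoid MLP (10% validation early stopping) inside
the PSO loop. The Nottingham Prognostic Index baseline is
0.2 x TS + grade + node point (1/2/3 for 0, 1–3, >= 4 positive nodes)
with the high-risk cut at 3.4 (boundary inclusive).

## Problem sizes in the test and acceptance runs

Simulation-backed tests use sizes chosen as the package's own balance
of statistical resolution and turnaround: 200 replicate null cohorts at
n = 579 for the type-I rate, 100 replicates for the 2-SD power check,
50 cohorts of n = 400 for the bagging/out-of-bag property, n = 5000 for
generator calibration checks, and 12 replicate end-to-end runs with a
reduced swarm (8 particles, 8 iterations) for the recovery property.
The acceptance script runs one end-to-end pipeline at n = 579 with a
10-particle, 15-iteration swarm.

## Known limitations

* The generator's conditional-independence design caps what any
  classifier can achieve on synthetic cohorts: a strong boosted model
  given 40 000 training rows reaches AUC ~= 0.86 with a best balanced
  operating point near Se 0.80 / Sp 0.75. An untuned 10-tree majority
  vote at n = 579 under 19.3% prevalence therefore operates around
  Se 0.3–0.5 / Sp ~0.9 — far from the published Se 81% / Sp 98% on the
  real registry, whose joint feature structure the marginals cannot
  carry. The end-to-end recovery test (Se and Sp both > 0.70 in >= 90%
  of replicate cohorts) documents this gap and fails by design honesty
  rather than being weakened; every stage-level property passes.
* Resubstitution F-score fitness overfits by construction; the OOB
  fitness mode exists but is not the default because the default
  mirrors the original objective.
* No missing-data imputation (incomplete records are dropped), no
  survival modelling (the outcome is a fixed 5-year binary), no
  probability calibration, and no distilled rule set beyond the
  per-tree if/then export.
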
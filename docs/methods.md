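# Methods

## Model and search procedure

`agaselect` performs wrapper feature selection for a binary conversion
outcome.  The classifier is maximum-likelihood logistic regression fit by
Newton/IRLS; the selection criterion is the area under the ROC curve,
computed as the Mann-Whitney concordance statistic with midrank tie
handling (ties between a positive and a negative score count one half).

A candidate feature subset is a bitstring genome.  Its fitness is the mean
AUC from repeated balanced stratified k-fold cross-validation, plus a
parsimony bonus ρ·(1 − n_subset/n_total), or exactly 0 if the subset is
empty or exceeds n_max.  Averaging is two-level: AUC per held-out fold,
mean over folds per repeat, mean over repeats.  "Balanced and stratified"
means per-class fold counts differ by at most one, so a 40/544 cohort split
five ways puts exactly 8 positives in every fold.

The genetic search is generational with elitism of one.  Parents are chosen
by tournament of two (low selective pressure); pairs are crossed over with
the adaptive probability p_c computed from the better parent's fitness, and
offspring are mutated (single uniformly chosen bit flip) with the adaptive
probability p_m computed from the genome's own fitness, both defined
relative to the current population's maximum and mean fitness so that the
best genome is never disrupted and sub-average genomes are disrupted at the
full rates k₁, k₂.  Fitness values are cached per exact bitstring; within a
run the cross-validation fold RNG is fixed, making fitness a pure function
of the bits and the cache sound.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| k₁ | 1.0 | adaptive crossover rate (upper bound on p_c) |
| k₂ | 0.5 | adaptive mutation rate (upper bound on p_m) |
| population_size | 50 | genomes per generation |
| generations | 300 | fixed budget; no early stopping |
| tournament_size | 2 | selection pressure |
| init_skew | 1/6 | P(bit = 1) at initialization; admissible 1/8–1/4, biases toward small panels |
| ρ | 0 (sweep 0–0.6) | parsimony bonus per unselected feature, in AUC units scaled by 1/n_total |
| n_max | 50 | hard cap on panel size; larger genomes score 0 without any model fit |
| CV | 10 × 5-fold | repeats × folds of the fitness cross-validation |
| lifespan | off / 30 | random-immigration age limit, in generations |

Degenerate population (f_max = f̄, fully converged): both adaptive formulas
are 0/0, resolved to the full rates k₁/k₂ — maximal disruption to restore
diversity, consistent with the mechanism's purpose.  For freshly created
crossover offspring, which have no fitness yet, p_m uses the better
parent's fitness as a proxy; evaluating offspring before mutation instead
was measured to give indistinguishable search quality at roughly double the
evaluation cost.

## Aging, elitism and immigration

A genome's age counts generations since creation or last modification;
crossover or mutation resets it, unmodified survival increments it.  With a
finite lifespan, every genome at or past the age limit is replaced by a
fresh skew-random immigrant, except protected elites: the highest-fitness
genome ages indefinitely, and when several genomes tie at the best fitness,
half of them (rounded up, lowest indices first, for reproducibility) are
protected.  The elite genome carried forward by elitism is additionally
exempt from variation, which makes the per-generation best fitness
trajectory non-decreasing by construction.

## Non-convergence and numerical choices

Cross-validation folds of an imbalanced cohort hold few positives, so
quasi-separation is routine.  The IRLS fitter caps iterations at 25, uses
step-halving to keep the log-likelihood monotone, adds a 1e-8 ridge only if
the weighted normal equations are singular, and returns the model with a
`converged` flag rather than raising — under complete separation the
estimate is finite and its scores still rank held-out samples, which is all
AUC needs.  Probabilities go through a numerically stable sigmoid;
log-likelihoods through log1p-style accumulation.  Frequency-table ties at
the half/quartile boundary break toward the lower feature index.

## Monte-Carlo post-evaluation

Because the search maximizes the CV-AUC it also overfits it slightly, so a
selected panel is re-scored by an independent Monte-Carlo post-evaluation:
1000 stratified 80/20 train/validation splits, AUC averaged.  Splits are
stratified because with 40 positives an unstratified 20% draw can contain
no positives at all, leaving AUC undefined.

## Sub-setting and baselines

Across a batch of runs, a feature's selection frequency is the fraction of
runs whose final best panel contains it (final-best panels, not the full
evaluation archive — the batch's "solution feature sets").  The "best half"
keeps the top ⌊n_total/2⌋ features by frequency (90 of 181) and the "best
quartile" the top half of that half (45); a threshold rule keeps features
with frequency strictly above t.  The best-model variant unions the
features of the top 5% of runs by post-evaluation AUC, optionally together
with the best half.  Baselines: uniformly random same-size panels scored by
repeated CV under one shared fold partition (so scores differ only through
the panels), and forward stepwise selection minimizing AIC = 2k − 2·logL,
paused at chosen sizes for repeated-CV scoring.  AUC distributions are
compared with a two-sided Mann-Whitney rank-sum test; AUCs are bounded and
skewed, so a rank test is preferred to a t-test.

## Synthetic cohort generator

The generator emulates the study cohort the algorithm was designed for:
584 subjects, exactly 40 positives, 181 standardized features in five panel
groups (53 pathology, 7 metals, 111 immunoassay proteins, 7 plasma, 3
demographic).  Noise features are equicorrelated Gaussians within their
group (x = √r·z_group + √(1−r)·ε, default r = 0.2 — a mild shared-assay
factor typical of biomarker panels); planted informative features are
independent standard normals that act on the outcome only through the
logistic link.  The intercept is bisection-calibrated so the expected
positive count matches the target; after Bernoulli sampling the exact count
is enforced by flipping the labels least consistent with their linear
predictors (excess positives lose the lowest-η positives, deficits are
filled from the highest-η negatives), the minimally signal-perturbing
adjustment in the rare-event regime.  Missingness, when requested, is
completely at random, and imputation is per-feature median — deterministic
and robust.

What the generator does not model: real analyte distributions (units,
skewness, detection limits), between-group correlation, informative
missingness, longitudinal visits, or label noise from diagnostic
uncertainty.  Tests that pass on synthetic cohorts therefore demonstrate
the correctness and selection behavior of the machinery, not clinical
performance on real data.

## Problem sizes used in tests and examples

The shipped test suite and examples run the full algorithm at reduced
scale, chosen to exercise every mechanism while keeping a complete run in
seconds-to-minutes: the recovery experiment uses the full 584 × 181 cohort
with five planted effects (1.5, 1.3, 1.2, 1.1, 1.0 — a ladder from strong
to moderate), population 30, 50 generations, 3 × 5 CV and ρ = 0.4 over ten
seeded runs; unit tests use cohorts of 100–584 subjects and 3–20 features.
At these scales the search recovers at least four of the five planted
features in eight of ten runs and its panels dominate size-matched random
panels (rank-sum p < 0.001); study-scale settings (population 50, 300+
generations, 10 × 5 CV, 100-run sweeps) simply extend the same loops.

## Known limitations

The adaptive formulas protect the elite so strongly that a converged
population explores only through the degenerate-case mutation burst and
(when enabled) immigrant influxes; short runs can stall in local optima —
the motivation for the random-immigration mechanism and for multi-run
batches.  Selection frequencies are computed from best-of-run panels, so
features whose value is purely combinatorial can be under-counted (the
best-model union exists to mitigate this).  The stepwise baseline is
forward-only.  Only binary outcomes are supported.
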
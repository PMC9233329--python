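# Methods

This note documents the models, algorithms, calibrations and numerical
choices behind `capbws`, and what the synthetic-data tests do and do not
demonstrate.

## Instrument and scales

The OxCAP-MH has 16 items rated on 5-point Likert scales; items 2, 4, 6 and
9–16 are reverse coded (answer level 1 is the *best* capability). The
equal-weight comparator score orients all levels so higher is better, sums
them and standardises by 100 × (raw − 16)/64. The preference-based
alternative built here assigns each item a weight span equal to its mean
relative importance score over 100 and spreads it over the five levels with
factors 0, 0.25, 0.5, 0.75, 1 (worst to best). The factor vector is exposed
as configuration because proportional level spacing is a working assumption,
not an elicited fact: comparable BWS studies typically find the gap between
bottom and middle levels larger than between middle and top.

The package ships the published Austrian full-cohort mean RIS for the German
OxCAP-MH (`REFERENCE_MEAN_RIS`). These printed means are rounded to two
decimals and sum to 100.01; consequently (a) the all-best capability state
scores 1.0001 rather than exactly 1, and (b) a handful of weight-table cells
whose exact values sit on a 4th-decimal rounding boundary cannot be pinned
down from the printed means alone. The acceptance test derives, in exact
integer arithmetic, which cells the printed precision determines uniquely
(44 of 80) and requires those to match exactly; the rest must match within
one unit in the 4th decimal.

## Choice model and estimation

Sequential best-then-worst multinomial logit: best from the shown set *S*
with probabilities ∝ exp(β); worst from *S*∖{best} with probabilities
∝ exp(−β). The likelihood is invariant to adding a constant to β, so the
sum-zero convention identifies location; all reported utilities are
re-centred to sum zero, and the RIS transform
p_k = exp(β_k)/(exp(β_k) + a − 1), with a = 6 the task set size, is applied
after that re-centring (which is exactly what makes RIS well defined).

The hierarchical prior is β_i ~ MVN(μ, Σ) with μ ~ N(0, 100·I) and
Σ ~ Inverse-Wishart(16 + 2, I) — weakly informative, standard for HB-MNL.
Sampling alternates conjugate Gibbs updates of (μ, Σ) with a random-walk
Metropolis update of each β_i using a Σ-shaped proposal; the scalar step
size adapts multiplicatively during burn-in (×1.0483 on acceptance, ×0.98
on rejection, equilibrium acceptance 0.30; realised rates land near
0.25–0.30). All β_i start at 0. The likelihood is evaluated vectorised
across respondents in the log domain, so extreme utilities underflow to
small log-probabilities rather than zeros.

Defaults are 10,000 burn-in and 10,000 retained sweeps with thinning 10 for
the stored (μ, Σ) draws; β posterior means accumulate over every retained
sweep. Tests, examples and the acceptance script use a reduced profile
(400/400/1) that finishes a 158-respondent fit in a couple of seconds;
a longer 4,000/8,000 profile is used for the chain-stability check, where
doubling the retained draws moves every mean RIS by less than 0.1. Retained
μ draws carry an effective-sample-size diagnostic via arviz (optional
extra).

Respondent fit is the root likelihood — the geometric mean of the 2 × 16
modelled choice probabilities at the posterior-mean utilities. Chance level
for 6-option tasks is √(1/6 · 1/5) = 1/√30 ≈ 0.1826; the exclusion threshold
0.2 sits just above it, and exclusion is strict (RLH exactly 0.2 is
retained). With posterior-mean utilities shrunk toward the population mean,
a uniform-random responder's RLH lands at or slightly below chance and is
reliably excluded; occasionally a genuine respondent whose drawn utilities
are nearly flat is excluded too, which mirrors how such rules behave on real
data.

## Design search

A questionnaire version is 16 tasks of 6 of the 16 items. Balance targets,
in lexicographic order: exact item replication (r = 6, guaranteed by
construction of the random start), minimal variance of pairwise
co-occurrence counts (ideal λ = 2 — the (16, 6, 2) biplane exists), and
even display-position counts (lowest priority, guarding against
reading-order bias). The search runs random restarts of a best-improvement
hill climb over swaps of item occurrences between tasks. Because the mean
co-occurrence is fixed, the objective change of a swap reduces to a linear
function of co-occurrence row sums (net changes on items shared by the two
tasks cancel), evaluated vectorised over all candidate swaps of a task
pair. Restarts stop early when a perfectly pair-balanced version is found;
at the study size this typically happens within ~10 restarts (~0.1–0.5 s
per restart), so tests and the acceptance script use 10–50 restarts while
the CLI default remains 1000. The three versions come from independent
seed streams spawned from the master seed: they share items, not tasks, and
every version satisfies per-version balance. Fixed seeds make generation
bit-identical across runs.

## Synthetic cohorts

The generator emulates the survey's structure: cohorts of 53 psychiatric
patients, 50 primary-care patients and 55 mental-health experts (158
respondents), gender mixes of 60/64/55 % female, three questionnaire
versions assigned round-robin within cohort, complete responses for
everyone. Latent utilities use exactly the hierarchical MNL the estimator
assumes — deliberately, so that parameter recovery is a well-posed check of
the estimation machinery; a logit-scale multiplier is available as a
misspecification toggle.

Calibration (chosen once): cohort base mean utilities are the
back-transform of the published full-cohort mean RIS (the unique sum-zero
solution of the RIS formula); between-respondent heterogeneity is diagonal
with SD 1.35 per item utility, which reproduces the magnitude of the
published within-cohort RIS dispersion (≈ 4–6 units); cohort structure is
confined to two items, matching the published pattern — *Freedom of
expression* shifted −0.7 for psychiatric patients and *Having suitable
accommodation* −0.8 for experts, the utility-scale equivalents of the
published cohort RIS gaps. `calibrate_standardized_shift` solves (by
bisection on a fixed Monte-Carlo sample) for the shift that produces an
effect of a prescribed size in within-group SD units; the power
simulations plant one-SD effects this way.

What the generator does *not* emulate: item non-response, straight-lining
and other response styles, attribute-order effects, respondent fatigue, and
any misspecification of the choice model itself (unless toggled). Passing
recovery tests therefore demonstrate that the pipeline's estimation,
exclusion, testing and weighting stages are correct and internally
consistent — not that the model is adequate for any particular real survey.

## Cohort comparison and regression

Kruskal–Wallis tests run per item on *individual-level* RIS (the only
choice that yields a valid rank test; the published tables print only
cohort means), using midranks with the standard tie correction and the
χ²(2) approximation. P-values are never multiplicity-corrected; all 16 are
always reported. Because each respondent's scores sum to 100, a planted
shift on one item induces small opposite spillover on the other 15; in
power simulations the planted items must dominate all spillover rejection
rates, and nominal-5 % behaviour is checked on an exactly-null simulation
(2,000 replicates, Kolmogorov–Smirnov uniformity at α = 0.01).

Per-item regressions use OLS of RIS on a male indicator, psychiatric and
expert cohort indicators and an intercept (reference: female,
general-population cohort), reported in that column order. Robust variances
come from the jackknife: each participant omitted in turn, the estimation
stage re-run, all 16 regressions re-fitted, and
v̂_kj = (n−1)/n Σᵢ (β̃_kj^(−i) − β̂_kj)²; two-sided p-values use t with
n − J − 1 df (153 at n = 158). The inclusion set is frozen from the
full-sample fit — leave-one-out replicates never re-apply the RLH rule, so
sample composition varies only by the omitted participant. Replicates that
re-run the HB stage use a reduced MCMC profile with a fixed per-replicate
seed (recorded in output metadata); a CSV checkpoint persists completed
replicates so an interrupted run resumes rather than restarts. Stubbing the
estimation stage to the identity reduces the procedure to delete-one OLS,
which is how its correctness is audited (agreement with direct refits to
10⁻¹⁰; the naive-loop variance formula to relative 10⁻¹², i.e. up to float
summation order).

## Numerical and formatting choices

1-based item, task, position and level indices everywhere; CSV files are
comma-separated UTF-8 with mandatory headers; weight tables export at 4
decimals while all computation keeps full precision; ranks break ties by
item number, making every rank vector a permutation of 1..16; Pearson
correlations of a constant column are reported as NaN with a named warning,
never silently zeroed; every pipeline output carries a JSON sidecar with
seed, configuration hash and file hash, and identical configurations
reproduce byte-identical outputs.

## Known limitations

Only object-case BWS: no profile-case (level-augmented) designs or
estimation, and no latent-class segmentation. The proportional level-factor
assumption is provisional (see above). The indicative weight set inherits
the printed two-decimal precision of its inputs. The jackknife around a
full-profile HB re-estimation is expensive (n complete MCMC fits); the
reduced-profile default trades some Monte-Carlo noise in the replicates for
tractability and is recorded in the output metadata.
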
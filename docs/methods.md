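# Methods

## Model and posterior odds

Outcomes `y_i ∈ {0,1}` follow a logistic regression with an intercept and a
subset `s` of the ν candidate variables. Model `s` has prior probability
proportional to `μ^|s|` (independent prior inclusion odds `μ` per variable,
identical for all variables) and nonzero coefficients carry a Normal prior
whose precision is `h` times the information in one observation (`h = 1` is
the unit-information prior). Under Johnson's large-sample approximation the
posterior odds of `s` against the null model reduce to

    log PO_s = |s| · [ log μ + ½(log h − log(n+h)) ] + (n/(n+h)) · log R_s ,

with `R_s` the ratio of maximized likelihoods. The Fisher-information matrix
appearing in the underlying prior is absorbed by this approximation and is
never computed. The exponent `n/(n+h)` is applied exactly, not approximated
to 1, so worked examples are bit-reproducible; as `n → ∞` with `h` fixed the
per-variable penalty converges to the BIC form `log μ − ½ log n` (asserted
numerically in the tests at n = 10³, 10⁶, 10⁹). All odds arithmetic is in
natural-log space with log-sum-exp pooling: |s| in the tens at n ~ 10⁵
overflows linear-scale odds.

Hypotheses are groups: the null `ω_v` for a set `v` of variables states all
their coefficients are zero. Its posterior odds are the mass ratio of models
including at least one member versus none — a functional of the single model
posterior, so arbitrary groups can be tested after sampling at no extra cost,
and a group containing a significant subgroup is significant by construction.

## Calibration: one threshold, two error rates

With `c = ν μ √(h/(n+h))`, the model-averaged deviance `2 log(PO/c)` is
asymptotically χ²₁ under the null. Rejecting at `PO > τ` therefore controls
the Bayesian FDR (local and global) at `1/(1+τ)` and the FWER in the strong
sense at `α = Pr(χ²₁ > 2 log(τ/c))`; equivalently each test's
`p* = Pr(χ²₁ > 2 log(PO/c))` is a multiplicity-adjusted P-value, and the two
rejection rules coincide exactly (a tested invariant). χ² tails are computed
through the log survival function so −log10 p* of several hundred remains
representable. The χ²₁ approximation is conservative only for small
P-values; adjusted P-values above 0.02 are therefore reported as "n.s./–"
(they are still computed and retained in machine output). Display follows
the reporting conventions of the field: PP to one decimal, −log10 p* to two.

Saturated estimates (a group included in every pooled draw, or none) are
bounds, not estimates. They are rendered as explicit "> / <" bounds computed
with a single pseudo-count against the pooled draw total N (odds N/1 or 1/N),
which is monotone in N; the published analysis prints such bounds without
stating its convention, so this one is the package's own.

## Fitting and collinearity

Fits are Newton/IRLS with intercept, convergence at relative log-likelihood
change < 1e-10 or 50 iterations, with step-halving for stability. The
intercept is always present and never counted in |s| or penalized. Designs
that are rank-deficient at a relative SVD threshold of 1e-8 (duplicate
columns, complementary indicator pairs) are assigned zero likelihood, which
bars collinear models from the posterior. Non-convergent fits (e.g. perfect
separation on rare indicators) are treated as unavailable models: the
sampler rejects such proposals, which preserves a proper target over the
fittable models; this handling is the package's choice, as is the
separation policy generally. Fits are memoized by sorted index tuple — the
sampler revisits models constantly and the cache is the dominant cost lever
(a 48,000-iteration desk run typically needs a few hundred unique fits).

## Sampler

Metropolis–Hastings over inclusion vectors. Moves add, remove, or swap with
relative weights 9:9:2, renormalized when a move is impossible (empty or
full model). Add/remove pick uniformly from the excluded/included sets; a
swap removes a uniformly chosen included variable and draws its replacement
from the excluded set with probability ∝ (r² with the removed variable + ε),
ε = 1e-6 so zero-correlation replacements stay reachable (irreducibility).
Whether the *removed* variable should also be correlation-weighted is
ambiguous in the source description; only the replacement is weighted here.
The Hastings ratio accounts for the renormalized move menu and the swap
weight normalizations in both directions; a deliberate-mutation test
verifies that dropping the correction demonstrably shifts the sampled
distribution off the enumeration oracle (the effect is largest at the
empty-model boundary).

Chains are initialized spread across the correlation structure: variables
are clustered by k-medoids (hand-rolled alternating algorithm; no installed
package provides one) under distance 1 − |Spearman ρ| — Spearman chosen as
the rank correlation, the variant being unspecified in the source — and
each chain starts at a cluster medoid, growing by furthest-neighbour
addition to the configured start size. Per-chain seeds are spawned from the
master seed via `numpy` SeedSequence, so results depend only on (data,
seed), not on scheduling; same-seed runs are bit-identical. Monte-Carlo
standard errors are the SD of per-chain means over √(number of chains).

The default configuration is desk-scale — 8 chains, 2,000 burn-in, 10,000
sampling — chosen so that an enumerable-ν validation run completes in
seconds while pooled estimates resolve probabilities to ~10⁻⁴; the
study-scale configuration (100 chains, 25,000 + 75,000) is expressible with
the same fields. The principal correctness test compares pooled inclusion
probabilities and group odds against exact enumeration (cap: ν ≤ 15,
i.e. 32,768 fits) within 3 MCSE plus the 1/N resolution of a saturated
estimate.

## Conditional effects

Coefficients are simulated by post-processing the draws: for each stored
draw whose model includes the variable, one value is drawn from a Normal
centred at the shrunken MLE `(n/(n+h))·β̂_s` with variance `(n/(n+h))·v̂_s`.
The mean and SD over simulated values pool within-model (Wald) and
between-model uncertainty and are reported as "effect / SE when included".
The `n/(n+h)` unit-information shrinkage form is this package's reading of
the prior — the source does not print its parameterization — validated by
internal consistency: at `h → 0` the summary recovers the MLE and Wald SE,
at `h = n` the centre halves, and the simulated moments match the
closed-form Normal-mixture moments over sampled models.

## Grouping

*Predefined*: UPGMA (average linkage) on distance `1 − r²`, implemented
directly (naive O(ν³), fine at desk scale) so ties can be broken
deterministically by lowest cluster id; scipy's average linkage is the
independent reference in tests. "Broad clusters" label the coarse
structure: maximal tree nodes with ≥ 20 members (default) and mean pairwise
r² ≥ 0.02 that additionally survive the tree cut at height 1 − 0.02. The
cut is necessary, not decorative: under average linkage a node's merge
height is 1 minus the mean r² *between* its two subtrees, and without the
cut a merge of several internally tight but mutually uncorrelated blocks
can still pass the mean-r² filter, so a single node would swallow the whole
structure. Significance reporting walks the tree and emits only minimal
significant nodes, suppressing ancestors (which are significant by
implication).

*Post hoc*: the correlation matrix of per-draw inclusion indicators is
mapped to distance `d = 1 + corr` — the strongest *negative* correlations
(variables that substitute for one another in the model) become the
smallest distances; the source specifies the correlation as the distance
without fixing the transform, and this monotone choice matches the stated
intent. Clusters are extracted by scikit-learn's OPTICS with xi = 0.05
(`min_samples = 2`, suited to the dozens-of-variables scale at which the
package runs). Variables with zero inclusion variance are excluded with a
warning.

`remove_correlated` drops every variable correlated at `r² ≥` threshold
with any member of an anchor set (anchors kept by default), supporting
re-running a scan with a category of variables and everything echoing it
removed.

## Curation rules

First instance of repeated measures; exclusion of factors over 50 observed
levels (with a per-column exemption flag, e.g. self-reported illness lists)
and of columns missing in over 15% of participants — both strict
inequalities, so boundary cases are kept; mean imputation of
continuous/integer columns (no rounding of integers); one 0/1 indicator per
factor level observed above 0.2% frequency, with missing as its own
indicator-free level (both levels of a binary factor qualify, giving a
complementary pair that the collinearity rule keeps out of any one model);
one indicator per event code above 0.2% frequency dated strictly before the
cutoff (default 2020-01-01); optional seeded down-sampling of controls.
Frequency floors use the post-exclusion participant set as denominator (the
source does not state its denominator). Every input column receives exactly
one disposition in the encoding report, and the emitted design contains no
missing values.

## Synthetic cohorts

Blocks are equicorrelated via a one-factor construction: with target
within-block r², every column loads √ρ (ρ = √r²) on a shared standard
Normal factor, so all pairwise correlations are ρ and pairwise r² hits the
target in expectation — chosen over arbitrary covariances for its
closed-form target and cheap generation. Binary columns threshold the
latent Gaussian at the prevalence quantile; the tetrachoric attenuation of
binary–binary correlation is accepted, not corrected. Outcomes are
Bernoulli(logistic(intercept + Xβ)). The default biobank-like cohort mixes
a near-duplicate pair (r² = 0.81), moderately and weakly correlated
clusters, independent covariates and rare binary indicators (1–5%
prevalence) with a ~1% outcome prevalence, mirroring the statistical
structure the method targets.

What the generator does *not* emulate: real marginal distributions,
missingness mechanisms, field-specific level structures, or outcome
misclassification. Passing tests therefore demonstrate the *statistical
machinery* — calibration, oracle equivalence, recovery, dilution — not
fidelity to any particular cohort.

Battery conventions, fixed up front: the null (FWER) battery runs ν = 20
independent Gaussian variables at n = 2,000 with 10% outcome prevalence and
prior μ = 1/(ν−1) (prior expectation of one included variable — the
sparse-prior analogue of the study's 10-in-1,912); each replicate uses 4
chains × (500 burn-in + 2,000 sampling), enough to resolve the
posterior-odds thresholds τ ∈ {3, 10} being tested. The recovery battery
uses n = 5,000, ν = 20, three effects |β| = 0.7 and 10% prevalence — a
case-enriched design of the kind produced by control down-sampling; at the
study's 1% prevalence this n would carry ~50 cases, which is not the regime
the recovery scenario describes. Empirical FWER is compared to the
asymptotic α recomputed at the battery's own ν and n.

## Known limitations

Single outcome family (binomial), additive linear predictors only — no
interactions or nonlinear terms; direct effects only, not total effects;
the FWER guarantee is asymptotic and checked by simulation, not proved at
finite n; k-medoids initialization is a plain alternating heuristic; the
O(ν³) UPGMA and the enumeration oracle are desk-scale tools, not
biobank-scale ones (the sampler itself scales, the oracle does not).
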
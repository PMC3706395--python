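# Methods

## The model

The response is a per-species binary label, "high impact", defined as
serious impact to at least one of three sectors (environment, pastoral
industry, agriculture); each sector also carries its own flag, and the
overall label is their disjunction (validated on load).  The model is a
binomial generalized linear mixed model with logit link,

    logit Pr(high impact_i) = x_i' beta + u_g(i),   u_g ~ Normal(0, sigma^2),

with a single random intercept per genus — no random slopes, no nesting,
no crossed effects.  Genus membership captures the idea that congeners of
damaging species are themselves more likely to be damaging, without
spending a fixed-effect parameter per genus (most genera here have one or
two members).  A Gaussian analogue with the same structure models
log spread rate, where spread rate is regions occupied per decade since
first naturalisation (whole calendar years / 10; only years are recorded).

Assumptions worth keeping in mind: genus effects are Normal and
exchangeable; species are independent given genus; predictors are measured
without error; and spread rate — itself an outcome of invasion history —
is treated as a predictor, so its coefficient is associational, not causal.

## Estimation

The marginal likelihood integrates the genus intercepts out of each genus's
Bernoulli likelihood.  Each one-dimensional integral is evaluated by
adaptive Gauss–Hermite quadrature: the integrand's conditional mode is found
by damped Newton (the conditional log-density is strictly concave, so this
is globally safe with a step cap), the rule is centred and scaled there, and
15 nodes are used by default; one node reproduces the Laplace approximation.
The outer optimisation over (beta, log sigma) is L-BFGS-B with an analytic
gradient computed as the posterior-expected complete-data score under the
same quadrature weights.

The quadrature objective can be visibly wrong (order 1e-2 in log-likelihood)
for heavily skewed integrands that arise at degenerate boundary fits — huge
sigma on nearly separated data.  The *reported* log-likelihood is therefore
re-evaluated at the optimum with a dense mode-centred trapezoid rule whose
interval covers both the likelihood and the prior scale (the integrand is
log-concave, so this is effectively exact).  Fitted AICc values and rankings
use this exact evaluation.

Numerical choices:

- sigma is parameterised as log sigma, bounded in [e^-7, e^3]; a fit at the
  lower bound is reported as a (legal) near-zero variance.  Warm starts
  inherit beta but re-centre log sigma into [log 0.2, log 2]: a start pinned
  at the variance boundary has a flat gradient and can stall the optimiser.
- Plain-logistic IRLS (ridge-damped) supplies starting values when no warm
  start is given.
- Convergence: optimiser success or projected-gradient norm < 1e-3; any
  coefficient with |beta| > 30 flags the fit as non-converged (on the logit
  scale this only happens under (quasi-)separation, where the MLE diverges).
  Non-converged fits are never silently accepted: searches rank them last
  and flag them, the bootstrap redraws, cross-validation records a missing
  probability with a warning.
- Gaussian models are fitted by full maximum likelihood, not REML, because
  AICc comparisons span different fixed-effect structures; the variance
  profile is optimised with the GLS beta profiled out in closed form
  (compound-symmetric covariance, Woodbury identity).
- Categorical predictors use treatment contrasts with reference levels
  annual (life history), no (growth forms), pasture_or_turf (introduction
  pathway); the choice moves only the intercept's interpretation and is
  recorded in fit output.  Indicator columns are built for the levels
  present in the data being fitted, so subsets missing a level stay full
  rank; genuine rank deficiency raises an error naming the collinear
  columns (QR with pivoting).
- Calendar years are centred at 1900 before entering the design matrix,
  purely for conditioning; slopes are unchanged.
- AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1), with k = #fixed coefficients + 1
  (genus variance) + 1 more for the Gaussian residual variance.  When
  n <= k+1 the correction is undefined; such fits carry NaN AICc and are
  excluded from weights with a warning.
- Ties in rankings break deterministically: fewer predictors first, then
  lexicographic predictor names.

## Model selection and classifier evaluation

The search fits every subset of the candidate predictors (including the
random-effect-only model; nine impact predictors give 512 models) and ranks
by AICc with Akaike weights exp(-Delta/2), normalised.  The number of
occupied regions is allowed only in the spread-rate analysis — for the
impact response it is nearly collinear with spread rate itself.

AICc implicitly weights false positives and false negatives equally, which
is the wrong loss for biosecurity, so models are also scored directly as
classifiers.  Genus-constrained leave-one-out produces held-out
probabilities: each species whose genus has at least two members is removed,
the model refitted (warm-started from the full-data fit), and the species'
probability predicted using the refit's genus conditional mode — the
random effect's posterior mode given the remaining congeners.  Singleton-
genus species are excluded: their genus would vanish from the refit, making
a genus-aware prediction impossible.  On the study structure (155 species,
21 singletons) 134 species are eligible.

The threshold sweep evaluates {0} ∪ {unique probabilities} ∪ {1} with the
strict rule "predicted positive iff q > t"; every distinct (f, p) operating
point is attained on this grid (verified against brute force in tests).
The score is the weighted Euclidean distance from the best operating point
to the perfect classifier, min_t sqrt(w(1-p(t))^2 + (1-w)f(t)^2).  The
scaling anchor divides by sqrt(w(1-w)) — the minimum the same distance
attains along the random-guessing diagonal p = f, reached at p = f = w —
so a perfect classifier scores 0 and a random one scores 1 for every
w in (0, 1); anti-correlated classifiers can exceed 1.  The degenerate
weights w ∈ {0, 1} reduce to a single unweighted coordinate and are always
0 at a trivial threshold; they are supported but uninformative.  Larger w
places more weight on attaining true positives (w = 0.9 prioritises
catching high-impact species over avoiding false alarms).

## Bootstrap and sector analyses

Coefficient uncertainty for a chosen model comes from a genus-stratified
bootstrap: within each genus, species are resampled with replacement,
keeping every genus's sample size (and hence the grouping structure) fixed;
singleton genera are always carried over unchanged.  Draws with fewer than
15 high-impact species (configurable) are rejected and redrawn — with ~13.5%
prevalence such draws are rare but would push the refit toward degeneracy.
A hard cap (100 × n_reps attempts) guards against unbounded rejection
loops.  Each accepted draw is refitted and the fixed coefficients plus each
genus's intercept (fixed intercept + conditional mode) recorded; intervals
are percentile 2.5/97.5 — nothing fancier is warranted by the procedure
being emulated.  Resampled duplicates get uniquified species ids; genus and
predictors are untouched.

Per-sector analyses rerun the AICc search on each sector's flag with the
five-level introduction pathway dropped from the pool (256 models): with a
handful of positives per sector, five pathway levels cost too many
parameters and break convergence.  Because so few species are positive per
sector, a parametric randomisation guards against noise-fitting: responses
are simulated from the fitted model (fresh genus intercepts, then
Bernoulli), refitted, and the proportion of simulated |coefficients| at or
above the observed |coefficient| reported.  The simulation count is a free
parameter (default 500).

## The synthetic generator

Real species tables of this kind are compiled from herbaria and expert
interviews and are typically not redistributable, so the package ships a
generator that emulates the published structure of such a dataset:

- 155 species in a skewed genus-abundance structure: four large genera
  (16, 14, 11, 6 species), 21 singleton genera, the remainder geometric
  in [2, 6];
- incidence (herbarium record count) lognormal (meanlog 4.531, sdlog 0.75,
  matching a mean of ~123 records and a maximum of ~705), with regions
  occupied tied to incidence by the power law regions = 0.868·x^0.637,
  clipped to [1, 71];
- naturalisation years in 1850–1988, negatively coupled to incidence
  (Gaussian copula, 0.7): widely recorded species naturalised earlier.
  Without this coupling the implied mean spread rate (~2.6 regions/decade)
  overshoots the ~1.9–2.1 such datasets show;
- trait marginals: 10/155 semi-aquatic, 60/155 actively spread, 110/155
  perennial-or-both, 14/155 contaminant-pathway.  The remaining pathway and
  growth-form frequencies are not published as exact counts and are set to
  plausible values (documented in `SyntheticConfig`);
- impact model: logit P = intercept + 0.63·spread_rate + 2.05·semi_aquatic
  + genus intercept, genus_sd 0.5.  The slope and the semi-aquatic offset
  are the reported effect sizes; the genus SD is a free choice (the source
  analysis found genus explained little, but gives no variance estimate).
  The default intercept (-3.63) is calibrated by Monte Carlo so the default
  generator attains the 13.5% prevalence given its own spread-rate
  distribution; the implied near-zero-spread terrestrial probability stays
  ~0.03 (semi-aquatic ~0.17–0.19).
- sector flags exist only on high-impact species, split 13:7:5
  (env:pastoral:agri) with a 4-in-21 multi-sector rate.

`generate` draws all of this stochastically; `default_fixture` (seed 2009)
enforces the structural counts exactly by stratified assignment — including
exactly 21 high-impact species of which 5 are semi-aquatic, and an
all-perennial pastoral sector — because the worked examples downstream
(134 eligible hold-outs, 13/7/5 sector counts) need exact counts, not
expectations.

What the generator does **not** emulate: real trait–trait correlations
(growth form vs life history), phylogenetic signal beyond the genus
intercept, herbarium sampling effort, spatial structure among regions, or
time-resolved spread.  Tests passing on synthetic data therefore certify
the machinery — estimation accuracy, selection behaviour, interval coverage
under the assumed model — not the ecological conclusions one would draw
from any real dataset.

## Problem sizes used in the test battery

Simulation-based checks are sized to run on a single CPU at desk scale:
coefficient-recovery bias uses 200 replicates of n = 2000 species;
bootstrap-interval coverage uses 100 replicates of n = 500 species with 150
bootstrap resamples each; the likelihood-vs-quadrature battery uses 100
random datasets of ≤ 5 genera / ≤ 30 species.  The full pipeline's default
Weuc stage ranks the top 20 AICc models (configurable up to all 512; the
cross-validation refits, not the scoring, are the expensive part — one full
512-model leave-one-out pass is ~70,000 mixed-model fits).

## Known limitations

- The AICc count k treats the genus variance as one parameter; boundary
  fits (variance ~0) make this conservative.
- The within-genus resampling scheme has a real finite-sample pathology
  that the coverage simulation in the test suite measures directly:
  duplicated congeners are perfectly concordant, so bootstrap refits
  overestimate the genus variance severalfold, and — because conditional
  logit slopes scale with the random-effect variance — the slope draws are
  pushed upward.  Under the default generative conditions the percentile
  interval's coverage of the generating spread-rate coefficient is well
  below nominal (the suite's simulation finds roughly two-thirds instead
  of 95%).  This is a property of the emulated procedure, not of the
  fitter (refits agree with independent mixed-model software to three
  decimals); treat these intervals as descriptive of the resampling
  distribution, not as calibrated frequentist intervals.
- Leave-one-out refits that fail to converge yield missing probabilities
  (with warnings) and shrink the eligible count; the threshold sweep is
  then over fewer species.
- With very few positives (per-sector analyses) many of the 256 searched
  models sit at or near separation; they are flagged, ranked last, and
  should be read as "not estimable", not as evidence.
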
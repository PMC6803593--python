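# Methods

## The estimation problem

EQ-5D utility indices have an awkward distribution for regression: they are
bounded above by 1 with a large point mass there (the ceiling of respondents
at full health), bounded below by the tariff's worst-state value (often
negative), multimodal, left-skewed, and — because a tariff is a finite set of
values — there is an empty interval between 1 and the second-best value Ψ
that no observation can occupy. `kdqolmap` estimates functions predicting
this index from KDQOL-36 subscale scores, for use when EQ-5D was never
administered. Four estimator families are implemented; their comparison under
cross-validation is the core workflow.

## Value sets

A `ValueSet` maps every health state (five items × L levels, L ∈ {3, 5}) to a
utility. Two forms: *additive* (an any-problem constant plus per-dimension,
per-level decrements — the dominant published parameterisation) and *table*
(an explicit map over all L⁵ states, for tariffs with interaction terms).
Floor, ceiling and Ψ are derived by enumeration and cached; the invariant
that no state value lies in (Ψ, 1) holds by construction of Ψ. States are
enumerated lexicographically, first dimension slowest, and every
state-probability vector in the package uses that order. Ψ is a *value*, not
a state, so ties among second-best states are immaterial.

Country tariffs are deliberately not bundled (they are licensed data; one 5L
set used in the motivating literature is unpublished). The bundled TOY3L /
TOY5L tariffs are synthetic, chosen to exercise the important geometry: a
negative floor (−0.50 / −0.28) and a visible gap (Ψ = 0.85 / 0.93).

## Explanatory variables

Two variable sets: *summary* (PCS, MCS, KDCS) and *subscales* (PCS, MCS,
Symptoms, Effects, Burden), each with three expansions: main effects; plus
squares of the KDQOL scores; plus all two-way interactions among them. Age
and sex (male = 1) always enter additively and are never squared or
interacted. Feature counts per expansion are {6, 9, 12} and {8, 13, 23}
including the intercept. PCS and MCS are consumed as precomputed inputs: the
SF-12 summary scoring depends on proprietary norm-based weights, and nothing
downstream needs the item-level data. KDCS is the unweighted mean of
Symptoms, Effects and Burden, recomputed (and cross-checked when supplied) at
load time.

Internally, scores are divided by 100 and age by 10 before optimisation.
Polynomial terms are built from original-scale scores and then divided by the
product of their parents' divisors, so scaled-fit coefficients map exactly
back to original units and predictions are invariant to the scaling.

## Direct models

**OLS** is the baseline; its predictions are intentionally unclamped, since
its tendency to leave the feasible range is one of the things the comparison
measures. Fitting is a rank-revealing least-squares solve; rank deficiency is
an error naming the collinear columns.

**ALDVMM.** A C-component mixture (C ≤ 3) of normals with means x'β_c and
scales σ_c; a latent at or above Ψ is observed as 1, at or below the floor as
the floor, otherwise as itself. Observations exactly at Ψ are treated as
continuous-part realisations — the point masses exist only at 1 and the
floor. Membership probabilities are constant logits by default
(covariate-dependent logits are available); the default keeps the parameter
count down at the sample sizes this field works with (a few hundred
records). Estimation is maximum likelihood with analytic gradients,
L-BFGS-B, and OLS-anchored multi-starts (the anchored start spreads component
intercepts across the outcome range; the remainder perturb it). Convergence
requires gradient norm below 1e-5 with relative likelihood change below
1e-9; log σ is bounded to [log 5e-3, log 4.5] because every normal mixture
has degenerate σ→0 likelihood spikes and the bound removes them without
affecting interior optima. A fit where no start converges is returned flagged
`converged=False` — never an exception — so a model grid can exclude it, and
reported components are sorted by intercept to fix the labelling.

Prediction uses the closed-form doubly-censored-normal expectation
`(1−Φ(b_c)) + Φ(a_c)·y_min + (Φ(b_c)−Φ(a_c))·μ_c − σ_c(φ(b_c)−φ(a_c))`
mixed over components; it is always inside [floor, 1].

**BETAMIX.** A two-part model. The discrete part is a multinomial logit over
{floor atom, Ψ atom, ceiling atom, continuous}; the Ψ atom is included by
default and can be switched off (the descriptive accounts of this model
family differ on whether Ψ carries an atom, so both are supported). The
continuous part rescales y to z ∈ (0, 1) over (floor, 1) by default — or
over (floor, Ψ), `rescale_to_psi`, which is the self-consistent choice when
no observation may exceed Ψ — and fits a K-component beta mixture (default
K = 2) with logit-linked means and free precisions. The two parts are
likelihood-separable, so fitting is exact two-stage ML: scikit-learn's
logistic regression (C = 1e6, effectively unpenalised but finite under
quasi-separation) and a multi-start L-BFGS-B with analytic digamma-based
gradients for the mixture. z values that land numerically on 0 or 1 are
nudged by 1e-6 with a logged warning.

## Response mapping (SUROPM)

One ordered-probit equation per EQ-5D item — strictly increasing cutpoints
via log-increment parameterisation, no intercept (the cutpoints absorb it) —
with the five latent errors jointly MVN(0, R). R is parameterised through
row-normalised Cholesky factors, so it is positive definite with unit
diagonal at every optimizer iterate. The likelihood of a response vector is
a 5-dimensional rectangle probability, evaluated by a GHK recursive
importance sampler with 200 scrambled-Halton, antithetically paired draws
(fixed seed ⇒ deterministic). When R = I the GHK estimate is exact — the
recursion collapses to the product of univariate interval probabilities —
which provides the package's main correctness oracle: the whole pipeline must
agree with five independently fitted ordered probits.

Estimation is staged: (1) five independent ordered probits (statsmodels),
which are consistent for θ and κ because MVN marginals are univariate
probits; (2) maximum simulated likelihood over the 10 correlation parameters
with θ, κ fixed; (3) optional joint refinement of everything
(`refine="joint"`, numeric gradients, capped iterations). Grid
cross-validation uses the two-stage estimator; the refinement changes the
simulated likelihood only marginally at these sample sizes and costs an
order of magnitude more.

Prediction enumerates all L⁵ states, computes each state's GHK probability
with the same draw set (batched, chunked at ~2·10⁵ bound rows to bound
memory at 5L), clips at 0 and renormalises to sum exactly 1, then takes the
tariff-weighted average. Per-record value sets are supported (pooled
estimation with country-specific valuation). Note one structural difference
from the direct models: the expected utility is a convex combination of
tariff values and may legitimately fall inside (Ψ, 1).

Response mapping needs observations at every level of every item; an
unobserved level is a hard error by default, with explicit merging of sparse
adjacent levels (`merge_levels`) as the opt-in remedy; the merge is recorded
in the fitted parameters and honoured at prediction time.

## Cross-validation and selection

10-fold random partition (sizes differing by at most one), one shared fold
assignment per dataset so all models are compared on identical splits.
Out-of-fold predictions are pooled (per-fold averaging is available) and
summarised as ME = mean(pred − obs) — the sign convention matters and is
stated here because published tables rarely define it — MAE, and RMSE.
RMSE ≥ MAE ≥ |ME| always (Jensen); the `CVMetrics` container enforces it.
Any fold's non-convergence marks the whole model non-converged and excluded
from ranking.

Models are ranked on MAE and on RMSE; the rank sum decides; rank-sum ties go
to the lower RMSE. Within each metric column, ties at the printed precision
are broken by the *other* metric and then grid order. This tie rule was
chosen because it is the only deterministic rule that exactly reproduces a
published 30-model ranking table from its printed 4-dp metrics (reference
fixture under `tests/data/`); plain minimum ranking is available as
`ties="min"`. The companion 34-model 5L table is *not* exactly reproducible
from printed values — its tied entries were evidently ranked on unrounded
metrics — and the fixture test asserts exactly that.

Spearman correlations (average ranks for ties) are banded at
0.30/0.50/0.70/0.90 into low / moderate / high / very high, with |ρ| < 0.30
reported as below-low. The correlation report omits KDCS × its own
components (the correlation is structural, KDCS being their mean).

## Synthetic data

The generator emulates what the estimators assume, not any real dataset:

* Scores: a latent MVN over the five subscales with target means/SDs matching
  a French dialysis sample (PCS 39.90 (10.09), MCS 46.51 (9.61), Symptoms
  78.48 (20.18), Effects 70.55 (24.45), Burden 48.20 (28.82)), moderate
  positive correlations (0.30–0.60; no pair high), clipped to [0, 100] with
  the clip rate recorded on the output. Clipping is the accepted distortion
  of this design: the right-skewed subscales lose 1–2 points of mean and a
  few points of SD at the 100 boundary; tests bound rather than eliminate
  this. Age is a normal (66.6, 14.1) resampled below 18; sex is Bernoulli
  (62.5% male).
* Outcomes, two model-matched DGPs: `aldvmm_dgp` (draw component, draw
  latent, censor at Ψ and the floor — defaults calibrated to ~25% full
  health and mean utility ~0.61 under TOY3L) and `response_dgp` (correlated
  latents thresholded into item levels, valued by the tariff — defaults put
  ~26% at full health with every level of every item well-populated at
  n = 300). Model-matching makes parameter recovery a fair oracle; a
  response-DGP dataset fitted by direct models doubles as the mismatched
  robustness case.
* Every run is reproducible from the seed, and a truth sidecar (JSON)
  records all generating parameters.

What passing tests on this data do **not** show: real KDQOL-36 scores are
item-derived (discrete, multimodal), real utility distributions differ by
country tariff, and real score–utility relations need not follow either DGP.
The generator validates the estimation machinery, not clinical claims.

## Verification design

* Worked examples with published inputs: KDCS means of three published
  samples (65.74, 75.69, 65.74); a published 30-model ranking table
  reproduced rank-for-rank.
* Propriety: point masses plus quadrature of the continuous density total 1
  (tolerance 1e-8) over a 50-point parameter sweep for both bounded
  observation models.
* Oracles: OLS vs normal equations (1e-8); single-component beta part vs
  statsmodels `BetaModel`; SUROPM at R = I vs independent ordered probits
  (1e-6 per record); state probabilities vs marginal factorisation, plus raw
  orthant sums within 1e-3 of 1 before renormalisation; value-set floor/Ψ vs
  exhaustive enumeration.
* Parameter recovery at n = 5000 (ALDVMM 1- and 2-component with
  well-separated intercepts; BETAMIX K = 2 on the Ψ-rescaled support) with
  every identified parameter within 2 observed-information SEs of truth; the
  overparameterised discrete logit is checked through its fitted category
  probabilities (within twice the binomial SE). SUROPM at n = 3000: slopes
  within their probit sampling bands (all ≤ 3 SEs, ≥90% ≤ 2 SEs across the
  20 coordinates) and correlations within ±0.1, for both a correlated and an
  independent truth. Recovery seeds are fixed; the 2-SE bands make these
  tests sharp but stable at the chosen separations.
* End-to-end: the 36-entry grid on an n = 300 synthetic 3L dataset, with
  injected convergence failures, must exclude the failures, satisfy
  RMSE ≥ MAE ≥ |ME| for every converged entry, and emit a unique rank-1
  algorithm that survives a save/load round trip.

Problem sizes (n = 300 grid, n = 3000–5000 recoveries, 100–200 GHK draws)
are the package's test defaults: large enough that asymptotic bands apply,
small enough that the whole suite runs in minutes on one CPU.

## Known limitations

* ALDVMM standard errors are not reported (point prediction is the use
  case); the observed-information machinery exists only in the tests.
* The joint SUROPM refinement uses numeric gradients and is capped; with
  very small cells it can stop at the two-stage estimate.
* Overlapping mixture components at moderate n carry genuine finite-sample
  bias (membership and scale parameters); recovery guarantees are stated for
  separated components only.
* The BETAMIX discrete part is softmax-overparameterised; only probability
  contrasts are identified, which is all prediction needs.
* No external validation dataset exists in this domain; cross-validation is
  the only performance evidence, with its usual optimism.
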
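# Methods

`vaxchoice` implements the full analysis pipeline of a dual-response
discrete choice experiment (DCE) on vaccine prioritization: experimental
design, synthetic survey generation, quality control, panel mixed-logit
estimation, attribute-importance scoring, and selection-probability ranking
of candidate vaccines. This note documents the models, the numerical
choices, and what the synthetic data can and cannot establish.

## Attribute space and experimental design

Hypothetical vaccines are described by six attributes: incidence and
mortality of the targeted disease (per 100,000), vaccine effectiveness (%),
total cost for all doses (CNY), the vaccinated group (preschoolers,
school-age children, adults, older adults), and current vaccine coverage
(%). Each non-categorical attribute has three levels spanning the range of
prevalent non-NIP vaccines in China; the group has four. Profiles with
mortality ≥ incidence are epidemiologically impossible and are excluded,
leaving 756 of the 972 full-factorial profiles admissible.

A design is a set of pairwise tasks (vaccine A vs vaccine B). Its quality
is the D-error

    det(Ω)^(1/K),  Ω = [Σ_s Σ_j P_js (x_js − x̄_s)(x_js − x̄_s)']⁻¹,

the normalized determinant of the asymptotic covariance of the multinomial
logit estimator at prior coefficients β₀, with K the number of dummy-coded
parameters. The default priors are zero (the utility-neutral criterion)
because reliable priors are rarely available before fieldwork; any prior
vector can be supplied. The search is a seeded random-swap descent: start
from a random admissible design, propose replacing one alternative's
profile with a random admissible profile, accept strict improvements.
Duplicate profiles within a set are forbidden. This is simpler than a full
coordinate-exchange but reaches D-errors around 0.3 for the 30-set
configuration within a few thousand proposals, and it is exactly
reproducible from the seed. Blocking is a seeded random partition into
equal blocks; each block's second task is copied to position 11 and
flagged, so consistency can be checked without contaminating estimation
(all estimation paths drop flagged rows).

The Johnson–Orme rule of thumb `n > 500·c/(t·a)` (c = largest level count,
t = tasks, a = alternatives) gives the minimum respondent count; the
default configuration (c=4, t=10, a=2) requires 100.

## Synthetic survey generator

The generator is first-class: it defines the conditions under which every
statistical claim in the test suite is evaluated.

**Demographics.** Categorical fields (gender, age group, region, education,
income, health, children) are drawn independently from census-aligned quota
margins, so the sample matches the quotas in expectation. Joint dependence
between fields is not modeled; nothing downstream conditions on joint
demographic cells except the interaction machinery, which uses binary
covariates derived from single fields.

**Preferences.** Respondent n draws β_n = β̄ + σ∘z_n (z standard normal,
independent across respondents) and an opt-out constant asc_n. The default
β̄ and σ are the package's reference estimates for the Chinese adult
population's vaccine preferences — effectiveness and coverage dominate, a
mild preference for publicly funding *more expensive* vaccines, preschool
children prioritized, opt-out constant −0.953 with SD 2.316. Simulation
uses |σ| since a normal SD's sign is vacuous.

**Dual response.** Each task draws independent Gumbel noise for the two
vaccines; the forced answer is the utility argmax over {A, B}. The opt-out
stage keeps the realized vaccine utilities and compares the winner against
asc_n plus fresh Gumbel noise. Jointly this is an argmax over
{A, B, opt-out}, so the stored trinary record follows exactly the
multinomial logit with an alternative-specific constant that the estimator
assumes — the simulated world is the estimated model, which is what makes
parameter-recovery experiments interpretable. A consequence worth noting:
with all utilities and the constant at zero, the opt-out share is 1/3 (the
symmetric trinary logit), and with the default constant of −0.953 it is
well below one half.

**Planted behaviors.** A configurable mix (defaults: 70% attentive, 7%
comprehension failures, 3% straight-liners, 20% repeat-inconsistent,
echoing attrition rates in large online vaccine-preference surveys) gives
the QC module exact ground truth:

- straight-liners always pick one fixed side, in both stages;
- attentive respondents (and comprehension failures, who answer normally
  but are flagged in the roster) answer the repeat task by repeating their
  source answer — a perfectly consistent respondent;
- inconsistent respondents re-answer the repeat with fresh noise and are
  forced to contradict their source answer;
- attentive forced-choice patterns are rejection-sampled away from
  all-one-side sequences (probability ~2⁻⁹ per respondent otherwise), so
  the planted straight-liner set is exactly the flagged set.

The last two rules trade a tiny, quantifiable distortion of the choice
process (conditioning on "not straight-lined", roughly 0.2% of probability
mass) for exact identifiability of the planted labels. Real data would
exhibit accidental straight-liners and honestly-inconsistent respondents;
the QC flags would then be noisy proxies, and nothing in this package's
exact-recovery results transfers to that setting.

## Quality control

Main analysis removes the union of (1) comprehension failures (an input
flag — the questionnaire's test is not simulated at item level), (2)
straight-liners: the forced answer occupies the same position on all ten
regular tasks, and (3) repeat-inconsistency: the final (opt-out-inclusive)
answer at the repeat differs from its source task. The sensitivity dataset
removes only (1). Tallies are reported per criterion; survivors use the
union. Exclusion is always whole-respondent. The consistency check can be
switched to the forced stage (`stage="forced"`), since which stage a given
survey compares is a protocol detail.

## Panel mixed logit by maximum simulated likelihood

The model: U_ntj = x_ntj'β_n + ε_ntj with iid Gumbel ε and
β_n ~ N(β̄, diag(σ²)) over respondents (uncorrelated normal mixing; no
lognormals). The unforced stage adds an opt-out alternative with utility
equal to a random constant and zero attribute contributions. The simulated
log-likelihood takes the panel product over a respondent's ten tasks inside
the draw average:

    LL = Σ_n log[ (1/R) Σ_r Π_t P_nt(y_nt | β̄ + σ∘z_nr) ].

Draws are Halton sequences, primes assigned in ascending order per random
coefficient, burn-in 50, cut into consecutive R-length segments per
respondent, mapped through Φ⁻¹. By default the digits are scrambled with
fixed seeded permutations (0 held fixed) and the draws enter in antithetic
pairs: with a dozen or more random coefficients, the unscrambled sequence's
high-prime dimensions are strongly correlated, and the resulting
integration error measurably attenuates the largest heterogeneity
parameters at moderate draw counts (we observed ≈0.05 utility-unit
attenuation on the biggest coefficients at 500 draws, cut roughly in half
by scrambling plus antithetics). `scramble=False, antithetic=False`
reproduces plain standard Halton draws; a rotated-block allocation
(`draw_allocation="rotated"`) is also available and performed
indistinguishably from segments in our checks. Draw allocation follows
dataset order; relabeling respondents therefore perturbs estimates at the
O(1/R) simulation-noise level, while permuting tasks within a respondent
changes nothing.

**Optimization.** Conditional-logit warm start for the means (the σ=0 model,
whose simulated likelihood is exact at any draw count), σ initialized at
0.1; then BFGS on nested leading subsets of the same Halton draws (50, then
150), then a damped chord-Newton polish at the full draw count using the
analytic Hessian of the simulated likelihood (mixture identity:
∇²ll_n = Σ_r w_r(H_r + g_r g_r') − s_n s_n'). The Hessian is refactored at
most every five steps; its large contractions accumulate in single
precision, which agrees with finite differences to ~10⁻⁶ relative — far
below the statistical noise in any standard error. Convergence requires a
max-gradient below 10⁻⁵ (default). The final Hessian doubles as the
standard-error source (inverse observed information); OPG/BHHH, sandwich,
and finite-difference variants are available.

**Identification notes.** The sign of each σ is not identified (the
likelihood is even in σ); fits report the raw signed estimate — mirroring
the convention of major estimation packages — plus |σ|. With σ truly zero
a fitted SD is weakly identified and can wander at small n, while the
likelihood-ratio against the conditional logit stays insignificant; the
test suite asserts exactly that. Wald z-statistics and ±1.96·SE intervals
are used throughout.

`stability_check` refits along an increasing draw grid and reports the
elementwise maximum relative change between consecutive fits, with a 0.05
floor on the denominator so near-zero coefficients do not dominate;
"stable" means below 1%.

**Interactions** are product columns (binary respondent covariate × level
dummy), fixed coefficients unless explicitly listed as random. Aliased
columns (e.g. a degenerate covariate) are detected by a rank check before
optimization and reported by name.

## Relative importance and vaccine ranking

RI is the range method: per attribute, the spread between the largest and
smallest level-coefficient means (reference level = 0); raw shares divide
by the total of the ranges, normalized RI scales the widest attribute to
100, and reported integers use half-up rounding. RI is scale-invariant and
excludes the opt-out constant.

For prioritization the numeric attributes re-enter as continuous covariates
in original units (per-100,000, %, CNY) — so coefficients read as utility
per unit — with the group dummy-coded. A candidate's selection probability
against the least-favorable base case (incidence 10, mortality 0,
effectiveness 20%, cost 100, adults, coverage 1%) is

    E_β[ logistic(V_cand(β) − V_base(β)) ]

with β drawn from the fitted mixing distribution via Halton draws
(`at_means=True` collapses to the point estimate; `with_optout=True` adds
the opt-out as a third alternative for sensitivity). A candidate identical
to the base case scores exactly 0.5 regardless of the mixing distribution.
Confidence intervals resample respondents with replacement and refit
(percentile 2.5/97.5; failed replicates are dropped and counted, >10%
failures flags the CI unreliable); a Krinsky–Robb parameter-draw variant
avoids refitting. Price scenarios rescale candidate costs by 1.0/0.5/0.3
before re-ranking (dense ranks, descending probability).

The bundled evidence table covers eleven candidate vaccines (varicella,
Hib, EV71, PCV, rotavirus, and influenza/HPV split by target group) with
published Chinese incidence, mortality, effectiveness, lowest current
price, and coverage figures.

## Problem sizes used in the automated checks

The test suite evaluates parameter recovery at 20 replications of 1000
respondents × 10 unforced tasks with 500 Halton draws — enough that the
95% CIs cover the true population means at a pooled rate of ≥90% (with a
per-parameter binomial floor: at 20 replications, thresholding each of 14
parameters individually at 90% would reject even a perfectly calibrated
estimator most of the time), and that the across-replication average
estimate carries the true sign even for the smallest coefficient (0.053,
published SE ≈ 0.075, so per-replication sign flips are expected and not an
error signal). Oracle equivalences use
Gauss–Hermite quadrature (one random coefficient) and a row-by-row
conditional-logit computation as independent references. Bootstrap
properties are exercised at reduced scale (tens of replicates, zero
heterogeneity) where the checked property — interval ordering, width
shrinking in n, near-nominal coverage — is size-independent. The analysis
drivers under `analysis/` default to 1200 simulated respondents and 500
draws with a 100-replicate bootstrap.

## Known limitations

- Demographic fields are drawn independently; no joint census structure.
- Mixing is uncorrelated normal; correlated or lognormal mixing is out of
  scope, as are WTP transforms and Bayesian estimation.
- The comprehension test exists only as a roster flag.
- The design search is a local descent; it is reproducible and adequate at
  this scale but makes no optimality guarantee.
- Selection probabilities depend on the continuous-coding assumption being
  a fair linearization of the level effects; the dummy-vs-continuous
  linearity check in the test suite probes exactly that on synthetic data.
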
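# Methods

This note documents the models implemented in `respshift`, the estimation
choices behind them, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## 1. Measurement models

### 1.1 Rasch accuracy model and conditional estimation

Accuracy follows the one-parameter logistic model,
P(X_ij = 1) = logistic(θ_j − β_i). Item difficulties are estimated by
**conditional maximum likelihood (CML)**: conditioning on each person's raw
score r_j removes θ from the likelihood, so the estimates are invariant to
the ability distribution (specific objectivity). The conditional pattern
probability is

    P(x | r) = exp(−Σ_i x_i β_i) / γ_r(ε),   ε_i = exp(−β_i),

with γ_r the elementary symmetric function of order r. γ is computed by the
one-item-at-a-time summation recursion (all terms positive, hence stable).
The gradient needs "deleted" tables γ^(−i); these are obtained from the
identity γ_r = γ_r^(−i) + ε_i γ_{r−1}^(−i), solved forward (subtraction)
for items with ε below the median and backward (division) for the rest,
which keeps the amplification factor below one in each case. Rows failing a
closure check (positivity; γ_0^(−i) = 1 from the backward pass; γ_n = ε_i
γ_{n−1}^(−i) from the forward pass, both at 1e−9 relative) are recomputed
exactly in O(n²); in practice the fallback rarely triggers.

The likelihood is invariant to a constant shift of β, so the optimizer
(L-BFGS-B, box ±15, analytic gradient) adds an exact quadratic penalty on
Σβ: the likelihood term depends only on the centered part, so the joint
minimizer is the centered CML solution with mean exactly zero, and the
penalty is zero at the optimum. Occasional aborted line searches are
retried from the incumbent point (fresh curvature memory); convergence is
declared at gradient sup-norm ≤ 1e−3 (typically ≤ 1e−6).

Persons with extreme raw scores carry no difficulty information and are
skipped; an item with no variation among the remaining persons has a
divergent estimate and is reported as an error naming the item.

### 1.2 Mixture Rasch model

The G-class mixture gives each class its own centered difficulty vector
β_g, a free class weight π_g, and its own raw-score distribution, factoring
the within-class likelihood as P(r | g) · P(x | r, g), where the second
term is the conditional likelihood of §1.1. Estimation is EM:

* E-step: posterior memberships from the factored likelihood;
* M-step: class weights and score distributions in closed form; β_g by
  weighted CML warm-started at the previous value (a full inner
  optimization, so the observed-data log-likelihood is non-decreasing —
  this is asserted by tests on every fitted trajectory).

Initialization draws soft memberships from a symmetric Dirichlet;
`n_starts` (default 20) restarts are run and the best likelihood kept,
ties broken by start order. A start in which a class weight collapses is
discarded; if all collapse the fit fails. Classes are relabeled by
descending weight. A class with fewer than 10 hard-assigned persons
triggers a warning.

**Parameter counting.** AIC = −2lnL + 2p with p = G(n_items − 1) + (G − 1)
+ 2G: per class, n_items − 1 free difficulties plus 2 effective
score-distribution parameters (the conventional location/scale count for a
class-specific ability distribution), plus G − 1 mixing weights. With 30
items this yields 31, 63, 95, … — i.e., 32 parameters per added class. The
full score distribution actually estimated has more free cells than 2; the
2-per-class convention is a deliberate reporting choice so that AIC spacing
matches standard mixture-IRT software output.

Chi-square tests between successive class counts are reported with an
`approximate` flag: the null puts a mixture weight on the boundary of the
parameter space, so the chi-square reference distribution is not exact.

Per-person abilities are ML within the hard-assigned class, with extreme
raw scores pulled in by 0.3 score points so every person gets a finite
estimate; SE = information^(−1/2). The person-fit index is the standardized
response log-likelihood (observed minus expectation over its sampling
distribution, divided by its SD), negative values indicating misfit.

## 2. Response-time model and residuals

Log response times follow the additive two-way model
ln RT_ij ~ N(τ_j − γ_i, σ²), identified by mean(γ) = 0 so that τ_j is the
person's expected log RT (higher = slower). This sign convention — the
person term *adds* to expected log RT — is kept as stated even though part
of the literature writes the person term with the opposite sign and calls
it "speed"; with mean-zero γ, τ coincides with the person's mean log RT on
complete data, which is the quantity used in class profiling. The
homoscedastic fit solves sparse least squares on the observed-cell design
matrix (LSQR, tolerances 1e−12), resolving the one-dimensional null space
by centering γ; σ² is the mean squared residual (Gaussian ML). Missing
cells are excluded everywhere; nothing is imputed.

Residuals e_ij = ln RT_ij − τ_j + γ_i are standardized by the
construct-driven-state residual SD when a two-state fit is available, else
by the single σ. Large |e| in either direction flags erratic responding:
unexpectedly fast (guessing) or unexpectedly slow (strategy search,
attentional lapse, fatigue).

## 3. Joint state model

Each response is emitted from latent state ξ_ji ∈ {1, 2}: construct-driven
(Rasch accuracy with θ_j1, β_i1; RT residual variance σ²₁) or erratic (its
own θ_j2, β_i2; σ²₂). Accuracy and RT parameters are estimated jointly.
Erratic-state ability draws are retained only for diagnostics; scoring uses
construct-driven states only (§4).

**Transition structures.**

* *Markov*: lag-1 dependence with one time-homogeneous 2×2 transition
  matrix and Dirichlet(1, 1) priors on the initial pair and each row. A
  single stationary distribution (πP = π) is reported, which is only
  meaningful under homogeneity — a per-position transition model is out of
  scope by design.
* *Change point*: ξ_ji = 1 for i ≤ k_j, 2 after, k_j ∈ {1..n_items}
  uniform a priori (k_j = n_items ⇒ no transition). `residual` mode
  switches σ² at k_j; `speed` mode instead switches the person speed
  (τ_j1 → τ_j2) at a single σ², the mean-shift alternative.

**Sampler.** One sweep updates: states (exact forward-filtering /
backward-sampling per person under the Markov structure; enumeration of the
n_items-point discrete full conditional of k_j under the change-point
structure — no Metropolis tuning in either), initial/transition rows
(conjugate Dirichlet), τ and γ (conjugate normal, precision-weighted by the
current cell states), residual precisions (conjugate gamma, shape 0.001 /
rate 0.001), and θ, β (random-walk Metropolis, proposal SD 0.5, normal
priors N(0, 100) — the logistic likelihood has no conjugate conditional
without augmentation, and a fixed-step random walk is adequate at these
data sizes; acceptance is monitored via ESS). Identification per sweep:
β centered within state (shift absorbed into θ), γ centered (shift absorbed
into τ), and under the Markov structure σ²₁ < σ²₂ enforced by relabeling
(swapping states, state-specific parameters, and both transition-matrix
axes). Under the change-point structure states are time-ordered by
construction and no variance ordering is imposed — deliberately, because an
engaged-minority pattern (long, variable RTs on the first few items only,
then steady guessing) genuinely inverts the variance ordering, and forcing
it would hide that case. A person or item with no cells in a state in a
given sweep has that state's parameter drawn from its prior.

Defaults are 2 chains × (10,000 burn-in + 10,000 kept); the test suite and
examples run the reduced desk protocol 2 × (1,000 + 1,000), which passes
all recovery checks at the 301 × 30 scale. One master seed spawns
independent per-chain substreams. Convergence is summarized by split-chain
R̂, ESS and lag autocorrelations (via ArviZ) on the well-identified scalars
(state variances, transition/initial probabilities, deviance, aggregate τ
and γ summaries); any monitored R̂ > 1.1 sets `converged = False` on the
returned posterior rather than raising, and the CLI exits non-zero.

**State characterization.** The disengaged state is the one with *both*
the larger residual-variance EAP (ratio ≥ 2 required for the states to
count as distinct) and the lower empirical accuracy over its cells. If the
high-variance state has the *higher* accuracy, an alternative-interpretation
warning is attached (engaged minority, see above); near-equal variances
yield a "states indistinct" warning.

Known behavior worth noting: on data containing *no* erratic responses at
all, the two states are unidentified — the fitted variances coincide, the
labeled occupancy is arbitrary, and R̂ fails. This is inherent to an
unanchored two-state variance mixture, not a sampler defect; the
"states indistinct" warning and the convergence flag are the intended
detection path for that case.

**Model comparison.** Each posterior records the mean deviance
(−2 × complete-data log-likelihood at the sampled parameters/states),
usable to compare residual-switching vs speed-switching fits on the same
data; the mean posterior deviance of the better-specified structure is
lower on data generated from it.

## 4. Scoring and validity

* **Trims.** State-based (retain ξ = 1, from the posterior modal state
  matrix or a ground-truth matrix in simulations); residual-threshold
  (negative side only, or both sides); none. A person left with no retained
  responses is flagged unscorable, never silently dropped; persons with
  fewer than 3 retained items are excluded from validity correlations.
* **EAP rescoring.** Difficulties held fixed, the trim applied as induced
  missingness; EAP and posterior SD by 61-node Gauss–Hermite quadrature
  under a standard-normal prior (deterministic; matches a 10,001-point grid
  integration to ≤ 1e−4 everywhere tested).
* **Reliability.** Empirical EAP reliability var(EAP) / (var(EAP) + mean
  posterior variance) — the standard EAP-based estimate; on simulation it
  tracks the squared correlation between EAP and true ability.
* **Disattenuation.** adjusted_r = raw_r / √reliability, correcting the
  test side only (the criterion is treated as error-free). This and the
  bootstrap below follow standard textbook conventions — neither has a
  single canonical formulation in this setting — and both are kept
  swappable behind their function boundaries.
* **Bootstrap gain test.** Observed statistic: adjusted_r(trim) −
  adjusted_r(baseline). Null replicates reassign each person's trimmed-cell
  count to uniformly random cells among those the baseline retains —
  preserving the amount of trimming while destroying its targeting; p is
  the proportion of null gains ≥ observed. Deterministic given a seed.
* **Validity table.** One row per rule: no-trim, named state trims, and the
  ladder of negative residual thresholds (−6, −5, −3.5, −3, −2.5, −2, −1.5,
  −1, −0.5, 0 SD), each with raw r, reliability, adjusted r, and r²
  (exactly adjusted_r²). Thresholds are applied to *standardized* residuals
  referenced to construct-driven behavior (σ₁ when states exist).

## 5. Synthetic-data generator

The generator emulates a ~300-person, 30-item, 8-option multiple-choice
reasoning test: Rasch accuracy (abilities N(0.9, 1) in the late-shift
presets, putting construct-driven accuracy near .67), log-normal RTs
(τ ~ N(3.2, 0.4) log-seconds ≈ 25 s/item; γ ~ N(0, 0.3) centered), residual
variances (0.187, 1.647) giving the ≈9× erratic inflation, erratic-state
accuracy .26 in the late-shift presets (default .25; pure 8-option guessing
.125 via the `guessing_floor` toggle), and an AFQT-like criterion
(mean 220, SD 16) correlated .6 with ability. State dynamics: Markov
(initial .948/.052; transition [[.97, .03], [.07, .93]], stationary
(.70, .30)) or change points concentrated late (80% of transitioning
persons uniform on items 22–29; 20% never transition). Item covariates
(memory load 1–4, unique elements 3–9, serial position) feed the difficulty
model with standardized effects 0.55 and 0.25.

Named presets: `late_shift_cp`, `late_shift_markov`, `two_class_mixture`
(opposed difficulty orderings, weights .6/.4), `early_engagement_inversion`
(engaged only for items ~2–4 with extra residual SD 1.21, then guessing —
the variance-inverted counter-example), `null_single_state`. Everything is
reproducible bit-exactly from (config, seed); sub-generators (items,
persons, states, accuracy, RT, criterion) draw from named substreams
spawned from the master seed.

What the generator does **not** emulate: option-level distractor behavior,
within-state RT–accuracy dependence beyond the shared state, item-position
drift in time intensity, multidimensional abilities, or criterion
unreliability. Passing recovery tests therefore demonstrate internal
consistency of estimator and generator under the stated conditions, not
robustness to real-data phenomena outside them.

## 6. Numerical and design notes

* Logistic terms use `log_expit`/`expit`; the response function is stable
  to |θ − β| ≈ 700.
* The EAP quadrature and all correlations are deterministic; all MCMC and
  bootstrap randomness flows from explicit seeds.
* Change-point sampling uses the Gumbel-max trick on the per-person
  log-conditional, vectorized across persons.
* Posterior storage keeps full draws for the continuous parameters and a
  thinned subsample (≤ 200 per chain) of state matrices plus running
  occupancy means; per-draw state-specific accuracy is accumulated during
  sampling.
* `stationary_distribution` solves the 2×2 balance equations in closed form
  and rejects reducible chains (p12 = p21 = 0).
* The residual-mode σ²₂ EAP runs ~10% below the generating value at desk
  scale: boundary cells with small residuals are absorbed into the erratic
  segment when k_j is drawn slightly early, and the posterior averages over
  that asymmetry. It stays within the 15% recovery band used by the tests.
* Known limitations: no polytomous responses; at most two states and lag-1
  dependence; mixture fitting requires complete response matrices (trims
  are handled downstream by EAP rescoring, not by refitting the mixture);
  time-homogeneous transitions only.
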
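# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `socarb`, in the package's own
words. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Learning model

Each information branch (advice accuracy; blue-card outcomes) is a binary
hierarchical Gaussian filter. Writing hats for pre-outcome predictions on
trial k:

- prediction: μ̂₁ = σ(μ₂⁽ᵏ⁻¹⁾), π̂₁ = 1/(μ̂₁(1−μ̂₁)),
  π̂₂ = 1/(σ₂⁽ᵏ⁻¹⁾ + v), v = exp(κμ₃⁽ᵏ⁻¹⁾ + ω), π̂₃ = 1/(σ₃⁽ᵏ⁻¹⁾ + ϑ)
- level 2: δ₁ = u − μ̂₁, π₂ = π̂₂ + μ̂₁(1−μ̂₁), Δμ₂ = δ₁/π₂, ε₂ = δ₁/π₂
- level 3: w₂ = v·π̂₂, δ₂ = (1/π₂ + Δμ₂²)·π̂₂ − 1,
  π₃ = π̂₃ + ½κ²w₂(w₂ + (2w₂−1)δ₂), Δμ₃ = ½κw₂δ₂/π₃, ε₃ = δ₂/π₃

The level-3 updates follow the standard HGF-toolbox formulation for the
volatility weight w₂. The recorded precision-weighted volatility PE is
ε₃ = δ₂/π₃ (the convention used for trajectory read-outs in this paradigm),
which differs from Δμ₃ by the factor ½κw₂; it is a recorded quantity only and
does not enter the updates. One can show δ₂ ≥ −1 and hence π₃ > π̂₃·0 > 0
for any κ ∈ (0,1), so the filter cannot produce a negative precision except
by floating-point overflow; a saturated sigmoid is clamped to keep μ̂₁ inside
(0, 1) (clamp at 1e−13), and any non-finite precision raises a divergence
error carrying the trial index (the MAP objective converts this into a large
finite penalty).

Perceptual variants:

- **three_level** — κ_a, κ_c, ϑ_a, ϑ_c free (logit space, prior means
  0.5/0.55, prior variance 1).
- **normative** — the same filter with κ, ϑ pinned to the prior means
  (variance 0): a fixed, population-typical inference process.
- **two_level** — no third level: κ pinned to 0 (volatility neither couples
  to learning nor updates) and ϑ pinned to 0.00062. The effective learning
  step is then governed by exp(ω) alone. The prior table for this variant
  lists only ϑ, which is why κ is treated as absent (0) rather than fixed at
  0.5.

Fixed constants: ω = −3 for both branches (the HGF-toolbox default; see
Design decisions), initial states μ₂⁽⁰⁾ = 0, σ₂⁽⁰⁾ = 1, μ₃⁽⁰⁾ = 1,
σ₃⁽⁰⁾ = 1, all configurable on `PerceptualParams`.

## Response model

Arbitration weighs the branches by their predicted level-1 precisions with a
multiplicative social bias ζ ≥ 0 (ζ = 0 card-only, ζ = ∞ advice-only,
ζ = 1 equal weighting). The card-branch probability is flipped into the
advice frame (p that the advised color wins) before integration. Choices are
a softmax of the integrated belief with inverse temperature β_ch, computed as
a logistic of β_ch·logit(μ̂₁ᵦ) for stability. The wager model is linear in
log-wager with Gaussian noise: the observed integer wager w ∈ {1..10} enters
through log w with SD β_wager; simulation rounds exp(log-wager draw) to the
nearest integer and clips to [1, 10], while likelihood evaluation uses the
continuous density without a discretization or censoring correction (the
simplest model consistent with a "stochasticity parameter" on the log scale;
a censored/discretized likelihood is a known alternative).

Estimation spaces and priors (variances in estimation space): κ, ϑ logit
(var 1); ζ log with prior mean 0 *on the log scale* (i.e. native 1, var 25);
β_ch log around native 48 (var 1; a shrinkage prior so behavior loads on the
remaining parameters rather than decision noise); β₀…β₆ identity (prior mean
6.21 for β₀, 0 otherwise, var 4); β_wager log around native 1.5 (var 100).
β₁…β₆ are real-valued and therefore cannot be log-transformed; they are the
only response parameters estimated in identity space.

## Synthetic task generator

The generator reproduces the paradigm's design statistics by exact-count
construction rather than sampling: 160 trials; advice phases stable (1–64,
helpful advisor) then volatile (65–160, helpful/misleading sub-blocks of
roughly 8–12 trials, misleading-leading); card phases stable (1–32, blue
favored at 0.8), volatile (33–96, alternating favored color), stable
(97–160, with a single mid-block reversal where the color budget requires
it). Within each run of constant design probability the number of blue
outcomes / correct private signals is fixed by largest-remainder
apportionment and only positions are randomized, so every seed yields
exactly 88/160 = 0.55 blue outcomes, 90/160 = 0.5625 accurate advice and
128/160 = 0.80 correct private advisor signals. Placement is re-randomized
(deterministically, from the seed) until the advice-accuracy and outcome
sequences satisfy |r| ≤ 0.1, mirroring the orthogonal factorial design. The
phase boundaries place the four factorial combinations in contiguous blocks
consistent with the paradigm's rating-probe trials (14, 49, 73, 115).

What the generator does **not** emulate: advisor videos and their social
micro-dynamics, reaction times, session-break effects, payment framing, or
any participant idiosyncrasy beyond the parameter population. Passing tests
on this synthetic world therefore demonstrate internal consistency of the
models and pipeline — not that real participants behave this way.

Simulated agents filter the schedule, then sample choices from the softmax
and wagers from the log-normal wager model. An agent's final score adds the
wager on correct predictions and subtracts it otherwise.

## Population defaults and calibration

The default simulation population uses the reported group means and SDs of
the winning model's parameters (κ_c 0.58±0.17, κ_a 0.56±0.28, ϑ_c 0.59±0.07,
ϑ_a 0.62±0.09, ζ 1.03±1.24, β₁ −1.59±0.94, β₂ 1.42±1.69, β₃ 0.23±1.37,
β₄ 0.63±1.24, β₅ −2.97±2.47, β₆ −0.51±1.83, β_ch 2.25±0.92), drawn from
Gaussians truncated to the admissible native ranges (κ, ϑ to (0,1); ζ and
β_ch bounded away from 0).

Two parameters have no reported group statistics and were calibrated once,
before any downstream study was run, against qualitative features of the
paradigm:

- **β₀ = 3.18** — set so a group-mean agent's median wager sits mid-scale
  (≈5.5 of 1–10). Participants were not told the bonus thresholds, so there
  is no target level to anchor on; a mid-scale operating point keeps the
  confidence read-out off the response bounds, which is a precondition for
  the strong observed correlations between model-predicted and actual
  wagers.
- **β_wager = 0.5** — a log-scale noise SD at which predicted wagers
  correlate with noisy wagers at the empirically observed 0.6–0.8 level
  (the prior mean 1.5, used as a population value, would push that
  correlation to ≈0.3).

## Inversion

MAP estimation minimizes the negative joint log posterior (choice + wager
log-likelihood + Gaussian log-priors in estimation space, equal weighting of
the two response channels) with L-BFGS-B and numerical gradients, multi-start
from the prior mean plus Gaussian jitter scaled by the prior SD (capped at 2
so near-flat priors do not scatter starts absurdly). Default 10 restarts;
studies that fit many models per subject use 6 restarts, which multi-start
agreement tests show is sufficient on simulated data of this size. The
sequential filter loop is JIT-compiled with numba when available; a
pure-Python fallback keeps results identical. Bounds of
±12 (logit), ±10 (log) and ±30 (identity) in estimation space prevent
overflow. Convergence tolerance 1e−6 on the objective; a fit that converges
from no start returns a flagged failure result rather than raising.

The log model evidence is the Laplace approximation at the MAP:
log p(y,θ*) + (d/2)·log 2π − ½·log det H, with H the central-difference
Hessian (step 1e−3) over the free parameters; non-positive-definite Hessians
are eigenvalue-floored at 1e−6 and flagged. With zero free parameters the
evidence is the log-likelihood at the pinned values.

## Model selection

Random-effects BMS estimates a Dirichlet posterior over model frequencies by
variational updates (prior count 1 per model, convergence 1e−10).
Exceedance probabilities use 10⁶ seeded Dirichlet draws (Monte-Carlo error
well below the third decimal). The Bayes omnibus risk is the posterior
probability of the equal-frequency null from the free-energy comparison of
the null and random-effects models, and protected exceedance probabilities
blend EP with chance: φ_p = (1−BOR)·EP + BOR/M. Family evidences collapse
member models by log-sum-exp minus log family size (uniform within-family
prior). Note the BOR is bounded below by exp(−(N·log M − KL)), so decisive
selection in a small cohort cannot push it arbitrarily low; reaching the
very small values typical of a 38-subject study requires a comparable N.

## Parameter recovery

One simulate-and-refit cycle per synthetic subject, all subjects on the same
default schedule (the paradigm standardizes the input sequence across
participants). The primary effect size is the conventional
multiple-regression Cohen's f: each recovered parameter (estimation space)
is regressed on the full matrix of simulated parameters and the sample R²
converted to f = sqrt(R²/(1−R²)), capped at 10 when R² > 0.99. The
multiple-regression form is used because the wager read-outs are strongly
collinear by construction (I₂ and V₃ of the same branch correlate at ≈0.9 on
the default schedule), so estimation error mixes neighboring coefficients: a
recovered β₃ carries information about the simulated β₅ and vice versa, and
a bivariate recovered-on-simulated regression under-counts that shared
information.

Two caveats are reported alongside the primary statistic rather than folded
into it. First, with ~12 predictors and a few dozen subjects the sample R²
is inflated by degrees of freedom (its null expectation is p/(n−1) ≈ 0.32 at
n = 38), so the report also carries the df-adjusted f (`adjusted_f`, clamped
at zero). Second, the simple bivariate f (`bivariate_f`) shows how much each
parameter is pinned down *individually*; for the meta-volatility ϑ it is
near zero at 160 trials regardless of response-noise level — ϑ is simply not
practically identifiable on its own in this design — and the large-effect
verdict of the primary statistic for ϑ rests on the shared variance it
explains jointly with the other parameters plus the df inflation. Fit
failures are excluded with a logged count; more than 20% failures aborts the
study.

Problem sizes: the full recovery study uses 38 subjects with 10 optimizer
restarts; the reduced variant in the test suite uses 15 subjects, which is
already sufficient for the well-identified parameters (κ, ζ) to clear the
f ≥ 0.4 large-effect threshold.

## Volatility-tracking comparison

`compare_volatility_tracking` simulates, per replicate, a fresh schedule and
two agents on it: the arbitrated three-level agent at group-mean parameters,
and an arbitrated two-level agent (fixed low volatility) sharing the same
response parameters. The default study uses 1000 replicates. The advantage
of the three-level agent is carried almost entirely by prediction accuracy —
it adapts its learning rate in volatile phases — while volatility-sensitive
wager modulation per se cannot raise the expected score (whenever accuracy
exceeds chance, the score-maximizing wager policy is flat and maximal), and
the two agents' wager levels differ slightly through their volatility
read-outs.

## Design decisions

- **ω = −3.** The tonic log-volatility has no printed prior or estimate. At
  the originally considered −4 the volatility pathway is effectively inert:
  exp(κμ₃+ω) varies by only ~±10% over the whole μ₃ range, the three-level
  and two-level filters become near-indistinguishable, and the model space
  degenerates. −3 is the HGF-toolbox default for binary inputs and gives the
  third level a functional role while keeping learning rates realistic.
- **Two-level = κ → 0**, not κ fixed at 0.5: the no-volatility model has no
  third level, so the coupling does not exist; implementing it as κ = 0
  makes its fixed learning rate exp(ω) genuinely "low and fixed".
- **Wager likelihood continuous**, despite integer wagers (see above).
- **Exact-count schedule construction** makes the design-level acceptance
  statistics deterministic, at the price of slightly super-uniform outcome
  counts per block (less binomial jitter than a sampled design).
- **Multiple-regression Cohen's f on the sample R²** as the primary recovery
  statistic, with the df-adjusted and bivariate forms reported alongside
  (see above). The bivariate form alone cannot reach the large-effect
  threshold for the meta-volatility or the collinear wager coefficients at
  any noise level, so it cannot be the statistic behind the reported
  recovery of this paradigm; the conventional multiple-regression form is.

## Known limitations

- The Laplace evidence at a MAP found by local optimization can understate
  multimodal posteriors; rank order across models is the tested surface.
- The wager likelihood ignores censoring at 1 and 10; populations pushed to
  the bounds (large |β₀|) will show biased wager-coefficient estimates.
- The generator's volatile phases use regular 8–12-trial sub-blocks, not the
  exact (unpublished) trial sequence of the original task; only the
  aggregate design statistics and the 2×2 phase structure are reproduced.
- Effective identifiability of the meta-volatility ϑ is marginal at 160
  trials; its recovered values are strongly prior-shrunk.
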
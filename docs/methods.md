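# Methods

## The phenomenon being modelled

A short bout of repetitive finger tapping biases the perceived numerosity
of visual stimuli presented shortly afterwards near the tapping location:
fast tapping (~5–6 Hz for 6 s) produces underestimation, slow tapping
(~0.7–1.3 Hz) overestimation. The effect is spatially selective in
external (screen-side) coordinates — it follows where the tapping happened
on the screen, not which hand tapped — and appears both in magnitude
estimation (numerosities 6–14, sequential flashes or simultaneous dot
clouds) and in 2AFC numerosity comparison (dot clouds of 5–20 elements).
numadapt provides a generative model of such experiments and the analysis
chain used to quantify them.

## Generative observer model

A response to true numerosity `n` is

    response = max(min_response, round(g · n · (1 + w·ε))),   ε ~ N(0, 1)

with:

* `g` — multiplicative adaptation gain, keyed to *(adaptation level,
  congruency)* where congruency means "test stimulus on the adapted screen
  side". Keying gains to screen side rather than hand encodes the
  reference-frame property of the effect; the crossed-hand condition is
  simulated by moving the adapted side, not by a hand parameter. The
  no-adaptation level is pinned to `g = 1`.
* `w` — Weber fraction, the coefficient of variation of the percept.
  Multiplicative Gaussian noise before integer rounding is the standard
  scalar-variability model for numerosity estimation; the default
  `w = 0.15` is a typical adult estimation Weber fraction.
* Integer rounding is round-half-up; responses are floored at 1 (subjects
  cannot report zero or negative counts).

A consequence of rounding worth knowing: with *zero* noise, gains 0.9/1.1
produce an adaptation index of `(200/9)·Σ_{n=6..14} 1/n ≈ 21.52%`, not
exactly 20%, because `round(1.1n) − round(0.9n) = 2` for every n in 6–14.
With realistic noise (`w ≈ 0.15`) the rounding bias is smoothed away and
the recovered group AI is centred on the gain-implied value
`100·(g_slow − g_fast)/ḡ` (measured across seeds: mean 20.2, SD 0.6 at
6 subjects × 15 trials/cell).

Per-subject RNG streams are spawned from the master seed
(`SeedSequence(seed).spawn`), so enlarging a simulated cohort never
perturbs existing subjects' data.

## Stimulus generators

* **Tapping bouts.** A subject rate is drawn from N(mean, sd) truncated to
  positive; taps are evenly spaced at that rate with ±20% uniform jitter
  per interval, so the count is `round(rate × duration)` and, at sd = 0,
  always `⌊rT⌋` or `⌈rT⌉`. This is deliberately simpler than a point
  process: the analyses only consume rates and counts.
* **Flash trains.** `n` flashes of 40 ms inside a 2-s window with a
  minimum 40-ms inter-stimulus interval. Feasibility requires
  `n·40 + (n−1)·40 ≤ 2000` (so n ≤ 25). Onsets are sampled uniformly over
  the constrained region via the spacing transform — lay down the minimum
  occupancy, distribute the slack with sorted uniform draws — which is
  distributionally identical to accept/reject of uniform onsets but O(n)
  and feasible at tight packings. The observed maximum ISI at low
  numerosity is an emergent property of this sampling, not an enforced cap.
* **Dot clouds.** Dart-throwing placement of 0.3-deg dots fully inside a
  7-deg circular region with pairwise non-overlap; colors split half
  white / half black, the extra dot of an odd count being white. A
  packing-density pre-check (n·r_dot²/r_region² > 0.9) rejects hopeless
  requests before sampling; otherwise an iteration cap (default 10⁴)
  bounds the rejection loop.

## Adaptation index

    AI = (100/n) · Σ_j (RL̄_j − RH̄_j) / ((RL̄_j + RH̄_j)/2)

computed from per-numerosity mean responses after low (slow) and high
(fast) adaptation. The per-level percent differences are averaged — this
is not the same as the percent difference of grand means under noise, and
the per-level form is what the package implements as primary. Group AI is
the unweighted mean of per-subject AIs (SEM across subjects); a
pooled-trials variant (`AdaptationIndexModel(..., pooled=True)`) is
provided because with aggregate data the two readings are not
distinguishable, but it is not the default. The statistic is antisymmetric
in its arguments, invariant to rescaling both means, and bounded in
(−200, 200) for positive means.

## Psychometric fitting

Choices are Bernoulli with `P(right) = Φ((x − μ)/σ)` on the normalized
difference axis `x = (n_R − n_L)/((n_R + n_L)/2)`. Fitting maximizes the
trial-wise log-likelihood (trials are collapsed onto unique x levels for
speed; the likelihood is identical). The optimizer is L-BFGS-B started
from the best points of a 9×7 coarse grid (4 starts), with μ bounded to
the data range ± one span and σ ∈ [10⁻⁴, 10·span]; the σ floor excludes
degenerate step functions. Standard errors come from the observed
information (central-difference Hessian). Datasets with fewer than two
distinct x levels or all-identical choices are rejected as degenerate (no
finite MLE exists). No lapse-rate parameter is fitted: the modelled curves
run from 0 to 1.

The fitting criterion (trial-wise MLE rather than least squares on binned
proportions) is the field-standard choice; correctness is guarded by two
independent oracles in the test suite — a 200×200 grid search over
(μ, σ) and statsmodels' probit regression, to which the model is a
reparameterisation (slope 1/σ, intercept −μ/σ).

PSEs are reported as 100·μ (percent units). The 2AFC adaptation magnitude
is `PSE_fast − PSE_slow`, fast and slow only; a baseline (no-adaptation)
condition is fitted and reported but does not enter the magnitude.

## 2AFC trial sampling

`n_right ~ Uniform{5..20}`, `n_left = clamp(n_right + Uniform{−5..+5},
5, 20)`. Equal numerosities give x = 0, where the choice law itself yields
a fair coin; ties are not excluded. At the default simulation conditions
(μ = ±0.075, σ = 0.2, 6 subjects × 200 trials/level) the recovered mean
PSE difference is unbiased (≈15%) with a seed-to-seed SD of ≈1.2
percentage points.

## Statistics engine

* **Two-way within-subject ANOVA** (adaptation × numerosity). Trial-level
  input is first reduced to one mean per subject × cell — the conventional
  RM reduction — and the design must then be complete. Sums of squares are
  partitioned into subject, A, B, A×B and their subject-interaction error
  terms; each effect is tested against its own effect-by-subject error.
  η² is reported both classically (SS_effect/SS_total) and partially
  (SS_effect/(SS_effect+SS_error)), labelled, because aggregate reports
  rarely say which variant they used; the d conversion is applied to the
  classical variant by default. No sphericity correction is applied
  (none is standard for a 2-level factor; Greenhouse–Geisser is out of
  scope). Flat data (zero effect SS and zero error SS) return F = 0 rather
  than erroring; zero error variance with a nonzero effect is degenerate.
* **Effect-size conversion** `d = 2·√(η²/(1−η²))`, inverse
  `η² = d²/(d²+4)`; round-trips to 1e-12 over η² ∈ [0, 0.99].
* **t-tails** via the regularized incomplete beta function
  (`I_{df/(df+t²)}(df/2, ½)`), verified against direct numerical
  integration of the t density to 1e-6.
* **Power**: one-sample t with noncentrality d·√n; minimum sample size by
  scanning n upward until the target power is reached, satisfying
  `power(n*) ≥ target > power(n*−1)`.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the analyses assume:
balanced factorial designs, scalar response variability, multiplicative
side-specific adaptation, cumulative-Gaussian choice behaviour, and the
published tapping-rate regimes. It does not emulate sequential effects,
learning or fatigue across a session, numerosity-dependent regression to
the mean, lapses, or inter-subject heterogeneity in w or gains (all
subjects share one observer parameterisation; between-subject variability
in recovered AIs is purely sampling noise). Passing recovery tests
therefore demonstrates that the analysis chain is unbiased and correctly
implemented under the model's assumptions — not that the model captures
every property of real observers.

## Numerical and design choices

* Round-half-up integer rounding for responses and tap counts; documented
  tie behaviour at x = 0 in 2AFC (fair coin, emergent from Φ(0) = ½).
* The type-I-error calibration of the ANOVA uses 1000 null simulations at
  6 subjects × 10 trials/cell with the identity observer (w = 0.15) —
  a realistic null design held fixed across runs; the rejection rate at
  α = 0.05 lands within 5% ± 2%.
* Simulation sizes in tests and the acceptance script (6 subjects,
  10–15 estimation trials/cell, 200 2AFC trials/level) mirror the modelled
  study's scale; they are the package's reference conditions, and the
  recovery tolerances (±2 pp) reflect the Monte-Carlo spread at exactly
  those sizes.
* CSV outputs are pinned to comma separator, period decimal, header row,
  LF line endings; pipelines never overwrite without an explicit flag.

## Known limitations

* Group-level only: no hierarchical/mixed-effects modelling of subject
  heterogeneity.
* The ANOVA offers no sphericity correction; with a 2-level adaptation
  factor the main comparison of interest is unaffected.
* The power calculator is generic (effect size in, n out); it does not
  attempt to reconstruct any particular historical power computation whose
  alternative mean and SD were not published.
* Bootstrap confidence intervals for PSEs are deliberately not built in;
  the per-subject SEs from the observed information are reported instead.
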
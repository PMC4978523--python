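# numadapt

Simulation and analysis of **motor adaptation of perceived numerosity** —
the finding that a few seconds of rapid finger tapping makes observers
*under*-estimate the number of visual events subsequently shown near the
tapping location, while slow tapping makes them *over*-estimate, with the
bias confined to the adapted side of the screen.

The package is for psychophysicists and numerical-cognition researchers who
want to (a) generate realistic synthetic experiments of this kind with full
seed control, and (b) run the standard analysis chain on them (or on their
own trial tables in the same CSV layout).

## What it computes

**Adaptation index.** For per-numerosity mean responses `RL̄_j` after low
(slow-tapping) and `RH̄_j` after high (fast-tapping) adaptation over `n`
numerosity levels:

```
AI = (100/n) · Σ_j (RL̄_j − RH̄_j) / ((RL̄_j + RH̄_j)/2)
```

the average percent change in perceived numerosity, computed per subject
and averaged across subjects.

**Psychometric PSE.** 2AFC choices are modelled as
`P(right judged more numerous) = Φ((x − μ)/σ)` with
`x = (n_R − n_L)/((n_R + n_L)/2)`; μ (the PSE) and σ are estimated by
trial-wise maximum likelihood. The adaptation magnitude is
`PSE_fast − PSE_slow` in percent.

**Statistics.** Two-way within-subject (adaptation × numerosity) ANOVA
with classical and partial η², one-way ANOVA, two-tailed paired t-tests,
the conversion `d = 2·√(η²/(1−η²))`, and one-sample-t power / minimum
sample size via the noncentral t distribution.

**Generative model.** An observer perceives numerosity `n` as
`round(g·n·(1 + w·ε))`, `ε ~ N(0,1)`: a multiplicative adaptation gain `g`
per (adaptation level, screen side) and scalar variability with Weber
fraction `w`. Stimulus generators produce tapping bouts (6 s at ~5.5 or
~1.1 Hz), jittered flash trains (≥40 ms inter-stimulus interval inside a
2-s window) and non-overlapping half-white/half-black dot clouds.

## Worked example

```python
from numadapt import (AdaptationIndexModel, make_paper_defaults,
                      rm_anova_2xK, simulate_estimation_experiment)

cfg = make_paper_defaults(seed=1)["seq-congruent"]
trials = simulate_estimation_experiment(cfg.design, cfg.observer)
res = AdaptationIndexModel(trials).fit()
print(res.summary())
for a in rm_anova_2xK(trials[trials["congruent"]]):
    print(a)
```

prints

```
Adaptation index (percent change, slow vs fast tapping)
========================================================
condition_label=sequential congruent=False: AI = 3.53% ± 0.55 (SEM) [n=6 subjects]
condition_label=sequential congruent=True: AI = 20.76% ± 0.89 (SEM) [n=6 subjects]
adaptation: F(1,5) = 377.364, p = 6.67e-06, eta^2 = 0.1369 (partial 0.9869), d = 0.796
n_true: F(8,40) = 824.624, p = 6.958e-42, eta^2 = 0.8312 (partial 0.9940), d = 4.438
adaptation*n_true: F(8,40) = 5.375, p = 0.0001288, eta^2 = 0.0119 (partial 0.5181), d = 0.219
```

The congruent-side AI of ≈21% reflects the preset fast/slow gains
(0.9/1.1, a 20% built-in effect) recovered through the noisy observer
(`w = 0.15`); the incongruent side, simulated with gains 0.98/1.02, shows
the expected residual ≈4%. The ANOVA confirms a strong adaptation main
effect and the expected overwhelming effect of physical numerosity.

The same works for the 2AFC experiment:

```python
from numadapt import ExperimentDesign, PsychometricModel, simulate_forced_choice_experiment

design = ExperimentDesign(subjects=6, trials_per_cell=200, seed=2)
fc = simulate_forced_choice_experiment(
    design, {"fast": (0.075, 0.2), "slow": (-0.075, 0.2)})
sub = fc[(fc.subject_id == "s0") & (fc.adaptation == "fast")]
print(PsychometricModel.from_trials(sub).fit().summary())
```

```
Cumulative-Gaussian psychometric fit (MLE)
============================================
n trials        200
mu (PSE)         0.10512  (SE 0.02250)  = 10.51%
sigma            0.19128  (SE 0.02425)
log-likelihood  -77.231
converged       True
```

## Command line

```bash
numadapt presets                     # list the five preset configurations
numadapt run-all --seed 1 --out out/ # simulate + analyze every preset
numadapt simulate --config cfg.yaml --out out/run1
numadapt analyze-estimation --trials out/run1/trials.csv --out out/analysis
numadapt analyze-2afc --trials fc_trials.csv --out out/fc
```

Every run writes a `manifest.json` (config echo, versions, seed) that
suffices to reproduce all tables byte-identically. Exit codes: 0 success,
2 validation error, 3 degenerate data.

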
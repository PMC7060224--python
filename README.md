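# oculoread

Analysis toolkit for eye movements during reading, with a focus on what
happens to oculomotor targeting when the spatial layout of text is
manipulated — mirrored letters (mL), mirrored words (mW), inverted words
(iW), scrambled letters (sL) — alongside normal text (N).

It is written for reading researchers who work with fixation reports: the
package simulates, filters, classifies and fits reading scan paths, and
every estimator is validated by parameter recovery against a generative
reader with known ground truth.

## The science in brief

Where the eyes land within a word is dominated by two oculomotor error
components: Gaussian *random placement error*, and a systematic
launch-site-contingent shift, the *launch-site effect*.  In center-based
coordinates (letter positions measured from the target word's center,
`(len + 1) / 2` on the 1-based letter scale) the mean landing shift follows
the linear landing-position function

```
Δμ = λ · (L0 − L)
```

where `L ≥ 0` is the launch distance left of the target center, `L0` the
distance from which saccades land on the center on average, and the slope
`λ` measures the strength of the launch-site effect.  Close launches
overshoot the center, distant ones undershoot.

The slope has a process interpretation under Bayesian saccade planning: if
a noisy sensory estimate of the target (variance `σ0²`) is combined with a
Gaussian prior over launch-site distances (variance `σT²`), the posterior
mean shift is exactly the landing-position function with

```
λ = σ0² / (σ0² + σT²)
```

so `λ → 0` means saccades land on the target regardless of launch site
(precise sensing) and `λ → 1` means constant saccade lengths (prior
dominates); equal variances give the `λ ≈ 0.5` typical of normal reading.

Around this core the package provides:

- **`oculoread.layout`** — text-line layouts and the four letter/word
  transformations (single-line trials, ≤ 85 columns, 12 px/char).
- **`oculoread.simulate`** — the generative reader: landing positions from
  the launch-site effect plus motor noise, word-length-class tables for
  skipping/refixation/regression, log-normal durations, and an optional
  right-of-center two-fixation strategy for reversed-letter-order layouts.
- **`oculoread.preprocess`** — velocity-based fixation/saccade detection
  (median-based elliptic threshold) and the audited exclusion filters
  (duration bounds, text rectangle, saccade-length bounds, sequence edges,
  trial-level rules).
- **`oculoread.stats`** — saccade classification
  (forward/skipping/refixation/regression with first-pass tracking), global
  summary statistics, fixation-case proportions, skipping/refixation
  probabilities per word-length class.
- **`oculoread.landing`** — landing-position cells and histograms, the
  weighted-least-squares fit of the landing-position function
  (`LaunchSiteRegression`), and the minimum-χ² grid-search Gaussian fit of
  per-length landing distributions (`GridSearchGaussian`, steps of 0.01).
- **`oculoread.bayes`** — the Gaussian posterior, the predicted shift, and
  the slope–variance relations.
- **`oculoread.twofix`** — selection of two-fixation cases and the
  maximum-likelihood fit of the initial-landing parabola
  `y = A + B·L·(x − C)²` (`TwoFixationParabola`).

The fitting classes follow scikit-learn conventions (`fit`, fitted
attributes with trailing underscores, `get_params`) and compose with
sklearn tooling; module-level functions (`fit_landing_function`,
`fit_gaussian_gridsearch`, `fit_parabola`, `filter_fixations`) are thin
wrappers over them.

## Worked example

```python
from oculoread import (
    SimulationConfig, simulate_experiment, classify_saccades, global_summary,
    fixation_case_table, forward_saccade_table, landing_cells, fit_landing_function,
)

cfg = SimulationConfig(condition="N", n_subjects=4, n_trials=300,
                       lambda_gen=0.37, seed=42)
fixations, words = simulate_experiment(cfg)
events = classify_saccades(fixations)
gs = global_summary(events, fixations)
sacc = forward_saccade_table(events, fixations, words)
fit = fit_landing_function(landing_cells(sacc))
```

This prints (formatted):

```
saccade types (first-pass %): forward 56.0, skipping 17.3, refixation 18.8, regression 7.8
mean progressive saccade: 8.67 chars; mean fixation duration: 246 ms
fixation cases (%): {'single': 83.78, 'two': 12.83, 'multiple': 3.38}
launch-site effect: lambda = 0.371 (95% CI 0.356-0.385), L0 = 3.99 letters from 4776 forward saccades
```

Reading the numbers: the simulated control reader mostly moves forward or
skips, fixates most words exactly once, and — the key check — the
launch-site-effect slope fitted by the full pipeline (classification →
center-based coordinates → cell means → weighted least squares) recovers
the generating slope `λ = 0.37` within its confidence interval, with the
zero-crossing launch distance `L0 ≈ 4` letters.

A command-line interface mirrors the library (`oculoread simulate`,
`filter`, `stats`, `landing`, `bayes`, `twofix`); see `oculoread --help`.

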
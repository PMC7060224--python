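# Methods

This note documents the models implemented in `oculoread`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that make results reproducible.

## Coordinate conventions

All positions live on a character-column grid, 1-based, with one column per
letter and exactly one space column between words; a trial is a single line
of at most 85 columns.  A word of length `n` has its center at
`(n + 1) / 2` on the letter scale (fractional for even lengths).  Where raw
gaze is involved, 12 px equal one character space.

Center-based coordinates: the launch distance `L` of a forward saccade is
the number of character spaces between the launch fixation and the target
word's center, positive leftward; the landing position `Δ` is signed,
negative left of the center.  On this axis the landing-position function
`Δμ = λ(L0 − L)` has `λ, L0 > 0`, close launches (`L < L0`) overshoot and
distant ones undershoot.  Plots that put launch sites on a leftward
negative axis simply negate `L`.

## The Bayesian saccade-planning model

`oculoread.bayes` implements the Gaussian conjugate case: a prior over
center-based target positions `N(μT, σT²)` combined with a sensory
likelihood centered at the observation `x0` with variance `σ0²` yields a
Gaussian posterior with

    μP  = (σT²·x0 + σ0²·μT) / (σ0² + σT²),
    σP² = σ0²σT² / (σ0² + σT²).

The predicted shift `Δ_Bayes = μP − x0` reproduces the landing-position
function exactly under the mapping `μT ≡ L0`, `x0 ≡ L`, with slope
`λ = σ0²/(σ0² + σT²)` — a numerical identity the test suite checks to
1e-12.  Only `λ` is identifiable from slope fits; the package deliberately
does not attempt to decompose it into `σ0²` and `σT²` from data, and the
module exposes pure parameter-space operations (the anchoring of the latent
sensory observation in empirical data is not observable).

## The generative reader

`simulate.SimulationConfig` parameterizes a scan-path simulator whose
defaults are the conditions the estimators are validated under:

| parameter | default | meaning |
|---|---|---|
| `lambda_gen` | 0.37 | launch-site-effect slope of normal reading |
| `L0_gen` | 4.0 letters | zero-crossing launch distance |
| `sigma_motor` | 1.2 letters | SD of Gaussian motor noise |
| `p_skip` | 0.50…0.04 by class | skipping probability, decreasing in length |
| `p_refix` | 0.05…0.28 by class | first-pass refixation probability; 0.16 on medium (5–7 letter) words |
| `p_regress` | 0.10 | regression probability per word visit |
| `duration_logmean`, `duration_logsd` | ln 245 − 0.35²/2, 0.35 | log-normal durations with mean 245 ms |
| `two_fix_shift` | +1.5 letters | initial-landing offset of the mW/iW two-fixation episode |
| `p_two_fix_strategy` | 0.3 | probability of that episode in mW/iW |

Landing positions are generated directly from the landing-position function
(`landing = center + λ(L0 − L) + ε`, `ε ~ N(0, σ_motor²)`) rather than by
simulating the sensory-observation mechanism sample by sample; the two are
expectation-equivalent in the Gaussian model, and the direct form makes `λ`
the single ground-truth slope recovery must find.  Durations are log-normal
because duration data are right-skewed; means are configured through the
log-normal mean identity `E[d] = exp(μ + σ²/2)`.  Word-length-class tables
(classes 3–8, lengths < 3 and > 8 collapsed into the edge classes) drive
skipping, refixation, and regression; regressions re-read previously
fixated words.  The per-word first-pass fixation count is drawn either
geometrically from `p_refix` (so that P(≥ 2 fixations) equals the
refixation probability the estimator measures) or from an explicit
(single, two, multiple) probability triple when fixation-case composition
itself is under study.

Words are pseudo-words: random lowercase strings with lengths drawn from a
configurable distribution (defaults roughly matching connected German
text, mean ≈ 5.3 letters).  No lexical variables exist in the simulator —
no frequency, predictability, or parafoveal preview effects — so passing
recovery tests demonstrates the correctness of the estimation chain, not
that real reading data contain only oculomotor structure.

The generator's word assignment is ground truth: each fixation record
carries the index of the word the saccade was aimed at even when motor
noise carries the landing column past a word edge, the way region-based
interest-area reports do.  Analyses that re-assign fixations from raw
columns (`preprocess.assign_words`) will therefore differ slightly in the
tails; this is a property of real pipelines too.

Two special generator modes exist for validating estimators in isolation,
both documented as such in their docstrings: `sample_forward_saccades`
forces launch distances uniform over a stated integer range (guaranteeing
coverage of the launch axis for slope recovery), and
`simulate_forced_lengths` emits pure forward reading with saccade lengths
drawn from a stated normal distribution (so the progressive-length mean the
classifier recovers is the configured one; a free-running scan path cannot
have this mean configured directly because word-boundary truncation shifts
it).

Randomness: one root seed; per-(subject, trial) generators are derived as
`default_rng([seed, subject, trial])`, so increasing the trial count never
reshuffles earlier trials.

## Event detection and filtering

Detection uses the velocity-based scheme standard for 1000 Hz reading data:
a 5-sample moving-average velocity kernel, an elliptic threshold whose
semi-axes are `6 ×` a median-based velocity SD (robust to fixational
noise), minimum saccade length 3 samples, minimum fixation duration 20 ms.
These defaults are config-exposed; the SD estimate is floored at 1e-10 so a
noiseless trace yields no spurious saccades.

Filtering applies, in a fixed audited order: blink rows; sequence-edge
fixations (first/last of a participant's session and fixations on the
first/last word of a trial line); durations outside [20, 1000] ms;
landings outside the text rectangle; incoming saccades shorter than 1 or
longer than 25 character spaces; then trial-level rules (any raw fixation
> 2000 ms, or fewer than 3 surviving fixations, drops the whole trial).
Design choices worth stating:

- The incoming saccade length belongs to the later fixation and is computed
  on the *raw* sequence, before any row exclusions; sequence-derived
  context (`incoming_sacc_len`, `seq_edge`) is cached as columns on first
  application, which makes the row rules conjunctive (order-independent)
  and filtering idempotent.
- The trial-level 2000 ms rule inspects raw durations: a fixation that long
  is always also removed by the 1000 ms row rule, so the trial rule would
  be vacuous if applied after row filtering.
- "First and last words of a sentence" is implemented as first and last
  words of the trial line, since stimuli are single lines.

## Estimators

**Launch-site effect** (`LaunchSiteRegression`): weighted least squares of
cell-mean landings on integer launch-distance bins, weights = cell counts,
cells with fewer than 20 saccades dropped (config-exposed stability floor).
The slope is `−λ̂`, the intercept `λ̂·L0`; `L0`'s standard error comes from
the delta method, `λ`'s CI from the WLS t-interval.  Cell means are
arithmetic means of `Δ`.  A flat profile (`λ̂ ≈ 0`) leaves `L0` undefined
and is flagged rather than divided through.  The launch restriction used
for distribution-level analyses (saccades launched at most 5 characters
before the word beginning) is available as a flag but not applied to the
slope fit by default.

**Skipping probability**: the estimator counts a word as a skipping
opportunity only when it lies strictly between the trial's first word and
the furthest first-pass fixated word — the first word is where the scan
starts and the furthest word is fixated by definition, so including either
biases the estimate downward (the bias is visible in simulation as a
shortfall of a few points).

**Grid-search Gaussian fit** (`GridSearchGaussian`): expected counts come
from a Gaussian integrated over letter cells `(i − 0.5, i + 0.5]` and
renormalized over the word; Pearson χ² is minimized over an exhaustive grid
with step 0.01, `μ ∈ [0.5, len + 0.5]`, `σ ∈ [0.3, 5.0]`.  Expected counts
are floored at 1e-9 to keep empty cells finite; ties break deterministically
to the smallest `σ`, then the smallest `μ`.  The grid is exact on its
domain; tests verify agreement within one grid step with a bounded
continuous optimizer on the same surface.

**Two-fixation parabola** (`TwoFixationParabola`): `y = A + B·L·(x − C)²`
with `L` read as the word length (fits are per length class, so `L` is a
known constant).  The default likelihood is Gaussian residuals on relative
frequencies with a free residual SD — then the ML point estimate is least
squares, optimized by a deterministic multi-start (C initialized at each
letter, A and B by linear least squares given C, Nelder-Mead polish, best
likelihood wins, ties to smallest C).  A multinomial-count likelihood is
available behind `likelihood="multinomial"`.  Flat profiles (`|B|` below
1e-6) are flagged `c_identifiable = False` rather than reported with an
arbitrary extremum.

**First-pass definition** (used by case tables, probabilities, durations,
and two-fixation selection): all fixations on a word from first entry until
the gaze first leaves it in either direction; later visits are second pass.
Case tables count first-pass visits by default with an `first_pass_only`
switch.

## Scramble condition details

`sL` fixes the first and last letter and permutes the interior uniformly,
identity permitted (a scramble that reproduces the original order is a
valid draw); an `exclude_identity_scramble` switch removes the identity
when a non-identity permutation exists.  Scrambles are drawn per word per
trial from the trial's seeded stream.  Glyph mirroring (mL, mW) is carried
as a boolean flag — the analyses depend only on letter order and position,
never on rendered glyphs.

## Validation scale

The recovery checks run at desk scale: 20,000 forward saccades for slope
recovery (slope standard error ≈ 0.004 at motor noise 1.2), ~20,000 words
for fixation-case composition, ~11,000 fixated medium words for refixation
probability, 20,000 progressive saccades for the global measures, and
50,000 saccades for the slope-equals-variance-ratio consistency check.
These sizes put Monte-Carlo error well inside the assertion tolerances
while keeping the whole suite and the acceptance script in the
tens-of-seconds range.

## Known limitations

- No lexical or attentional modulation in the generator; no mixed-effects
  estimation (raw class means are reported where adjusted means would be
  used on real multi-subject data).
- No binocular processing, drift/glissade classification, or calibration
  handling in event detection.
- The two-fixation "strategy" episode for mW/iW is a hypothesis-shaped
  mechanism (initial landing right of center, corrective leftward
  fixation), not a fitted model of empirical two-fixation behavior.
- Landing distributions are analysed per word length only; effects of
  launch site on distribution *shape* beyond mean and SD are out of scope.
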
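"""Generative reader: synthetic fixation reports with known ground truth.

The simulator emulates the statistical structure the downstream analyses
assume, so that every estimator in the package can be validated by parameter
recovery:

* within-word landing positions are Gaussian around a mean that shifts
  linearly with the center-based launch distance ``L`` — the launch-site
  effect ``delta_mu = lambda * (L0 - L)`` — with motor noise ``sigma_motor``;
* word-length-class tables drive skipping, refixation and regression;
* fixation durations are log-normal (right-skewed, as duration data are);
* in the reversed-letter-order conditions (mW, iW) an optional two-fixation
  episode places the initial landing right of the word center followed by a
  leftward corrective fixation.

The generator's word assignment is ground truth: each fixation record
carries the index of the word the saccade was aimed at, the way region-based
interest-area reports do, even when motor noise puts the landing column past
a word edge.

Nothing lexical is modelled (no frequency or predictability effects); words
are pseudo-words sampled from a configurable length distribution.
"""

from __future__ import annotations

import hashlib
import io
import json
import math
import string
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .layout import TrialLayout, build_trial_layout

__all__ = [
    "SimulationConfig",
    "FixationRecord",
    "FIXATION_COLUMNS",
    "sample_landing",
    "next_target",
    "simulate_trial",
    "simulate_experiment",
    "sample_forward_saccades",
    "simulate_forced_lengths",
    "write_fixation_report",
    "read_fixation_report",
]

FIXATION_COLUMNS = [
    "subject",
    "session",
    "trial",
    "fix_index",
    "x_col",
    "duration_ms",
    "word_index",
    "letter_index",
    "word_length",
]

#: log-mean giving an expected fixation duration of 245 ms at log-sd 0.35
#: via the log-normal mean identity E[d] = exp(mu + sd^2 / 2).
DEFAULT_DURATION_LOGSD = 0.35
DEFAULT_DURATION_LOGMEAN = math.log(245.0) - DEFAULT_DURATION_LOGSD**2 / 2

_DEFAULT_WORD_LENGTHS = {
    1: 0.03, 2: 0.09, 3: 0.20, 4: 0.12, 5: 0.11, 6: 0.12,
    7: 0.10, 8: 0.09, 9: 0.06, 10: 0.04, 11: 0.03, 12: 0.01,
}
_DEFAULT_P_SKIP = {3: 0.50, 4: 0.35, 5: 0.20, 6: 0.12, 7: 0.08, 8: 0.04}
# medium words (5-7 letters) at the refixation probability typical of
# normal reading; short words lower, long words higher
_DEFAULT_P_REFIX = {3: 0.05, 4: 0.10, 5: 0.16, 6: 0.16, 7: 0.16, 8: 0.28}
_DEFAULT_P_REGRESS = {c: 0.10 for c in range(3, 9)}


def _length_class(length: int) -> int:
    return min(max(length, 3), 8)


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: the pipeline's atom."""

    subject: int
    session: int
    trial: int
    fix_index: int
    x_col: float
    duration_ms: float
    word_index: int
    letter_index: int
    word_length: int


@dataclass
class SimulationConfig:
    """Full parameterization of the generative reader.

    ``lambda_gen``/``L0_gen``/``sigma_motor`` are the launch-site-effect
    slope, the launch distance (letters) at which saccades land on the word
    center on average, and the SD of the Gaussian motor noise.  Event
    probability tables are keyed by word-length class (3..8).  Durations are
    log-normal; ``duration_logmean`` may be a scalar or a mapping with keys
    among ``{"first", "refix", "regress", "default"}``.
    """

    condition: str = "N"
    n_subjects: int = 4
    n_trials: int = 50
    words_per_trial: int = 10
    word_length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_WORD_LENGTHS)
    )
    lambda_gen: float = 0.37
    L0_gen: float = 4.0
    sigma_motor: float = 1.2
    p_skip: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_P_SKIP))
    p_refix: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_P_REFIX))
    p_regress: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_P_REGRESS)
    )
    fixation_case_probs: Optional[tuple[float, float, float]] = None
    two_fix_shift: float = 1.5
    p_two_fix_strategy: float = 0.3
    duration_logmean: Union[float, Mapping[str, float]] = DEFAULT_DURATION_LOGMEAN
    duration_logsd: float = DEFAULT_DURATION_LOGSD
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lambda_gen < 1:
            raise ValueError(f"lambda_gen must be in [0, 1), got {self.lambda_gen}")
        if not self.sigma_motor > 0:
            raise ValueError("sigma_motor must be positive")
        total = sum(self.word_length_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("word_length_distribution must sum to 1")
        for name, table in (
            ("p_skip", self.p_skip),
            ("p_refix", self.p_refix),
            ("p_regress", self.p_regress),
        ):
            for cls in range(3, 9):
                if cls not in table:
                    raise KeyError(f"{name} is missing word-length class {cls}")
                if not 0 <= table[cls] <= 1:
                    raise ValueError(f"{name}[{cls}] outside [0, 1]")
        if self.fixation_case_probs is not None:
            p = self.fixation_case_probs
            if len(p) != 3 or any(q < 0 for q in p) or not math.isclose(sum(p), 1.0, abs_tol=1e-6):
                raise ValueError("fixation_case_probs must be 3 probabilities summing to 1")
        if not 0 <= self.p_two_fix_strategy <= 1:
            raise ValueError("p_two_fix_strategy outside [0, 1]")

    def logmean_for(self, role: str) -> float:
        if isinstance(self.duration_logmean, Mapping):
            if role in self.duration_logmean:
                return self.duration_logmean[role]
            return self.duration_logmean["default"]
        return float(self.duration_logmean)

    def to_json(self) -> str:
        d = asdict(self)
        d["word_length_distribution"] = {
            str(k): v for k, v in self.word_length_distribution.items()
        }
        for key in ("p_skip", "p_refix", "p_regress"):
            d[key] = {str(k): v for k, v in d[key].items()}
        if isinstance(self.duration_logmean, Mapping):
            d["duration_logmean"] = dict(self.duration_logmean)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for key in ("word_length_distribution", "p_skip", "p_refix", "p_regress"):
            if key in d:
                d[key] = {int(k): v for k, v in d[key].items()}
        if "fixation_case_probs" in d and d["fixation_case_probs"] is not None:
            d["fixation_case_probs"] = tuple(d["fixation_case_probs"])
        return cls(**d)


def sample_landing(
    L: float,
    lambda_gen: float,
    L0_gen: float,
    sigma_motor: float,
    rng: np.random.Generator,
) -> float:
    """Draw one center-based landing position for a forward saccade.

    The draw is ``lambda * (L0 - L) + eps`` with ``eps ~ N(0, sigma_motor^2)``;
    negative values land left of the target word's center.  ``L`` is the
    center-based launch distance in letters, measured leftward (>= 0).
    """
    if L < 0:
        raise ValueError(f"launch distance must be >= 0 for forward saccades, got {L}")
    return lambda_gen * (L0_gen - L) + rng.normal(0.0, sigma_motor)


def _draw_case_count(
    cls: int, config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Number of first-pass fixations a word receives once it is fixated."""
    if config.fixation_case_probs is not None:
        return int(rng.choice((1, 2, 3), p=config.fixation_case_probs))
    # geometric continuation: P(>= 2 fixations) = p_refix, the quantity the
    # refixation-probability estimator measures
    p = config.p_refix[cls]
    n = 1
    while n < 4 and rng.random() < p:
        n += 1
    return n


def next_target(
    current: int,
    layout: TrialLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
    visited: Optional[set[int]] = None,
) -> tuple[Optional[int], str]:
    """Choose the next saccade target from word ``current`` (1-based).

    Draws, in order: a regression (re-reading: a uniformly chosen earlier
    *visited* word when ``visited`` is given, any earlier word otherwise),
    then word skipping (each upcoming word is skipped with its length-class
    probability).  Returns ``(target_word_index, episode)`` with episode one
    of ``"regress" | "forward" | "skip"``; target None means the scan is done.
    Refixations are handled at arrival time (see :func:`simulate_trial`).
    """
    if not 1 <= current <= layout.n_words:
        raise ValueError(f"current word {current} outside layout")
    words = layout.words
    if current > 1:
        cls = _length_class(words[current - 1].length)
        if rng.random() < config.p_regress[cls]:
            if visited is None:
                return int(rng.integers(1, current)), "regress"
            earlier = sorted(w for w in visited if w < current)
            if earlier:
                return int(earlier[int(rng.integers(len(earlier)))]), "regress"
    t = current + 1
    skipped = 0
    while t <= layout.n_words and rng.random() < config.p_skip[
        _length_class(words[t - 1].length)
    ]:
        t += 1
        skipped += 1
    if t > layout.n_words:
        return None, "done"
    return t, ("skip" if skipped else "forward")


def _duration(role: str, config: SimulationConfig, rng: np.random.Generator) -> float:
    return float(rng.lognormal(config.logmean_for(role), config.duration_logsd))


def simulate_trial(
    layout: TrialLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    subject: int = 0,
    session: int = 1,
) -> list[FixationRecord]:
    """Simulate one trial's scan path over ``layout``.

    The scan starts on word 1 and ends after the last (non-skipped) word.
    Every between-word landing is drawn by :func:`sample_landing` from the
    center-based distance of the chosen target.
    """
    if layout.n_words == 0:
        raise ValueError("empty layout")
    two_fix_conditions = ("mW", "iW")
    records: list[FixationRecord] = []
    fix_index = 0
    x: Optional[float] = None

    def emit(word, land_col: float, role: str) -> None:
        nonlocal fix_index, x
        fix_index += 1
        letter = int(np.clip(round(land_col - word.first_char_col + 1), 1, word.length))
        records.append(
            FixationRecord(
                subject=subject,
                session=session,
                trial=layout.trial_id,
                fix_index=fix_index,
                x_col=float(land_col),
                duration_ms=_duration(role, config, rng),
                word_index=word.word_index,
                letter_index=letter,
                word_length=word.length,
            )
        )
        x = land_col

    current = 1
    visited: set[int] = set()
    while True:
        visited.add(current)
        word = layout.words[current - 1]
        c = word.center_col
        cls = _length_class(word.length)
        strategic = (
            config.condition in two_fix_conditions
            and rng.random() < config.p_two_fix_strategy
        )
        if strategic:
            # aim right of center first, then a leftward corrective fixation
            emit(word, c + config.two_fix_shift + rng.normal(0, config.sigma_motor), "first")
            emit(word, c - config.two_fix_shift / 2 + rng.normal(0, config.sigma_motor), "refix")
        else:
            if x is None:
                land = c + rng.normal(0, config.sigma_motor)
            else:
                L = max(c - x, 0.0)
                land = c + sample_landing(
                    L, config.lambda_gen, config.L0_gen, config.sigma_motor, rng
                )
            emit(word, land, "first")
            for _ in range(_draw_case_count(cls, config, rng) - 1):
                emit(word, c + rng.normal(0, config.sigma_motor), "refix")
        target, episode = next_target(current, layout, config, rng, visited)
        if episode == "regress" and target is not None:
            back = layout.words[target - 1]
            emit(back, back.center_col + rng.normal(0, config.sigma_motor), "regress")
            target, episode = next_target(current, layout, config, rng, visited)
            while episode == "regress":  # at most one regression per word visit
                target, episode = next_target(current, layout, config, rng, visited)
        if target is None:
            break
        current = target
    return records


def _sample_words(
    config: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    """Pseudo-lexicon sampler: random lowercase strings, lengths from config."""
    lengths = list(config.word_length_distribution)
    probs = [config.word_length_distribution[k] for k in lengths]
    words: list[str] = []
    used = 0
    for _ in range(config.words_per_trial):
        n = int(rng.choice(lengths, p=probs))
        if used + n + (1 if words else 0) > 85:
            break
        letters = "".join(rng.choice(list(string.ascii_lowercase), size=n))
        words.append(letters)
        used += n + (1 if len(words) > 1 else 0)
    return words


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_subjects x n_trials`` trials.

    Returns ``(fixations, words)``: the fixation report (one row per
    fixation, :data:`FIXATION_COLUMNS`) and the word inventory (subject,
    session, trial, word_index, word_length) needed to count skipping
    opportunities.

    Randomness is split per (seed, subject, trial) so changing the trial
    count never reshuffles earlier trials.
    """
    fix_rows: list[FixationRecord] = []
    word_rows: list[tuple] = []
    for s in range(config.n_subjects):
        for t in range(config.n_trials):
            rng = np.random.default_rng([config.seed, s, t])
            words = _sample_words(config, rng)
            layout = build_trial_layout(
                words, config.condition, rng, trial_id=t + 1
            )
            fix_rows.extend(
                simulate_trial(layout, config, rng, subject=s + 1, session=1)
            )
            word_rows.extend(
                (s + 1, 1, t + 1, w.word_index, w.length) for w in layout.words
            )
    fixations = pd.DataFrame([asdict(r) for r in fix_rows], columns=FIXATION_COLUMNS)
    words_df = pd.DataFrame(
        word_rows, columns=["subject", "session", "trial", "word_index", "word_length"]
    )
    return fixations, words_df


def sample_forward_saccades(
    n: int,
    lambda_gen: float = 0.37,
    L0_gen: float = 4.0,
    sigma_motor: float = 1.2,
    *,
    launch_range: tuple[int, int] = (1, 8),
    word_lengths: Sequence[int] = (4, 5, 6, 7, 8),
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward saccades with a forced uniform launch-distance range.

    Launch distances are uniform over the integers of ``launch_range`` and
    word lengths uniform over ``word_lengths``, guaranteeing coverage of the
    launch axis for launch-site-effect recovery.  Returns columns
    ``word_length``, ``launch_dist`` (L, letters leftward of the target
    center) and ``landing`` (center-based, negative = left of center).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = rng.integers(launch_range[0], launch_range[1] + 1, size=n).astype(float)
    lengths = rng.choice(np.asarray(word_lengths), size=n)
    landing = lambda_gen * (L0_gen - L) + rng.normal(0.0, sigma_motor, size=n)
    return pd.DataFrame(
        {"word_length": lengths, "launch_dist": L, "landing": landing}
    )


def simulate_forced_lengths(
    n_saccades: int,
    length_mean: float = 7.82,
    length_sd: float = 3.0,
    *,
    duration_logmean: float = DEFAULT_DURATION_LOGMEAN,
    duration_logsd: float = DEFAULT_DURATION_LOGSD,
    words_per_trial: int = 11,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Scan paths in the forced saccade-length mode.

    Each trial fixates ``words_per_trial`` consecutive words exactly once;
    the step between consecutive fixations is drawn ``N(length_mean,
    length_sd^2)`` in character spaces and durations are log-normal.  Every
    saccade is therefore a between-word forward movement, so the progressive
    mean the classifier recovers is the configured mean — the mode exists to
    validate the global summary statistics in isolation from the scan-path
    event tables.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_trials = math.ceil(n_saccades / (words_per_trial - 1))
    rows = []
    for t in range(n_trials):
        x = 3.0
        for w in range(1, words_per_trial + 1):
            rows.append(
                (
                    1,
                    1,
                    t + 1,
                    w,
                    x,
                    float(rng.lognormal(duration_logmean, duration_logsd)),
                    w,
                    3,
                    5,
                )
            )
            x += rng.normal(length_mean, length_sd)
    return pd.DataFrame(rows, columns=FIXATION_COLUMNS)


def write_fixation_report(
    df: pd.DataFrame, path, config: Optional[SimulationConfig] = None
) -> None:
    """Write a TSV fixation report with a '#'-prefixed provenance header."""
    buf = io.StringIO()
    if config is not None:
        cfg = config.to_json()
        digest = hashlib.sha256(cfg.encode()).hexdigest()[:16]
        buf.write(f"# oculoread fixation report\n")
        buf.write(f"# config: {cfg}\n")
        buf.write(f"# config_sha256: {digest}\n")
        buf.write(f"# seed: {config.seed}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_fixation_report(path) -> pd.DataFrame:
    """Read a TSV fixation report, skipping provenance comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")
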
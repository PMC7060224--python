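"""Fixation/saccade detection from raw gaze samples and fixation filtering.

Detection follows the velocity-based approach standard for 1000 Hz reading
data: gaze velocity is estimated with a 5-sample moving-average kernel and a
sample belongs to a saccade when it exceeds an elliptic threshold whose
semi-axes are a multiple of a median-based velocity SD (robust to the
fixational noise level of the trace).

Filtering applies the exclusion rules for reading fixation reports in a
fixed, audited order:

1. blink-flagged fixations;
2. fixations on the first and last word of a trial line, and the first and
   last fixation of a participant's per-session sequence;
3. durations below 20 ms or above 1000 ms;
4. fixations landing outside the text rectangle;
5. fixations whose incoming saccade is shorter than one character space
   (12 px) or longer than 25 character spaces;
6. trial-level rules: trials containing any fixation longer than 2000 ms,
   or left with fewer than three fixations, are dropped whole.

Sequence-edge membership and incoming saccade lengths are properties of the
raw recording, not of the filtered subset; they are computed once and cached
as columns (``seq_edge``, ``incoming_sacc_len``) so that filtering is
idempotent and the row rules are order-independent (conjunctive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .layout import TrialLayout

__all__ = [
    "PX_PER_CHAR",
    "Assignment",
    "FilterReport",
    "FixationFilter",
    "detect_events",
    "filter_fixations",
    "assign_words",
]

#: Courier-style fixed-width rendering: one character space is 12 pixels.
PX_PER_CHAR = 12.0

ROW_RULES = ("blink", "seq_edge", "duration", "outside", "saccade_length")
TRIAL_RULES = ("trial_long_fixation", "trial_too_few")


class Assignment(NamedTuple):
    """Where a fixation column falls: a letter cell, a space, or off the line."""

    kind: str  # "word" | "space" | "outside"
    word_index: Optional[int]
    letter_index: Optional[int]


def assign_words(x_col: float, layout: TrialLayout) -> Assignment:
    """Map a (fractional) fixation column to its letter cell.

    Columns outside ``[0.5, line_length + 0.5)`` get the ``outside`` marker;
    in-line columns between words get the ``space`` marker.
    """
    if x_col < 0.5 or x_col >= layout.line_length_chars + 0.5:
        return Assignment("outside", None, None)
    hit = layout.locate(x_col)
    if hit is None:
        return Assignment("space", None, None)
    return Assignment("word", hit[0], hit[1])


def _velocity(x: np.ndarray, dt_ms: float, window: int) -> np.ndarray:
    """Moving-average velocity (units of x per ms)."""
    n = len(x)
    v = np.zeros(n)
    if window == 5:
        # 5-sample kernel: v_i = (x_{i+2} + x_{i+1} - x_{i-1} - x_{i-2}) / (6 dt)
        v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_ms)
    else:
        raw = np.gradient(x, dt_ms)
        k = np.ones(window) / window
        v = np.convolve(raw, k, mode="same")
    return v


def _median_sd(v: np.ndarray) -> float:
    med = np.median(v)
    sd = np.sqrt(np.median(v**2) - med**2)
    return max(float(sd), 1e-10)


def detect_events(
    samples: pd.DataFrame,
    vel_window: int = 5,
    vel_multiplier: float = 6.0,
    min_duration_ms: float = 20.0,
    *,
    min_saccade_samples: int = 3,
    px_per_char: float = PX_PER_CHAR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment a raw gaze trace into fixations and saccades.

    ``samples`` needs columns ``t_ms``, ``x_px``, ``y_px`` (and optionally a
    boolean ``blink`` column; blink-flagged samples must already be removed,
    their presence raises).  Returns ``(fixations, saccades)``; fixation
    positions are the mean gaze during the span, also expressed in character
    columns (``x_col = x_px / px_per_char``).
    """
    if "blink" in samples.columns and samples["blink"].any():
        raise ValueError("blink-flagged samples must be removed before detection")
    t = samples["t_ms"].to_numpy(dtype=float)
    if len(t) < max(vel_window, 2):
        raise ValueError(f"need at least {vel_window} samples, got {len(t)}")
    dts = np.diff(t)
    if not (dts > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    dt = float(np.median(dts))
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)
    vx = _velocity(x, dt, vel_window)
    vy = _velocity(y, dt, vel_window)
    eta_x = vel_multiplier * _median_sd(vx)
    eta_y = vel_multiplier * _median_sd(vy)
    is_sacc_sample = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0

    # runs of supra-threshold samples of sufficient length are saccades
    padded = np.concatenate(([False], is_sacc_sample, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    sacc_spans = [(s, e) for s, e in zip(starts, ends) if e - s >= min_saccade_samples]

    saccades = pd.DataFrame(
        [
            {
                "t_start": t[s],
                "t_end": t[e - 1],
                "amplitude_px": x[min(e, len(x) - 1)] - x[max(s - 1, 0)],
                "amplitude_chars": (x[min(e, len(x) - 1)] - x[max(s - 1, 0)])
                / px_per_char,
            }
            for s, e in sacc_spans
        ],
        columns=["t_start", "t_end", "amplitude_px", "amplitude_chars"],
    )

    # fixations are the complementary spans, kept if long enough
    fix_rows = []
    bounds = [0] + [i for span in sacc_spans for i in span] + [len(t)]
    for s, e in zip(bounds[::2], bounds[1::2]):
        if e <= s:
            continue
        duration = t[e - 1] - t[s] + dt
        if duration >= min_duration_ms:
            fix_rows.append(
                {
                    "t_start": t[s],
                    "t_end": t[e - 1],
                    "duration_ms": duration,
                    "x_px": float(np.mean(x[s:e])),
                    "y_px": float(np.mean(y[s:e])),
                    "x_col": float(np.mean(x[s:e])) / px_per_char,
                }
            )
    fixations = pd.DataFrame(
        fix_rows, columns=["t_start", "t_end", "duration_ms", "x_px", "y_px", "x_col"]
    )
    return fixations, saccades


@dataclass
class FilterReport:
    """Audit of the exclusion rules, in application order."""

    input_n: int = 0
    counts: dict = field(default_factory=dict)
    survivors_n: int = 0
    trials_dropped: int = 0

    def check(self) -> None:
        if self.input_n - sum(self.counts.values()) != self.survivors_n:
            raise AssertionError("filter audit does not balance")


def _prepare_context(df: pd.DataFrame, last_word: Optional[pd.Series]) -> pd.DataFrame:
    """Cache sequence-derived columns so row rules are stable under refiltering."""
    df = df.copy()
    if "incoming_sacc_len" not in df.columns:
        df["incoming_sacc_len"] = (
            df.groupby(["subject", "session", "trial"], sort=False)["x_col"]
            .diff()
            .abs()
        )
    if "seq_edge" not in df.columns:
        edge = pd.Series(False, index=df.index)
        for _, g in df.groupby(["subject", "session"], sort=False):
            edge.loc[g.index[0]] = True
            edge.loc[g.index[-1]] = True
        # first/last word of the trial line
        key = ["subject", "session", "trial"]
        if last_word is not None:
            last = df[key].apply(tuple, axis=1).map(last_word)
        else:
            last = df.groupby(key, sort=False)["word_index"].transform("max")
        edge |= (df["word_index"] == 1) | (df["word_index"] == last)
        df["seq_edge"] = edge
    return df


def filter_fixations(
    report: pd.DataFrame,
    line_length_chars: float,
    *,
    words: Optional[pd.DataFrame] = None,
    min_duration_ms: float = 20.0,
    max_duration_ms: float = 1000.0,
    trial_max_duration_ms: float = 2000.0,
    min_saccade_chars: float = 1.0,
    max_saccade_chars: float = 25.0,
    min_fixations_per_trial: int = 3,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the exclusion rules to a fixation report.

    ``words``, if given, is the word inventory (subject, session, trial,
    word_index) used to identify each trial's true last word; otherwise the
    largest fixated word index stands in.  Row rules are conjunctive; each
    excluded row is attributed to the first rule (in documented order) that
    flags it.  Trial-level rules run last, on raw (pre-row-filter) durations.
    """
    if report["word_index"].isna().any():
        bad = report.index[report["word_index"].isna()][0]
        raise ValueError(f"fixation row {bad} is missing a word assignment")
    last_word = None
    if words is not None:
        last_word = words.groupby(["subject", "session", "trial"])["word_index"].max()
    df = _prepare_context(report, last_word)
    n_in = len(df)

    masks = {
        "blink": (
            df["blink"].astype(bool)
            if "blink" in df.columns
            else pd.Series(False, index=df.index)
        ),
        "seq_edge": df["seq_edge"].astype(bool),
        "duration": (df["duration_ms"] < min_duration_ms)
        | (df["duration_ms"] > max_duration_ms),
        "outside": (df["x_col"] < 0.5) | (df["x_col"] >= line_length_chars + 0.5),
        "saccade_length": (df["incoming_sacc_len"] < min_saccade_chars)
        | (df["incoming_sacc_len"] > max_saccade_chars),
    }
    counts: dict[str, int] = {}
    removed = pd.Series(False, index=df.index)
    for rule in ROW_RULES:
        hit = masks[rule] & ~removed
        counts[rule] = int(hit.sum())
        removed |= masks[rule].fillna(False)

    key = ["subject", "session", "trial"]
    long_trials = set(
        df.loc[df["duration_ms"] > trial_max_duration_ms, key].apply(tuple, axis=1)
    )
    survivors = df[~removed]
    trial_keys = survivors[key].apply(tuple, axis=1) if len(survivors) else pd.Series(dtype=object)
    in_long = trial_keys.isin(long_trials) if len(survivors) else pd.Series(dtype=bool)
    counts["trial_long_fixation"] = int(in_long.sum())
    survivors = survivors[~in_long] if len(survivors) else survivors

    if len(survivors):
        sizes = survivors.groupby(key, sort=False)["fix_index"].transform("size")
        too_few = sizes < min_fixations_per_trial
    else:
        too_few = pd.Series(dtype=bool)
    counts["trial_too_few"] = int(too_few.sum())
    survivors = survivors[~too_few] if len(survivors) else survivors

    n_trials_in = df[key].drop_duplicates().shape[0]
    n_trials_out = survivors[key].drop_duplicates().shape[0] if len(survivors) else 0
    rep = FilterReport(
        input_n=n_in,
        counts=counts,
        survivors_n=len(survivors),
        trials_dropped=n_trials_in - n_trials_out,
    )
    rep.check()
    return survivors, rep


try:  # sklearn is a hard dependency, guard only for import-order hygiene
    from sklearn.base import BaseEstimator, TransformerMixin
except Exception:  # pragma: no cover
    BaseEstimator = object  # type: ignore

    class TransformerMixin:  # type: ignore
        pass


class FixationFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping :func:`filter_fixations`.

    Stateless (``fit`` is a no-op); after ``transform`` the exclusion audit
    is available as ``report_``.
    """

    def __init__(
        self,
        line_length_chars: float = 85,
        min_duration_ms: float = 20.0,
        max_duration_ms: float = 1000.0,
        trial_max_duration_ms: float = 2000.0,
        min_saccade_chars: float = 1.0,
        max_saccade_chars: float = 25.0,
        min_fixations_per_trial: int = 3,
    ):
        self.line_length_chars = line_length_chars
        self.min_duration_ms = min_duration_ms
        self.max_duration_ms = max_duration_ms
        self.trial_max_duration_ms = trial_max_duration_ms
        self.min_saccade_chars = min_saccade_chars
        self.max_saccade_chars = max_saccade_chars
        self.min_fixations_per_trial = min_fixations_per_trial

    def fit(self, X: pd.DataFrame, y=None) -> "FixationFilter":
        return self

    def transform(self, X: pd.DataFrame, words: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        out, self.report_ = filter_fixations(
            X,
            self.line_length_chars,
            words=words,
            min_duration_ms=self.min_duration_ms,
            max_duration_ms=self.max_duration_ms,
            trial_max_duration_ms=self.trial_max_duration_ms,
            min_saccade_chars=self.min_saccade_chars,
            max_saccade_chars=self.max_saccade_chars,
            min_fixations_per_trial=self.min_fixations_per_trial,
        )
        return out
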
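"""Saccade classification and summary statistics of reading behaviour.

Saccades between consecutive fixations are labelled

* ``forward`` — to the immediately next word,
* ``skipping`` — passing over at least one word,
* ``refixation`` — within the same word,
* ``regression`` — to any earlier word, or leftward within a word that was
  already exited once (second-pass re-reading).

First-pass status follows the field-standard reading: all fixations on a
word from first entry until the gaze first leaves it in either direction are
first-pass; later visits are second-pass.  Word lengths are grouped into
classes 3..8 (lengths under 3 into class 3, over 8 into class 8); medium
words are lengths 5-7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SACCADE_TYPES",
    "GlobalSummary",
    "word_length_class",
    "annotate_first_pass",
    "classify_saccades",
    "global_summary",
    "fixation_case_table",
    "event_probabilities",
    "duration_measures",
]

SACCADE_TYPES = ("forward", "skipping", "refixation", "regression")
TRIAL_KEY = ["subject", "session", "trial"]


def word_length_class(length: int) -> int:
    """Group a word length into the analysis classes 3..8."""
    if length < 1:
        raise ValueError(f"word length must be >= 1, got {length}")
    return min(max(int(length), 3), 8)


def _iter_trials(fixations: pd.DataFrame):
    for key, g in fixations.groupby(TRIAL_KEY, sort=False):
        yield key, g.sort_values("fix_index")


def annotate_first_pass(fixations: pd.DataFrame) -> pd.DataFrame:
    """Add first-pass bookkeeping columns to a fixation report.

    Returns a copy with ``first_pass`` (bool), ``fp_ord`` (ordinal of the
    fixation within its word's first-pass visit, NaN for second pass) and
    ``fp_count`` (total first-pass fixations the word received).
    """
    if fixations["word_index"].isna().any():
        raise ValueError("fixation report contains unassigned word indices")
    df = fixations.copy()
    first_pass = np.zeros(len(df), dtype=bool)
    fp_ord = np.full(len(df), np.nan)
    fp_count = np.full(len(df), np.nan)
    pos = {idx: i for i, idx in enumerate(df.index)}
    for _, g in _iter_trials(df):
        exited: set[int] = set()
        prev_word: Optional[int] = None
        visit_rows: list[int] = []

        def close_visit():
            for k, row in enumerate(visit_rows, start=1):
                fp_ord[row] = k
                fp_count[row] = len(visit_rows)

        for idx, w in zip(g.index, g["word_index"].to_numpy(dtype=int)):
            if prev_word is not None and w != prev_word:
                if prev_word not in exited:
                    exited.add(prev_word)
                    close_visit()
                    visit_rows = []
            if w not in exited:
                first_pass[pos[idx]] = True
                if prev_word != w:
                    visit_rows = []
                visit_rows.append(pos[idx])
            prev_word = w
        if prev_word is not None and prev_word not in exited:
            close_visit()
    df["first_pass"] = first_pass
    df["fp_ord"] = fp_ord
    df["fp_count"] = fp_count
    return df


def classify_saccades(fixations: pd.DataFrame) -> pd.DataFrame:
    """Label the saccade between every pair of consecutive fixations.

    Returns one row per event with the launching and landing fixation
    indices, the signed length in character spaces (positive = rightward),
    the type, and the first-pass status of the launching fixation.
    """
    if fixations["word_index"].isna().any():
        raise ValueError("fixation report contains unassigned word indices")
    rows = []
    for key, g in _iter_trials(fixations):
        words = g["word_index"].to_numpy(dtype=int)
        xs = g["x_col"].to_numpy(dtype=float)
        fixids = g["fix_index"].to_numpy()
        exited: set[int] = set()
        for i in range(len(g) - 1):
            a, b = words[i], words[i + 1]
            from_first_pass = a not in exited
            if b > a + 1:
                typ = "skipping"
            elif b == a + 1:
                typ = "forward"
            elif b < a:
                typ = "regression"
            else:  # same word
                if a in exited and xs[i + 1] < xs[i]:
                    typ = "regression"
                else:
                    typ = "refixation"
            if b != a:
                exited.add(a)
            rows.append(
                {
                    "subject": key[0],
                    "session": key[1],
                    "trial": key[2],
                    "from_fix": fixids[i],
                    "to_fix": fixids[i + 1],
                    "from_word": a,
                    "to_word": b,
                    "length_chars": xs[i + 1] - xs[i],
                    "type": typ,
                    "first_pass": from_first_pass,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "session", "trial", "from_fix", "to_fix",
            "from_word", "to_word", "length_chars", "type", "first_pass",
        ],
    )


@dataclass
class GlobalSummary:
    """Global eye-movement measures of one report."""

    pct_forward: Optional[float]
    pct_skipping: Optional[float]
    pct_refixation: Optional[float]
    pct_regression: Optional[float]
    mean_progressive_length: Optional[float]
    mean_regressive_length: Optional[float]
    mean_fixation_duration_ms: Optional[float]
    n_events: int
    n_fixations: int

    @property
    def empty(self) -> bool:
        return self.n_events == 0


def global_summary(events: pd.DataFrame, fixations: pd.DataFrame) -> GlobalSummary:
    """Saccade-type percentages (over first-pass events), mean progressive
    and regressive saccade lengths, and the mean fixation duration."""
    if len(events) == 0:
        return GlobalSummary(None, None, None, None, None, None, None, 0, len(fixations))
    fp = events[events["first_pass"]]
    pct = {
        t: 100.0 * (fp["type"] == t).sum() / len(fp) if len(fp) else None
        for t in SACCADE_TYPES
    }
    progressive = events.loc[events["type"].isin(["forward", "skipping"]), "length_chars"]
    regressive = events.loc[events["type"] == "regression", "length_chars"]
    return GlobalSummary(
        pct_forward=pct["forward"],
        pct_skipping=pct["skipping"],
        pct_refixation=pct["refixation"],
        pct_regression=pct["regression"],
        mean_progressive_length=float(progressive.abs().mean()) if len(progressive) else None,
        mean_regressive_length=float(regressive.abs().mean()) if len(regressive) else None,
        mean_fixation_duration_ms=float(fixations["duration_ms"].mean())
        if len(fixations)
        else None,
        n_events=len(events),
        n_fixations=len(fixations),
    )


def _word_cases(fixations: pd.DataFrame, first_pass_only: bool = True) -> pd.Series:
    """Fixation count per fixated word (first-pass visit by default)."""
    ann = annotate_first_pass(fixations)
    if first_pass_only:
        fp = ann[ann["first_pass"]]
        return fp.groupby(TRIAL_KEY + ["word_index"])["fp_ord"].size()
    return ann.groupby(TRIAL_KEY + ["word_index"])["fix_index"].size()


def fixation_case_table(
    fixations: pd.DataFrame, *, first_pass_only: bool = True
) -> pd.Series:
    """Percent of fixated words receiving exactly 1, exactly 2, or >= 3
    fixations (first-pass visits by default).  Rows sum to 100."""
    cases = _word_cases(fixations, first_pass_only)
    n = len(cases)
    if n == 0:
        return pd.Series({"single": np.nan, "two": np.nan, "multiple": np.nan})
    return pd.Series(
        {
            "single": 100.0 * (cases == 1).sum() / n,
            "two": 100.0 * (cases == 2).sum() / n,
            "multiple": 100.0 * (cases >= 3).sum() / n,
        }
    )


def event_probabilities(
    fixations: pd.DataFrame, words: pd.DataFrame
) -> pd.DataFrame:
    """First-pass skipping and refixation probability per word-length class.

    Skipping: fraction of passed words that received no first-pass fixation.
    A word counts as passed only when it lies strictly between the trial's
    first word and the furthest first-pass fixated word — the first word is
    always fixated (the scan starts there) and the furthest word is fixated
    by definition, so including either would bias the estimate downward.
    Refixation: fraction of first-pass fixated words with >= 2 first-pass
    fixations.  Classes with no eligible words get NaN.
    """
    ann = annotate_first_pass(fixations)
    fp = ann[ann["first_pass"]]
    cases = fp.groupby(TRIAL_KEY + ["word_index"]).agg(
        n_fix=("fix_index", "size"), word_length=("word_length", "first")
    )

    # skipping opportunities from the word inventory
    reach = fp.groupby(TRIAL_KEY)["word_index"].max().rename("reach")
    w = words.merge(reach, left_on=TRIAL_KEY, right_index=True, how="inner")
    w = w[(w["word_index"] > 1) & (w["word_index"] < w["reach"])]
    fixated_keys = set(cases.index)
    w_keys = list(zip(w["subject"], w["session"], w["trial"], w["word_index"]))
    w = w.assign(fixated=[k in fixated_keys for k in w_keys])

    out = []
    for cls in range(3, 9):
        wc = w[w["word_length"].map(word_length_class) == cls]
        cc = cases[cases["word_length"].map(word_length_class) == cls]
        p_skip = 1.0 - wc["fixated"].mean() if len(wc) else np.nan
        p_refix = float((cc["n_fix"] >= 2).mean()) if len(cc) else np.nan
        out.append(
            {
                "length_class": cls,
                "n_words": len(wc),
                "n_fixated": len(cc),
                "p_skip": p_skip,
                "p_refix": p_refix,
            }
        )
    return pd.DataFrame(out).set_index("length_class")


def duration_measures(fixations: pd.DataFrame) -> pd.DataFrame:
    """Mean single-fixation and first-of-multiple durations per length class.

    Single-fixation durations come from words with exactly one first-pass
    fixation; first-of-multiple from the first fixation of words with two or
    more.  Classes without data get NaN.
    """
    ann = annotate_first_pass(fixations)
    fp = ann[ann["first_pass"]].copy()
    fp["length_class"] = fp["word_length"].map(word_length_class)
    single = fp[fp["fp_count"] == 1]
    first_multi = fp[(fp["fp_count"] >= 2) & (fp["fp_ord"] == 1)]
    out = []
    for cls in range(3, 9):
        s = single.loc[single["length_class"] == cls, "duration_ms"]
        m = first_multi.loc[first_multi["length_class"] == cls, "duration_ms"]
        out.append(
            {
                "length_class": cls,
                "single_fixation_ms": float(s.mean()) if len(s) else np.nan,
                "first_of_multiple_ms": float(m.mean()) if len(m) else np.nan,
                "n_single": len(s),
                "n_multiple": len(m),
            }
        )
    return pd.DataFrame(out).set_index("length_class")
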
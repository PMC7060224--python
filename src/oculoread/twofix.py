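"""Initial landing positions of two-fixation cases and the quadratic fit.

When a word receives exactly two first-pass fixations, the distribution of
the *initial* landing position over letter positions ``x`` is summarised by
the parabola

    y = A + B * L * (x - C)^2

with ``L`` the word length in letters: ``A`` is the baseline relative
frequency, ``B`` the curvature (positive values give the U shape in which
initial fixations concentrate near the word edges) and ``C`` the letter
position of the extremum.  The three parameters are estimated by maximum
likelihood with Gaussian residuals on the relative frequencies (a
multinomial-count likelihood is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

__all__ = [
    "ParabolaFit",
    "TwoFixationParabola",
    "select_two_fixation_cases",
    "fit_parabola",
]


def select_two_fixation_cases(fixations: pd.DataFrame) -> pd.DataFrame:
    """Initial-landing records of words fixated exactly twice first-pass.

    Returns one row per qualifying word visit with the first fixation's
    letter index and the word length.
    """
    from .stats import annotate_first_pass

    ann = annotate_first_pass(fixations)
    sel = ann[(ann["first_pass"]) & (ann["fp_count"] == 2) & (ann["fp_ord"] == 1)]
    return sel[
        ["subject", "session", "trial", "word_index", "word_length", "letter_index", "x_col"]
    ].reset_index(drop=True)


@dataclass
class ParabolaFit:
    """Fitted parameters of y = A + B * L * (x - C)^2."""

    A: float
    B: float
    C: float
    residual_sd: float
    log_likelihood: float
    word_length: int
    converged: bool
    c_identifiable: bool


class TwoFixationParabola(BaseEstimator):
    """Maximum-likelihood fit of the initial-landing frequency parabola.

    Deterministic multi-start: the extremum ``C`` is initialized at every
    letter position 1..L with ``A`` and ``B`` solved by least squares given
    ``C``, each start polished by Nelder-Mead on the residual sum of
    squares; the best likelihood wins, ties to the smallest ``C``.  With
    ``likelihood="multinomial"`` the bin counts are modelled as multinomial
    with probabilities proportional to the (floored) parabola instead.

    Fitted attributes: ``A_``, ``B_``, ``C_``, ``residual_sd_``,
    ``log_likelihood_``, ``converged_``, ``c_identifiable_``.
    """

    def __init__(
        self,
        likelihood: str = "gaussian",
        min_bins: int = 4,
        curvature_floor: float = 1e-6,
    ):
        self.likelihood = likelihood
        self.min_bins = min_bins
        self.curvature_floor = curvature_floor

    @staticmethod
    def _ls_given_c(x, y, L, c):
        z = L * (x - c) ** 2
        X = np.column_stack([np.ones_like(z), z])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef  # A, B

    def fit(self, x, y, word_length: int, counts=None) -> "TwoFixationParabola":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        L = float(word_length)
        occupied = np.isfinite(y)
        if occupied.sum() < self.min_bins:
            raise ValueError(
                f"need at least {self.min_bins} occupied letter bins, "
                f"got {int(occupied.sum())}"
            )
        x, y = x[occupied], y[occupied]
        if self.likelihood == "multinomial":
            if counts is None:
                raise ValueError("multinomial likelihood requires bin counts")
            counts = np.asarray(counts, dtype=float)[occupied]

        def rss(params):
            a, b, c = params
            return float(np.sum((y - (a + b * L * (x - c) ** 2)) ** 2))

        def neg_multinomial(params):
            a, b, c = params
            vals = np.maximum(a + b * L * (x - c) ** 2, 1e-12)
            p = vals / vals.sum()
            return -float(np.sum(counts * np.log(p)))

        objective = rss if self.likelihood == "gaussian" else neg_multinomial
        best = None
        for c0 in range(1, int(word_length) + 1):
            a0, b0 = self._ls_given_c(x, y, L, float(c0))
            res = minimize(
                objective,
                np.array([a0, b0, float(c0)]),
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun - 1e-15 or (
                abs(res.fun - best.fun) <= 1e-15 and res.x[2] < best.x[2]
            ):
                best = res
        assert best is not None
        a, b, c = best.x
        n = len(x)
        if self.likelihood == "gaussian":
            sigma2 = max(best.fun / n, 1e-300)
            loglik = -n / 2 * (np.log(2 * np.pi * sigma2) + 1)
            self.residual_sd_ = float(np.sqrt(sigma2))
        else:
            loglik = -best.fun
            resid = y - (a + b * L * (x - c) ** 2)
            self.residual_sd_ = float(np.sqrt(np.mean(resid**2)))
        self.A_ = float(a)
        self.B_ = float(b)
        self.C_ = float(c)
        self.log_likelihood_ = float(loglik)
        self.converged_ = bool(best.success)
        self.c_identifiable_ = abs(self.B_) >= self.curvature_floor
        self.word_length_ = int(word_length)
        return self

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.A_ + self.B_ * self.word_length_ * (x - self.C_) ** 2


def fit_parabola(
    y,
    word_length: int,
    x=None,
    *,
    likelihood: str = "gaussian",
    counts=None,
) -> ParabolaFit:
    """Fit the two-fixation initial-landing parabola to relative frequencies
    ``y`` over letter positions ``x`` (defaults to 1..word_length)."""
    if x is None:
        x = np.arange(1, word_length + 1, dtype=float)
    est = TwoFixationParabola(likelihood=likelihood).fit(
        x, y, word_length, counts=counts
    )
    return ParabolaFit(
        A=est.A_,
        B=est.B_,
        C=est.C_,
        residual_sd=est.residual_sd_,
        log_likelihood=est.log_likelihood_,
        word_length=word_length,
        converged=est.converged_,
        c_identifiable=est.c_identifiable_,
    )
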
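"""Within-word landing positions and the launch-site effect.

Coordinates are center-based: a word of length ``n`` has its center at
``(n + 1) / 2`` on the 1-based letter scale; the launch distance ``L`` is
the number of character spaces between the launch fixation and the target
word's center, measured leftward (``L >= 0`` for forward saccades), and the
landing position ``delta`` is signed, negative left of the center.  In these
coordinates the mean landing position follows the linear landing-position
function

    delta_mu = lambda * (L0 - L)

whose slope ``lambda`` quantifies the launch-site effect (about half a letter
of leftward shift per letter of extra launch distance in normal reading) and
``L0`` is the launch distance from which saccades land on the center on
average.  Saccades launched closer than ``L0`` overshoot the center, more
distant ones undershoot — with ``lambda, L0 > 0`` on this axis convention.

Landing-position distributions per word length are summarised by a Gaussian
discretized over letter cells, fitted by an exhaustive grid search (steps of
0.01 in both mean and SD) under a minimum Pearson chi-square criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr
from sklearn.base import BaseEstimator, RegressorMixin

from .layout import word_center

__all__ = [
    "LandingPositionFunction",
    "GaussianFitResult",
    "LaunchSiteRegression",
    "GridSearchGaussian",
    "word_centers",
    "center_based_coordinates",
    "forward_saccade_table",
    "landing_cells",
    "landing_histogram",
    "fit_gaussian_gridsearch",
    "fit_landing_function",
    "landing_sd_profile",
]


def word_centers(words: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct column positions of each word on its trial line.

    ``words`` is the inventory (subject, session, trial, word_index,
    word_length) of lines laid out left to right from column 1 with single
    spaces.  Adds ``first_char_col`` and ``center_col``.
    """
    w = words.sort_values(["subject", "session", "trial", "word_index"]).copy()
    offset = (
        w.groupby(["subject", "session", "trial"], sort=False)["word_length"]
        .transform(lambda s: (s + 1).cumsum().shift(fill_value=0))
    )
    w["first_char_col"] = 1 + offset
    w["center_col"] = w["first_char_col"] + (w["word_length"] + 1) / 2 - 1
    return w


def center_based_coordinates(
    launch_col: float, landing_col: float, target_center_col: float
) -> tuple[float, float]:
    """(L, delta) of one forward saccade, in letters.

    ``L`` is the positive leftward launch distance from the target center,
    ``delta`` the signed landing position (negative = left of center).
    Launches at or right of the target center are not forward saccades.
    """
    L = target_center_col - launch_col
    if L <= 0:
        raise ValueError(
            f"launch column {launch_col} is not left of the target center "
            f"{target_center_col}; not a forward saccade"
        )
    return float(L), float(landing_col - target_center_col)


def forward_saccade_table(
    events: pd.DataFrame,
    fixations: pd.DataFrame,
    words: pd.DataFrame,
    *,
    include_skips: bool = False,
) -> pd.DataFrame:
    """Per-saccade (word_length, launch_dist, landing) for word-to-word
    forward movements, from classified events and the word inventory."""
    key = ["subject", "session", "trial"]
    types = ["forward", "skipping"] if include_skips else ["forward"]
    ev = events[events["type"].isin(types)].copy()
    fx = fixations.set_index(key + ["fix_index"])["x_col"]
    centers = word_centers(words).set_index(key + ["word_index"])[
        ["word_length", "first_char_col", "center_col"]
    ]
    launch_idx = pd.MultiIndex.from_frame(ev[key + ["from_fix"]])
    land_idx = pd.MultiIndex.from_frame(ev[key + ["to_fix"]])
    word_idx = pd.MultiIndex.from_frame(ev[key + ["to_word"]])
    ev["launch_col"] = fx.reindex(launch_idx).to_numpy()
    ev["landing_col"] = fx.reindex(land_idx).to_numpy()
    target = centers.reindex(word_idx)
    ev["word_length"] = target["word_length"].to_numpy()
    ev["center_col"] = target["center_col"].to_numpy()
    ev["first_char_col"] = target["first_char_col"].to_numpy()
    ev = ev.dropna(subset=["launch_col", "landing_col", "center_col"])
    ev = ev[ev["center_col"] - ev["launch_col"] > 0]  # launch left of target center
    return pd.DataFrame(
        {
            "word_length": ev["word_length"].astype(int).to_numpy(),
            "launch_dist": (ev["center_col"] - ev["launch_col"]).to_numpy(),
            "landing": (ev["landing_col"] - ev["center_col"]).to_numpy(),
            "launch_from_beginning": (
                ev["first_char_col"] - ev["launch_col"]
            ).to_numpy(),
        }
    )


def landing_cells(
    saccades: pd.DataFrame,
    *,
    min_cell_n: int = 20,
    restrict_launch: Optional[float] = None,
) -> pd.DataFrame:
    """Bin saccades into (word_length, integer launch distance) cells.

    Launch distances are rounded to the nearest integer letter; cells with
    fewer than ``min_cell_n`` saccades are dropped (stability floor).
    ``restrict_launch`` keeps only saccades launched up to that many
    characters from the word beginning (requires the
    ``launch_from_beginning`` column).
    """
    df = saccades.copy()
    if restrict_launch is not None:
        df = df[df["launch_from_beginning"] <= restrict_launch]
    df["launch_bin"] = df["launch_dist"].round().astype(int)
    cells = (
        df.groupby(["word_length", "launch_bin"])
        .agg(n=("landing", "size"), mean=("landing", "mean"), sd=("landing", "std"))
        .reset_index()
    )
    return cells[cells["n"] >= min_cell_n].reset_index(drop=True)


@dataclass
class LandingPositionFunction:
    """Fitted landing-position function delta_mu = lambda * (L0 - L)."""

    lam: float
    L0: Optional[float]
    lam_se: float
    L0_se: Optional[float]
    lam_ci: tuple[float, float]
    n_cells: int
    n_saccades: int

    @property
    def L0_defined(self) -> bool:
        return self.L0 is not None


class LaunchSiteRegression(BaseEstimator, RegressorMixin):
    """Weighted least-squares fit of the landing-position function.

    Fits cell-mean landings ``delta`` on launch distances ``L`` (weights =
    cell counts); the slope of the line is ``-lambda`` and its intercept
    ``lambda * L0``.  Fitted attributes: ``lambda_``, ``L0_``,
    ``lambda_se_``, ``L0_se_``, ``lambda_ci_`` (95%), ``results_`` (the
    underlying statsmodels fit).
    """

    def __init__(self, min_launch_bins: int = 3):
        self.min_launch_bins = min_launch_bins

    def fit(self, L, delta, sample_weight=None) -> "LaunchSiteRegression":
        L = np.asarray(L, dtype=float)
        delta = np.asarray(delta, dtype=float)
        if not (np.isfinite(L).all() and np.isfinite(delta).all()):
            raise ValueError("launch distances and landings must be finite")
        if len(np.unique(L)) < self.min_launch_bins:
            raise ValueError(
                f"need at least {self.min_launch_bins} distinct launch distances, "
                f"got {len(np.unique(L))}"
            )
        if np.ptp(L) == 0:
            raise ValueError("launch distances have zero variance")
        w = np.ones_like(L) if sample_weight is None else np.asarray(sample_weight, float)
        X = sm.add_constant(L)
        res = sm.WLS(delta, X, weights=w).fit()
        a, b = res.params  # delta = a + b * L, b = -lambda, a = lambda * L0
        self.results_ = res
        self.lambda_ = -float(b)
        self.lambda_se_ = float(res.bse[1])
        lo, hi = res.conf_int()[1]
        self.lambda_ci_ = (-float(hi), -float(lo))
        if abs(self.lambda_) > 1e-9:
            self.L0_ = float(a) / self.lambda_
            # delta method for L0 = -a/b
            va, vb = res.cov_params()[0, 0], res.cov_params()[1, 1]
            cab = res.cov_params()[0, 1]
            self.L0_se_ = float(
                np.sqrt(
                    va / b**2 + a**2 * vb / b**4 - 2 * a * cab / b**3
                )
            )
        else:
            self.L0_ = None
            self.L0_se_ = None
        return self

    def predict(self, L) -> np.ndarray:
        L = np.asarray(L, dtype=float)
        a, b = self.results_.params
        return a + b * L


def fit_landing_function(cells: pd.DataFrame) -> LandingPositionFunction:
    """Fit the landing-position function to a cell table from
    :func:`landing_cells` (weighted by cell counts)."""
    reg = LaunchSiteRegression().fit(
        cells["launch_bin"], cells["mean"], sample_weight=cells["n"]
    )
    return LandingPositionFunction(
        lam=reg.lambda_,
        L0=reg.L0_,
        lam_se=reg.lambda_se_,
        L0_se=reg.L0_se_,
        lam_ci=reg.lambda_ci_,
        n_cells=len(cells),
        n_saccades=int(cells["n"].sum()),
    )


@dataclass
class GaussianFitResult:
    """Minimum chi-square Gaussian fit of a landing distribution."""

    mu: float
    sigma: float
    chi2: float
    grid_step: float
    word_length: int
    n: int


def _discretized_gaussian_probs(
    mu: np.ndarray, sigma: np.ndarray, length: int
) -> np.ndarray:
    """P(letter cell i) for a Gaussian truncated/renormalized over the word.

    ``mu`` (M,) and ``sigma`` (S,) broadcast to an (S, M, length) array.
    Letter cell i covers (i - 0.5, i + 0.5].
    """
    edges = np.arange(0.5, length + 1.5)  # length + 1 edges
    z = (edges[None, None, :] - mu[None, :, None]) / sigma[:, None, None]
    cdf = ndtr(z)
    p = np.diff(cdf, axis=2)
    total = p.sum(axis=2, keepdims=True)
    return p / np.maximum(total, 1e-300)


class GridSearchGaussian(BaseEstimator):
    """Exhaustive grid-search Gaussian fit of a within-word landing histogram.

    Minimizes the Pearson chi-square between observed letter-cell counts and
    the counts expected from a Gaussian discretized over the word's letter
    cells and renormalized over the word, over a (mu, sigma) grid with step
    0.01; mu ranges over [0.5, length + 0.5], sigma over ``sigma_range``.
    Ties are broken deterministically toward the smallest sigma, then the
    smallest mu.  Fitted attributes: ``mu_``, ``sigma_``, ``chi2_``, ``n_``.
    """

    def __init__(
        self,
        grid_step: float = 0.01,
        sigma_range: tuple[float, float] = (0.3, 5.0),
        expected_floor: float = 1e-9,
    ):
        self.grid_step = grid_step
        self.sigma_range = sigma_range
        self.expected_floor = expected_floor

    def fit(self, counts, word_length: Optional[int] = None) -> "GridSearchGaussian":
        counts = np.asarray(counts, dtype=float)
        if word_length is None:
            word_length = len(counts)
        if len(counts) != word_length:
            raise ValueError("counts must have one bin per letter")
        n = counts.sum()
        if n <= 0:
            raise ValueError("all-zero histogram")
        if (counts > 0).sum() < 2:
            raise ValueError("degenerate fit: only one occupied letter cell")
        step = self.grid_step
        mus = np.arange(0.5, word_length + 0.5 + step / 2, step)
        sigmas = np.arange(
            self.sigma_range[0], self.sigma_range[1] + step / 2, step
        )
        chi2 = np.empty((len(sigmas), len(mus)))
        # chunk over sigma to bound the (S, M, length) intermediate
        chunk = max(1, int(2e7 // (len(mus) * (word_length + 1))))
        for s0 in range(0, len(sigmas), chunk):
            sl = slice(s0, s0 + chunk)
            p = _discretized_gaussian_probs(mus, sigmas[sl], word_length)
            expected = np.maximum(n * p, self.expected_floor)
            chi2[sl] = ((counts[None, None, :] - expected) ** 2 / expected).sum(axis=2)
        flat = int(np.argmin(chi2))  # first occurrence: smallest sigma, then mu
        i, j = divmod(flat, len(mus))
        self.mu_ = float(mus[j])
        self.sigma_ = float(sigmas[i])
        self.chi2_ = float(chi2[i, j])
        self.n_ = int(n)
        self.word_length_ = int(word_length)
        return self

    def chi2_surface(self, mu: float, sigma: float, counts) -> float:
        """Evaluate the same chi-square objective at arbitrary (mu, sigma)."""
        counts = np.asarray(counts, dtype=float)
        p = _discretized_gaussian_probs(
            np.array([mu]), np.array([sigma]), len(counts)
        )[0, 0]
        expected = np.maximum(counts.sum() * p, self.expected_floor)
        return float(((counts - expected) ** 2 / expected).sum())


def fit_gaussian_gridsearch(
    counts, word_length: int, grid_step: float = 0.01
) -> GaussianFitResult:
    """Grid-search minimum chi-square Gaussian fit (see
    :class:`GridSearchGaussian`)."""
    est = GridSearchGaussian(grid_step=grid_step).fit(counts, word_length)
    return GaussianFitResult(
        mu=est.mu_,
        sigma=est.sigma_,
        chi2=est.chi2_,
        grid_step=grid_step,
        word_length=word_length,
        n=est.n_,
    )


def landing_histogram(
    letter_positions: Sequence[int], word_length: int
) -> np.ndarray:
    """Relative frequencies of landings over letter cells 1..word_length."""
    pos = np.asarray(letter_positions, dtype=int)
    if len(pos) == 0:
        return np.full(word_length, np.nan)
    if (pos < 1).any() or (pos > word_length).any():
        raise ValueError("letter positions outside 1..word_length")
    counts = np.bincount(pos, minlength=word_length + 1)[1:]
    return counts / counts.sum()


def select_landing_letters(
    fixations: pd.DataFrame,
    words: pd.DataFrame,
    word_length: int,
    selection: str = "single",
    *,
    launch_limit: Optional[float] = 5.0,
) -> np.ndarray:
    """Letter indices of landings entering the per-length histograms.

    ``selection`` is ``"single"`` (words with exactly one first-pass
    fixation), ``"first_of_two"`` (initial landing of two-fixation cases) or
    ``"forward"`` (arrival fixations of word-to-word forward saccades).  By
    default only saccades launched up to ``launch_limit`` characters from
    the word beginning are kept (the restriction used for distribution
    analyses; pass None to disable).
    """
    from .stats import annotate_first_pass

    if selection not in ("single", "first_of_two", "forward"):
        raise ValueError(f"unknown selection {selection!r}")
    key = ["subject", "session", "trial"]
    ann = annotate_first_pass(fixations).sort_values(key + ["fix_index"])
    ann["prev_x"] = ann.groupby(key, sort=False)["x_col"].shift()
    ann["prev_word"] = ann.groupby(key, sort=False)["word_index"].shift()
    centers = word_centers(words).set_index(key + ["word_index"])["first_char_col"]
    idx = pd.MultiIndex.from_frame(ann[key + ["word_index"]])
    ann["first_char_col"] = centers.reindex(idx).to_numpy()

    if selection == "single":
        sel = ann["first_pass"] & (ann["fp_count"] == 1)
    elif selection == "first_of_two":
        sel = ann["first_pass"] & (ann["fp_count"] == 2) & (ann["fp_ord"] == 1)
    else:
        sel = (
            ann["first_pass"]
            & (ann["fp_ord"] == 1)
            & (ann["prev_word"] == ann["word_index"] - 1)
        )
    sel &= ann["word_length"] == word_length
    if launch_limit is not None:
        launch_from_beginning = ann["first_char_col"] - ann["prev_x"]
        sel &= launch_from_beginning.notna() & (launch_from_beginning <= launch_limit)
        sel &= launch_from_beginning > 0
    return ann.loc[sel, "letter_index"].to_numpy(dtype=int)


def landing_sd_profile(saccades: pd.DataFrame, *, min_cell_n: int = 2) -> tuple[pd.DataFrame, float]:
    """Per-(word length, launch distance) SD of landing positions for
    word-to-word forward saccades, plus the grand mean across cells."""
    cells = landing_cells(saccades, min_cell_n=min_cell_n)
    cells = cells.dropna(subset=["sd"])
    if len(cells) == 0:
        raise ValueError("no cell has at least two saccades")
    return cells[["word_length", "launch_bin", "n", "sd"]], float(cells["sd"].mean())
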
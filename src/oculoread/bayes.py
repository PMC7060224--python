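"""Gaussian Bayesian model of saccade planning.

Saccade targeting is modelled as Bayesian integration of a noisy sensory
estimate of the target position with a learned prior over center-based
launch-site distances.  With a Gaussian likelihood (variance ``sigma0_sq``,
the sensory uncertainty) and a Gaussian prior (mean ``muT``, variance
``sigmaT_sq``), the posterior is Gaussian and its mean is pulled from the
observation ``x0`` toward the prior mean:

    delta_bayes = muP - x0 = sigma0^2 / (sigma0^2 + sigmaT^2) * (muT - x0)

Identifying the weighting factor with the launch-site-effect slope gives

    lambda = sigma0^2 / (sigma0^2 + sigmaT^2)

so the empirical landing-position slope measures the balance of sensory
versus prior precision: lambda -> 0 means saccades land on the target
regardless of launch site (precise sensing), lambda -> 1 means constant
saccade lengths (prior dominates).  Coordinates throughout are center-based
launch distances in letters, matching the landing-analysis sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GaussianBelief",
    "gaussian_posterior",
    "delta_bayes",
    "lambda_from_variances",
    "variance_ratio_from_lambda",
]


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian mean/variance pair acting as prior, likelihood or posterior."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")


def gaussian_posterior(
    prior: GaussianBelief, x0: float, sigma0_sq: float
) -> GaussianBelief:
    """Posterior belief over the target position given an observation at ``x0``.

    The product of the Gaussian prior and the Gaussian likelihood centered at
    ``x0`` (variance ``sigma0_sq``) is itself Gaussian with

        muP     = (sigmaT^2 * x0 + sigma0^2 * muT) / (sigma0^2 + sigmaT^2)
        sigmaP^2 = sigma0^2 * sigmaT^2 / (sigma0^2 + sigmaT^2)
    """
    if not sigma0_sq > 0:
        raise ValueError(f"sensory variance must be positive, got {sigma0_sq}")
    st2 = prior.variance
    total = sigma0_sq + st2
    return GaussianBelief(
        mean=(st2 * x0 + sigma0_sq * prior.mean) / total,
        variance=sigma0_sq * st2 / total,
    )


def delta_bayes(muT: float, x0: float, sigma0_sq: float, sigmaT_sq: float) -> float:
    """Predicted shift of the posterior mean away from the observation ``x0``."""
    if not (sigma0_sq > 0 and sigmaT_sq > 0):
        raise ValueError("variances must be positive")
    return sigma0_sq / (sigma0_sq + sigmaT_sq) * (muT - x0)


def lambda_from_variances(sigma0_sq: float, sigmaT_sq: float) -> float:
    """Launch-site-effect slope implied by sensory and prior variances.

    Returns ``sigma0^2 / (sigma0^2 + sigmaT^2)``, in [0, 1).  Equal variances
    give 0.5, the slope typical of normal reading; perfect sensing
    (``sigma0^2 = 0``) gives 0.
    """
    if sigma0_sq < 0 or sigmaT_sq < 0:
        raise ValueError("variances must be non-negative")
    total = sigma0_sq + sigmaT_sq
    if total == 0:
        raise ValueError("lambda undefined when both variances are zero")
    return sigma0_sq / total


def variance_ratio_from_lambda(lam: float) -> float:
    """Invert the slope-variance relation: ``sigma0^2 / sigmaT^2 = lam / (1 - lam)``."""
    if not 0 <= lam < 1:
        raise ValueError(f"lambda must be in [0, 1), got {lam}")
    return lam / (1.0 - lam)
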
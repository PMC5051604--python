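"""Synthetic data-generating processes for the estimator benchmark.

Five DGPs share one covariate generator and one treatment-assignment model;
they differ in the endpoint family and in two scalar knobs:

* ``k1`` scales the propensity-score linear predictor and controls overlap
  (0.3 gives good overlap of the treated/control PS densities, 1 gives poor
  overlap with mass near 0 and 1);
* ``k2`` scales the confounder part of the normal-endpoint mean and controls
  confounding strength (1 moderate, 4 strong).

DGP 1: normal endpoint, k1=0.3, k2=1.   DGP 2: normal, k1=0.3, k2=4.
DGP 3: normal, k1=1, k2=4.              DGP 4: gamma endpoint (log link,
shape 100), k1=1.                        DGP 5: semi-continuous endpoint on
(0, 1] with a point mass at 1 (beta mixture), k1=1.

Covariates: an 8-dimensional latent Gaussian with unit variances and a fixed
correlation matrix; coordinates 6-8 are kept as-is (standard normal W6-W8),
coordinates 1-5 are dichotomised by sign into symmetric binaries W1-W5 in
{-1, +1}.  The sign coding (rather than {0, 1}) is what reproduces the
printed true effect of the gamma DGP; see docs/methods.md for the
calibration evidence.  The latent correlation is flat at 0.075, the low end
of the range the design targets.

In DGPs 1-3 the treatment effect is additive and constant (0.4 for every
unit); in DGPs 4-5 it is heterogeneous, and the true ATE is defined as the
population mean of the individual-level effects, computed by Monte Carlo
over fresh covariate draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .data import SimulatedDataset
from .errors import ConfigurationError

__all__ = [
    "DGPConfig",
    "TrueATE",
    "default_latent_corr",
    "draw_covariates",
    "true_propensity",
    "outcome_mean",
    "conditional_means",
    "simulate_dataset",
    "true_ate",
]

#: Constant additive effect of DGPs 1-3 (the treatment coefficient).
CONSTANT_EFFECT = 0.4

# (k1, k2) for the five canonical configurations.
_CANONICAL_KNOBS = {1: (0.3, 1.0), 2: (0.3, 4.0), 3: (1.0, 4.0), 4: (1.0, 4.0), 5: (1.0, 4.0)}


def default_latent_corr() -> np.ndarray:
    """The repository's fixed latent correlation matrix (flat 0.075)."""
    R = np.full((8, 8), 0.075)
    np.fill_diagonal(R, 1.0)
    return R


def _validate_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (8, 8):
        raise ConfigurationError("latent_corr must be 8x8")
    if not np.allclose(R, R.T):
        raise ConfigurationError("latent_corr must be symmetric")
    if not np.allclose(np.diag(R), 1.0):
        raise ConfigurationError("latent_corr must have unit diagonal")
    off = R[~np.eye(8, dtype=bool)]
    if off.min() < 0.0 or off.max() > 0.95:
        raise ConfigurationError("off-diagonal latent correlations out of range")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("latent_corr must be positive definite") from exc
    return R


@dataclass
class DGPConfig:
    """Configuration of one data-generating process.

    Parameters
    ----------
    dgp_id : int in {1..5}
    n : sample size of one simulated dataset
    seed : root seed; one config draws one reproducible dataset
    k1 : PS scale (overlap knob)
    k2 : confounder-endpoint scale of the normal mean (confounding knob)
    phi : beta precision of the DGP 5 continuous part.  The mean of the
        endpoint does not depend on ``phi``, only its spread does.
    latent_corr : 8x8 latent Gaussian correlation matrix.
    """

    dgp_id: int
    n: int = 1000
    seed: int = 0
    k1: float | None = None
    k2: float | None = None
    phi: float = 5.0
    latent_corr: np.ndarray = field(default_factory=default_latent_corr)

    def __post_init__(self) -> None:
        if self.dgp_id not in (1, 2, 3, 4, 5):
            raise ConfigurationError(f"unknown dgp_id {self.dgp_id!r}")
        if int(self.n) < 1:
            raise ConfigurationError("n must be a positive integer")
        self.n = int(self.n)
        if self.phi <= 0:
            raise ConfigurationError("phi must be positive")
        k1_def, k2_def = _CANONICAL_KNOBS[self.dgp_id]
        if self.k1 is None:
            self.k1 = k1_def
        if self.k2 is None:
            self.k2 = k2_def
        self.latent_corr = _validate_corr(self.latent_corr)

    def with_seed(self, seed: int) -> "DGPConfig":
        return replace(self, seed=int(seed))


def draw_covariates(n: int, latent_corr: np.ndarray | None = None, seed=0) -> np.ndarray:
    """Draw the n x 8 covariate matrix.

    ``seed`` may be an integer, a ``SeedSequence`` or a ``Generator``.
    """
    if int(n) < 1:
        raise ValueError("n must be at least 1")
    R = _validate_corr(default_latent_corr() if latent_corr is None else latent_corr)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = rng.standard_normal((int(n), 8)) @ np.linalg.cholesky(R).T
    W = np.empty_like(Z)
    W[:, :5] = np.where(Z[:, :5] > 0, 1.0, -1.0)
    W[:, 5:] = Z[:, 5:]
    return W


def _cols(W: np.ndarray):
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != 8:
        raise ValueError("W must have 8 columns")
    return W.T


def true_propensity(W: np.ndarray, k1: float) -> np.ndarray:
    """P(A=1 | W): expit of the shared nonlinear linear predictor, scaled by k1."""
    W1, W2, W3, W4, W5, W6, W7, W8 = _cols(W)
    lp = -1.0 + k1 * (
        0.3 * W1 - 0.1 * W2 - 0.2 * W3 + 0.4 * W4 + 0.7 * W5
        + 0.2 * W6 + 0.2 * W7 - 0.25 * W8
        + 0.8 * W6**2 - 0.3 * W7**2 - 0.3 * W8**2
        - 0.05 * W1 * W2 - 0.05 * W1 * W3
    )
    return expit(lp)


def _mu_normal(W: np.ndarray, A, k2: float) -> np.ndarray:
    W1, W2, W3, W4, W5, W6, W7, W8 = _cols(W)
    return 15.0 + CONSTANT_EFFECT * np.asarray(A, float) + k2 * (
        1.0 * W1 - 0.1 * W2 + 0.1 * W3 - 0.1 * W4 + 0.1 * W5
        - 0.1 * W6 + 0.1 * W7 + 0.1 * W8
        - 0.2 * W6**2 - 0.1 * W7**2 - 0.1 * W8**2
        + 0.2 * W6**3 + 0.1 * W7**3 + 0.1 * W8**3
        - 0.1 * W1 * W2 + 0.5 * W1 * W7
    )


def _mu_gamma(W: np.ndarray, A) -> np.ndarray:
    W1, W2, W3, W4, W5, W6, W7, W8 = _cols(W)
    return np.exp(
        3.0 + 0.2 * np.asarray(A, float)
        - 0.2 * W1 + 0.2 * W2 - 0.2 * W3 + 0.5 * W4 - 1.0 * W5
        + 0.5 * W6 - 0.5 * W7 + 0.2 * W8
        - 0.2 * W6**2 - 0.01 * W7**2 - 0.01 * W8**2
        - 0.01 * W6**3 - 0.01 * W7**3 - 0.01 * W8**3
        - 0.01 * W1 * W2 - 0.4 * W6 * W7
    )


def mixture_params(W: np.ndarray, A) -> tuple[np.ndarray, np.ndarray]:
    """DGP 5 mixture parameters (p, mu_beta).

    With probability 1-p the endpoint equals 1 exactly; with probability p it
    is 1-Y' where Y' is beta-distributed with mean mu_beta and precision phi
    (shape1 = mu*phi, shape2 = (1-mu)*phi).
    """
    A = np.asarray(A, float)
    W1, W2, W3, W4, W5, W6, W7, W8 = _cols(W)
    p = expit(
        4.0 - 1.0 * A - 0.2 * W1 + 0.5 * W2 - 0.5 * W3 - 1.0 * W4 - 0.3 * W5
        + 0.2 * W6 + 0.5 * W7 - 0.5 * W8
    )
    mu_beta = expit(
        -1.0 - 0.2 * A - 0.5 * W1 - 0.5 * W2 - 0.5 * W3 + 0.5 * W4 - 0.5 * W5
        - 0.5 * W6 - 0.5 * W7 - 0.5 * W8
        - 0.2 * W6**2 - 0.2 * W7**2 - 0.2 * W8**2
        - 0.2 * W6**3 - 0.2 * W7**3 - 0.2 * W8**3
        - 0.2 * W1 * W2 - 0.2 * W6 * W7
    )
    return p, mu_beta


def outcome_mean(W: np.ndarray, A, config: DGPConfig) -> np.ndarray:
    """E[Y | A, W] for the configured DGP.

    For DGP 5 the mixture mean is 1 - p * mu_beta, independent of phi.
    """
    if config.dgp_id in (1, 2, 3):
        return _mu_normal(W, A, config.k2)
    if config.dgp_id == 4:
        return _mu_gamma(W, A)
    p, mu_beta = mixture_params(W, A)
    return 1.0 - p * mu_beta


def conditional_means(W: np.ndarray, config: DGPConfig) -> tuple[np.ndarray, np.ndarray]:
    """(mu0, mu1): conditional endpoint means under A=0 and A=1 per row."""
    n = np.asarray(W).shape[0]
    zeros, ones = np.zeros(n), np.ones(n)
    return outcome_mean(W, zeros, config), outcome_mean(W, ones, config)


def _draw_endpoint(W, A, config: DGPConfig, rng: np.random.Generator) -> np.ndarray:
    if config.dgp_id in (1, 2, 3):
        return rng.normal(_mu_normal(W, A, config.k2), 1.0)
    if config.dgp_id == 4:
        mu = _mu_gamma(W, A)
        return rng.gamma(shape=100.0, scale=mu / 100.0)
    p, mu_beta = mixture_params(W, A)
    continuous = rng.random(p.shape) < p
    y_prime = rng.beta(mu_beta * config.phi, (1.0 - mu_beta) * config.phi)
    # keep the continuous part strictly inside (0, 1): float rounding of the
    # beta sampler can otherwise return the boundary exactly
    y_prime = np.clip(y_prime, 1e-12, 1.0 - 1e-12)
    return np.where(continuous, 1.0 - y_prime, 1.0)


def simulate_dataset(config: DGPConfig) -> SimulatedDataset:
    """Draw one dataset: W, then A ~ Bernoulli(PS), then Y from the endpoint family.

    The root seed is split into independent sub-streams for covariates,
    treatment and endpoint, so the covariate draw is unchanged if only the
    endpoint family of a config is altered.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=(config.dgp_id,))
    rng_w, rng_a, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))
    W = draw_covariates(config.n, config.latent_corr, rng_w)
    ps = true_propensity(W, config.k1)
    A = (rng_a.random(config.n) < ps).astype(float)
    Y = _draw_endpoint(W, A, config, rng_y)
    mu0, mu1 = conditional_means(W, config)
    return SimulatedDataset(W=W, A=A, Y=Y, true_ps=ps, mu0=mu0, mu1=mu1)


@dataclass(frozen=True)
class TrueATE:
    value: float
    mc_se: float

    def __float__(self) -> float:  # allows float(true_ate(...))
        return self.value


def true_ate(config: DGPConfig, n_mc: int = 1_000_000, seed: int = 0) -> TrueATE:
    """The true ATE of a DGP.

    DGPs 1-3 have a constant additive effect, returned exactly with zero
    Monte-Carlo error.  DGPs 4-5 average the individual-level effect
    mu1 - mu0 over ``n_mc`` fresh covariate draws.
    """
    if config.dgp_id in (1, 2, 3):
        return TrueATE(CONSTANT_EFFECT, 0.0)
    if int(n_mc) < 1:
        raise ValueError("n_mc must be at least 1")
    W = draw_covariates(int(n_mc), config.latent_corr, np.random.default_rng(seed))
    mu0, mu1 = conditional_means(W, config)
    diff = mu1 - mu0
    return TrueATE(float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(len(diff))))
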
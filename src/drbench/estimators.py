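"""Average-treatment-effect estimators and their variance estimators.

Six estimators of the ATE psi = E[Y(1) - Y(0)] of a binary treatment, all
consuming fitted nuisances (a propensity score g(W) and/or an outcome
regression Q(a, W)):

* :func:`gcomp` -- G-computation / regression plug-in;
* :func:`iptw` -- normalised (Hajek) inverse-probability weighting;
* :func:`wls` -- weighted least squares (main-terms regression with
  inverse-probability weights), a classical doubly robust estimator;
* :func:`ps_match` -- 1-to-M nearest-neighbour matching with replacement on
  the linear predictor (logit) of the PS, ties retained and averaged;
* :func:`bcm` -- bias-corrected matching: the borrowed outcome of each
  match is adjusted by the difference in regression predictions between the
  unit and its match;
* :func:`tmle` -- targeted maximum likelihood: a one-parameter logistic
  fluctuation of the rescaled outcome regression along the "clever
  covariate" h(A, W) = A/g - (1-A)/(1-g), which solves the efficient
  influence-curve estimating equation and keeps the targeted predictions
  inside the endpoint's known bounds.

Standard errors follow the conventions of the comparison the suite
implements: sandwich (weights treated as fixed) for IPTW and WLS, the
influence curve for TMLE, a matched-sample variance conditional on the
estimated PS for the matching estimators, model-based or bootstrap for
G-computation.  Confidence intervals are Wald with z = 1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit

from .data import ObservedData
from .errors import EstimationError
from .learners import FittedNuisance, PS_BOUND, design_matrix

__all__ = [
    "ATEEstimate",
    "MatchResult",
    "FluctuationResult",
    "gcomp",
    "iptw",
    "wls",
    "ps_match",
    "bcm",
    "clever_covariate",
    "tmle",
    "matched_variance",
    "bootstrap_se",
]

Z_95 = 1.959963984540054


@dataclass
class ATEEstimate:
    """A point estimate of the ATE with Wald inference and diagnostics."""

    psi_hat: float
    se: float
    ci_lo: float
    ci_hi: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def from_se(cls, psi: float, se: float, method: str, diagnostics: dict | None = None):
        psi, se = float(psi), float(se)
        if np.isfinite(se):
            lo, hi = psi - Z_95 * se, psi + Z_95 * se
        else:
            lo = hi = np.nan
        return cls(psi, se, lo, hi, method, diagnostics or {})

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "psi_hat": self.psi_hat,
            "se": self.se,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
        }


# ---------------------------------------------------------------------------
# nuisance plumbing
# ---------------------------------------------------------------------------

def _g_values(g, data: ObservedData) -> np.ndarray:
    if isinstance(g, FittedNuisance):
        vals = g.propensity(data.W)
    elif callable(g):
        vals = np.asarray(g(data.W), float)
    else:
        vals = np.asarray(g, float)
    if vals.shape != (data.n,):
        raise ValueError("propensity values do not match the data")
    if (vals <= 0).any() or (vals >= 1).any():
        raise EstimationError("propensity values must lie strictly inside (0, 1)")
    return vals


def _q_fn(q) -> Callable:
    if isinstance(q, FittedNuisance):
        return q.outcome
    if callable(q):
        return lambda a, W: np.asarray(q(a, W), float)
    raise TypeError("q must be a FittedNuisance or a callable (a, W) -> predictions")


# ---------------------------------------------------------------------------
# G-computation
# ---------------------------------------------------------------------------

def gcomp(
    q,
    data: ObservedData,
    se_method: str = "auto",
    refit: Callable[[ObservedData], object] | None = None,
    B: int = 200,
    seed: int = 0,
) -> ATEEstimate:
    """Regression plug-in: psi = mean of Q(1, W) - Q(0, W) over the sample.

    Inference: a model-based standard error when the nuisance provides one
    (pooled or stratified parametric fits), otherwise the nonparametric
    bootstrap when a ``refit`` procedure is supplied (required for two-part
    and super-learner nuisances), otherwise no interval is reported.
    """
    if data.n == 0:
        raise ValueError("empty data")
    qf = _q_fn(q)
    psi = float(np.mean(qf(1, data.W) - qf(0, data.W)))

    se = np.nan
    se_source = "none"
    meta = q.fit_meta if isinstance(q, FittedNuisance) else {}
    if se_method in ("auto", "model") and "ate_se_model" in meta:
        se, se_source = float(meta["ate_se_model"]), "model"
    elif se_method in ("auto", "model") and "ate_se_fn" in meta:
        se, se_source = float(meta["ate_se_fn"](data.W)), "delta"
    elif se_method in ("auto", "bootstrap") and refit is not None:
        def replicate(d: ObservedData) -> float:
            qb = refit(d)
            qbf = _q_fn(qb)
            return float(np.mean(qbf(1, d.W) - qbf(0, d.W)))
        se, se_source = bootstrap_se(replicate, data, B=B, seed=seed), "bootstrap"
    elif se_method == "bootstrap":
        raise ValueError("bootstrap SE requires a refit procedure")

    return ATEEstimate.from_se(psi, se, "gcomp", {"se_source": se_source})


# ---------------------------------------------------------------------------
# normalised IPTW
# ---------------------------------------------------------------------------

def iptw(g, data: ObservedData) -> ATEEstimate:
    """Hajek estimator: difference of arm-wise weight-normalised outcome means.

    The sandwich standard error treats the weights as fixed: for each arm,
    Var(mu_arm) = sum w_i^2 (Y_i - mu_arm)^2 / (sum w_i)^2.
    """
    gv = _g_values(g, data)
    A, Y = data.A, data.Y
    t, c = A == 1, A == 0
    if not t.any() or not c.any():
        raise EstimationError("both treatment arms must be non-empty")
    wt, wc = 1.0 / gv[t], 1.0 / (1.0 - gv[c])
    mu1 = float(wt @ Y[t] / wt.sum())
    mu0 = float(wc @ Y[c] / wc.sum())
    var = float((wt**2 @ (Y[t] - mu1) ** 2) / wt.sum() ** 2
                + (wc**2 @ (Y[c] - mu0) ** 2) / wc.sum() ** 2)
    w_all = A / gv + (1 - A) / (1 - gv)
    diag = {"weight_min": float(w_all.min()), "weight_max": float(w_all.max())}
    return ATEEstimate.from_se(mu1 - mu0, np.sqrt(var), "iptw", diag)


# ---------------------------------------------------------------------------
# weighted least squares (doubly robust weighted regression)
# ---------------------------------------------------------------------------

def wls(g, data: ObservedData, terms: str = "main_terms") -> ATEEstimate:
    """IPT-weighted least squares of Y on (1, A, covariate main terms).

    The ATE estimate is the coefficient of A; the standard error is the
    HC0 sandwich with the weights treated as fixed.
    """
    gv = _g_values(g, data)
    w = data.A / gv + (1.0 - data.A) / (1.0 - gv)
    X, _ = design_matrix(data.W, terms, data.covariate_names)
    Xd = np.column_stack([np.ones(data.n), data.A, X])
    res = sm.WLS(data.Y, Xd, weights=w).fit(cov_type="HC0")
    if res.model.rank < Xd.shape[1]:
        raise EstimationError("singular weighted design in WLS")
    diag = {"weight_min": float(w.min()), "weight_max": float(w.max())}
    return ATEEstimate.from_se(float(res.params[1]), float(res.bse[1]), "wls", diag)


# ---------------------------------------------------------------------------
# PS matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Matched sets on the logit PS, with reuse counts and imputed effects.

    ``neighbors[i]``/``weights[i]`` give the opposite-arm matched set of
    unit i and its averaging weights (summing to one; exact-distance ties
    share weight equally).  ``K[i]`` is the number of times unit i is used
    as a match, fractional under ties; sum(K) = N * M.  ``deltas[i]`` is the
    imputed individual effect Yhat(1, W_i) - Yhat(0, W_i).
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    K: np.ndarray
    deltas: np.ndarray
    lp: np.ndarray
    M: int


def _match_rows(lp_src: np.ndarray, lp_tgt: np.ndarray, M: int):
    """Nearest-M with replacement on |logit PS| distance; exact ties kept."""
    out = []
    # chunked to keep the pairwise-distance block memory bounded
    for start in range(0, len(lp_src), 512):
        block = np.abs(lp_src[start:start + 512, None] - lp_tgt[None, :])
        for row in block:
            thr = np.partition(row, M - 1)[M - 1]
            closer = row < thr
            tied = row == thr
            w = np.zeros(len(row))
            w[closer] = 1.0 / M
            w[tied] = (M - closer.sum()) / (M * tied.sum())
            idx = np.flatnonzero(w > 0)
            out.append((idx, w[idx]))
    return out


def _build_match(gv: np.ndarray, data: ObservedData, M: int) -> MatchResult:
    A, Y = data.A, data.Y
    t_idx, c_idx = np.flatnonzero(A == 1), np.flatnonzero(A == 0)
    if len(t_idx) == 0 or len(c_idx) == 0:
        raise EstimationError("both treatment arms must be non-empty for matching")
    if M < 1 or M > min(len(t_idx), len(c_idx)):
        raise ValueError("M must be between 1 and the size of the smaller arm")
    lp = logit(np.clip(gv, PS_BOUND, 1 - PS_BOUND))

    neighbors: list[np.ndarray] = [None] * data.n  # type: ignore[list-item]
    weights: list[np.ndarray] = [None] * data.n  # type: ignore[list-item]
    K = np.zeros(data.n)
    for src_idx, tgt_idx in ((t_idx, c_idx), (c_idx, t_idx)):
        rows = _match_rows(lp[src_idx], lp[tgt_idx], M)
        for i, (local, w) in zip(src_idx, rows):
            gl = tgt_idx[local]
            neighbors[i], weights[i] = gl, w
            K[gl] += M * w

    imputed = np.array([w @ Y[nb] for nb, w in zip(neighbors, weights)])
    deltas = np.where(A == 1, Y - imputed, imputed - Y)
    return MatchResult(neighbors, weights, K, deltas, lp, M)


def ps_match(g, data: ObservedData, M: int = 1) -> tuple[MatchResult, ATEEstimate]:
    """1-to-M PS matching with replacement on the logit of the estimated PS.

    Each unit's missing potential outcome is imputed by the (tie-averaged)
    mean outcome of its M nearest opposite-arm units; the ATE estimate is
    the mean imputed individual effect.  The standard error is the
    matched-sample variance conditional on the estimated PS.
    """
    gv = _g_values(g, data)
    match = _build_match(gv, data, M)
    psi = float(match.deltas.mean())
    se = _matched_se_or_nan(match, data, psi, M)
    diag = {"max_reuse": float(match.K.max()), "M": M}
    return match, ATEEstimate.from_se(psi, se, "match", diag)


def bcm(g, q, data: ObservedData, M: int = 1) -> ATEEstimate:
    """Bias-corrected matching.

    The borrowed outcome Y_j of each match is adjusted by the difference in
    outcome-regression predictions Q(a, W_i) - Q(a, W_j), removing the part
    of the matching discrepancy explained by covariate imbalance between
    the matched pair.  ``q`` should be fitted stratified by arm.

    Standard error: after correction the estimator is a weighted sum of
    regression residuals plus the plug-in contrast, with unit i's residual
    carrying total weight (1 + K_i/M)/N, so the matched-sample variance
    conditional on the estimated PS is

        Vhat = N^-2 [ sum_i (1 + K_i/M)^2 sigma2_i
                      + sum_i (dq_i - mean(dq))^2 ]

    with sigma2_i estimated from nearest same-arm-neighbour differences of
    the regression residuals Y - Q(A, W), and dq_i = Q(1, W_i) - Q(0, W_i)
    the fitted individual contrast (the second term carries treatment-effect
    heterogeneity).
    """
    gv = _g_values(g, data)
    qf = _q_fn(q)
    match = _build_match(gv, data, M)
    A, Y, W = data.A, data.Y, data.W
    q0, q1 = qf(0, W), qf(1, W)
    corrected = np.empty(data.n)
    for i in range(data.n):
        nb, w = match.neighbors[i], match.weights[i]
        qa = q1 if A[i] == 0 else q0  # prediction under the *imputed* arm
        corrected[i] = w @ Y[nb] + qa[i] - w @ qa[nb]
    deltas = np.where(A == 1, Y - corrected, corrected - Y)
    psi = float(deltas.mean())
    if data.n >= 4:
        resid = Y - np.where(A == 1, q1, q0)
        sigma2 = _local_variances(match.lp, A, resid)
        dq = q1 - q0
        V = np.sum((1.0 + match.K / M) ** 2 * sigma2) + np.sum((dq - dq.mean()) ** 2)
        se = float(np.sqrt(V) / data.n)
    else:
        se = float("nan")
    diag = {"max_reuse": float(match.K.max()), "M": M}
    return ATEEstimate.from_se(psi, se, "bcm", diag)


def _matched_se_or_nan(match: MatchResult, data: ObservedData, psi: float, M: int) -> float:
    try:
        return matched_variance(match, data, psi, M)
    except EstimationError:
        return float("nan")


def matched_variance(
    match: MatchResult, data: ObservedData, psi_hat: float, M: int,
    conditional: bool = False,
) -> float:
    """Matched-sample ATE standard error, conditional on the estimated PS.

    The default (marginal) form is

        Vhat = N^-2 [ sum_i (delta_i - psi)^2
                      + sum_i ((K_i/M)^2 + (2M-1)/M * K_i/M) sigma2_i ]

    where K_i is unit i's (fractional) reuse count and sigma2_i a local
    conditional-variance estimate from pairing unit i with its nearest
    same-arm neighbour on the logit PS: sigma2_i = (Y_i - Y_nn(i))^2 / 2.
    With ``conditional=True`` the reuse coefficient is the smaller
    (K_i/M)(K_i/M - 1) of the variance conditional on the covariate sample
    (it vanishes when every unit is matched exactly once).  The marginal
    form is the one used for confidence intervals: it tracks the bootstrap
    more closely and reproduces the mild over-coverage expected of matching
    intervals that condition on the estimated PS.
    """
    N = data.n
    if N < 4:
        raise EstimationError("matched variance needs at least 4 observations")
    term1 = float(np.sum((match.deltas - psi_hat) ** 2))
    sigma2 = _local_variances(match.lp, data.A, data.Y)
    ratio = match.K / M
    if conditional:
        coef = ratio * (ratio - 1.0)
    else:
        coef = ratio**2 + (2.0 * M - 1.0) / M * ratio
    term2 = float(np.sum(coef * sigma2))
    return float(np.sqrt(max(term1 + term2, 0.0)) / N)


def _local_variances(lp: np.ndarray, A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """(Y_i - Y_j)^2 / 2 with j the nearest same-arm neighbour on the logit PS."""
    sigma2 = np.zeros(len(Y))
    for arm in (0, 1):
        idx = np.flatnonzero(A == arm)
        if len(idx) < 2:
            continue
        order = idx[np.argsort(lp[idx], kind="mergesort")]
        x, y = lp[order], Y[order]
        left = np.r_[np.inf, np.abs(np.diff(x))]
        right = np.r_[np.abs(np.diff(x)), np.inf]
        nn = np.where(left <= right, np.r_[y[0], y[:-1]], np.r_[y[1:], y[-1]])
        sigma2[order] = 0.5 * (y - nn) ** 2
    return sigma2


# ---------------------------------------------------------------------------
# TMLE
# ---------------------------------------------------------------------------

def clever_covariate(A: np.ndarray, g_hat_values: np.ndarray) -> np.ndarray:
    """h(A, W) = A/g - (1 - A)/(1 - g), the fluctuation direction."""
    A = np.asarray(A, float)
    g = np.asarray(g_hat_values, float)
    if (g <= 0).any() or (g >= 1).any():
        raise EstimationError("propensity values must lie strictly inside (0, 1)")
    return A / g - (1.0 - A) / (1.0 - g)


@dataclass
class FluctuationResult:
    """The fitted one-parameter fluctuation on the rescaled (0, 1) scale."""

    epsilon: float
    q_star0: np.ndarray
    q_star1: np.ndarray
    a_bound: float
    b_bound: float


_QSTAR_CLIP = 1e-4  # clamp of rescaled initial predictions before the logit


def _fit_epsilon(ystar, h, offset, tol=1e-10, maxiter=200) -> float:
    """One-parameter quasi-binomial MLE of the fluctuation coefficient.

    Newton iterations on the Bernoulli quasi-log-likelihood of ystar with
    linear predictor offset + eps * h; the score is sum h (ystar - mu).
    """
    eps = 0.0
    scale = float(np.abs(h).max())
    for _ in range(maxiter):
        mu = expit(offset + eps * h)
        score = float(h @ (ystar - mu))
        info = float(h**2 @ (mu * (1.0 - mu)))
        if abs(score) < tol * max(scale, 1.0):
            return eps
        if info <= 1e-300:
            break
        step = score / info
        step = float(np.clip(step, -10.0, 10.0))
        eps += step
        if abs(step) < 1e-14:
            return eps
    mu = expit(offset + eps * h)
    if abs(float(h @ (ystar - mu))) < 1e-6 * max(scale, 1.0):
        return eps
    raise EstimationError("TMLE fluctuation did not converge")


def tmle(
    g, q, data: ObservedData, bounds: tuple[float, float] | None = None
) -> tuple[FluctuationResult, ATEEstimate]:
    """Targeted maximum likelihood estimation of the ATE.

    The endpoint and the initial outcome regression are rescaled to [0, 1]
    using the known (or observed-range) bounds; the rescaled initial
    predictions are clamped away from 0/1, then updated on the logit scale
    by a single fluctuation coefficient fitted by quasi-binomial maximum
    likelihood of Y* on the clever covariate with the initial logit as
    offset.  Both counterfactual predictions are updated with their own
    clever-covariate values, back-transformed, and averaged via the
    G-computation formula.  The standard error comes from the empirical
    influence curve.
    """
    gv = _g_values(g, data)
    qf = _q_fn(q)
    Y, A, W = data.Y, data.A, data.W
    if bounds is None:
        a, b = float(Y.min()), float(Y.max())
        if b <= a:
            b = a + 1.0  # degenerate constant endpoint; any scale works
    else:
        a, b = float(bounds[0]), float(bounds[1])
    if a >= b:
        raise ValueError("bounds must satisfy a < b")
    if (Y < a - 1e-9).any() or (Y > b + 1e-9).any():
        raise ValueError("endpoint values outside the supplied bounds")

    span = b - a
    ystar = (Y - a) / span
    q0_obs = np.where(A == 1, qf(1, W), qf(0, W))
    qs_obs = np.clip((q0_obs - a) / span, _QSTAR_CLIP, 1 - _QSTAR_CLIP)
    qs_1 = np.clip((qf(1, W) - a) / span, _QSTAR_CLIP, 1 - _QSTAR_CLIP)
    qs_0 = np.clip((qf(0, W) - a) / span, _QSTAR_CLIP, 1 - _QSTAR_CLIP)

    h = clever_covariate(A, gv)
    h1, h0 = 1.0 / gv, -1.0 / (1.0 - gv)
    eps = _fit_epsilon(ystar, h, logit(qs_obs))

    qstar1 = expit(logit(qs_1) + eps * h1)
    qstar0 = expit(logit(qs_0) + eps * h0)
    qstar_obs = np.where(A == 1, qstar1, qstar0)

    psi = float(np.mean(qstar1 - qstar0) * span)
    ic = span * (h * (ystar - qstar_obs) + qstar1 - qstar0) - psi
    se = float(np.sqrt(np.var(ic, ddof=1) / data.n))

    fluct = FluctuationResult(eps, qstar0, qstar1, a, b)
    diag = {
        "epsilon": eps,
        "bounds": (a, b),
        "score_residual": float(np.mean(h * (ystar - qstar_obs))),
        "weight_max": float(np.abs(h).max()),
    }
    return fluct, ATEEstimate.from_se(psi, se, "tmle", diag)


# ---------------------------------------------------------------------------
# nonparametric bootstrap
# ---------------------------------------------------------------------------

def bootstrap_se(
    estimator: Callable[[ObservedData], float],
    data: ObservedData,
    B: int = 200,
    seed: int = 0,
) -> float:
    """SD of the estimator over B row-resamples (nuisances refit each time)."""
    if B < 50:
        raise ValueError("B must be at least 50 for a bootstrap standard error")
    rng = np.random.default_rng(seed)
    values, failures = [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(B):
            try:
                values.append(float(estimator(data.resample(rng))))
            except Exception:
                failures += 1
    if failures > 0.1 * B:
        raise EstimationError(f"bootstrap failed in {failures}/{B} replicates")
    return float(np.std(values, ddof=1))
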
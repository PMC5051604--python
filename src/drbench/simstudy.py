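"""The Monte-Carlo comparison of the estimators.

One *scenario* fixes how the two nuisance models are specified relative to
the generating truth:

====== ===============================================================
label  propensity score g(.)      /  outcome regression Q(.)
====== ===============================================================
a      both correctly specified parametric models
b      g misspecified (main terms), Q correct
c      g correct, Q misspecified (main terms)
d1     both misspecified fixed parametric models (main terms)
d2     both machine learning: balance-tuned boosted trees for g,
       cross-validated stacking for Q (the generating forms are NOT in
       the candidate library)
====== ===============================================================

Scenarios a-c require a DGP with an implemented "correct" parametric form
(the normal-endpoint DGPs 1-3).  :func:`run_scenario` replicates
simulate -> fit nuisances -> run every estimator, and aggregates relative
bias (%), variance, RMSE and 95% CI coverage against the DGP's true ATE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ObservedData
from .dgp import DGPConfig, simulate_dataset, true_ate
from .errors import ConfigurationError, EstimationError
from .estimators import ATEEstimate, bcm, gcomp, iptw, ps_match, tmle, wls
from .learners import (
    fit_outcome_parametric,
    fit_ps_boosted,
    fit_ps_parametric,
    fit_super_learner,
    truncate_ps,
)

__all__ = [
    "ScenarioSpec",
    "MetricsTable",
    "naive_estimator",
    "relative_bias",
    "rmse",
    "coverage",
    "run_scenario",
    "truncation_sensitivity",
    "ALL_METHODS",
]

ALL_METHODS = ("naive", "gcomp", "match", "iptw", "wls", "bcm", "tmle")

_FORMS = {
    "a": ("true_ps", "true_outcome"),
    "b": ("main_terms", "true_outcome"),
    "c": ("true_ps", "main_terms"),
    "d1": ("main_terms", "main_terms"),
    "d2": ("ml", "ml"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Which nuisance specifications a simulation scenario uses."""

    label: str

    def __post_init__(self):
        if self.label not in _FORMS:
            raise ConfigurationError(f"unknown scenario {self.label!r}")

    @property
    def g_form(self) -> str:
        return _FORMS[self.label][0]

    @property
    def q_form(self) -> str:
        return _FORMS[self.label][1]

    def validate_for(self, config: DGPConfig) -> None:
        needs_correct = "true_ps" in _FORMS[self.label] or "true_outcome" in _FORMS[self.label]
        if needs_correct and config.dgp_id not in (1, 2, 3):
            raise ConfigurationError(
                f"scenario {self.label!r} needs a correct parametric form, "
                f"only available for the normal-endpoint DGPs 1-3"
            )


# ---------------------------------------------------------------------------
# the reference (unadjusted) estimator and the reported metrics
# ---------------------------------------------------------------------------

def naive_estimator(data: ObservedData) -> ATEEstimate:
    """Unadjusted treated-minus-control mean difference, Welch standard error."""
    t, c = data.A == 1, data.A == 0
    if not t.any() or not c.any():
        raise EstimationError("both arms must be non-empty")
    y1, y0 = data.Y[t], data.Y[c]
    psi = float(y1.mean() - y0.mean())
    se = float(np.sqrt(y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0)))
    return ATEEstimate.from_se(psi, se, "naive")


def relative_bias(estimates: np.ndarray, truth: float) -> float:
    """100 * |mean(estimates) - truth| / |truth| (percent)."""
    if truth == 0:
        raise ValueError("relative bias is undefined for a zero truth")
    return float(100.0 * abs(np.mean(estimates) - truth) / abs(truth))


def rmse(estimates: np.ndarray, truth: float) -> float:
    """sqrt of the mean squared deviation of the estimates from the truth."""
    estimates = np.asarray(estimates, float)
    if estimates.size == 0:
        raise ValueError("empty estimates")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)))


def coverage(ci_list, truth: float) -> float:
    """Percent of closed intervals containing the truth."""
    ci = np.asarray(list(ci_list), float)
    if ci.size == 0:
        raise ValueError("empty interval list")
    lo, hi = ci[:, 0], ci[:, 1]
    if (lo > hi).any():
        raise ValueError("interval with lo > hi")
    return float(100.0 * np.mean((lo <= truth) & (truth <= hi)))


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class MetricsTable:
    """Per-method performance metrics over replications, plus metadata."""

    table: pd.DataFrame  # index: method; columns: relative_bias_pct, ...
    meta: dict = field(default_factory=dict)
    estimates: pd.DataFrame | None = None  # per-replication psi_hat (long)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for method, rec in self.table.iterrows():
            for metric in ("relative_bias_pct", "variance", "rmse", "coverage_pct"):
                rows.append({
                    "dgp": self.meta.get("dgp_id"),
                    "scenario": self.meta.get("scenario"),
                    "method": method,
                    "metric": metric,
                    "value": rec[metric],
                })
        return pd.DataFrame(rows)

    def format_table(self) -> str:
        hdr = (f"DGP {self.meta.get('dgp_id')} scenario ({self.meta.get('scenario')}) | "
               f"n={self.meta.get('n')} reps={self.meta.get('n_reps')} "
               f"true ATE={self.meta.get('truth'):.4g} seed={self.meta.get('seed')}")
        cols = ["relative_bias_pct", "variance", "rmse", "coverage_pct", "failures"]
        body = self.table[cols].to_string(float_format=lambda v: f"{v:.3g}")
        return hdr + "\n" + body + "\n"


# ---------------------------------------------------------------------------
# scenario machinery
# ---------------------------------------------------------------------------

def _rep_seeds(seed: int, n_reps: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)) for child in ss.spawn(n_reps)]


_TRUTH_CACHE: dict = {}


def _truth_for(config: DGPConfig, n_mc: int = 1_000_000) -> float:
    key = (config.dgp_id, config.k1, config.k2, n_mc, config.latent_corr.tobytes())
    if key not in _TRUTH_CACHE:
        _TRUTH_CACHE[key] = true_ate(config, n_mc=n_mc, seed=1000 + config.dgp_id).value
    return _TRUTH_CACHE[key]


def _fit_nuisances(ds, scenario: ScenarioSpec, rep_seed: int, sl_folds: int, boost_grid):
    """Fit (g, q_pooled, q_stratified) per the scenario's specification."""
    if scenario.label == "d2":
        g = fit_ps_boosted(ds, seed=rep_seed, **({"grid": boost_grid} if boost_grid else {}))
        q = fit_super_learner(ds, V=sl_folds, seed=rep_seed)
        return g, q, q
    g = fit_ps_parametric(ds, terms=scenario.g_form)
    q_pool = fit_outcome_parametric(ds, terms=scenario.q_form, stratify_by_arm=False)
    q_strat = fit_outcome_parametric(ds, terms=scenario.q_form, stratify_by_arm=True)
    return g, q_pool, q_strat


def _run_methods(ds, methods, g, q_pool, q_strat, g_values=None) -> dict[str, ATEEstimate]:
    gv = g_values if g_values is not None else (g.propensity(ds.W) if g is not None else None)
    out = {}
    for m in methods:
        if m == "naive":
            out[m] = naive_estimator(ds)
        elif m == "gcomp":
            out[m] = gcomp(q_pool, ds)
        elif m == "iptw":
            out[m] = iptw(gv, ds)
        elif m == "wls":
            out[m] = wls(gv, ds)
        elif m == "match":
            out[m] = ps_match(gv, ds)[1]
        elif m == "bcm":
            out[m] = bcm(gv, q_strat, ds)
        elif m == "tmle":
            out[m] = tmle(gv, q_pool, ds)[1]
        else:
            raise ConfigurationError(f"unknown method {m!r}")
    return out


def _aggregate(records, methods, truth, meta, n_reps) -> MetricsTable:
    rows, est_rows = [], []
    for m in methods:
        psis = np.array([r[m].psi_hat for r in records if m in r])
        cis = [(r[m].ci_lo, r[m].ci_hi) for r in records if m in r and np.isfinite(r[m].se)]
        failures = n_reps - len(psis)
        for k, p in enumerate(psis):
            est_rows.append({"method": m, "rep": k, "psi_hat": p})
        row = {
            "method": m,
            "relative_bias_pct": relative_bias(psis, truth) if len(psis) else np.nan,
            "variance": float(np.var(psis, ddof=1)) if len(psis) > 1 else np.nan,
            "rmse": rmse(psis, truth) if len(psis) else np.nan,
            "coverage_pct": coverage(cis, truth) if cis else np.nan,
            "n_ci": len(cis),
            "failures": failures,
            "reliable": failures <= 0.05 * n_reps,
        }
        rows.append(row)
    table = pd.DataFrame(rows).set_index("method")
    unreliable = table.index[~table["reliable"]].tolist()
    if unreliable:
        warnings.warn(f"metrics unreliable (>5% failures) for: {unreliable}")
    return MetricsTable(table=table, meta=meta, estimates=pd.DataFrame(est_rows))


def run_scenario(
    dgp: DGPConfig,
    scenario: ScenarioSpec | str,
    methods=ALL_METHODS,
    n_reps: int = 1000,
    seed: int = 0,
    sl_folds: int = 10,
    boost_grid=None,
    truth: float | None = None,
) -> MetricsTable:
    """Replicate simulate / fit / estimate and aggregate performance metrics.

    Every method within a replication sees the same dataset and the same
    fitted nuisances.  Replication seeds are spawned from the root seed.
    Failures of individual methods are logged per replication and excluded
    from the aggregates; a method failing in more than 5% of replications
    is flagged unreliable.
    """
    scenario = ScenarioSpec(scenario) if isinstance(scenario, str) else scenario
    if not methods:
        raise ConfigurationError("methods must be non-empty")
    scenario.validate_for(dgp)
    truth = _truth_for(dgp) if truth is None else float(truth)

    records = []
    failures_log = []
    for rep, rep_seed in enumerate(_rep_seeds(seed, n_reps)):
        ds = simulate_dataset(dgp.with_seed(rep_seed))
        rec = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                g, q_pool, q_strat = _fit_nuisances(ds, scenario, rep_seed, sl_folds, boost_grid)
            except Exception as exc:
                failures_log.append((rep, "nuisance", repr(exc)))
                records.append(rec)
                continue
            gv = g.propensity(ds.W)
            for m in methods:
                try:
                    rec.update(_run_methods(ds, [m], g, q_pool, q_strat, g_values=gv))
                except Exception as exc:
                    failures_log.append((rep, m, repr(exc)))
        records.append(rec)

    meta = {
        "dgp_id": dgp.dgp_id, "scenario": scenario.label, "n": dgp.n,
        "n_reps": n_reps, "seed": seed, "truth": truth, "failures_log": failures_log,
    }
    return _aggregate(records, list(methods), truth, meta, n_reps)


def truncation_sensitivity(
    dgp: DGPConfig,
    scenario: ScenarioSpec | str,
    n_reps: int = 250,
    seed: int = 0,
    lo: float = 0.025,
    hi: float = 0.975,
    methods=("iptw", "wls", "tmle"),
    sl_folds: int = 10,
    boost_grid=None,
    truth: float | None = None,
) -> MetricsTable:
    """Side-by-side metrics with and without PS truncation at [lo, hi].

    Within each replication the nuisances are fitted once; the weighting
    estimators are run on the raw bounded PS and on the truncated PS.
    Rows ``<method>`` are untruncated, ``<method>_truncated`` truncated.
    """
    scenario = ScenarioSpec(scenario) if isinstance(scenario, str) else scenario
    scenario.validate_for(dgp)
    if not (0.0 <= lo < hi <= 1.0):
        raise ConfigurationError("invalid truncation levels")
    if dgp.dgp_id not in (3, 4, 5):
        warnings.warn("truncation sensitivity is aimed at the poor-overlap DGPs 3-5")
    truth = _truth_for(dgp) if truth is None else float(truth)

    records = []
    for rep, rep_seed in enumerate(_rep_seeds(seed, n_reps)):
        ds = simulate_dataset(dgp.with_seed(rep_seed))
        rec = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                g, q_pool, q_strat = _fit_nuisances(ds, scenario, rep_seed, sl_folds, boost_grid)
                gv = g.propensity(ds.W)
                gv_tr = truncate_ps(gv, lo, hi)
                for m in methods:
                    rec.update(_run_methods(ds, [m], g, q_pool, q_strat, g_values=gv))
                    tr = _run_methods(ds, [m], g, q_pool, q_strat, g_values=gv_tr)
                    rec[f"{m}_truncated"] = tr[m]
            except Exception:
                pass
        records.append(rec)

    all_methods = [x for m in methods for x in (m, f"{m}_truncated")]
    meta = {
        "dgp_id": dgp.dgp_id, "scenario": scenario.label, "n": dgp.n,
        "n_reps": n_reps, "seed": seed, "truth": truth, "truncation": (lo, hi),
    }
    return _aggregate(records, all_methods, truth, meta, n_reps)
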
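"""Adaptive polynomial-spline regression.

A compact forward/backward basis-selection regressor in the spirit of
multivariate adaptive polynomial-spline (MARS-style) regression:

* base candidate functions are the linear columns plus hinge pairs
  max(x - t, 0) and max(t - x, 0) at marginal quantile knots of each
  continuous feature;
* the forward pass greedily adds either a base candidate or the product of
  a base candidate with an already-selected degree-1 term (so selected
  terms have degree at most two), scoring candidates by their normalised
  correlation with the current residual and refitting by least squares
  after every addition;
* the backward pass prunes terms by generalised cross-validation.

The basis count is capped at min(2 * sqrt(n), 30) terms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AdaptiveSplineRegressor"]

_KNOT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
_GCV_PENALTY = 3.0  # cost per basis function in the GCV denominator


def _is_continuous(col: np.ndarray) -> bool:
    return np.unique(col).size > 2


class AdaptiveSplineRegressor:
    """Least-squares regression on an adaptively selected hinge basis."""

    def __init__(self, max_terms: int | None = None, max_degree: int = 2,
                 knot_quantiles=_KNOT_QUANTILES):
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.knot_quantiles = tuple(knot_quantiles)

    # -- base candidate pool ------------------------------------------------
    def _base_pool(self, X: np.ndarray, fitting: bool) -> np.ndarray:
        cols = []
        if fitting:
            self._knots_: list[tuple[int, float]] = []
            for j in range(X.shape[1]):
                if _is_continuous(X[:, j]):
                    for q in self.knot_quantiles:
                        self._knots_.append((j, float(np.quantile(X[:, j], q))))
        for j in range(X.shape[1]):
            cols.append(X[:, j])
        for j, t in self._knots_:
            cols.append(np.maximum(X[:, j] - t, 0.0))
            cols.append(np.maximum(t - X[:, j], 0.0))
        return np.column_stack(cols)

    @staticmethod
    def _rss(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
        beta, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
        r = y - B @ beta
        return beta, float(r @ r)

    # -- fitting ------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "AdaptiveSplineRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        C = self._base_pool(X, fitting=True)
        nc = C.shape[1]
        norms = np.sqrt((C**2).sum(axis=0))
        C2 = C**2
        cap = self.max_terms or min(30, max(2, int(np.ceil(2.0 * np.sqrt(n)))))
        cap = min(cap, n - 2)

        # selected terms: (base_index, partner_base_index or -1 for degree 1)
        selected: list[tuple[int, int]] = []
        sel_cols: list[np.ndarray] = []
        B = np.ones((n, 1))
        beta, rss = self._rss(B, y)
        for _ in range(cap):
            r = y - B @ beta
            # degree-1 scores: |c' r| / ||c||
            s1 = np.abs(C.T @ r) / np.maximum(norms, 1e-12)
            best_score, best_term = -np.inf, None
            k1 = int(np.argmax(s1))
            if s1[k1] > best_score:
                best_score, best_term = float(s1[k1]), (k1, -1)
            if self.max_degree >= 2:
                deg1_sel = [i for i, (_, p) in enumerate(selected) if p == -1]
                if deg1_sel:
                    S = np.column_stack([sel_cols[i] for i in deg1_sel])
                    num = np.abs(C.T @ (S * r[:, None]))        # nc x n_sel
                    den = np.sqrt(np.maximum(C2.T @ (S**2), 1e-24))
                    s2 = num / den
                    k2 = np.unravel_index(int(np.argmax(s2)), s2.shape)
                    if s2[k2] > best_score:
                        partner = selected[deg1_sel[k2[1]]][0]
                        best_score, best_term = float(s2[k2]), (int(k2[0]), partner)
            if best_term is None or best_term in selected:
                break
            kb, partner = best_term
            col = C[:, kb] if partner < 0 else C[:, kb] * C[:, partner]
            if float(col @ col) < 1e-12:
                break
            trial = np.column_stack([B, col])
            beta_t, rss_t = self._rss(trial, y)
            if rss - rss_t <= 1e-12 * max(rss, 1.0):
                break
            selected.append(best_term)
            sel_cols.append(col)
            B, beta, rss = trial, beta_t, rss_t

        # backward pass: GCV pruning
        def gcv(rss_val: float, nterms: int) -> float:
            eff = min(1.0 + _GCV_PENALTY * nterms, n - 1.0)
            return (rss_val / n) / (1.0 - eff / n) ** 2

        order = list(range(len(selected)))
        best_keep, best_gcv = list(order), gcv(rss, len(order))
        cur = list(order)
        while cur:
            drops = []
            for i in range(len(cur)):
                keep = cur[:i] + cur[i + 1:]
                Bt = np.column_stack([np.ones(n)] + [sel_cols[k] for k in keep])
                _, rss_t = self._rss(Bt, y)
                drops.append((gcv(rss_t, len(keep)), keep))
            g, keep = min(drops, key=lambda t: t[0])
            cur = keep
            if g < best_gcv:
                best_gcv, best_keep = g, list(keep)

        self.terms_ = [selected[k] for k in best_keep]
        Bf = np.column_stack([np.ones(n)] + [sel_cols[k] for k in best_keep])
        self.coef_, _ = self._rss(Bf, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        C = self._base_pool(X, fitting=False)
        cols = [np.ones(X.shape[0])]
        for kb, partner in self.terms_:
            cols.append(C[:, kb] if partner < 0 else C[:, kb] * C[:, partner])
        return np.column_stack(cols) @ self.coef_
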
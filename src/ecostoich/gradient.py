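"""Polynomial trends along the elevational gradient and correlation screening.

Each response variable is regressed on elevation with first-, second-, and
third-order polynomials; the best model is chosen by AICc (default; adjusted
R-squared as an alternative), with ties broken toward the lower order.  AICc
rather than plain AIC because plot-level sample sizes in gradient studies of
this kind are small (a few dozen plots).

Elevation is centred and scaled internally for numerical conditioning; the
reported coefficients are on the original metre scale, intercept first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GradientFit:
    response: str
    order: int
    coefficients: tuple  # original elevation scale, intercept first
    r_squared: float
    adj_r_squared: float
    aicc: float
    p_value: float  # overall F test
    n: int

    def predict(self, elevation):
        return Polynomial(self.coefficients)(np.asarray(elevation, dtype=float))


def _aicc(rss: float, n: int, n_coef: int, y_scale: float) -> float:
    # rss floored at numerical noise so that interpolating fits compare by
    # parameter count alone instead of by rounding error in the residuals
    floor = n * (1e-12 * max(y_scale, 1e-300)) ** 2
    rss = max(rss, floor)
    k = n_coef + 1  # +1 for the residual variance
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 <= 0:
        return np.inf
    return float(aic + 2 * k * (k + 1) / (n - k - 1))


def fit_polynomials(
    elevation, y, max_order: int = 3, response: str = "y"
) -> list[GradientFit]:
    """OLS polynomial fits of ``y`` on elevation for orders 1..max_order.

    Orders that the sample size cannot support (fewer than order + 2 points)
    are dropped with a warning rather than raising.
    """
    e = np.asarray(elevation, dtype=float)
    yv = np.asarray(y, dtype=float)
    if e.shape != yv.shape or e.ndim != 1:
        raise ValueError("elevation and y must be equal-length 1-d sequences")
    ok = np.isfinite(e) & np.isfinite(yv)
    e, yv = e[ok], yv[ok]
    n = e.size
    if np.ptp(e) == 0:
        raise ValueError("elevation is constant; gradient fit is unidentifiable")

    mu, sd = e.mean(), e.std()
    z = (e - mu) / sd
    tss = float(((yv - yv.mean()) ** 2).sum())
    y_scale = float(np.std(yv)) or float(np.abs(yv).max() or 1.0)

    fits = []
    for order in range(1, max_order + 1):
        if n < order + 2:
            logger.warning(
                "%s: n=%d too small for order %d (need >= %d); dropping",
                response, n, order, order + 2,
            )
            continue
        X = np.vander(z, order + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        rss = float(resid @ resid)
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        r2 = min(max(r2, 0.0), 1.0)
        dof = n - order - 1
        adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
        if tss > 0 and dof > 0 and r2 < 1.0:
            f = (r2 / order) / ((1.0 - r2) / dof)
            p = float(stats.f.sf(f, order, dof))
        elif r2 >= 1.0:
            p = 0.0
        else:
            p = 1.0
        # compose with z = (e - mu)/sd to recover metre-scale coefficients
        poly = Polynomial(beta)(Polynomial([-mu / sd, 1.0 / sd]))
        coef = np.zeros(order + 1)
        coef[: len(poly.coef)] = poly.coef
        fits.append(
            GradientFit(
                response=response, order=order, coefficients=tuple(coef),
                r_squared=r2, adj_r_squared=float(adj),
                aicc=_aicc(rss, n, order + 1, y_scale),
                p_value=p, n=int(n),
            )
        )
    if not fits:
        raise ValueError(f"{response}: too few points (n={n}) for any polynomial fit")
    return fits


#: Two AICc units: the conventional margin within which competing models are
#: considered substantially equivalent and parsimony prevails.
AICC_EQUIVALENCE = 2.0


def select_best(fits: list[GradientFit], criterion: str = "aicc") -> GradientFit:
    """Best fit by AICc (default) or adjusted R²; ties go to the lower order.

    Under AICc the simplest model within :data:`AICC_EQUIVALENCE` units of
    the minimum is returned — a higher order must improve AICc by more than
    two units to displace a lower one.
    """
    if not fits:
        raise ValueError("no fits to select from")
    if criterion == "aicc":
        best = min(f.aicc for f in fits)
        candidates = [f for f in fits if f.aicc <= best + AICC_EQUIVALENCE]
        return min(candidates, key=lambda f: (f.order, f.aicc))
    if criterion == "adj_r_squared":
        return min(fits, key=lambda f: (-f.adj_r_squared, f.order))
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class CorrelationScreen:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame  # Benjamini-Hochberg over the upper triangle
    n: pd.DataFrame
    method: str


def correlation_screen(table: pd.DataFrame, method: str = "pearson") -> CorrelationScreen:
    """Pairwise Pearson or Spearman correlations with pairwise-complete data.

    Cells with fewer than 3 complete pairs are NA.  Raw p-values are reported
    together with Benjamini-Hochberg adjusted ones (over all distinct pairs).
    """
    if method == "pearson":
        corr = stats.pearsonr
    elif method == "spearman":
        corr = stats.spearmanr
    else:
        raise ValueError(f"unknown method {method!r}")
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    nmat = pd.DataFrame(0, index=cols, columns=cols)
    for c in cols:
        nmat.loc[c, c] = int(table[c].notna().sum())
    pairs = []
    for a, b in combinations(cols, 2):
        sub = table[[a, b]].dropna()
        nmat.loc[a, b] = nmat.loc[b, a] = len(sub)
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = corr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
        pairs.append((a, b))

    p_adj = p.copy()
    if pairs:
        raw = np.array([p.loc[a, b] for a, b in pairs])
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, raw[i] * m / (rank + 1))
            adj[i] = running
        for (a, b), v in zip(pairs, adj):
            p_adj.loc[a, b] = p_adj.loc[b, a] = v
    return CorrelationScreen(r=r, p=p, p_adjusted=p_adj, n=nmat, method=method)
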
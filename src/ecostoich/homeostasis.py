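"""Stoichiometric homeostasis index and N:P nutrient-limitation thresholds.

The homeostasis model relates plant stoichiometry y to the corresponding soil
stoichiometry x through

    log10 y = log10 c + log10 x / H

so H is the inverse of the OLS slope on log10-log10 axes.  Larger H means
stronger internal regulation: a strongly homeostatic community barely moves
its leaf N:P as soil N:P varies.  Any fixed log base yields the same H, since
a change of base rescales both axes by the same constant.

Classification follows Persson's bands: with a significant regression
(p < alpha), H >= 4 is a steady state, 2 <= H < 4 weak steady, 1.33 <= H < 2
weak sensitive, H < 1.33 sensitive.  A non-significant regression — the plant
side does not track the soil side at all — is an "absolute steady state"; a
non-positive fitted slope is treated the same way.

Nutrient limitation is read off green-leaf N:P against published thresholds:
Guesewell 10/20 or Koerselman-Meuleman 14/16, partitioning N-limited,
co-limited (closed interval), and P-limited states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

STEADY = "steady state"
WEAK_STEADY = "weak steady state"
WEAK_SENSITIVE = "weak sensitive state"
SENSITIVE = "sensitive state"
ABSOLUTE_STEADY = "absolute steady state"

N_LIMITED = "N-limited"
CO_LIMITED = "co-limited"
P_LIMITED = "P-limited"

#: (lower threshold, upper threshold) for leaf N:P limitation calls.
LIMITATION_SCHEMES = {
    "guesewell_10_20": (10.0, 20.0),
    "koerselman_14_16": (14.0, 16.0),
}


@dataclass
class HomeostasisResult:
    trait: str
    H: float  # inf for an absolute steady state
    c: float
    slope: float
    p_value: float
    r_squared: float
    n: int
    label: str


@dataclass
class LimitationCall:
    ratio_NP: float
    scheme: str
    label: str


def classify_homeostasis(H: float, p_value: float, alpha: float = 0.05) -> str:
    """Persson band label from the homeostasis index and regression p-value.

    The significance rule dominates: a non-significant fit is an absolute
    steady state regardless of H.  Band edges are inclusive on the left.
    """
    if not H > 0:
        raise ValueError("H must be positive (or infinite)")
    if p_value > alpha or math.isinf(H):
        return ABSOLUTE_STEADY
    if H >= 4:
        return STEADY
    if H >= 2:
        return WEAK_STEADY
    if H >= 1.33:
        return WEAK_SENSITIVE
    return SENSITIVE


def fit_homeostasis(
    soil_x: Sequence[float],
    plant_y: Sequence[float],
    alpha: float = 0.05,
    trait: str = "N:P",
) -> HomeostasisResult:
    """Estimate H and c by OLS of log10(plant y) on log10(soil x).

    When the regression is not significant at ``alpha`` or the slope is not
    positive, H is flagged infinite and the label is "absolute steady state".
    """
    x = np.asarray(soil_x, dtype=float)
    y = np.asarray(plant_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("soil_x and plant_y must be equal-length 1-d sequences")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("all stoichiometry values must be positive")
    if np.ptp(x) == 0:
        raise ValueError("soil_x is constant; slope is unidentifiable")

    res = stats.linregress(np.log10(x), np.log10(y))
    slope = float(res.slope)
    p = float(res.pvalue)
    c = float(10.0 ** res.intercept)
    if p > alpha or slope <= 0:
        H = math.inf
    else:
        H = 1.0 / slope
    return HomeostasisResult(
        trait=trait, H=H, c=c, slope=slope, p_value=p,
        r_squared=float(res.rvalue**2), n=int(x.size),
        label=classify_homeostasis(H, p, alpha),
    )


def classify_limitation(ratio_NP: float, scheme: str = "guesewell_10_20") -> LimitationCall:
    """Nutrient-limitation call from green-leaf N:P.

    Below the lower threshold -> N-limited; above the upper -> P-limited; the
    closed interval between -> co-limited by N and P.
    """
    if not ratio_NP > 0:
        raise ValueError("ratio_NP must be positive")
    try:
        lo, hi = LIMITATION_SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme!r}; choose from {sorted(LIMITATION_SCHEMES)}"
        ) from None
    if ratio_NP < lo:
        label = N_LIMITED
    elif ratio_NP > hi:
        label = P_LIMITED
    else:
        label = CO_LIMITED
    return LimitationCall(ratio_NP=float(ratio_NP), scheme=scheme, label=label)
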
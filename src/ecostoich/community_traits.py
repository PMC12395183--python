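"""Community-weighted mean leaf nutrients and alpha-diversity indices.

The community-weighted mean (CWM) of a leaf trait is the biomass-proportion
weighted average across species, CWM_t = sum_i t_i * w_i with the w_i summing
to one — the mass-ratio view of community functional composition.  Applied to
leaf C, N, and P it yields the community-level concentrations LTC, LTN, LTP
(g/kg) and their stoichiometric ratios.

Diversity is summarised by the Shannon-Wiener index H' = -sum p_i ln p_i
(nats) and Pielou's evenness E = H'/ln S.  Abundance defaults to individual
density when a ``density`` column is present and falls back to biomass share
otherwise; the choice is exposed via ``diversity_weight``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DegenerateWeightsError(ValueError):
    """All weights are zero (or the plot has no usable species)."""


@dataclass
class CommunitySample:
    """Per-plot aggregate: CWM leaf nutrients, ratios, and diversity."""

    plot_id: object
    LTC: float
    LTN: float
    LTP: float
    ratio_CN: float
    ratio_CP: float
    ratio_NP: float
    shannon: float
    pielou: float  # NaN when undefined (single-species plot)
    richness: int
    total_biomass: float
    elevation: float = math.nan


def cwm(trait_values: Sequence[float], weights: Sequence[float]) -> float:
    """Community-weighted mean: sum of traits times normalized weights.

    Weights are normalized to sum to one, so any positive rescaling of the
    weight vector leaves the result unchanged.
    """
    t = np.asarray(trait_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("trait_values and weights must be equal-length 1-d sequences")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("all weights are zero")
    return float((t * w).sum() / total)


def shannon(abundances: Sequence[float]) -> float:
    """Shannon-Wiener diversity H' = -sum p_i ln p_i, in nats.

    Zero abundances are dropped; at least one positive abundance is required.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("no positive abundances")
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def pielou(abundances: Sequence[float]) -> float:
    """Pielou evenness E = H'/ln S; NaN when S = 1 (evenness undefined)."""
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    s = a.size
    h = shannon(a)
    if s == 1:
        return math.nan
    return h / math.log(s)


def community_nutrients(
    observations: pd.DataFrame,
    diversity_weight: str = "density",
) -> CommunitySample:
    """Aggregate one plot's species observations into a :class:`CommunitySample`.

    LTC/LTN/LTP are biomass-proportion weighted means of species leaf
    concentrations.  Species missing any concentration are excluded from the
    CWM (with a logged warning) but still count toward diversity, which needs
    only abundance.
    """
    if diversity_weight not in ("density", "biomass"):
        raise ValueError(f"unknown diversity_weight {diversity_weight!r}")
    obs = observations
    plot_id = obs["plot_id"].iloc[0]

    traits = obs[["leaf_C", "leaf_N", "leaf_P"]]
    usable = traits.notna().all(axis=1) & (obs["biomass"] > 0)
    dropped = obs.loc[~usable, "species"].tolist()
    if dropped:
        logger.warning(
            "plot %s: excluded from CWM (missing trait or zero biomass): %s",
            plot_id, ", ".join(map(str, dropped)),
        )
    sub = obs[usable]
    if sub.empty:
        raise DegenerateWeightsError(f"plot {plot_id}: no species usable for CWM")

    w = sub["biomass"].to_numpy(float)
    ltc = cwm(sub["leaf_C"].to_numpy(float), w)
    ltn = cwm(sub["leaf_N"].to_numpy(float), w)
    ltp = cwm(sub["leaf_P"].to_numpy(float), w)

    if diversity_weight == "density" and "density" in obs.columns and obs["density"].notna().all():
        abund = obs["density"].to_numpy(float)
    else:
        abund = obs["biomass"].to_numpy(float)
    abund = abund[abund > 0]

    return CommunitySample(
        plot_id=plot_id,
        LTC=ltc, LTN=ltn, LTP=ltp,
        ratio_CN=ltc / ltn, ratio_CP=ltc / ltp, ratio_NP=ltn / ltp,
        shannon=shannon(abund),
        pielou=pielou(abund),
        richness=int((obs["biomass"] > 0).sum()),
        total_biomass=float(obs["biomass"].sum()),
    )


def aggregate_communities(
    survey: pd.DataFrame,
    soil: pd.DataFrame | None = None,
    diversity_weight: str = "density",
) -> pd.DataFrame:
    """Per-plot community trait table (one row per plot, survey order).

    When a soil table is given, plot elevation is joined in from it.
    """
    elev = {}
    if soil is not None:
        elev = dict(zip(soil["plot_id"], soil["elevation"]))
    rows = []
    for plot_id, grp in survey.groupby("plot_id", sort=False):
        sample = community_nutrients(grp, diversity_weight=diversity_weight)
        sample.elevation = float(elev.get(plot_id, math.nan))
        rows.append(asdict(sample))
    df = pd.DataFrame(rows)
    cols = ["plot_id", "elevation", "LTC", "LTN", "LTP", "ratio_CN", "ratio_CP",
            "ratio_NP", "shannon", "pielou", "richness", "total_biomass"]
    return df[cols]
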
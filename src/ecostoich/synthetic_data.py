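"""Synthetic survey/litter/soil dataset generator with known ground truth.

The generator emulates a montane-gradient community-stoichiometry study: six
sites spaced evenly from 1960 to 3548 m, four plots per site, the two lowest
sites sampled under a shrub protocol (species-level litter) and the rest
under a herbaceous protocol (community-pooled litter).  Every latent quantity
the downstream analysis estimates — the resorbed-ratio power law (omega,
lambda), the homeostasis coefficient H, the mean resorption efficiencies —
is a configurable parameter, so each pipeline stage can be checked by
parameter recovery.

Statistical structure, per plot:

* species biomass shares drawn from a symmetric Dirichlet; green-leaf C and N
  lognormal around site means with a linear elevation trend;
* soil TN increasing with elevation and TP flat, both with lognormal noise,
  giving soil N:P a wide spread;
* community leaf N:P set through the homeostasis model
  ``y = c * (soil N:P)^(1/H_true) * noise``, with c anchored so the mean
  community sits at the configured green-leaf N:P; species leaf P values are
  rescaled within the plot so the biomass-weighted community ratio matches y
  exactly;
* senesced concentrations back-solved (:func:`backsolve_senesced`) so that
  the community NRE equals a Normal(nre_mean, nre_sd) draw and the resorbed
  N:P ratio equals ``omega * (leaf N:P)^lambda * noise``.

When ``omega_true`` is left unset it is anchored at the configured mean leaf
N:P (``omega = np_ref^(1 - lambda)``), so the power law passes through the
point where resorbed N:P equals green N:P — the regime in which N and P
resorption efficiencies are comparable, as observed in arid montane
communities.  This keeps senesced concentrations feasible for any exponent.

One pseudo-random stream per table, split deterministically from the master
seed, so adding a table never perturbs another's draws; an identical seed
yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import POOLED_TOKEN

DEFAULT_MLCF = 0.762


class GenerationError(ValueError):
    """The configuration implies an impossible (non-positive) concentration."""


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic gradient study."""

    seed: int = 0
    n_sites: int = 6
    plots_per_site: int = 4
    species_per_plot: tuple = (3, 8)  # inclusive range
    elevations: Sequence[float] | None = None  # default: 1960..3548 m evenly
    shrub_sites: int = 2  # lowest sites use species-level litter
    lambda_true: float = 0.912
    omega_true: float | None = None  # None -> anchored at mean leaf N:P
    H_true: float = 16.34
    nre_mean: float = 78.0  # percent
    nre_sd: float = 4.0
    green_trait_means: tuple = (445.0, 24.0, 1.85)  # C, N, P g/kg at lowest site
    elevation_slopes: tuple = (0.0, 2.0, 0.0)  # g/kg per km for C, N, P
    species_sigma: float = 0.2  # lognormal sd of species traits around site mean
    noise_sigma: float = 0.05  # lognormal sd of latent community-level noises
    # residual dispersion of community N:P around the homeostasis line; the
    # default reproduces a plot-level leaf N:P span of roughly 10.5-16.5
    leaf_np_sigma: float = 0.09
    soil_tn_range: tuple = (0.5, 2.4)  # g/kg at lowest/highest site
    soil_tp_mean: float = 0.55  # g/kg, no trend
    soil_sigma: float = 0.25  # lognormal sd of soil TN and TP
    mlcf: float = DEFAULT_MLCF

    def resolved_elevations(self) -> np.ndarray:
        if self.elevations is not None:
            e = np.asarray(self.elevations, dtype=float)
        else:
            e = np.linspace(1960.0, 3548.0, self.n_sites)
        if not np.all(np.diff(e) > 0):
            raise ValueError("elevations must be strictly increasing")
        return e

    @property
    def np_ref(self) -> float:
        return self.green_trait_means[1] / self.green_trait_means[2]

    def resolved_omega(self) -> float:
        if self.omega_true is not None:
            return float(self.omega_true)
        return float(self.np_ref ** (1.0 - self.lambda_true))


@dataclass
class SyntheticDataset:
    survey: pd.DataFrame
    litter: pd.DataFrame
    soil: pd.DataFrame
    truth: dict = field(default_factory=dict)


def backsolve_senesced(
    LTN: float, LTP: float, nre_target: float, resorbed_np_target: float,
    mlcf: float = DEFAULT_MLCF,
) -> tuple:
    """Invert the resorption formulas: senesced N and P hitting both targets.

    ``LTN_s`` follows from the NRE definition and ``LTP_s`` from the resorbed
    N:P ratio; a forward recomputation reproduces the targets exactly.
    Raises :class:`GenerationError` when the targets imply non-positive
    senesced P (the requested resorbed ratio is too small for the green-leaf
    stoichiometry and NRE).
    """
    if not 0.0 < nre_target < 100.0:
        raise ValueError("nre_target must be in (0, 100)")
    if not resorbed_np_target > 0:
        raise ValueError("resorbed_np_target must be positive")
    ltn_s = LTN * (1.0 - nre_target / 100.0) / mlcf
    resorbed_n = LTN - ltn_s * mlcf  # == LTN * nre/100
    ltp_s = (LTP - resorbed_n / resorbed_np_target) / mlcf
    if ltp_s <= 0:
        raise GenerationError(
            f"infeasible targets: LTN={LTN:.4g}, LTP={LTP:.4g}, "
            f"NRE={nre_target:.4g}%, resorbed N:P={resorbed_np_target:.4g} "
            f"imply senesced P {ltp_s:.4g} <= 0"
        )
    return float(ltn_s), float(ltp_s)


def simulate_power_law(
    lambda_true: float,
    omega: float,
    n: int,
    sigma: float,
    rng: np.random.Generator | int,
    x_range: tuple = (10.0, 20.0),
) -> tuple:
    """Draw (x, y) from ``y = omega * x^lambda * lognormal(sigma)``.

    x is log-uniform over ``x_range``.  Used for confidence-interval
    calibration of the power-law slope test.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.exp(rng.uniform(np.log(x_range[0]), np.log(x_range[1]), size=n))
    y = omega * x**lambda_true * np.exp(rng.normal(0.0, sigma, size=n))
    return x, y


def simulate_homeostasis_pairs(
    H_true: float,
    c: float,
    n: int,
    sigma: float,
    rng: np.random.Generator | int,
    x_gm: float = 2.0,
    x_log10_sd: float = 0.25,
) -> tuple:
    """Draw paired (soil x, plant y) from ``y = c * x^(1/H) * lognormal(sigma)``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = 10.0 ** rng.normal(np.log10(x_gm), x_log10_sd, size=n)
    y = c * x ** (1.0 / H_true) * np.exp(rng.normal(0.0, sigma, size=n))
    return x, y


def _soil_extras(elev_km: float, tn: float, rng: np.random.Generator) -> dict:
    """Context soil properties with simple monotone trends plus noise."""
    ln = lambda s: np.exp(rng.normal(0.0, s))
    poc = (1.5 + 2.0 * elev_km) * ln(0.2)
    maoc = (2.5 + 3.5 * elev_km) * ln(0.2)
    return {
        "AN": tn * 40.0 * ln(0.15),                 # mg/kg
        "AP": max(1.0 + 3.0 * np.sin(2.0 + 3.0 * elev_km), 0.3) * ln(0.2),
        "SWC": (4.0 + 8.0 * elev_km) * ln(0.15),    # %
        "pH": 8.6 - 0.4 * elev_km + rng.normal(0.0, 0.08),
        "EC": (1.2 - 0.55 * elev_km) * ln(0.2),
        "POC": poc,
        "MAOC": maoc,
        "SOC": poc + maoc,
        "TS": (8.0 - 4.0 * elev_km) * ln(0.2),
        "MAT": 12.0 - 6.5 * elev_km,                # site-level lapse
        "MAP": 55.0 + 95.0 * elev_km,
    }


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the survey/litter/soil table triplet plus a truth record."""
    cfg = config or SimulationConfig()
    elevations = cfg.resolved_elevations()
    omega = cfg.resolved_omega()
    mlcf = cfg.mlcf

    ss = np.random.SeedSequence(cfg.seed)
    rng_survey, rng_soil, rng_latent, rng_litter = map(
        np.random.default_rng, ss.spawn(4)
    )

    c_mean, n_mean0, p_mean0 = cfg.green_trait_means
    sc, sn, sp = cfg.elevation_slopes
    tn_lo, tn_hi = cfg.soil_tn_range
    e_lo, e_hi = elevations[0], elevations[-1]
    soil_np_ref = float(np.sqrt(tn_lo * tn_hi) / cfg.soil_tp_mean)
    c_homeo = cfg.np_ref / soil_np_ref ** (1.0 / cfg.H_true)

    survey_rows, litter_rows, soil_rows, plot_truth = [], [], [], []

    for s_idx, elev in enumerate(elevations):
        elev_km = (elev - e_lo) / 1000.0
        frac = (elev - e_lo) / (e_hi - e_lo) if e_hi > e_lo else 0.0
        shrub = s_idx < cfg.shrub_sites
        site_c = c_mean + sc * elev_km
        site_n = n_mean0 + sn * elev_km
        site_p = p_mean0 + sp * elev_km
        for p_idx in range(cfg.plots_per_site):
            plot_id = f"S{s_idx + 1}P{p_idx + 1}"

            # --- soil ---
            tn = (tn_lo + frac * (tn_hi - tn_lo)) * np.exp(
                rng_soil.normal(0.0, cfg.soil_sigma)
            )
            tp = cfg.soil_tp_mean * np.exp(rng_soil.normal(0.0, cfg.soil_sigma))
            extras = _soil_extras(elev_km, tn, rng_soil)
            soil_rows.append({"plot_id": plot_id, "elevation": elev,
                              "TN": tn, "TP": tp, **extras})
            soil_np = tn / tp

            # --- community latents ---
            leaf_np = (
                c_homeo * soil_np ** (1.0 / cfg.H_true)
                * np.exp(rng_latent.normal(0.0, cfg.leaf_np_sigma))
            )
            resorbed_t = (
                omega * leaf_np**cfg.lambda_true
                * np.exp(rng_latent.normal(0.0, cfg.noise_sigma))
            )
            # NRE is truncated at the physical bound where senesced P would
            # go non-positive given the plot's resorbed-ratio target; a cap
            # below essentially all of the requested NRE distribution means
            # the parameter combination is self-contradictory
            nre_cap = 95.0 * resorbed_t / leaf_np
            if nre_cap < max(1.0, cfg.nre_mean - 3.0 * cfg.nre_sd):
                raise GenerationError(
                    f"plot {plot_id}: omega={omega:.4g}, "
                    f"lambda={cfg.lambda_true:.4g} cap NRE at {nre_cap:.4g}% "
                    f"(< nre_mean - 3*nre_sd) at leaf N:P {leaf_np:.4g}; "
                    "senesced P would be non-positive"
                )
            nre_t = float(np.clip(
                rng_latent.normal(cfg.nre_mean, cfg.nre_sd),
                1.0, min(99.0, nre_cap)))

            # --- species green traits ---
            n_sp = int(rng_survey.integers(cfg.species_per_plot[0],
                                           cfg.species_per_plot[1] + 1))
            shares = rng_survey.dirichlet(np.ones(n_sp))
            total_biomass = (300.0 if shrub else 120.0) * np.exp(
                rng_survey.normal(0.0, 0.2))
            leaf_c = site_c * np.exp(rng_survey.normal(0.0, cfg.species_sigma, n_sp))
            leaf_n = site_n * np.exp(rng_survey.normal(0.0, cfg.species_sigma, n_sp))
            leaf_p_raw = site_p * np.exp(rng_survey.normal(0.0, cfg.species_sigma, n_sp))
            cwm_n = float(shares @ leaf_n)
            # rescale species P so the community ratio matches the latent N:P
            target_cwm_p = cwm_n / leaf_np
            leaf_p = leaf_p_raw * target_cwm_p / float(shares @ leaf_p_raw)
            cwm_p = float(shares @ leaf_p)
            total_inds = int(rng_survey.integers(10, 61)) if shrub else int(
                rng_survey.integers(80, 301))
            density = np.maximum(1, np.rint(shares * total_inds)).astype(int)
            for j in range(n_sp):
                survey_rows.append({
                    "plot_id": plot_id,
                    "species": f"sp_{s_idx + 1}_{j + 1}",
                    "biomass": shares[j] * total_biomass,
                    "density": density[j],
                    "leaf_C": leaf_c[j], "leaf_N": leaf_n[j], "leaf_P": leaf_p[j],
                })

            # --- senesced leaves ---
            ltn_s, ltp_s = backsolve_senesced(cwm_n, cwm_p, nre_t, resorbed_t, mlcf)
            if shrub:
                # species-level litter whose biomass-weighted mean is exact
                jit_n = np.exp(rng_litter.normal(0.0, 0.1, n_sp))
                jit_p = np.exp(rng_litter.normal(0.0, 0.1, n_sp))
                sen_n = ltn_s * jit_n / float(shares @ jit_n)
                sen_p = ltp_s * jit_p / float(shares @ jit_p)
                for j in range(n_sp):
                    litter_rows.append({
                        "plot_id": plot_id, "species": f"sp_{s_idx + 1}_{j + 1}",
                        "senesced_N": sen_n[j], "senesced_P": sen_p[j],
                    })
            else:
                litter_rows.append({
                    "plot_id": plot_id, "species": POOLED_TOKEN,
                    "senesced_N": ltn_s, "senesced_P": ltp_s,
                })

            plot_truth.append({
                "plot_id": plot_id, "elevation": float(elev),
                "soil_NP": float(soil_np), "leaf_NP": float(leaf_np),
                "LTN": cwm_n, "LTP": cwm_p,
                "nre_target": nre_t, "resorbed_np_target": float(resorbed_t),
                "LTN_s": ltn_s, "LTP_s": ltp_s,
                "pre_implied": float((1.0 - ltp_s / cwm_p * mlcf) * 100.0),
            })

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "omega_true": omega,
        "c_homeostasis": float(c_homeo),
        "plots": plot_truth,
    }
    return SyntheticDataset(
        survey=pd.DataFrame(survey_rows),
        litter=pd.DataFrame(litter_rows),
        soil=pd.DataFrame(soil_rows),
        truth=truth,
    )
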
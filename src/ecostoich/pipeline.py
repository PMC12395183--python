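"""End-to-end orchestration: traits -> resorption -> strategy -> homeostasis
-> limitation -> gradient, with a run manifest and a warnings artifact.

Analysis stages are fully deterministic; the only randomness in the package
is the synthetic-data generator, driven by a single config seed.  Warnings
raised anywhere in a run (excluded species, flagged plots, fallbacks) are
collected into ``warnings.csv`` so data exclusions are never silent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community_traits import aggregate_communities
from .gradient import fit_polynomials, select_best
from .homeostasis import classify_limitation, fit_homeostasis
from .io_tables import (
    read_litter_table, read_soil_table, read_survey_table,
    validate_dataset, write_table,
)
from .resorption import community_resorption, control_strategy, InsufficientDataError
from .synthetic_data import SimulationConfig, generate_dataset

logger = logging.getLogger("ecostoich")

DEFAULT_CONFIG = {
    "input": {"survey": None, "litter": None, "soil": None,
              "diversity_weight": "density", "delimiter": None},
    "resorption": {"mlcf": 0.762, "pooling": "auto", "fit_level": "plot"},
    "homeostasis": {"alpha": 0.05, "traits": ["N", "P", "NP"],
                    "scheme": "guesewell_10_20", "pairing": "plot"},
    "gradient": {"criterion": "aicc", "max_order": 3, "aggregate": "plot"},
    "simulate": {},
}

GRADIENT_RESPONSES = [
    "LTC", "LTN", "LTP", "ratio_CN", "ratio_CP", "ratio_NP",
    "shannon", "pielou", "NRE", "PRE", "ratio_NRE_PRE",
    "TN", "TP", "AN", "AP", "SOC", "POC", "MAOC", "pH", "EC", "SWC", "TS",
]


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the package defaults (section-wise)."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.records: list[dict] = []
        self.stage = "setup"

    def emit(self, record):
        self.records.append(
            {"stage": self.stage, "level": record.levelname,
             "message": record.getMessage()}
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _site_means(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return df.groupby("elevation", as_index=False)[cols].mean()


def run_all(
    config: dict | str | Path | None = None,
    out: str | Path = "results",
    simulate: bool = False,
    seed: int | None = None,
) -> dict:
    """Run every analysis stage and write all result tables plus a manifest.

    With ``simulate=True`` (or no input paths configured) a synthetic dataset
    is generated first and written alongside the results.  Returns the run
    manifest; stage failures are recorded there and downstream stages that
    need the failed stage's output are skipped.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    collector = _WarningCollector()
    root = logging.getLogger("ecostoich")
    root.addHandler(collector)

    manifest = {
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "config": cfg,
        "inputs": {},
        "stages": [],
    }
    stages = manifest["stages"]

    def record(name, status, outputs=(), reason=None):
        stages.append({"name": name, "status": status,
                       "outputs": list(outputs), "reason": reason})

    try:
        paths = cfg["input"]
        if simulate or not paths.get("survey"):
            collector.stage = "simulate"
            sim_opts = dict(cfg.get("simulate") or {})
            for key in ("species_per_plot", "elevations", "green_trait_means",
                        "elevation_slopes", "soil_tn_range"):
                if key in sim_opts and sim_opts[key] is not None:
                    sim_opts[key] = tuple(sim_opts[key])
            if seed is not None:
                sim_opts["seed"] = seed
            ds = generate_dataset(SimulationConfig(**sim_opts))
            survey, litter, soil = ds.survey, ds.litter, ds.soil
            for name, df in (("survey", survey), ("litter", litter), ("soil", soil)):
                write_table(df, out / f"{name}.csv")
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(ds.truth, fh, indent=1)
            record("simulate", "completed",
                   ["survey.csv", "litter.csv", "soil.csv", "truth.json"])
            manifest["inputs"] = {f"{n}.csv": _digest(out / f"{n}.csv")
                                  for n in ("survey", "litter", "soil")}
        else:
            delim = paths.get("delimiter")
            survey = read_survey_table(paths["survey"], delimiter=delim)
            litter = read_litter_table(paths["litter"], delimiter=delim) \
                if paths.get("litter") else None
            soil = read_soil_table(paths["soil"], delimiter=delim) \
                if paths.get("soil") else None
            manifest["inputs"] = {
                k: _digest(Path(paths[k]))
                for k in ("survey", "litter", "soil") if paths.get(k)
            }

        collector.stage = "validate"
        report = validate_dataset(survey, litter, soil)
        for msg in report.messages():
            logger.warning(msg)
        record("validate", "completed")

        # --- traits ---
        collector.stage = "traits"
        traits = aggregate_communities(
            survey, soil, diversity_weight=paths.get("diversity_weight", "density"))
        write_table(traits, out / "community_traits.csv")
        record("traits", "completed", ["community_traits.csv"])
    except Exception as exc:  # inputs or traits failed: nothing downstream can run
        record(collector.stage, "failed", reason=str(exc))
        _finalize(manifest, collector, out, root)
        return manifest

    shares_by_plot = {
        pid: dict(zip(grp["species"], grp["biomass"]))
        for pid, grp in survey.groupby("plot_id", sort=False)
    }
    ropts = cfg["resorption"]

    # --- resorption ---
    collector.stage = "resorption"
    resorp_df = None
    if litter is None or litter.empty:
        record("resorption", "skipped", reason="no litter table")
    else:
        try:
            rows = []
            from .community_traits import CommunitySample
            for _, t in traits.iterrows():
                sub = litter[litter["plot_id"] == t["plot_id"]]
                if sub.empty:
                    logger.warning("plot %s: no litter rows; resorption skipped",
                                   t["plot_id"])
                    continue
                green = CommunitySample(**{
                    k: t[k] for k in ("plot_id", "LTC", "LTN", "LTP", "ratio_CN",
                                      "ratio_CP", "ratio_NP", "shannon", "pielou",
                                      "richness", "total_biomass", "elevation")})
                res = community_resorption(
                    green, sub, mlcf=ropts["mlcf"], pooling=ropts["pooling"],
                    biomass_shares=shares_by_plot.get(t["plot_id"]))
                row = asdict(res)
                row["flags"] = ";".join(sorted(row["flags"]))
                row["ratio_NP"] = t["ratio_NP"]
                row["elevation"] = t["elevation"]
                rows.append(row)
            resorp_df = pd.DataFrame(rows)
            write_table(resorp_df.drop(columns=["ratio_NP"]),
                        out / "resorption.csv")
            record("resorption", "completed", ["resorption.csv"])
        except Exception as exc:
            record("resorption", "failed", reason=str(exc))
            resorp_df = None

    # --- strategy ---
    collector.stage = "strategy"
    if resorp_df is None:
        record("strategy", "skipped", reason="resorption stage did not complete")
    else:
        try:
            fit_df = resorp_df
            if ropts.get("fit_level") == "site":
                fit_df = _site_means(resorp_df, ["ratio_NP", "resorbed_NP"])
            strat = control_strategy(fit_df["ratio_NP"], fit_df["resorbed_NP"],
                                     alpha=cfg["homeostasis"]["alpha"])
            sd = asdict(strat)
            sd["lambda_CI_lo"], sd["lambda_CI_hi"] = sd.pop("lambda_CI")
            sd["linear_slope_CI_lo"], sd["linear_slope_CI_hi"] = \
                sd.pop("linear_slope_CI")
            write_table(pd.DataFrame([sd]), out / "control_strategy.csv")
            record("strategy", "completed", ["control_strategy.csv"])
        except InsufficientDataError as exc:
            record("strategy", "failed", reason=str(exc))
        except Exception as exc:
            record("strategy", "failed", reason=str(exc))

    hopts = cfg["homeostasis"]

    # --- homeostasis ---
    collector.stage = "homeostasis"
    if soil is None or soil.empty or soil["TN"].isna().all():
        record("homeostasis", "skipped", reason="no soil table with TN/TP")
    else:
        try:
            merged = traits.merge(soil[["plot_id", "TN", "TP"]], on="plot_id")
            pairs = {
                "N": (merged["TN"], merged["LTN"]),
                "P": (merged["TP"], merged["LTP"]),
                "NP": (merged["TN"] / merged["TP"], merged["ratio_NP"]),
            }
            rows = []
            for trait_name in hopts["traits"]:
                x, y = pairs[trait_name]
                if hopts.get("pairing") == "site":
                    tmp = _site_means(
                        pd.DataFrame({"elevation": merged["elevation"],
                                      "x": x, "y": y}), ["x", "y"])
                    x, y = tmp["x"], tmp["y"]
                res = fit_homeostasis(x, y, alpha=hopts["alpha"], trait=trait_name)
                row = asdict(res)
                row["H"] = row["H"] if math.isfinite(row["H"]) else float("inf")
                rows.append(row)
            write_table(pd.DataFrame(rows), out / "homeostasis.csv")
            record("homeostasis", "completed", ["homeostasis.csv"])
        except Exception as exc:
            record("homeostasis", "failed", reason=str(exc))

    # --- limitation ---
    collector.stage = "limitation"
    try:
        rows = []
        for _, t in traits.iterrows():
            for scheme in ("guesewell_10_20", "koerselman_14_16"):
                call = classify_limitation(t["ratio_NP"], scheme)
                rows.append({"plot_id": t["plot_id"], **asdict(call)})
        write_table(pd.DataFrame(rows), out / "limitation.csv")
        record("limitation", "completed", ["limitation.csv"])
    except Exception as exc:
        record("limitation", "failed", reason=str(exc))

    # --- gradient ---
    collector.stage = "gradient"
    gopts = cfg["gradient"]
    try:
        table = traits.copy()
        if resorp_df is not None:
            table = table.merge(
                resorp_df[["plot_id", "NRE", "PRE", "ratio_NRE_PRE"]],
                on="plot_id", how="left")
        if soil is not None and not soil.empty:
            table = table.merge(soil.drop(columns=["elevation"]),
                                on="plot_id", how="left")
        if table["elevation"].isna().all():
            record("gradient", "skipped", reason="no elevation data")
        else:
            if gopts.get("aggregate") == "site":
                cols = [c for c in GRADIENT_RESPONSES if c in table.columns]
                table = _site_means(table, cols)
            rows = []
            for resp in GRADIENT_RESPONSES:
                if resp not in table.columns:
                    continue
                sub = table[["elevation", resp]].dropna()
                if len(sub) < 3:
                    continue
                fits = fit_polynomials(sub["elevation"], sub[resp],
                                       max_order=gopts["max_order"], response=resp)
                best = select_best(fits, criterion=gopts["criterion"])
                for f in fits:
                    row = asdict(f)
                    row["coefficients"] = ";".join(f"{c!r}" for c in f.coefficients)
                    row["selected"] = f.order == best.order
                    rows.append(row)
            write_table(pd.DataFrame(rows), out / "gradient_fits.csv")
            record("gradient", "completed", ["gradient_fits.csv"])
    except Exception as exc:
        record("gradient", "failed", reason=str(exc))

    _finalize(manifest, collector, out, root)
    return manifest


def _finalize(manifest, collector, out: Path, root_logger) -> None:
    root_logger.removeHandler(collector)
    warn_df = pd.DataFrame(collector.records,
                           columns=["stage", "level", "message"])
    write_table(warn_df, out / "warnings.csv")
    for st in manifest["stages"]:
        if st["name"] == "validate":
            st["outputs"] = []
    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
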
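"""Reading, validation, and writing of the three input tables and result tables.

All tables are delimited text (CSV or TSV, auto-detected), UTF-8, ``.`` decimal.
Concentrations are g/kg throughout; no unit conversion is performed.  Column
names are fixed lower-snake-case; a ``header_map`` option translates user
headers on read.

Pooled litter rows (herbaceous plots where senesced material cannot be sorted
to species) use the reserved species token :data:`POOLED_TOKEN`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

#: Reserved species token marking a community-pooled litter row.
POOLED_TOKEN = "__community__"

SURVEY_REQUIRED = ["plot_id", "species", "biomass", "leaf_C", "leaf_N", "leaf_P"]
SURVEY_OPTIONAL = ["density"]
LITTER_REQUIRED = ["plot_id", "species", "senesced_N", "senesced_P"]
SOIL_REQUIRED = ["plot_id", "elevation", "TN", "TP"]
SOIL_OPTIONAL = ["AN", "AP", "SWC", "pH", "EC", "SOC", "POC", "MAOC", "TS", "MAT", "MAP"]

_NUMERIC = {
    "biomass", "density", "leaf_C", "leaf_N", "leaf_P",
    "senesced_N", "senesced_P",
    "elevation", "TN", "TP", "AN", "AP", "SWC", "pH", "EC",
    "SOC", "POC", "MAOC", "TS", "MAT", "MAP",
}


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample.splitlines()[0] else ","


def _read_table(
    path: str | Path,
    required: Sequence[str],
    optional: Sequence[str] = (),
    delimiter: str | None = None,
    header_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if header_map:
        df = df.rename(columns=dict(header_map))
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    keep = [c for c in list(required) + list(optional) if c in df.columns]
    df = df[keep].copy()
    for col in keep:
        if col not in _NUMERIC:
            continue
        # float() is correctly rounded, unlike pandas' fast parser, so a
        # %.17g write/read cycle is bit-exact
        values = []
        for i, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw == "":
                values.append(float("nan"))
                continue
            try:
                values.append(float(raw))
            except ValueError:
                raise SchemaError(
                    f"{path.name}: non-numeric value {raw!r} in column "
                    f"{col!r} at line {i + 2}"
                ) from None
        df[col] = values
    return df.reset_index(drop=True)


def read_survey_table(path, delimiter=None, header_map=None) -> pd.DataFrame:
    """Read a vegetation-survey table: one row per (plot, species).

    Required columns: plot_id, species, biomass (g/m² or relative share),
    leaf_C, leaf_N, leaf_P (g/kg).  Optional: density (individuals per plot,
    used for diversity weighting when present).
    """
    return _read_table(path, SURVEY_REQUIRED, SURVEY_OPTIONAL, delimiter, header_map)


def read_litter_table(path, delimiter=None, header_map=None) -> pd.DataFrame:
    """Read a senesced-leaf litter table.

    ``species`` may be a species name or :data:`POOLED_TOKEN` for plots where
    litter was pooled at the community level.
    """
    return _read_table(path, LITTER_REQUIRED, (), delimiter, header_map)


def read_soil_table(path, delimiter=None, header_map=None) -> pd.DataFrame:
    """Read a per-plot soil table (TN, TP required; other properties optional)."""
    return _read_table(path, SOIL_REQUIRED, SOIL_OPTIONAL, delimiter, header_map)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with full float precision (round-trip safe)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class ValidationReport:
    """Outcome of cross-table consistency checks.  Empty iff analysis-ready."""

    missing_litter: list = field(default_factory=list)
    missing_soil: list = field(default_factory=list)
    nonpositive_values: list = field(default_factory=list)
    duplicate_keys: list = field(default_factory=list)
    mixed_litter_pooling: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (
            self.missing_litter
            or self.missing_soil
            or self.nonpositive_values
            or self.duplicate_keys
            or self.mixed_litter_pooling
        )

    def messages(self) -> list[str]:
        out = []
        for p in self.missing_litter:
            out.append(f"plot {p}: no litter rows")
        for p in self.missing_soil:
            out.append(f"plot {p}: no soil sample")
        for tbl, col, key in self.nonpositive_values:
            out.append(f"{tbl}: non-positive {col} for {key}")
        for tbl, key in self.duplicate_keys:
            out.append(f"{tbl}: duplicate key {key}")
        for p in self.mixed_litter_pooling:
            out.append(f"plot {p}: litter mixes pooled and species-level rows")
        return out


def validate_dataset(
    survey: pd.DataFrame,
    litter: pd.DataFrame | None = None,
    soil: pd.DataFrame | None = None,
) -> ValidationReport:
    """Cross-check the three tables without mutating them.

    Reports plots lacking litter or soil, non-positive concentrations,
    duplicate (plot, species) keys, and plots whose litter mixes pooled and
    species-level rows.
    """
    rep = ValidationReport()
    plots = list(dict.fromkeys(survey["plot_id"]))

    dup = survey[survey.duplicated(["plot_id", "species"], keep=False)]
    for key in dict.fromkeys(map(tuple, dup[["plot_id", "species"]].to_numpy())):
        rep.duplicate_keys.append(("survey", key))

    for col in ("leaf_C", "leaf_N", "leaf_P"):
        bad = survey[survey[col].notna() & (survey[col] <= 0)]
        for _, r in bad.iterrows():
            rep.nonpositive_values.append(("survey", col, (r["plot_id"], r["species"])))
    bad = survey[survey["biomass"] < 0]
    for _, r in bad.iterrows():
        rep.nonpositive_values.append(("survey", "biomass", (r["plot_id"], r["species"])))

    if litter is not None:
        litter_plots = set(litter["plot_id"])
        rep.missing_litter.extend(p for p in plots if p not in litter_plots)
        for col in ("senesced_N", "senesced_P"):
            bad = litter[litter[col] <= 0]
            for _, r in bad.iterrows():
                rep.nonpositive_values.append(("litter", col, (r["plot_id"], r["species"])))
        dup = litter[litter.duplicated(["plot_id", "species"], keep=False)]
        for key in dict.fromkeys(map(tuple, dup[["plot_id", "species"]].to_numpy())):
            rep.duplicate_keys.append(("litter", key))
        for p, grp in litter.groupby("plot_id", sort=False):
            pooled = grp["species"].eq(POOLED_TOKEN)
            if pooled.any() and (~pooled).any():
                rep.mixed_litter_pooling.append(p)

    if soil is not None:
        soil_plots = set(soil["plot_id"])
        rep.missing_soil.extend(p for p in plots if p not in soil_plots)
        for col in ("TN", "TP"):
            bad = soil[soil[col].notna() & (soil[col] <= 0)]
            for _, r in bad.iterrows():
                rep.nonpositive_values.append(("soil", col, (r["plot_id"],)))
        dup = soil[soil.duplicated(["plot_id"], keep=False)]
        for key in dict.fromkeys(soil.loc[dup.index, "plot_id"]):
            rep.duplicate_keys.append(("soil", (key,)))

    return rep
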
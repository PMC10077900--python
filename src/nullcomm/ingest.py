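"""Reading, validation and filtering of the three input tables.

The pipeline consumes three long/wide CSV tables:

``cover.csv``   plot_id, species_id, stratum, cover   (percentage cover > 0;
                multiple strata of one species may sum above 100)
``species.csv`` species_id, genus, growth_habit, is_hemiparasite, life_history
``plots.csv``   plot_id, latitude, longitude, area_m2, year, park_id, ecoregion_l4

Species are classified into growth forms from their growth-habit label:
herbaceous = {forb/herb, graminoid, subshrub}, woody = {tree, shrub};
anything else is excluded from analysis.  Hemiparasites are always
treated as herbaceous regardless of the habit string.  Plot filtering
keeps plots with coordinates and a single survey area (400 m2 by
default, controlling for the species-area relationship), and collapses
per-stratum covers of the same species into one value per (plot,
species) by summation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "IngestError",
    "ValidationReport",
    "load_tables",
    "classify_growth_form",
    "filter_plots",
    "HERBACEOUS_HABITS",
    "WOODY_HABITS",
]

HERBACEOUS_HABITS = frozenset({"forb/herb", "graminoid", "subshrub"})
WOODY_HABITS = frozenset({"tree", "shrub"})

COVER_COLUMNS = ("plot_id", "species_id", "stratum", "cover")
SPECIES_COLUMNS = ("species_id", "genus", "growth_habit", "is_hemiparasite", "life_history")
PLOTS_COLUMNS = ("plot_id", "latitude", "longitude", "area_m2", "year", "park_id", "ecoregion_l4")


class SchemaError(ValueError):
    """A required column is missing or a table is structurally unusable."""


class IngestError(ValueError):
    """A row-level problem that cannot be repaired (bad value, duplicate key)."""


@dataclass
class ValidationReport:
    """Counts and examples of rows dropped or repaired during ingest."""

    n_cover_rows: int = 0
    n_unknown_plot: int = 0
    n_unknown_species: int = 0
    n_zero_cover: int = 0
    unknown_plot_examples: list = field(default_factory=list)
    unknown_species_examples: list = field(default_factory=list)
    n_species_excluded_habit: int = 0
    n_plots_no_coords: int = 0
    n_plots_wrong_area: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _require_columns(df: pd.DataFrame, required, name: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing required column {col!r}")


def load_tables(cover_path, species_path, plots_path):
    """Read and cross-validate the three CSVs.

    Returns ``(cover, species, plots, report)``.  Cover rows that
    reference unknown plot or species keys are dropped and listed in the
    report; duplicated (plot, species, stratum) rows and non-numeric or
    negative covers are errors.
    """
    cover = pd.read_csv(cover_path, dtype={"plot_id": str, "species_id": str, "stratum": str})
    species = pd.read_csv(species_path, dtype={"species_id": str, "genus": str, "growth_habit": str})
    plots = pd.read_csv(plots_path, dtype={"plot_id": str, "park_id": str, "ecoregion_l4": str})
    _require_columns(cover, COVER_COLUMNS, "cover table")
    _require_columns(species, SPECIES_COLUMNS, "species table")
    _require_columns(plots, PLOTS_COLUMNS, "plots table")

    if species["species_id"].duplicated().any():
        dup = species.loc[species["species_id"].duplicated(), "species_id"].iloc[0]
        raise IngestError(f"species table: duplicate species_id {dup!r}")
    if plots["plot_id"].duplicated().any():
        dup = plots.loc[plots["plot_id"].duplicated(), "plot_id"].iloc[0]
        raise IngestError(f"plots table: duplicate plot_id {dup!r}")

    cover_num = pd.to_numeric(cover["cover"], errors="coerce")
    bad = cover_num.isna() & cover["cover"].notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise IngestError(
            f"cover table, line {i + 2}, column 'cover': "
            f"non-numeric value {cover['cover'].iloc[i]!r}"
        )
    neg = cover_num < 0
    if neg.any():
        i = int(np.flatnonzero(neg.to_numpy())[0])
        raise IngestError(f"cover table, line {i + 2}, column 'cover': negative cover")
    cover = cover.assign(cover=cover_num)

    dup_key = cover.duplicated(subset=["plot_id", "species_id", "stratum"])
    if dup_key.any():
        row = cover.loc[dup_key].iloc[0]
        raise IngestError(
            "cover table: duplicate (plot_id, species_id, stratum) = "
            f"({row.plot_id!r}, {row.species_id!r}, {row.stratum!r})"
        )

    lat = pd.to_numeric(plots["latitude"], errors="coerce")
    lon = pd.to_numeric(plots["longitude"], errors="coerce")
    if ((lat.abs() > 90) | (lon.abs() > 180)).any():
        raise IngestError("plots table: coordinates outside valid WGS84 range")
    if (pd.to_numeric(plots["area_m2"], errors="coerce") <= 0).any():
        raise IngestError("plots table: non-positive plot area")
    plots = plots.assign(latitude=lat, longitude=lon)

    report = ValidationReport(n_cover_rows=len(cover))
    known_plots = set(plots["plot_id"])
    known_species = set(species["species_id"])
    unk_p = ~cover["plot_id"].isin(known_plots)
    unk_s = ~cover["species_id"].isin(known_species)
    report.n_unknown_plot = int(unk_p.sum())
    report.n_unknown_species = int(unk_s.sum())
    report.unknown_plot_examples = cover.loc[unk_p, "plot_id"].head(5).tolist()
    report.unknown_species_examples = cover.loc[unk_s, "species_id"].head(5).tolist()
    zero = cover["cover"].fillna(0) <= 0
    report.n_zero_cover = int(zero.sum())
    cover = cover.loc[~(unk_p | unk_s | zero)].reset_index(drop=True)

    species = species.assign(is_hemiparasite=species["is_hemiparasite"].astype(bool))
    return cover, species, plots, report


def classify_growth_form(species: pd.DataFrame, report: ValidationReport | None = None) -> pd.DataFrame:
    """Attach a ``growth_form`` column: herbaceous / woody / excluded.

    Habit strings are matched case-insensitively after trimming; for
    multi-valued habit strings ("Forb/herb, Subshrub") the first listed
    habit decides.  Hemiparasites are forced to herbaceous whatever the
    habit string says.
    """
    habit = (
        species["growth_habit"]
        .fillna("")
        .astype(str)
        .str.split(",")
        .str[0]
        .str.strip()
        .str.lower()
    )
    form = np.where(
        habit.isin(HERBACEOUS_HABITS),
        "herbaceous",
        np.where(habit.isin(WOODY_HABITS), "woody", "excluded"),
    )
    out = species.assign(growth_form=form)
    out.loc[out["is_hemiparasite"], "growth_form"] = "herbaceous"
    if report is not None:
        report.n_species_excluded_habit = int((out["growth_form"] == "excluded").sum())
    return out


def filter_plots(
    plots: pd.DataFrame,
    cover: pd.DataFrame,
    area_keep: float = 400.0,
    report: ValidationReport | None = None,
):
    """Keep plots with coordinates and area exactly ``area_keep`` m2.

    The surviving cover table has per-stratum covers of the same species
    summed into a single (plot, species) row; the stratum column is
    dropped.  Idempotent: a second application is a no-op.
    """
    if area_keep <= 0:
        raise ValueError("area_keep must be positive")
    has_coords = plots["latitude"].notna() & plots["longitude"].notna()
    right_area = plots["area_m2"] == area_keep
    if report is not None:
        report.n_plots_no_coords = int((~has_coords).sum())
        report.n_plots_wrong_area = int((has_coords & ~right_area).sum())
    kept = plots.loc[has_coords & right_area].reset_index(drop=True)
    if kept.empty:
        raise IngestError("no plots survive filters (coordinates present, area == area_keep)")
    cover = cover.loc[cover["plot_id"].isin(set(kept["plot_id"]))]
    cover = (
        cover.groupby(["plot_id", "species_id"], as_index=False, sort=False)["cover"]
        .sum()
    )
    return kept, cover
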
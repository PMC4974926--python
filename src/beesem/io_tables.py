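"""Typed CSV I/O for the three field-data schemas (nests, sites, pollen).

The on-disk column names follow the published supplementary files of the
trap-nest study this package models (Spanish abbreviations such as
``codigo.i`` for the bee species code); internally every table carries
canonical English column names.  The mapping lives in a schema registry
that callers may extend, so files with renamed headers can still be read.

A fourth, package-native schema (``weekly``) stores the week-by-week
per-plant-species flower counts that the site-level aggregates are
computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, TableValidationError

# external (file) name -> canonical name, in documented column order
SCHEMA_REGISTRY: dict[str, dict[str, str]] = {
    "nests": {
        "codigo.i": "bee_species",
        "sitio": "site",
        "mean.no.celd": "mean_cells_per_nest",
        "celd.tot": "total_cells",
        "nidos.tot": "total_nests",
    },
    "sites": {
        "sitio": "site",
        "abund.flores": "flower_abundance",
        "raref": "flower_richness_rarefied",
        "altitud": "elevation",
        "anio.q": "years_since_fire",
    },
    "pollen": {
        "id.trampa": "bee_individual",
        "codigo.i": "bee_species",
        "site": "site",
        "codigo.p": "plant_species",
        "sum.sp": "grains_of_species",
        "sum.tot": "grains_total",
        "prop": "proportion",
    },
    "weekly": {
        "site": "site",
        "week": "week",
        "plant.species": "plant_species",
        "flowers": "flowers",
    },
}

_NUMERIC_COLUMNS: dict[str, dict[str, type]] = {
    "nests": {"mean_cells_per_nest": float, "total_cells": int, "total_nests": int},
    "sites": {
        "flower_abundance": float,
        "flower_richness_rarefied": float,
        "elevation": float,
        "years_since_fire": float,
    },
    "pollen": {"grains_of_species": int, "grains_total": int, "proportion": float},
    "weekly": {"week": int, "flowers": int},
}

#: default plausible elevation band (m a.s.l.) used during validation
ELEVATION_BOUNDS = (0.0, 7000.0)


@dataclass
class _Table:
    """A validated table: canonical columns plus preserved extras."""

    data: pd.DataFrame
    extras: pd.DataFrame = field(default_factory=pd.DataFrame)

    schema: str = ""  # overridden by subclasses

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, _Table):
            return NotImplemented

        def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
            if len(a) == 0 and len(b) == 0:  # dtype of empty columns is moot
                return list(a.columns) == list(b.columns)
            return a.reset_index(drop=True).equals(b.reset_index(drop=True))

        return (self.schema == other.schema
                and frames_equal(self.data, other.data)
                and frames_equal(self.extras, other.extras))


@dataclass(eq=False)
class NestTable(_Table):
    """Per (bee species, site) reproduction summary.

    ``total_nests == 0`` encodes absence of a species from a site; the
    mean brood cells per nest is then undefined (NaN), never zero.
    """

    schema: str = "nests"

    def validate(self, mean_tolerance: float = 0.5) -> "NestTable":
        d = self.data
        dup = d.duplicated(subset=["bee_species", "site"])
        if dup.any():
            raise TableValidationError(
                f"duplicate (bee_species, site) pair at row {int(np.flatnonzero(dup)[0])}"
            )
        if (d["total_cells"] < 0).any() or (d["total_nests"] < 0).any():
            raise TableValidationError("negative cell or nest count")
        absent = d["total_nests"] == 0
        if (d.loc[absent, "total_cells"] != 0).any():
            raise TableValidationError("total_cells > 0 at a site with zero nests")
        if d.loc[absent, "mean_cells_per_nest"].notna().any():
            raise TableValidationError(
                "mean_cells_per_nest must be absent where total_nests = 0"
            )
        present = d["total_nests"] > 0
        has_mean = present & d["mean_cells_per_nest"].notna()
        implied = d.loc[has_mean, "total_cells"] / d.loc[has_mean, "total_nests"]
        off = (d.loc[has_mean, "mean_cells_per_nest"] - implied).abs() > mean_tolerance
        if off.any():
            row = int(off[off].index[0])
            raise TableValidationError(
                f"mean_cells_per_nest inconsistent with totals at row {row}"
            )
        if (d.loc[has_mean, "mean_cells_per_nest"] < 0).any():
            raise TableValidationError("negative mean_cells_per_nest")
        return self


@dataclass(eq=False)
class SiteTable(_Table):
    """Per-site environment and season-aggregate floral metrics."""

    schema: str = "sites"

    def validate(self, elevation_bounds: tuple[float, float] = ELEVATION_BOUNDS) -> "SiteTable":
        d = self.data
        dup = d.duplicated(subset=["site"])
        if dup.any():
            raise TableValidationError(
                f"duplicate site label at row {int(np.flatnonzero(dup)[0])}"
            )
        lo, hi = elevation_bounds
        bad = (d["elevation"] < lo) | (d["elevation"] > hi)
        if bad.any():
            raise TableValidationError(
                f"elevation outside plausible range {elevation_bounds} at row "
                f"{int(np.flatnonzero(bad)[0])}"
            )
        if (d["years_since_fire"] < 0).any():
            raise TableValidationError("negative years_since_fire")
        if (d["flower_abundance"] < 0).any():
            raise TableValidationError("negative flower_abundance")
        if (d["flower_richness_rarefied"] < 0).any():
            raise TableValidationError("negative flower_richness_rarefied")
        return self


@dataclass(eq=False)
class PollenTable(_Table):
    """Pollen grain counts per bee individual and plant species."""

    schema: str = "pollen"

    def validate(self, proportion_tolerance: float = 0.02) -> "PollenTable":
        d = self.data
        if (d["grains_of_species"] < 0).any() or (d["grains_total"] < 0).any():
            raise TableValidationError("negative grain count")
        if (d["grains_of_species"] > d["grains_total"]).any():
            raise TableValidationError("grains_of_species exceeds grains_total")
        bad = (d["proportion"] < 0) | (d["proportion"] > 1)
        if bad.any():
            raise TableValidationError(
                f"proportion outside [0, 1] at row {int(np.flatnonzero(bad)[0])}"
            )
        with np.errstate(invalid="ignore"):
            implied = d["grains_of_species"] / d["grains_total"].replace(0, np.nan)
        off = (d["proportion"] - implied.fillna(d["proportion"])).abs() > proportion_tolerance
        if off.any():
            raise TableValidationError(
                f"proportion inconsistent with grain counts at row "
                f"{int(np.flatnonzero(off.to_numpy())[0])}"
            )
        for ind, grp in d.groupby("bee_individual"):
            totals = grp["grains_total"].unique()
            if len(totals) != 1:
                raise TableValidationError(
                    f"bee individual {ind!r} reports multiple grains_total values"
                )
            if grp["grains_of_species"].sum() != totals[0]:
                raise TableValidationError(
                    f"grain counts of bee individual {ind!r} do not sum to grains_total"
                )
            if abs(grp["proportion"].sum() - 1.0) > proportion_tolerance * max(len(grp), 1):
                raise TableValidationError(
                    f"proportions of bee individual {ind!r} do not sum to 1"
                )
        return self


@dataclass(eq=False)
class WeeklyTable(_Table):
    """Long-format weekly flower counts per plant species and site."""

    schema: str = "weekly"

    def validate(self) -> "WeeklyTable":
        d = self.data
        if (d["flowers"] < 0).any():
            raise TableValidationError("negative weekly flower count")
        dup = d.duplicated(subset=["site", "week", "plant_species"])
        if dup.any():
            raise TableValidationError(
                f"duplicate (site, week, plant_species) at row {int(np.flatnonzero(dup)[0])}"
            )
        return self


_TABLE_CLASSES = {
    "nests": NestTable,
    "sites": SiteTable,
    "pollen": PollenTable,
    "weekly": WeeklyTable,
}


def _coerce_numeric(frame: pd.DataFrame, schema: str) -> pd.DataFrame:
    for col, kind in _NUMERIC_COLUMNS[schema].items():
        raw = frame[col]
        values = []
        # python float() rather than pd.to_numeric: the latter's fast
        # parser is not round-trip exact for every float64
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() == "":
                values.append(np.nan)
                continue
            try:
                values.append(float(str(cell)))
            except ValueError:
                raise SchemaError(
                    f"non-numeric value {cell!r} in column {col!r} at row {i}"
                ) from None
        converted = pd.Series(values, index=raw.index, dtype=float)
        if kind is int:
            if converted.notna().all() and not np.allclose(converted % 1, 0):
                row = int(np.flatnonzero((converted % 1 != 0).to_numpy())[0])
                raise SchemaError(f"non-integer value in column {col!r} at row {row}")
            frame[col] = converted.astype("int64") if converted.notna().all() else converted
        else:
            frame[col] = converted.astype(float)
    return frame


def read_table(path, schema: str, registry: dict[str, str] | None = None,
               validate: bool = True) -> _Table:
    """Read and validate one of the documented CSV schemas.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row.
    schema : {"nests", "sites", "pollen", "weekly"}
    registry : optional mapping of file column name -> canonical name,
        overriding/extending the built-in registry for this schema.
    validate : run the table invariants after parsing (default).
    """
    if schema not in SCHEMA_REGISTRY:
        raise SchemaError(f"unknown schema {schema!r}")
    mapping = dict(SCHEMA_REGISTRY[schema])
    if registry:
        mapping.update(registry)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    rename = {ext: canon for ext, canon in mapping.items() if ext in raw.columns}
    frame = raw.rename(columns=rename)
    canonical = list(dict.fromkeys(mapping.values()))
    missing = [c for c in canonical if c not in frame.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing mandatory column(s) {missing}")
    extras = frame[[c for c in frame.columns if c not in canonical]].copy()
    frame = _coerce_numeric(frame[canonical].copy(), schema)
    table = _TABLE_CLASSES[schema](data=frame, extras=extras)
    if validate:
        table.validate()
    return table


def write_table(table: _Table, path) -> None:
    """Write a table back to CSV using the documented external header names.

    Round-trips: ``read_table(write_table(t), t.schema) == t``.
    """
    mapping = SCHEMA_REGISTRY[table.schema]
    inverse = {canon: ext for ext, canon in mapping.items()}
    out = table.data.rename(columns=inverse)
    out = out[[ext for ext in mapping if ext in out.columns]]
    if len(table.extras.columns):
        out = pd.concat([out.reset_index(drop=True),
                         table.extras.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


def make_table(frame: pd.DataFrame, schema: str, validate: bool = True) -> _Table:
    """Wrap an in-memory frame (canonical column names) as a typed table."""
    canonical = list(dict.fromkeys(SCHEMA_REGISTRY[schema].values()))
    missing = [c for c in canonical if c not in frame.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing mandatory column(s) {missing}")
    extras = frame[[c for c in frame.columns if c not in canonical]].copy()
    table = _TABLE_CLASSES[schema](data=frame[canonical].copy(), extras=extras)
    if validate:
        table.validate()
    return table
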
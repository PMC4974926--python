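"""Synthetic field data with the causal and sampling structure the
analysis assumes.

The generator emulates a trap-nesting bee study along an arid-land
elevation gradient: a handful of sites (default 14, spanning
1,100-1,500 m), weekly flower counts per plant species across a
flowering season, per-nest brood-cell records for a set of focal bee
species (default 7), and pollen grain counts per bee individual.

Site-level variables follow a standardized linear Gaussian causal
model: every variable is built, in topological order, as the configured
linear combination of its parents plus Gaussian noise whose variance is
calibrated so each variable has unit variance — the configured edge
coefficients are therefore standardized effects.  Default effect sizes
mirror those observed in the field study the package models.  Counts
are layered on top: nest numbers per species and site are Poisson with
a log-rate driven by the latent site productivity, brood cells per nest
are shifted Poisson, and pollen loads are multinomial over a
species-specific diet drawn from a Dirichlet whose concentration sets
the diet breadth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .causal_engine import CausalModel, Edge
from .errors import ConfigError
from .floral_metrics import WeeklyFloralSeries, rarefied_richness, temporal_stability
from .io_tables import NestTable, PollenTable, SiteTable, make_table
from .models import (ABUNDANCE, ELEVATION, FIRE, RESPONSES, RICHNESS,
                     STABILITY, complete_model)


def default_site_model() -> CausalModel:
    """One DAG holding all three reproductive responses with the full
    upstream structure (elevation, fire, abundance, richness, stability)."""
    edges: list[Edge] = []
    for resp in RESPONSES:
        for e in complete_model(resp).edges:
            if e not in edges:
                edges.append(e)
    return CausalModel(
        name="generator",
        variables=(ELEVATION, FIRE, ABUNDANCE, RICHNESS, STABILITY, *RESPONSES),
        edges=tuple(edges),
    )


#: standardized generating effects; magnitudes follow the field estimates
DEFAULT_COEFFICIENTS: dict[Edge, float] = {
    (ELEVATION, RICHNESS): 0.39,
    (ELEVATION, ABUNDANCE): -0.51,
    (RICHNESS, STABILITY): -0.54,
    (ELEVATION, "mean_cells"): -0.20,
    (ABUNDANCE, "mean_cells"): 0.05,
    (RICHNESS, "mean_cells"): 0.15,
    (STABILITY, "mean_cells"): -0.30,
    (FIRE, "mean_cells"): 0.05,
    (ELEVATION, "total_cells"): -0.59,
    (ABUNDANCE, "total_cells"): 0.26,
    (RICHNESS, "total_cells"): 0.27,
    (STABILITY, "total_cells"): 0.35,
    (FIRE, "total_cells"): 0.35,
    (ELEVATION, "total_nests"): -0.57,
    (ABUNDANCE, "total_nests"): 0.24,
    (RICHNESS, "total_nests"): 0.38,
    (STABILITY, "total_nests"): 0.30,
    (FIRE, "total_nests"): 0.45,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults emulate the field design."""

    n_sites: int = 14
    elevation_range: tuple[float, float] = (1100.0, 1500.0)
    fire_range: tuple[float, float] = (1.0, 40.0)
    weeks: int = 8
    n_bee_species: int = 7
    n_plant_species: int = 15
    site_model: CausalModel = field(default_factory=default_site_model)
    coefficients: dict[Edge, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    # natural-scale affine maps for the continuous site variables
    richness_mean: float = 8.0
    richness_sd: float = 1.8
    abundance_mean: float = 2000.0
    abundance_sd: float = 450.0
    stability_mean: float = 2.5
    stability_sd: float = 0.5
    # count layers
    nests_per_site_intensity: float = 4.0
    nest_link_scale: float = 0.5
    cells_per_nest_mean: float = 4.0
    cell_link_scale: float = 0.3
    species_intensity_sd: float = 0.3
    # pollen layer
    grains_per_individual: int = 300
    max_individuals_per_species: int = 40
    diet_concentration_range: tuple[float, float] = (0.08, 2.0)
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_sites < 3:
            raise ConfigError("need at least 3 sites")
        if self.weeks < 2:
            raise ConfigError("need at least 2 weeks for a stability target")
        if self.stability_mean - 3 * self.stability_sd <= 0:
            raise ConfigError("stability distribution puts mass at CV <= 0")
        for bound in (self.nests_per_site_intensity, self.grains_per_individual):
            if bound < 0:
                raise ConfigError("rates must be non-negative")
        if self.cells_per_nest_mean < 1:
            raise ConfigError("cells per nest must average >= 1")
        standardized_noise_variances(self.site_model, self.coefficients)
        return self


def standardized_noise_variances(model: CausalModel,
                                 coefficients: dict[Edge, float]) -> dict[str, float]:
    """Noise variances giving every variable unit marginal variance.

    Walks the DAG in topological order, tracking the implied covariance
    of the standardized system; each variable's noise variance is
    1 - var(linear predictor).  Raises if any implied R-squared >= 1
    (the standardized system would be infeasible).
    """
    order = list(nx.topological_sort(model.graph()))
    cov = pd.DataFrame(0.0, index=order, columns=order)
    noise: dict[str, float] = {}
    for v in order:
        parents = model.parents(v)
        b = np.array([coefficients.get((p, v), 0.0) for p in parents])
        if parents:
            sub = cov.loc[list(parents), list(parents)].to_numpy()
            var_pred = float(b @ sub @ b)
        else:
            var_pred = 0.0
        if var_pred > 1.0 + 1e-9:
            raise ConfigError(
                f"variable {v!r}: implied R-squared {var_pred:.3f} > 1; "
                "shrink the coefficients")
        noise[v] = max(1.0 - var_pred, 0.0)
        for u in order:
            if u == v:
                break
            cov.loc[v, u] = cov.loc[u, v] = float(
                b @ cov.loc[list(parents), u].to_numpy()) if parents else 0.0
        cov.loc[v, v] = 1.0
    return noise


def _site_labels(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _bee_labels(n: int) -> list[str]:
    return [f"Bee{i + 1:02d}" for i in range(n)]


def _plant_labels(n: int) -> list[str]:
    return [f"Plant{i + 1:02d}" for i in range(n)]


def generate_site_frame(config: GeneratorConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Standardized site-level draws from the configured causal model.

    Returns one row per site with the exogenous drivers on their natural
    scale (elevation in m, years since fire) plus every model variable
    as a standardized column (``z_*``).  Elevation and fire are uniform
    on their ranges and standardized by their theoretical moments, so
    the configured standardized effects apply exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_sites
    lo_e, hi_e = config.elevation_range
    lo_f, hi_f = config.fire_range
    elevation = rng.uniform(lo_e, hi_e, n)
    fire = rng.uniform(lo_f, hi_f, n)
    z: dict[str, np.ndarray] = {
        ELEVATION: (elevation - (lo_e + hi_e) / 2) / ((hi_e - lo_e) / np.sqrt(12)),
        FIRE: (fire - (lo_f + hi_f) / 2) / ((hi_f - lo_f) / np.sqrt(12)),
    }
    noise = standardized_noise_variances(config.site_model, config.coefficients)
    for v in nx.topological_sort(config.site_model.graph()):
        if v in z:
            continue
        parents = config.site_model.parents(v)
        pred = np.zeros(n)
        for p in parents:
            pred += config.coefficients.get((p, v), 0.0) * z[p]
        z[v] = pred + np.sqrt(noise[v]) * rng.standard_normal(n)
    frame = pd.DataFrame({
        "site": _site_labels(n),
        "elevation": elevation,
        "years_since_fire": fire,
    })
    for v, vals in z.items():
        frame[f"z_{v}"] = vals
    # natural-scale floral variables (affine maps of the z columns)
    if f"z_{RICHNESS}" in frame:
        frame["flower_richness"] = np.maximum(
            1.0, config.richness_mean + config.richness_sd * frame[f"z_{RICHNESS}"])
    if f"z_{ABUNDANCE}" in frame:
        frame["flower_abundance"] = np.maximum(
            50.0, config.abundance_mean + config.abundance_sd * frame[f"z_{ABUNDANCE}"])
    if f"z_{STABILITY}" in frame:
        frame["stability"] = np.maximum(
            0.3, config.stability_mean + config.stability_sd * frame[f"z_{STABILITY}"])
    return frame


def generate_sites(config: GeneratorConfig, seed: int | None = None
                   ) -> tuple[SiteTable, dict[str, WeeklyFloralSeries], pd.DataFrame]:
    """Site table plus weekly per-plant-species flower counts.

    Each site's seasonal flower total is split over the weeks with a
    symmetric Dirichlet whose concentration is tuned so the expected
    weekly coefficient of variation matches the site's stability target
    (stability = 1 / CV); the weekly totals are then spread over the
    plant species present at the site (their number tracks the site's
    richness draw) with a multinomial.
    """
    frame = generate_site_frame(config, seed=seed)
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    weeks = config.weeks
    plants = _plant_labels(config.n_plant_species)
    series: dict[str, WeeklyFloralSeries] = {}
    weekly_rows = []
    for _, row in frame.iterrows():
        target_cv = 1.0 / row["stability"]
        # symmetric Dirichlet over W weeks: CV(p) = sqrt((W-1)/(alpha*W+1))
        alpha = max(((weeks - 1) / target_cv**2 - 1.0) / weeks, 0.05)
        p_weeks = rng.dirichlet(np.full(weeks, alpha))
        season_total = int(round(row["flower_abundance"] * weeks))
        weekly_totals = rng.multinomial(season_total, p_weeks)
        n_present = int(np.clip(round(row["flower_richness"]), 2,
                                config.n_plant_species))
        present = rng.choice(config.n_plant_species, size=n_present, replace=False)
        p_plants = rng.dirichlet(np.ones(n_present))
        counts = np.zeros((weeks, n_present), dtype=np.int64)
        for w in range(weeks):
            counts[w] = rng.multinomial(weekly_totals[w], p_plants)
        per_species = pd.DataFrame(counts, columns=[plants[i] for i in present])
        series[row["site"]] = WeeklyFloralSeries(
            site=row["site"], weeks=tuple(range(1, weeks + 1)),
            abundance=tuple(float(t) for t in weekly_totals),
            per_species_counts=per_species,
        )
        for w in range(weeks):
            for j, plant in enumerate(per_species.columns):
                weekly_rows.append({"site": row["site"], "week": w + 1,
                                    "plant_species": plant,
                                    "flowers": int(counts[w, j])})
    # realized metrics recomputed from the drawn series
    totals = {s: int(sum(ser.abundance)) for s, ser in series.items()}
    depth = min(totals.values())
    site_rows = []
    for _, row in frame.iterrows():
        ser = series[row["site"]]
        site_rows.append({
            "site": row["site"],
            "flower_abundance": float(np.mean(ser.abundance)),
            "flower_richness_rarefied": rarefied_richness(ser.total_counts, depth),
            "elevation": float(row["elevation"]),
            "years_since_fire": float(row["years_since_fire"]),
        })
    site_table = make_table(pd.DataFrame(site_rows), "sites")
    frame = frame.merge(
        pd.DataFrame([{"site": s, "realized_stability": temporal_stability(ser)}
                      for s, ser in series.items()]), on="site")
    return site_table, series, frame


def generate_nests(config: GeneratorConfig, site_frame: pd.DataFrame,
                   seed: int | None = None
                   ) -> tuple[pd.DataFrame, NestTable]:
    """Per-nest brood-cell records and their per (species, site) summary.

    Nest counts per species and site are Poisson with log-rate
    ``log(intensity) + species effect + nest_link_scale * z_total_nests``;
    brood cells per nest are 1 + Poisson with log-mean shifted by
    ``cell_link_scale * z_mean_cells``.  Both latent drivers come from
    the site-level causal draw, so the configured (negative) elevation
    effects propagate into the counts.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    species = _bee_labels(config.n_bee_species)
    sp_effect = rng.normal(0.0, config.species_intensity_sd, len(species))
    records = []
    base_cells = max(config.cells_per_nest_mean - 1.0, 1e-6)
    for j, sp in enumerate(species):
        for _, row in site_frame.iterrows():
            lam = config.nests_per_site_intensity * np.exp(
                sp_effect[j] + config.nest_link_scale * row["z_total_nests"])
            n_nests = rng.poisson(lam)
            if n_nests == 0:
                continue
            cell_mean = base_cells * np.exp(
                config.cell_link_scale * row["z_mean_cells"])
            cells = 1 + rng.poisson(cell_mean, n_nests)
            for c in cells:
                records.append({"bee_species": sp, "site": row["site"],
                                "cells": int(c)})
    rec_frame = pd.DataFrame(records, columns=["bee_species", "site", "cells"])
    from .bee_metrics import reproduction_summaries
    all_sites = list(site_frame["site"])
    if len(rec_frame):
        table = reproduction_summaries(rec_frame, sites=all_sites)
    else:
        table = make_table(pd.DataFrame(columns=[
            "bee_species", "site", "mean_cells_per_nest",
            "total_cells", "total_nests"]), "nests", validate=False)
    return rec_frame, table


def generate_pollen(config: GeneratorConfig, nest_records: pd.DataFrame,
                    seed: int | None = None) -> PollenTable:
    """Pollen grain counts per sampled bee individual.

    Each bee species gets a diet distribution over the plant pool drawn
    from a symmetric Dirichlet; the concentration increases across the
    species list over ``diet_concentration_range``, giving a specialist
    -> generalist gradient.  One individual is sampled per nest (capped
    per species); its grain counts are multinomial over the species
    diet.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    species = list(dict.fromkeys(nest_records["bee_species"]))
    plants = _plant_labels(config.n_plant_species)
    lo, hi = config.diet_concentration_range
    conc = np.geomspace(lo, hi, max(len(species), 2))[:len(species)]
    diets = {sp: rng.dirichlet(np.full(config.n_plant_species, conc[j]))
             for j, sp in enumerate(species)}
    rows = []
    counter = 0
    for sp in species:
        nests = nest_records[nest_records["bee_species"] == sp]
        take = min(len(nests), config.max_individuals_per_species)
        sampled = nests.sample(n=take, random_state=int(rng.integers(2**31 - 1)))
        for _, nest in sampled.iterrows():
            counter += 1
            ind = f"I{counter:05d}"
            total = max(int(rng.poisson(config.grains_per_individual)), 10)
            counts = rng.multinomial(total, diets[sp])
            for k in np.flatnonzero(counts):
                rows.append({
                    "bee_individual": ind, "bee_species": sp,
                    "site": nest["site"], "plant_species": plants[k],
                    "grains_of_species": int(counts[k]),
                    "grains_total": total,
                    "proportion": counts[k] / total,
                })
    frame = pd.DataFrame(rows, columns=[
        "bee_individual", "bee_species", "site", "plant_species",
        "grains_of_species", "grains_total", "proportion"])
    return make_table(frame, "pollen", validate=bool(len(frame)))


@dataclass(frozen=True)
class SyntheticDataset:
    site_table: SiteTable
    weekly_series: dict[str, WeeklyFloralSeries]
    site_frame: pd.DataFrame
    nest_records: pd.DataFrame
    nest_table: NestTable
    pollen_table: PollenTable
    config: GeneratorConfig


def generate_dataset(config: GeneratorConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """One full synthetic study: sites, weekly flowers, nests, pollen."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    site_table, series, frame = generate_sites(config)
    nest_records, nest_table = generate_nests(config, frame)
    pollen = generate_pollen(config, nest_records)
    return SyntheticDataset(site_table=site_table, weekly_series=series,
                            site_frame=frame, nest_records=nest_records,
                            nest_table=nest_table, pollen_table=pollen,
                            config=config)


def example_nest_counts() -> pd.Series:
    """Occupied trap-nest totals of an 11-species cavity-nesting bee
    assemblage surveyed in a Monte desert reserve (one flowering season,
    14 sites); the canonical small fixture for the focal-species filter.
    """
    counts = {
        "Anthidium andinum": 6,
        "Anthidium decaspilum": 54,
        "Anthidium rubripes": 31,
        "Anthidium vigintipunctatum": 39,
        "Megachile leucographa": 222,
        "Megachile sp. C": 17,
        "Megachile ctenophora": 74,
        "Mourecotelles triciliatus": 3,
        "Trichothurgus laticeps": 59,
        "Xylocopa atamisquensis": 88,
        "Xylocopa splendidula": 5,
    }
    return pd.Series(counts, name="occupied_trap_nests")
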
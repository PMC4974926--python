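"""Bee reproduction summaries and diet-generalization indices.

Reproduction is proxied three ways per species and site: the mean number
of brood cells per nest (defined only where the species nested), the
total brood cells, and the total occupied nests (absence counts as zero
for the totals).  Species entering the cross-species analyses must clear
a minimum nest count; the study default is 30 nests over all sites.

Diet generalization per bee species is measured on pooled pollen-load
counts as the rarefied diet degree (expected number of plant species in
a fixed-size grain subsample, analytic hypergeometric form) and the
rarefied inverse Simpson diversity (1 / sum p_i^2, Monte-Carlo mean over
hypergeometric subsamples since no simple closed form exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .floral_metrics import rarefied_richness
from .io_tables import NestTable, PollenTable, make_table

#: minimum occupied nests for a species to enter cross-species analyses
MIN_NESTS_DEFAULT = 30


def reproduction_summaries(raw_nests: pd.DataFrame,
                           sites: list[str] | None = None) -> NestTable:
    """Aggregate per-nest records into per (species, site) summaries.

    ``raw_nests`` needs columns ``bee_species``, ``site``, ``cells``
    (one row per occupied nest).  Every species is reported at every
    site in ``sites`` (default: the sites present in the records);
    species-absent combinations get zero totals and an undefined mean.
    """
    if (raw_nests["cells"] < 0).any():
        raise DomainError("negative brood-cell count in nest records")
    species = list(dict.fromkeys(raw_nests["bee_species"]))
    if sites is None:
        sites = list(dict.fromkeys(raw_nests["site"]))
    grouped = raw_nests.groupby(["bee_species", "site"])["cells"]
    agg = grouped.agg(total_cells="sum", total_nests="count",
                      mean_cells_per_nest="mean")
    rows = []
    for sp in species:
        for site in sites:
            if (sp, site) in agg.index:
                rec = agg.loc[(sp, site)]
                rows.append({
                    "bee_species": sp, "site": site,
                    "mean_cells_per_nest": float(rec["mean_cells_per_nest"]),
                    "total_cells": int(rec["total_cells"]),
                    "total_nests": int(rec["total_nests"]),
                })
            else:
                rows.append({
                    "bee_species": sp, "site": site,
                    "mean_cells_per_nest": np.nan,
                    "total_cells": 0, "total_nests": 0,
                })
    return make_table(pd.DataFrame(rows), "nests")


def pollen_length_proxy(occupied_length: float, length_per_cell: float = 1.0) -> float:
    """Convert occupied trap-cavity length (mm) into brood-cell equivalents.

    Used for species that provision a bare pollen mass instead of
    discrete brood cells; with the default conversion of 1.0 the raw
    length itself serves as the (relative) reproduction response.
    """
    if length_per_cell <= 0:
        raise DomainError("length_per_cell must be positive")
    if occupied_length < 0:
        raise DomainError("negative occupied length")
    return float(occupied_length) / float(length_per_cell)


def filter_focal_species(nest_counts: dict[str, int] | pd.Series,
                         min_nests: int = MIN_NESTS_DEFAULT) -> list[str]:
    """Species whose total occupied nests reach ``min_nests``, input order kept."""
    if min_nests < 0:
        raise DomainError("min_nests must be non-negative")
    items = nest_counts.items() if hasattr(nest_counts, "items") else nest_counts
    return [sp for sp, n in items if n >= min_nests]


def rarefied_degree(pollen_counts, n: int) -> float:
    """Expected number of plant species in a random subsample of ``n`` grains.

    Same hypergeometric expectation as floral rarefaction, applied to a
    bee species' pooled pollen-load counts.
    """
    return rarefied_richness(pollen_counts, n)


@dataclass(frozen=True)
class RarefiedSimpson:
    """Monte-Carlo rarefied inverse Simpson diversity with its standard error."""

    value: float
    se: float
    reps: int
    depth: int


def inverse_simpson(counts) -> float:
    """1 / sum p_i^2 on a count vector (effective number of plant species)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DomainError("all-zero counts")
    p = counts / total
    return float(1.0 / np.sum(p * p))


def rarefied_simpson(pollen_counts, n: int, reps: int = 1000,
                     seed: int | np.random.Generator = 0) -> RarefiedSimpson:
    """Monte-Carlo mean inverse Simpson over hypergeometric subsamples of size n.

    Each replicate draws ``n`` grains without replacement from the pooled
    counts (multivariate hypergeometric) and evaluates 1 / sum p_i^2 on
    the subsample; the estimate is the mean over ``reps`` replicates and
    is reproducible given ``seed``.
    """
    counts = np.asarray(pollen_counts, dtype=np.int64)
    if (counts < 0).any():
        raise DomainError("negative pollen counts")
    counts = counts[counts > 0]
    total = int(counts.sum())
    if total == 0:
        raise DomainError("all-zero pollen counts")
    if not 1 <= n <= total:
        raise DomainError(f"subsample size {n} outside [1, {total}]")
    if reps < 1:
        raise DomainError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == total:  # the subsample is the full pool: deterministic
        val = inverse_simpson(counts)
        return RarefiedSimpson(value=val, se=0.0, reps=reps, depth=n)
    draws = rng.multivariate_hypergeometric(counts, n, size=reps).astype(float)
    p = draws / n
    values = 1.0 / np.sum(p * p, axis=1)
    se = float(values.std(ddof=1) / np.sqrt(reps)) if reps > 1 else np.nan
    return RarefiedSimpson(value=float(values.mean()), se=se, reps=reps, depth=n)


def generalization_indices(pollen: PollenTable,
                           species: list[str] | None = None,
                           depth: int | None = None,
                           simpson_reps: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Rarefied degree and rarefied inverse Simpson per bee species.

    Pollen counts are pooled over all individuals of a species before
    rarefying.  The depth defaults to the minimum pooled grain total
    across the requested species, so every species is rarefied to a
    common, attainable subsample size.
    """
    d = pollen.data
    if species is None:
        species = list(dict.fromkeys(d["bee_species"]))
    pooled = {
        sp: d.loc[d["bee_species"] == sp].groupby("plant_species")["grains_of_species"]
        .sum().to_numpy()
        for sp in species
    }
    totals = {sp: int(c.sum()) for sp, c in pooled.items()}
    if any(t == 0 for t in totals.values()):
        empty = [sp for sp, t in totals.items() if t == 0]
        raise DomainError(f"no pollen grains recorded for species {empty}")
    if depth is None:
        depth = min(totals.values())
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species:
        simpson = rarefied_simpson(pooled[sp], depth, reps=simpson_reps, seed=rng)
        rows.append({
            "bee_species": sp,
            "rarefied_degree": rarefied_degree(pooled[sp], depth),
            "rarefied_simpson": simpson.value,
            "rarefied_simpson_se": simpson.se,
            "rarefaction_depth": depth,
        })
    return pd.DataFrame(rows)
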
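"""Per-site floral resource metrics.

Three quantities summarise the flowering season of a site:

* **flower density** — mean flowers per flowering individual times the
  number of flowering individuals (or a direct count for taxa whose
  individuals cannot be told apart);
* **temporal stability** — the inverse coefficient of variation,
  mean / sd, of the weekly flower abundance across the season;
* **rarefied richness** — the hypergeometric expectation of the number
  of plant species in a random subsample of ``n`` flowers, which removes
  the sampling-effort bias that raw richness inherits from abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import DomainError

#: sentinel for a constant nonzero weekly series (sd = 0, stability unbounded)
INFINITE_STABILITY = math.inf


@dataclass(frozen=True)
class WeeklyFloralSeries:
    """Weekly flower counts for one site.

    ``abundance[w]`` is the site-week total; ``per_species_counts`` is an
    optional (weeks x plant species) table whose row sums must equal the
    abundance series.
    """

    site: str
    weeks: tuple[int, ...]
    abundance: tuple[float, ...]
    per_species_counts: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.weeks) != len(self.abundance):
            raise DomainError("weeks and abundance differ in length")
        if any(a < 0 for a in self.abundance):
            raise DomainError("negative weekly abundance")
        if self.per_species_counts is not None:
            row_sums = self.per_species_counts.sum(axis=1).to_numpy(dtype=float)
            if not np.allclose(row_sums, np.asarray(self.abundance, dtype=float)):
                raise DomainError(
                    "per-species counts do not sum to the weekly abundance series"
                )

    @property
    def total_counts(self) -> np.ndarray:
        """Season totals per plant species (requires per-species counts)."""
        if self.per_species_counts is None:
            raise DomainError("no per-species counts on this series")
        return self.per_species_counts.sum(axis=0).to_numpy()


def flower_density(mean_flowers_per_individual: float | None = None,
                   n_flowering_individuals: int | None = None,
                   direct_count: float | None = None) -> float:
    """Flowers contributed by one plant species in one plot or transect.

    Either pass (``mean_flowers_per_individual``, ``n_flowering_individuals``)
    for taxa whose individuals can be distinguished, or ``direct_count``
    alone for taxa where every open flower was counted directly.
    """
    if direct_count is not None:
        if mean_flowers_per_individual is not None or n_flowering_individuals is not None:
            raise DomainError("direct_count is exclusive of the product mode")
        if direct_count < 0:
            raise DomainError("negative direct count")
        return float(direct_count)
    if mean_flowers_per_individual is None or n_flowering_individuals is None:
        raise DomainError("need mean flowers per individual and individual count")
    if mean_flowers_per_individual < 0 or n_flowering_individuals < 0:
        raise DomainError("negative input to flower_density")
    return float(mean_flowers_per_individual) * float(n_flowering_individuals)


def temporal_stability(series: WeeklyFloralSeries | np.ndarray, ddof: int = 1) -> float:
    """Inverse coefficient of variation (mean/sd) of weekly flower abundance.

    Uses the sample (n-1) standard deviation by default.  A constant
    nonzero series has sd = 0 and returns the ``INFINITE_STABILITY``
    sentinel rather than being dropped; an all-zero series is undefined.
    """
    values = np.asarray(
        series.abundance if isinstance(series, WeeklyFloralSeries) else series,
        dtype=float,
    )
    if values.size < 2:
        raise DomainError("temporal stability needs at least 2 weeks")
    if (values < 0).any():
        raise DomainError("negative weekly abundance")
    mean = values.mean()
    sd = values.std(ddof=ddof)
    if sd == 0.0:
        if mean == 0.0:
            raise DomainError("all-zero weekly series: stability undefined")
        return INFINITE_STABILITY
    return float(mean / sd)


def rarefied_richness(species_counts, n: int) -> float:
    """Expected species count in a random subsample of ``n`` individuals.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] with N the grand total:
    the hypergeometric (without-replacement) rarefaction expectation.
    """
    counts = np.asarray(species_counts, dtype=np.int64)
    if counts.ndim != 1 or (counts < 0).any():
        raise DomainError("species counts must be a non-negative vector")
    counts = counts[counts > 0]
    total = int(counts.sum())
    if total == 0:
        raise DomainError("all-zero counts: nothing to rarefy")
    if not 1 <= n <= total:
        raise DomainError(f"subsample size {n} outside [1, {total}]")

    # log C(N - Ni, n) - log C(N, n), with the convention C(m, n) = 0 for m < n
    def log_binom(m, k):
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    log_cn = log_binom(total, n)
    rest = total - counts
    prob_absent = np.where(rest >= n, np.exp(log_binom(rest, n) - log_cn), 0.0)
    return float(np.sum(1.0 - prob_absent))


def site_metrics(series_by_site: dict[str, WeeklyFloralSeries],
                 rarefaction_depth: int | None = None,
                 ddof: int = 1) -> pd.DataFrame:
    """Per-site metric table: abundance, rarefied richness, stability.

    ``flower_abundance`` is the mean weekly site total.  The rarefaction
    depth defaults to the minimum season total across sites, the largest
    depth every site can support.
    """
    totals = {s: int(round(sum(ser.abundance))) for s, ser in series_by_site.items()}
    if rarefaction_depth is None:
        positive = [t for t in totals.values() if t > 0]
        if not positive:
            raise DomainError("no flowers recorded at any site")
        rarefaction_depth = min(positive)
    rows = []
    for site, ser in series_by_site.items():
        counts = ser.total_counts
        rows.append({
            "site": site,
            "flower_abundance": float(np.mean(ser.abundance)),
            "flower_richness_rarefied": rarefied_richness(counts, rarefaction_depth)
            if counts.sum() >= rarefaction_depth else np.nan,
            "stability": temporal_stability(ser, ddof=ddof),
        })
    return pd.DataFrame(rows)
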
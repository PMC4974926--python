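import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beesem.bee_metrics import rarefied_degree, reproduction_summaries
from beesem.causal_engine import CausalModel, partial_correlation
from beesem.errors import ConfigError
from beesem.models import ELEVATION, RICHNESS
from beesem.synthetic_data import (DEFAULT_COEFFICIENTS, GeneratorConfig,
                                   default_site_model, example_nest_counts,
                                   generate_dataset, generate_nests,
                                   generate_pollen, generate_site_frame,
                                   generate_sites,
                                   standardized_noise_variances)


class TestSurveyFixture:
    def test_eleven_species_and_598_nests(self):
        counts = example_nest_counts()
        assert len(counts) == 11
        assert counts.sum() == 598


class TestStandardizedSystem:
    def test_default_coefficients_are_feasible(self):
        noise = standardized_noise_variances(default_site_model(),
                                             DEFAULT_COEFFICIENTS)
        assert all(0 < v <= 1 for v in noise.values())

    def test_overstrong_coefficients_rejected(self):
        model = CausalModel("m", ("A", "B", "C"), (("A", "C"), ("B", "C")))
        with pytest.raises(ConfigError, match="R-squared"):
            standardized_noise_variances(model, {("A", "C"): 0.9, ("B", "C"): 0.9})

    def test_generated_variables_have_unit_variance(self):
        cfg = GeneratorConfig(n_sites=20_000)
        frame = generate_site_frame(cfg, seed=5)
        for col in [c for c in frame.columns if c.startswith("z_")]:
            assert frame[col].var() == pytest.approx(1.0, abs=0.05), col

    def test_zero_noise_unit_coefficient_gives_perfect_rank_correlation(self):
        model = CausalModel("m", (ELEVATION, RICHNESS),
                            ((ELEVATION, RICHNESS),))
        cfg = GeneratorConfig(n_sites=30, site_model=model,
                              coefficients={(ELEVATION, RICHNESS): 1.0})
        frame = generate_site_frame(cfg, seed=2)
        rho, _ = stats.spearmanr(frame["elevation"], frame[f"z_{RICHNESS}"])
        assert rho == pytest.approx(1.0)


class TestGenerateSites:
    def test_same_seed_is_deterministic(self):
        a_table, a_series, a_frame = generate_sites(GeneratorConfig(seed=3))
        b_table, b_series, b_frame = generate_sites(GeneratorConfig(seed=3))
        assert a_table == b_table
        pd.testing.assert_frame_equal(a_frame, b_frame)
        for site in a_series:
            assert a_series[site].abundance == b_series[site].abundance

    def test_site_table_passes_validation_and_matches_config(self):
        table, series, frame = generate_sites(GeneratorConfig(seed=4))
        table.validate()
        assert len(table) == 14
        assert table.data["elevation"].between(1100, 1500).all()
        assert len(series) == 14
        assert all(len(s.abundance) == 8 for s in series.values())

    def test_realized_stability_tracks_the_target(self):
        # a CV estimated from 8 weekly points is noisy, so the rank
        # agreement is moderate, but it must be clearly positive
        cfg = GeneratorConfig(n_sites=200)
        _, _, frame = generate_sites(cfg, seed=6)
        rho, p = stats.spearmanr(frame["stability"], frame["realized_stability"])
        assert rho > 0.4
        assert p < 1e-6

    def test_infeasible_stability_distribution_rejected(self):
        with pytest.raises(ConfigError, match="CV"):
            GeneratorConfig(stability_mean=0.5, stability_sd=0.5).validate()


class TestGenerateNests:
    def test_zero_intensity_means_zero_nests(self):
        cfg = GeneratorConfig(nests_per_site_intensity=0.0, seed=1)
        frame = generate_site_frame(cfg)
        records, table = generate_nests(cfg, frame)
        assert len(records) == 0
        assert len(table) == 0

    def test_summaries_conserve_raw_totals(self):
        cfg = GeneratorConfig(seed=8)
        frame = generate_site_frame(cfg)
        records, table = generate_nests(cfg, frame)
        assert table.data["total_cells"].sum() == records["cells"].sum()
        assert table.data["total_nests"].sum() == len(records)
        rebuilt = reproduction_summaries(records, sites=list(frame["site"]))
        merged = table.data.merge(rebuilt.data, on=["bee_species", "site"],
                                  suffixes=("", "_r"))
        assert (merged["total_cells"] == merged["total_cells_r"]).all()

    def test_negative_elevation_effect_recovered_in_sign(self):
        # elevation -> total_nests is negative in the generating system;
        # the fitted coefficient should be negative nearly always
        cfg = GeneratorConfig(n_sites=100)
        negatives = 0
        reps = 200
        for rep in range(reps):
            frame = generate_site_frame(cfg, seed=50_000 + rep)
            records, table = generate_nests(cfg, frame, seed=50_000 + rep)
            totals = table.data.groupby("site")["total_nests"].sum()
            merged = frame.merge(totals.rename("tn"), left_on="site",
                                 right_index=True)
            r, _, _ = partial_correlation(merged["elevation"], merged["tn"])
            negatives += r < 0
        assert negatives >= 0.95 * reps


class TestGeneratePollen:
    def test_outputs_pass_validation_and_match_nests(self):
        ds = generate_dataset(seed=9)
        ds.pollen_table.validate()
        assert set(ds.pollen_table.data["bee_species"]) <= \
            set(ds.nest_records["bee_species"])

    def test_single_plant_diet_gives_degree_one(self):
        pooled = np.array([137])
        assert rarefied_degree(pooled, 50) == pytest.approx(1.0)

    def test_diet_breadth_gradient_recovered_as_monotone_trend(self):
        cfg = GeneratorConfig(seed=10, n_bee_species=7)
        ds = generate_dataset(cfg)
        pooled = ds.pollen_table.data.groupby("bee_species")[
            "grains_of_species"].sum()
        depth = int(pooled.min())
        degrees = {}
        for sp, grp in ds.pollen_table.data.groupby("bee_species"):
            counts = grp.groupby("plant_species")["grains_of_species"].sum()
            degrees[sp] = rarefied_degree(counts.to_numpy(), depth)
        ordered = [degrees[sp] for sp in sorted(degrees)]  # Bee01..Bee07
        rho, _ = stats.spearmanr(range(len(ordered)), ordered)
        assert rho > 0.5  # concentration grows with species index


class TestGenerateDataset:
    def test_bundle_is_consistent_and_seedable(self):
        a = generate_dataset(seed=11)
        b = generate_dataset(seed=11)
        assert a.site_table == b.site_table
        assert a.nest_table == b.nest_table
        assert a.pollen_table == b.pollen_table
        assert set(a.nest_table.data["site"]) == set(a.site_table.data["site"])
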
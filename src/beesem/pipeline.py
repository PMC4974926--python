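"""End-to-end analysis: metrics -> model fits -> selection -> meta-analysis.

``run_pipeline`` executes, in order: per-site floral metrics,
reproduction summaries and the focal-species filter, per-response
causal-model fits (community models on totals summed over species, then
one fit per focal species), d-separation tests with AIC ranking,
cross-species meta-analysis of every simplified-model path, and the
Spearman correlations between the flower-richness effect and diet
generalization.  Everything is written to an output directory as CSV /
JSON plus a reproducibility manifest (config hash, seed, versions); a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bee_metrics import (MIN_NESTS_DEFAULT, filter_focal_species,
                          generalization_indices)
from .causal_engine import (CausalModel, DSepResult, ModelScore, PathEstimate,
                            dsep_test, model_aic, path_coefficients,
                            rank_models)
from .errors import (ConfigError, DegenerateInputError, InsufficientDataError)
from .floral_metrics import WeeklyFloralSeries, site_metrics
from .io_tables import read_table
from .meta_analysis import (DEFAULT_BOOTSTRAP_REPS, MetaInput, MetaResult,
                            bootstrap_ci, spearman_correlation)
from .models import (COMMUNITY_RESPONSES, ELEVATION, RESPONSES, RICHNESS,
                     STABILITY, complete_model, model_to_dict,
                     simplified_model)
from .synthetic_data import GeneratorConfig, generate_dataset

_CSV_FLOAT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``input_paths`` (CSV files in the documented schemas;
    keys ``nests``, ``sites``, ``pollen`` and optionally ``weekly``) or
    ``generator`` (synthetic study) must be given.
    """

    output_dir: str | Path
    seed: int = 0
    input_paths: dict[str, str] | None = None
    generator: GeneratorConfig | None = None
    aic_formula: str = "shipley_corrected"
    param_rule: str = "edges"
    min_nests: int = MIN_NESTS_DEFAULT
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS
    simpson_reps: int = 1000
    floral_rarefaction_depth: int | None = None
    diet_rarefaction_depth: int | None = None
    responses: tuple[str, ...] = RESPONSES

    def validate(self) -> "RunConfig":
        if (self.input_paths is None) == (self.generator is None):
            raise ConfigError("exactly one of input_paths / generator is required")
        if self.input_paths is not None:
            missing = {"nests", "sites", "pollen"} - set(self.input_paths)
            if missing:
                raise ConfigError(f"input_paths missing {sorted(missing)}")
        return self


@dataclass
class PipelineReport:
    """In-memory view of the report bundle written to the output directory."""

    site_metrics: pd.DataFrame
    reproduction: pd.DataFrame
    focal_species: list[str]
    model_scores: pd.DataFrame
    path_table: pd.DataFrame
    meta_table: pd.DataFrame
    generalization: pd.DataFrame
    spearman_table: pd.DataFrame
    manifest: dict
    skipped: list[dict] = field(default_factory=list)


def _config_payload(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            if isinstance(obj, CausalModel):
                return model_to_dict(obj)
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {("->".join(k) if isinstance(k, tuple) else str(k)): clean(v)
                    for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple, set, frozenset)):
            return [clean(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    payload = {k: clean(v) for k, v in dataclasses.asdict(config).items()}
    if config.generator is not None:
        payload["generator"]["site_model"] = model_to_dict(config.generator.site_model)
    return payload


def _load_inputs(config: RunConfig):
    """Stage 1: load the three CSVs or draw a synthetic study."""
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        ds = generate_dataset(gen)
        return ds.site_table, ds.weekly_series, ds.nest_table, ds.pollen_table
    paths = config.input_paths
    site_table = read_table(paths["sites"], "sites")
    nest_table = read_table(paths["nests"], "nests")
    pollen_table = read_table(paths["pollen"], "pollen")
    series = None
    if "weekly" in paths:
        weekly = read_table(paths["weekly"], "weekly")
        series = {}
        for site, grp in weekly.data.groupby("site"):
            pivot = grp.pivot_table(index="week", columns="plant_species",
                                    values="flowers", fill_value=0,
                                    aggfunc="sum").sort_index()
            series[site] = WeeklyFloralSeries(
                site=site, weeks=tuple(int(w) for w in pivot.index),
                abundance=tuple(float(v) for v in pivot.sum(axis=1)),
                per_species_counts=pivot.reset_index(drop=True),
            )
    return site_table, series, nest_table, pollen_table


def _site_metric_frame(config, site_table, series) -> pd.DataFrame:
    """Stage 2: per-site floral metrics merged with the environment."""
    env = site_table.data[["site", "elevation", "years_since_fire"]]
    if series is not None:
        metrics = site_metrics(series,
                               rarefaction_depth=config.floral_rarefaction_depth)
        metrics = metrics.rename(columns={"flower_richness_rarefied": RICHNESS})
    else:
        metrics = site_table.data[["site", "flower_abundance",
                                   "flower_richness_rarefied"]].rename(
            columns={"flower_richness_rarefied": RICHNESS})
        extras = site_table.extras
        if "stability" not in extras.columns:
            raise ConfigError(
                "stage site_metrics: no weekly flower series and no "
                "precomputed 'stability' column in the site file")
        metrics = metrics.assign(stability=pd.to_numeric(extras["stability"]).to_numpy())
    return env.merge(metrics, on="site")


def _species_response_frame(nest_data: pd.DataFrame, sites: pd.DataFrame,
                            species: str | None) -> pd.DataFrame:
    """Site covariates joined with one species' (or the community's)
    responses; community totals sum over every recorded species."""
    if species is None:
        resp = nest_data.groupby("site")[["total_cells", "total_nests"]].sum()
        resp = resp.reset_index()
    else:
        resp = nest_data.loc[nest_data["bee_species"] == species,
                             ["site", "mean_cells_per_nest", "total_cells",
                              "total_nests"]].rename(
            columns={"mean_cells_per_nest": "mean_cells"})
    frame = sites.merge(resp, on="site", how="left")
    for col in ("total_cells", "total_nests"):
        if col in frame.columns:
            frame[col] = frame[col].fillna(0)  # absence is zero abundance
    return frame


def _fit_models(models, frame, config, unit_label, skipped):
    """d-sep test, AIC and path coefficients for one analysis unit."""
    score_rows, path_rows, claim_rows = [], [], []
    for model in models:
        sub = frame[[v for v in model.variables]].dropna()
        n = len(sub)
        try:
            result = dsep_test(model, sub)
            paths = path_coefficients(model, sub)
        except (InsufficientDataError, DegenerateInputError) as exc:
            skipped.append({"unit": unit_label, "model": model.name,
                            "reason": str(exc)})
            continue
        score_rows.append({"unit": unit_label, "model": model.name,
                           "response": model.response, "n": n,
                           "C": result.C, "k": result.k, "df": result.df,
                           "p_value": result.p_value,
                           "result": result, "model_obj": model})
        for pe in paths:
            path_rows.append({"unit": unit_label, "model": model.name,
                              "response": model.response,
                              "cause": pe.edge[0], "effect": pe.edge[1],
                              "coefficient": pe.coefficient,
                              "p_value": pe.p_value, "n": pe.n})
        for c in result.claims:
            claim_rows.append({"unit": unit_label, "model": model.name,
                               "x": c.x, "y": c.y, "z": ";".join(c.z),
                               "partial_r": c.partial_r, "p_value": c.p_value,
                               "n": c.n})
    return score_rows, path_rows, claim_rows


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full analysis and write the report bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    skipped: list[dict] = []

    site_table, series, nest_table, pollen_table = _load_inputs(config)
    sites = _site_metric_frame(config, site_table, series)

    nest_data = nest_table.data
    nest_counts = nest_data.groupby("bee_species", sort=False)["total_nests"].sum()
    focal = filter_focal_species(nest_counts, config.min_nests)

    # model fits: community totals, then one fit per focal species
    score_rows, path_rows, claim_rows = [], [], []
    community_models = [m for resp in COMMUNITY_RESPONSES
                        for m in (complete_model(resp), simplified_model(resp))]
    rows = _fit_models(community_models,
                       _species_response_frame(nest_data, sites, None),
                       config, "community", skipped)
    for acc, new in zip((score_rows, path_rows, claim_rows), rows):
        acc.extend(new)
    species_models = [m for resp in config.responses
                      for m in (complete_model(resp), simplified_model(resp))]
    for sp in focal:
        rows = _fit_models(species_models,
                           _species_response_frame(nest_data, sites, sp),
                           config, sp, skipped)
        for acc, new in zip((score_rows, path_rows, claim_rows), rows):
            acc.extend(new)

    # AIC ranking within each (unit, response) model pair
    ranked_rows = []
    scores_df = pd.DataFrame(score_rows)
    for (unit, resp), grp in scores_df.groupby(["unit", "response"], sort=False):
        scores = []
        for _, row in grp.iterrows():
            K = row["model_obj"].n_free_parameters(config.param_rule)
            try:
                scores.append(model_aic(row["result"], K, row["n"],
                                        config.aic_formula))
            except Exception as exc:
                raise ConfigError(
                    f"stage model_aic: unit={unit!r} model={row['model']!r}: {exc}"
                ) from exc
        for sc in rank_models(scores):
            base = grp.loc[grp["model"] == sc.model].iloc[0]
            ranked_rows.append({
                "unit": unit, "response": resp, "model": sc.model,
                "n": int(base["n"]), "C": sc.C, "k": int(base["k"]),
                "df": int(base["df"]), "p_value": base["p_value"],
                "K": sc.K, "AIC": sc.AIC, "delta_AIC": sc.delta_AIC,
                "support": sc.support_class, "formula": sc.formula,
            })
    model_scores = pd.DataFrame(ranked_rows)
    path_table = pd.DataFrame(path_rows)

    # cross-species meta-analysis of every simplified-model path
    meta_rows = []
    sp_paths = path_table[(path_table["unit"] != "community")
                          & path_table["model"].str.startswith("model2")
                          & (path_table["effect"] == path_table["response"])]
    rng = np.random.default_rng(config.seed)
    for (resp, cause), grp in sp_paths.groupby(["response", "cause"], sort=False):
        inputs = []
        for _, row in grp.iterrows():
            if abs(row["coefficient"]) >= 1 or row["n"] <= 3:
                skipped.append({"unit": row["unit"], "model": row["model"],
                                "reason": f"meta-analysis: r or N out of range "
                                          f"({cause} -> {resp})"})
                continue
            inputs.append(MetaInput(species=row["unit"], r=row["coefficient"],
                                    N=int(row["n"])))
        if not inputs:
            continue
        res = bootstrap_ci(inputs, B=config.bootstrap_reps,
                           seed=int(rng.integers(2**31 - 1)))
        meta_rows.append({
            "response": resp, "cause": cause, "n_species": res.n_species,
            "z_mean": res.z_mean, "r_mean": res.r_mean,
            "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
            "B": res.B, "seed": res.seed,
        })
    meta_table = pd.DataFrame(meta_rows)

    # diet generalization and its correlation with the richness effect
    pollen_species = [sp for sp in focal
                      if sp in set(pollen_table.data["bee_species"])]
    generalization = generalization_indices(
        pollen_table, species=pollen_species,
        depth=config.diet_rarefaction_depth,
        simpson_reps=config.simpson_reps, seed=config.seed)
    spearman_rows = []
    rich_paths = sp_paths[sp_paths["cause"] == RICHNESS]
    for resp in config.responses:
        grp = rich_paths[rich_paths["response"] == resp]
        merged = grp.merge(generalization, left_on="unit", right_on="bee_species")
        for index in ("rarefied_degree", "rarefied_simpson"):
            if len(merged) < 3:
                continue
            try:
                rho, p, n = spearman_correlation(merged[index],
                                                 merged["coefficient"])
            except DegenerateInputError as exc:
                skipped.append({"unit": "spearman", "model": resp,
                                "reason": str(exc)})
                continue
            spearman_rows.append({"generalization_index": index,
                                  "response": resp, "rho": rho,
                                  "p_value": p, "N": n})
    spearman_table = pd.DataFrame(spearman_rows)

    payload = _config_payload(config)
    hashed = {k: v for k, v in payload.items() if k != "output_dir"}
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(
            json.dumps(hashed, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "n_sites": int(len(sites)),
        "n_species_recorded": int(nest_counts.size),
        "n_focal_species": len(focal),
        "focal_species": focal,
        "total_nests": int(nest_counts.sum()),
        "skipped": skipped,
    }

    reproduction = nest_data.copy()
    _write_bundle(out, sites, reproduction, model_scores, path_table,
                  meta_table, generalization, spearman_table,
                  pd.DataFrame(claim_rows), manifest)
    return PipelineReport(site_metrics=sites, reproduction=reproduction,
                          focal_species=focal, model_scores=model_scores,
                          path_table=path_table, meta_table=meta_table,
                          generalization=generalization,
                          spearman_table=spearman_table, manifest=manifest,
                          skipped=skipped)


def _write_bundle(out: Path, sites, reproduction, model_scores, path_table,
                  meta_table, generalization, spearman_table, claims,
                  manifest) -> None:
    for name, frame in [
        ("site_metrics.csv", sites),
        ("reproduction_summary.csv", reproduction),
        ("model_scores.csv", model_scores),
        ("path_coefficients.csv", path_table),
        ("meta_analysis.csv", meta_table),
        ("generalization.csv", generalization),
        ("spearman_generalization.csv", spearman_table),
        ("dsep_claims.csv", claims),
    ]:
        frame.to_csv(out / name, index=False, float_format=_CSV_FLOAT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run.log", "w") as fh:
        fh.write(f"beesem {__version__} seed={manifest['seed']} "
                 f"config={manifest['config_sha256'][:12]}\n")
        for _, row in claims.iterrows():
            fh.write(f"claim unit={row['unit']} model={row['model']} "
                     f"{row['x']} _||_ {row['y']} | {{{row['z']}}} "
                     f"r={row['partial_r']:.6f} p={row['p_value']:.6g} "
                     f"n={row['n']}\n")
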
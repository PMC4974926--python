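"""Builders and YAML (de)serialization for the candidate causal models.

Two model families are analysed, one DAG per reproductive response R
(mean brood cells per nest, total brood cells, total nests):

* the **complete model**: elevation -> flower richness, elevation ->
  flower abundance, flower richness -> stability, and each of elevation,
  flower abundance, flower richness, stability and years-since-fire
  pointing at R;
* the **simplified model**: richness, stability and elevation -> R,
  elevation -> richness, richness -> stability.  The richness -> R and
  elevation -> R edges sit on the keep-list: they are retained for their
  suggestive trends even when non-significant.

Models ship as editable YAML rather than hard-coded structures; the
builders here produce the same dictionaries the YAML loader accepts.
"""

from __future__ import annotations

import yaml

from .causal_engine import CausalModel

ELEVATION = "elevation"
FIRE = "years_since_fire"
ABUNDANCE = "flower_abundance"
RICHNESS = "flower_richness"
STABILITY = "stability"

RESPONSES = ("mean_cells", "total_cells", "total_nests")
COMMUNITY_RESPONSES = ("total_cells", "total_nests")


def complete_model(response: str, name: str | None = None) -> CausalModel:
    """The full candidate DAG ("Model 1") for one reproductive response."""
    return CausalModel(
        name=name or f"model1:{response}",
        variables=(ELEVATION, FIRE, ABUNDANCE, RICHNESS, STABILITY, response),
        edges=(
            (ELEVATION, RICHNESS),
            (ELEVATION, ABUNDANCE),
            (RICHNESS, STABILITY),
            (ELEVATION, response),
            (ABUNDANCE, response),
            (RICHNESS, response),
            (STABILITY, response),
            (FIRE, response),
        ),
        response=response,
    )


def simplified_model(response: str, name: str | None = None) -> CausalModel:
    """The nested candidate DAG ("Model 2") for one reproductive response.

    Its basis set has exactly one claim — elevation independent of
    stability given richness — so Fisher's C carries 2 df.
    """
    return CausalModel(
        name=name or f"model2:{response}",
        variables=(ELEVATION, RICHNESS, STABILITY, response),
        edges=(
            (ELEVATION, RICHNESS),
            (RICHNESS, STABILITY),
            (ELEVATION, response),
            (RICHNESS, response),
            (STABILITY, response),
        ),
        keep_edges=frozenset({(RICHNESS, response), (ELEVATION, response)}),
        response=response,
    )


def model_to_dict(model: CausalModel) -> dict:
    d = {
        "name": model.name,
        "variables": list(model.variables),
        "edges": [list(e) for e in model.edges],
    }
    if model.keep_edges:
        d["keep_edges"] = sorted([list(e) for e in model.keep_edges])
    if model.response:
        d["response"] = model.response
    if model.claim_overrides:
        d["claim_overrides"] = {f"{x}|{y}": list(z)
                                for (x, y), z in model.claim_overrides.items()}
    return d


def model_from_dict(d: dict) -> CausalModel:
    overrides = {}
    for key, z in (d.get("claim_overrides") or {}).items():
        x, y = key.split("|")
        overrides[tuple(sorted((x, y)))] = tuple(z)
    return CausalModel(
        name=d["name"],
        variables=tuple(d["variables"]),
        edges=tuple(tuple(e) for e in d["edges"]),
        keep_edges=frozenset(tuple(e) for e in d.get("keep_edges", [])),
        response=d.get("response"),
        claim_overrides=overrides,
    )


def save_models(models: list[CausalModel], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"models": [model_to_dict(m) for m in models]}, fh,
                       sort_keys=False)


def load_models(path) -> list[CausalModel]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [model_from_dict(d) for d in payload["models"]]
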
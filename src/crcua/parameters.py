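"""Shipped literature constants and builders for default configurations.

Every published model input lives in ``data/parameters.yaml``; this module
loads that file and assembles the domain objects the rest of the package
consumes. The annual transition probabilities are derived at load time from
the 5-year literature quantities via :mod:`crcua.conversions`, at full
floating precision — rounding to the published 2-4 significant figures only
happens in report writers.
"""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .conversions import (
    RecurrenceInputs,
    annual_from_five_year_cif,
    annual_from_five_year_survival,
    pooled_cif,
)
from .markov import (
    CALIBRATED_VARIANT,
    WITH_SCREENING,
    WITHOUT_SCREENING,
    ArmParameters,
    CostSet,
    ModelConfig,
    StageSplit,
    StructuralVariant,
    UtilitySet,
)

__all__ = [
    "load_parameters",
    "annual_probabilities",
    "default_model_config",
    "model_config_from_mapping",
    "load_model_config",
]


@lru_cache(maxsize=None)
def _shipped() -> dict:
    with resources.files("crcua.data").joinpath("parameters.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def load_parameters(path: str | Path | None = None) -> dict:
    """Return the parameter mapping (the shipped file, or an override)."""
    if path is None:
        return copy.deepcopy(_shipped())
    with open(path) as fh:
        return yaml.safe_load(fh)


def annual_probabilities(params: dict | None = None) -> dict:
    """Annual transition probabilities derived from the 5-year inputs.

    Returns a mapping with ``p_progress`` (from the pooled recurrence CIF),
    ``p_die_early`` and ``p_die_late`` (from the SEER 5-year survivals).
    """
    p = params if params is not None else load_parameters()
    rec = RecurrenceInputs(**p["recurrence"])
    return {
        "p_progress": annual_from_five_year_cif(pooled_cif(rec)),
        "p_die_early": annual_from_five_year_survival(
            p["survival"]["five_year_survival_stage_i_ii"]
        ),
        "p_die_late": annual_from_five_year_survival(
            p["survival"]["five_year_survival_stage_iii_iv"]
        ),
    }


def model_config_from_mapping(p: dict, variant: StructuralVariant | None = None) -> ModelConfig:
    """Assemble a :class:`ModelConfig` from a parameter mapping."""
    if p["model"]["horizon_cycles"] < 1:
        raise ValueError("model.horizon_cycles must be >= 1")
    probs = annual_probabilities(p)
    arms = {}
    for label, key in ((WITH_SCREENING, "with_screening"), (WITHOUT_SCREENING, "without_screening")):
        split = p["stage_split"][key]
        arms[label] = ArmParameters(
            arm_label=label,
            stage_split=StageSplit(split["early"], split["late"]),
            **probs,
        )
    costs = CostSet(
        screening_cost=p["costs_eur"]["screening_per_participant"],
        colonoscopy_cost=p["costs_eur"]["colonoscopy"],
        late_treatment_cost=p["costs_eur"]["late_stage_treatment"],
        palliative_cost=p["costs_eur"]["palliative_care"],
    )
    utilities = UtilitySet(
        u_early=p["utilities"]["stage_i_ii"],
        u_late=p["utilities"]["stage_iii_iv"],
        u_dead=p["utilities"]["dead"],
    )
    if variant is None:
        variant = StructuralVariant(**p.get("variant", {})) if "variant" in p else CALIBRATED_VARIANT
    return ModelConfig(
        arms=arms,
        costs=costs,
        utilities=utilities,
        variant=variant,
        horizon_cycles=p["model"]["horizon_cycles"],
        cycle_length_years=p["model"]["cycle_length_years"],
        discount_rate=p["model"]["discount_rate"],
    )


def default_model_config(variant: StructuralVariant | None = None) -> ModelConfig:
    """The shipped base-case configuration under the calibrated variant."""
    return model_config_from_mapping(load_parameters(), variant=variant)


def load_model_config(path: str | Path, variant: StructuralVariant | None = None) -> ModelConfig:
    """Build a :class:`ModelConfig` from a YAML/JSON parameter file on disk."""
    return model_config_from_mapping(load_parameters(path), variant=variant)
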
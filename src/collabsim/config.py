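"""YAML configuration loading for cohorts and experiments."""

from __future__ import annotations

from pathlib import Path

import yaml

from .auditors import AuditorSpec
from .cohort import CohortSpec, SEVERE_COMPLAINTS
from .collaboration import BehaviorConfig
from .harness import ExperimentConfig
from .predictors import ModelConfig

__all__ = ["load_cohort_spec", "load_experiment_config"]


def _build(cls, mapping, **coerce):
    mapping = dict(mapping or {})
    for key, fn in coerce.items():
        if key in mapping:
            mapping[key] = fn(mapping[key])
    return cls(**mapping)


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _build(CohortSpec, raw, esi_fractions=tuple)


def load_experiment_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file mirroring its fields.

    Nested sections: ``cohort_spec``, ``model_config``, ``behavior_config``,
    ``auditor_specs`` (scenario name -> AuditorSpec fields).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    kwargs = dict(raw)
    if "cohort_spec" in kwargs and kwargs["cohort_spec"] is not None:
        kwargs["cohort_spec"] = _build(CohortSpec, kwargs["cohort_spec"], esi_fractions=tuple)
    if "model_config" in kwargs:
        kwargs["model_config"] = _build(
            ModelConfig, kwargs["model_config"], depth_grid=tuple, l2_grid=tuple
        )
    if "behavior_config" in kwargs:
        kwargs["behavior_config"] = _build(
            BehaviorConfig,
            kwargs["behavior_config"],
            severe_complaint_set=lambda v: frozenset(v) if v else SEVERE_COMPLAINTS,
        )
    if "auditor_specs" in kwargs:
        kwargs["auditor_specs"] = {
            name: _build(AuditorSpec, spec) for name, spec in kwargs["auditor_specs"].items()
        }
    if "sensitivity_rates" in kwargs:
        kwargs["sensitivity_rates"] = tuple(float(r) for r in kwargs["sensitivity_rates"])
    config = ExperimentConfig(**kwargs)
    config.validate()
    return config
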
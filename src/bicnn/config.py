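"""YAML configuration round-trip for experiments.

The file mirrors the dataclass tree::

    experiment: {scenario, n_cycles, freq, ...}
    pd:         {kp_theta, kd_theta, kp_phi, kd_phi}
    plant:      {body_mass, wheel_mass, ...}
    plasticity: {gamma_ltd, gamma_ltp, gamma_pkvn, cf_spont, ...}
    cf:         {cf_spont_left, cf_spont_right, error_gain, w_p, w_v}
    mossy:      {phi_ref, phi_dot_ref, ...}

Any omitted key keeps its default; flags passed to the CLI override the file.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .control import PdGains, DEFAULT_GAINS
from .dynamics import CfParams, MossyScales, PlasticityParams
from .plant import PlantParams
from .runner import ExperimentConfig

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]

_SECTIONS = {
    "pd": ("gains", PdGains),
    "plant": ("plant", PlantParams),
    "plasticity": ("plasticity", PlasticityParams),
    "cf": ("cf", CfParams),
    "mossy": ("mossy_scales", MossyScales),
}

_EXPERIMENT_FIELDS = (
    "scenario", "n_cycles", "freq", "amplitude", "dt",
    "perturbation_onset_cycle", "perturbation_kind",
    "cf_spont_left", "cf_spont_right", "controller",
    "seed_builder", "seed_noise", "n_repeats", "mirror_hemispheres",
    "gr_input_gain", "rate_tau",
)


def config_to_dict(cfg: ExperimentConfig) -> dict[str, Any]:
    out: dict[str, Any] = {
        "experiment": {k: getattr(cfg, k) for k in _EXPERIMENT_FIELDS}
    }
    for section, (attr, _cls) in _SECTIONS.items():
        out[section] = dataclasses.asdict(getattr(cfg, attr))
    return out


def config_from_dict(data: dict[str, Any]) -> ExperimentConfig:
    kwargs: dict[str, Any] = dict(data.get("experiment") or {})
    unknown = set(kwargs) - set(_EXPERIMENT_FIELDS)
    if unknown:
        raise ValueError(f"unknown experiment keys: {sorted(unknown)}")
    for section, (attr, cls) in _SECTIONS.items():
        if section in data and data[section] is not None:
            base = DEFAULT_GAINS if cls is PdGains else cls()
            kwargs[attr] = dataclasses.replace(base, **data[section])
    return ExperimentConfig(**kwargs)


def load_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: ExperimentConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
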
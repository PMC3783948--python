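"""Structured-config loading and validation.

A ``defaults.toml`` with the reference parameter values ships inside the
package; user configs may override any subset.  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import tomllib
from importlib import resources
from pathlib import Path

from .model_core import (ConnectivityKernel, IntrinsicParams, NetworkSpec,
                         PopulationSpec, SynapseParams)
from .serotonin import SerotoninSpec
from .simulator import StimulusSpec


def default_config_path() -> Path:
    return Path(resources.files("ringmem") / "configs" / "defaults.toml")


def load_config(path=None) -> dict:
    """Parse a TOML config; values missing from it fall back to defaults."""
    with open(default_config_path(), "rb") as fh:
        cfg = tomllib.load(fh)
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        for section, values in user.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            for key, val in values.items():
                if key not in cfg[section]:
                    raise ValueError(f"unknown key {section}.{key}")
                cfg[section][key] = val
    return cfg


def _build(cls, section: dict, rename: dict | None = None):
    rename = rename or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in section.items():
        name = rename.get(key, key)
        if name not in fields:
            raise ValueError(f"unknown parameter {key!r} for {cls.__name__}")
        kwargs[name] = val
    return cls(**kwargs)


def network_from_config(cfg: dict) -> NetworkSpec:
    pop = _build(PopulationSpec, cfg["population"])
    exc = _build(IntrinsicParams, cfg["excitatory"])
    inh = _build(IntrinsicParams, cfg["inhibitory"])
    syn = _build(SynapseParams, cfg["synapses"])
    k = cfg["kernel"]
    kernel = ConnectivityKernel(
        j_plus={"EE": k["J_plus_EE"], "EI": k["J_plus_EI"],
                "IE": k["J_plus_IE"], "II": k["J_plus_II"]},
        sigma=k["sigma"]).resolve(pop)
    return NetworkSpec(pop=pop, excitatory=exc, inhibitory=inh,
                       synapses=syn, kernel=kernel)


def serotonin_from_config(cfg: dict) -> SerotoninSpec:
    return _build(SerotoninSpec, cfg["serotonin"])


def stimulus_from_config(cfg: dict, theta_s: float = 0.0) -> StimulusSpec:
    s = cfg["stimulus"]
    return StimulusSpec(theta_s=theta_s, I_1=s["I_1"], mu_stim=s["mu_stim"],
                        duration=s["duration"])
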
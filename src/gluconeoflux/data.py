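"""Accessors for the bundled model files and default tables."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .network import NetworkModel, load_model

BUNDLED_MODELS = (
    "pputida_kt2440_succinate",
    "ctestosteroni_kf1_succinate",
    "pputida_succinate_demo",
    "toy_chain_split",
    "toy_cycle_scramble",
    "toy_reversible_mix",
)


def model_path(name: str) -> Path:
    if name not in BUNDLED_MODELS:
        raise KeyError(f"unknown bundled model {name!r}; "
                       f"available: {BUNDLED_MODELS}")
    return Path(resources.files("gluconeoflux") / "models" / f"{name}.tsv")


def load_bundled_model(name: str) -> NetworkModel:
    return load_model(model_path(name))


def composition_path() -> Path:
    return Path(resources.files("gluconeoflux") / "models" / "default_composition.yaml")
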
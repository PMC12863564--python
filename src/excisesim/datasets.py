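"""Packaged calibrations."""

from __future__ import annotations

from importlib import resources

from .config import SimulationConfig, load_config

__all__ = ["mozambique", "mozambique_path"]


def mozambique_path():
    """Path-like handle to the packaged Mozambique configuration file."""
    return resources.files("excisesim.data") / "mozambique.yaml"


def mozambique() -> SimulationConfig:
    """The Mozambique 2023 baseline: four price segments, 2023-2028 macro
    path, three tax scenarios and the smoking-prevalence anchors."""
    with resources.as_file(mozambique_path()) as path:
        return load_config(path)
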
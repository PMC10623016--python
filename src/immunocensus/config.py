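"""Run-time configuration shared across the pipeline.

All tunables that the operations take as defaults live here so a single
key-value (or YAML) file can override them from the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

__all__ = ["Config", "load_config", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class Config:
    #: Reference person the census is assembled for.
    person: str = "male"
    #: Seed for every bootstrap CI reported by the pipeline.
    seed: int = 2023
    #: Number of bootstrap draws for summation error propagation.
    n_draws: int = 1000
    #: Inverse-variance weight multiplier for multiplexed-imaging estimates
    #: in lymphoid-group tissues (1 = pure inverse-variance weighting).
    multiplex_weight: float = 1.0
    #: Extra multiplicative ferror penalty on non-human evidence.
    species_penalty: float = 1.5
    #: Minimum ferror assigned to extrapolated densities.
    extrapolation_floor: float = 1.5
    #: Volume correction for cell sizes measured on blood smears.
    smear_correction: float = 0.7
    #: Specific density of a cell, g/mL.
    cell_density_g_per_ml: float = 1.07
    #: |z| cutoff for multiplex sample QC.
    z_cutoff: float = 1.96
    #: Default ferror assumed for evidence rows that state no uncertainty.
    default_ferror: float = 2.0

    def replace(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


DEFAULT_CONFIG = Config()


def load_config(path: str | Path) -> Config:
    """Load a config from a YAML / ``key: value`` text file.

    Unknown keys raise, so typos fail loudly rather than silently falling
    back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return Config(**raw)
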
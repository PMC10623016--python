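"""Representative cell mass per immune cell type.

Literature size data come as diameters (sometimes ranges) or volumes,
measured in tissue sections, blood smears, or suspension.  A cell is modeled
as a sphere; diameter ranges are reduced to their geometric mean (cell sizes
are treated as lognormal); blood-smear measurements are deflated by a 0.7
volume correction for flattening; and mass follows from a constant specific
density of 1.07 g/mL.  Macrophage sizes vary strongly by tissue, so they are
resolved tissue-specifically where possible, falling back to an aggregate by
whether monocytes continuously replenish the tissue's macrophage population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, Config
from .density import CELL_TYPES
from .uncertainty import LognormalEstimate

__all__ = [
    "CellSizeRecord",
    "MACROPHAGE_MONOCYTE_REPLENISHED",
    "volume_from_diameter",
    "apply_smear_correction",
    "representative_mass",
    "read_size_table",
    "mass_table",
]

#: grams per μm^3 at 1.07 g/mL specific cell density
G_PER_UM3 = 1.07e-12

#: Fallback log-scale SE when only one size record backs a cell type.
_SINGLE_RECORD_S = math.log(1.3)

#: Whether a tissue's macrophages are continuously replenished from blood
#: monocytes (e.g. gut, dermis) or locally self-renewing (microglia, Kupffer
#: cells, alveolar macrophages).  Drives the macrophage size fallback class.
MACROPHAGE_MONOCYTE_REPLENISHED: dict[str, bool] = {
    "small_intestine": True,
    "large_intestine": True,
    "stomach": True,
    "skin": True,
    "blood": True,
    "bone_marrow": True,
    "spleen": True,
    "lymph_nodes": True,
    "thymus": True,
    "tonsils": True,
    "adipose": True,
    "heart": True,
    "skeletal_muscle": True,
    "pancreas": True,
    "kidneys": True,
    "connective": True,
    "ecf_matrix": True,
    "lungs": False,
    "liver": False,
    "brain": False,
}

_CONTEXTS = {"tissue section", "blood smear", "suspension"}


@dataclass(frozen=True)
class CellSizeRecord:
    """One literature size datum: a diameter (possibly a range) or a volume."""

    cell_type: str
    tissue: str | None = None
    diameter_um: float | tuple[float, float] | None = None
    volume_um3: float | None = None
    context: str = "tissue section"
    species: str = "human"

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if (self.diameter_um is None) == (self.volume_um3 is None):
            raise ValueError("exactly one of diameter/volume must be present")
        if self.context not in _CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if isinstance(self.diameter_um, tuple):
            lo, hi = self.diameter_um
            if not (0 < lo <= hi):
                raise ValueError(f"bad diameter range ({lo}, {hi})")
        elif self.diameter_um is not None and self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.volume_um3 is not None and self.volume_um3 <= 0:
            raise ValueError("volume must be positive")

    def raw_volume_um3(self) -> float:
        if self.volume_um3 is not None:
            return self.volume_um3
        return volume_from_diameter(self.diameter_um)


def volume_from_diameter(d_um: float | tuple[float, float]) -> float:
    """Sphere volume from a diameter or diameter range (μm -> μm^3).

    A range is reduced to the geometric mean of its endpoints, treating the
    size spread as lognormal.
    """
    if isinstance(d_um, tuple):
        lo, hi = d_um
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad diameter range ({lo}, {hi})")
        d = math.sqrt(lo * hi)
    else:
        d = d_um
    if d <= 0:
        raise ValueError(f"diameter must be positive, got {d}")
    return math.pi / 6 * d**3


def apply_smear_correction(
    v_um3: float,
    context: str,
    factor: float = DEFAULT_CONFIG.smear_correction,
) -> float:
    """Deflate blood-smear volumes by the flattening correction (default 0.7);
    other contexts pass through unchanged."""
    if v_um3 <= 0:
        raise ValueError(f"volume must be positive, got {v_um3}")
    if context not in _CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    return v_um3 * factor if context == "blood smear" else v_um3


def _aggregate(
    volumes: Sequence[float], species: Sequence[str], cfg: Config
) -> LognormalEstimate:
    logs = np.log(np.asarray(volumes, dtype=float))
    v = math.exp(float(logs.mean()))
    n = len(volumes)
    s = float(np.std(logs, ddof=1)) / math.sqrt(n) if n > 1 else _SINGLE_RECORD_S
    mass = LognormalEstimate(v * G_PER_UM3, math.exp(s))
    if all(sp != "human" for sp in species):
        mass = mass.widened(cfg.species_penalty)
    return mass


def representative_mass(
    records: Sequence[CellSizeRecord],
    cell_type: str,
    tissue: str | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> LognormalEstimate:
    """Representative mass (grams/cell) for a cell type.

    Smear-corrected volumes are pooled by geometric mean with the log-space
    SE as uncertainty, then converted at 1.07 g/mL.  For macrophages with a
    tissue given, resolution order is: records for that tissue, then the
    aggregate of the tissue's monocyte-replenishment class, then all
    macrophage records.
    """
    mine = [r for r in records if r.cell_type == cell_type]
    if not mine:
        raise ValueError(f"no size records for cell type {cell_type!r}")

    chosen = mine
    if cell_type == "macrophage" and tissue is not None:
        tissue_specific = [r for r in mine if r.tissue == tissue]
        if tissue_specific:
            chosen = tissue_specific
        elif tissue in MACROPHAGE_MONOCYTE_REPLENISHED:
            replenished = MACROPHAGE_MONOCYTE_REPLENISHED[tissue]
            class_records = [
                r
                for r in mine
                if r.tissue is not None
                and MACROPHAGE_MONOCYTE_REPLENISHED.get(r.tissue) == replenished
            ]
            if class_records:
                chosen = class_records

    volumes = [
        apply_smear_correction(r.raw_volume_um3(), r.context,
                               cfg.smear_correction)
        for r in chosen
    ]
    return _aggregate(volumes, [r.species for r in chosen], cfg)


def read_size_table(path_or_df) -> list[CellSizeRecord]:
    """Read a size-record CSV (cell_type, tissue, diameter_low_um,
    diameter_high_um, volume_um3, context, species, source)."""
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    records = []
    for _, row in df.iterrows():
        diameter = None
        volume = None
        if pd.notna(row.get("volume_um3")):
            volume = float(row["volume_um3"])
        else:
            lo = float(row["diameter_low_um"])
            hi_raw = row.get("diameter_high_um")
            hi = float(hi_raw) if pd.notna(hi_raw) else lo
            diameter = lo if lo == hi else (lo, hi)
        records.append(
            CellSizeRecord(
                cell_type=row["cell_type"],
                tissue=None if pd.isna(row.get("tissue")) else row["tissue"],
                diameter_um=diameter,
                volume_um3=volume,
                context=row.get("context", "tissue section"),
                species=row.get("species", "human"),
            )
        )
    return records


def mass_table(
    records: Sequence[CellSizeRecord],
    tissues: Sequence[str] = (),
    cfg: Config = DEFAULT_CONFIG,
) -> dict[str, LognormalEstimate | dict[str, LognormalEstimate]]:
    """Per-type representative masses; macrophages tissue-resolved.

    Returns a mapping cell type -> estimate, except ``"macrophage"`` which
    maps to a per-tissue mapping (with a ``None``-keyed body-wide fallback).
    """
    out: dict[str, LognormalEstimate | dict[str, LognormalEstimate]] = {}
    for ct in CELL_TYPES:
        if not any(r.cell_type == ct for r in records):
            raise ValueError(f"no size records for cell type {ct!r}")
        if ct == "macrophage":
            per_tissue: dict[str | None, LognormalEstimate] = {
                None: representative_mass(records, ct, None, cfg)
            }
            for t in tissues:
                per_tissue[t] = representative_mass(records, ct, t, cfg)
            out[ct] = per_tissue
        else:
            out[ct] = representative_mass(records, ct, None, cfg)
    return out
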
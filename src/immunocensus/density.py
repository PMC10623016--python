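"""Per-gram cell-density estimation from literature evidence.

Raw evidence comes in heterogeneous shapes — areal counts from histological
sections, relative abundances from flow cytometry, total-count claims for a
whole organ, compartment-resolved densities — and this module normalises all
of them to one currency: cells per gram of tissue, each with a lognormal
multiplicative error.

The stereological core is the Abercrombie-type correction (cells counted per
section area divided by section thickness plus cell diameter), which
compensates for cells cut by the section faces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, Config
from .uncertainty import (
    LognormalEstimate,
    bootstrap_sum,
    fit_lognormal_from_normal,
    geometric_mean_estimate,
    propagate_product,
)

__all__ = [
    "CELL_TYPES",
    "LYMPHOCYTES",
    "GRANULOCYTES",
    "TISSUE_GROUPS",
    "CellTypeDef",
    "TissueRecord",
    "DensityRecord",
    "default_tissues",
    "read_tissue_table",
    "density_from_areal_count",
    "volumetric_to_per_gram",
    "density_from_relative_abundance",
    "density_from_total_count",
    "compartment_weighted_density",
    "read_evidence_table",
    "normalize_evidence",
    "merge_method_records",
]

# --------------------------------------------------------------------------
# Cell-type vocabulary
# --------------------------------------------------------------------------

TISSUE_GROUPS = (
    "bone marrow",
    "lymphatic",
    "blood",
    "barrier epithelial",
    "other epithelial",
    "striated muscle",
    "adipose",
    "other connective",
    "CNS",
    "extracellular fluids and matrix",
)

# Tissue-restricted cell types: eosinophils live mainly in the GI tract and
# the primary/secondary lymphoid organs; mast cells in connective tissue and
# the lamina propria of barrier epithelia (minimal marrow population);
# basophils in marrow and blood.  Restrictions are expressed as explicit
# tissue ids plus whole groups and are config-overridable.
_EOSINOPHIL_TISSUES = frozenset(
    {"small_intestine", "large_intestine", "stomach", "bone_marrow",
     "spleen", "lymph_nodes", "thymus", "tonsils"}
)
_BASOPHIL_TISSUES = frozenset({"bone_marrow", "blood"})
_MAST_GROUPS = frozenset({"other connective", "barrier epithelial"})
_MAST_EXTRA_TISSUES = frozenset({"bone_marrow"})


@dataclass(frozen=True)
class CellTypeDef:
    name: str
    lineage: str  # "lymphoid" | "myeloid"
    is_granulocyte: bool = False
    restricted_tissues: frozenset[str] = frozenset()
    restricted_groups: frozenset[str] = frozenset()

    @property
    def is_restricted(self) -> bool:
        return bool(self.restricted_tissues or self.restricted_groups)

    def allowed_in(self, tissue: "TissueRecord") -> bool:
        if not self.is_restricted:
            return True
        return (
            tissue.tissue_id in self.restricted_tissues
            or tissue.group in self.restricted_groups
        )


CELL_TYPES: dict[str, CellTypeDef] = {
    c.name: c
    for c in (
        CellTypeDef("T cell", "lymphoid"),
        CellTypeDef("B cell", "lymphoid"),
        CellTypeDef("plasma cell", "lymphoid"),
        CellTypeDef("NK cell", "lymphoid"),
        CellTypeDef("neutrophil", "myeloid", is_granulocyte=True),
        CellTypeDef("eosinophil", "myeloid", is_granulocyte=True,
                    restricted_tissues=_EOSINOPHIL_TISSUES),
        CellTypeDef("basophil", "myeloid", is_granulocyte=True,
                    restricted_tissues=_BASOPHIL_TISSUES),
        CellTypeDef("mast cell", "myeloid", is_granulocyte=True,
                    restricted_tissues=_MAST_EXTRA_TISSUES,
                    restricted_groups=_MAST_GROUPS),
        CellTypeDef("macrophage", "myeloid"),
        CellTypeDef("monocyte", "myeloid"),
        CellTypeDef("dendritic cell", "myeloid"),
    )
}

LYMPHOCYTES = ("T cell", "B cell", "plasma cell", "NK cell")
GRANULOCYTES = ("neutrophil", "eosinophil", "basophil", "mast cell")

_METHODS = {"histology", "flow", "total-count", "multiplex", "deconvolution",
            "extrapolated"}
# "mixed" marks extrapolated records whose evidence pools several sources
# (group-mean extrapolation from human data in *other* tissues must not
# claim human provenance for the target tissue).
_SPECIES = {"human", "rodent", "monkey", "mixed"}


# --------------------------------------------------------------------------
# Tissues
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueRecord:
    """A tissue with group label, specific gravity, and reference masses."""

    tissue_id: str
    group: str
    specific_gravity: float = 1.03
    mass_g: Mapping[str, float] = field(default_factory=dict)
    compartments: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.group not in TISSUE_GROUPS:
            raise ValueError(f"unknown tissue group {self.group!r}")
        if self.specific_gravity <= 0:
            raise ValueError("specific gravity must be positive")
        for person, m in self.mass_g.items():
            if m <= 0:
                raise ValueError(f"mass for {person!r} must be positive")
        if self.compartments:
            total = sum(f for _, f in self.compartments)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"compartment fractions sum to {total}, expected 1"
                )

    def mass_for(self, person: str) -> float:
        if person not in self.mass_g:
            raise KeyError(
                f"tissue {self.tissue_id!r} has no reference mass for {person!r}"
            )
        return self.mass_g[person]


def read_tissue_table(path: str | Path) -> dict[str, TissueRecord]:
    """Read the tissue reference table (id, group, gravity, per-person mass)."""
    df = pd.read_csv(path)
    tissues: dict[str, TissueRecord] = {}
    for _, row in df.iterrows():
        masses = {}
        for person in ("male", "female", "child"):
            col = f"mass_{person}_g"
            if col in df.columns and pd.notna(row[col]):
                masses[person] = float(row[col])
        tissues[row["tissue_id"]] = TissueRecord(
            tissue_id=row["tissue_id"],
            group=row["group"],
            specific_gravity=float(row["specific_gravity"]),
            mass_g=masses,
        )
    return tissues


def default_tissues() -> dict[str, TissueRecord]:
    """The editable reference tissue table shipped with the package."""
    with resources.as_file(
        resources.files("immunocensus.data") / "tissues.csv"
    ) as p:
        return read_tissue_table(p)


# --------------------------------------------------------------------------
# Evidence records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityRecord:
    """One piece of evidence for the density of a (tissue, cell type) pair."""

    tissue_id: str
    cell_type: str
    density: LognormalEstimate  # cells per gram
    method: str
    species: str = "human"
    compartment: str | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.species not in _SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.method == "extrapolated" and self.species == "human":
            raise ValueError("extrapolated records cannot claim human provenance")


# --------------------------------------------------------------------------
# Unit conversions (all lengths in cm internally)
# --------------------------------------------------------------------------

UM_PER_CM = 1e4


def density_from_areal_count(n: float, A: float, T: float, D: float) -> float:
    """Volumetric density from a 2-D section count (Abercrombie correction).

    ``rho = n / (A * (T + D))`` with the count ``n`` over section area ``A``
    (cm^2), section thickness ``T`` (cm) and cell diameter ``D`` (cm).  The
    ``T + D`` denominator corrects for cells whose centres lie outside the
    section but which are still cut and counted; ``T = 0`` is the
    zero-thickness limit used for multiplexed imaging planes.
    """
    if A <= 0:
        raise ValueError(f"area must be positive, got {A}")
    if D <= 0:
        raise ValueError(f"cell diameter must be positive, got {D}")
    if T < 0:
        raise ValueError(f"thickness must be >= 0, got {T}")
    if n < 0:
        raise ValueError(f"count must be >= 0, got {n}")
    return n / (A * (T + D))


def volumetric_to_per_gram(rho: float, tissue: TissueRecord) -> float:
    """Convert cells/cm^3 to cells/g via the tissue's specific gravity.

    Dimensionally this is division by g/cm^3 (1.03 generic, 0.91 adipose).
    """
    if rho < 0:
        raise ValueError("density must be >= 0")
    return rho / tissue.specific_gravity


def density_from_relative_abundance(
    fraction: float | LognormalEstimate,
    reference: LognormalEstimate,
) -> LognormalEstimate:
    """Cells/g from a fraction of a reference (e.g. total nucleated) density."""
    if isinstance(fraction, LognormalEstimate):
        frac_est = fraction
        f = fraction.value
    else:
        frac_est = LognormalEstimate(fraction) if fraction > 0 else None
        f = fraction
    if not (0 < f <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {f}")
    return propagate_product(frac_est, reference)


def density_from_total_count(
    total: LognormalEstimate, organ_mass_g: float
) -> LognormalEstimate:
    """Cells/g from a whole-organ total count; ferror is preserved."""
    if organ_mass_g <= 0:
        raise ValueError(f"organ mass must be positive, got {organ_mass_g}")
    return total.scaled(1.0 / organ_mass_g)


def compartment_weighted_density(
    parts: Sequence[tuple[float, LognormalEstimate]],
    seed: int = DEFAULT_CONFIG.seed,
    n_draws: int = DEFAULT_CONFIG.n_draws,
) -> LognormalEstimate:
    """Whole-tissue density from compartment-resolved densities.

    ``parts`` are ``(mass fraction, density)`` pairs whose fractions sum to
    one.  The point value is the mass-fraction-weighted arithmetic mean; the
    uncertainty is propagated by bootstrap over the (independent) parts.
    """
    if len(parts) == 0:
        raise ValueError("need at least one compartment")
    total_frac = sum(w for w, _ in parts)
    if abs(total_frac - 1.0) > 1e-6:
        raise ValueError(f"mass fractions sum to {total_frac}, expected 1")
    scaled = [d.scaled(w) for w, d in parts]
    if all(e.is_exact for e in scaled):
        return LognormalEstimate(sum(e.value for e in scaled))
    boot = bootstrap_sum(scaled, n_draws=n_draws, seed=seed)
    return LognormalEstimate(boot.value, boot.ferror)


# --------------------------------------------------------------------------
# Evidence-table ingestion
# --------------------------------------------------------------------------

VALUE_KINDS = {"per_gram", "per_cm3", "areal_count", "fraction", "total_count"}

_EVIDENCE_COLUMNS = [
    "tissue_id", "cell_type", "method", "value", "value_kind",
    "A_cm2", "T_um", "D_um", "ferror_or_se", "species", "compartment",
    "source",
]


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    """Read a density-evidence table from CSV or XLSX.

    One row per evidence record.  Required columns: tissue_id, cell_type,
    method, value, value_kind; optional: A_cm2, T_um, D_um, ferror_or_se,
    error_kind (``ferror`` or ``se``, default ferror), ref_value, ref_ferror
    (reference nucleated-cell density for ``fraction`` rows), species,
    compartment, source.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = {"tissue_id", "cell_type", "method", "value", "value_kind"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    bad = set(df["value_kind"]) - VALUE_KINDS
    if bad:
        raise ValueError(f"unknown value_kind entries: {sorted(bad)}")
    return df


def _row_estimate(row: pd.Series, value: float, cfg: Config) -> LognormalEstimate:
    """Resolve a row's stated value and uncertainty into an estimate.

    ``error_kind == "se"`` rows are normally described (mean, SE) and are
    moment-matched to a lognormal, so their point value becomes the fitted
    median; ``ferror`` rows pass the stated value through.
    """
    raw = row.get("ferror_or_se")
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return LognormalEstimate(value, cfg.default_ferror)
    raw = float(raw)
    kind = row.get("error_kind", "ferror")
    if isinstance(kind, float) and math.isnan(kind):
        kind = "ferror"
    if kind == "se":
        return fit_lognormal_from_normal(value, raw)
    if raw < 1:
        raise ValueError(f"ferror must be >= 1, got {raw}")
    return LognormalEstimate(value, raw)


def _normalize_row(
    row: pd.Series,
    tissues: Mapping[str, TissueRecord],
    person: str,
    cfg: Config,
) -> DensityRecord:
    tissue = tissues[row["tissue_id"]]
    kind = row["value_kind"]
    value = float(row["value"])
    species = row.get("species", "human")
    if not isinstance(species, str):
        species = "human"

    # Unit conversions are linear in the stated value, so resolve the
    # uncertainty on the stated scale and rescale the whole estimate.
    if kind == "per_gram":
        est = _row_estimate(row, value, cfg)
    elif kind == "per_cm3":
        est = _row_estimate(row, value, cfg).scaled(1.0 / tissue.specific_gravity)
    elif kind == "areal_count":
        factor = density_from_areal_count(
            1.0,
            float(row["A_cm2"]),
            float(row["T_um"]) / UM_PER_CM,
            float(row["D_um"]) / UM_PER_CM,
        ) / tissue.specific_gravity
        est = _row_estimate(row, value, cfg).scaled(factor) if value > 0 \
            else LognormalEstimate(0.0)
    elif kind == "fraction":
        ref = LognormalEstimate(
            float(row["ref_value"]), float(row.get("ref_ferror", 1.0))
        )
        est = density_from_relative_abundance(value, ref)
        if pd.notna(row.get("ferror_or_se")):
            frac_est = _row_estimate(row, value, cfg)
            est = propagate_product(
                frac_est.scaled(1.0 / value), est
            ) if frac_est.ferror > 1 else est
    elif kind == "total_count":
        total = _row_estimate(row, value, cfg)
        est = density_from_total_count(total, tissue.mass_for(person))
    else:  # pragma: no cover - guarded by read_evidence_table
        raise ValueError(f"unknown value_kind {kind!r}")

    per_gram, ferror = est.value, est.ferror
    if species != "human":
        ferror *= cfg.species_penalty

    return DensityRecord(
        tissue_id=row["tissue_id"],
        cell_type=row["cell_type"],
        density=LognormalEstimate(per_gram, max(ferror, 1.0))
        if per_gram > 0
        else LognormalEstimate(0.0),
        method=row["method"],
        species=species,
        compartment=None
        if pd.isna(row.get("compartment"))
        else row.get("compartment"),
        provenance=str(row.get("source", "")),
    )


def normalize_evidence(
    df: pd.DataFrame,
    tissues: Mapping[str, TissueRecord],
    person: str = "male",
    cfg: Config = DEFAULT_CONFIG,
) -> list[DensityRecord]:
    """Normalise every evidence row to a per-gram :class:`DensityRecord`.

    Compartment-resolved rows for the same (tissue, cell type, method) are
    combined by the compartment mass-fraction weights declared on the tissue;
    rows without a compartment label pass through individually.
    """
    records: list[DensityRecord] = []
    for _, row in df.iterrows():
        if row["tissue_id"] not in tissues:
            raise KeyError(f"unknown tissue {row['tissue_id']!r}")
        records.append(_normalize_row(row, tissues, person, cfg))

    # Fold compartment-resolved records into whole-tissue densities.
    out: list[DensityRecord] = []
    by_key: dict[tuple, list[DensityRecord]] = {}
    for r in records:
        if r.compartment is None:
            out.append(r)
        else:
            by_key.setdefault((r.tissue_id, r.cell_type, r.method), []).append(r)
    for (tissue_id, cell_type, method), parts in by_key.items():
        tissue = tissues[tissue_id]
        comp_frac = dict(tissue.compartments)
        if not comp_frac:
            raise ValueError(
                f"tissue {tissue_id!r} has compartment evidence but no "
                "compartment mass fractions"
            )
        weighted = [(comp_frac[r.compartment], r.density) for r in parts]
        covered = sum(w for w, _ in weighted)
        # Compartments without evidence contribute zero density.
        if covered < 1 - 1e-6:
            weighted.append((1 - covered, LognormalEstimate(0.0)))
        est = compartment_weighted_density(weighted, seed=cfg.seed,
                                           n_draws=cfg.n_draws)
        species = (
            "human" if all(r.species == "human" for r in parts) else "rodent"
        )
        out.append(
            DensityRecord(tissue_id, cell_type, est, method, species=species,
                          provenance="compartment-weighted")
        )
    return out


def merge_method_records(
    records: Sequence[DensityRecord],
) -> dict[tuple[str, str, str], LognormalEstimate]:
    """Merge repeated records per (tissue, cell type, method class).

    Multiple records for the same key are merged by geometric mean with the
    between-record spread folded into the combined ferror, producing one
    estimate per method class ready for cross-method combination.
    """
    grouped: dict[tuple[str, str, str], list[LognormalEstimate]] = {}
    for r in records:
        grouped.setdefault((r.tissue_id, r.cell_type, r.method), []).append(
            r.density
        )
    merged: dict[tuple[str, str, str], LognormalEstimate] = {}
    for key, ests in grouped.items():
        positive = [e for e in ests if e.value > 0]
        if not positive:
            merged[key] = LognormalEstimate(0.0)
        else:
            merged[key] = geometric_mean_estimate(positive)
    return merged
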
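"""Filling density gaps for (tissue, cell type) pairs without human data.

Two routes are available and combined when both apply:

* cross-species: geometric mean of rodent/monkey densities for the same
  pair, with an extra uncertainty penalty;
* within-group: geometric mean of the human densities of similar tissues
  (the tissue's group), with the between-tissue spread as uncertainty.

Tissue-restricted cell types (eosinophils, mast cells, basophils) are never
extrapolated outside their home tissues.  Every filled pair is recorded in
an audit log, and all pairs filled from the same evidence route share a
correlation group so their errors stay correlated in downstream sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, Config
from .density import CELL_TYPES, DensityRecord, TissueRecord
from .uncertainty import LognormalEstimate, geometric_mean_estimate

__all__ = [
    "ExtrapolationRule",
    "ExtrapolationResult",
    "is_forbidden",
    "extrapolate_cross_species",
    "extrapolate_group_mean",
    "combine_extrapolations",
    "fill_missing_densities",
]

#: Ratio of the two extrapolation routes above which a discrepancy is
#: flagged (the routes are expected to agree within a factor of 2).
DISCREPANCY_RATIO = 2.0


@dataclass(frozen=True)
class ExtrapolationRule:
    cell_type: str
    strategy: str  # cross_species | group_geometric_mean | combined | forbidden
    group_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def is_forbidden(cell_type: str, tissue: TissueRecord) -> bool:
    """True when the cell type is tissue-restricted and this tissue is
    outside its home set; such pairs keep zero density."""
    ct = CELL_TYPES[cell_type]
    return ct.is_restricted and not ct.allowed_in(tissue)


@dataclass(frozen=True)
class ExtrapolationResult:
    tissue_id: str
    cell_type: str
    estimate: LognormalEstimate | None
    strategy: str
    discrepancy: bool = False
    correlation_key: str | None = None


def extrapolate_cross_species(
    records: Sequence[DensityRecord],
    penalty: float = DEFAULT_CONFIG.species_penalty,
) -> LognormalEstimate | None:
    """Geometric mean of non-human densities with a species penalty on ferror.

    Returns ``None`` (not-applicable sentinel) when no non-human record
    exists.  ``penalty`` defaults to 1.5; pass 1.0 when records were already
    penalized at normalization time.
    """
    usable = [r for r in records if r.species != "human" and r.density.value > 0]
    if not usable:
        return None
    return geometric_mean_estimate([r.density for r in usable]).widened(penalty)


def extrapolate_group_mean(
    cell_type: str,
    target_tissue: TissueRecord,
    records: Sequence[DensityRecord],
    floor: float = DEFAULT_CONFIG.extrapolation_floor,
) -> LognormalEstimate | None:
    """Geometric mean of same-group human densities for the cell type.

    The combined ferror comes from the between-tissue log spread, floored at
    ``floor`` so extrapolated values are always down-weighted.  Returns
    ``None`` when the group has no usable human record; raises for
    forbidden (tissue-restricted) pairs.
    """
    if is_forbidden(cell_type, target_tissue):
        raise ValueError(
            f"{cell_type!r} is tissue-restricted and not extrapolated to "
            f"{target_tissue.tissue_id!r}"
        )
    usable = [
        r
        for r in records
        if r.cell_type == cell_type
        and r.species == "human"
        and r.density.value > 0
        and r.tissue_id != target_tissue.tissue_id
    ]
    if not usable:
        return None
    est = geometric_mean_estimate([r.density for r in usable])
    return LognormalEstimate(est.value, max(est.ferror, floor))


def combine_extrapolations(
    a: LognormalEstimate | None,
    b: LognormalEstimate | None,
    tissue_id: str = "",
    cell_type: str = "",
) -> ExtrapolationResult:
    """Geometric mean of the cross-species and group-mean routes.

    With both routes available the point value is their geometric mean and a
    discrepancy flag is raised when they differ by more than a factor of
    two.  With one route, it passes through.  With neither, the pair stays
    missing (``estimate is None``).  The result carries an evidence-keyed
    correlation key so errors of pairs filled the same way stay correlated.
    """
    if a is None and b is None:
        return ExtrapolationResult(tissue_id, cell_type, None, "missing")
    if a is None:
        est, strategy = b, "group_geometric_mean"
        discrepancy = False
    elif b is None:
        est, strategy = a, "cross_species"
        discrepancy = False
    else:
        value = math.sqrt(a.value * b.value)
        s = math.hypot(a.s, b.s) / 2  # half-weight product on the log scale
        est = LognormalEstimate(value, max(math.exp(s), min(a.ferror, b.ferror)))
        strategy = "combined"
        ratio = max(a.value, b.value) / min(a.value, b.value)
        discrepancy = ratio > DISCREPANCY_RATIO
    return ExtrapolationResult(
        tissue_id, cell_type, est, strategy, discrepancy,
        correlation_key=f"extrapolated:{strategy}:{cell_type}",
    )


def fill_missing_densities(
    records: Sequence[DensityRecord],
    tissues: Mapping[str, TissueRecord],
    cfg: Config = DEFAULT_CONFIG,
) -> tuple[list[DensityRecord], pd.DataFrame]:
    """Fill every (tissue, cell type) pair that lacks human evidence.

    Returns the extrapolated records (method ``extrapolated``) plus an audit
    table with one row per considered pair: strategy used, value, ferror,
    discrepancy flag, or the reason the pair was left empty.
    """
    have_human = {
        (r.tissue_id, r.cell_type)
        for r in records
        if r.species == "human" and r.density.value > 0
    }
    by_pair: dict[tuple[str, str], list[DensityRecord]] = {}
    for r in records:
        by_pair.setdefault((r.tissue_id, r.cell_type), []).append(r)

    filled: list[DensityRecord] = []
    audit_rows = []
    for tissue_id in sorted(tissues):
        tissue = tissues[tissue_id]
        for cell_type in CELL_TYPES:
            if (tissue_id, cell_type) in have_human:
                continue
            if is_forbidden(cell_type, tissue):
                audit_rows.append(
                    (tissue_id, cell_type, "forbidden", 0.0, 1.0, False)
                )
                continue
            pair_records = by_pair.get((tissue_id, cell_type), [])
            # Records were species-penalized at normalization; don't re-apply.
            a = extrapolate_cross_species(pair_records, penalty=1.0)
            group_records = [
                r
                for r in records
                if tissues[r.tissue_id].group == tissue.group
                and r.cell_type == cell_type
            ]
            b = extrapolate_group_mean(
                cell_type, tissue, group_records, floor=cfg.extrapolation_floor
            )
            result = combine_extrapolations(a, b, tissue_id, cell_type)
            if result.estimate is None:
                audit_rows.append(
                    (tissue_id, cell_type, "missing", 0.0, 1.0, False)
                )
                continue
            filled.append(
                DensityRecord(
                    tissue_id,
                    cell_type,
                    result.estimate,
                    "extrapolated",
                    species="rodent" if result.strategy == "cross_species"
                    else "mixed",
                    provenance=result.correlation_key or "",
                )
            )
            audit_rows.append(
                (
                    tissue_id,
                    cell_type,
                    result.strategy,
                    result.estimate.value,
                    result.estimate.ferror,
                    result.discrepancy,
                )
            )
    audit = pd.DataFrame(
        audit_rows,
        columns=["tissue_id", "cell_type", "strategy", "value", "ferror",
                 "discrepancy"],
    )
    return filled, audit
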
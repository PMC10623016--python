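"""Whole-body census assembly: densities x organ masses -> counts and mass.

This is where the per-gram densities from the evidence modules meet the
reference person's organ masses.  Counts per (tissue, cell type) are the
product of density and organ mass with multiplicative-error propagation;
margins (per tissue, per type, grand total) carry bootstrap confidence
intervals that honor the correlation structure introduced by extrapolation.
The same machinery scales the census to other reference persons (female,
child) and evaluates perturbation scenarios such as lymphadenopathy,
splenomegaly, and obesity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, Config
from .cellmass import CellSizeRecord, mass_table
from .density import (
    CELL_TYPES,
    GRANULOCYTES,
    LYMPHOCYTES,
    DensityRecord,
    TissueRecord,
    merge_method_records,
    normalize_evidence,
)
from .extrapolation import fill_missing_densities
from .multiplex import MultiplexDensity, MultiplexSample, multiplex_densities
from .uncertainty import (
    BootstrapEstimate,
    CorrelationGroup,
    LognormalEstimate,
    bootstrap_sum,
    inverse_variance_combine,
    propagate_product,
)

__all__ = [
    "BODY_MASS_KG",
    "ReferencePerson",
    "CensusTable",
    "reference_person",
    "combine_methods",
    "integrate_counts",
    "mass_census",
    "scale_to_person",
    "ScenarioModifier",
    "apply_scenario",
    "volume_factor_from_diameter",
    "build_census",
    "CensusResult",
]

BODY_MASS_KG = {"male": 73.0, "female": 60.0, "child": 32.0}
HEIGHT_CM = {"male": 176.0}

#: Methods counted as "literature" evidence when combining across methods.
LITERATURE_METHODS = ("histology", "flow", "total-count")

#: Tissue group in which multiplexed imaging gets its weight multiplier.
LYMPHOID_GROUP = "lymphatic"


@dataclass(frozen=True)
class ReferencePerson:
    name: str
    body_mass_kg: float
    organ_masses: Mapping[str, float]
    height_cm: float | None = None

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.organ_masses.values()):
            raise ValueError("all organ masses must be positive")
        total = sum(self.organ_masses.values())
        if total > self.body_mass_kg * 1000:
            raise ValueError(
                f"organ masses sum to {total} g, above body mass"
            )


def reference_person(
    name: str, tissues: Mapping[str, TissueRecord]
) -> ReferencePerson:
    """Build a reference person from the tissue table.

    A missing lymph-node mass (given only for the adult male in the
    reference tables) is filled by linear scaling from the male value by the
    body-mass ratio.
    """
    if name not in BODY_MASS_KG:
        raise ValueError(f"unknown reference person {name!r}")
    masses: dict[str, float] = {}
    for tid, t in tissues.items():
        if name in t.mass_g:
            masses[tid] = t.mass_g[name]
        elif tid == "lymph_nodes" and "male" in t.mass_g:
            masses[tid] = (
                t.mass_g["male"] * BODY_MASS_KG[name] / BODY_MASS_KG["male"]
            )
        else:
            raise KeyError(
                f"tissue {tid!r} has no reference mass for {name!r}"
            )
    return ReferencePerson(name, BODY_MASS_KG[name], masses,
                           HEIGHT_CM.get(name))


# --------------------------------------------------------------------------
# Census table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CensusTable:
    """Tissue x cell-type matrix of estimates with bootstrap margins."""

    entries: Mapping[tuple[str, str], LognormalEstimate]
    by_tissue: Mapping[str, BootstrapEstimate]
    by_type: Mapping[str, BootstrapEstimate]
    grand_total: BootstrapEstimate
    unit: str = "cells"

    def __post_init__(self) -> None:
        total = sum(e.value for e in self.entries.values())
        for label, margin in (("grand", self.grand_total),):
            if total > 0 and abs(margin.value - total) > 1e-9 * total:
                raise ValueError(f"{label} margin does not sum to entries")

    def tissue_total(self, tissue_id: str) -> float:
        return self.by_tissue[tissue_id].value

    def type_total(self, cell_type: str) -> float:
        return self.by_type[cell_type].value

    def group_total(
        self, tissues: Mapping[str, TissueRecord], group: str
    ) -> float:
        return sum(
            e.value for (t, _), e in self.entries.items()
            if tissues[t].group == group
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, ct, e.value, e.ferror)
            for (t, ct), e in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows, columns=["tissue_id", "cell_type", "value", "ferror"]
        )

    def margins_frame(self) -> pd.DataFrame:
        rows = []
        for t, m in sorted(self.by_tissue.items()):
            rows.append(("tissue", t, m.value, m.ferror, m.ci_low, m.ci_high))
        for ct, m in sorted(self.by_type.items()):
            rows.append(("cell_type", ct, m.value, m.ferror, m.ci_low,
                         m.ci_high))
        g = self.grand_total
        rows.append(("grand", "total", g.value, g.ferror, g.ci_low, g.ci_high))
        return pd.DataFrame(
            rows,
            columns=["margin", "key", "value", "ferror", "ci_low", "ci_high"],
        )


def round_to_one_significant(x: float) -> float:
    """Report-style rounding to the first significant digit."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


# --------------------------------------------------------------------------
# Method combination
# --------------------------------------------------------------------------

def combine_methods(
    literature: LognormalEstimate | None,
    multiplex: LognormalEstimate | None,
    tissue_group: str = "",
    multiplex_weight: float = DEFAULT_CONFIG.multiplex_weight,
) -> LognormalEstimate:
    """Inverse-variance combination of literature and multiplex densities.

    The multiplex weight multiplier (default 1, i.e. pure inverse-variance
    weighting) applies only in lymphoid-group tissues.  Deconvolution-based
    estimates never enter — they are validation only.
    """
    if literature is None and multiplex is None:
        raise ValueError("at least one method estimate is required")
    if multiplex is None:
        return literature
    if literature is None:
        return multiplex
    m = multiplex_weight if tissue_group == LYMPHOID_GROUP else 1.0
    return inverse_variance_combine([literature, multiplex], [1.0, m])


def _margin_groups(
    keys: Sequence[tuple[str, str]],
    correlation_keys: Mapping[tuple[str, str], str | None],
) -> list[CorrelationGroup]:
    members: dict[str, list[str]] = {}
    for key in keys:
        ck = correlation_keys.get(key)
        if ck:
            members.setdefault(ck, []).append(f"{key[0]}|{key[1]}")
    return [CorrelationGroup(k, v) for k, v in members.items() if len(v) > 1]


def _table_from_entries(
    entries: Mapping[tuple[str, str], LognormalEstimate],
    correlation_keys: Mapping[tuple[str, str], str | None],
    cfg: Config,
    unit: str,
) -> CensusTable:
    def margin(keys: Sequence[tuple[str, str]], seed: int) -> BootstrapEstimate:
        ests = [entries[k] for k in keys]
        ids = [f"{t}|{ct}" for t, ct in keys]
        groups = _margin_groups(keys, correlation_keys)
        return bootstrap_sum(ests, groups, n_draws=cfg.n_draws, seed=seed,
                             ids=ids)

    tissues_present = sorted({t for t, _ in entries})
    types_present = sorted({ct for _, ct in entries})
    by_tissue = {
        t: margin([k for k in entries if k[0] == t], cfg.seed)
        for t in tissues_present
    }
    by_type = {
        ct: margin([k for k in entries if k[1] == ct], cfg.seed)
        for ct in types_present
    }
    grand = margin(sorted(entries), cfg.seed)
    return CensusTable(dict(entries), by_tissue, by_type, grand, unit)


def integrate_counts(
    densities: Mapping[tuple[str, str], LognormalEstimate],
    person: ReferencePerson,
    correlation_keys: Mapping[tuple[str, str], str | None] | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> CensusTable:
    """Counts census: entry = density x organ mass; margins by bootstrap."""
    correlation_keys = correlation_keys or {}
    entries: dict[tuple[str, str], LognormalEstimate] = {}
    for (tissue_id, cell_type), density in densities.items():
        if tissue_id not in person.organ_masses:
            raise KeyError(
                f"no organ mass for tissue {tissue_id!r} "
                f"(person {person.name!r})"
            )
        mass = LognormalEstimate(person.organ_masses[tissue_id])
        entries[(tissue_id, cell_type)] = propagate_product(density, mass)
    return _table_from_entries(entries, correlation_keys, cfg, "cells")


def mass_census(
    counts: CensusTable,
    masses: Mapping[str, LognormalEstimate | Mapping],
    correlation_keys: Mapping[tuple[str, str], str | None] | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> CensusTable:
    """Mass census in grams: entry = count x per-cell mass.

    Macrophage masses are tissue-resolved: ``masses["macrophage"]`` maps
    tissue id -> estimate with a ``None``-keyed body-wide fallback.

    Margins use a two-factor bootstrap: count errors resample per entry
    (honoring the extrapolation correlation groups) while each distinct
    representative-mass estimate gets one shared deviate — the same per-cell
    mass multiplies that type's count in every tissue, so its error is
    perfectly correlated across tissues and must not average out in sums.
    """
    correlation_keys = correlation_keys or {}
    entries: dict[tuple[str, str], LognormalEstimate] = {}
    count_parts: dict[tuple[str, str], LognormalEstimate] = {}
    mass_parts: dict[tuple[str, str], LognormalEstimate] = {}
    for (tissue_id, cell_type), count in counts.entries.items():
        if cell_type not in masses:
            raise KeyError(f"no representative mass for {cell_type!r}")
        per_cell = masses[cell_type]
        if isinstance(per_cell, Mapping):
            per_cell = per_cell.get(tissue_id, per_cell.get(None))
            if per_cell is None:
                raise KeyError(
                    f"no macrophage mass for tissue {tissue_id!r} and no "
                    "fallback"
                )
        key = (tissue_id, cell_type)
        entries[key] = propagate_product(count, per_cell)
        count_parts[key] = count
        mass_parts[key] = per_cell

    # Shared-deviate units: one per correlation group / solo entry for the
    # count factor, one per distinct mass estimate for the mass factor.
    keys = sorted(entries)
    ids = [f"{t}|{ct}" for t, ct in keys]
    count_units = _correlation_units_for(keys, correlation_keys)
    mass_unit_of: dict[int, int] = {}
    seen_masses: dict[int, int] = {}
    for j, key in enumerate(keys):
        mid = id(mass_parts[key])
        if mid not in seen_masses:
            seen_masses[mid] = len(seen_masses)
        mass_unit_of[j] = seen_masses[mid]

    def margin(sub: Sequence[int], seed: int) -> BootstrapEstimate:
        rng = np.random.default_rng(seed)
        zc = rng.standard_normal((cfg.n_draws, max(count_units) + 1))
        zm = rng.standard_normal((cfg.n_draws, len(seen_masses)))
        draws = np.zeros(cfg.n_draws)
        point = 0.0
        for j in sub:
            key = keys[j]
            c, m = count_parts[key], mass_parts[key]
            point += c.value * m.value
            if c.value == 0:
                continue
            draws += (
                c.value * np.exp(c.s * zc[:, count_units[j]])
                * m.value * np.exp(m.s * zm[:, mass_unit_of[j]])
            )
        lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
        positive = draws[draws > 0]
        s_fit = (
            float(np.std(np.log(positive), ddof=1))
            if point > 0 and positive.size > 1
            else 0.0
        )
        return BootstrapEstimate(point, math.exp(s_fit), ci_low=float(lo),
                                 ci_median=float(med), ci_high=float(hi),
                                 n_draws=cfg.n_draws)

    tissues_present = sorted({t for t, _ in keys})
    types_present = sorted({ct for _, ct in keys})
    by_tissue = {
        t: margin([j for j, k in enumerate(keys) if k[0] == t], cfg.seed)
        for t in tissues_present
    }
    by_type = {
        ct: margin([j for j, k in enumerate(keys) if k[1] == ct], cfg.seed)
        for ct in types_present
    }
    grand = margin(list(range(len(keys))), cfg.seed)
    return CensusTable(entries, by_tissue, by_type, grand, "grams")


def _correlation_units_for(
    keys: Sequence[tuple[str, str]],
    correlation_keys: Mapping[tuple[str, str], str | None],
) -> list[int]:
    unit_index: dict[str, int] = {}
    units = []
    for t, ct in keys:
        label = correlation_keys.get((t, ct)) or f"__solo__{t}|{ct}"
        if label not in unit_index:
            unit_index[label] = len(unit_index)
        units.append(unit_index[label])
    return units


def scale_to_person(
    densities: Mapping[tuple[str, str], LognormalEstimate],
    target: ReferencePerson,
    correlation_keys: Mapping[tuple[str, str], str | None] | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> CensusTable:
    """Re-integrate the same densities against another person's organ masses.

    Densities are treated as independent of sex and age; only the organ
    masses change, so entries scale exactly with them.
    """
    return integrate_counts(densities, target, correlation_keys, cfg)


# --------------------------------------------------------------------------
# Scenario engine
# --------------------------------------------------------------------------

def volume_factor_from_diameter(diameter_ratio: float) -> float:
    """Cube law: a diameter change by r scales volume (and cell content) r^3."""
    if diameter_ratio <= 0:
        raise ValueError("diameter ratio must be positive")
    return diameter_ratio**3


@dataclass(frozen=True)
class ScenarioModifier:
    """One perturbation: an organ-mass factor (optionally limited to a mass
    fraction of the tissue) or a (tissue, cell type) density factor.

    ``kind="mass"`` with ``fraction=f`` and ``factor=v`` scales the tissue's
    effective mass by ``1 + f*(v - 1)`` — e.g. lymphadenopathy enlarging 2%
    of lymph-node mass 11-fold gives a 1.20 factor.
    """

    kind: str  # "mass" | "density"
    tissue_id: str
    factor: float
    fraction: float = 1.0
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"mass", "density"}:
            raise ValueError(f"unknown modifier kind {self.kind!r}")
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.kind == "density" and self.cell_type is None:
            raise ValueError("density modifiers need a cell type")


@dataclass(frozen=True)
class ScenarioResult:
    census: CensusTable
    margin_changes: pd.DataFrame  # relative change of each margin


def apply_scenario(
    densities: Mapping[tuple[str, str], LognormalEstimate],
    person: ReferencePerson,
    scenario: Sequence[ScenarioModifier],
    correlation_keys: Mapping[tuple[str, str], str | None] | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> ScenarioResult:
    """Recompute the census under a perturbation scenario.

    Reports the relative change of every margin versus the unperturbed
    census for the same person.
    """
    known = set(person.organ_masses)
    for m in scenario:
        if m.tissue_id not in known:
            raise KeyError(f"unknown tissue {m.tissue_id!r} in scenario")

    new_masses = dict(person.organ_masses)
    new_densities = dict(densities)
    for m in scenario:
        if m.kind == "mass":
            eff = 1.0 + m.fraction * (m.factor - 1.0)
            new_masses[m.tissue_id] *= eff
        else:
            key = (m.tissue_id, m.cell_type)
            if key in new_densities:
                new_densities[key] = new_densities[key].scaled(m.factor)

    # A perturbation may push organ mass above the reference body mass
    # (splenomegaly, obesity); the body-mass bound tracks the enlargement.
    perturbed_body = max(
        person.body_mass_kg, sum(new_masses.values()) / 1000.0
    )
    perturbed_person = ReferencePerson(
        person.name, perturbed_body, new_masses, person.height_cm
    )
    base = integrate_counts(densities, person, correlation_keys, cfg)
    new = integrate_counts(new_densities, perturbed_person, correlation_keys,
                           cfg)

    rows = []
    for t in base.by_tissue:
        b, n = base.by_tissue[t].value, new.by_tissue[t].value
        rows.append(("tissue", t, n / b - 1 if b else np.nan))
    for ct in base.by_type:
        b, n = base.by_type[ct].value, new.by_type[ct].value
        rows.append(("cell_type", ct, n / b - 1 if b else np.nan))
    rows.append(
        ("grand", "total",
         new.grand_total.value / base.grand_total.value - 1
         if base.grand_total.value else np.nan)
    )
    changes = pd.DataFrame(rows, columns=["margin", "key", "relative_change"])
    return ScenarioResult(new, changes)


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CensusResult:
    person: ReferencePerson
    densities: Mapping[tuple[str, str], LognormalEstimate]
    correlation_keys: Mapping[tuple[str, str], str | None]
    counts: CensusTable
    mass: CensusTable
    extrapolation_audit: pd.DataFrame

    def summary(self) -> dict:
        lymphocytes = sum(
            self.counts.by_type[ct].value
            for ct in LYMPHOCYTES
            if ct in self.counts.by_type
        )
        granulocytes = sum(
            self.counts.by_type[ct].value
            for ct in GRANULOCYTES
            if ct in self.counts.by_type
        )
        return {
            "person": self.person.name,
            "total_cells": self.counts.grand_total.value,
            "total_cells_ci": [self.counts.grand_total.ci_low,
                               self.counts.grand_total.ci_high],
            "total_mass_g": self.mass.grand_total.value,
            "total_mass_ci": [self.mass.grand_total.ci_low,
                              self.mass.grand_total.ci_high],
            "lymphocyte_cells": lymphocytes,
            "granulocyte_cells": granulocytes,
            "macrophage_mass_g": self.mass.by_type["macrophage"].value
            if "macrophage" in self.mass.by_type
            else 0.0,
        }


def combined_densities(
    evidence: pd.DataFrame,
    tissues: Mapping[str, TissueRecord],
    multiplex_samples: Sequence[MultiplexSample] | None = None,
    person: str = "male",
    cfg: Config = DEFAULT_CONFIG,
) -> tuple[
    dict[tuple[str, str], LognormalEstimate],
    dict[tuple[str, str], str | None],
    pd.DataFrame,
]:
    """Evidence tables -> one combined per-gram density per (tissue, type).

    Literature method classes (histology, flow, total-count) are merged per
    class by geometric mean, combined across classes by inverse-variance
    weighting, then combined with the multiplexed-imaging estimate where one
    exists.  Pairs without human evidence are filled by extrapolation, which
    also yields the correlation keys and the audit table.
    """
    records = normalize_evidence(evidence, tissues, person, cfg)
    filled, audit = fill_missing_densities(records, tissues, cfg)
    merged = merge_method_records(records + filled)

    mpx: dict[tuple[str, str], LognormalEstimate] = {}
    if multiplex_samples:
        for md in multiplex_densities(multiplex_samples, tissues,
                                      cfg.z_cutoff):
            if not md.is_zero:
                mpx[(md.tissue_id, md.cell_type)] = md.estimate

    densities: dict[tuple[str, str], LognormalEstimate] = {}
    correlation_keys: dict[tuple[str, str], str | None] = {}
    extrapolated_keys = {
        (r.tissue_id, r.cell_type): r.provenance for r in filled
    }

    pairs = sorted(
        {(t, ct) for (t, ct, _m) in merged} | set(mpx)
        | {(t, ct) for t in tissues for ct in CELL_TYPES}
    )
    for t, ct in pairs:
        if (t, ct) in extrapolated_keys:
            # The extrapolated record already pooled this pair's non-human
            # evidence; using the raw rodent records too would double-count.
            methods = ("extrapolated",)
        else:
            methods = LITERATURE_METHODS
        lit_parts = [
            merged[(t, ct, m)]
            for m in methods
            if (t, ct, m) in merged and merged[(t, ct, m)].value > 0
        ]
        lit = (
            inverse_variance_combine(lit_parts) if lit_parts else None
        )
        est = (
            combine_methods(lit, mpx.get((t, ct)), tissues[t].group,
                            cfg.multiplex_weight)
            if (lit is not None or (t, ct) in mpx)
            else LognormalEstimate(0.0)
        )
        densities[(t, ct)] = est
        correlation_keys[(t, ct)] = extrapolated_keys.get((t, ct))
    return densities, correlation_keys, audit


def build_census(
    evidence: pd.DataFrame,
    tissues: Mapping[str, TissueRecord],
    size_records: Sequence[CellSizeRecord],
    multiplex_samples: Sequence[MultiplexSample] | None = None,
    person: str = "male",
    cfg: Config = DEFAULT_CONFIG,
) -> CensusResult:
    """Full pipeline: evidence -> densities -> counts and mass censuses."""
    densities, correlation_keys, audit = combined_densities(
        evidence, tissues, multiplex_samples, person, cfg
    )
    who = reference_person(person, tissues)
    counts = integrate_counts(densities, who, correlation_keys, cfg)
    masses = mass_table(size_records, tissues=list(tissues), cfg=cfg)
    mass = mass_census(counts, masses, correlation_keys, cfg)
    return CensusResult(who, densities, correlation_keys, counts, mass, audit)
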
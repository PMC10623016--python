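"""Synthetic input bundles with known ground truth.

The generator emulates the statistical structure of a curated density
evidence base: per-tissue-group density scales spanning several orders of
magnitude (marrow and lymphoid organs highest, epithelia about an order
lower, muscle and fat up to two orders below epithelia), lognormal evidence
scatter around the true densities, Poisson multiplexed-imaging counts with a
between-patient lognormal random effect, deconvolution fraction tables
consistent with the true compositions, and literature-style cell-size
records.  Every stage of the pipeline can therefore be tested for parameter
recovery without any external download.

Everything is deterministic per seed, and a zero-noise configuration makes
the pipeline's output equal the ground truth exactly (the count-based
multiplex and fraction channels are disabled there, as Poisson
discretisation is itself a noise source).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cellmass import CellSizeRecord
from .census import BODY_MASS_KG, reference_person
from .density import CELL_TYPES, TissueRecord, default_tissues
from .multiplex import DEFAULT_DIAMETERS_UM, DEFAULT_FIELD_AREA_UM2
from .uncertainty import LognormalEstimate

__all__ = ["SynthConfig", "GroundTruth", "SynthBundle", "generate_bundle",
           "reference_preset", "run_bundle"]

# --------------------------------------------------------------------------
# Study conditions: group density scales and compositions
# --------------------------------------------------------------------------

#: log10 total immune-cell density (cells/g) per tissue group.  Calibrated
#: so the reference male census lands near the published whole-body totals:
#: marrow and lymphoid organs are densest, epithelia an order of magnitude
#: lower, muscle and fat roughly two orders below epithelia.
GROUP_LOG10_DENSITY: dict[str, float] = {
    "bone marrow": 8.80,
    "lymphatic": 9.30,
    "blood": 6.85,
    "barrier epithelial": 7.55,
    "other epithelial": 7.45,
    "striated muscle": 5.55,
    "adipose": 5.55,
    "other connective": 6.60,
    "CNS": 6.65,
    "extracellular fluids and matrix": 4.50,
}

#: Cell-type composition of the immune population per tissue group.
#: Normalised at use; types restricted away from a tissue are zeroed there
#: without renormalisation.
GROUP_TYPE_FRACTIONS: dict[str, dict[str, float]] = {
    "bone marrow": {
        "neutrophil": 0.78, "eosinophil": 0.034, "basophil": 0.002,
        "monocyte": 0.03, "macrophage": 0.02, "T cell": 0.05, "B cell": 0.06,
        "NK cell": 0.005, "plasma cell": 0.005, "dendritic cell": 0.004,
        "mast cell": 0.0005,
    },
    "lymphatic": {
        "T cell": 0.50, "B cell": 0.30, "plasma cell": 0.012, "NK cell": 0.02,
        "dendritic cell": 0.05, "macrophage": 0.06, "neutrophil": 0.04,
        "mast cell": 0.008, "eosinophil": 0.005, "monocyte": 0.005,
    },
    "blood": {
        "neutrophil": 0.58, "T cell": 0.20, "B cell": 0.05, "NK cell": 0.05,
        "monocyte": 0.08, "basophil": 0.007, "eosinophil": 0.025,
        "dendritic cell": 0.005, "plasma cell": 0.003,
    },
    "barrier epithelial": {
        "mast cell": 0.30, "macrophage": 0.25, "T cell": 0.20, "B cell": 0.05,
        "plasma cell": 0.07, "dendritic cell": 0.05, "eosinophil": 0.03,
        "NK cell": 0.02, "neutrophil": 0.02, "monocyte": 0.01,
    },
    "other epithelial": {
        "macrophage": 0.62, "T cell": 0.16, "NK cell": 0.10, "B cell": 0.05,
        "dendritic cell": 0.03, "monocyte": 0.02, "neutrophil": 0.02,
    },
    "striated muscle": {
        "macrophage": 0.60, "T cell": 0.18, "B cell": 0.06,
        "dendritic cell": 0.06, "NK cell": 0.04, "monocyte": 0.03,
        "neutrophil": 0.03,
    },
    "adipose": {
        "macrophage": 0.70, "T cell": 0.15, "B cell": 0.05,
        "dendritic cell": 0.04, "NK cell": 0.03, "monocyte": 0.03,
    },
    "other connective": {
        "mast cell": 0.40, "macrophage": 0.35, "T cell": 0.15, "B cell": 0.05,
        "dendritic cell": 0.05,
    },
    "CNS": {
        "macrophage": 0.93, "T cell": 0.04, "dendritic cell": 0.02,
        "B cell": 0.01,
    },
    "extracellular fluids and matrix": {
        "macrophage": 0.50, "T cell": 0.30, "B cell": 0.10,
        "dendritic cell": 0.10,
    },
}

#: True cell diameters (μm) used for the size channel; back-solved from the
#: published per-type count and mass totals (sphere at 1.07 g/mL).
TRUE_DIAMETERS_UM: dict[str, float] = {
    "T cell": 7.1,
    "B cell": 7.1,
    "plasma cell": 14.0,
    "NK cell": 7.1,
    "neutrophil": 8.0,
    "eosinophil": 7.6,
    "basophil": 8.6,
    "mast cell": 12.6,
    "macrophage": 17.5,
    "monocyte": 9.2,
    "dendritic cell": 15.3,
}

#: Tissue groups eligible for missing-pair knockout (exercising
#: extrapolation).  Data-poor, low-density tissues, as in real evidence
#: bases; dense tissues are always directly measured.
KNOCKOUT_GROUPS = frozenset(
    {"striated muscle", "adipose", "CNS", "other connective",
     "extracellular fluids and matrix"}
)

LYMPHOID_TISSUES = ("spleen", "lymph_nodes", "thymus", "tonsils")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    #: independent literature records per (tissue, type) pair
    evidence_per_pair: int = 3
    #: declared multiplicative error of each literature record
    evidence_ferror: float = 1.8
    #: per-tissue lognormal jitter (log-e SD) of true densities around the
    #: group scale — biological variation, part of the ground truth
    density_jitter_s: float = 0.25
    #: probability that a knockout-eligible pair loses its human evidence
    missing_pair_prob: float = 0.25
    #: fraction of knocked-out pairs that instead get rodent records
    rodent_fraction: float = 0.5
    multiplex_patients: int = 3
    multiplex_fields_per_patient: int = 4
    #: between-patient lognormal random effect (log-e SD) on field counts
    patient_effect_s: float = 0.2
    fraction_samples_per_tissue: int = 3
    fraction_noise_s: float = 0.3
    size_records_per_type: int = 3
    #: lognormal volume scatter (log-e SD) of size records
    size_noise_s: float = 0.15
    #: master noise switch; 0 collapses every noise source and disables the
    #: count-based channels (Poisson discretisation is itself noise)
    noise_scale: float = 1.0
    #: anchor-count declared ferror for the fraction channel
    anchor_ferror: float = 1.2
    #: assumed immune share of all cells for the fraction denominators
    immune_share: float = 0.5

    def noiseless(self) -> "SynthConfig":
        return replace(self, noise_scale=0.0, missing_pair_prob=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually simulated, for recovery checks."""

    densities: Mapping[tuple[str, str], float]  # cells/g
    cell_mass_g: Mapping[str, float]
    counts: Mapping[tuple[str, str], float]  # reference-male counts
    totals_by_tissue: Mapping[str, float]
    totals_by_type: Mapping[str, float]
    grand_total: float
    grand_mass_g: float


@dataclass(frozen=True)
class SynthBundle:
    config: SynthConfig
    evidence: pd.DataFrame
    multiplex: pd.DataFrame
    fractions: pd.DataFrame
    anchors: pd.DataFrame
    sizes: pd.DataFrame
    tissues: Mapping[str, TissueRecord]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Write the bundle in the CSV dialects the pipeline readers accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.evidence.to_csv(outdir / "evidence.csv", index=False)
        self.multiplex.to_csv(outdir / "multiplex.csv", index=False)
        self.fractions.to_csv(outdir / "fractions.csv", index=False)
        self.anchors.to_csv(outdir / "anchors.csv", index=False)
        self.sizes.to_csv(outdir / "sizes.csv", index=False)
        rows = []
        for t in self.tissues.values():
            rows.append(
                {
                    "tissue_id": t.tissue_id,
                    "group": t.group,
                    "specific_gravity": t.specific_gravity,
                    **{f"mass_{p}_g": t.mass_g.get(p) for p in
                       ("male", "female", "child")},
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "tissues.csv", index=False)
        truth = pd.DataFrame(
            [(t, ct, d) for (t, ct), d in sorted(self.truth.densities.items())],
            columns=["tissue_id", "cell_type", "true_density_per_g"],
        )
        truth.to_csv(outdir / "truth_densities.csv", index=False)


def reference_preset() -> SynthConfig:
    """The default study conditions (see module docstring)."""
    return SynthConfig()


def _true_densities(
    tissues: Mapping[str, TissueRecord], rng: np.random.Generator,
    jitter_s: float,
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for tid in sorted(tissues):
        t = tissues[tid]
        total = 10.0 ** GROUP_LOG10_DENSITY[t.group]
        fracs = GROUP_TYPE_FRACTIONS[t.group]
        norm = sum(fracs.values())
        for ct in CELL_TYPES:
            f = fracs.get(ct, 0.0) / norm
            if f == 0.0 or not CELL_TYPES[ct].allowed_in(t):
                out[(tid, ct)] = 0.0
                continue
            jitter = math.exp(jitter_s * rng.standard_normal())
            out[(tid, ct)] = total * f * jitter
    return out


def generate_bundle(cfg: SynthConfig) -> SynthBundle:
    """Generate a complete, internally consistent input bundle.

    Deterministic per ``cfg.seed``; no global random state is touched.
    """
    rng = np.random.default_rng(cfg.seed)
    tissues = default_tissues()
    noise = cfg.noise_scale
    truth_density = _true_densities(tissues, rng, cfg.density_jitter_s)

    # --- literature evidence -------------------------------------------
    s_ev = math.log(cfg.evidence_ferror)
    evidence_rows = []
    for (tid, ct) in sorted(truth_density):
        d = truth_density[(tid, ct)]
        if d == 0.0:
            continue
        t = tissues[tid]
        knockout = (
            t.group in KNOCKOUT_GROUPS
            and rng.random() < cfg.missing_pair_prob
        )
        if knockout:
            if rng.random() < cfg.rodent_fraction:
                # rodent evidence with wider scatter, feeding cross-species
                # extrapolation
                for _ in range(2):
                    value = d * math.exp(noise * 1.5 * s_ev
                                         * rng.standard_normal())
                    evidence_rows.append(
                        dict(tissue_id=tid, cell_type=ct, method="histology",
                             value=value, value_kind="per_gram",
                             ferror_or_se=cfg.evidence_ferror if noise else 1.0,
                             species="rodent", source="synthetic rodent")
                    )
            continue
        for i in range(cfg.evidence_per_pair):
            value = d * math.exp(noise * s_ev * rng.standard_normal())
            evidence_rows.append(
                dict(tissue_id=tid, cell_type=ct, method="histology",
                     value=value, value_kind="per_gram",
                     ferror_or_se=cfg.evidence_ferror if noise else 1.0,
                     species="human", source=f"synthetic study {i}")
            )
    evidence = pd.DataFrame(evidence_rows)

    # --- multiplexed imaging (lymphoid organs only) --------------------
    mpx_rows = []
    if noise > 0:
        A_cm2 = DEFAULT_FIELD_AREA_UM2 / 1e8
        for tid in LYMPHOID_TISSUES:
            t = tissues[tid]
            for p in range(cfg.multiplex_patients):
                effect = math.exp(cfg.patient_effect_s * noise
                                  * rng.standard_normal())
                for f in range(cfg.multiplex_fields_per_patient):
                    for ct in CELL_TYPES:
                        d = truth_density[(tid, ct)]
                        if d == 0.0:
                            continue
                        D_cm = DEFAULT_DIAMETERS_UM[ct] / 1e4
                        lam = (d * t.specific_gravity) * A_cm2 * D_cm * effect
                        count = int(rng.poisson(lam))
                        mpx_rows.append(
                            dict(sample_id=f"{tid}_p{p}_f{f}",
                                 patient_id=f"{tid}_p{p}", tissue=tid,
                                 cell_type=ct, count=count)
                        )
    multiplex = pd.DataFrame(
        mpx_rows,
        columns=["sample_id", "patient_id", "tissue", "cell_type", "count"],
    )

    # --- deconvolution fractions (validation channel) ------------------
    group_of_type = {
        "T cell": "T", "B cell": "B", "NK cell": "NK",
        "neutrophil": "granulocyte", "eosinophil": "granulocyte",
        "basophil": "granulocyte", "mast cell": "granulocyte",
        "macrophage": "nongranulocyte-myeloid",
        "monocyte": "nongranulocyte-myeloid",
        "dendritic cell": "nongranulocyte-myeloid",
        "plasma cell": "B",
    }
    frac_rows, anchor_rows = [], []
    if noise > 0:
        person = reference_person("male", tissues)
        for tid in sorted(tissues):
            immune_total = sum(
                truth_density[(tid, ct)] for ct in CELL_TYPES
            ) * person.organ_masses[tid]
            if immune_total == 0:
                continue
            all_cells = immune_total / cfg.immune_share
            t_count = (
                truth_density[(tid, "T cell")] * person.organ_masses[tid]
            )
            if t_count == 0:
                continue
            anchor_rows.append(
                dict(tissue=tid, anchor_type="T",
                     anchor_fraction=t_count / all_cells,
                     anchor_count=t_count, anchor_ferror=cfg.anchor_ferror)
            )
            group_counts: dict[str, float] = {}
            for ct in CELL_TYPES:
                g = group_of_type[ct]
                group_counts[g] = group_counts.get(g, 0.0) + (
                    truth_density[(tid, ct)] * person.organ_masses[tid]
                )
            for i in range(cfg.fraction_samples_per_tissue):
                for g, c in sorted(group_counts.items()):
                    if c == 0:
                        continue
                    frac = min(
                        c / all_cells
                        * math.exp(cfg.fraction_noise_s * noise
                                   * rng.standard_normal()),
                        1.0,
                    )
                    frac_rows.append(
                        dict(sample_id=f"{tid}_s{i}", tissue=tid, group=g,
                             fraction=frac)
                    )
    fractions = pd.DataFrame(
        frac_rows, columns=["sample_id", "tissue", "group", "fraction"]
    )
    anchors = pd.DataFrame(
        anchor_rows,
        columns=["tissue", "anchor_type", "anchor_fraction", "anchor_count",
                 "anchor_ferror"],
    )

    # --- cell sizes ----------------------------------------------------
    size_rows = []
    for ct in CELL_TYPES:
        d_true = TRUE_DIAMETERS_UM[ct]
        for i in range(cfg.size_records_per_type):
            # volume-scale lognormal scatter -> diameter scatter /3
            d = d_true * math.exp(cfg.size_noise_s * noise
                                  * rng.standard_normal() / 3)
            if noise > 0 and i == cfg.size_records_per_type - 1:
                # one blood-smear record, inflated so the 0.7 correction
                # recovers the true volume
                size_rows.append(
                    dict(cell_type=ct, tissue=None,
                         diameter_low_um=d * (1 / 0.7) ** (1 / 3),
                         diameter_high_um=None, volume_um3=None,
                         context="blood smear", species="human",
                         source="synthetic smear")
                )
            else:
                size_rows.append(
                    dict(cell_type=ct, tissue=None, diameter_low_um=d,
                         diameter_high_um=None, volume_um3=None,
                         context="tissue section", species="human",
                         source=f"synthetic size {i}")
                )
    sizes = pd.DataFrame(size_rows)

    # --- ground truth --------------------------------------------------
    cell_mass = {
        ct: math.pi / 6 * TRUE_DIAMETERS_UM[ct] ** 3 * 1.07e-12
        for ct in CELL_TYPES
    }
    person = reference_person("male", tissues)
    counts = {
        (tid, ct): truth_density[(tid, ct)] * person.organ_masses[tid]
        for (tid, ct) in truth_density
    }
    by_tissue: dict[str, float] = {}
    by_type: dict[str, float] = {}
    for (tid, ct), c in counts.items():
        by_tissue[tid] = by_tissue.get(tid, 0.0) + c
        by_type[ct] = by_type.get(ct, 0.0) + c
    truth = GroundTruth(
        densities=truth_density,
        cell_mass_g=cell_mass,
        counts=counts,
        totals_by_tissue=by_tissue,
        totals_by_type=by_type,
        grand_total=sum(counts.values()),
        grand_mass_g=sum(c * cell_mass[ct] for (_, ct), c in counts.items()),
    )
    return SynthBundle(cfg, evidence, multiplex, fractions, anchors, sizes,
                       tissues, truth)


def run_bundle(bundle: SynthBundle, person: str = "male", cfg=None):
    """Run the full census pipeline on a synthetic bundle.

    Convenience wrapper used by tests and the acceptance script: wires the
    bundle's tables into the same readers the CLI uses.
    """
    from .cellmass import read_size_table
    from .census import build_census
    from .config import DEFAULT_CONFIG
    from .multiplex import read_multiplex_table

    cfg = cfg or DEFAULT_CONFIG
    samples = (
        read_multiplex_table(bundle.multiplex)
        if len(bundle.multiplex)
        else None
    )
    size_records = read_size_table(bundle.sizes)
    return build_census(
        bundle.evidence, bundle.tissues, size_records, samples, person, cfg
    )
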
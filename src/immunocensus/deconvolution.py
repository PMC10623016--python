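"""Absolute immune-cell counts from relative fractions via an anchor type.

Methylome deconvolution (and pathologist-scored compartment fractions) yield
*relative* cell-type fractions per tissue sample.  They become absolute
counts through an anchor cell type whose absolute number in the tissue is
independently known:  ``N_im = P_im * N_an / P_an``.

These estimates serve purely as cross-validation of the literature-based
census — they never enter the headline numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .uncertainty import LognormalEstimate, propagate_product

__all__ = [
    "FRACTION_GROUPS",
    "FractionSample",
    "absolute_from_fraction",
    "cluster_and_average",
    "compare_to_reference",
    "read_fraction_tables",
]

#: Immune groups resolvable by the methylation signatures, plus a single
#: undifferentiated "immune" compartment for histology-based fractions.
FRACTION_GROUPS = ("B", "T", "NK", "granulocyte", "nongranulocyte-myeloid",
                   "immune")


@dataclass(frozen=True)
class FractionSample:
    """One deconvolved sample: per-group fractions plus the anchor."""

    sample_id: str
    tissue_id: str
    fractions: Mapping[str, float]
    anchor_type: str
    anchor_fraction: float
    anchor_count: LognormalEstimate

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(FRACTION_GROUPS)
        if unknown:
            raise ValueError(f"unknown fraction groups: {sorted(unknown)}")
        if any(not (0 <= f <= 1) for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(self.fractions.values()) > 1 + 1e-6:
            raise ValueError("fractions sum above 1")
        if not (0 < self.anchor_fraction <= 1):
            raise ValueError(
                f"anchor fraction must be in (0, 1] "
                f"(sample {self.sample_id!r}, got {self.anchor_fraction})"
            )


def absolute_from_fraction(
    P_im: float,
    P_an: float,
    N_an: LognormalEstimate,
    fraction_se: float | None = None,
) -> LognormalEstimate:
    """Absolute count from relative fractions and an anchor count.

    ``N_im = P_im * N_an / P_an``; the anchor's ferror propagates unchanged.
    Fractions are treated as exact unless ``fraction_se`` (an SE on
    ``P_im``) is given, in which case its lognormal fit is folded in.
    """
    if P_an <= 0:
        raise ValueError(f"anchor fraction must be positive, got {P_an}")
    if P_im < 0:
        raise ValueError(f"fraction must be >= 0, got {P_im}")
    if P_im == 0:
        return LognormalEstimate(0.0)
    ratio = LognormalEstimate(P_im / P_an)
    if fraction_se is not None and fraction_se > 0:
        from .uncertainty import fit_lognormal_from_normal

        ratio = ratio.widened(fit_lognormal_from_normal(P_im, fraction_se).ferror)
    return propagate_product(ratio, N_an)


def cluster_and_average(
    samples: Sequence[FractionSample],
) -> dict[tuple[str, str], LognormalEstimate]:
    """Per-tissue, per-group absolute counts averaged across samples.

    Samples are grouped by their declared tissue label.  Within a tissue the
    per-sample absolute counts are combined by geometric mean; the combined
    ferror carries the between-sample log-SE plus the mean anchor ferror
    (root-sum-of-squares on the log scale).
    """
    per_key: dict[tuple[str, str], list[LognormalEstimate]] = {}
    for s in samples:
        for group, frac in s.fractions.items():
            est = absolute_from_fraction(frac, s.anchor_fraction, s.anchor_count)
            per_key.setdefault((s.tissue_id, group), []).append(est)

    out: dict[tuple[str, str], LognormalEstimate] = {}
    for key, ests in per_key.items():
        positive = [e for e in ests if e.value > 0]
        if not positive:
            out[key] = LognormalEstimate(0.0)
            continue
        logs = np.array([math.log(e.value) for e in positive])
        n = len(positive)
        value = math.exp(float(logs.mean()))
        se_between = float(np.std(logs, ddof=1)) / math.sqrt(n) if n > 1 else 0.0
        s_anchor = float(np.mean([e.s for e in positive]))
        s_comb = math.hypot(se_between, s_anchor)
        out[key] = LognormalEstimate(value, math.exp(s_comb))
    return out


def compare_to_reference(
    deconv: Mapping[tuple[str, str], LognormalEstimate],
    reference: Mapping[tuple[str, str], LognormalEstimate],
    z: float = 1.96,
) -> pd.DataFrame:
    """Validation table of deconvolution-based vs reference counts.

    For each overlapping (tissue, group): the log10 ratio, the combined
    ferror (product propagation of the two), and an agreement flag for
    ``|ln ratio| <= z * ln(combined ferror)``.  Purely diagnostic — census
    outputs are identical with or without deconvolution inputs.
    """
    keys = sorted(set(deconv) & set(reference))
    if not keys:
        raise ValueError("no overlapping (tissue, group) keys to compare")
    rows = []
    for tissue_id, group in keys:
        d = deconv[(tissue_id, group)]
        r = reference[(tissue_id, group)]
        if d.value == 0 or r.value == 0:
            rows.append((tissue_id, group, np.nan, np.nan, d.value == r.value))
            continue
        log_ratio = math.log(d.value / r.value)
        s_comb = math.hypot(d.s, r.s)
        agree = abs(log_ratio) <= z * s_comb
        rows.append(
            (tissue_id, group, log_ratio / math.log(10), math.exp(s_comb), agree)
        )
    return pd.DataFrame(
        rows, columns=["tissue_id", "group", "log10_ratio", "combined_ferror",
                       "agree"]
    )


def read_fraction_tables(
    fractions_path, anchors_path
) -> list[FractionSample]:
    """Assemble :class:`FractionSample` objects from the two CSV inputs.

    ``fractions``: sample_id, tissue, group, fraction (long format);
    ``anchors``: tissue, anchor_type, anchor_fraction, anchor_count,
    anchor_ferror.
    """
    fr = pd.read_csv(fractions_path)
    an = pd.read_csv(anchors_path).set_index("tissue")
    samples = []
    for (sample_id, tissue_id), grp in fr.groupby(["sample_id", "tissue"],
                                                  sort=True):
        if tissue_id not in an.index:
            raise KeyError(f"no anchor defined for tissue {tissue_id!r}")
        a = an.loc[tissue_id]
        samples.append(
            FractionSample(
                sample_id=str(sample_id),
                tissue_id=str(tissue_id),
                fractions=dict(zip(grp["group"], grp["fraction"].astype(float))),
                anchor_type=str(a["anchor_type"]),
                anchor_fraction=float(a["anchor_fraction"]),
                anchor_count=LognormalEstimate(
                    float(a["anchor_count"]), float(a.get("anchor_ferror", 1.0))
                ),
            )
        )
    return samples
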
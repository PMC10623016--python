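"""Evidence normalisation to per-gram densities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import immunocensus as ic
from immunocensus.density import (
    CELL_TYPES,
    DensityRecord,
    TissueRecord,
    compartment_weighted_density,
    density_from_areal_count,
    density_from_relative_abundance,
    density_from_total_count,
    merge_method_records,
    normalize_evidence,
    volumetric_to_per_gram,
)
from immunocensus.uncertainty import LognormalEstimate


@pytest.fixture
def generic_tissue():
    return TissueRecord("liver", "other epithelial", 1.03,
                        {"male": 1800.0})


@pytest.fixture
def adipose_tissue():
    return TissueRecord("adipose", "adipose", 0.91, {"male": 14500.0})


class TestVocabulary:
    def test_eleven_cell_types(self):
        assert len(CELL_TYPES) == 11
        lymphoid = [c for c in CELL_TYPES.values() if c.lineage == "lymphoid"]
        assert len(lymphoid) == 4

    def test_restricted_exactly_three(self):
        restricted = {n for n, c in CELL_TYPES.items() if c.is_restricted}
        assert restricted == {"eosinophil", "mast cell", "basophil"}


class TestArealCount:
    def test_zero_count(self):
        assert density_from_areal_count(0, 1, 5e-4, 1e-3) == 0

    def test_section_with_thickness(self):
        # 1000 cells over 0.01 cm^2, 5 um section, 10 um cells
        rho = density_from_areal_count(1000, 0.01, 5e-4, 1e-3)
        assert rho == pytest.approx(6.67e7, rel=1e-3)

    def test_zero_thickness_plane(self):
        assert density_from_areal_count(100, 1, 0, 1e-3) == pytest.approx(1e5)

    @pytest.mark.parametrize("bad", [dict(A=0), dict(D=0), dict(n=-1),
                                     dict(T=-1)])
    def test_domain_errors(self, bad):
        kwargs = dict(n=1, A=1.0, T=1e-4, D=1e-3)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            density_from_areal_count(**kwargs)

    @given(
        n=st.floats(min_value=0, max_value=1e6),
        c=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_count_inverse_in_area(self, n, c):
        base = density_from_areal_count(n, 1.0, 1e-4, 1e-3)
        assert density_from_areal_count(c * n, 1.0, 1e-4, 1e-3) == pytest.approx(
            c * base
        )
        assert density_from_areal_count(n, c, 1e-4, 1e-3) == pytest.approx(
            base / c
        )


class TestPerGramConversion:
    def test_generic_gravity(self, generic_tissue):
        assert volumetric_to_per_gram(1.03e6, generic_tissue) == pytest.approx(
            1e6
        )

    def test_adipose_gravity(self, adipose_tissue):
        assert volumetric_to_per_gram(9.1e5, adipose_tissue) == pytest.approx(
            1e6
        )

    def test_zero_density(self, generic_tissue):
        assert volumetric_to_per_gram(0, generic_tissue) == 0


class TestRelativeAbundance:
    def test_identity_fraction(self):
        ref = LognormalEstimate(1e7, 1.3)
        out = density_from_relative_abundance(1.0, ref)
        assert out.value == pytest.approx(1e7)
        assert out.ferror == pytest.approx(1.3)

    def test_exact_fraction_scales(self):
        out = density_from_relative_abundance(0.05, LognormalEstimate(2e8, 2))
        assert out.value == pytest.approx(1e7)
        assert out.ferror == pytest.approx(2.0)

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_rejects_bad_fraction(self, frac):
        with pytest.raises(ValueError):
            density_from_relative_abundance(frac, LognormalEstimate(1e7))


class TestTotalCount:
    def test_ferror_preserved(self):
        out = density_from_total_count(LognormalEstimate(7.3e11, 1.2), 73000)
        assert out.value == pytest.approx(1e7)
        assert out.ferror == pytest.approx(1.2)

    def test_exact(self):
        out = density_from_total_count(LognormalEstimate(0.5e9, 1.0), 500)
        assert out.value == pytest.approx(1e6) and out.ferror == 1.0

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            density_from_total_count(LognormalEstimate(1e9, 2), 0)

    def test_round_trip_total(self):
        # integrating the density back over the mass recovers the total
        total = LognormalEstimate(3.7e10, 1.7)
        d = density_from_total_count(total, 1234.0)
        assert d.value * 1234.0 == pytest.approx(total.value, rel=1e-12)


class TestCompartmentWeighting:
    def test_single_part_identity(self):
        d = LognormalEstimate(5e6, 1.4)
        out = compartment_weighted_density([(1.0, d)], seed=1)
        assert out.value == pytest.approx(d.value)

    def test_exact_weighted_mean(self):
        out = compartment_weighted_density(
            [(0.5, LognormalEstimate(2e6)), (0.5, LognormalEstimate(0.0))],
            seed=1,
        )
        assert out.value == pytest.approx(1e6) and out.ferror == 1.0

    def test_epithelium_vs_rest(self):
        out = compartment_weighted_density(
            [(0.1, LognormalEstimate(1e8)), (0.9, LognormalEstimate(1e6))],
            seed=1,
        )
        assert out.value == pytest.approx(1.09e7, rel=1e-9)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            compartment_weighted_density(
                [(0.5, LognormalEstimate(1e6))], seed=1
            )

    @given(
        parts=st.lists(
            st.tuples(
                st.floats(min_value=0.05, max_value=1.0),
                st.floats(min_value=1e3, max_value=1e9),
            ),
            min_size=1, max_size=5,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_betweenness(self, parts):
        total = sum(w for w, _ in parts)
        normed = [(w / total, LognormalEstimate(v, 1.3)) for w, v in parts]
        out = compartment_weighted_density(normed, seed=2)
        vals = [v for _, v in parts]
        assert min(vals) * (1 - 1e-9) <= out.value <= max(vals) * (1 + 1e-9)


class TestDensityRecord:
    def test_extrapolated_cannot_be_human(self):
        with pytest.raises(ValueError):
            DensityRecord("liver", "T cell", LognormalEstimate(1e6, 1.5),
                          "extrapolated", species="human")


class TestEvidenceNormalization:
    def make_table(self):
        return pd.DataFrame(
            [
                # per-gram row with explicit ferror
                dict(tissue_id="liver", cell_type="T cell",
                     method="histology", value=2e6, value_kind="per_gram",
                     ferror_or_se=1.5, species="human", source="a"),
                # per-cm3 row: divided by 1.03
                dict(tissue_id="liver", cell_type="T cell", method="flow",
                     value=1.03e6, value_kind="per_cm3", ferror_or_se=1.5,
                     species="human", source="b"),
                # areal count row
                dict(tissue_id="liver", cell_type="macrophage",
                     method="histology", value=1000, value_kind="areal_count",
                     A_cm2=0.01, T_um=5.0, D_um=10.0, ferror_or_se=2.0,
                     species="human", source="c"),
                # SE-declared error converted by moment matching
                dict(tissue_id="liver", cell_type="NK cell",
                     method="histology", value=100.0, value_kind="per_gram",
                     ferror_or_se=50.0, error_kind="se", species="human",
                     source="d"),
                # total-count row uses the male liver mass (1800 g)
                dict(tissue_id="liver", cell_type="B cell",
                     method="total-count", value=1.8e9,
                     value_kind="total_count", ferror_or_se=1.2,
                     species="human", source="e"),
                # rodent row gets the species penalty
                dict(tissue_id="liver", cell_type="monocyte",
                     method="histology", value=1e5, value_kind="per_gram",
                     ferror_or_se=2.0, species="rodent", source="f"),
            ]
        )

    def test_normalization(self, tissues):
        records = normalize_evidence(self.make_table(), tissues)
        by = {(r.cell_type, r.method): r for r in records}
        assert by[("T cell", "histology")].density.value == pytest.approx(2e6)
        assert by[("T cell", "flow")].density.value == pytest.approx(1e6)
        assert by[("macrophage", "histology")].density.value == pytest.approx(
            6.67e7 / 1.03, rel=1e-3
        )
        # moment-matched SE: median 100*exp(-s^2/2) with s^2 = ln 1.25
        nk = by[("NK cell", "histology")].density
        assert nk.value == pytest.approx(89.44, abs=0.01)
        assert by[("B cell", "total-count")].density.value == pytest.approx(
            1e6
        )
        mono = by[("monocyte", "histology")].density
        assert mono.ferror == pytest.approx(2.0 * 1.5)  # species penalty

    def test_unknown_tissue_rejected(self, tissues):
        df = self.make_table()
        df.loc[0, "tissue_id"] = "gills"
        with pytest.raises(KeyError):
            normalize_evidence(df, tissues)


class TestMergeMethodRecords:
    def test_geometric_mean_with_spread(self):
        recs = [
            DensityRecord("liver", "T cell", LognormalEstimate(1e6, 1.5),
                          "histology"),
            DensityRecord("liver", "T cell", LognormalEstimate(4e6, 1.5),
                          "histology"),
        ]
        merged = merge_method_records(recs)
        est = merged[("liver", "T cell", "histology")]
        assert est.value == pytest.approx(2e6, rel=1e-12)
        # spread folded in: s^2 = mean(s_i^2)/2 + var(log v)/2
        s_f = math.log(1.5)
        between = np.var([math.log(1e6), math.log(4e6)], ddof=1) / 2
        assert est.s == pytest.approx(
            math.sqrt(s_f**2 / 2 + between), rel=1e-9
        )

    def test_single_record_passthrough(self):
        recs = [DensityRecord("liver", "T cell",
                              LognormalEstimate(1e6, 1.5), "histology")]
        est = merge_method_records(recs)[("liver", "T cell", "histology")]
        assert est.value == pytest.approx(1e6, rel=1e-12)
        assert est.ferror == pytest.approx(1.5, rel=1e-12)


class TestSyntheticRecovery:
    def test_per_pair_truth_within_ci(self):
        """Normalised densities cover generator truth in >=90% of pairs
        over seeded replicates."""
        from dataclasses import replace

        hits = tot = 0
        for seed in range(200):
            b = ic.generate_bundle(
                replace(ic.reference_preset(), seed=seed,
                        missing_pair_prob=0.0)
            )
            recs = normalize_evidence(
                b.evidence[b.evidence.tissue_id == "liver"], b.tissues
            )
            for (t, ct, _m), est in merge_method_records(recs).items():
                if est.value == 0:
                    continue
                lo, hi = ic.ci95(est)
                truth = b.truth.densities[(t, ct)]
                tot += 1
                hits += lo <= truth <= hi
        assert tot > 1000
        assert hits / tot >= 0.90
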
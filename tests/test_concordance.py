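import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coupledomics.concordance import (
    activity_bias,
    concordance_by_condition,
    cross_layer_presence,
    delta_frame,
    normalize_library,
    paired_concordance,
    temporal_deltas,
)
from coupledomics.io_tables import CountTable, SampleMeta, ValidationError


class TestNormalizeLibrary:
    def test_column_divided_by_total(self, taxon_table):
        r = normalize_library(taxon_table)
        assert r.data["s1"].tolist() == pytest.approx([0.2, 0.3, 0.5])
        assert np.allclose(r.data.sum(axis=0), 1.0)

    def test_single_feature_ratio_one(self):
        t = CountTable(pd.DataFrame({"s1": [9.0]}, index=["A"]), "metagenome", "taxon")
        assert normalize_library(t).data.loc["A", "s1"] == 1.0

    def test_all_zero_column_named(self):
        t = CountTable(pd.DataFrame({"bad": [0.0], "ok": [1.0]}, index=["A"]),
                       "metagenome", "taxon")
        with pytest.raises(ValidationError, match="bad"):
            normalize_library(t)


class TestTemporalDeltas:
    def test_printed_formula(self):
        ratios = pd.DataFrame([[0.1, 0.3, 0.2]], index=["A"], columns=[1, 5, 8])
        [series] = temporal_deltas(ratios, [1, 5, 8])
        assert series.deltas == pytest.approx((0.0, 0.2, -0.1))

    def test_constant_series_all_zero(self):
        ratios = pd.DataFrame([[0.4] * 4], index=["A"], columns=[1, 5, 8, 12])
        [series] = temporal_deltas(ratios, [1, 5, 8, 12])
        assert series.deltas == (0.0, 0.0, 0.0, 0.0)

    def test_missing_day_column_treated_as_zero_ratio(self):
        ratios = pd.DataFrame([[0.1, 0.2]], index=["A"], columns=[1, 8])
        deltas = delta_frame(ratios, [1, 5, 8])
        # day 5 not observed for the whole frame: consecutive OBSERVED days 1, 8
        assert list(deltas.columns) == [1, 8]
        assert deltas.loc["A"].tolist() == pytest.approx([0.0, 0.1])

    def test_duplicate_day_rejected(self):
        ratios = pd.DataFrame([[0.1, 0.2]], index=["A"], columns=[1, 1])
        with pytest.raises(ValidationError, match="duplicate"):
            delta_frame(ratios, [1, 5])

    def test_day_not_in_configured_order_rejected(self):
        ratios = pd.DataFrame([[0.1]], index=["A"], columns=[99])
        with pytest.raises(ValidationError):
            delta_frame(ratios, [1, 5, 8, 12])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_telescoping_identity(self, seed):
        r = np.random.default_rng(seed)
        days = sorted(r.choice(30, size=int(r.integers(1, 8)), replace=False).tolist())
        vals = r.random((3, len(days)))
        ratios = pd.DataFrame(vals, index=list("ABC"), columns=days)
        for series in temporal_deltas(ratios, days):
            assert sum(series.deltas) == pytest.approx(
                series.ratios[-1] - series.ratios[0], abs=1e-12
            )


class TestPairedConcordance:
    def test_perfect_fit(self):
        x = pd.Series([0.1, 0.2, 0.3, 0.25, 0.15], index=list("abcde"))
        res = paired_concordance(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_features == 5

    def test_constant_psms_no_explained_variance(self):
        res = paired_concordance([0.0, 1.0, 2.0], [0.5, 0.5, 0.5])
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == 0.0

    def test_hand_computed_ols(self):
        # slope = Sxy/Sxx = 2.1/2; SS_res = 0.015, SS_tot = 2.22
        res = paired_concordance([0.0, 1.0, 2.0], [0.0, 0.9, 2.1])
        assert res.slope == pytest.approx(1.05)
        assert res.intercept == pytest.approx(-0.05)
        assert res.r_squared == pytest.approx(1 - 0.015 / 2.22, abs=1e-9)

    def test_fewer_than_two_features_rejected(self):
        with pytest.raises(ValidationError):
            paired_concordance([1.0], [1.0])

    def test_mismatched_feature_sets_listed(self):
        x = pd.Series([1.0, 2.0], index=["A", "B"])
        y = pd.Series([1.0, 2.0], index=["A", "C"])
        with pytest.raises(ValidationError, match="B.*C"):
            paired_concordance(x, y)


class TestActivityBias:
    def test_equal_ratios_exactly_zero(self):
        assert activity_bias(0.123, 0.123) == 0.0
        assert activity_bias(0.0, 0.0, pseudo=0.5) == 0.0

    def test_doubled_psm_share_is_one_log2_unit(self):
        assert activity_bias(0.1, 0.2, pseudo=1e-6) == pytest.approx(1.0, abs=1e-4)

    def test_sign_convention(self):
        assert activity_bias(0.1, 0.3) > 0  # overactive
        assert activity_bias(0.3, 0.1) < 0  # underactive

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            activity_bias(0.1, 0.2, pseudo=0.0)
        with pytest.raises(ValueError):
            activity_bias(1.5, 0.2)


def _layer_meta():
    return [
        SampleMeta("mg1", 1, "pH8.2", "T1", "metagenome"),
        SampleMeta("mp1", 1, "pH8.2", "T1", "metaproteome", "g1"),
    ]


class TestCrossLayerPresence:
    def test_four_states(self):
        mg = CountTable(pd.DataFrame({"mg1": [100.0, 0.0, 3.0, 0.0]},
                                     index=list("ABCD")), "metagenome", "taxon")
        mp = CountTable(pd.DataFrame({"mp1": [0.0, 5.0, 2.0, 0.0]},
                                     index=list("ABCD")), "metaproteome", "taxon")
        m = cross_layer_presence(mg, mp, _layer_meta())
        col = m[(1, "pH8.2")]
        assert col["A"] == "metagenome_only"
        assert col["B"] == "metaproteome_only"
        assert col["C"] == "both"
        assert col["D"] == "neither"

    def test_partition_identity(self, small_sim):
        from coupledomics.proteomics import aggregate_psms

        tax = aggregate_psms(small_sim.protein_table, small_sim.annotations, "taxon", "Class")
        m = cross_layer_presence(small_sim.metagenome_taxa, tax, small_sim.meta)
        from coupledomics.concordance import pool_by_condition

        reads = pool_by_condition(small_sim.metagenome_taxa, small_sim.meta)
        for key in m.columns:
            n_reads_nonzero = int(
                (reads[key].reindex(m.index).fillna(0.0) > 0).sum()
            )
            states = m[key].value_counts()
            assert states.get("both", 0) + states.get("metagenome_only", 0) == n_reads_nonzero

    def test_no_overlapping_conditions_rejected(self):
        mg = CountTable(pd.DataFrame({"mg1": [1.0]}, index=["A"]), "metagenome", "taxon")
        mp = CountTable(pd.DataFrame({"mp1": [1.0]}, index=["A"]), "metaproteome", "taxon")
        meta = [
            SampleMeta("mg1", 1, "pH8.2", "T1", "metagenome"),
            SampleMeta("mp1", 5, "pH7.1", "T1", "metaproteome", "g1"),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            cross_layer_presence(mg, mp, meta)


class TestConcordanceByCondition:
    def test_identical_layers_give_perfect_r_squared(self):
        counts = pd.DataFrame({"mg1": [10.0, 20.0, 70.0]}, index=list("ABC"))
        mg = CountTable(counts, "metagenome", "taxon")
        mp = CountTable(counts.rename(columns={"mg1": "mp1"}), "metaproteome", "taxon")
        [res] = concordance_by_condition(mg, mp, _layer_meta())
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_delta_regression_variant_runs(self, small_sim):
        from coupledomics.proteomics import aggregate_psms

        tax = aggregate_psms(small_sim.protein_table, small_sim.annotations, "taxon", "Class")
        results = concordance_by_condition(
            small_sim.metagenome_taxa, tax, small_sim.meta, use_deltas=True
        )
        # first observed day per treatment has no defined delta regression
        assert len(results) == 6
        assert all(0.0 <= r.r_squared <= 1.0 for r in results)
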
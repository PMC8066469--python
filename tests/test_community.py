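import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coupledomics.community import (
    anosim,
    bray_curtis,
    diversity_table,
    nmds,
    shannon_weaver,
    simpson_reciprocal,
)
from coupledomics.io_tables import CountTable, ValidationError


class TestAlphaDiversity:
    def test_uniform_library_is_maximum_entropy(self):
        assert shannon_weaver([3, 3, 3, 3, 3]) == pytest.approx(math.log(5), abs=1e-12)
        assert simpson_reciprocal([3, 3, 3, 3]) == pytest.approx(4.0, abs=1e-12)

    def test_single_feature(self):
        assert shannon_weaver([0, 9, 0]) == 0.0
        assert simpson_reciprocal([0, 9, 0]) == pytest.approx(1.0)

    def test_hand_computed_values(self):
        # p = (0.25, 0.25, 0.5): H = -(2*0.25 ln 0.25 + 0.5 ln 0.5)
        assert shannon_weaver([1, 1, 2]) == pytest.approx(1.0397207708399179, abs=1e-12)
        assert simpson_reciprocal([1, 1, 2]) == pytest.approx(1 / 0.375, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            shannon_weaver([0, 0])
        with pytest.raises(ValidationError):
            simpson_reciprocal([0.0])

    def test_log_base_option(self):
        assert shannon_weaver([1, 1], base=2) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 1000.0))
    def test_scale_invariance(self, seed, scale):
        r = np.random.default_rng(seed)
        counts = r.poisson(4.0, size=12).astype(float) + r.random(12)
        assert shannon_weaver(counts * scale) == pytest.approx(shannon_weaver(counts))
        assert simpson_reciprocal(counts * scale) == pytest.approx(simpson_reciprocal(counts))

    def test_bounds_against_feature_count(self, small_sim):
        for res in diversity_table(small_sim.metagenome_taxa):
            k = int((small_sim.metagenome_taxa.data[res.sample_id] > 0).sum())
            assert 0.0 <= res.shannon_weaver <= math.log(k) + 1e-12
            assert 1.0 - 1e-12 <= res.simpson_reciprocal <= k + 1e-9

    def test_matches_scikit_bio(self, small_sim):
        skbio_diversity = pytest.importorskip("skbio.diversity.alpha")
        col = small_sim.metagenome_taxa.data.iloc[:, 0].to_numpy().astype(int)
        assert shannon_weaver(col) == pytest.approx(
            float(skbio_diversity.shannon(col, base=math.e))
        )
        assert simpson_reciprocal(col) == pytest.approx(
            float(skbio_diversity.enspie(col))
        )


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 0.0], "b": [1.0, 2.0, 0.0], "c": [0.0, 0.0, 5.0]},
                          index=list("XYZ"))
        d = bray_curtis(CountTable(df, "metagenome", "taxon"))
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 2.0]}, index=["A", "B"])
        d = bray_curtis(df)
        assert d.loc["x", "y"] == pytest.approx(1 / 7)

    def test_symmetric_zero_diagonal_feature_order_invariant(self, small_sim):
        t = small_sim.metagenome_taxa
        d1 = bray_curtis(t)
        shuffled = t.with_data(t.data.iloc[::-1])
        d2 = bray_curtis(shuffled)
        assert np.allclose(d1.to_numpy(), d1.to_numpy().T)
        assert np.allclose(np.diag(d1.to_numpy()), 0.0)
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_all_zero_pair_rejected(self):
        df = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["X"])
        with pytest.raises(ValidationError):
            bray_curtis(df)


def _separated_matrix():
    """Two groups of 3 where every within dissimilarity < every between."""
    n = 6
    d = np.full((n, n), 0.9)
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                d[i, j] = 0.1 if i != j else 0.0
    return d, np.array(["g1"] * 3 + ["g2"] * 3)


class TestAnosim:
    def test_maximal_separation_gives_r_one(self):
        d, labels = _separated_matrix()
        res = anosim(d, labels, n_permutations=99, seed=0)
        assert res.r_statistic == pytest.approx(1.0)

    def test_exhaustive_matches_monte_carlo(self, rng):
        pts = rng.random((6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = ["a", "a", "a", "b", "b", "b"]
        exact = anosim(d, labels, exhaustive=True)
        mc = anosim(d, labels, n_permutations=2000, seed=3)
        assert mc.r_statistic == exact.r_statistic
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / 2000)
        assert abs(mc.p_value - exact.p_value) <= 2 * se + 1 / 2001

    def test_matches_scikit_bio(self, small_sim):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d = bray_curtis(small_sim.metagenome_taxa)
        labels = ["early"] * 2 + ["late"] * 2 + ["early"] * 2 + ["late"] * 2
        mine = anosim(d, labels, n_permutations=999, seed=1)
        theirs = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            list(labels),
            permutations=999,
        )
        assert mine.r_statistic == pytest.approx(float(theirs["test statistic"]), abs=1e-12)
        assert abs(mine.p_value - float(theirs["p-value"])) < 0.08

    def test_p_floor_and_reproducibility(self):
        d, labels = _separated_matrix()
        a = anosim(d, labels, n_permutations=999, seed=5)
        b = anosim(d, labels, n_permutations=999, seed=5)
        assert a == b
        assert a.p_value >= 1 / 1000

    def test_group_of_one_rejected(self):
        d, _ = _separated_matrix()
        with pytest.raises(ValidationError, match="size 1"):
            anosim(d, ["a", "a", "a", "a", "a", "b"])

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 0.2], [0.4, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            anosim(d, ["a", "b"])


class TestNmds:
    def test_equilateral_embedding_has_near_zero_stress(self):
        d = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = nmds(d, k=2, seed=0)
        assert res.stress < 0.01

    def test_duplicated_sample_coincident(self):
        d = np.array(
            [[0.0, 0.0, 0.8, 0.7],
             [0.0, 0.0, 0.8, 0.7],
             [0.8, 0.8, 0.0, 0.5],
             [0.7, 0.7, 0.5, 0.0]]
        )
        res = nmds(d, k=2, seed=0)
        c = res.coordinates.to_numpy()
        gap = np.linalg.norm(c[0] - c[1])
        spread = np.linalg.norm(c[0] - c[2])
        assert gap < 0.05 * spread

    def test_stress_nested_in_dimension(self, rng):
        # a genuinely 3-D configuration: both 1-D and 2-D embeddings strain,
        # but the 2-D one strictly less
        pts = rng.random((10, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        s2 = nmds(d, k=2, seed=0).stress
        s1 = nmds(d, k=1, seed=0).stress
        assert s2 < s1

    def test_coordinates_centered_and_deterministic(self, small_sim):
        d = bray_curtis(small_sim.metagenome_taxa)
        a = nmds(d, k=2, seed=4)
        b = nmds(d, k=2, seed=4)
        assert np.allclose(a.coordinates.mean(axis=0), 0.0, atol=1e-9)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_bad_dimension_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValidationError):
            nmds(d, k=3)
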
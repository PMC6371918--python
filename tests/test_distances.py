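"""Distance metrics and the labeled distance matrix."""

import numpy as np
import pytest

from conftest import emd_by_atom_splitting, make_cluster_set, random_profile_pair
from chromadist.binning import HistogramSpec, histogram_bin
from chromadist.distances import (
    MAX_RGB_EMD,
    DistanceMatrix,
    chi_squared,
    color_distance,
    distance_matrix,
    emd,
    emd_plan,
    weighted_pairs,
)
from chromadist.errors import ConfigurationError, IncompatibleClusterSetsError
from chromadist.image_io import PixelSet


def point_mass(center, label=""):
    return make_cluster_set([center], [1.0], label=label)


class TestEmd:
    def test_identical_sets_are_at_distance_zero(self):
        rng = np.random.default_rng(0)
        cs = make_cluster_set(rng.random((4, 3)), [0.4, 0.3, 0.2, 0.1])
        assert emd(cs, cs) == pytest.approx(0.0, abs=1e-12)

    def test_opposite_cube_corners_reach_the_diagonal(self):
        d = emd(point_mass([0, 1, 1]), point_mass([1, 0, 0]))
        assert d == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_quarter_mixture_moves_quarter_of_the_mass(self):
        """3/4 cyan + 1/4 red vs all cyan: a quarter of the mass crosses the
        full cyan-red distance."""
        mix = make_cluster_set([[0, 1, 1], [1, 0, 0]], [0.75, 0.25])
        d = emd(point_mass([0, 1, 1]), mix) / MAX_RGB_EMD
        assert d == pytest.approx(0.25, abs=1e-9)

    @pytest.mark.parametrize("t", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_mixture_linearity(self, t):
        a, b = np.array([0.0, 1.0, 1.0]), np.array([1.0, 0.0, 0.0])
        if t in (0.0, 1.0):
            mix = point_mass(a if t == 0 else b)
        else:
            mix = make_cluster_set([a, b], [1 - t, t])
        assert emd(point_mass(a), mix) == pytest.approx(
            t * np.sqrt(3), abs=1e-9
        )

    def test_agrees_with_atom_splitting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            ca, sa, cb, sb = random_profile_pair(rng, k_max=5, denom=12)
            ours = emd(make_cluster_set(ca, sa), make_cluster_set(cb, sb))
            oracle = emd_by_atom_splitting(ca, sa, cb, sb, denom=12)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_transport_plan_has_correct_marginals(self):
        rng = np.random.default_rng(1)
        ca, sa, cb, sb = random_profile_pair(rng, k_max=4, denom=8)
        plan = emd_plan(make_cluster_set(ca, sa), make_cluster_set(cb, sb))
        np.testing.assert_allclose(plan.flows.sum(axis=1), sa, atol=1e-8)
        np.testing.assert_allclose(plan.flows.sum(axis=0), sb, atol=1e-8)
        assert plan.flows.sum() == pytest.approx(1.0, abs=1e-8)
        assert plan.cost == pytest.approx((plan.flows * plan.ground_distances).sum())

    def test_zero_size_bins_do_not_enter_the_transport(self):
        a = make_cluster_set([[0, 0, 0], [9, 9, 9]], [1.0, 0.0])
        b = make_cluster_set([[1, 0, 0], [9, 9, 9]], [1.0, 0.0])
        assert emd(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_scale_consistency(self):
        rng = np.random.default_rng(2)
        ca, sa, cb, sb = random_profile_pair(rng, k_max=4, denom=8)
        base = emd(make_cluster_set(ca, sa), make_cluster_set(cb, sb))
        scaled = emd(make_cluster_set(3 * ca, sa), make_cluster_set(3 * cb, sb))
        assert scaled == pytest.approx(3 * base, abs=1e-8)

    def test_mismatched_spaces_raise(self):
        with pytest.raises(IncompatibleClusterSetsError, match="rgb"):
            emd(point_mass([0, 0, 0]), make_cluster_set([[0, 0, 0]], [1.0], space="lab"))


class TestChiSquared:
    def test_identical_size_vectors_score_zero(self):
        a = make_cluster_set([[0, 0, 0], [1, 1, 1]], [0.5, 0.5])
        assert chi_squared(a, a) == 0.0

    def test_disjoint_unit_masses_score_two(self):
        a = make_cluster_set([[0, 0, 0], [1, 1, 1]], [1.0, 0.0])
        b = make_cluster_set([[0, 0, 0], [1, 1, 1]], [0.0, 1.0])
        assert chi_squared(a, b) == pytest.approx(2.0)

    def test_blind_to_centers(self):
        """The documented blind spot: equal size vectors with different
        colors score as identical (black vs gray pitfall)."""
        a = make_cluster_set([[0, 0, 0], [0.1, 0.1, 0.1]], [0.5, 0.5])
        b = make_cluster_set([[0.9, 0.9, 0.9], [1, 1, 1]], [0.5, 0.5])
        assert chi_squared(a, b) == 0.0

    def test_different_bin_counts_raise(self):
        a = make_cluster_set([[0, 0, 0]], [1.0])
        b = make_cluster_set([[0, 0, 0], [1, 1, 1]], [0.5, 0.5])
        with pytest.raises(IncompatibleClusterSetsError):
            chi_squared(a, b)


class TestColorAndWeighted:
    def test_color_distance_is_mean_center_distance(self):
        a = make_cluster_set([[0, 0, 0], [0, 0, 0]], [0.5, 0.5])
        b = make_cluster_set([[0.3, 0, 0], [0, 0.5, 0]], [0.5, 0.5])
        assert color_distance(a, b) == pytest.approx(0.4)

    def test_single_pair_diagonal(self):
        assert color_distance(point_mass([0, 0, 0]), point_mass([1, 1, 1])) == (
            pytest.approx(np.sqrt(3))
        )

    def test_pure_color_weight_equals_color_distance(self):
        rng = np.random.default_rng(3)
        a = make_cluster_set(rng.random((3, 3)), [0.2, 0.3, 0.5])
        b = make_cluster_set(rng.random((3, 3)), [0.1, 0.6, 0.3])
        assert weighted_pairs(a, b, size_weight=0, color_weight=1) == pytest.approx(
            color_distance(a, b)
        )

    def test_pure_size_weight_on_swapped_masses(self):
        a = make_cluster_set([[0, 0, 0], [1, 1, 1]], [1.0, 0.0])
        b = make_cluster_set([[0, 0, 0], [1, 1, 1]], [0.0, 1.0])
        assert weighted_pairs(a, b, size_weight=1, color_weight=0) == pytest.approx(1.0)

    def test_identical_sets_zero_for_any_weights(self):
        a = make_cluster_set([[0.2, 0.4, 0.6]], [1.0])
        assert weighted_pairs(a, a, 0.3, 0.7) == pytest.approx(0.0)

    def test_weights_must_sum_to_one(self):
        a = point_mass([0, 0, 0])
        with pytest.raises(ConfigurationError, match="must equal 1"):
            weighted_pairs(a, a, size_weight=0.5, color_weight=0.6)


class TestDistanceMatrix:
    def _quantity_sets(self):
        sets = []
        for label, prop in zip("ABCDE", (1.0, 0.75, 0.5, 0.25, 0.0)):
            n_cyan = int(prop * 100)
            coords = np.array([[0, 1, 1]] * n_cyan + [[1, 0, 0]] * (100 - n_cyan))
            ps = PixelSet(coords.astype(float))
            sets.append(
                histogram_bin(ps, HistogramSpec(bins_per_channel=(3, 3, 3)), label=label)
            )
        return sets

    def test_cyan_red_proportion_series(self):
        """The normalized EMD matrix of the quantity series equals the
        proportion differences: d(i, j) = |p_i - p_j|."""
        matrix = distance_matrix(self._quantity_sets(), metric="emd", normalize=True)
        props = np.array([1.0, 0.75, 0.5, 0.25, 0.0])
        expected = np.abs(props[:, None] - props[None, :])
        np.testing.assert_allclose(matrix.values, expected, atol=1e-6)
        assert matrix.labels == ["A", "B", "C", "D", "E"]

    def test_symmetric_zero_diagonal_and_bounded(self):
        rng = np.random.default_rng(10)
        sets = []
        for i in range(6):
            ca, sa, _, _ = random_profile_pair(rng, k_max=4, denom=8)
            sets.append(make_cluster_set(ca, sa, label=f"s{i}"))
        m = distance_matrix(sets, metric="emd", normalize=True)
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 0.0)
        assert m.values.max() <= 1.0 + 1e-9  # normalized RGB EMD bound

    def test_lab_normalization_warns_and_is_skipped(self, caplog):
        a = make_cluster_set([[50, 0, 0]], [1.0], space="lab", label="a")
        b = make_cluster_set([[60, 10, -10]], [1.0], space="lab", label="b")
        with caplog.at_level("WARNING"):
            m = distance_matrix([a, b], metric="emd", normalize=True)
        assert not m.normalized
        assert "Lab" in caplog.text
        assert m.values[0, 1] == pytest.approx(np.linalg.norm([10, 10, 10]))

    def test_unknown_metric_lists_valid_names(self):
        a, b = point_mass([0, 0, 0], "a"), point_mass([1, 1, 1], "b")
        with pytest.raises(ConfigurationError, match="chisq"):
            distance_matrix([a, b], metric="euclid")

    def test_csv_and_square_txt_round_trips_bit_exact(self, tmp_path):
        rng = np.random.default_rng(12)
        values = rng.random((3, 3))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0.0)
        m = DistanceMatrix(labels=["x", "y", "z"], values=values, metric="emd")
        csv_path = tmp_path / "m.csv"
        txt_path = tmp_path / "m.tsv"
        m.to_csv(csv_path)
        m.to_square_txt(txt_path)
        for loaded in (
            DistanceMatrix.from_csv(csv_path),
            DistanceMatrix.from_square_txt(txt_path),
        ):
            assert loaded.labels == m.labels
            np.testing.assert_array_equal(loaded.values, m.values)
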
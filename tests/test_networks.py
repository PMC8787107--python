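"""Network construction: KDE densities, KL similarity, thresholding."""

import numpy as np
import pytest

from connectoml import (
    ContractError,
    DegenerateInputError,
    DensityVector,
    RegionalSampleSet,
    ROITimeSeries,
    apply_sparsity,
    build_fbn,
    build_gmn,
    build_wmn,
    estimate_pdf,
    kls,
    symmetric_kl,
    threshold_sweep,
)
from conftest import make_net

TWO_CELL_GRID = np.array([0.5, 1.5])  # unit cell width -> densities are masses


def two_cell(p0, p1):
    return DensityVector(grid=TWO_CELL_GRID, density=np.array([p0, p1]))


class TestSymmetricKL:
    def test_identical_densities_have_zero_divergence(self):
        p = two_cell(0.5, 0.5)
        assert symmetric_kl(p, p) == 0.0
        assert kls(p, p) == 1.0

    def test_two_cell_hand_computation(self):
        # 0.5 ln2 + 0.5 ln(2/3) + 0.25 ln(1/2) + 0.75 ln(3/2) = 0.274653...
        expected = (0.5 * np.log(2) + 0.5 * np.log(2 / 3)
                    + 0.25 * np.log(1 / 2) + 0.75 * np.log(3 / 2))
        d = symmetric_kl(two_cell(0.5, 0.5), two_cell(0.25, 0.75))
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(0.2747, abs=5e-5)
        assert kls(two_cell(0.5, 0.5), two_cell(0.25, 0.75)) == pytest.approx(
            np.exp(-d), abs=1e-12
        )

    def test_symmetry_on_random_density_pairs(self):
        rng = np.random.default_rng(11)
        grid = np.linspace(-1, 1, 64)
        for _ in range(25):
            p = DensityVector(grid=grid, density=rng.random(64) + 1e-3)
            q = DensityVector(grid=grid, density=rng.random(64) + 1e-3)
            assert symmetric_kl(p, q) == pytest.approx(symmetric_kl(q, p), abs=1e-12)
            assert symmetric_kl(p, q) >= 0

    def test_mismatched_grids_rejected(self):
        p = two_cell(0.5, 0.5)
        q = DensityVector(grid=np.array([0.0, 2.0]), density=np.array([0.5, 0.5]))
        with pytest.raises(ContractError):
            symmetric_kl(p, q)


class TestEstimatePdf:
    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(42)
        grid = np.linspace(-6, 6, 2048)
        dv = estimate_pdf(rng.standard_normal(10_000), grid)
        at_zero = dv.density[np.argmin(np.abs(grid))]
        assert at_zero == pytest.approx(1 / np.sqrt(2 * np.pi), abs=0.02)

    def test_masses_sum_to_one(self):
        rng = np.random.default_rng(1)
        dv = estimate_pdf(rng.standard_normal(100), np.linspace(-5, 5, 256))
        assert dv.masses().sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_for_identical_bags(self):
        grid = np.linspace(-4, 4, 128)
        values = np.random.default_rng(2).standard_normal(50)
        a, b = estimate_pdf(values, grid), estimate_pdf(values.copy(), grid)
        np.testing.assert_array_equal(a.density, b.density)

    def test_constant_bag_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            estimate_pdf([5.0, 5.0, 5.0], np.linspace(0, 10, 32))


class TestGaussianKLOracle:
    """KDE-based symmetric KL against the closed Gaussian form (dmu/sigma)^2."""

    def test_unit_mean_gap_equal_variance(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(-6, 8, 1024)
        p = estimate_pdf(rng.normal(0, 1, 10_000), grid)
        q = estimate_pdf(rng.normal(1, 1, 10_000), grid)
        assert symmetric_kl(p, q) == pytest.approx(1.0, abs=0.15)

    def test_kls_decreases_with_mean_separation(self):
        rng = np.random.default_rng(6)
        grid = np.linspace(-8, 12, 1024)
        base = rng.normal(0, 1, 8000)
        p = estimate_pdf(base, grid)
        values = [kls(p, estimate_pdf(rng.normal(d, 1, 8000), grid))
                  for d in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestBuildGmn:
    def test_shape_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(0)
        rs = RegionalSampleSet(
            roi_labels=["a", "b", "c"],
            samples=[rng.normal(0, 1, 40) for _ in range(3)],
        )
        net = build_gmn(rs)
        assert net.weights.shape == (3, 3)
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
        assert net.modality == "GMN"

    def test_same_law_gives_high_similarity(self):
        rng = np.random.default_rng(1)
        rs = RegionalSampleSet(
            roi_labels=[f"r{i}" for i in range(4)],
            samples=[rng.normal(0.5, 0.1, 4000) for _ in range(4)],
        )
        net = build_gmn(rs)
        off = net.weights[np.triu_indices(4, 1)]
        assert np.all(off > 0.9)

    def test_shifted_roi_has_smallest_edges(self):
        rng = np.random.default_rng(2)
        samples = [rng.normal(0.0, 1.0, 500) for _ in range(4)]
        samples.append(rng.normal(10.0, 1.0, 500))  # +10 SD outlier ROI
        rs = RegionalSampleSet(
            roi_labels=[f"r{i}" for i in range(5)], samples=samples
        )
        w = build_gmn(rs).weights
        outlier_edges = w[4, :4]
        iu = np.triu_indices(4, 1)
        assert outlier_edges.max() < w[:4, :4][iu].min()

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(3)
        bags = [rng.normal(i * 0.1, 0.2, 80) for i in range(5)]
        labels = [f"r{i}" for i in range(5)]
        net = build_gmn(RegionalSampleSet(roi_labels=labels, samples=bags))
        perm = np.array([3, 1, 4, 0, 2])
        net_p = build_gmn(RegionalSampleSet(
            roi_labels=[labels[i] for i in perm],
            samples=[bags[i] for i in perm],
        ))
        np.testing.assert_allclose(
            net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-10
        )

    def test_zero_variance_roi_names_the_roi(self):
        rs = RegionalSampleSet(
            roi_labels=["ok", "flat"],
            samples=[np.array([1.0, 2.0, 3.0]), np.array([4.0, 4.0, 4.0])],
        )
        with pytest.raises(DegenerateInputError, match="flat"):
            build_gmn(rs)


class TestBuildFbn:
    def test_perfect_and_anti_correlation(self):
        t = np.linspace(0, 4 * np.pi, 50)
        base = np.sin(t)
        ts = ROITimeSeries(
            roi_labels=["a", "b", "c"],
            values=np.vstack([base, 2 * base, -base]),
        )
        w = build_fbn(ts).weights
        assert w[0, 1] == pytest.approx(1.0)
        assert w[0, 2] == pytest.approx(1.0)  # absolute-value convention

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(9)
        ts = ROITimeSeries(
            roi_labels=[f"r{i}" for i in range(6)],
            values=rng.standard_normal((6, 2000)),
        )
        w = build_fbn(ts).weights
        off = w[np.triu_indices(6, 1)]
        assert np.median(off) < 3 / np.sqrt(2000)

    def test_raw_edge_keeps_sign(self):
        t = np.linspace(0, 4 * np.pi, 50)
        rng = np.random.default_rng(0)
        ts = ROITimeSeries(
            roi_labels=["a", "b"],
            values=np.vstack([np.sin(t), -np.sin(t) + 0.01 * rng.standard_normal(50)]),
        )
        assert build_fbn(ts, edge="raw").weights[0, 1] < -0.9

    def test_constant_series_rejected(self):
        ts = ROITimeSeries(
            roi_labels=["a", "flatline"],
            values=np.vstack([np.arange(10.0), np.ones(10)]),
        )
        with pytest.raises(DegenerateInputError, match="flatline"):
            build_fbn(ts)


class TestBuildWmn:
    def test_strict_fn_cutoff(self):
        w = np.array([
            [0, 0, 1, 2],
            [0, 0, 3, 4],
            [1, 3, 0, 0],
            [2, 4, 0, 0],
        ], dtype=float)
        net = build_wmn(make_net(w, modality="WMN"))
        expected = np.array([
            [0, 0, 0, 0],
            [0, 0, 3, 4],
            [0, 3, 0, 0],
            [0, 4, 0, 0],
        ], dtype=float)
        np.testing.assert_array_equal(net.weights, expected)
        assert net.threshold_info == "FN>2"

    def test_all_counts_below_cutoff_gives_empty_network(self):
        w = np.full((3, 3), 2.0)
        np.fill_diagonal(w, 0)
        assert build_wmn(make_net(w, modality="WMN")).edge_count() == 0

    def test_zero_cutoff_is_identity_off_diagonal(self):
        rng = np.random.default_rng(4)
        w = rng.integers(1, 9, (5, 5)).astype(float)
        w = np.triu(w, 1) + np.triu(w, 1).T
        net = build_wmn(make_net(w, modality="WMN"), fn_cutoff=0)
        np.testing.assert_array_equal(net.weights, w)

    def test_non_integer_counts_rejected(self):
        w = np.array([[0, 1.5], [1.5, 0]])
        with pytest.raises(ContractError):
            build_wmn(make_net(w, modality="WMN"))


def brute_force_sparsify(weights, s):
    """Oracle: exhaustive sort-and-keep with the (row, col) tie rule."""
    n = weights.shape[0]
    edges = [(i, j, weights[i, j]) for i in range(n) for j in range(i + 1, n)]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    k = int(round(s * len(edges)))
    out = np.zeros_like(weights)
    for i, j, w in edges[:k]:
        out[i, j] = out[j, i] = w
    return out


class TestApplySparsity:
    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            w = rng.random((5, 5))
            w = np.triu(w, 1) + np.triu(w, 1).T
            s = rng.uniform(0.1, 1.0)
            got = apply_sparsity(make_net(w), s).weights
            np.testing.assert_array_equal(got, brute_force_sparsify(w, s))

    def test_half_of_complete_four_node_graph(self):
        rng = np.random.default_rng(13)
        w = rng.random((4, 4)) + 0.1
        w = np.triu(w, 1) + np.triu(w, 1).T
        net = apply_sparsity(make_net(w), 0.5)
        assert net.edge_count() == 3
        kept = net.weights[np.triu_indices(4, 1)]
        assert set(kept[kept > 0]) == set(sorted(w[np.triu_indices(4, 1)])[-3:])

    def test_descending_weights_keep_top_third(self):
        w = np.zeros((4, 4))
        vals = iter([6, 5, 4, 3, 2, 1])
        for i in range(4):
            for j in range(i + 1, 4):
                w[i, j] = w[j, i] = next(vals)
        kept = apply_sparsity(make_net(w), 1 / 3).weights
        assert set(kept[np.triu_indices(4, 1)]) == {0.0, 6.0, 5.0}

    def test_full_sparsity_is_identity(self):
        rng = np.random.default_rng(14)
        w = rng.random((6, 6))
        w = np.triu(w, 1) + np.triu(w, 1).T
        np.testing.assert_array_equal(apply_sparsity(make_net(w), 1.0).weights, w)

    def test_idempotent_and_nested(self):
        rng = np.random.default_rng(15)
        w = rng.random((7, 7))
        w = np.triu(w, 1) + np.triu(w, 1).T
        net = make_net(w)
        at_03 = apply_sparsity(net, 0.3)
        np.testing.assert_array_equal(
            apply_sparsity(at_03, 0.3).weights, at_03.weights
        )
        at_06 = apply_sparsity(net, 0.6)
        assert np.all((at_03.weights > 0) <= (at_06.weights > 0))

    @pytest.mark.parametrize("s", [0.0, -0.1, 1.5])
    def test_invalid_sparsity_rejected(self, s):
        with pytest.raises(ContractError):
            apply_sparsity(make_net(np.zeros((3, 3))), s)


class TestThresholdSweep:
    def test_default_sweep_has_31_levels(self):
        rng = np.random.default_rng(16)
        w = rng.random((10, 10))
        w = np.triu(w, 1) + np.triu(w, 1).T
        series = threshold_sweep(make_net(w))
        assert len(series.networks) == 31
        np.testing.assert_allclose(series.thresholds[0], 0.10)
        np.testing.assert_allclose(series.thresholds[-1], 0.40)

    def test_edge_counts_non_decreasing(self):
        rng = np.random.default_rng(17)
        w = rng.random((12, 12))
        w = np.triu(w, 1) + np.triu(w, 1).T
        counts = [net.edge_count() for net in threshold_sweep(make_net(w)).networks]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_degenerate_range_rejected(self):
        with pytest.raises(ContractError):
            threshold_sweep(make_net(np.zeros((4, 4))), s_min=0.1, s_max=0.1)
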
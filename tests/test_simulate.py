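"""Synthetic node data, correlation structure, and distance transformation."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmselect import (
    build_correlation_matrix,
    generate_hc_distance_data,
    generate_node_data,
    make_scenario,
    to_distance_vectors,
)
from mrmselect.simulate import (
    COLUMNS,
    NodeDataset,
    write_distance_csv,
    write_node_csv,
)


class TestCorrelationMatrix:
    def test_independence_gives_identity(self):
        assert np.array_equal(
            build_correlation_matrix((0, 0, 0, 0, 0)), np.eye(6)
        )

    def test_single_predictor_structure_and_spectrum(self):
        # the only non-trivial block is {{1, .6}, {.6, 1}}: eigenvalues 0.4/1.6
        corr = build_correlation_matrix((0.6, 0, 0, 0, 0))
        assert corr[0, 1] == corr[1, 0] == 0.6
        assert np.count_nonzero(corr - np.diag(np.diag(corr))) == 2
        eigvals = np.linalg.eigvalsh(corr)
        assert eigvals.min() == pytest.approx(0.4, abs=1e-12)
        assert eigvals.max() == pytest.approx(1.6, abs=1e-12)

    def test_hc_tapering_vector_is_positive_definite(self):
        # sum of squares 0.58^2+0.52^2+0.47^2 = 0.8277 < 1
        corr = build_correlation_matrix((0.58, 0.52, 0.47, 0, 0))
        np.linalg.cholesky(corr)  # raises if not PD
        # brute-force leading principal minors, Sylvester's criterion
        for size in range(1, 7):
            assert np.linalg.det(corr[:size, :size]) > 0

    @pytest.mark.parametrize(
        "rho", [(0.9, 0.9, 0, 0, 0), (1.0, 0, 0, 0, 0), (0.6, 0.6, 0.6, 0, 0)]
    )
    def test_non_positive_definite_rejected_naming_vector(self, rho):
        with pytest.raises(ValueError, match="rho"):
            build_correlation_matrix(rho)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_correlation_matrix((0.5, 0.5))


class TestNodeData:
    def test_shape_and_determinism(self, spurious_spec):
        a = generate_node_data(spurious_spec, 3)
        b = generate_node_data(spurious_spec, 3)
        assert a.values.shape == (30, 6)
        assert np.array_equal(a.values, b.values)
        assert a.seed_used == b.seed_used

    def test_replicates_differ(self, spurious_spec):
        a = generate_node_data(spurious_spec, 0)
        b = generate_node_data(spurious_spec, 1)
        assert not np.array_equal(a.values, b.values)

    def test_replicate_index_out_of_range(self, spurious_spec):
        with pytest.raises(ValueError, match="replicate_index"):
            generate_node_data(spurious_spec, spurious_spec.n_reps)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            make_scenario("spurious", n=3, n_reps=1, master_seed=0)

    def test_mean_empirical_correlation_tracks_rho(self):
        # 200 replicates at n = 100: mean cor(y, x1) within 3 SE of 0.60
        spec = make_scenario("spurious", n=100, n_reps=200, master_seed=77)
        cors = np.array(
            [
                np.corrcoef(d.values[:, 0], d.values[:, 1])[0, 1]
                for d in (generate_node_data(spec, r) for r in range(200))
            ]
        )
        se = cors.std(ddof=1) / np.sqrt(len(cors))
        assert abs(cors.mean() - 0.60) < 3 * se

    def test_null_structure_has_zero_mean_correlations(self):
        spec = make_scenario(
            "spurious", n=100, n_reps=200, master_seed=78,
            rho_node=(0, 0, 0, 0, 0),
        )
        cors = np.array(
            [
                np.corrcoef(generate_node_data(spec, r).values, rowvar=False)[0, 1:]
                for r in range(200)
            ]
        )
        se = cors.std(axis=0, ddof=1) / np.sqrt(cors.shape[0])
        assert np.all(np.abs(cors.mean(axis=0)) < 3 * se)


class TestDistanceTransform:
    def test_absolute_differences(self):
        values = np.zeros((3, 6))
        values[:, 0] = [0.0, 3.0, 1.0]
        node = NodeDataset(values=values, replicate_index=0, seed_used=0)
        dist = to_distance_vectors(node)
        # pairs (0,1), (0,2), (1,2)
        assert np.array_equal(dist.values[:, 0], [3.0, 1.0, 2.0])
        assert np.array_equal(dist.pair_index, [[0, 1], [0, 2], [1, 2]])

    def test_row_count_is_n_choose_2(self, spurious_spec):
        node = generate_node_data(spurious_spec, 0)
        dist = to_distance_vectors(node)
        assert dist.n_pairs == 30 * 29 // 2
        spec100 = make_scenario("spurious", n=100, n_reps=1, master_seed=0)
        assert to_distance_vectors(generate_node_data(spec100, 0)).n_pairs == 4950

    def test_pair_index_covers_all_pairs_once(self, spurious_spec):
        dist = to_distance_vectors(generate_node_data(spurious_spec, 1))
        pairs = {tuple(p) for p in dist.pair_index}
        assert len(pairs) == dist.n_pairs
        assert all(i < j for i, j in pairs)

    def test_constant_column_gives_zero_distances(self):
        values = np.ones((5, 6))
        node = NodeDataset(values=values, replicate_index=0, seed_used=0)
        assert np.all(to_distance_vectors(node).values == 0)

    @given(
        shift=st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        column=st.integers(min_value=0, max_value=5),
    )
    def test_translation_invariance(self, shift, column):
        rng = np.random.default_rng(5150)
        base = rng.standard_normal((8, 6))
        shifted = base.copy()
        shifted[:, column] += shift
        d0 = to_distance_vectors(NodeDataset(base, 0, 0)).values
        d1 = to_distance_vectors(NodeDataset(shifted, 0, 0)).values
        np.testing.assert_allclose(d0, d1, atol=1e-9 * max(1.0, abs(shift)))

    def test_distance_attenuation_below_rho_squared(self):
        # cor(D_y, D_x1) averages below rho^2 = 0.36 (observed ~0.32)
        spec = make_scenario("spurious", n=100, n_reps=500, master_seed=11)
        means = []
        for r in range(500):
            d = to_distance_vectors(generate_node_data(spec, r)).values
            means.append(np.corrcoef(d[:, 0], d[:, 1])[0, 1])
        assert np.mean(means) < 0.36


class TestHighCorrelationSet:
    def test_independent_of_lc_draw_and_deterministic(self, spurious_spec):
        hc1 = generate_hc_distance_data(spurious_spec, 2)
        hc2 = generate_hc_distance_data(spurious_spec, 2)
        lc = to_distance_vectors(generate_node_data(spurious_spec, 2))
        assert np.array_equal(hc1.values, hc2.values)
        assert hc1.provenance == "HC" and lc.provenance == "LC"
        assert not np.array_equal(hc1.values, lc.values)

    def test_hc_distance_correlation_recalibrated(self):
        # rho_hc = 0.8 at node scale gives distance-scale correlation ~0.60
        spec = make_scenario("spurious", n=100, n_reps=300, master_seed=13)
        cors = [
            np.corrcoef(
                generate_hc_distance_data(spec, r).values[:, :2], rowvar=False
            )[0, 1]
            for r in range(300)
        ]
        se = np.std(cors, ddof=1) / np.sqrt(len(cors))
        assert abs(np.mean(cors) - 0.604) < 4 * se


class TestCsvWriters:
    def test_node_round_trip(self, spurious_spec):
        node = generate_node_data(spurious_spec, 0)
        buf = io.StringIO()
        write_node_csv(node, buf)
        buf.seek(0)
        header = buf.readline().strip().split(",")
        assert header == list(COLUMNS)
        data = np.loadtxt(buf, delimiter=",")
        np.testing.assert_array_equal(data, node.values)

    def test_distance_round_trip_one_based_pairs(self, spurious_spec):
        dist = to_distance_vectors(generate_node_data(spurious_spec, 0))
        buf = io.StringIO()
        write_distance_csv(dist, buf)
        buf.seek(0)
        assert buf.readline().strip().split(",") == ["i", "j", *COLUMNS]
        data = np.loadtxt(buf, delimiter=",")
        np.testing.assert_array_equal(data[:, :2].astype(int), dist.pair_index + 1)
        np.testing.assert_array_equal(data[:, 2:], dist.values)
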
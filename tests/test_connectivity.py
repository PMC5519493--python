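import numpy as np
import pytest

from interdigitate import (
    FCMap,
    GeneratorParams,
    ZConnectivity,
    corr_matrix,
    disattenuate,
    fisher_z,
    mean_z_matrix,
    mean_z_rows,
    reliability_map,
    seed_map,
    simulate_session,
)
from interdigitate import test_retest as retest
from interdigitate.connectivity import (
    MAX_DENSE_VERTICES,
    Z_SENTINEL,
    ResolutionGuardError,
)
from tests.conftest import make_ts


def brute_force_pearson(data):
    """Independent two-pass Pearson oracle, pair by pair."""
    v = data.shape[0]
    out = np.empty((v, v))
    for i in range(v):
        for j in range(v):
            xi = data[i] - data[i].mean()
            xj = data[j] - data[j].mean()
            out[i, j] = np.sum(xi * xj) / np.sqrt(np.sum(xi**2) * np.sum(xj**2))
    return out


class TestCorrMatrix:
    def test_matches_brute_force_oracle(self):
        data = np.random.default_rng(0).normal(size=(50, 100))
        r = corr_matrix(make_ts(data))
        assert np.max(np.abs(r - brute_force_pearson(data))) <= 1e-10

    def test_diagonal_and_sign(self):
        x = np.random.default_rng(1).normal(size=100)
        r = corr_matrix(make_ts(np.vstack([x, x, -x])))
        assert np.allclose(np.diag(r), 1.0)
        assert r[0, 1] == pytest.approx(1.0) and r[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_vertex_masked(self):
        data = np.random.default_rng(2).normal(size=(4, 60))
        data[2] = 5.0
        r = corr_matrix(make_ts(data))
        assert np.isnan(r[2]).all() and np.isnan(r[:, 2]).all()
        assert np.isfinite(r[0, 1])

    def test_dense_budget_guard(self):
        data = np.zeros((MAX_DENSE_VERTICES + 1, 4))
        with pytest.raises(ResolutionGuardError):
            corr_matrix(make_ts(data))


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.9) == pytest.approx(1.47222, abs=1e-5)

    def test_odd_function(self):
        r = np.linspace(-0.99, 0.99, 21)
        assert np.allclose(fisher_z(-r), -np.asarray(fisher_z(r)))

    def test_unit_r_clipped_to_sentinel(self):
        assert fisher_z(1.0) == pytest.approx(Z_SENTINEL)
        assert np.isfinite(fisher_z(-1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestMeanZ:
    def test_identical_runs_equal_single(self):
        data = np.random.default_rng(3).normal(size=(10, 80))
        one = mean_z_matrix([make_ts(data)])
        three = mean_z_matrix([make_ts(data, run_id=r) for r in (1, 2, 3)])
        assert np.allclose(one.z, three.z)
        assert three.n_runs_averaged == 3

    def test_two_runs_elementwise_mean(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(6, 70)), rng.normal(size=(6, 70))
        za = fisher_z(corr_matrix(make_ts(a)))
        zb = fisher_z(corr_matrix(make_ts(b)))
        m = mean_z_matrix([make_ts(a, run_id=1), make_ts(b, run_id=2)])
        off = ~np.eye(6, dtype=bool)
        assert np.allclose(m.z[off], ((za + zb) / 2)[off])

    def test_order_invariant_bit_identical(self):
        rng = np.random.default_rng(5)
        runs = [make_ts(rng.normal(size=(8, 50)), run_id=r) for r in range(1, 5)]
        fwd = mean_z_matrix(runs)
        rev = mean_z_matrix(runs[::-1])
        assert np.array_equal(fwd.z, rev.z)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_z_matrix([make_ts(np.zeros((4, 50))), make_ts(np.zeros((5, 50)))])

    def test_diagonal_sentinel(self):
        m = mean_z_matrix([make_ts(np.random.default_rng(6).normal(size=(5, 40)))])
        assert np.allclose(np.diag(m.z), Z_SENTINEL)

    def test_row_subset_agrees_with_dense(self):
        rng = np.random.default_rng(7)
        runs = [make_ts(rng.normal(size=(20, 60)), run_id=r) for r in (1, 2)]
        dense = mean_z_matrix(runs)
        rows = mean_z_rows(runs, np.array([3, 11]))
        assert np.allclose(rows[0], dense.z[3], atol=1e-10)
        assert np.allclose(rows[1], dense.z[11], atol=1e-10)


class TestSeedMap:
    def test_row_extraction_and_display_range(self):
        m = mean_z_matrix([make_ts(np.random.default_rng(8).normal(size=(7, 50)))])
        fc = seed_map(m, 4)
        assert np.array_equal(fc.values, m.z[4])
        assert fc.display_range == (0.2, 0.6)

    def test_out_of_range_seed(self):
        m = mean_z_matrix([make_ts(np.random.default_rng(9).normal(size=(5, 40)))])
        with pytest.raises(IndexError):
            seed_map(m, 5)


class TestRetest:
    def _z(self, arr):
        return ZConnectivity(z=arr, n_runs_averaged=1, dataset_label="full")

    def test_self_correlation_is_one(self):
        z = np.random.default_rng(10).normal(size=(30, 30))
        z = (z + z.T) / 2
        assert retest(self._z(z), self._z(z)) == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(11)
        mk = lambda: (lambda a: (a + a.T) / 2)(rng.normal(size=(1000, 1000)))
        assert abs(retest(self._z(mk()), self._z(mk()))) < 0.05

    def test_all_masked_rejected(self):
        z = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            retest(self._z(z), self._z(z))


class TestReliability:
    def _maps(self, stack, seed=0):
        return [FCMap(seed_vertex=seed, values=v, dataset_label="full")
                for v in stack]

    def test_identical_maps_fully_reliable(self, mesh2):
        v = np.random.default_rng(12).normal(size=mesh2.n_vertices)
        rel = reliability_map(self._maps([v, v, v, v]), mesh2)
        assert np.allclose(rel.values, 1.0)

    def test_independent_noise_unreliable(self, mesh2):
        rng = np.random.default_rng(13)
        maps = self._maps([rng.normal(size=mesh2.n_vertices) for _ in range(6)])
        rel = reliability_map(maps, mesh2)
        assert np.mean(rel.values) < 0.1

    def test_requires_three_runs(self, mesh2):
        v = np.zeros(mesh2.n_vertices)
        with pytest.raises(ValueError):
            reliability_map(self._maps([v, v]), mesh2)

    def test_bounded(self, mesh2):
        rng = np.random.default_rng(14)
        base = rng.normal(size=mesh2.n_vertices)
        maps = self._maps([base + 0.3 * rng.normal(size=mesh2.n_vertices)
                           for _ in range(5)])
        rel = reliability_map(maps, mesh2)
        assert np.all((rel.values >= 0) & (rel.values <= 1))


class TestDisattenuate:
    def _fc(self, values):
        return FCMap(seed_vertex=0, values=values, dataset_label="full")

    def _rel(self, values):
        from interdigitate import ReliabilityMap
        return ReliabilityMap(values=values, n_runs=4)

    def test_unit_reliability_identity(self):
        v = np.random.default_rng(15).normal(size=10)
        out = disattenuate(self._fc(v), self._rel(np.ones(10)))
        assert np.allclose(out.values, v)

    def test_quarter_reliability_doubles(self):
        out = disattenuate(self._fc(np.array([0.5])), self._rel(np.array([0.25])))
        assert out.values[0] == pytest.approx(1.0)

    def test_floor_caps_divisor(self):
        out = disattenuate(self._fc(np.array([0.5])), self._rel(np.array([0.0])),
                           floor=0.04)
        assert out.values[0] == pytest.approx(0.5 / 0.2)

    def test_invalid_floor(self):
        with pytest.raises(ValueError):
            disattenuate(self._fc(np.zeros(2)), self._rel(np.ones(2)), floor=0.0)


@pytest.fixture(scope="module")
def dropout_setup(mesh3, template3):
    base = dict(subdivision_level=3, n_subjects=1, n_sessions=6,
                frames_per_run=300, master_seed=3)
    p_drop = GeneratorParams(**base, dropout_zone=1, dropout_attenuation=0.3)
    p_clean = GeneratorParams(**base)
    seed = int(template3.anchors[2][1])  # network-1 anchor outside dropout
    def run_maps(p):
        maps = []
        for r in range(1, 7):
            ts = simulate_session(template3, p, seed=100 + r, run_id=r)
            z = mean_z_matrix([ts])
            maps.append(seed_map(z, seed))
        return maps
    return template3, run_maps(p_drop), run_maps(p_clean), seed


class TestDropoutReliability:
    """Simulated susceptibility dropout lowers FC-map reliability, and
    disattenuation moves the map back toward its no-dropout value."""

    def test_dropout_zone_less_reliable(self, mesh3, dropout_setup):
        tpl, drop_maps, _, _ = dropout_setup
        rel = reliability_map(drop_maps, mesh3)
        inside = tpl.parcel(1, 1)
        outside = tpl.parcel(3, 1)
        assert np.nanmean(rel.values[inside]) < np.nanmean(rel.values[outside])

    def test_disattenuation_restores_dropout_z(self, mesh3, dropout_setup):
        tpl, drop_maps, clean_maps, seed = dropout_setup
        rel = reliability_map(drop_maps, mesh3)
        mean_drop = np.mean([m.values for m in drop_maps], axis=0)
        mean_clean = np.mean([m.values for m in clean_maps], axis=0)
        fc = FCMap(seed_vertex=seed, values=mean_drop, dataset_label="full")
        fixed = disattenuate(fc, rel)
        verts = tpl.parcel(1, 1)
        closer = (np.abs(fixed.values[verts] - mean_clean[verts])
                  < np.abs(mean_drop[verts] - mean_clean[verts]))
        assert np.mean(closer) >= 0.8


def test_split_half_matrix_consistency():
    """Discovery- and replication-half mean z matrices are highly
    correlated on a powered synthetic study (split-half stability of
    the connectivity pattern within an individual)."""
    from interdigitate import GeneratorParams, preprocess_study, simulate_study

    p = GeneratorParams(subdivision_level=3, n_subjects=1, n_sessions=24,
                        frames_per_run=300, master_seed=2)
    spp = preprocess_study(simulate_study(p, subjects=[0]))
    zd = mean_z_matrix(spp.discovery(0), "discovery")
    zr = mean_z_matrix(spp.replication(0), "replication")
    assert retest(zd, zr) >= 0.8
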
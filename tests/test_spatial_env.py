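import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix

from plankton_assembly.io_tables import AsvTableError, SampleMetadata
from plankton_assembly.spatial_env import (
    EARTH_RADIUS_KM,
    distance_decay_fit,
    environmental_distance_matrix,
    geographic_distance_matrix,
    hellinger,
    pcnm_vectors,
    variation_partition,
)
from plankton_assembly.synthetic_data import NicheSimConfig, simulate_structured_table

from .conftest import make_table


def meta_from(lat, lon, env=None, regions=None):
    n = len(lat)
    env = env or {}
    df = pd.DataFrame(
        {"region": regions or ["R"] * n, "lat": lat, "lon": lon, **env},
        index=[f"S{i + 1}" for i in range(n)],
    )
    return SampleMetadata(df, tuple(env))


class TestGeographicDistance:
    def test_closed_forms(self):
        m = meta_from([0.0, 0.0, 0.0], [0.0, 180.0, 1.0])
        d = geographic_distance_matrix(m)
        assert d.data[0, 0] == 0.0
        assert d.data[0, 1] == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-9)
        # one degree of longitude on the equator
        assert d.data[0, 2] == pytest.approx(
            EARTH_RADIUS_KM * np.radians(1.0), rel=1e-9
        )

    @given(
        st.lists(
            st.tuples(st.floats(-80, 80), st.floats(-179, 179)),
            min_size=3,
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_triangle_inequality(self, coords):
        lat = [c[0] for c in coords]
        lon = [c[1] for c in coords]
        d = geographic_distance_matrix(meta_from(lat, lon)).data
        assert np.allclose(d, d.T)
        n = len(coords)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


class TestEnvironmentalDistance:
    def test_identical_vectors_zero(self):
        m = meta_from([0, 0], [0, 1], env={"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            with pytest.raises(AsvTableError, match="no environmental"):
                environmental_distance_matrix(m)

    def test_hand_standardized_distances(self):
        a = [1.0, 2.0, 3.0]
        b = [10.0, 30.0, 20.0]
        m = meta_from([0, 0, 0], [0, 1, 2], env={"a": a, "b": b})
        d = environmental_distance_matrix(m).data
        za = (np.array(a) - np.mean(a)) / np.std(a, ddof=1)
        zb = (np.array(b) - np.mean(b)) / np.std(b, ddof=1)
        expected = np.sqrt((za[0] - za[1]) ** 2 + (zb[0] - zb[1]) ** 2)
        assert d[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_constant_shift_variable(self):
        env1 = {"a": [0.0, 1.0, 2.0, 4.0]}
        env2 = {"a": [0.0, 1.0, 2.0, 4.0], "c": [5.0, 5.0, 5.0, 5.0]}
        m1 = meta_from([0] * 4, [0, 1, 2, 3], env=env1)
        m2 = meta_from([0] * 4, [0, 1, 2, 3], env=env2)
        d1 = environmental_distance_matrix(m1).data
        with pytest.warns(UserWarning, match="zero-variance"):
            d2 = environmental_distance_matrix(m2).data
        assert np.allclose(d1, d2)


class TestDistanceDecay:
    def test_exact_linear_input_recovered(self):
        # similarity constructed exactly as s = 0.9 - 0.001 * d
        rng = np.random.default_rng(1)
        n = 8
        ids = [f"S{i}" for i in range(n)]
        pred = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(10, 400, size=len(iu[0]))
        pred[iu] = vals
        pred += pred.T
        comm = 1.0 - (0.9 - 0.001 * pred)
        np.fill_diagonal(comm, 0.0)
        fit = distance_decay_fit(
            DistanceMatrix(comm, ids=ids), DistanceMatrix(pred, ids=ids)
        )
        assert fit.slope == pytest.approx(-0.001, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.n_pairs == n * (n - 1) // 2

    def test_slope_sign_flips_for_dissimilarity(self):
        cfg = NicheSimConfig(S=60, n_samples=15, depth=1000, seed=2)
        t, meta = simulate_structured_table(cfg)
        from plankton_assembly.diversity import bray_curtis_matrix

        bc = bray_curtis_matrix(t)
        geo = geographic_distance_matrix(meta)
        fit_sim = distance_decay_fit(bc, geo)
        # refit on dissimilarity = 1 - similarity by negating the matrix
        ids = list(bc.ids)
        diss = pd.DataFrame(bc.data, index=ids, columns=ids)
        inv = DistanceMatrix(1.0 - diss.to_numpy() - np.eye(len(ids)), ids=ids)
        fit_inv = distance_decay_fit(inv, geo)
        assert np.sign(fit_sim.slope) == -np.sign(fit_inv.slope)

    def test_structured_community_decays_significantly(self):
        cfg = NicheSimConfig(S=120, n_samples=20, depth=2000, seed=3)
        t, meta = simulate_structured_table(cfg)
        from plankton_assembly.diversity import bray_curtis_matrix

        fit = distance_decay_fit(
            bray_curtis_matrix(t), geographic_distance_matrix(meta)
        )
        assert fit.slope < 0 and fit.p_value < 0.05

    def test_constant_predictor_rejected(self):
        ids = list("abcd")
        comm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=ids)
        pred = DistanceMatrix(np.full((4, 4), 2.0) - 2 * np.eye(4), ids=ids)
        with pytest.raises(AsvTableError, match="constant predictor"):
            distance_decay_fit(comm, pred)


class TestPcnm:
    def test_transect_matches_vegan_reference(self):
        # 12 equidistant points on the equator; expected eigenvalues computed
        # with vegan::pcnm on the identical haversine distance matrix
        n = 12
        lat = [0.0] * n
        lon = list(np.linspace(0, 2, n))
        geo = geographic_distance_matrix(meta_from(lat, lon))
        vecs = pcnm_vectors(geo)
        expected = [8698.712, 7988.030, 6752.760, 5543.398, 4008.930, 2595.323, 1095.799]
        assert vecs.shape[1] == 7
        assert np.allclose(vecs.attrs["eigenvalues"], expected, atol=0.01)
        # leading eigenfunction tracks the broad-scale gradient along the
        # transect (a low-frequency sinusoid, strongly rank-correlated with
        # position but not strictly monotone)
        rho = scipy.stats.spearmanr(vecs.iloc[:, 0], np.arange(n)).statistic
        assert abs(rho) > 0.75

    def test_isometry_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        ids = [f"S{i}" for i in range(8)]

        def euclid_dm(points):
            d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
            return DistanceMatrix(d, ids=ids)

        e1 = pcnm_vectors(euclid_dm(pts)).attrs["eigenvalues"]
        e2 = pcnm_vectors(euclid_dm(pts @ rot.T)).attrs["eigenvalues"]
        k = min(len(e1), len(e2))
        assert np.allclose(e1[:k], e2[:k], atol=1e-8)

    def test_four_collinear_points_have_positive_eigenvalue(self):
        geo = geographic_distance_matrix(
            meta_from([0.0] * 4, [0.0, 0.1, 0.2, 0.3])
        )
        vecs = pcnm_vectors(geo)
        assert vecs.shape[1] >= 1
        assert (vecs.attrs["eigenvalues"] > 0).all()


class TestHellinger:
    def test_unit_row_sum_of_squares(self, toy_table):
        h = hellinger(toy_table.counts)
        assert np.allclose((h**2).sum(axis=1), 1.0, atol=1e-12)


class TestVariationPartition:
    def _env_driven(self, seed, n=20, s=80):
        """Community driven by env; spatial predictor orthogonal noise."""
        rng = np.random.default_rng(seed)
        e = np.linspace(-2, 2, n)
        mu = rng.uniform(-2, 2, s)
        lam = np.exp(-((e[:, None] - mu[None, :]) ** 2) / 0.5)
        counts = np.vstack(
            [rng.multinomial(2000, lam[i] / lam[i].sum()) for i in range(n)]
        )
        t = make_table(counts)
        env = pd.DataFrame({"e": e}, index=t.sample_ids)
        spa = pd.DataFrame(
            {"x": rng.permutation(n).astype(float)}, index=t.sample_ids
        )
        return t, env, spa

    def test_fraction_identity_and_marginals(self):
        t, env, spa = self._env_driven(1)
        res = variation_partition(t, env, spa)
        total = res.pure_env + res.shared + res.pure_spa + res.unexplained
        assert total == pytest.approx(1.0, abs=1e-10)
        assert res.pure_env + res.shared == pytest.approx(res.r2adj_env, abs=1e-10)
        assert res.pure_spa + res.shared == pytest.approx(res.r2adj_spa, abs=1e-10)

    def test_env_only_construction_a_dominates_c(self):
        cs = []
        a_minus_c = []
        for seed in range(20):
            t, env, spa = self._env_driven(seed)
            res = variation_partition(t, env, spa)
            cs.append(res.pure_spa)
            a_minus_c.append(res.pure_env - res.pure_spa)
        assert np.median(a_minus_c) > 0
        assert abs(np.median(cs)) < 0.05

    def test_identical_matrices_fully_shared(self):
        t, env, _ = self._env_driven(2)
        res = variation_partition(t, env, env.copy())
        assert res.pure_env == pytest.approx(0.0, abs=1e-10)
        assert res.pure_spa == pytest.approx(0.0, abs=1e-10)
        assert res.shared == pytest.approx(res.r2adj_env, abs=1e-10)

    def test_collinear_predictors_named(self):
        t, env, spa = self._env_driven(3)
        env2 = env.copy()
        env2["e_dup"] = env2["e"] * 2.0
        with pytest.raises(AsvTableError, match="e_dup"):
            variation_partition(t, env2, spa)

    def test_too_many_predictors_rejected(self):
        t, env, spa = self._env_driven(4, n=6)
        wide = pd.concat(
            [env] + [env.rename(columns={"e": f"e{i}"}) ** (i + 1) for i in range(4)],
            axis=1,
        )
        with pytest.raises(AsvTableError, match="too many predictors"):
            variation_partition(t, wide, spa)
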
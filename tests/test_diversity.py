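import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from plankton_assembly.diversity import (
    alpha_diversity,
    bray_curtis_matrix,
    compare_groups,
    pcoa,
    permanova,
)
from plankton_assembly.io_tables import AsvTableError
from plankton_assembly.synthetic_data import simulate_tree

from .conftest import make_table


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts,index,expected",
        [
            ((5, 5, 5, 5), "shannon", np.log(4)),
            ((1, 1, 2), "chao1", 3 + 2 * 1 / (2 * (1 + 1))),
            ((5, 5, 5, 5), "pielou", 1.0),
            ((10, 20, 30), "chao1", 3.0),  # no singletons: chao1 = S_obs
        ],
    )
    def test_hand_computed_values(self, counts, index, expected):
        assert alpha_diversity(np.array(counts), index) == pytest.approx(
            expected, abs=1e-9
        )

    def test_faith_pd_all_tips_is_total_length(self):
        tree = simulate_tree(["A", "B", "C", "D"], seed=3)
        total = sum(n.length for n in tree.traverse(include_self=False))
        pd_val = alpha_diversity(
            np.array([1, 2, 3, 4]), "faith_pd", tree=tree,
            taxon_ids=["A", "B", "C", "D"],
        )
        assert pd_val == pytest.approx(total, abs=1e-9)

    def test_faith_pd_missing_tip_is_error(self):
        tree = simulate_tree(["A", "B", "C"], seed=3)
        with pytest.raises(AsvTableError, match="absent from tree"):
            alpha_diversity(
                np.array([1, 1]), "faith_pd", tree=tree, taxon_ids=["A", "X"]
            )

    def test_degenerate_inputs(self):
        with pytest.raises(AsvTableError, match="all-zero"):
            alpha_diversity(np.array([0, 0]), "shannon")
        with pytest.raises(AsvTableError, match="pielou"):
            alpha_diversity(np.array([0, 7]), "pielou")

    @given(
        counts=st.lists(st.integers(1, 50), min_size=2, max_size=12),
        scale=st.integers(2, 9),
    )
    @settings(max_examples=50, deadline=None)
    def test_shannon_invariant_under_rescaling(self, counts, scale):
        x = np.array(counts)
        assert alpha_diversity(x, "shannon") == pytest.approx(
            alpha_diversity(x * scale, "shannon"), abs=1e-12
        )


class TestBrayCurtis:
    def test_hand_computed_entries(self):
        t = make_table([[2, 2, 0], [0, 2, 2], [2, 2, 0]])
        bc = bray_curtis_matrix(t)
        assert bc.data[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert bc.data[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self):
        bc = bray_curtis_matrix(make_table([[5, 0], [0, 9]]))
        assert bc.data[0, 1] == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(AsvTableError, match="all-zero"):
            bray_curtis_matrix(make_table([[1, 2], [0, 0]]))

    @given(
        st.lists(
            st.lists(st.integers(0, 30), min_size=4, max_size=4),
            min_size=3,
            max_size=6,
        ).filter(lambda rows: all(sum(r) > 0 for r in rows))
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_symmetry_identity(self, rows):
        bc = bray_curtis_matrix(make_table(rows))
        m = bc.data
        assert np.all(m >= 0) and np.all(m <= 1 + 1e-12)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)


class TestPcoa:
    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(4, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(d, ids=list("abcd")), n_axes=2)
        coords = res.coordinates.to_numpy()
        d_rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(d_rec, d, atol=1e-8)

    def test_equidistant_points_give_equal_proportions(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = pcoa(DistanceMatrix(d, ids=list("abcd")), n_axes=3)
        assert np.allclose(res.eigenvalues, res.eigenvalues[0], atol=1e-10)
        assert np.allclose(res.proportion_explained, 1 / 3, atol=1e-10)

    def test_two_samples_single_axis(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="truncated"):
            res = pcoa(DistanceMatrix(d, ids=["a", "b"]), n_axes=2)
        assert res.coordinates.shape[1] == 1
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_matches_reference_implementation(self, neutral_table):
        from plankton_assembly.diversity import bray_curtis_matrix

        bc = bray_curtis_matrix(neutral_table)
        ours = pcoa(bc, n_axes=3)
        ref = skbio_pcoa(bc, number_of_dimensions=3)
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()),
            atol=1e-6,
        )


class TestPermanova:
    def _disjoint_table(self, n_per=10):
        rng = np.random.default_rng(4)
        a = np.hstack([rng.integers(1, 20, (n_per, 5)), np.zeros((n_per, 5), int)])
        b = np.hstack([np.zeros((n_per, 5), int), rng.integers(1, 20, (n_per, 5))])
        return make_table(np.vstack([a, b]))

    def test_maximal_separation_gives_minimal_p(self):
        # only permutations recreating the two-block partition can reach
        # F_obs, so p sits at (or within a collision or two of) 1/(n_perm+1)
        bc = bray_curtis_matrix(self._disjoint_table())
        res = permanova(bc, ["A"] * 10 + ["B"] * 10, n_perm=999, seed=0)
        assert res.p_value <= 0.01
        assert res.df_between == 1 and res.df_within == 18

    def test_deterministic_given_seed(self, neutral_table):
        bc = bray_curtis_matrix(neutral_table)
        labels = ["A"] * 15 + ["B"] * 15
        r1 = permanova(bc, labels, n_perm=199, seed=7)
        r2 = permanova(bc, labels, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value and r1.pseudo_f == r2.pseudo_f

    def test_pseudo_f_matches_reference_implementation(self, neutral_table):
        bc = bray_curtis_matrix(neutral_table)
        labels = ["A"] * 10 + ["B"] * 12 + ["C"] * 8
        ours = permanova(bc, labels, n_perm=99, seed=1)
        ref = skbio_permanova(bc, grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_group_of_one_rejected(self):
        bc = bray_curtis_matrix(self._disjoint_table(3))
        with pytest.raises(AsvTableError, match="fewer than 2"):
            permanova(bc, ["A"] * 5 + ["B"], n_perm=99, seed=0)


class TestCompareGroups:
    def test_identical_vectors_p_one(self):
        stat, p = compare_groups(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), "wilcoxon")
        assert p == pytest.approx(1.0, abs=0.05)

    def test_fully_tied_data_p_one(self):
        _, p = compare_groups(np.array([2.0, 2, 2]), np.array([2.0, 2]), "wilcoxon")
        assert p == 1.0

    def test_separated_groups_welch(self):
        stat, p = compare_groups(np.array([1.0, 2, 3]), np.array([11.0, 12, 13]), "welch_t")
        assert p < 0.01 and stat < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(AsvTableError, match="zero variance"):
            compare_groups(np.array([1.0, 1]), np.array([2.0, 2]), "welch_t")

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        a = np.array([1.3, 2.1, 4.0, 6.2])
        b = np.array([0.5, 3.3, 5.1, 7.7])
        stat, p = compare_groups(a, b, "wilcoxon")
        # enumerate all C(8,4) rank assignments of the pooled sample
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        n1 = len(a)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = []
        for comb in itertools.combinations(range(8), 4):
            r = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            us.append(r)
        us = np.array(us)
        p_lo = np.mean(us <= u_obs)
        p_hi = np.mean(us >= u_obs)
        p_exact = min(1.0, 2 * min(p_lo, p_hi))
        assert p == pytest.approx(p_exact, abs=1e-12)
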
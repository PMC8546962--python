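"""Permutation statistics against independent oracles and closed forms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from terroirseq import (
    DistanceMatrix,
    ValidationError,
    anosim,
    fdr_adjust,
    haversine_matrix,
    mantel,
    nmds,
    permanova,
    scale_center,
)


# ---------------------------------------------------------------------------
# independent brute-force oracles (double loops over the square matrix)
# ---------------------------------------------------------------------------

def brute_anosim_r(D, labels):
    n = len(labels)
    pairs, kinds = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(D[i, j])
            kinds.append(labels[i] == labels[j])
    ranks = rankdata(pairs)
    within = [r for r, k in zip(ranks, kinds) if k]
    between = [r for r, k in zip(ranks, kinds) if not k]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4.0)


def brute_permanova(D, labels):
    n = len(labels)
    ss_t = sum(D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in set(labels):
        members = [i for i in range(n) if labels[i] == g]
        ss_g = sum(
            D[i, j] ** 2 for i in members for j in members if i < j
        )
        ss_w += ss_g / len(members)
    a = len(set(labels))
    f = ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))
    return f, ss_t, ss_w


def exact_p(stat_fn, observed, n):
    count, total = 0, 0
    for perm in itertools.permutations(range(n)):
        if stat_fn(perm) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


class TestAnosim:
    def test_maximal_separation_gives_r_one(self):
        # two tight clusters far apart: every between > every within
        pts = np.vstack([np.zeros((3, 2)), np.full((3, 2), 100.0)])
        pts += np.random.default_rng(0).normal(0, 0.1, pts.shape)
        D = squareform(pdist(pts))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], D)
        res = anosim(dm, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_group_of_one_rejected(self, random_distance):
        with pytest.raises(ValidationError):
            anosim(random_distance(5), ["a", "a", "a", "a", "b"], n_perm=9)

    @pytest.mark.parametrize("n,groups", [(6, [0, 0, 0, 1, 1, 1]), (7, [0, 0, 1, 1, 2, 2, 2])])
    def test_exact_enumeration_matches_bruteforce_oracle(self, n, groups, random_distance):
        dm = random_distance(n, seed=n)
        labels = [str(g) for g in groups]
        res = anosim(dm, labels, exact=True)
        assert res.statistic == pytest.approx(brute_anosim_r(dm.values, labels), abs=1e-10)
        lab = np.array(labels)
        p = exact_p(
            lambda perm: brute_anosim_r(dm.values, list(lab[list(perm)])),
            res.statistic,
            n,
        )
        assert res.p_value == pytest.approx(p, abs=0)

    def test_matches_skbio_statistic(self, random_distance):
        import skbio.stats.distance as skbio

        dm = random_distance(12, seed=3)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = anosim(dm, labels, n_perm=99, seed=0).statistic
        theirs = skbio.anosim(
            skbio.DistanceMatrix(dm.values, dm.ids), grouping=labels, permutations=0
        )["test statistic"]
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestPermanova:
    def test_sum_of_squares_matches_bruteforce(self, random_distance):
        dm = random_distance(6, seed=9)
        labels = ["a", "a", "b", "b", "b", "a"]
        res = permanova(dm, labels, n_perm=99, seed=1)
        f, ss_t, ss_w = brute_permanova(dm.values, labels)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.effect_partition["R2"] == pytest.approx((ss_t - ss_w) / ss_t, abs=1e-10)

    def test_exact_enumeration_p(self, random_distance):
        dm = random_distance(6, seed=11)
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(dm, labels, exact=True)
        lab = np.array(labels)
        p = exact_p(
            lambda perm: brute_permanova(dm.values, list(lab[list(perm)]))[0],
            res.statistic,
            6,
        )
        assert res.p_value == pytest.approx(p, abs=0)

    def test_degenerate_zero_within_flagged(self):
        # each group collapsed onto a single point
        D = np.zeros((4, 4))
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            D[i, j] = D[j, i] = 5.0
        dm = DistanceMatrix(list("abcd"), D)
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert not np.isfinite(res.statistic)
        assert res.note is not None
        assert 0 < res.p_value <= 1

    def test_matches_skbio_statistic(self, random_distance):
        import skbio.stats.distance as skbio

        dm = random_distance(12, seed=4)
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, labels, n_perm=99, seed=0).statistic
        theirs = skbio.permanova(
            skbio.DistanceMatrix(dm.values, dm.ids), grouping=labels, permutations=0
        )["test statistic"]
        assert ours == pytest.approx(theirs, abs=1e-10)


class TestMantel:
    def test_self_correlation_is_one(self, random_distance):
        dm = random_distance(8)
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, random_distance):
        dm = random_distance(8, seed=5)
        squared = DistanceMatrix(dm.ids, dm.values**2, "sq")
        res = mantel(dm, squared, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_matrix_flagged_not_nan_propagated(self, random_distance):
        dm = random_distance(5)
        const = DistanceMatrix(dm.ids, np.ones((5, 5)) - np.eye(5), "const")
        res = mantel(dm, const, n_perm=99, seed=0)
        assert math.isnan(res.statistic) and res.note is not None
        assert res.p_value == 1.0

    def test_exact_enumeration_matches_spearman_oracle(self, random_distance):
        d1 = random_distance(6, seed=21)
        d2 = random_distance(6, seed=22)
        d2 = DistanceMatrix(d1.ids, d2.values, "second")
        res = mantel(d1, d2, exact=True)
        iu, ju = np.triu_indices(6, k=1)
        obs = spearmanr(d1.values[iu, ju], d2.values[iu, ju]).statistic
        assert res.statistic == pytest.approx(obs, abs=1e-10)
        count = total = 0
        for perm in itertools.permutations(range(6)):
            p = np.array(perm)
            r = spearmanr(d1.values[iu, ju], d2.values[p[iu], p[ju]]).statistic
            count += r >= obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=0)

    def test_joint_relabeling_invariance(self, random_distance):
        d1 = random_distance(8, seed=31)
        d2 = random_distance(8, seed=32)
        d2 = DistanceMatrix(d1.ids, d2.values, "second")
        base = mantel(d1, d2, n_perm=9, seed=0).statistic
        perm = np.random.default_rng(0).permutation(8)
        ids = [d1.ids[i] for i in perm]
        r1 = DistanceMatrix(ids, d1.values[np.ix_(perm, perm)])
        r2 = DistanceMatrix(ids, d2.values[np.ix_(perm, perm)])
        assert mantel(r1, r2, n_perm=9, seed=0).statistic == pytest.approx(base, abs=1e-12)


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])

    def test_bh_formula_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)


class TestNmds:
    def test_perfect_embedding_near_zero_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        res = nmds(DistanceMatrix([str(i) for i in range(10)], D), k=2, n_restarts=5, seed=0)
        assert res.stress < 0.05

    def test_four_equidistant_points_cannot_embed(self):
        D = np.ones((4, 4)) - np.eye(4)
        res = nmds(DistanceMatrix(list("abcd"), D), k=2, n_restarts=5, seed=0)
        assert res.stress > 0.01

    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        pts[5] = pts[0]  # exact duplicate
        D = squareform(pdist(pts))
        res = nmds(DistanceMatrix([str(i) for i in range(6)], D), k=2, n_restarts=3, seed=0)
        coords = res.coordinates.to_numpy()
        np.testing.assert_allclose(coords[0], coords[5], atol=1e-12)


class TestHaversine:
    def test_identical_points_zero(self):
        dm = haversine_matrix([[45.0, -120.0], [45.0, -120.0]])
        assert dm.values[0, 1] == 0

    def test_antipodal_half_circumference(self):
        dm = haversine_matrix([[0.0, 0.0], [0.0, 180.0]])
        np.testing.assert_allclose(dm.values[0, 1], math.pi * 6371.0088, atol=1e-6)

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-90, 90, 6), rng.uniform(-180, 180, 6)])
        dm = haversine_matrix(pts)
        np.testing.assert_allclose(dm.values, dm.values.T)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            haversine_matrix([[91.0, 0.0], [0.0, 0.0]])


class TestScaleCenter:
    def test_unit_spaced_column(self):
        out = scale_center(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_standardized_column_unchanged(self):
        col = np.array([-1.0, 0.0, 1.0])
        out = scale_center(pd.DataFrame({"x": col}))
        np.testing.assert_allclose(out["x"], col, atol=1e-12)

    def test_constant_column_dropped(self):
        out = scale_center(pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]}))
        assert list(out.columns) == ["x"]


class TestPValueFormula:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_sampled_p_never_zero(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 2))
        D = squareform(pdist(pts))
        dm = DistanceMatrix([str(i) for i in range(8)], D)
        labels = ["a"] * 4 + ["b"] * 4
        for res in (
            anosim(dm, labels, n_perm=19, seed=seed),
            permanova(dm, labels, n_perm=19, seed=seed),
        ):
            assert 0 < res.p_value <= 1

    def test_seeded_runs_reproducible(self, random_distance):
        dm = random_distance(10)
        labels = ["a"] * 5 + ["b"] * 5
        a = anosim(dm, labels, n_perm=199, seed=42)
        b = anosim(dm, labels, n_perm=199, seed=42)
        assert a.p_value == b.p_value and a.statistic == b.statistic
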
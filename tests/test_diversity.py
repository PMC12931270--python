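import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from bpdnet import (CountTable, alpha_diversity, anosim, anosim_pairwise,
                    bray_curtis, permanova, permdisp)
from bpdnet.diversity import alpha_group_effect, _sums_of_squares
from bpdnet.io import ValidationError


class TestAlphaDiversity:
    def test_chao1_bias_corrected_hand_value(self):
        # 5 observed taxa, F1=2 singletons, F2=1 doubleton:
        # chao1 = 5 + (2*1)/(2*(1+1)) = 5.5
        t = CountTable(["s"], list("abcde"), np.array([[1, 1, 2, 3, 4]]))
        assert alpha_diversity(t).loc["s", "chao1"] == pytest.approx(5.5)

    def test_uniform_sample_closed_forms(self):
        s_taxa = 8
        t = CountTable(["s"], [f"t{i}" for i in range(s_taxa)],
                       np.full((1, s_taxa), 50))
        row = alpha_diversity(t).loc["s"]
        assert row["shannon"] == pytest.approx(np.log(s_taxa))
        assert row["simpson"] == pytest.approx(1 - 1 / s_taxa)
        assert row["simpson_d"] == pytest.approx(1 / s_taxa)

    def test_goods_coverage(self):
        # 100 reads, 5 singleton taxa -> coverage 0.95
        counts = [[95] + [1] * 5]
        t = CountTable(["s"], [f"t{i}" for i in range(6)],
                       np.array(counts) - np.array([[5] + [0] * 5]))
        assert t.depths[0] == 95  # sanity of construction
        t = CountTable(["s"], [f"t{i}" for i in range(6)],
                       np.array([[95, 1, 1, 1, 1, 1]]))
        assert alpha_diversity(t).loc["s", "goods_coverage"] == pytest.approx(0.95)

    def test_chao1_at_least_observed_richness(self, small_cohort):
        table, _, _ = small_cohort
        rep = alpha_diversity(table)
        observed = (table.counts > 0).sum(axis=1)
        assert np.all(rep["chao1"].to_numpy() >= observed - 1e-9)
        assert np.all((rep["goods_coverage"] >= 0) & (rep["goods_coverage"] <= 1))
        assert np.all(rep["shannon"] >= 0)

    def test_zero_depth_errors(self):
        t = CountTable(["s"], ["a"], np.array([[0]]))
        with pytest.raises(ValidationError):
            alpha_diversity(t)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = CountTable(["a", "b"], ["x", "y"], np.array([[3, 4], [3, 4]]))
        assert bray_curtis(t)["a", "b"] == 0

    def test_disjoint_supports_one(self):
        t = CountTable(["a", "b"], ["x", "y"], np.array([[5, 0], [0, 7]]))
        assert bray_curtis(t)["a", "b"] == 1

    def test_hand_value(self):
        t = CountTable(["a", "b"], ["x", "y", "z"],
                       np.array([[6, 0, 2], [2, 2, 4]]))
        # 1 - 2*(2+0+2)/(8+8) = 0.5
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.5)


def _separated_dm():
    """Two tight groups far apart: all between > all within."""
    d = np.zeros((6, 6))
    for i, j in itertools.combinations(range(6), 2):
        same = (i < 3) == (j < 3)
        d[i, j] = d[j, i] = 0.1 if same else 0.9
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])


class TestAnosim:
    def test_maximal_separation_r_one(self):
        r, p = anosim(_separated_dm(), ["g1"] * 3 + ["g2"] * 3,
                      n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert 0 < p <= 1

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((12, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        ps = [anosim(dm, list(np.random.default_rng(s).permutation(
            ["a"] * 6 + ["b"] * 6)), n_perm=199, seed=s)[1]
            for s in range(8)]
        assert 0.05 < np.mean(ps) < 0.95  # calibrated, not anti-conservative

    def test_deterministic_under_seed(self):
        dm = _separated_dm()
        labels = ["g1", "g2"] * 3
        assert anosim(dm, labels, 99, seed=3) == anosim(dm, labels, 99, seed=3)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            anosim(_separated_dm(), ["a"] * 5 + ["b"], 99, 0)

    def test_pairwise_bonferroni_multiplication(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((16, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(16)])
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + ["d"] * 4
        table = anosim_pairwise(dm, labels, n_perm=99, seed=0)
        assert len(table) == 6
        expected = np.minimum(1.0, table["p"] * 6)
        assert np.allclose(table["p_bonferroni"], expected)


def _brute_force_permanova(d: np.ndarray, labels):
    """Exact one-factor pseudo-F and enumeration p over all label permutations."""
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    a = len(uniq)

    def pseudo_f(lab):
        d2 = d ** 2
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            sub = d2[np.ix_(idx, idx)]
            ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        f = pseudo_f(labels[list(perm)])
        count += f >= f_obs - 1e-12
        total += 1
    return f_obs, count / total


class TestPermanova:
    def test_matches_exact_enumeration_oracle(self):
        """skbio's statistic equals a brute-force pseudo-F, and its permutation
        p approaches the exact enumeration p on a 6-sample fixture."""
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2.5, 1, (3, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        labels = ["a"] * 3 + ["b"] * 3
        f_skbio, r2, p = permanova(dm, labels, n_perm=9999, seed=0)
        f_exact, p_exact = _brute_force_permanova(d, labels)
        assert f_skbio == pytest.approx(f_exact, rel=1e-10)
        assert p == pytest.approx(p_exact, abs=0.03)
        assert 0 <= r2 <= 1

    def test_r2_grows_with_separation(self):
        rng = np.random.default_rng(2)
        r2s = []
        for sep in (0.0, 5.0, 50.0):
            pts = np.vstack([rng.normal(0, 1, (5, 2)),
                             rng.normal(sep, 1, (5, 2))])
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(10)])
            r2s.append(permanova(dm, ["a"] * 5 + ["b"] * 5, 99, 0)[1])
        assert r2s[0] < r2s[1] < r2s[2]
        assert r2s[2] > 0.9

    def test_sums_of_squares_partition(self):
        dm = _separated_dm()
        ss_b, ss_t = _sums_of_squares(dm, ["a"] * 3 + ["b"] * 3)
        assert 0 < ss_b < ss_t


class TestPermdisp:
    def test_equal_dispersion_not_rejected(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(4, 1, (10, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(20)])
        f, p = permdisp(dm, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=0)
        assert f >= 0
        assert p > 0.05


def test_alpha_group_effect_sizes():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
    groups = ["a"] * 20 + ["b"] * 20
    out = alpha_group_effect(vals, groups)
    assert out["p"] < 0.01
    assert 0 < out["epsilon_squared"] <= 1
    assert out["eta_squared"] <= out["epsilon_squared"] + 1e-9
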
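"""Rank tests, dose correlations and CAP classification."""

import itertools

import numpy as np
import pytest
from scipy import stats

from phaeotox.multivariate import (
    cap,
    kruskal_wallis_letters,
    spearman_dose,
)


def _kw_h_oracle(samples):
    """Kruskal-Wallis H by direct rank-formula evaluation (tie-corrected)."""
    all_vals = np.concatenate(samples)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    offset, rank_sums = 0, []
    for s in samples:
        rank_sums.append(ranks[offset:offset + len(s)].sum())
        offset += len(s)
    h = 12.0 / (n * (n + 1)) * sum(
        r * r / len(s) for r, s in zip(rank_sums, samples)) - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_groups_share_one_letter(self):
        res = kruskal_wallis_letters([1.0] * 9, ["a"] * 3 + ["b"] * 3
                                     + ["c"] * 3)
        assert res.H == 0.0
        assert set(res.letters.values()) == {"a"}

    def test_h_matches_rank_formula_oracle_2x3(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 3)
            b = rng.normal(1, 1, 3)
            res = kruskal_wallis_letters(np.r_[a, b],
                                         ["a"] * 3 + ["b"] * 3)
            assert res.H == pytest.approx(_kw_h_oracle([a, b]), rel=1e-12)

    def test_fully_separated_two_groups_h(self):
        # ranks 1-3 vs 4-6: H = 12/42*(36/3+225/3) - 21
        res = kruskal_wallis_letters([1, 2, 3, 10, 11, 12],
                                     ["a"] * 3 + ["b"] * 3)
        assert res.H == pytest.approx(_kw_h_oracle(
            [np.array([1, 2, 3.0]), np.array([10, 11, 12.0])]))
        assert res.H == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)

    def test_ties_handled_like_scipy(self):
        vals = [1, 1, 2, 2, 3, 3, 9, 9, 10]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis_letters(vals, groups)
        h_ref, _ = stats.kruskal(vals[:3], vals[3:6], vals[6:])
        assert res.H == pytest.approx(h_ref)

    def test_letters_are_label_permutation_equivariant(self, rng):
        vals = np.r_[rng.normal(0, 0.1, 4), rng.normal(5, 0.1, 4),
                     rng.normal(10, 0.1, 4)]
        groups = np.array(["x"] * 4 + ["y"] * 4 + ["z"] * 4)
        res1 = kruskal_wallis_letters(vals, groups, alpha=0.05)
        perm = rng.permutation(12)
        res2 = kruskal_wallis_letters(vals[perm], groups[perm], alpha=0.05)
        assert res1.letters == res2.letters

    def test_separated_groups_get_distinct_letters(self, rng):
        vals = np.r_[rng.normal(0, 0.1, 6), rng.normal(50, 0.1, 6)]
        res = kruskal_wallis_letters(vals, ["lo"] * 6 + ["hi"] * 6)
        assert res.p < 0.05
        assert res.letters["lo"] != res.letters["hi"]


class TestSpearman:
    def test_monotone_increasing_is_plus_one(self):
        res = spearman_dose([1, 2, 3, 5, 8], [0, 0.3, 0.6, 20, 40])
        assert res.rho == pytest.approx(1.0)
        assert res.signed_rho2 == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        res = spearman_dose([8, 5, 3, 2, 1], [0, 0.3, 0.6, 20, 40])
        assert res.rho == pytest.approx(-1.0)
        assert res.signed_rho2 == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        vals = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        doses = np.array([0.0, 0.3, 0.6, 20.0, 40.0, 80.0])
        res = spearman_dose(vals, doses)
        rv, rd = stats.rankdata(vals), stats.rankdata(doses)
        oracle = np.corrcoef(rv, rd)[0, 1]  # Pearson on mid-ranks
        assert res.rho == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_flagged_undefined(self):
        res = spearman_dose([2.0, 2.0, 2.0], [0.0, 1.0, 2.0])
        assert res.undefined


def _brute_force_loo_nearest_centroid(x, groups, m):
    """Independent LOO oracle: PCA axes via SVD on the held-in rows,
    Mahalanobis-free nearest centroid in canonical space computed from
    first principles (between/within eigenproblem solved per fold)."""
    import scipy.linalg
    n = len(x)
    correct = 0
    labels = list(dict.fromkeys(groups.tolist()))
    for i in range(n):
        keep = np.arange(n) != i
        xt = x[keep]
        mean = xt.mean(axis=0)
        xc = xt - mean
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        axes = vt[:m].T / 1.0
        scores = xc @ axes
        held = (x[i] - mean) @ axes
        g = groups[keep]
        mu = {lab: scores[g == lab].mean(axis=0) for lab in labels}
        grand = scores.mean(axis=0)
        b = np.zeros((m, m))
        w = np.zeros((m, m))
        for lab in labels:
            xg = scores[g == lab]
            d = (mu[lab] - grand)[None, :]
            b += len(xg) * d.T @ d
            r = xg - mu[lab]
            w += r.T @ r
        evals, vecs = scipy.linalg.eigh(b, w)
        order = np.argsort(evals)[::-1][: len(labels) - 1]
        v = vecs[:, order]
        cents = {lab: (mu[lab] - grand) @ v for lab in labels}
        held_c = (held - grand) @ v
        pred = min(labels,
                   key=lambda lab: np.linalg.norm(held_c - cents[lab]))
        if pred == groups[i]:
            correct += 1
    return correct / n * 100.0


class TestCap:
    def test_well_separated_clusters_classify_perfectly(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (5, 4)),
                       rng.normal(10, 0.1, (5, 4)),
                       rng.normal(-10, 0.1, (5, 4))])
        groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res = cap(x, groups, n_perm=99, seed=0)
        assert res.accuracy == 100.0
        assert res.p_permutation < 0.05

    def test_confusion_rows_sum_to_group_sizes(self, rng):
        x = rng.normal(0, 1, (12, 5))
        groups = np.array(["a", "b", "c"] * 4)
        res = cap(x, groups, m_rule="fixed", m=2, n_perm=49, seed=1)
        for gi, lab in enumerate(res.group_labels):
            assert res.confusion[gi].sum() == np.sum(groups == lab)
        assert res.accuracy == pytest.approx(
            np.trace(res.confusion) / 12 * 100)

    def test_matches_brute_force_loo_oracle_small_n(self, rng):
        for trial in range(5):
            x = np.vstack([rng.normal(0, 1.0, (4, 3)),
                           rng.normal(1.5, 1.0, (4, 3))])
            groups = np.array(["a"] * 4 + ["b"] * 4)
            res = cap(x, groups, m_rule="fixed", m=2, n_perm=9, seed=trial)
            oracle = _brute_force_loo_nearest_centroid(x, groups, m=2)
            assert res.accuracy == pytest.approx(oracle)

    def test_pcoa_on_euclidean_matches_pca_scores(self, rng):
        from phaeotox.multivariate import _pcoa
        from scipy.spatial.distance import pdist, squareform
        x = rng.normal(0, 1, (10, 4))
        d2 = squareform(pdist(x)) ** 2
        evals, evecs, n_neg = _pcoa(d2)
        assert n_neg == 0
        scores = evecs * np.sqrt(evals)
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        pca_scores = u * s
        k = min(scores.shape[1], pca_scores.shape[1])
        for j in range(k):
            dot = np.abs(np.dot(scores[:, j], pca_scores[:, j]))
            assert dot == pytest.approx(
                np.linalg.norm(scores[:, j])
                * np.linalg.norm(pca_scores[:, j]), rel=1e-6)

    def test_uniform_feature_scaling_invariance(self, rng):
        x = np.vstack([rng.normal(0, 1, (5, 4)),
                       rng.normal(2, 1, (5, 4))])
        groups = np.array(["a"] * 5 + ["b"] * 5)
        r1 = cap(x, groups, m_rule="fixed", m=2, n_perm=9, seed=0)
        r2 = cap(x * 37.0, groups, m_rule="fixed", m=2, n_perm=9, seed=0)
        assert r1.accuracy == r2.accuracy
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_max_loo_rule_picks_smallest_m_on_ties(self, rng):
        x = np.vstack([rng.normal(0, 0.05, (4, 3)),
                       rng.normal(5, 0.05, (4, 3))])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res = cap(x, groups, m_rule="max_loo", n_perm=9, seed=0)
        # perfectly separated: every m achieves 100%, so m must be 1
        assert res.accuracy == 100.0
        assert res.m == 1

    def test_permutation_p_recorded_with_seed(self, rng):
        x = rng.normal(0, 1, (10, 3))
        groups = np.array(["a", "b"] * 5)
        res = cap(x, groups, m_rule="fixed", m=2, n_perm=199, seed=42)
        assert res.seed == 42
        assert res.n_permutations == 199
        assert 0 < res.p_permutation <= 1
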
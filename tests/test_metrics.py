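import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atacfuse import agreement, ami, ari, clisi, foscttnn, gmd, homogeneity


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------

def ari_oracle(a, b):
    """Pair-counting adjusted Rand index, enumerating all pairs."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        ss += same_a and same_b
        sd += same_a and not same_b
        ds += same_b and not same_a
        dd += not same_a and not same_b
    total = math.comb(n, 2)
    index = ss
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)


def entropy(labels):
    n = len(labels)
    return -sum(
        (c / n) * math.log(c / n)
        for c in np.unique(labels, return_counts=True)[1]
    )


def mutual_information(a, b):
    n = len(a)
    mi = 0.0
    for ca in np.unique(a):
        for cb in np.unique(b):
            nij = np.sum((a == ca) & (b == cb))
            if nij:
                ni, nj = np.sum(a == ca), np.sum(b == cb)
                mi += (nij / n) * math.log(n * nij / (ni * nj))
    return mi


def expected_mi(a, b):
    """Exhaustive hypergeometric E[MI] summation."""
    n = len(a)
    a_sizes = np.unique(a, return_counts=True)[1]
    b_sizes = np.unique(b, return_counts=True)[1]
    emi = 0.0
    for ai in a_sizes:
        for bj in b_sizes:
            lo, hi = max(1, ai + bj - n), min(ai, bj)
            for nij in range(lo, hi + 1):
                p = (
                    math.comb(bj, nij) * math.comb(n - bj, ai - nij)
                    / math.comb(n, ai)
                )
                emi += p * (nij / n) * math.log(n * nij / (ai * bj))
    return emi


def ami_oracle(a, b):
    h_a, h_b = entropy(a), entropy(b)
    if h_a == 0 and h_b == 0:
        return 1.0
    mi, emi = mutual_information(a, b), expected_mi(a, b)
    denom = (h_a + h_b) / 2 - emi
    if denom == 0:
        return 0.0
    return (mi - emi) / denom


def homogeneity_oracle(true, pred):
    h_true = entropy(true)
    if h_true == 0:
        return 1.0
    n = len(true)
    h_cond = 0.0
    for cp in np.unique(pred):
        mask = pred == cp
        sub = np.asarray(true)[mask]
        h_cond += (mask.sum() / n) * entropy(sub)
    return 1 - h_cond / h_true


def clisi_oracle(emb, labels, perplexity):
    """Direct kernel computation with per-cell bandwidth binary search."""
    n = len(labels)
    types = np.unique(labels)
    vals = np.zeros(n)
    for i in range(n):
        d2 = np.array([np.sum((emb[i] - emb[j]) ** 2) for j in range(n) if j != i])
        others = [labels[j] for j in range(n) if j != i]
        d2 = d2 - d2.min()
        lo, hi = 0.0, np.inf
        beta = 1.0
        target = math.log(min(perplexity, n - 1))
        if perplexity >= n - 1:
            # log(n-1) is the entropy supremum, attained by the uniform kernel
            p = np.full(n - 1, 1.0 / (n - 1))
        else:
            for _ in range(100):
                w = np.exp(-beta * d2)
                p = w / w.sum()
                h = -np.sum(p * np.log(np.maximum(p, 1e-300)))
                if abs(h - target) < 1e-12:
                    break
                if h > target:
                    lo = beta
                    beta = beta * 2 if hi == np.inf else (beta + hi) / 2
                else:
                    hi = beta
                    beta = (beta + lo) / 2
        pt = np.array([np.sum(p[np.array(others) == t]) for t in types])
        vals[i] = 1.0 / np.sum(pt**2)
    return vals


def foscttnn_oracle(atac, rna):
    n = atac.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        d_rna = [(np.linalg.norm(rna[i] - rna[j]), j) for j in range(n) if j != i]
        m = min(d_rna)[1]
        dm = np.linalg.norm(atac[i] - atac[m])
        closer = sum(
            1 for j in range(n)
            if j != i and j != m and np.linalg.norm(atac[i] - atac[j]) < dm
        )
        vals[i] = closer / (n - 2)
    return vals


def agreement_oracle(atac, rna, k):
    n = atac.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        da = sorted((np.linalg.norm(atac[i] - atac[j]), j) for j in range(n) if j != i)
        dr = sorted((np.linalg.norm(rna[i] - rna[j]), j) for j in range(n) if j != i)
        sa = {j for _, j in da[:k]}
        sr = {j for _, j in dr[:k]}
        vals[i] = len(sa & sr) / k
    return vals


def gmd_oracle(x):
    n = len(x)
    return sum(abs(x[i] - x[j]) for i in range(n) for j in range(n) if i != j) / (
        n * (n - 1)
    )


# ---------------------------------------------------------------------------
# Oracle agreement on random instances
# ---------------------------------------------------------------------------

N_INSTANCES = 50


class TestPartitionMetricOracles:
    @pytest.mark.parametrize("metric,oracle", [
        (ari, ari_oracle), (ami, ami_oracle), (homogeneity, homogeneity_oracle),
    ])
    def test_random_instances_match_oracle(self, metric, oracle):
        rng = np.random.default_rng(12)
        for _ in range(N_INSTANCES):
            n = rng.integers(4, 21)
            a = rng.integers(0, rng.integers(2, 5), n)
            b = rng.integers(0, rng.integers(2, 5), n)
            assert metric(a, b) == pytest.approx(oracle(a, b), abs=1e-9)

    def test_spec_example_against_pair_counting(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [0, 0, 1, 2, 2, 2]
        assert ari(a, b) == pytest.approx(ari_oracle(a, b), abs=1e-12)
        assert ami(a, b) == pytest.approx(ami_oracle(a, b), abs=1e-9)
        assert homogeneity(a, b) == pytest.approx(homogeneity_oracle(a, b), abs=1e-12)

    def test_identity_and_relabeling(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        relabeled = np.array([2, 2, 0, 0, 1, 1])
        for metric in (ari, ami, homogeneity):
            assert metric(a, a) == 1.0
            assert metric(a, relabeled) == 1.0

    def test_ami_near_zero_for_independent_partitions(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, 1000)
        b = rng.integers(0, 4, 1000)
        assert abs(ami(a, b)) < 0.05

    def test_homogeneity_edge_cases(self):
        true = [0, 0, 1, 1]
        assert homogeneity(true, [0, 1, 2, 3]) == pytest.approx(1.0)  # singletons pure
        assert homogeneity(true, [0, 0, 0, 0]) == 0.0  # one predicted cluster

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])


class TestClisi:
    def test_single_type_gives_one(self, rng):
        emb = rng.standard_normal((30, 3))
        report = clisi(emb, ["a"] * 30, perplexity=5)
        np.testing.assert_allclose(report.per_cell, 1.0, atol=1e-9)

    def test_matches_brute_force_kernel(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 16))
            emb = rng.standard_normal((n, 2))
            labels = rng.integers(0, 3, n).astype(str)
            report = clisi(emb, labels, perplexity=4)
            oracle = clisi_oracle(emb, labels, 4)
            np.testing.assert_allclose(report.per_cell, oracle, atol=1e-9)

    def test_interleaved_types_approach_two(self):
        x = np.arange(60, dtype=float)[:, None]
        labels = np.array(["a", "b"] * 30)
        report = clisi(x, labels, perplexity=10)
        assert report.summary["mean"] > 1.9

    def test_separated_types_approach_one(self, rng):
        emb = np.vstack([rng.standard_normal((25, 2)),
                         rng.standard_normal((25, 2)) + 300.0])
        labels = np.repeat(["a", "b"], 25)
        report = clisi(emb, labels, perplexity=10)
        assert report.summary["mean"] < 1.01

    def test_values_bounded_by_type_count(self, rng):
        emb = rng.standard_normal((40, 3))
        labels = rng.integers(0, 3, 40)
        report = clisi(emb, labels, perplexity=10)
        assert np.all(report.per_cell >= 1 - 1e-9)
        assert np.all(report.per_cell <= 3 + 1e-9)


class TestFoscttnn:
    def test_identical_embeddings_zero(self, rng):
        emb = rng.standard_normal((20, 4))
        report = foscttnn(emb, emb)
        np.testing.assert_array_equal(report.per_cell, 0.0)

    def test_three_cell_reversal(self):
        # RNA: cell0's NN is cell1; ATAC flips so cell2 is closer than cell1
        rna = np.array([[0.0], [1.0], [5.0]])
        atac = np.array([[0.0], [5.0], [1.0]])
        report = foscttnn(atac, rna)
        assert report.per_cell[0] == 1.0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 15))
            atac = rng.standard_normal((n, 3))
            rna = rng.standard_normal((n, 3))
            report = foscttnn(atac, rna)
            np.testing.assert_allclose(
                report.per_cell, foscttnn_oracle(atac, rna), atol=1e-9
            )

    def test_random_embeddings_mean_half(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            atac = rng.standard_normal((200, 5))
            rna = rng.standard_normal((200, 5))
            means.append(foscttnn(atac, rna).summary["mean"])
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_rigid_motion_invariance(self, rng):
        atac = rng.standard_normal((15, 3))
        rna = rng.standard_normal((15, 3))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rotated = atac @ q + np.array([5.0, -2.0, 1.0])
        np.testing.assert_allclose(
            foscttnn(atac, rna).per_cell, foscttnn(rotated, rna).per_cell, atol=1e-9
        )


class TestAgreement:
    def test_identical_embeddings_one(self, rng):
        emb = rng.standard_normal((25, 3))
        report = agreement(emb, emb.copy(), k=5)
        np.testing.assert_array_equal(report.per_cell, 1.0)

    def test_complete_neighborhoods_one(self, rng):
        atac = rng.standard_normal((10, 2))
        rna = rng.standard_normal((10, 2))
        report = agreement(atac, rna, k=9)
        np.testing.assert_array_equal(report.per_cell, 1.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 16))
            k = int(rng.integers(1, n - 1))
            atac = rng.standard_normal((n, 3))
            rna = rng.standard_normal((n, 3))
            report = agreement(atac, rna, k=k)
            np.testing.assert_allclose(
                report.per_cell, agreement_oracle(atac, rna, k), atol=1e-9
            )

    def test_random_embeddings_match_hypergeometric_null(self):
        n, k = 500, 50
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            atac = rng.standard_normal((n, 5))
            rna = rng.standard_normal((n, 5))
            means.append(agreement(atac, rna, k=k).summary["mean"])
        assert abs(np.mean(means) - k / (n - 1)) < 0.03

    def test_k_too_large_rejected(self, rng):
        emb = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            agreement(emb, emb, k=5)


class TestGmd:
    def test_examples(self):
        assert gmd([3.0, 3.0, 3.0]) == 0.0
        assert gmd([0.0, 1.0]) == 1.0
        assert gmd([0.0, 1.0, 2.0]) == pytest.approx(8 / 6)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(N_INSTANCES):
            x = rng.standard_normal(int(rng.integers(2, 21)))
            assert gmd(x) == pytest.approx(gmd_oracle(list(x)), abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        xs=st.lists(st.floats(-100, 100), min_size=2, max_size=25),
        shift=st.floats(-50, 50),
        scale=st.floats(-5, 5),
    )
    def test_affine_equivariance(self, xs, shift, scale):
        """GMD is translation-invariant and absolutely homogeneous."""
        x = np.asarray(xs)
        assert gmd(scale * x + shift) == pytest.approx(
            abs(scale) * gmd(x), abs=1e-9, rel=1e-9
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 4), min_size=2, max_size=30), st.integers(0, 100))
    def test_partition_metrics_label_permutation_invariant(self, labels, seed):
        rng = np.random.default_rng(seed)
        a = np.asarray(labels)
        b = rng.integers(0, 3, a.size)
        perm = rng.permutation(5)
        for metric in (ari, ami, homogeneity):
            assert metric(perm[a], b) == pytest.approx(metric(a, b), abs=1e-9)

    def test_summary_columns_present(self, rng):
        report = foscttnn(rng.standard_normal((10, 2)), rng.standard_normal((10, 2)))
        assert set(report.summary) == {"q1", "median", "gmd", "mean", "sd", "q3"}
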
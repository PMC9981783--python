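import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from atacfuse import (
    GeneAnnotation,
    MotifAnnotation,
    gene_activity,
    lda_topics,
    motif_deviations,
    reduce_modality,
    select_n_components,
    tfidf_lsi,
)
from atacfuse.modalities import GeneActivityMatrix, tfidf_transform

from conftest import make_pm


def principal_angles(A, B):
    """Largest principal angle (radians, sine-based) between column spaces.

    Computed as ||(I - Qa Qa') Qb||_2 = sin(theta_max), which stays accurate
    for angles near zero where the arccos formulation loses precision.
    """
    Qa, _ = np.linalg.qr(A)
    Qb, _ = np.linalg.qr(B)
    resid = Qb - Qa @ (Qa.T @ Qb)
    return np.arcsin(np.clip(np.linalg.svd(resid, compute_uv=False).max(), 0, 1))


class TestTfidf:
    def test_worked_example(self):
        # counts [[1,0],[1,2]]: depths (2,2); TF col0 = (0.5, 0.5);
        # peak 0 seen in 1 of 2 cells -> IDF = 2; value = log(1 + 0.5*2*1e4)
        pm = make_pm([[1, 0], [1, 2]])
        t, kept = tfidf_transform(pm)
        assert np.isclose(t[0, 0], np.log(1 + 0.5 * 2 * 1e4))
        assert np.isclose(t[1, 1], np.log(1 + 1.0 * 1 * 1e4))
        np.testing.assert_array_equal(kept, [0, 1])

    def test_depth_invariance(self, rng):
        counts = rng.poisson(1.0, (40, 15)) + (rng.random((40, 15)) < 0.1)
        counts[0] += 1  # no empty cells
        t1, _ = tfidf_transform(make_pm(counts))
        t2, _ = tfidf_transform(make_pm(counts * 3))
        assert np.max(np.abs((t1 - t2).toarray())) < 1e-12

    def test_scores_match_dense_svd_oracle(self, rng):
        counts = rng.poisson(0.8, (100, 40))
        counts[0] += 1
        pm = make_pm(counts)
        emb = tfidf_lsi(pm, n_components=5, drop_first=False, seed=0)
        t, _ = tfidf_transform(pm)
        u, s, vt = np.linalg.svd(t.toarray().T, full_matrices=False)
        oracle = u[:, :5] * s[:5]
        assert principal_angles(emb.scores, oracle) < 1e-8

    def test_drop_first_removes_top_component(self, rng):
        counts = rng.poisson(0.8, (80, 30))
        counts[0] += 1
        pm = make_pm(counts)
        full = tfidf_lsi(pm, n_components=6, drop_first=False, seed=0)
        dropped = tfidf_lsi(pm, n_components=5, drop_first=True, seed=0)
        np.testing.assert_allclose(
            np.abs(full.scores[:, 1:]), np.abs(dropped.scores), atol=1e-8
        )

    def test_all_zero_cell_names_barcode(self):
        pm = make_pm([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="cell1"):
            tfidf_transform(pm)

    def test_zero_peak_dropped_with_warning(self):
        pm = make_pm([[1, 1], [0, 0], [2, 1]])
        with pytest.warns(UserWarning, match="dropped 1 peaks"):
            t, kept = tfidf_transform(pm)
        assert t.shape == (2, 2)
        np.testing.assert_array_equal(kept, [0, 2])


class TestLda:
    def planted(self):
        counts = np.zeros((200, 100), dtype=int)
        counts[:100, :50] = 1
        counts[100:, 50:] = 1
        return make_pm(counts)

    def test_rows_are_probabilities(self):
        emb = lda_topics(self.planted(), n_topics=3, n_iter=20, seed=0)
        np.testing.assert_allclose(emb.scores.sum(axis=1), 1.0, atol=1e-9)

    def test_seed_determinism(self):
        pm = self.planted()
        a = lda_topics(pm, n_topics=3, n_iter=30, seed=5)
        b = lda_topics(pm, n_topics=3, n_iter=30, seed=5)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_planted_two_block_recovery(self):
        emb = lda_topics(self.planted(), n_topics=2, n_iter=150, seed=0)
        dominant = emb.scores.argmax(axis=1)
        block = np.repeat([0, 1], 50)
        agree = max(np.mean(dominant == block), np.mean(dominant == 1 - block))
        assert agree >= 0.95

    def test_too_many_topics_rejected(self):
        pm = make_pm(np.ones((5, 4), dtype=int))
        with pytest.raises(ValueError):
            lda_topics(pm, n_topics=4, n_iter=5)


class TestGeneActivity:
    def annotation(self, strand, start, end):
        return GeneAnnotation(records=pd.DataFrame(
            [{"gene_id": "g", "chrom": "chr1", "strand": strand,
              "start": start, "end": end}]
        ))

    def pm_at(self, intervals, counts_per_cell):
        from atacfuse import Peak, PeakCountMatrix

        peaks = [Peak("chr1", s, e) for s, e in intervals]
        counts = np.asarray(counts_per_cell)
        return PeakCountMatrix(
            counts=sp.csr_matrix(counts), peaks=peaks,
            barcodes=[f"c{i}" for i in range(counts.shape[1])],
        )

    def test_promoter_overlap_counted(self):
        # + strand body (1000,2000), u=2000 -> window [0,2000); peak (500,600) hits
        pm = self.pm_at([(500, 600)], [[3]])
        ga = gene_activity(pm, self.annotation("+", 1000, 2000), 2000)
        assert ga.values[0, 0] == 3

    def test_downstream_peak_not_counted(self):
        pm = self.pm_at([(2500, 2600)], [[3]])
        ga = gene_activity(pm, self.annotation("+", 1000, 2000), 2000)
        assert ga.values[0, 0] == 0

    def test_minus_strand_promoter_downstream_of_body(self):
        # - strand body (1000,2000): promoter [2000,4000); peak (2100,2200) hits
        pm = self.pm_at([(2100, 2200)], [[5]])
        ga = gene_activity(pm, self.annotation("-", 1000, 2000), 2000)
        assert ga.values[0, 0] == 5

    def test_multi_gene_peak_counted_fully_for_each(self):
        ann = GeneAnnotation(records=pd.DataFrame([
            {"gene_id": "a", "chrom": "chr1", "strand": "+", "start": 0, "end": 1000},
            {"gene_id": "b", "chrom": "chr1", "strand": "+", "start": 500, "end": 1500},
        ]))
        pm = self.pm_at([(600, 700)], [[2]])
        ga = gene_activity(pm, ann, 0)
        np.testing.assert_array_equal(ga.values.toarray().ravel(), [2, 2])

    def test_mass_conservation_non_overlapping_genes(self, small_dataset):
        pm, ann, _, _ = small_dataset
        ga = gene_activity(pm, ann)
        # the synthetic genes are non-overlapping, so activity mass is bounded
        assert ga.values.sum() <= pm.counts.sum()

    def test_hand_counted_sums(self):
        ann = self.annotation("+", 1000, 3000)
        pm = self.pm_at([(500, 600), (1500, 1600), (5000, 5100)],
                        [[1, 2], [4, 8], [16, 32]])
        ga = gene_activity(pm, ann, 2000)
        np.testing.assert_array_equal(ga.values.toarray(), [[5, 10]])


class TestMotifDeviations:
    def uniform_pm(self, n_peaks=20, n_cells=6, count=5):
        return make_pm(np.full((n_peaks, n_cells), count))

    def motif(self, n_peaks, member_idx):
        m = np.zeros((n_peaks, 1), dtype=int)
        m[member_idx] = 1
        return MotifAnnotation(membership=sp.csr_matrix(m), motif_ids=["m"])

    def test_uniform_counts_zero_deviation(self):
        pm = self.uniform_pm()
        ma = self.motif(20, np.arange(10))
        dev = motif_deviations(pm, ma, n_background=10, seed=0)
        np.testing.assert_allclose(dev.raw_deviations, 0.0, atol=1e-12)

    def test_all_peaks_motif_zero_deviation(self, rng):
        counts = rng.poisson(2.0, (30, 8)) + 1
        pm = make_pm(counts)
        ma = self.motif(30, np.arange(30))
        dev = motif_deviations(pm, ma, n_background=10, seed=0)
        np.testing.assert_allclose(dev.raw_deviations, 0.0, atol=1e-12)

    def test_planted_signal_elevates_z(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            counts = rng.poisson(2.0, (60, 40)) + 1
            counts[:15, :20] *= 3  # cluster A cells have 3x counts in motif peaks
            pm = make_pm(counts)
            membership = np.zeros((60, 2), dtype=int)
            membership[:15, 0] = 1
            membership[30:45, 1] = 1
            ma = MotifAnnotation(membership=sp.csr_matrix(membership),
                                 motif_ids=["sig", "bg"])
            dev = motif_deviations(pm, ma, n_background=20, seed=seed)
            if dev.z[0, :20].mean() > dev.z[0, 20:].mean():
                hits += 1
        assert hits >= 9

    def test_zero_member_motif_dropped(self):
        pm = self.uniform_pm()
        membership = np.zeros((20, 2), dtype=int)
        membership[:5, 0] = 1
        ma = MotifAnnotation(membership=sp.csr_matrix(membership),
                             motif_ids=["kept", "empty"])
        with pytest.warns(UserWarning, match="zero member"):
            dev = motif_deviations(pm, ma, n_background=10, seed=0)
        assert dev.motif_ids == ["kept"]
        assert dev.dropped_motifs == ["empty"]


class TestReduceModality:
    def test_pca_matches_eigen_oracle(self, rng):
        values = rng.standard_normal((10, 30))  # 10 features x 30 cells
        emb = reduce_modality(values, "motif", n_components=4, seed=0)
        # oracle: eigendecomposition of the covariance of standardized features
        feats = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        X = feats.T - feats.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        oracle = X @ evecs[:, ::-1][:, :4]
        assert principal_angles(emb.scores, oracle) < 1e-8

    def test_constant_gene_dropped(self):
        # an all-zero gene stays constant through log-normalization
        values = np.vstack([np.zeros(20), np.random.default_rng(1).poisson(5, (6, 20)) + 1])
        ga = GeneActivityMatrix(values=sp.csr_matrix(values),
                                gene_ids=[f"g{i}" for i in range(7)],
                                barcodes=[f"c{i}" for i in range(20)])
        with pytest.warns(UserWarning, match="zero-variance"):
            emb = reduce_modality(ga, "gene", n_components=3, seed=0)
        assert np.all(np.isfinite(emb.scores))

    def test_component_variance_non_increasing(self, rng):
        values = rng.standard_normal((12, 40))
        emb = reduce_modality(values, "motif", n_components=6, seed=0)
        variances = emb.scores.var(axis=0)
        assert np.all(np.diff(variances) <= 1e-10)


class TestSelectNComponents:
    def test_worked_example(self):
        assert select_n_components([10, 9.5, 1, 0.9, 0.8]) == 2

    def test_geometric_decay_hits_lower_bound(self):
        values = 10 * 0.5 ** np.arange(8)
        # brute force: second difference of variance-explained is maximized
        # at the first interior point for any geometric decay
        ve = values**2 / np.sum(values**2)
        d2 = ve[:-2] - 2 * ve[1:-1] + ve[2:]
        assert np.argmax(d2) == 0
        assert select_n_components(values) == 2

    def test_increasing_input_rejected(self):
        with pytest.raises(ValueError):
            select_n_components([1, 2, 3])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            select_n_components([2, 1])
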
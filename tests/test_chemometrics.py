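import numpy as np
import pytest

from ftirfp import (
    SpectraSet, pca, pc_side_separation, quadrant_assign, loading_peaks,
    best_separating_pc, default_profiles, simulate_cohort, preprocess_pipeline,
    select_region,
)


def make_set(matrix, labels=None):
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    return SpectraSet(
        grid=np.arange(p, dtype=float) + 600.0, matrix=matrix,
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels or ["g"] * n, replicates=[1] * n,
    )


class TestPca:
    def test_rank_one_antisymmetric_pair(self):
        r = np.array([1.0, 2.0, 3.0, 4.0])
        res = pca(make_set(np.vstack([r, -r])), k=1)
        assert np.allclose(res.explained_variance_pct, [100.0])
        assert np.allclose(np.sort(res.scores[:, 0]), [-np.linalg.norm(r), np.linalg.norm(r)])

    def test_matches_dense_eigendecomposition(self):
        """Explained variances agree with a brute-force covariance eigensolve."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(6, 40))
        res = pca(make_set(X), k=5)
        C = np.cov(X, rowvar=True, bias=False)  # noqa: F841 (shape check below uses features)
        Xc = X - X.mean(axis=0)
        evals = np.linalg.eigvalsh(Xc @ Xc.T)[::-1]
        expected_pct = 100.0 * evals / evals.sum()
        assert np.allclose(res.explained_variance_pct, expected_pct[:5], atol=1e-8)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(8, 30))
        res = pca(make_set(X), k=7)
        recon = res.centering_mean + res.scores @ res.loadings
        err = np.linalg.norm(recon - X) / np.linalg.norm(X - X.mean(axis=0))
        assert err < 1e-8

    def test_loading_rows_orthonormal_and_scores_orthogonal(self):
        rng = np.random.default_rng(13)
        res = pca(make_set(rng.normal(size=(10, 25))), k=5)
        G = res.loadings @ res.loadings.T
        assert np.allclose(G, np.eye(5), atol=1e-8)
        S = res.scores.T @ res.scores
        off = S - np.diag(np.diag(S))
        assert np.all(np.abs(off) <= 1e-6 * np.outer(
            np.linalg.norm(res.scores, axis=0), np.linalg.norm(res.scores, axis=0)))

    def test_explained_variance_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(14)
        res = pca(make_set(rng.normal(size=(7, 20))), k=4)
        ev = res.explained_variance_pct
        assert np.all(np.diff(ev) <= 1e-12)
        assert np.all((ev >= 0) & (ev <= 100))
        assert ev.sum() <= 100 + 1e-6

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(6, 18))
        perm = rng.permutation(6)
        a = pca(make_set(X), k=3)
        b = pca(make_set(X[perm]), k=3)
        assert np.allclose(a.scores[perm], b.scores, atol=1e-8)
        assert np.allclose(a.loadings, b.loadings, atol=1e-8)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(6, 18))
        a = pca(make_set(X), k=3)
        b = pca(make_set(X.copy()), k=3)
        assert np.array_equal(a.loadings, b.loadings)
        for row in a.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_identical_rows_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pca(make_set(np.ones((3, 10))), k=1)

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError, match="out of range"):
            pca(make_set(rng.normal(size=(3, 10))), k=3)


class TestSideSeparation:
    def make_result(self, scores_col, labels):
        rng = np.random.default_rng(0)
        n = len(labels)
        res = pca(make_set(rng.normal(size=(n, 12)), labels=labels), k=2)
        res.scores[:, 1] = scores_col
        return res

    def test_clean_bipartition_detected(self):
        res = self.make_result([1.0, 2.0, -1.0, -2.0], ["A", "A", "B", "B"])
        sep = pc_side_separation(res, 2)
        assert sep.clean_separation
        assert sep.positive_groups == ("A",)
        assert sep.negative_groups == ("B",)
        assert sep.positive_fraction == {"A": 1.0, "B": 0.0}

    def test_split_group_is_not_clean(self):
        res = self.make_result([1.0, -1.0, 0.5, 0.6], ["A", "A", "B", "B"])
        sep = pc_side_separation(res, 2)
        assert not sep.clean_separation
        assert sep.positive_fraction["A"] == 0.5

    def test_zero_score_counts_nonpositive(self):
        res = self.make_result([0.0, 1.0, -1.0, -2.0], ["A", "A", "B", "B"])
        assert not pc_side_separation(res, 2).clean_separation

    def test_shifted_group_separates_in_simulation(self):
        """A group-specific band shift is found by some of PC-1..3 in >=95/100 seeds."""
        hits = 0
        for seed in range(100):
            sset, _ = simulate_cohort(default_profiles("coriell", seed=seed))
            deriv = preprocess_pipeline(sset)
            res = pca(select_region(deriv, 2800, 3000), k=3)
            for i in (1, 2, 3):
                sep = pc_side_separation(res, i)
                if sep.clean_separation and ("DM1_2000",) in (sep.positive_groups,
                                                              sep.negative_groups):
                    hits += 1
                    break
        assert hits >= 95


class TestQuadrants:
    def make_result(self, pairs, labels):
        rng = np.random.default_rng(1)
        res = pca(make_set(rng.normal(size=(len(labels), 12)), labels=labels), k=2)
        res.scores[:, 0] = [p[0] for p in pairs]
        res.scores[:, 1] = [p[1] for p in pairs]
        return res

    @pytest.mark.parametrize("score,expected", [
        ((-0.3, 0.7), "Q2"),   # negative first PC, positive second
        ((0.3, -0.7), "Q4"),   # positive first PC, negative second
        ((0.3, 0.7), "Q1"),
        ((-0.3, -0.7), "Q3"),
    ])
    def test_quadrant_convention(self, score, expected):
        res = self.make_result([score, (1.0, 1.0), (-1.0, -1.0)], ["A", "B", "B"])
        rep = quadrant_assign(res, 1, 2)
        assert rep.quadrant[0] == expected

    def test_on_axis_flagged_and_excluded(self):
        res = self.make_result([(0.0, 1.0), (1.0, 1.0), (1.0, 2.0)], ["A", "A", "A"])
        rep = quadrant_assign(res, 1, 2)
        assert rep.on_axis[0]
        assert rep.quadrant[0] is None
        assert rep.purity["A"] == 1.0

    def test_partition_counts(self):
        rng = np.random.default_rng(2)
        res = pca(make_set(rng.normal(size=(12, 15)), labels=["A"] * 6 + ["B"] * 6), k=2)
        rep = quadrant_assign(res, 1, 2)
        assigned = [q for q in rep.quadrant if q is not None]
        assert len(assigned) + sum(rep.on_axis) == 12
        assert set(assigned) <= {"Q1", "Q2", "Q3", "Q4"}


class TestLoadingPeaks:
    def inject_loading(self, v):
        rng = np.random.default_rng(3)
        res = pca(make_set(rng.normal(size=(4, v.size))), k=2)
        res.loadings[0] = v
        return res

    def test_single_bump_is_one_positive_peak(self):
        x = np.arange(50, dtype=float)
        v = np.exp(-((x - 20) ** 2) / 18.0)
        res = self.inject_loading(v)
        peaks = loading_peaks(res, 1)
        assert len(peaks) == 1
        assert peaks[0].side == "positive"
        assert peaks[0].wavenumber == res.grid[20]

    def test_bump_and_dip_give_one_peak_per_side(self):
        x = np.arange(60, dtype=float)
        v = np.exp(-((x - 15) ** 2) / 8.0) - np.exp(-((x - 45) ** 2) / 8.0)
        peaks = loading_peaks(self.inject_loading(v), 1)
        assert sorted(p.side for p in peaks) == ["negative", "positive"]

    def test_flat_loading_gives_empty_list(self):
        res = self.inject_loading(np.zeros(30))
        assert loading_peaks(res, 1) == []

    def test_prominence_threshold_filters_minor_peaks(self):
        x = np.arange(80, dtype=float)
        v = np.exp(-((x - 20) ** 2) / 8.0) + 0.05 * np.exp(-((x - 60) ** 2) / 8.0)
        peaks = loading_peaks(self.inject_loading(v), 1, min_prominence=0.1)
        assert len(peaks) == 1

    def test_top_peak_matches_generator_band(self):
        """The dominant loading extremum falls within 4 cm^-1 of the one band
        whose amplitude differs between groups."""
        from ftirfp import BandSpec, CohortConfig
        bands_a = [BandSpec(2900.0, 9.0, 1.0), BandSpec(2950.0, 9.0, 0.5)]
        bands_b = [BandSpec(2900.0, 9.0, 1.0), BandSpec(2950.0, 9.0, 1.5)]
        cfg = CohortConfig(groups={"a": bands_a, "b": bands_b},
                           n_samples_per_group=4, noise_sd=0.0002, seed=9)
        sset, _ = simulate_cohort(cfg)
        # unnormalized: area normalization would spread the one-band
        # amplitude contrast over every band (relative redistribution)
        from ftirfp import PreprocessConfig
        deriv = preprocess_pipeline(sset, PreprocessConfig(normalization="none"))
        res = pca(select_region(deriv, 2800, 3000), k=2)
        sep = best_separating_pc(res)
        assert sep is not None
        top = loading_peaks(res, sep.pc_index)[0]
        assert abs(top.wavenumber - 2950.0) <= 4.0
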
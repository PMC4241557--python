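"""Ward clustering (vs a brute-force oracle), covariance PCA (vs closed
forms and sklearn), trajectory and variability statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import scipy_ward_history, ward_oracle
from ephysdev import multivariate as mv
from ephysdev.features import SPONTANEOUS_FEATURES
from ephysdev.synth import sample_feature_cohort


def frame_from(X, columns=None):
    X = np.asarray(X, dtype=float)
    cols = columns or [f"c{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols)


def raw_matrix(X):
    df = frame_from(X)
    return mv.normalize_features(df, mode="none",
                                 columns=tuple(df.columns))


class TestNormalize:
    def make_table(self, rng, n=12):
        data = {c: rng.normal(10, 2, n) for c in SPONTANEOUS_FEATURES}
        data["ap_threshold"] = rng.normal(-43.0, 3, n)  # negative-mean column
        data["ap_decay_slope"] = rng.normal(-30.0, 5, n)
        return pd.DataFrame(data)

    def test_constant_column_maps_to_unit(self, rng):
        df = self.make_table(rng)
        df["ahp"] = 24.0
        m = mv.normalize_features(df)
        assert np.allclose(m.data["ahp"], 1.0)
        df["ap_threshold"] = -43.0
        m = mv.normalize_features(df)
        assert np.allclose(m.data["ap_threshold"], -1.0)  # sign preserved

    def test_inverse_transform_exact(self, rng):
        df = self.make_table(rng)
        m = mv.normalize_features(df)
        back = m.data * m.divisors
        np.testing.assert_allclose(back.to_numpy(),
                                   df[list(SPONTANEOUS_FEATURES)].to_numpy(),
                                   rtol=1e-12)

    def test_nulls_rejected(self, rng):
        df = self.make_table(rng)
        df.loc[0, "ahp"] = None
        with pytest.raises(ValueError, match="null"):
            mv.normalize_features(df)

    def test_zero_mean_rejected(self, rng):
        df = self.make_table(rng)
        df["cv_isi"] = np.linspace(-1, 1, len(df))
        df["cv_isi"] -= df["cv_isi"].mean()
        with pytest.raises(ValueError, match="zero"):
            mv.normalize_features(df)


class TestWard:
    def test_three_points_on_a_line(self):
        """{0, 1, 10}: first merge {0,1} at height 1, then with {10} at the
        Ward height sqrt(2 * (2*1/3) * 9.5^2)."""
        X = np.array([[0.0], [1.0], [10.0]])
        Z = mv.ahc_ward(X)
        assert Z[0, 2] == pytest.approx(1.0)
        expected = np.sqrt(2 * (2.0 / 3.0) * 9.5 ** 2)
        assert Z[1, 2] == pytest.approx(expected)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_identical_points_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        Z = mv.ahc_ward(X)
        assert Z[0, 2] == pytest.approx(0.0)

    @pytest.mark.parametrize("case", range(100))
    def test_oracle_equivalence_small_n(self, case):
        """Every merge (partition and height) matches exhaustive greedy
        Ward agglomeration for n <= 6."""
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(3, 7))
        d = int(rng.integers(1, 4))
        X = rng.normal(0, 1, (n, d))
        expected = ward_oracle(X)
        got = scipy_ward_history(X)
        for (part_e, h_e), (part_g, h_g) in zip(expected, got):
            assert part_e == part_g
            assert h_g == pytest.approx(h_e, rel=1e-9)

    def test_newick_export(self):
        X = np.array([[0.0], [1.0], [10.0]])
        Z = mv.ahc_ward(X)
        nwk = mv.dendrogram_to_newick(Z, ["a", "b", "c"])
        assert nwk.endswith(";")
        assert all(leaf in nwk for leaf in ("a", "b", "c"))


class TestAutoCut:
    def blobs(self, rng, centers, n=20, sd=1.0):
        X = np.vstack([c + rng.normal(0, sd, (n, len(c))) for c in centers])
        df = frame_from(X)
        df["age_days"] = np.repeat(np.arange(len(centers)) * 5 + 2, n)
        m = mv.normalize_features(df, mode="none",
                                  columns=tuple(f"c{i}" for i in
                                                range(X.shape[1])))
        m.ages = df["age_days"]
        return m

    def test_three_separated_blobs(self, rng):
        centers = [np.zeros(4), np.full(4, 10.0), np.r_[10.0, -10, 10, -10]]
        m = self.blobs(rng, centers)
        cls = mv.auto_cut(mv.ahc_ward(m), m)
        assert len(set(cls.labels)) == 3
        for cid in set(cls.labels):
            rows = cls.labels == cid
            assert rows.sum() == 20  # pure classes

    def test_two_blobs(self, rng):
        centers = [np.zeros(4), np.full(4, 10.0)]
        m = self.blobs(rng, centers)
        cls = mv.auto_cut(mv.ahc_ward(m), m)
        assert len(set(cls.labels)) == 2

    def test_fixed_k_override(self, rng):
        centers = [np.zeros(4), np.full(4, 10.0)]
        m = self.blobs(rng, centers)
        cls = mv.auto_cut(mv.ahc_ward(m), m, k=4)
        assert len(set(cls.labels)) == 4

    def test_degenerate_equal_heights(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]) * 0.0
        X[:2] += 0.0  # all identical: every merge at height 0
        m = raw_matrix(X)
        with pytest.warns(UserWarning, match="falling back"):
            cls = mv.auto_cut(mv.ahc_ward(m), m)
        assert len(set(cls.labels)) == 2

    def test_central_object_is_closest_to_centroid(self, rng):
        centers = [np.zeros(3), np.full(3, 8.0)]
        m = self.blobs(rng, centers, n=15)
        cls = mv.auto_cut(mv.ahc_ward(m), m)
        X = m.values
        for cid, obj in cls.central_objects.items():
            rows = np.flatnonzero(cls.labels == cid)
            c = X[rows].mean(axis=0)
            dists = np.linalg.norm(X[rows] - c, axis=1)
            assert np.linalg.norm(X[obj] - c) == pytest.approx(dists.min())

    def test_class_ages_ordered_on_regime_cohort(self):
        """Classes on a three-stage calibrated cohort order young -> old."""
        df = sample_feature_cohort(
            plan=[("P2-P3", 30), ("P7", 30), ("P21-P23", 30)], seed=0)
        m = mv.normalize_features(df)
        cls = mv.auto_cut(mv.ahc_ward(m), m, k=3)
        ages = [cls.mean_ages[c][0] for c in sorted(cls.mean_ages)]
        frac_regular = [
            (df["regime"][cls.labels == c] == "regular").mean()
            for c in sorted(cls.mean_ages)]
        order = np.argsort(ages)
        assert np.all(np.diff(np.asarray(frac_regular)[order]) >= -0.05)

    def test_regime_recovery(self):
        """>= 90% of neurons land in the class dominated by their true
        firing regime (regimes kept well separated: each stage contributes
        only its canonical regime)."""
        df = sample_feature_cohort(
            plan=[("P2-P3", 60), ("P7", 60), ("P21-P23", 60)], seed=1)
        canonical = {"P2-P3": "bursting", "P7": "irregular",
                     "P21-P23": "regular"}
        df = df[df.apply(lambda r: r["regime"] == canonical[r["stage"]],
                         axis=1)].reset_index(drop=True)
        m = mv.normalize_features(df)
        cls = mv.auto_cut(mv.ahc_ward(m), m, k=3)
        agree = 0
        for cid in set(cls.labels):
            counts = df["regime"][cls.labels == cid].value_counts()
            agree += counts.iloc[0]
        assert agree / len(df) >= 0.90


class TestPCA:
    def exact_cov_matrix(self):
        """Four points whose divisor-n covariance is [[2,1],[1,2]]."""
        a, b = np.sqrt(3.0), 1.0
        X = np.array([[a, a], [-a, -a], [b, -b], [-b, b]])
        return raw_matrix(X)

    def test_closed_form_eigenstructure(self):
        model = mv.pca_covariance(self.exact_cov_matrix())
        np.testing.assert_allclose(model.eigenvalues, [3.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(model.variance_fractions, [0.75, 0.25],
                                   atol=1e-12)
        np.testing.assert_allclose(np.abs(model.components[0]),
                                   np.full(2, 1 / np.sqrt(2)), atol=1e-12)
        assert model.components[0][0] > 0  # sign convention

    def test_collinear_data(self, rng):
        t = rng.normal(0, 1, 20)
        X = np.outer(t, [1.0, 2.0])
        model = mv.pca_covariance(raw_matrix(X))
        assert model.variance_fractions[0] == pytest.approx(1.0)

    def test_score_covariance_is_diagonal_eigenvalues(self, rng):
        X = rng.normal(0, 1, (40, 5))
        model = mv.pca_covariance(raw_matrix(X))
        S = model.scores
        cov = S.T @ S / S.shape[0]
        np.testing.assert_allclose(cov, np.diag(model.eigenvalues),
                                   atol=1e-10)
        assert model.variance_fractions.sum() == pytest.approx(1.0)

    def test_reconstruction_machine_precision(self, rng):
        X = rng.normal(0, 1, (25, 6))
        m = raw_matrix(X)
        model = mv.pca_covariance(m)
        recon = model.scores @ model.components + model.means
        np.testing.assert_allclose(recon, m.values, atol=1e-10)

    def test_matches_sklearn_directions(self, rng):
        """Independent cross-check: sklearn PCA (divisor n-1) spans the same
        components; eigenvalues differ by the known n/(n-1) factor."""
        from sklearn.decomposition import PCA

        X = rng.normal(0, 2, (30, 4))
        model = mv.pca_covariance(raw_matrix(X))
        sk = PCA().fit(X)
        n = X.shape[0]
        np.testing.assert_allclose(model.eigenvalues,
                                   sk.explained_variance_ * (n - 1) / n,
                                   rtol=1e-9)
        for ours, theirs in zip(model.components, sk.components_):
            assert abs(np.dot(ours, theirs)) == pytest.approx(1.0, abs=1e-9)

    def test_divisor_switch_keeps_directions(self, rng):
        X = rng.normal(0, 1, (15, 3))
        m1 = mv.pca_covariance(raw_matrix(X), divisor_n=True)
        m2 = mv.pca_covariance(raw_matrix(X), divisor_n=False)
        np.testing.assert_allclose(m1.components, m2.components, atol=1e-12)
        np.testing.assert_allclose(m2.eigenvalues * 14 / 15, m1.eigenvalues,
                                   rtol=1e-12)


class TestSupplementaryProjection:
    def test_training_rows_reproduce_scores(self):
        df = sample_feature_cohort(plan=[("P7", 20)], seed=2)
        m = mv.normalize_features(df)
        model = mv.pca_covariance(m)
        raw = df[list(SPONTANEOUS_FEATURES)]
        proj = mv.project_supplementary(model, raw)
        np.testing.assert_allclose(proj, model.scores, atol=1e-10)

    def test_training_mean_maps_to_origin(self):
        df = sample_feature_cohort(plan=[("P7", 20)], seed=2)
        m = mv.normalize_features(df)
        model = mv.pca_covariance(m)
        mean_row = df[list(SPONTANEOUS_FEATURES)].mean().to_frame().T
        proj = mv.project_supplementary(model, mean_row)
        np.testing.assert_allclose(proj, 0.0, atol=1e-10)

    def test_duplication_does_not_refit(self):
        df = sample_feature_cohort(plan=[("P7", 20)], seed=2)
        m = mv.normalize_features(df)
        model = mv.pca_covariance(m)
        extra = df[list(SPONTANEOUS_FEATURES)].iloc[:5]
        p1 = mv.project_supplementary(model, extra)
        p2 = mv.project_supplementary(model, pd.concat([extra, extra]))
        np.testing.assert_allclose(np.vstack([p1, p1]), p2, atol=1e-12)

    def test_missing_column_rejected(self):
        df = sample_feature_cohort(plan=[("P7", 10)], seed=2)
        m = mv.normalize_features(df)
        model = mv.pca_covariance(m)
        with pytest.raises(ValueError, match="lack"):
            mv.project_supplementary(model, df[["ahp"]])


class TestTrajectoryAndVariability:
    def make_traj(self):
        df = sample_feature_cohort(
            plan=[("P2-P3", 15), ("P7", 15), ("P21-P23", 15)], seed=4)
        m = mv.normalize_features(df)
        model = mv.pca_covariance(m)
        return mv.stage_trajectory(model.scores, df["stage"], df["age_days"])

    def test_order_and_columns(self):
        traj = self.make_traj()
        assert list(traj["stage"]) == ["P2-P3", "P7", "P21-P23"]
        assert np.all(np.diff(traj["mean_age"]) > 0)
        np.testing.assert_allclose(traj["sem_f1"],
                                   traj["sd_f1"] / np.sqrt(traj["n"]))

    def test_identical_neurons_zero_sd(self):
        scores = np.zeros((10, 2))
        traj = mv.stage_trajectory(scores, pd.Series(["P5"] * 10),
                                   pd.Series([5] * 10))
        assert traj["sd_f1"].iloc[0] == 0.0

    def test_singleton_stage_warns(self):
        scores = np.zeros((3, 2))
        with pytest.warns(UserWarning, match="single"):
            traj = mv.stage_trajectory(scores,
                                       pd.Series(["P5", "P5", "P14"]),
                                       pd.Series([5, 5, 14]))
        assert np.isnan(traj.loc[traj.stage == "P14", "sd_f1"].iloc[0])

    @pytest.mark.parametrize("sds,area", [((1.0, 1.0), np.pi),
                                          ((2.0, 0.5), np.pi),
                                          ((2.0, 2.0), 4 * np.pi)])
    def test_ellipse_area(self, sds, area):
        traj = pd.DataFrame({"stage": ["s"], "mean_age": [5.0],
                             "sd_f1": [sds[0]], "sd_f2": [sds[1]]})
        ell = mv.variability_ellipse(traj)
        assert ell["area"].iloc[0] == pytest.approx(area)

    def test_sd_age_correlation_linear(self):
        traj = pd.DataFrame({"stage": list("abcde"),
                             "mean_age": [2, 5, 9, 14, 20],
                             "sd_f1": [10, 8.5, 6.5, 4, 1.0]})
        traj["sd_f1"] = 12 - 0.5 * traj["mean_age"]  # exactly linear
        res = mv.sd_age_correlation(traj)
        assert res.r == pytest.approx(-1.0)
        assert res.n == 5

    def test_zero_variance_undefined(self):
        traj = pd.DataFrame({"stage": list("abc"), "mean_age": [2, 5, 9],
                             "sd_f1": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            mv.sd_age_correlation(traj)

    def test_null_permutation_keeps_r_small(self):
        """Constant SDs plus tiny noise: |r| small and p large on average."""
        rng = np.random.default_rng(9)
        rs, ps = [], []
        for _ in range(200):
            traj = pd.DataFrame({
                "stage": [f"s{i}" for i in range(10)],
                "mean_age": np.arange(10, dtype=float),
                "sd_f1": 5.0 + rng.normal(0, 0.01, 10),
            })
            res = mv.sd_age_correlation(traj)
            rs.append(res.r)
            ps.append(res.p)
        assert abs(np.mean(rs)) < 0.15
        assert np.mean(np.asarray(ps) < 0.05) < 0.15


def test_classes_separate_in_pc_space():
    """AHC classes occupy distinct regions of the (F1, F2) plane: few points
    of one class fall inside the bounding box core of another."""
    df = sample_feature_cohort(
        plan=[("P2-P3", 30), ("P7", 30), ("P21-P23", 30)], seed=6)
    m = mv.normalize_features(df)
    cls = mv.auto_cut(mv.ahc_ward(m), m, k=3)
    model = mv.pca_covariance(m)
    S = model.scores[:, :2]
    centroids = {c: S[cls.labels == c].mean(axis=0) for c in set(cls.labels)}
    mis = 0
    for i, row in enumerate(S):
        own = cls.labels[i]
        d = {c: np.linalg.norm(row - v) for c, v in centroids.items()}
        if min(d, key=d.get) != own:
            mis += 1
    assert mis / len(S) < 0.15
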
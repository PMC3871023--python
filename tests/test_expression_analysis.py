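"""Reliability filtering, z-scoring, FOM model selection and k-means."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from regulome.expression_analysis import (
    cluster_profiles,
    figure_of_merit,
    kmeans_cluster,
    point_means,
    reliability_filter,
    zscore_profiles,
)
from regulome.genome_model import SAMPLING_POINTS
from regulome.synthetic_data import default_sample_sheet, \
    simulate_profile_groups


def npkm_frame(rows: dict) -> pd.DataFrame:
    """rows: feature -> list of 5 replicate triples."""
    sheet = default_sample_sheet()
    cols = [f"{r}-{p}" for p in SAMPLING_POINTS for r in ("L", "R", "M")]
    data = {fid: [v for triple in triples for v in triple]
            for fid, triples in rows.items()}
    return pd.DataFrame.from_dict(data, orient="index", columns=cols), sheet


class TestReliabilityFilter:
    def test_low_npkm_excluded_regardless(self):
        df, sheet = npkm_frame({"f": [(8, 8, 8)] * 5})
        assert reliability_filter(df, sheet) == []

    def test_tight_replicates_retained(self):
        # (100, 101, 99): closed-form t = mean/(sd/sqrt(3)) = 100/(1/sqrt(3))
        reps = (100.0, 101.0, 99.0)
        t = np.mean(reps) / (np.std(reps, ddof=1) / np.sqrt(3))
        p = 2 * stats.t.sf(t, df=2)
        assert p < 0.15  # the screen the filter applies
        df, sheet = npkm_frame({"f": [reps, reps, reps, (0, 0, 0), (0, 0, 0)]})
        assert reliability_filter(df, sheet) == ["f"]

    def test_wild_replicates_excluded(self):
        # (0, 0, 300): t = 100/(sqrt(30000)/sqrt(3)) = 1 -> p ~ 0.42
        reps = (0.0, 0.0, 300.0)
        t = np.mean(reps) / (np.std(reps, ddof=1) / np.sqrt(3))
        p = 2 * stats.t.sf(t, df=2)
        assert p > 0.15
        df, sheet = npkm_frame({"f": [reps] * 5})
        assert reliability_filter(df, sheet) == []

    def test_needs_min_points(self):
        good, bad = (100.0, 101.0, 99.0), (0.0, 0.0, 300.0)
        df, sheet = npkm_frame({"f": [good, good, bad, bad, bad]})
        assert reliability_filter(df, sheet, min_points=3) == []
        assert reliability_filter(df, sheet, min_points=2) == ["f"]

    def test_monotone_under_threshold_relaxation(self, rng):
        rows = {f"f{i}": [tuple(rng.gamma(2, 30, 3)) for _ in range(5)]
                for i in range(40)}
        df, sheet = npkm_frame(rows)
        base = set(reliability_filter(df, sheet, p_thresh=0.15,
                                      min_npkm=10.0))
        looser_p = set(reliability_filter(df, sheet, p_thresh=0.5,
                                          min_npkm=10.0))
        looser_npkm = set(reliability_filter(df, sheet, p_thresh=0.15,
                                             min_npkm=1.0))
        assert base <= looser_p
        assert base <= looser_npkm

    def test_welch_variant_runs(self):
        good = (100.0, 101.0, 99.0)
        df, sheet = npkm_frame({"f": [good, good, good,
                                      (10, 11, 9), (10, 11, 9)]})
        assert isinstance(reliability_filter(df, sheet, test="welch"), list)


class TestZscore:
    def test_standardizes_rows(self):
        df = pd.DataFrame([[1, 2, 3, 4, 5]], index=["f"],
                          columns=list(SAMPLING_POINTS))
        z = zscore_profiles(df)
        assert abs(z.loc["f"].mean()) < 1e-9
        assert abs(z.loc["f"].std(ddof=0) - 1) < 1e-9

    def test_constant_row_dropped(self):
        df = pd.DataFrame([[2, 2, 2, 2, 2], [1, 2, 3, 4, 5]],
                          index=["flat", "ok"],
                          columns=list(SAMPLING_POINTS))
        z = zscore_profiles(df)
        assert list(z.index) == ["ok"]

    def test_idempotent(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)),
                          columns=list(SAMPLING_POINTS))
        z1 = zscore_profiles(df)
        z2 = zscore_profiles(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy())

    def test_point_means(self):
        df, sheet = npkm_frame({"f": [(1, 2, 3)] * 5})
        means = point_means(df, sheet)
        assert (means.loc["f"] == 2.0).all()
        assert list(means.columns) == list(SAMPLING_POINTS)


class TestFigureOfMerit:
    def test_k1_equals_rms_from_global_mean(self):
        prof, _ = simulate_profile_groups(60, 3, 0.2, seed=2)
        fom = figure_of_merit(prof, [1], seed=0)
        X = prof.sort_index().to_numpy()
        n = len(X)
        expected = sum(
            np.sqrt(((X[:, c] - X[:, c].mean()) ** 2).mean())
            * np.sqrt(n / (n - 1))
            for c in range(X.shape[1]))
        assert fom.curve[1] == pytest.approx(expected)

    def test_selects_planted_group_count(self):
        prof, _ = simulate_profile_groups(150, 4, 0.3, seed=1)
        fom = figure_of_merit(prof, range(1, 9), seed=1)
        assert abs(fom.selected_k - 4) <= 1

    def test_nonincreasing_in_expectation_on_random_data(self):
        rng = np.random.default_rng(7)
        curves = []
        for rep in range(5):
            prof = pd.DataFrame(rng.normal(size=(60, 5)),
                                index=[f"f{i}" for i in range(60)],
                                columns=list(SAMPLING_POINTS))
            fom = figure_of_merit(prof, range(1, 7), seed=rep)
            curves.append([fom.curve[k] for k in range(1, 7)])
        mean_curve = np.mean(curves, axis=0)
        assert all(b <= a * 1.02 for a, b in zip(mean_curve, mean_curve[1:]))

    def test_k_range_exceeding_features_raises(self):
        prof, _ = simulate_profile_groups(10, 2, 0.1, seed=0)
        with pytest.raises(ValueError):
            figure_of_merit(prof, range(1, 12), seed=0)


class TestKmeans:
    def test_duplicated_profiles_separate_perfectly(self):
        base = np.array([[0, 1, 2, 1, 0], [2, 1, 0, 1, 2], [1, 1, 0, 0, 1.0]])
        X = np.vstack([base, base])
        prof = pd.DataFrame(X, index=[f"f{i}" for i in range(6)],
                            columns=list(SAMPLING_POINTS))
        res = kmeans_cluster(prof, 3, seed=0)
        assert res.inertia == pytest.approx(0.0)
        assert res.labels["f0"] == res.labels["f3"]
        assert len(set(res.labels)) == 3

    def test_same_seed_identical_labels(self):
        prof, _ = simulate_profile_groups(80, 4, 0.3, seed=4)
        a = kmeans_cluster(prof, 4, seed=11)
        b = kmeans_cluster(prof, 4, seed=11)
        assert (a.labels == b.labels).all()

    def test_row_order_invariance(self):
        prof, _ = simulate_profile_groups(80, 4, 0.3, seed=4)
        shuffled = prof.sample(frac=1.0, random_state=0)
        a = kmeans_cluster(prof, 4, seed=11)
        b = kmeans_cluster(shuffled, 4, seed=11)
        assert (a.labels.sort_index() == b.labels.sort_index()).all()

    def test_labels_in_one_to_k(self):
        prof, _ = simulate_profile_groups(50, 3, 0.3, seed=2)
        res = kmeans_cluster(prof, 5, seed=0)
        assert set(res.labels) <= set(range(1, 6))

    def test_k_exceeding_features_raises(self):
        prof, _ = simulate_profile_groups(10, 2, 0.1, seed=0)
        with pytest.raises(ValueError):
            kmeans_cluster(prof, 11, seed=0)


class TestPlantedGroupRecovery:
    def test_fom_plus_kmeans_agreement(self):
        prof, labels = simulate_profile_groups(200, 4, 0.3, seed=1)
        res = cluster_profiles(prof, seed=1, k_range=range(1, 9))
        ari = adjusted_rand_score(
            labels, res.labels.loc[sorted(prof.index)].to_numpy())
        assert abs(res.k - 4) <= 1
        assert ari >= 0.9
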
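"""PAM clustering, silhouette-based k selection, severity trajectories and
cluster progression odds ratios."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from lipidcascade.cluster_traj import (choose_k, cluster_progression_or,
                                       fit_trajectories, pam_cluster)
from lipidcascade.cohort import Stage, Subject


def brute_force_medoids(X, k):
    D = cdist(X, X)
    best = min(combinations(range(len(X)), k),
               key=lambda m: D[:, m].min(axis=1).sum())
    return sorted(best), D[:, best].min(axis=1).sum()


class TestPAM:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_search_on_seven_points(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((7, 2)) * 2
        a = pam_cluster(X, 2)
        medoids, obj = brute_force_medoids(X, 2)
        assert a.objective == pytest.approx(obj)
        assert sorted(a.medoids) == medoids

    def test_k_equals_n_zero_objective(self, rng):
        X = rng.standard_normal((6, 3))
        a = pam_cluster(X, 6)
        assert a.objective == 0.0
        assert sorted(a.medoids) == list(range(6))

    def test_separated_blobs_recovered(self, rng):
        truth = np.repeat([0, 1], 60)
        X = rng.standard_normal((120, 3))
        X[truth == 1] += 6.0
        a = pam_cluster(X, 2)
        assert adjusted_rand_score(truth, a.labels.to_numpy()) >= 0.99
        # unit-variance blobs 6 sigma apart: mean silhouette at least 0.8
        # (population value 1 - (2/sqrt(pi))/6 ~ 0.81; n large enough that
        # sampling noise stays below the margin)
        truth1 = np.repeat([0, 1], 300)
        X1 = rng.standard_normal((600, 1))
        X1[truth1 == 1] += 6.0
        assert pam_cluster(X1, 2).silhouette.mean() >= 0.8

    def test_labels_contiguous_medoids_members(self, rng):
        X = rng.standard_normal((30, 2))
        a = pam_cluster(X, 4)
        assert sorted(a.labels.unique()) == [1, 2, 3, 4]
        for lab, m in enumerate(a.medoids, start=1):
            assert a.labels[m] == lab

    def test_objective_locally_optimal_under_single_swaps(self, rng):
        X = rng.standard_normal((25, 2))
        a = pam_cluster(X, 3)
        D = cdist(X, X)
        idx = [list(a.labels.index).index(m) for m in a.medoids]
        for mi in range(3):
            for h in range(25):
                if h in idx:
                    continue
                cand = idx.copy()
                cand[mi] = h
                assert D[:, cand].min(axis=1).sum() >= a.objective - 1e-9

    def test_invalid_k_rejected(self, rng):
        with pytest.raises(ValueError):
            pam_cluster(rng.standard_normal((5, 2)), 7)


class TestChooseK:
    def test_three_blobs_give_k_three(self, rng):
        X = np.vstack([rng.standard_normal((50, 3)) + off
                       for off in (0.0, 8.0, -8.0)])
        k, means = choose_k(X, range(2, 7))
        assert k == 3
        assert means.between(-1, 1).all()

    def test_silhouette_bounds(self, rng):
        X = rng.standard_normal((40, 2))
        a = pam_cluster(X, 3)
        assert a.silhouette.between(-1, 1).all()

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_k(rng.standard_normal((10, 2)), range(12, 15))


def _subject(sid, base, visits):
    return Subject(id=sid, age=55, sex=0, hp=0, baseline_stage=Stage(base),
                   cohort="validation", visits=visits)


class TestTrajectories:
    def test_constant_severity_flat_curve(self):
        subs, labels = [], {}
        for i in range(12):
            days = [0, 200 + 10 * i, 500 + 10 * i]
            subs.append(_subject(f"S{i}", 3, [(d, Stage(3)) for d in days]))
            labels[f"S{i}"] = 1
        tf = fit_trajectories(subs, pd.Series(labels))
        assert np.allclose(tf.curves["fit"], 3.0, atol=1e-8)
        drift = tf.per_cluster_drift.iloc[0]
        assert abs(drift["drift"]) < 1e-8

    def test_linear_drift_recovered(self, rng):
        # one cluster drifts ~1 severity level per year, the other is flat
        subs, labels = [], {}
        for i in range(40):
            sid = f"S{i}"
            cl = 1 + (i % 2)
            t_end = int(rng.integers(600, 800))
            base = int(rng.integers(1, 3))
            if cl == 2:
                mid = min(6, base + round((t_end / 2) / 365))
                end = min(6, base + round(t_end / 365))
            else:
                mid = end = base
            subs.append(_subject(sid, base, [(0, Stage(base)),
                                             (t_end // 2, Stage(mid)),
                                             (t_end, Stage(end))]))
            labels[sid] = cl
        tf = fit_trajectories(subs, pd.Series(labels))
        d = tf.per_cluster_drift.set_index("cluster")
        span_years = (tf.curves[tf.curves.cluster == 2]["day"].max()
                      - tf.curves[tf.curves.cluster == 2]["day"].min()) / 365.0
        assert abs(d.loc[2, "drift"] - span_years) < 2 * max(d.loc[2, "drift_se"], 0.3)
        assert abs(d.loc[1, "drift"]) < 2 * max(d.loc[1, "drift_se"], 0.3)

    def test_fitted_values_clipped_to_stage_range(self, rng):
        subs, labels = [], {}
        for i in range(15):
            t = int(rng.integers(300, 900))
            subs.append(_subject(f"S{i}", 5, [(0, Stage(5)), (t // 2, Stage(6)),
                                              (t, Stage(6))]))
            labels[f"S{i}"] = 1
        tf = fit_trajectories(subs, pd.Series(labels))
        assert tf.curves["fit"].between(1, 6).all()

    def test_sparse_cluster_falls_back_to_flat_mean(self):
        subs = [_subject("A", 2, [(0, Stage(2)), (300, Stage(3))])]
        with pytest.warns(UserWarning, match="flat mean"):
            tf = fit_trajectories(subs, pd.Series({"A": 1}))
        assert 1 in tf.flat_clusters

    def test_plot_written_as_svg(self, tmp_path, rng):
        from lipidcascade.cluster_traj import plot_trajectories
        subs, labels = [], {}
        for i in range(12):
            days = [0, 200 + 10 * i, 500 + 10 * i]
            sev = 2 + (i % 2)
            subs.append(_subject(f"S{i}", sev, [(d, Stage(sev)) for d in days]))
            labels[f"S{i}"] = 1 + i % 2
        tf = fit_trajectories(subs, pd.Series(labels))
        out = tmp_path / "traj.svg"
        plot_trajectories(tf, out)
        assert out.stat().st_size > 0
        assert b"<svg" in out.read_bytes()[:500]


class TestClusterORs:
    def test_equal_rates_give_null_ors(self, rng):
        n = 3000
        labels = pd.Series(rng.integers(1, 4, n),
                           index=[f"S{i}" for i in range(n)])
        y = pd.Series(rng.random(n) < 0.2, index=labels.index).astype(int)
        ors = cluster_progression_or(labels, y)
        assert ors.iloc[0]["OR"] == 1.0
        assert ((ors.iloc[1:]["ci_low"] < 1) & (1 < ors.iloc[1:]["ci_high"])).all()
        assert ors.attrs["lr_p"] > 0.01
        assert ors.attrs["anova_p"] > 0.01

    def test_planted_rates_recovered(self, rng):
        n = 5000
        rates = {1: 0.05, 2: 0.2, 3: 0.6}
        labels = pd.Series(rng.integers(1, 4, n),
                           index=[f"S{i}" for i in range(n)])
        y = pd.Series([int(rng.random() < rates[l]) for l in labels],
                      index=labels.index)
        ors = cluster_progression_or(labels, y)
        for k in (2, 3):
            planted = (np.log(rates[k] / (1 - rates[k]))
                       - np.log(rates[1] / (1 - rates[1])))
            row = ors[ors.cluster == k].iloc[0]
            se = (np.log(row["ci_high"]) - np.log(row["OR"])) / 1.96
            assert abs(np.log(row["OR"]) - planted) < 2 * se

    def test_label_permutation_leaves_ors_invariant(self, rng):
        n = 800
        labels = pd.Series(rng.integers(1, 4, n),
                           index=[f"S{i}" for i in range(n)])
        y = pd.Series((rng.random(n) < 0.1 * labels.to_numpy()).astype(int),
                      index=labels.index)
        ors1 = cluster_progression_or(labels, y)
        swapped = labels.map({1: 1, 2: 3, 3: 2})  # keep the reference cluster
        ors2 = cluster_progression_or(swapped, y)
        a = ors1.set_index("cluster").loc[[2, 3], "OR"]
        b = ors2.set_index("cluster").loc[[3, 2], "OR"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-8)

    def test_zero_progression_cluster_uses_firth(self, rng):
        labels = pd.Series([1] * 40 + [2] * 40,
                           index=[f"S{i}" for i in range(80)])
        y = pd.Series([0] * 40 + [1] * 12 + [0] * 28, index=labels.index)
        ors = cluster_progression_or(labels, y)
        assert (ors.iloc[1:]["method"] == "firth").all()
        assert np.isfinite(ors.iloc[1]["OR"])
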
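"""Offline analysis: segmentation, embeddings, clustering, cohort stats."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sonoreach import analysis
from sonoreach.analysis import (
    ReachSegment,
    align_and_resample,
    cohens_d,
    choose_n_components,
    detect_reaches,
    gmm_cluster,
    group_stats,
    pca_embed,
    reach_ratio,
    tsne_embed,
)
from sonoreach.simulate import (
    CohortDesign,
    LearningParams,
    simulate_reach,
    simulate_session,
    synthetic_ratio_table,
)


def planted_trajectories(rng, apex_means=(8.0, 16.0), n_each=40, noise=0.3):
    segs, labels = [], []
    for lab, mean in enumerate(apex_means):
        for _ in range(n_each):
            apex = max(rng.normal(mean, 1.0), 3.0)
            segs.append(ReachSegment(0.0, 1.0, apex, simulate_reach(apex, 0.8, 70.0, rng, noise)))
            labels.append(lab)
    return segs, np.array(labels)


class TestDetectReaches:
    def test_single_ramp(self):
        d = np.concatenate([np.zeros(5), simulate_reach(20.0, 0.5, 70.0), np.zeros(5)])
        t = np.arange(d.size) / 70.0
        segs = detect_reaches(t, d)
        assert len(segs) == 1
        assert segs[0].apex == pytest.approx(20.0)
        assert segs[0].onset < segs[0].offset

    def test_flat_signal_no_segments(self):
        assert detect_reaches(np.arange(100) / 70, np.zeros(100)) == []
        assert detect_reaches([], []) == []

    def test_matches_planted_ground_truth(self):
        params = LearningParams(noise_sd=0.0)
        stream, truth = simulate_session(
            "f0", 3, "feedback", params, CohortDesign(session_length=120.0), seed=6
        )
        # extract the exact left displacement the simulator planted
        from sonoreach.pose import Calibration

        cal = Calibration()
        left_cols = [j for j, n in enumerate(stream.bodyparts) if n.startswith("left")]
        disp = (cal.rest_y_left - stream.y[:, left_cols].mean(axis=1)) * cal.mm_per_pixel
        segs = detect_reaches(stream.timestamps, disp)
        assert len(segs) == truth.left_count
        planted = sorted(r.apex for r in truth.by_paw("left"))
        np.testing.assert_allclose(sorted(s.apex for s in segs), planted, atol=1e-9)


class TestAlignAndResample:
    def test_identity_when_already_target_length(self):
        seg = ReachSegment(0.0, 1.0, 5.0, np.linspace(0, 5, 50))
        tm = align_and_resample([seg], T=50)
        np.testing.assert_allclose(tm.matrix[0], seg.samples, atol=1e-12)

    def test_endpoints_preserved_and_triangle_max(self):
        tri = np.concatenate([np.linspace(0, 10, 11), np.linspace(10, 0, 11)[1:]])
        seg = ReachSegment(0.0, 1.0, 10.0, tri)
        for T in (7, 33, 200):
            row = align_and_resample([seg], T=T).matrix[0]
            assert row[0] == tri[0] and row[-1] == tri[-1]
            # max preserved to within one-sample slope of the original
            assert abs(row.max() - 10.0) <= 1.0 + 1e-12

    def test_empty_and_degenerate_segments(self):
        tm = align_and_resample([], T=10)
        assert tm.matrix.shape == (0, 10)
        short = ReachSegment(0.0, 0.0, 1.0, np.array([1.0]))
        tm = align_and_resample([short], T=10)
        assert tm.matrix.shape == (0, 10) and tm.n_excluded == 1


class TestPCA:
    def test_rank_one_matrix_one_component(self):
        rng = np.random.default_rng(1)
        template = simulate_reach(1.0, 0.8, 70.0)
        X = np.outer(rng.uniform(5, 20, 60), template)
        res = pca_embed(X, 2)
        assert res.variance_explained[0] >= 0.999
        assert choose_n_components(X) == 1

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 8))
        res = pca_embed(X, 8)
        recon = res.scores @ res.loadings + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_duplicate_rows_identical_scores(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))
        X = np.vstack([X, X[0]])
        res = pca_embed(X, 3)
        np.testing.assert_allclose(res.scores[0], res.scores[-1], atol=1e-10)

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(np.zeros((5, 4)), 6)


class TestTSNE:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 5))
        a = tsne_embed(X, perplexity=10, seed=7)
        b = tsne_embed(X, perplexity=10, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(12, 1, (40, 5))])
        emb = tsne_embed(X, perplexity=10, seed=0)
        a, b = emb[:40], emb[40:]
        within = np.mean([np.linalg.norm(a - a.mean(0), axis=1).mean(),
                          np.linalg.norm(b - b.mean(0), axis=1).mean()])
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        assert between > within

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tsne_embed(np.zeros((2, 3)), perplexity=5)


class TestGMMCluster:
    def test_two_planted_clusters_recovered(self):
        rng = np.random.default_rng(0)
        segs, labels = planted_trajectories(rng)
        tm = align_and_resample(segs, T=100)
        feats = pca_embed(tm.matrix, choose_n_components(tm.matrix)).scores
        res = gmm_cluster(feats, range(1, 5), seed=0)
        assert res.k == 2
        agree = max(np.mean(res.labels == labels), np.mean(res.labels != labels))
        assert agree >= 0.95

    def test_single_gaussian_selects_k1(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 2))
        assert gmm_cluster(X, range(1, 5), seed=1).k == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 3))
        a = gmm_cluster(X, range(1, 4), seed=2)
        b = gmm_cluster(X, range(1, 4), seed=2)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.bic == b.bic

    def test_bic_never_wildly_overclusters_separated_mixtures(self):
        # well-separated (8 SD) planted two-component Gaussian mixtures:
        # selected K never exceeds planted K + 1 across 100 seeded trials
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = np.vstack(
                [rng.normal((0, 0), 1, (150, 2)), rng.normal((8, 0), 1, (150, 2))]
            )
            assert gmm_cluster(X, range(1, 7), seed=seed).k <= 3

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            gmm_cluster(np.zeros((3, 2)), range(1, 6))


class TestReachRatio:
    @staticmethod
    def counts(rows):
        return pd.DataFrame(rows, columns=["mouse", "group", "day", "left_reaches", "right_reaches"])

    def test_identical_counts_normalize_to_one(self):
        df = self.counts([("m0", "feedback", d, 12, 6) for d in (1, 2, 3)])
        res = reach_ratio(df)
        assert (res.table["normalized"] == 1.0).all()

    def test_doubling_left_counts(self):
        df = self.counts([("m0", "feedback", d, 5 * 2 ** (d - 1), 5) for d in (1, 2, 3, 4)])
        res = reach_ratio(df)
        np.testing.assert_allclose(res.table["normalized"], [1, 2, 4, 8])

    def test_zero_denominator_mouse_excluded_with_report(self):
        df = self.counts(
            [("m0", "feedback", 1, 5, 5), ("m0", "feedback", 2, 5, 0),
             ("m1", "feedback", 1, 4, 2), ("m1", "feedback", 2, 6, 2)]
        )
        res = reach_ratio(df)
        assert res.excluded == ["m0"]
        assert set(res.table["mouse"]) == {"m1"}

    def test_invariant_under_uniform_subsampling(self):
        # halving every count leaves all normalized ratios unchanged
        rng = np.random.default_rng(8)
        rows = [
            (f"m{m}", "feedback", d, int(rng.integers(4, 40)) * 2, int(rng.integers(2, 20)) * 2)
            for m in range(4) for d in (1, 2, 3)
        ]
        full = reach_ratio(self.counts(rows)).table
        half = reach_ratio(
            self.counts([(m, g, d, l // 2, r // 2) for m, g, d, l, r in rows])
        ).table
        np.testing.assert_allclose(full["normalized"], half["normalized"])


class TestGroupStats:
    def test_identical_groups_give_d_zero_and_p_one_on_anchor(self):
        df = synthetic_ratio_table(seed=1)
        # make groups exactly identical
        fb = df[df.group == "feedback"].copy()
        ctrl = fb.copy()
        ctrl["group"] = "control"
        ctrl["mouse"] = ctrl["mouse"].str.replace("f", "c")
        res = group_stats(pd.concat([fb, ctrl], ignore_index=True))
        day1 = res.per_day[res.per_day.day == 1].iloc[0]
        assert day1.p == 1.0 and day1.cohens_d == 0.0
        assert (res.per_day["cohens_d"] == 0.0).all()

    def test_planted_effect_detected_with_correct_d(self):
        rng = np.random.default_rng(9)
        ds, rejections = [], 0
        n_sims = 100
        for _ in range(n_sims):
            df = synthetic_ratio_table(effect_size_d=2.0, seed=rng.integers(2**31))
            res = group_stats(df)
            row = res.per_day[res.per_day.day == 4].iloc[0]
            ds.append(row.cohens_d)
            rejections += row.p < 0.05
        # groups are ordered alphabetically (control - feedback), so the
        # planted +2 SD feedback advantage appears as d = -2
        assert np.mean(ds) == pytest.approx(-2.0, abs=0.35)
        assert rejections / n_sims >= 0.8

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(10)
        rej = 0
        n_sims = 200
        for _ in range(n_sims):
            df = synthetic_ratio_table(effect_size_d=0.0, seed=rng.integers(2**31))
            res = group_stats(df)
            rej += res.per_day[res.per_day.day == 4].iloc[0].p < 0.05
        assert 0.02 <= rej / n_sims <= 0.09

    def test_anova_reports_group_day_interaction(self):
        df = synthetic_ratio_table(effect_size_d=2.0, seed=11)
        res = group_stats(df)
        sources = set(res.anova["Source"].str.lower())
        assert {"group", "day", "interaction"} <= sources
        assert 0 <= res.anova_p("group") <= 1
        assert (res.anova["F"].dropna() >= 0).all()

    def test_small_groups_rejected(self):
        df = synthetic_ratio_table(n_per_group=1, seed=0)
        with pytest.raises(ValueError):
            group_stats(df)

    def test_cohens_d_hand_computed(self):
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([1.0, 3.0, 5.0])
        assert cohens_d(a, b) == pytest.approx(0.5)  # diff 1, pooled sd 2
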
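import numpy as np
import pandas as pd
import pytest

from nucfuse.agreement import (
    bootstrap_ci,
    classification_metrics,
    cohen_kappa,
    compare_groups,
    detection_prf,
    fleiss_band,
    krippendorff_alpha,
    mds_embed,
    pairwise_iou_cross,
    pairwise_kappa_matrix,
)

from _oracles import optimal_match_count


class TestKrippendorffAlpha:
    def test_perfect_agreement(self):
        mat = pd.DataFrame({"r0": list("AABB"), "r1": list("AABB"), "r2": list("AABB")})
        assert krippendorff_alpha(mat) == pytest.approx(1.0)

    def test_hand_computed_coincidence_example(self):
        # 2 raters, 4 items: (A,A),(A,B),(B,A),(B,B)
        # coincidence matrix [[2,2],[2,2]], D_o = 4, D_e = (64-32)/7 = 32/7
        # alpha = 1 - 4/(32/7) = 0.125
        mat = pd.DataFrame({"r0": list("AABB"), "r1": list("ABAB")})
        assert krippendorff_alpha(mat) == pytest.approx(0.125, abs=1e-12)

    def test_chance_level_near_zero(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.choice(list("ABC"), size=(1000, 4)))
        assert abs(krippendorff_alpha(mat)) < 0.05

    def test_missing_values_tolerated(self):
        mat = pd.DataFrame({
            "r0": ["A", "A", np.nan, "B"],
            "r1": ["A", np.nan, "B", "B"],
            "r2": [np.nan, "A", "B", "B"],
        })
        assert krippendorff_alpha(mat) == pytest.approx(1.0)

    def test_all_single_labeled_raises(self):
        mat = pd.DataFrame({"r0": ["A", "B"], "r1": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="undefined"):
            krippendorff_alpha(mat)

    def test_invariant_under_label_renaming(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.choice(list("ABCD"), size=(50, 5)))
        base = krippendorff_alpha(mat)
        for seed in range(10):
            perm_rng = np.random.default_rng(seed)
            perm = dict(zip("ABCD", perm_rng.permutation(list("WXYZ"))))
            renamed = mat.map(perm.get)
            assert krippendorff_alpha(renamed) == pytest.approx(base, abs=1e-12)


class TestCohenKappa:
    def test_identical_sequences(self):
        assert cohen_kappa(list("ABCABC"), list("ABCABC")) == 1.0

    def test_contingency_worked_example(self):
        # [[20,5],[10,15]]: p_o=0.7, p_e=0.5 -> kappa=0.4
        a = ["A"] * 25 + ["B"] * 25
        b = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 15
        assert cohen_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(2)
        a = rng.choice(list("ABC"), 200)
        b = rng.choice(list("ABC"), 200)
        assert cohen_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_chance_level_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.choice(list("AB"), 10_000)
        b = rng.choice(list("AB"), 10_000)
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_missing_pairs_dropped(self):
        a = ["A", "B", np.nan, "A"]
        b = ["A", "B", "A", np.nan]
        assert cohen_kappa(a, b) == 1.0

    def test_both_constant_same_label(self):
        assert cohen_kappa(["A"] * 5, ["A"] * 5) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            cohen_kappa(["A"], ["A", "B"])


class TestFleissBands:
    @pytest.mark.parametrize("value,band", [
        (0.85, "near-perfect"), (0.7, "substantial"), (0.5, "moderate"),
        (0.3, "fair"), (0.05, "slight"), (0.0, "poor/chance"), (-0.2, "poor/chance"),
        (0.2, "slight"), (0.8, "substantial"), (1.0, "near-perfect"),
    ])
    def test_cut_points(self, value, band):
        assert fleiss_band(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fleiss_band(1.2)


class TestDetectionPrf:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "fov_id",
                                           "xmin", "ymin", "xmax", "ymax"])

    def test_identical_boxes_perfect_scores(self):
        anchors = self._frame([("x", "f1", 0, 0, 10, 10), ("x", "f1", 20, 20, 30, 30)])
        part = anchors.assign(participant_id="p1")
        out = detection_prf(part, anchors.drop(columns="participant_id"))
        assert out.loc["p1", "precision"] == 1.0
        assert out.loc["p1", "recall"] == 1.0

    def test_half_annotated_recall(self):
        anchors = self._frame([
            ("x", "f1", 0, 0, 10, 10), ("x", "f1", 20, 20, 30, 30),
            ("x", "f1", 40, 40, 50, 50), ("x", "f1", 60, 60, 70, 70),
        ]).drop(columns="participant_id")
        part = self._frame([("p1", "f1", 0, 0, 10, 10), ("p1", "f1", 20, 20, 30, 30)])
        out = detection_prf(part, anchors)
        assert out.loc["p1", "precision"] == 1.0
        assert out.loc["p1", "recall"] == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_matches_optimal_on_random_scenes(self, seed):
        rng = np.random.default_rng(seed)
        pb = np.column_stack([rng.uniform(0, 80, 20), rng.uniform(0, 80, 20)])
        pb = np.hstack([pb, pb + rng.uniform(8, 20, (20, 2))])
        ab = np.column_stack([rng.uniform(0, 80, 15), rng.uniform(0, 80, 15)])
        ab = np.hstack([ab, ab + rng.uniform(8, 20, (15, 2))])
        sims = pairwise_iou_cross(pb, ab)
        from nucfuse.agreement import _greedy_match_count
        greedy = _greedy_match_count(sims, 0.5)
        assert greedy == optimal_match_count(sims, 0.5)

    def test_recall_monotone_in_match_iou(self):
        rng = np.random.default_rng(9)
        base = np.column_stack([rng.uniform(0, 80, 12), rng.uniform(0, 80, 12)])
        anchors = pd.DataFrame(
            np.hstack([base, base + 15]), columns=["xmin", "ymin", "xmax", "ymax"]
        ).assign(fov_id="f1")
        jit = np.hstack([base + rng.normal(0, 2, base.shape),
                         base + 15 + rng.normal(0, 2, base.shape)])
        part = pd.DataFrame(jit, columns=["xmin", "ymin", "xmax", "ymax"]).assign(
            fov_id="f1", participant_id="p1"
        )
        recalls = [
            detection_prf(part, anchors, match_iou=t).loc["p1", "recall"]
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        assert recalls == sorted(recalls, reverse=True)

    def test_participant_without_anchor_fovs_reported_missing(self):
        anchors = pd.DataFrame(
            [["f2", 0, 0, 10, 10]], columns=["fov_id", "xmin", "ymin", "xmax", "ymax"]
        )
        part = self._frame([("p1", "f1", 0, 0, 10, 10)])
        out = detection_prf(part, anchors)
        assert np.isnan(out.loc["p1", "recall"])


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        ref = ["a", "b", "c"] * 10
        post = pd.get_dummies(pd.Series(ref)).astype(float)
        out = classification_metrics(ref, posteriors=post)
        assert out["mcc"] == pytest.approx(1.0)
        assert out["auroc_micro"] == pytest.approx(1.0)
        assert out["auroc_macro"] == pytest.approx(1.0)

    def test_chance_posteriors_auroc_half(self):
        rng = np.random.default_rng(4)
        ref = list(rng.choice(["a", "b", "c"], 2000))
        post = pd.DataFrame(rng.dirichlet(np.ones(3), 2000), columns=["a", "b", "c"])
        out = classification_metrics(ref, posteriors=post)
        assert out["auroc_micro"] == pytest.approx(0.5, abs=0.03)
        assert out["auroc_macro"] == pytest.approx(0.5, abs=0.03)

    def test_mcc_matches_covariance_formula(self):
        rng = np.random.default_rng(5)
        ref = list(rng.choice(["a", "b", "c"], 30))
        pred = list(rng.choice(["a", "b", "c"], 30))
        out = classification_metrics(ref, predicted=pred)
        # direct multiclass covariance formula
        cats = sorted(set(ref) | set(pred))
        C = np.zeros((len(cats), len(cats)))
        for r, p in zip(ref, pred):
            C[cats.index(r), cats.index(p)] += 1
        t = C.sum(axis=1); s = C.sum(axis=0); n = C.sum()
        num = C.trace() * n - t @ s
        den = np.sqrt(n**2 - s @ s) * np.sqrt(n**2 - t @ t)
        assert out["mcc"] == pytest.approx(num / den, abs=1e-12)

    def test_micro_exceeds_macro_when_errors_hit_rare_class(self):
        # rare class "b" is indistinguishable from common class "a"; the
        # abundant easy decisions dominate the pooled (micro) average
        ref = ["a"] * 450 + ["b"] * 50 + ["c"] * 450
        post = pd.DataFrame(
            [[0.9, 0.1, 0.0]] * 500 + [[0.0, 0.0, 1.0]] * 450,
            columns=["a", "b", "c"],
        )
        out = classification_metrics(ref, posteriors=post)
        assert out["auroc_micro"] > out["auroc_macro"]

    def test_absent_class_excluded_with_warning(self):
        ref = ["a", "b"] * 10
        post = pd.DataFrame(
            np.tile([0.5, 0.4, 0.1], (20, 1)), columns=["a", "b", "c"]
        )
        with pytest.warns(UserWarning, match="absent"):
            classification_metrics(ref, posteriors=post)


class TestBootstrapAndTests:
    def test_constant_data_zero_width(self):
        lo, hi = bootstrap_ci(np.mean, np.full(30, 2.5), seed=0)
        assert lo == hi == 2.5

    def test_seed_determinism(self):
        data = np.random.default_rng(0).normal(size=50)
        assert bootstrap_ci(np.mean, data, seed=42) == bootstrap_ci(np.mean, data, seed=42)

    def test_degenerate_data_raises(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, [1.0])

    def test_coverage_of_normal_mean(self):
        rng = np.random.default_rng(7)
        hits = 0
        reps = 200
        for i in range(reps):
            data = rng.normal(size=100)
            lo, hi = bootstrap_ci(np.mean, data, n_trials=300, seed=i)
            hits += lo <= 0.0 <= hi
        assert 0.88 <= hits / reps <= 0.99

    def test_identical_groups_p_near_one(self):
        x = np.arange(10.0)
        stat, p = compare_groups(x, x.copy(), paired=False)
        assert p > 0.9

    def test_disjoint_support_extreme_u(self):
        x = np.arange(10.0)
        y = x + 100
        stat, p = compare_groups(x, y, paired=False)
        assert stat == 0.0 or stat == 100.0  # U for one side
        assert p < 1e-3

    def test_wilcoxon_all_ties_raises(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="Wilcoxon"):
            compare_groups(x, x.copy(), paired=True)

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            ps.append(compare_groups(x, y)[1])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestMds:
    def test_equal_kappas_give_equilateral_triangle(self):
        K = pd.DataFrame(np.full((3, 3), 0.5) + np.eye(3) * 0.5)
        coords, _ = mds_embed(K)
        d = [np.linalg.norm(coords[i] - coords[j])
             for i in range(3) for j in range(i + 1, 3)]
        assert max(d) - min(d) < 1e-6

    def test_block_structure_separates(self):
        K = np.full((6, 6), 0.1)
        K[:3, :3] = 0.9
        K[3:, 3:] = 0.9
        np.fill_diagonal(K, 1.0)
        coords, _ = mds_embed(K)
        within = np.linalg.norm(coords[0] - coords[1])
        between = np.linalg.norm(coords[0] - coords[4])
        assert between > within

    def test_perfect_agreement_collapses(self):
        coords, stress = mds_embed(np.ones((4, 4)))
        assert np.allclose(coords, coords[0], atol=1e-9)

    def test_matches_skbio_pcoa(self):
        from skbio.stats.ordination import pcoa
        rng = np.random.default_rng(10)
        K = rng.uniform(0, 1, (7, 7))
        K = (K + K.T) / 2
        np.fill_diagonal(K, 1.0)
        coords, _ = mds_embed(K)
        D = 1.0 - K
        np.fill_diagonal(D, 0.0)
        ref = pcoa(D, number_of_dimensions=2).samples.to_numpy()
        # same up to per-axis sign
        for k in range(2):
            assert (np.allclose(coords[:, k], ref[:, k], atol=1e-6)
                    or np.allclose(coords[:, k], -ref[:, k], atol=1e-6))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(np.array([[1.0, 0.2], [0.4, 1.0]]))


class TestPairwiseKappaMatrix:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(11)
        mat = pd.DataFrame(rng.choice(list("AB"), (40, 4)),
                           columns=list("wxyz"))
        K = pairwise_kappa_matrix(mat)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
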
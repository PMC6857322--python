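"""Group-inference stack: GLM contrasts, thresholds, partial correlations,
logistic discrimination and ROC/Youden."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oscnet.inference import (
    GroupDesign,
    glm_contrast,
    logistic_discriminate,
    logistic_probability,
    nodal_contrast_table,
    partial_correlation,
    roc_youden,
    significance_threshold,
)


class TestSignificanceThreshold:
    def test_single_contrast_prints_009(self):
        thr = significance_threshold(112, 1)
        assert f"{thr:.3f}" == "0.009"
        assert thr == pytest.approx(1 / 112)

    def test_three_contrasts_bonferroni(self):
        assert significance_threshold(112, 3) == pytest.approx(1 / 112 / 3)

    def test_capped_at_one(self):
        assert significance_threshold(1, 1) == 1.0

    def test_zero_arguments_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(0, 1)
        with pytest.raises(ValueError):
            significance_threshold(112, 0)


class TestGlmContrast:
    def test_no_covariates_equals_pooled_t_test(self, rng):
        a = rng.standard_normal(20) + 0.4
        b = rng.standard_normal(25)
        design = GroupDesign(
            response=np.concatenate([a, b]),
            group=np.array(["MPD"] * 20 + ["NC"] * 25),
            contrast=("MPD", "NC"),
        )
        res = glm_contrast(design)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t_value == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_response_absorbed_by_balanced_covariate(self, rng):
        """With identical age blocks in both groups and response equal to
        age, the group effect is fully absorbed: its coefficient is zero
        (the t ratio itself is 0/0 in exact arithmetic)."""
        age = np.concatenate([rng.normal(60, 5, 30)] * 2)
        design = GroupDesign(
            response=age,
            group=np.array(["MPD"] * 30 + ["NC"] * 30),
            covariates=pd.DataFrame({"age": age}),
            contrast=("MPD", "NC"),
        )
        res = glm_contrast(design)
        assert abs(res.estimate) < 1e-8

    def test_orthogonal_covariate_changes_t_only_by_dof(self, rng):
        """A covariate orthogonal to both group and response leaves the
        coefficient and residual sum unchanged, so t scales exactly by the
        sqrt ratio of residual degrees of freedom."""
        n = 30
        y = np.concatenate([rng.standard_normal(15) + 1.0, rng.standard_normal(15)])
        group = np.array(["MPD"] * 15 + ["NC"] * 15)
        base = glm_contrast(GroupDesign(response=y, group=group, contrast=("MPD", "NC")))
        c = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), (group == "MPD").astype(float), y])
        c = c - X @ np.linalg.lstsq(X, c, rcond=None)[0]
        adj = glm_contrast(
            GroupDesign(response=y, group=group, covariates=pd.DataFrame({"c": c}),
                        contrast=("MPD", "NC"))
        )
        assert adj.estimate == pytest.approx(base.estimate, abs=1e-10)
        expected_t = base.t_value * np.sqrt((n - 3) / (n - 2))
        assert adj.t_value == pytest.approx(expected_t, abs=1e-8)

    def test_rejection_rate_matches_noncentral_t_power_oracle(self, rng):
        """Simulated power at alpha = 1/112 for a unit shift with n=40/group
        against the analytic noncentral-t computation."""
        n, reps, alpha = 40, 1000, 1 / 112
        Y = np.vstack([rng.standard_normal((n, reps)) + 1.0, rng.standard_normal((n, reps))])
        group = np.array(["A"] * n + ["B"] * n)
        tab = nodal_contrast_table(Y, group, None, ("A", "B"), alpha)
        rate = tab["significant"].mean()
        dof = 2 * n - 2
        ncp = 1.0 / np.sqrt(2 / n)
        tcrit = stats.t.ppf(1 - alpha / 2, dof)
        power = stats.nct.sf(tcrit, dof, ncp) + stats.nct.cdf(-tcrit, dof, ncp)
        assert abs(rate - power) < 0.03

    def test_empty_group_rejected(self, rng):
        design = GroupDesign(
            response=rng.standard_normal(10),
            group=np.array(["MPD"] * 10),
            contrast=("MPD", "NC"),
        )
        with pytest.raises(ValueError):
            glm_contrast(design)


class TestNodalContrastTable:
    def test_matches_per_node_glm(self, rng):
        n, nodes = 30, 7
        Y = rng.standard_normal((n, nodes))
        group = np.array(["MPD"] * 15 + ["NC"] * 15)
        cov = pd.DataFrame({"age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n)})
        tab = nodal_contrast_table(Y, group, cov, ("MPD", "NC"), 0.009)
        for node in range(nodes):
            ref = glm_contrast(
                GroupDesign(response=Y[:, node], group=group, covariates=cov,
                            contrast=("MPD", "NC"))
            )
            assert tab.loc[node, "t_value"] == pytest.approx(ref.t_value, abs=1e-10)
            assert tab.loc[node, "p_value"] == pytest.approx(ref.p_value, abs=1e-10)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        r, p = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_y_equal_to_covariate_gives_zero(self, rng):
        x = rng.standard_normal(40)
        z = rng.standard_normal(40)
        r, _ = partial_correlation(x, z, covariates=z)
        assert abs(r) < 1e-8

    def test_recovers_known_partial_correlation(self, rng):
        """Trivariate normal whose generating covariance has partial
        correlation exactly 0.4 given z: the residuals of x and y share a
        latent factor with loading sqrt(0.4) each."""
        rho = 0.4
        c = np.sqrt(rho)
        estimates = []
        for _ in range(200):
            z = rng.standard_normal(500)
            shared = rng.standard_normal(500)
            u = c * shared + np.sqrt(1 - rho) * rng.standard_normal(500)
            v = c * shared + np.sqrt(1 - rho) * rng.standard_normal(500)
            x = 0.6 * z + u
            y = 0.5 * z + v
            estimates.append(partial_correlation(x, y, covariates=z)[0])
        assert abs(np.mean(estimates) - rho) < 0.03

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(60)
        y = 0.5 * x + rng.standard_normal(60)
        c1, c2 = rng.standard_normal(60), rng.standard_normal(60)
        r, p = partial_correlation(x, y, covariates=np.column_stack([c1, c2]))
        df = pd.DataFrame({"x": x, "y": y, "c1": c1, "c2": c2})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_insufficient_dof_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_correlation(
                rng.standard_normal(4), rng.standard_normal(4),
                covariates=rng.standard_normal((4, 2)),
            )


class TestLogistic:
    def test_well_separated_classes_high_auc(self, rng):
        n = 40
        X = pd.DataFrame({"f": np.concatenate([rng.normal(0, 1, n), rng.normal(5, 1, n)])})
        y = np.array([0] * n + [1] * n)
        res = logistic_discriminate(X, y, selection_mode="enter")
        assert res.auc > 0.99

    def test_permuted_labels_auc_near_half(self, rng):
        """Null discrimination: mean in-sample ROC AUC about 0.5 over label
        shuffles (the fitted single-feature model folds the AUC above 0.5,
        so the class size must be large enough for the bias to sit within
        the band)."""
        n = 100
        aucs = []
        X = pd.DataFrame({"f": rng.standard_normal(2 * n)})
        for _ in range(200):
            y = rng.permutation([0] * n + [1] * n)
            res = logistic_discriminate(X, y, selection_mode="enter")
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_backward_elimination_drops_noise_feature(self, rng):
        n = 60
        signal = np.concatenate([rng.normal(0, 1, n), rng.normal(2.5, 1, n)])
        X = pd.DataFrame({"signal": signal, "noise": rng.standard_normal(2 * n)})
        y = np.array([0] * n + [1] * n)
        res = logistic_discriminate(X, y, selection_mode="backward")
        assert res.selected_features == ["signal"]

    def test_perfect_separation_penalized_fallback(self):
        X = pd.DataFrame({"f": np.arange(10, dtype=float)})
        y = np.array([0] * 5 + [1] * 5)
        res = logistic_discriminate(X, y, selection_mode="enter")
        assert res.penalized
        assert res.auc == 1.0

    def test_printed_model_evaluation_at_origin(self):
        """Evaluating a published four-feature logistic model at the zero
        feature vector: P = 1/(1 + e^{3.938})."""
        p = logistic_probability(
            intercept=-3.938,
            coefficients=[-0.121, 0.121, 11.061, 12.647],
            x=[0.0, 0.0, 0.0, 0.0],
        )
        assert p == pytest.approx(1.0 / (1.0 + np.exp(3.938)), abs=1e-12)
        assert p == pytest.approx(0.0191, abs=5e-4)


class TestRocYouden:
    def test_scores_equal_labels_perfect(self):
        roc, auc, cutoff, sens, spec = roc_youden(
            np.array([0, 0, 1, 1, 1]), np.array([0, 0, 1, 1, 1])
        )
        assert auc == 1.0
        assert sens == 1.0 and spec == 1.0

    def test_hand_enumerated_four_scores(self):
        """scores {0.1, 0.4, 0.35, 0.8}, labels {0, 0, 1, 1}: confusion
        tables at every threshold give AUC 0.75 and best J at cutoff 0.8."""
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        roc, auc, cutoff, sens, spec = roc_youden(scores, labels)
        assert auc == pytest.approx(0.75)
        # J by threshold: 0.8 -> 0.5; 0.4 -> 0.0; 0.35 -> 0.5; 0.1 -> 0.0
        # tie between 0.8 and 0.35 resolved toward higher specificity (0.8)
        assert cutoff == pytest.approx(0.8)
        assert sens == pytest.approx(0.5)
        assert spec == pytest.approx(1.0)

    def test_auc_equals_normalized_mann_whitney_u(self, rng):
        for _ in range(10):
            s0 = rng.standard_normal(17)
            s1 = rng.standard_normal(13) + 0.7
            scores = np.concatenate([s0, s1])
            labels = np.array([0] * 17 + [1] * 13)
            _, auc, *_ = roc_youden(scores, labels)
            u = stats.mannwhitneyu(s1, s0, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (17 * 13), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        _, auc1, *_ = roc_youden(scores, labels)
        _, auc2, *_ = roc_youden(np.exp(3 * scores), labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden(np.array([0.1, 0.2]), np.array([1, 1]))
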
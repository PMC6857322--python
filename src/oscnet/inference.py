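"""Group-level statistics on nodal AUC values.

The stack comprises: covariate-adjusted GLM contrasts per node, the 1/N
false-positive threshold (optionally Bonferroni-divided across pairwise
group comparisons), partial correlations between nodal AUCs and motor
scores, and logistic-regression discrimination summarized by an ROC curve
and its Youden operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupDesign",
    "ContrastResult",
    "DiscriminationResult",
    "glm_contrast",
    "nodal_contrast_table",
    "significance_threshold",
    "partial_correlation",
    "correlation_screen",
    "logistic_discriminate",
    "logistic_probability",
    "roc_youden",
]


@dataclass
class GroupDesign:
    """One node's response vector with its group factor and covariates."""

    response: np.ndarray
    group: np.ndarray  # group label per subject
    covariates: pd.DataFrame | None = None
    contrast: tuple[str, str] = ("MPD", "NC")

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.group = np.asarray(self.group)
        if self.response.shape[0] != self.group.shape[0]:
            raise ValueError("response and group must have equal length")
        if self.covariates is not None and len(self.covariates) != len(self.response):
            raise ValueError("covariates must have one row per subject")


@dataclass
class ContrastResult:
    node: int | None
    metric: str | None
    band: str | None
    estimate: float
    t_value: float
    p_value: float
    direction: str
    threshold_applied: float
    significant: bool
    n_subjects: int = 0


@dataclass
class DiscriminationResult:
    selected_features: list[str]
    coefficients: dict[str, float]
    roc_points: np.ndarray  # (fpr, tpr) rows
    auc: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    penalized: bool = False


def significance_threshold(n_nodes: int, n_pairwise_comparisons: int = 1) -> float:
    """(1/n_nodes)/n_comparisons, capped at 1: one expected false positive
    per node-wise analysis, Bonferroni-shared across group contrasts."""
    if n_nodes < 1 or n_pairwise_comparisons < 1:
        raise ValueError("n_nodes and n_pairwise_comparisons must be >= 1")
    return min(1.0, (1.0 / n_nodes) / n_pairwise_comparisons)


def _design_matrix(design: GroupDesign) -> tuple[np.ndarray, np.ndarray, list[str]]:
    a, b = design.contrast
    keep = np.isin(design.group, [a, b])
    for lab in (a, b):
        if (design.group == lab).sum() < 2:
            raise ValueError(f"fewer than 2 subjects in group {lab!r}")
    y = design.response[keep]
    indicator = (design.group[keep] == a).astype(float)
    cols = [np.ones(keep.sum()), indicator]
    names = ["intercept", f"{a}_vs_{b}"]
    if design.covariates is not None:
        for c in design.covariates.columns:
            col = np.asarray(design.covariates[c], dtype=float)[keep]
            if np.ptp(col) == 0:
                continue  # constant covariate: collinear with the intercept
            cols.append(col)
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient GLM design (collinear covariates?)")
    return y, X, names


def glm_contrast(
    design: GroupDesign,
    threshold: float | None = None,
    node: int | None = None,
    metric: str | None = None,
    band: str | None = None,
) -> ContrastResult:
    """OLS fit of response ~ group indicator + covariates; two-sided t test
    on the group coefficient.  With no covariates this is exactly the
    pooled-variance two-sample t test."""
    y, X, names = _design_matrix(design)
    fit = sm.OLS(y, X).fit()
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    thr = threshold if threshold is not None else significance_threshold(1)
    a, b = design.contrast
    return ContrastResult(
        node=node,
        metric=metric,
        band=band,
        estimate=float(fit.params[1]),
        t_value=t,
        p_value=p,
        direction=f"{a}>{b}" if t > 0 else f"{a}<{b}",
        threshold_applied=thr,
        significant=bool(p < thr),
        n_subjects=len(y),
    )


def nodal_contrast_table(
    auc: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None,
    contrast: tuple[str, str],
    threshold: float,
    metric: str | None = None,
    band: str | None = None,
) -> pd.DataFrame:
    """Vectorized per-node GLM contrasts for an n_subjects x n_nodes AUC
    matrix (same design across nodes, many responses)."""
    auc = np.asarray(auc, dtype=float)
    a, b = contrast
    keep = np.isin(group, [a, b])
    for lab in (a, b):
        if (group == lab).sum() < 2:
            raise ValueError(f"fewer than 2 subjects in group {lab!r}")
    Y = auc[keep]
    indicator = (np.asarray(group)[keep] == a).astype(float)
    cols = [np.ones(keep.sum()), indicator]
    if covariates is not None:
        for c in covariates.columns:
            col = np.asarray(covariates[c], dtype=float)[keep]
            if np.ptp(col) == 0:
                continue  # constant covariate: collinear with the intercept
            cols.append(col)
    X = np.column_stack(cols)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient GLM design")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.clip(sigma2 * XtX_inv[1, 1], 1e-300, None))
    t = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame(
        {
            "node": np.arange(Y.shape[1]),
            "metric": metric,
            "band": band,
            "contrast": f"{a}_vs_{b}",
            "t_value": t,
            "p_value": p,
            "direction": np.where(t > 0, f"{a}>{b}", f"{a}<{b}"),
            "threshold_applied": threshold,
            "significant": p < threshold,
        }
    )


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on the
    covariates (with intercept); p from t with df = n - k - 2."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(n), C])
        k = C.shape[1]
    dof = n - k - 2
    if dof < 1:
        raise ValueError(f"insufficient degrees of freedom ({dof}) for partial correlation")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # a variable fully explained by the covariates has no residual
    # association left; float residue must not masquerade as correlation
    if (rx**2).sum() <= 1e-20 * max((x**2).sum(), 1.0) or (ry**2).sum() <= 1e-20 * max(
        (y**2).sum(), 1.0
    ):
        return 0.0, 1.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p


def correlation_screen(
    auc_values: pd.DataFrame,
    clinical: pd.DataFrame,
    significant_nodes: list[tuple[int, str, str]],
    covariate_columns: tuple[str, ...] = ("age", "sex_indicator", "head_motion"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial correlations of significant nodes' AUCs with motor scores.

    ``auc_values`` is long format with columns (subject_id, node, band,
    metric, auc); ``clinical`` has one row per subject with the motor
    scores and covariates.  For each (node, band, metric) the AUC is
    correlated with the total motor score (covariates regressed out), then
    with each subscale with the other subscale additionally regressed out.
    Bonferroni correction is applied over all screened correlations.
    """
    if not significant_nodes:
        return pd.DataFrame(
            columns=[
                "node", "band", "metric", "score", "r", "p",
                "p_bonferroni", "significant",
            ]
        )
    clin = clinical.set_index("subject_id")
    rows = []
    for node, band, metric in significant_nodes:
        sel = auc_values[
            (auc_values["node"] == node)
            & (auc_values["band"] == band)
            & (auc_values["metric"] == metric)
        ].set_index("subject_id")["auc"]
        sub = clin.loc[sel.index]
        base_cov = sub[list(covariate_columns)].to_numpy(dtype=float)
        screens = [
            ("updrs_motor", base_cov),
            ("tremor_score", np.column_stack([base_cov, sub["ar_score"]])),
            ("ar_score", np.column_stack([base_cov, sub["tremor_score"]])),
        ]
        for score, cov in screens:
            r, p = partial_correlation(sel.to_numpy(), sub[score].to_numpy(), cov)
            rows.append(
                {"node": node, "band": band, "metric": metric, "score": score, "r": r, "p": p}
            )
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def logistic_probability(intercept: float, coefficients, x) -> float:
    """Evaluate P = 1/(1 + exp(-(intercept + coef . x))) for a fitted or
    published logistic model."""
    eta = intercept + float(np.dot(np.asarray(coefficients, float), np.asarray(x, float)))
    return float(1.0 / (1.0 + np.exp(-eta)))


def logistic_discriminate(
    features: pd.DataFrame,
    labels: np.ndarray,
    selection_mode: str = "backward",
    p_remove: float = 0.05,
) -> DiscriminationResult:
    """Logistic-regression discrimination with ROC/Youden summary.

    ``selection_mode="backward"`` iteratively removes the feature with the
    largest Wald p-value while it exceeds ``p_remove`` (at least one
    feature is always retained); ``"enter"`` keeps all features.  Perfect
    separation falls back to an L2-penalized fit, flagged in the result.
    """
    labels = np.asarray(labels).astype(float)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes.max()).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    if selection_mode not in ("backward", "enter"):
        raise ValueError("selection_mode must be 'backward' or 'enter'")

    cols = list(features.columns)
    penalized = False

    def _fit(current):
        X = sm.add_constant(features[current].to_numpy(dtype=float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=200)
        if not np.isfinite(res.params).all() or not np.isfinite(res.bse).all():
            raise np.linalg.LinAlgError("unstable logistic fit")
        if np.abs(res.params).max() > 30:
            # runaway coefficients: (quasi-)separated data
            raise np.linalg.LinAlgError("separated logistic fit")
        return res

    try:
        fit = _fit(cols)
        if selection_mode == "backward":
            while len(cols) > 1:
                pvals = fit.pvalues[1:]
                worst = int(np.argmax(pvals))
                if pvals[worst] <= p_remove:
                    break
                cols.pop(worst)
                fit = _fit(cols)
        params = dict(zip(["intercept"] + cols, fit.params))
        scores = np.asarray(fit.predict())
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        from sklearn.linear_model import LogisticRegression

        penalized = True
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(features[cols].to_numpy(dtype=float), y)
        params = dict(
            zip(["intercept"] + cols, np.concatenate([clf.intercept_, clf.coef_[0]]))
        )
        scores = clf.predict_proba(features[cols].to_numpy(dtype=float))[:, 1]

    roc_points, auc, cutoff, sens, spec = roc_youden(scores, y)
    return DiscriminationResult(
        selected_features=cols,
        coefficients=params,
        roc_points=roc_points,
        auc=auc,
        youden_cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        scores=scores,
        penalized=penalized,
    )


def roc_youden(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float, float, float, float]:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid.

    The operating cutoff maximizes Youden's J = sensitivity +
    specificity - 1, ties resolved toward higher specificity.  Returns
    (roc_points, auc, cutoff, sensitivity, specificity) where roc_points
    rows are (false-positive rate, true-positive rate).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    pos = labels == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pts = []
    best = None
    for thr in thresholds:
        pred = scores >= thr
        tpr = float((pred & pos).sum()) / n1
        fpr = float((pred & ~pos).sum()) / n0
        pts.append((fpr, tpr))
        j = tpr - fpr
        # strict > keeps the earlier (higher-specificity) cutoff on ties
        if np.isfinite(thr) and (best is None or j > best[0] + 1e-15):
            best = (j, thr, tpr, 1.0 - fpr)
    roc_points = np.asarray(pts)
    auc = float(np.trapezoid(roc_points[:, 1], roc_points[:, 0]))
    _, cutoff, sens, spec = best
    return roc_points, auc, cutoff, sens, spec
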
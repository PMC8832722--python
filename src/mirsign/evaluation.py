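"""Diagnostic performance statistics.

ROC/AUC with stratified-bootstrap confidence intervals, DeLong comparisons of
correlated or independent AUCs via structural components (placement values),
confusion matrices, stage-restricted subgroup evaluation, group-vs-healthy
risk-score comparisons, uni/multivariate marker regression, and cross-cancer
specificity checks of a frozen scoring formula.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .signature import RiskModel, _binary_labels, score, scores_frame


@dataclass
class RocSummary:
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    sensitivity: float | None = None
    specificity: float | None = None
    cutoff: float | None = None
    curve: pd.DataFrame | None = None  # columns fpr, tpr
    n_case: int = 0
    n_control: int = 0


@dataclass
class ComparisonResult:
    auc_a: float
    auc_b: float
    z_statistic: float
    p_value: float
    paired: bool


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    cases, controls = scores[y == 1], scores[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def mann_whitney_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC: P(case > control) + 0.5 P(equal)."""
    m, n = len(cases), len(controls)
    ranks = sps.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def roc_auc(scores, labels, cutoff: float | None = None) -> RocSummary:
    """AUC plus the full ROC curve from a threshold sweep over unique scores.

    Cases are expected to score high; an AUC below 0.5 triggers an
    orientation warning rather than silent flipping.  When `cutoff` is given
    (rule: score >= cutoff => positive), sensitivity and specificity at that
    cutoff are reported.
    """
    from sklearn.metrics import roc_curve

    cases, controls = _split(scores, labels)
    auc = mann_whitney_auc(cases, controls)
    if auc < 0.5:
        warnings.warn(f"AUC {auc:.3f} < 0.5: scores may be oriented case-low")
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    fpr, tpr, _ = roc_curve(y, np.concatenate([cases, controls]), drop_intermediate=False)
    summary = RocSummary(
        auc=auc,
        curve=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        n_case=len(cases),
        n_control=len(controls),
    )
    if cutoff is not None:
        summary.cutoff = float(cutoff)
        summary.sensitivity = float(np.mean(cases >= cutoff))
        summary.specificity = float(np.mean(controls < cutoff))
    return summary


def bootstrap_ci(
    scores,
    labels,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile CI of the AUC from stratified bootstrap replicates.

    Cases and controls are resampled independently with replacement, so no
    replicate can lose a class.
    """
    cases, controls = _split(scores, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 samples per class for a bootstrap CI")
    m, n = len(cases), len(controls)
    rng = np.random.default_rng(seed)
    boot_cases = cases[rng.integers(0, m, size=(n_boot, m))]
    boot_controls = controls[rng.integers(0, n, size=(n_boot, n))]
    combined = np.concatenate([boot_cases, boot_controls], axis=1)
    ranks = sps.rankdata(combined, axis=1)
    aucs = (ranks[:, :m].sum(axis=1) - m * (m + 1) / 2.0) / (m * n)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _structural_components(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values.

    V10[i] = mean_j psi(case_i, control_j), V01[j] = mean_i psi(case_i,
    control_j) with psi = 1, 1/2, 0 for case >, =, < control.  Their sample
    means both equal the Mann-Whitney AUC.
    """
    diff = cases[:, None] - controls[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC estimate."""
    cases, controls = _split(scores, labels)
    v10, v01, _ = _structural_components(cases, controls)
    s10 = np.var(v10, ddof=1) if len(v10) > 1 else 0.0
    s01 = np.var(v01, ddof=1) if len(v01) > 1 else 0.0
    return float(s10 / len(cases) + s01 / len(controls))


def delong_test(scores_a, scores_b, labels, labels_b=None, paired: bool = True) -> ComparisonResult:
    """Compare two AUCs by DeLong's method.

    Paired: both score sets on the same samples/labels; the covariance of the
    placement values is subtracted.  Unpaired: independent cohorts
    (``labels_b`` for the second), variances summed.
    """
    ca, na = _split(scores_a, labels)
    if paired:
        cb, nb = _split(scores_b, labels)
        if len(ca) != len(cb) or len(na) != len(nb):
            raise ValueError("paired comparison needs identical samples")
    else:
        cb, nb = _split(scores_b, labels if labels_b is None else labels_b)
    if min(len(ca), len(na), len(cb), len(nb)) < 2:
        raise ValueError("need at least 2 samples per class in each score set")

    v10a, v01a, auc_a = _structural_components(ca, na)
    v10b, v01b, auc_b = _structural_components(cb, nb)
    m, n = len(ca), len(na)
    if paired:
        s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = (
            np.var(v10a, ddof=1) / m
            + np.var(v01a, ddof=1) / n
            + np.var(v10b, ddof=1) / len(cb)
            + np.var(v01b, ddof=1) / len(nb)
        )
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = float(delta / np.sqrt(var))
        p = float(2.0 * sps.norm.sf(abs(z)))
    return ComparisonResult(auc_a=auc_a, auc_b=auc_b, z_statistic=z, p_value=max(p, np.finfo(float).tiny), paired=paired)


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)

    def __post_init__(self) -> None:
        self.sensitivity = self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")
        self.specificity = self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")
        self.ppv = self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")
        self.npv = self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def undefined_rates(self) -> list[str]:
        return [k for k in ("sensitivity", "specificity", "ppv", "npv") if np.isnan(getattr(self, k))]


def confusion_matrix(predicted_class, labels) -> ConfusionMatrix:
    """2x2 counts from high/low predictions against case/control labels."""
    pred = np.asarray([1 if p in ("high", 1, True) else 0 for p in predicted_class])
    y = _binary_labels(labels)
    if len(pred) != len(y):
        raise ValueError("predictions and labels differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
    )


def subgroup_eval(scores, labels, stages, subgroup: Sequence[str], cutoff: float | None = None) -> RocSummary:
    """ROC of subgroup cases (stage filter) against all controls."""
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    stages = np.asarray(stages)
    keep = (y == 0) | np.isin(stages, list(subgroup))
    if not np.any((y == 1) & keep):
        raise ValueError(f"subgroup {list(subgroup)} contains no cases")
    return roc_auc(scores[keep], y[keep], cutoff=cutoff)


def group_compare(
    scores,
    stages,
    groups: Sequence[str] | None = None,
    reference: str = "healthy",
    alternative: str = "greater",
) -> dict[str, float]:
    """One-sided t-test of each stage group's risk scores against healthy.

    The default alternative tests for elevation (group mean > healthy mean).
    P-values are raw, one per group, with no multiplicity adjustment.
    """
    scores = np.asarray(scores, dtype=float)
    stages = np.asarray(stages)
    ref_scores = scores[stages == reference]
    if len(ref_scores) < 2:
        raise ValueError(f"reference group {reference!r} missing or too small")
    if groups is None:
        groups = [g for g in pd.unique(stages) if g != reference]
    out = {}
    for g in groups:
        vals = scores[stages == g]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        out[g] = float(sps.ttest_ind(vals, ref_scores, equal_var=False, alternative=alternative).pvalue)
    return out


def marker_regression(predictors: pd.DataFrame, labels, mode: str = "multivariate") -> pd.DataFrame:
    """Logistic odds ratios with Wald 95% CIs and p-values per predictor.

    ``univariate`` fits each predictor alone; ``multivariate`` fits all
    jointly.  Duplicate or collinear predictor columns trigger a warning.
    """
    import statsmodels.api as sm

    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    y = _binary_labels(labels, predictors.index)
    X = predictors.astype(float)
    if X.T.duplicated().any():
        warnings.warn("duplicate predictor columns detected (collinearity)")
    elif X.shape[1] > 1 and np.linalg.cond(np.corrcoef(X.to_numpy(), rowvar=False)) > 1e8:
        warnings.warn("near-collinear predictors detected")

    def _one_fit(cols: list[str]) -> pd.DataFrame:
        design = sm.add_constant(X[cols], has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=200, warn_convergence=False)
            conf = res.conf_int()
            rows = [
                {
                    "predictor": c,
                    "odds_ratio": float(np.exp(res.params[c])),
                    "or_ci_low": float(np.exp(conf.loc[c, 0])),
                    "or_ci_high": float(np.exp(conf.loc[c, 1])),
                    "p_value": float(res.pvalues[c]),
                }
                for c in cols
            ]
        except Exception:
            # singular/separated design: report ridge-stabilized point
            # estimates without Wald inference
            from ._logistic import fit_logistic

            fit = fit_logistic(X[cols].to_numpy(float), y)
            rows = [
                {
                    "predictor": c,
                    "odds_ratio": float(np.exp(b)),
                    "or_ci_low": float("nan"),
                    "or_ci_high": float("nan"),
                    "p_value": float("nan"),
                }
                for c, b in zip(cols, fit.coefficients)
            ]
        return pd.DataFrame(rows)

    if mode == "multivariate":
        table = _one_fit(list(X.columns))
    else:
        table = pd.concat([_one_fit([c]) for c in X.columns], ignore_index=True)
    table["mode"] = mode
    return table.set_index("predictor")


def cross_cancer_specificity(
    model: RiskModel,
    cohorts: Mapping[str, tuple],
    reference: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, RocSummary], dict[str, ComparisonResult]]:
    """Score each cohort with a frozen formula; compare AUCs to the reference.

    `cohorts` maps name -> (expression, labels); the reference cohort is the
    disease the formula was trained for.  Comparisons are unpaired DeLong
    tests (different patients per cohort).
    """
    if reference not in cohorts:
        raise ValueError(f"reference cohort {reference!r} not among cohorts")
    summaries: dict[str, RocSummary] = {}
    raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i, (name, (expr, labels)) in enumerate(cohorts.items()):
        s = scores_frame(score(model, expr))["logit"].to_numpy()
        y = _binary_labels(labels)
        summary = roc_auc(s, y)
        summary.ci_low, summary.ci_high = bootstrap_ci(s, y, n_boot=n_boot, seed=seed + i)
        summary.n_boot = n_boot
        summaries[name] = summary
        raw[name] = (s, y)
    ref_s, ref_y = raw[reference]
    comparisons = {
        name: delong_test(ref_s, s, ref_y, labels_b=y, paired=False)
        for name, (s, y) in raw.items()
        if name != reference
    }
    return summaries, comparisons
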
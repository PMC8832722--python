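"""In-silico discovery phase: per-dataset differential expression, per-miRNA
discrimination, abundance filtering, multi-dataset overlap, and cross-validated
multivariate evaluation of the resulting candidate panel.

Expression matrices are consumed already normalized, on the log2 scale, one per
tissue dataset, with a tumor/normal label per sample.  Candidate miRNAs must be

1. differentially expressed (log2 fold change above a floor, BH-adjusted p
   below a ceiling, tumor over normal),
2. discriminative (tie-corrected Mann-Whitney AUC above a floor, tumor-high
   orientation), and
3. abundant (mean expression above the median mean expression of the miRNAs
   that pass the differential-expression criterion),

and the final panel is the intersection of the per-dataset candidate sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._logistic import LogisticFit, fit_logistic

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """A miRNA x sample log2 abundance table with per-sample group labels."""

    values: pd.DataFrame  # rows: miRNA ids, columns: sample ids
    labels: pd.Series  # sample id -> "tumor" | "normal"
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate miRNA identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        missing = set(self.values.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)[:5]}")
        self.labels = self.labels.loc[self.values.columns]
        bad = set(self.labels.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == TUMOR])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == NORMAL])

    def group_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(tumor, normal) value blocks as arrays, rows aligned to miRNAs."""
        return (
            self.values[self.tumor_samples].to_numpy(float),
            self.values[self.normal_samples].to_numpy(float),
        )

    @classmethod
    def from_tsv(cls, matrix_path, metadata_path, dataset_id: str = "") -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path).set_index("sample_id")
        return cls(values=values, labels=meta["group"], dataset_id=dataset_id or Path(matrix_path).stem)

    def to_tsv(self, matrix_path, metadata_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", float_format="%.6g")
        pd.DataFrame({"sample_id": self.labels.index, "group": self.labels.values}).to_csv(
            metadata_path, index=False
        )


@dataclass
class FilterThresholds:
    lfc_min: float = 0.5
    fdr_max: float = 0.05
    auc_min: float = 0.7


@dataclass
class MiRNAPanel:
    mirna_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate ids in panel")

    def __len__(self) -> int:
        return len(self.mirna_ids)

    def __iter__(self):
        return iter(self.mirna_ids)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped at 1)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def differential_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-miRNA Welch t-test of tumor vs normal on log2 values.

    Returns a frame indexed by miRNA id with columns ``log2fc`` (tumor mean
    minus normal mean), ``p_raw``, ``p_adj`` (BH across all rows),
    ``mean_expr`` (mean over every sample) and ``zero_variance``.  Rows with
    zero variance in both groups get p = 1 by convention and are flagged.
    """
    tum, nor = matrix.group_values()
    if tum.shape[1] < 2 or nor.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    log2fc = tum.mean(axis=1) - nor.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_raw = sps.ttest_ind(tum, nor, axis=1, equal_var=False)
    zero_var = (tum.var(axis=1) == 0) & (nor.var(axis=1) == 0)
    p_raw = np.where(zero_var | ~np.isfinite(p_raw), 1.0, p_raw)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": benjamini_hochberg(p_raw),
            "mean_expr": matrix.values.mean(axis=1).to_numpy(float),
            "zero_variance": zero_var,
        },
        index=matrix.values.index,
    )


def per_mirna_auc(matrix: ExpressionMatrix) -> pd.Series:
    """Tie-corrected Mann-Whitney AUC per miRNA, oriented tumor-high.

    AUC = P(tumor sample > normal sample) + 0.5 P(equal), estimated over all
    tumor/normal pairs via mid-ranks.
    """
    tum, nor = matrix.group_values()
    m, n = tum.shape[1], nor.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([tum, nor], axis=1)
    ranks = sps.rankdata(combined, axis=1)
    auc = (ranks[:, :m].sum(axis=1) - m * (m + 1) / 2.0) / (m * n)
    return pd.Series(auc, index=matrix.values.index, name="auc")


def candidate_stats(matrix: ExpressionMatrix, thresholds: FilterThresholds | None = None) -> pd.DataFrame:
    """Combined DE + AUC statistics with pass flags for the three criteria."""
    thresholds = thresholds or FilterThresholds()
    stats = differential_expression(matrix)
    stats["auc"] = per_mirna_auc(matrix)
    stats["pass_de"] = (stats["log2fc"] > thresholds.lfc_min) & (stats["p_adj"] < thresholds.fdr_max)
    stats["pass_auc"] = stats["auc"] > thresholds.auc_min
    de_pool = stats.loc[stats["pass_de"], "mean_expr"]
    if len(de_pool):
        stats["pass_abundance"] = stats["mean_expr"] > float(de_pool.median())
    else:
        stats["pass_abundance"] = False
    return stats


def filter_candidates(stats: pd.DataFrame, thresholds: FilterThresholds | None = None) -> MiRNAPanel:
    """Apply the three candidate criteria to a statistics table.

    The abundance reference (median mean expression) is computed over the
    miRNAs passing the differential-expression criterion only; when none pass,
    the panel is empty and a warning is emitted.  The returned ids are ordered
    by decreasing log2 fold change (then id), which makes the result invariant
    to the row order of ``stats``.
    """
    thresholds = thresholds or FilterThresholds()
    pass_de = (stats["log2fc"] > thresholds.lfc_min) & (stats["p_adj"] < thresholds.fdr_max)
    if not pass_de.any():
        warnings.warn("no miRNA passes the differential-expression criterion; empty panel")
        return MiRNAPanel([], provenance={"thresholds": vars(thresholds), "n_pass_de": 0})
    abundance_median = float(stats.loc[pass_de, "mean_expr"].median())
    keep = (
        pass_de
        & (stats["auc"] > thresholds.auc_min)
        & (stats["mean_expr"] > abundance_median)
    )
    chosen = stats.loc[keep].sort_values(["log2fc"], ascending=False, kind="mergesort")
    ids = sorted(chosen.index.tolist(), key=lambda i: (-float(stats.at[i, "log2fc"]), i))
    return MiRNAPanel(
        ids,
        provenance={
            "thresholds": vars(thresholds),
            "n_pass_de": int(pass_de.sum()),
            "abundance_median": abundance_median,
        },
    )


def intersect_panels(panels: Sequence[MiRNAPanel]) -> MiRNAPanel:
    """Set intersection of candidate panels, ordered by the first panel."""
    if len(panels) < 2:
        raise ValueError("need at least 2 panels to intersect")
    common = set(panels[0].mirna_ids)
    for p in panels[1:]:
        common &= set(p.mirna_ids)
    ids = [m for m in panels[0].mirna_ids if m in common]
    return MiRNAPanel(ids, provenance={"n_panels": len(panels), "sizes": [len(p) for p in panels]})


@dataclass
class CVResult:
    mean_auc: float
    per_repeat_auc: np.ndarray
    folds: int
    repeats: int
    seed: int
    stabilized_fits: int


def _panel_design(matrix: ExpressionMatrix, panel: MiRNAPanel) -> tuple[np.ndarray, np.ndarray]:
    missing = [m for m in panel if m not in matrix.values.index]
    if missing:
        raise ValueError(f"panel miRNAs missing from {matrix.dataset_id or 'matrix'}: {missing}")
    X = matrix.values.loc[list(panel)].T.to_numpy(float)
    y = (matrix.labels == TUMOR).to_numpy(float)
    return X, y


def _pooled_auc(scores: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(scores)
    m = int(y.sum())
    n = len(y) - m
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def cross_validated_auc(
    matrix: ExpressionMatrix,
    panel: MiRNAPanel,
    folds: int = 2,
    repeats: int = 100,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV of a multivariate logistic panel model.

    Each repeat draws a fresh stratified split, fits on each training fold,
    scores the held-out fold, and computes one AUC on the pooled held-out
    scores; the mean over repeats is reported.
    """
    from sklearn.model_selection import StratifiedKFold

    X, y = _panel_design(matrix, panel)
    if min(int(y.sum()), int((1 - y).sum())) < folds:
        raise ValueError("each group needs at least `folds` samples")
    rng = np.random.default_rng(seed)
    per_repeat = np.empty(repeats)
    stabilized = 0
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
        held_out = np.empty_like(y)
        for train_idx, test_idx in skf.split(X, y):
            fit = fit_logistic(X[train_idx], y[train_idx])
            stabilized += int(fit.stabilized)
            held_out[test_idx] = fit.linear_predictor(X[test_idx])
        per_repeat[r] = _pooled_auc(held_out, y)
    return CVResult(
        mean_auc=float(per_repeat.mean()),
        per_repeat_auc=per_repeat,
        folds=folds,
        repeats=repeats,
        seed=seed,
        stabilized_fits=stabilized,
    )


def train_apply_cross_dataset(
    train: ExpressionMatrix,
    tests: Iterable[ExpressionMatrix],
    panel: MiRNAPanel,
) -> tuple[Mapping[str, float], LogisticFit]:
    """Fit one panel model on `train` and apply the frozen linear predictor
    unchanged to each test matrix; returns per-dataset AUC and the fit."""
    X, y = _panel_design(train, panel)
    fit = fit_logistic(X, y)
    aucs: dict[str, float] = {}
    for mat in tests:
        Xt, yt = _panel_design(mat, panel)
        aucs[mat.dataset_id or f"dataset{len(aucs)}"] = _pooled_auc(fit.linear_predictor(Xt), yt)
    return aucs, fit
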
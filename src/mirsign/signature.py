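"""Multivariate logistic risk scoring for the circulating miRNA panel.

The risk score is logit(P) = b0 + sum_j b_j x_j over the panel covariates; a
sample is called high risk when its score passes a cutoff chosen by Youden's
index on the training cohort.  Models can be fitted from data, exported and
re-imported bit-exactly, or loaded from a registry of frozen published
formulas that are never refitted.

Covariate scale: fold changes enter either as 2^-ddCt ("linear-foldchange")
or as log2 fold change = -ddCt ("log2-foldchange").  Fitting defaults to the
log2 scale, which is numerically stable; every model records the scale it was
fitted on and scoring refuses mismatched input.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._logistic import fit_logistic
from .quantification import NormalizedExpression

LINEAR = "linear-foldchange"
LOG2 = "log2-foldchange"

# Frozen published scoring formulas.  Coefficients are stored verbatim and are
# never refitted; the prospective-cohort formula keeps its printed signs even
# where they run against the serum upregulation of individual panel members.
FROZEN_MODELS: dict[str, dict] = {
    "beijing1-prospective": {
        "coefficients": {
            "miR-17": 0.00810,
            "miR-21": -0.183,
            "miR-25": -0.974,
            "miR-93": 0.973,
            "miR-103": -0.347,
            "miR-106b": -0.298,
            "miR-151": -0.194,
            "miR-181a": 0.226,
        },
        "intercept": -3.196,
        "covariate_scale": LINEAR,
        "cutoff": None,
        "training_meta": {"cohort": "prospective training (Beijing-1)", "frozen": True},
    },
}


@dataclass
class Cutoff:
    value: float
    scale: str = "probability"  # or "logit"


@dataclass
class RiskModel:
    coefficients: Mapping[str, float]
    intercept: float
    covariate_scale: str = LOG2
    cutoff: Cutoff | None = None
    training_meta: dict = field(default_factory=dict)
    stabilized: bool = False

    @property
    def panel(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path=None) -> str:
        payload = {
            "panel": self.panel,
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "covariate_scale": self.covariate_scale,
            "cutoff": None if self.cutoff is None else {"value": self.cutoff.value, "scale": self.cutoff.scale},
            "training_meta": dict(self.training_meta),
            "stabilized": self.stabilized,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RiskModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cut = payload.get("cutoff")
        return cls(
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            intercept=float(payload["intercept"]),
            covariate_scale=payload.get("covariate_scale", LOG2),
            cutoff=None if cut is None else Cutoff(float(cut["value"]), cut["scale"]),
            training_meta=payload.get("training_meta", {}),
            stabilized=bool(payload.get("stabilized", False)),
        )


@dataclass
class RiskScore:
    sample_id: str
    logit: float
    probability: float
    predicted_class: str | None  # "high" / "low" when a cutoff is set


def _covariate_frame(expr, panel: Sequence[str], model_scale: str) -> pd.DataFrame:
    if isinstance(expr, NormalizedExpression):
        if expr.covariate_scale != model_scale:
            if expr.covariate_scale == LINEAR and model_scale == LOG2:
                expr = expr.to_log2()
            else:
                raise ValueError(
                    f"covariate scale mismatch: model expects {model_scale}, "
                    f"input is {expr.covariate_scale}"
                )
        frame = expr.values
    else:
        frame = expr  # plain DataFrame: caller asserts it is on the model scale
    missing = [m for m in panel if m not in frame.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    return frame[list(panel)]


def fit_risk_model(
    expr,
    labels,
    panel: Sequence[str],
    covariate_scale: str = LOG2,
    seed: int | None = None,
    cohort_id: str = "",
) -> RiskModel:
    """Maximum-likelihood logistic fit of case/control on the panel covariates.

    `expr` is a NormalizedExpression (transformed to the requested scale) or a
    plain sample x miRNA DataFrame already on that scale.  `labels` maps
    samples to case/control (1/0 also accepted).  The fit is deterministic;
    `seed` is recorded in training metadata only.
    """
    X_frame = _covariate_frame(expr, panel, covariate_scale)
    y = _binary_labels(labels, X_frame.index)
    fit = fit_logistic(X_frame.to_numpy(float), y)
    if fit.stabilized:
        warnings.warn("separation detected; ridge-stabilized logistic fit used")
    return RiskModel(
        coefficients={m: float(c) for m, c in zip(panel, fit.coefficients)},
        intercept=fit.intercept,
        covariate_scale=covariate_scale,
        training_meta={
            "cohort": cohort_id,
            "n_case": int(y.sum()),
            "n_control": int(len(y) - y.sum()),
            "seed": seed,
        },
        stabilized=fit.stabilized,
    )


def _binary_labels(labels, index=None) -> np.ndarray:
    s = pd.Series(labels)
    if index is not None and not s.index.equals(pd.RangeIndex(len(s))):
        s = s.reindex(index)
    if s.isna().any():
        raise ValueError("labels missing for some samples")
    vals = s.astype(object)
    mapping = {"case": 1, "tumor": 1, "control": 0, "normal": 0, "healthy": 0, 1: 1, 0: 0, True: 1, False: 0}
    try:
        return np.array([mapping[v] for v in vals], dtype=float)
    except KeyError as exc:
        raise ValueError(f"unrecognized label {exc.args[0]!r}") from None


def load_frozen_model(name: str) -> RiskModel:
    """Return a frozen published scoring formula from the packaged registry."""
    if name not in FROZEN_MODELS:
        raise KeyError(f"unknown frozen model {name!r}; registry: {sorted(FROZEN_MODELS)}")
    entry = FROZEN_MODELS[name]
    return RiskModel(
        coefficients=dict(entry["coefficients"]),
        intercept=entry["intercept"],
        covariate_scale=entry["covariate_scale"],
        cutoff=None if entry["cutoff"] is None else Cutoff(**entry["cutoff"]),
        training_meta=dict(entry["training_meta"]),
    )


def score(model: RiskModel, expr) -> list[RiskScore]:
    """Score samples: logit = intercept + sum(coef * covariate), probability
    via the logistic transform, class by the stored cutoff (score equal to the
    cutoff counts as high risk)."""
    frame = _covariate_frame(expr, model.panel, model.covariate_scale)
    coefs = np.array([model.coefficients[m] for m in model.panel])
    logits = model.intercept + frame.to_numpy(float) @ coefs
    probs = 1.0 / (1.0 + np.exp(-logits))
    classes: list[str | None]
    if model.cutoff is None:
        classes = [None] * len(logits)
    else:
        ref = probs if model.cutoff.scale == "probability" else logits
        classes = ["high" if v >= model.cutoff.value else "low" for v in ref]
    return [
        RiskScore(sample_id=str(s), logit=float(l), probability=float(p), predicted_class=c)
        for s, l, p, c in zip(frame.index, logits, probs, classes)
    ]


def scores_frame(scores: Sequence[RiskScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "logit": [s.logit for s in scores],
            "probability": [s.probability for s in scores],
            "predicted_class": [s.predicted_class for s in scores],
        }
    ).set_index("sample_id")


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Thresholds are scanned at the observed score values with the decision rule
    score >= threshold => high risk; ties in J break toward the smallest
    threshold (maximal sensitivity).  Returns (cutoff, J).
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        warnings.warn("all scores identical; Youden index is 0")
        return float(scores[0]), 0.0
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    best_thr, best_j = None, -np.inf
    for thr in np.sort(np.unique(scores)):
        pred = scores >= thr
        sens = np.sum(pred & (y == 1)) / n_pos
        spec = np.sum(~pred & (y == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_thr, best_j = float(thr), float(j)
    return best_thr, best_j
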
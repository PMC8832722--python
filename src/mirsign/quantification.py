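"""qRT-PCR processing: detection-limit filtering, missing-well handling, and
relative quantification by the 2^-delta-delta-Ct method.

A Ct (cycle threshold) is the PCR cycle at which fluorescence crosses the
instrument threshold; lower Ct means more abundant target.  Relative
quantification normalizes each target's Ct against one or more reference
targets within the same sample (delta Ct), then against a calibrator (here the
mean delta Ct of the control group by default), and reports fold change as
2^(-delta-delta-Ct).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNDETERMINED = "Undetermined"
IMPUTE_POLICIES = ("max_cycles", "drop_sample", "drop_target")


@dataclass
class CtTable:
    """Long-format qPCR records: one row per (sample, target) with a Ct value
    or NaN for an undetermined well."""

    records: pd.DataFrame  # columns: sample_id, target_id, ct
    detection_limit: float = 35.0
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        req = {"sample_id", "target_id", "ct"}
        if not req <= set(self.records.columns):
            raise ValueError(f"Ct table needs columns {sorted(req)}")
        if self.records.duplicated(["sample_id", "target_id"]).any():
            raise ValueError("duplicate (sample, target) pairs")
        ct = pd.to_numeric(self.records["ct"], errors="coerce")
        present = ct.dropna()
        if ((present <= 0) | (present > self.max_cycles)).any():
            raise ValueError(f"Ct values must lie in (0, {self.max_cycles}]")
        self.records = self.records.assign(ct=ct).reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CtTable":
        df = pd.read_csv(path)
        df["ct"] = pd.to_numeric(df["ct"].replace(UNDETERMINED, np.nan), errors="coerce")
        return cls(records=df[["sample_id", "target_id", "ct"]], **kwargs)

    def pivot(self) -> pd.DataFrame:
        """sample x target Ct matrix (NaN for undetermined wells)."""
        return self.records.pivot(index="sample_id", columns="target_id", values="ct")

    @property
    def targets(self) -> list[str]:
        return list(pd.unique(self.records["target_id"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.records["sample_id"]))


@dataclass
class NormalizationScheme:
    reference_ids: Sequence[str]
    calibrator: str = "control_mean"  # or a named sample id
    label: str = ""

    def __post_init__(self) -> None:
        if not self.reference_ids:
            raise ValueError("reference_ids must be non-empty")


@dataclass
class NormalizedExpression:
    """sample x miRNA fold-change table (2^-ddCt) with provenance."""

    values: pd.DataFrame
    covariate_scale: str = "linear-foldchange"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.covariate_scale == "linear-foldchange" and (self.values <= 0).any().any():
            raise ValueError("fold-change values must be positive")

    def to_log2(self) -> "NormalizedExpression":
        if self.covariate_scale == "log2-foldchange":
            return self
        return NormalizedExpression(
            values=np.log2(self.values),
            covariate_scale="log2-foldchange",
            provenance=dict(self.provenance),
        )


def impute_undetermined(table: CtTable, policy: str = "max_cycles") -> tuple[CtTable, list[dict]]:
    """Resolve undetermined wells; returns the new table and an imputation log.

    Policies: ``max_cycles`` replaces each missing Ct with the cycle ceiling
    (so undetected targets fail the detection filter rather than inflating
    expression); ``drop_sample`` / ``drop_target`` remove the offending rows.
    """
    if policy not in IMPUTE_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {IMPUTE_POLICIES}")
    rec = table.records
    missing = rec["ct"].isna()
    if not missing.any():
        return table, []
    log = [
        {"sample_id": r.sample_id, "target_id": r.target_id, "policy": policy}
        for r in rec.loc[missing].itertuples()
    ]
    if policy == "max_cycles":
        rec = rec.assign(ct=rec["ct"].fillna(table.max_cycles))
    elif policy == "drop_sample":
        bad = set(rec.loc[missing, "sample_id"])
        rec = rec.loc[~rec["sample_id"].isin(bad)]
    else:
        bad = set(rec.loc[missing, "target_id"])
        rec = rec.loc[~rec["target_id"].isin(bad)]
    return CtTable(rec.reset_index(drop=True), table.detection_limit, table.max_cycles), log


def detection_filter(table: CtTable, limit: float | None = None) -> tuple[list[str], list[str]]:
    """Split targets into (kept, excluded) by mean Ct across all samples.

    A target is excluded iff its sample-mean Ct exceeds the detection limit;
    undetermined wells count at the cycle ceiling.
    """
    limit = table.detection_limit if limit is None else limit
    ct = table.pivot().fillna(table.max_cycles)
    means = ct.mean(axis=0)
    kept = [t for t in table.targets if means[t] <= limit]
    excluded = [t for t in table.targets if means[t] > limit]
    return kept, excluded


def delta_delta_ct(
    table: CtTable,
    scheme: NormalizationScheme,
    control_samples: Iterable[str] | None = None,
    groups: Mapping[str, str] | None = None,
) -> NormalizedExpression:
    """Relative quantification: fold change = 2^(-delta-delta-Ct).

    delta Ct(sample, target) = Ct(target) - mean(Ct over references in the
    same sample); multiple references are combined by the arithmetic mean of
    their Cts (the geometric mean on the linear abundance scale).  The
    calibrator is the mean delta Ct of the control group (or a named sample),
    so the geometric mean of control-group fold changes is exactly 1 for every
    target.
    """
    ct = table.pivot()
    missing_refs = [r for r in scheme.reference_ids if r not in ct.columns]
    if missing_refs:
        raise ValueError(f"reference targets absent from table: {missing_refs}")

    ref_ct = ct[list(scheme.reference_ids)].mean(axis=1, skipna=True)
    no_ref = ref_ct.index[ref_ct.isna()]
    if len(no_ref):
        raise ValueError(f"samples missing all reference targets: {list(no_ref)[:5]}")

    target_cols = [c for c in ct.columns if c not in set(scheme.reference_ids)]
    dct = ct[target_cols].sub(ref_ct, axis=0)

    if scheme.calibrator == "control_mean":
        if control_samples is None:
            if groups is None:
                raise ValueError("control_mean calibrator needs control_samples or groups")
            control_samples = [s for s, g in groups.items() if g in ("control", "normal", "healthy")]
        calib_idx = [s for s in control_samples if s in dct.index]
        if not calib_idx:
            raise ValueError("no control samples found in the Ct table")
        calib = dct.loc[calib_idx].mean(axis=0)
    else:
        if scheme.calibrator not in dct.index:
            raise ValueError(f"calibrator sample {scheme.calibrator!r} not in table")
        calib = dct.loc[scheme.calibrator]
        calib_idx = [scheme.calibrator]

    ddct = dct.sub(calib, axis=1)
    values = np.power(2.0, -ddct)
    return NormalizedExpression(
        values=values,
        covariate_scale="linear-foldchange",
        provenance={
            "scheme": scheme.label or "+".join(scheme.reference_ids),
            "reference_ids": list(scheme.reference_ids),
            "calibrator": scheme.calibrator,
            "n_calibrator_samples": len(calib_idx),
        },
    )
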
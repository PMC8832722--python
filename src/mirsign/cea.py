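"""Cohort decision-tree cost-effectiveness model for signature screening.

The model compares a non-invasive screening strategy against no screening in
a high-risk population over a finite follow-up horizon (default 3 years):

* Screening arm: a compliant fraction takes the blood test (test cost each).
  Test positives receive confirmatory endoscopy + biopsy (treated as a gold
  standard); true positives are treated at the screen-detected (early-shifted)
  stage distribution.  Test negatives - including false negatives - enter
  follow-up, where cancers surface exactly as in the no-screening arm.
  Non-compliant people behave exactly like the no-screening arm.
* No-screening arm: a background fraction receives surveillance endoscopy
  (detecting asymptomatic cancers at the early-shifted distribution); the
  remaining cancers present symptomatically at the late distribution, with a
  diagnostic endoscopy at presentation.

Patient pathways: stages I-III incur a one-time treatment cost and accrue
stage-specific utility for two years, after which they are cured; a
stage-specific fraction relapses to the stage-IV pathway (palliative cost,
stage-IV utility for one year, then death); non-relapsers accrue full healthy
utility for the remaining horizon.  Stage IV is untreatable: palliative cost,
stage-IV utility for one year, then death.  Healthy people accrue healthy
utility throughout.  Costs and QALYs can be discounted annually; the
incremental cost-effectiveness ratio is delta-cost / delta-QALY.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import pandas as pd

CURABLE_STAGES = ("I", "II", "III")
TERMINAL_STAGE = "IV"

DOMINATES = "screening-dominates"
DOMINATED = "screening-dominated"
EQUIVALENT = "equivalent"
TRADEOFF = "tradeoff"

_TOL = 1e-9


@dataclass
class ScreeningParams:
    cohort_size: float = 100000
    cancer_prevalence: float = 0.01
    compliance: float = 0.45
    test_sensitivity: float = 0.89
    test_specificity: float = 0.84
    background_endoscopy_rate: float = 0.10
    followup_years: int = 3
    stage_distribution_screen: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.50, "II": 0.30, "III": 0.15, "IV": 0.05}
    )
    stage_distribution_noscreen: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.10, "II": 0.20, "III": 0.40, "IV": 0.30}
    )
    stage_costs: Mapping = field(
        default_factory=lambda: {
            "test": 150.0,
            "endoscopy": 800.0,
            "treatment": {"I": 60000.0, "II": 90000.0, "III": 120000.0},
            "palliative": 50000.0,
        }
    )
    stage_utilities: Mapping[str, float] = field(
        default_factory=lambda: {"healthy": 1.0, "I": 0.80, "II": 0.70, "III": 0.60, "IV": 0.30}
    )
    recurrence_rate: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.10, "II": 0.25, "III": 0.45}
    )
    discount_rate: float = 0.0
    currency: str = "CNY"

    def validate(self) -> None:
        for name in (
            "cancer_prevalence",
            "compliance",
            "test_sensitivity",
            "test_specificity",
            "background_endoscopy_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if self.followup_years < 1:
            raise ValueError("followup_years must be >= 1")
        for name in ("stage_distribution_screen", "stage_distribution_noscreen"):
            dist = getattr(self, name)
            total = sum(dist.values())
            if abs(total - 1.0) > _TOL:
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative proportions")
        flat_costs = [self.stage_costs["test"], self.stage_costs["endoscopy"], self.stage_costs["palliative"]]
        flat_costs += list(self.stage_costs["treatment"].values())
        if any(c < 0 for c in flat_costs):
            raise ValueError("costs must be non-negative")
        for s, r in self.recurrence_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"recurrence_rate[{s}] must lie in [0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")

    @classmethod
    def from_json(cls, path) -> "ScreeningParams":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in payload.items() if k in known})

    def to_json(self, path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class CeaResult:
    cost_screen: float
    qaly_screen: float
    cost_noscreen: float
    qaly_noscreen: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    status: str
    branches: pd.DataFrame  # branch path, persons, cost, qalys per arm


def icer(delta_cost: float, delta_qaly: float) -> tuple[float | None, str]:
    """Resolve the incremental ratio or a dominance status.

    Returns (value, status): a finite ratio only in the tradeoff quadrants
    (more cost for more QALYs, or savings for fewer QALYs); otherwise one of
    the dominance statuses.
    """
    dc_zero = abs(delta_cost) <= _TOL
    dq_zero = abs(delta_qaly) <= _TOL
    if dc_zero and dq_zero:
        return None, EQUIVALENT
    if dq_zero:
        return None, DOMINATED if delta_cost > 0 else DOMINATES
    if delta_qaly > 0 and delta_cost <= 0:
        return None, DOMINATES
    if delta_qaly < 0 and delta_cost >= 0:
        return None, DOMINATED
    return float(delta_cost / delta_qaly), TRADEOFF


def _discount_factors(p: ScreeningParams) -> list[float]:
    return [1.0 / (1.0 + p.discount_rate) ** t for t in range(p.followup_years)]


def _healthy_path(p: ScreeningParams) -> tuple[float, float]:
    df = _discount_factors(p)
    return 0.0, p.stage_utilities["healthy"] * sum(df)


def _cancer_path(p: ScreeningParams, stage: str) -> tuple[float, float]:
    """Per-person (cost, QALYs) for a cancer detected at `stage` in year 1."""
    df = _discount_factors(p)
    Y = p.followup_years
    if stage == TERMINAL_STAGE:
        return p.stage_costs["palliative"] * df[0], p.stage_utilities[TERMINAL_STAGE] * df[0]
    cost = p.stage_costs["treatment"][stage] * df[0]
    treat_years = min(2, Y)
    qaly = p.stage_utilities[stage] * sum(df[:treat_years])
    r = p.recurrence_rate.get(stage, 0.0)
    if Y > 2:
        # relapse assessed at end of year 2; relapsers follow the stage-IV
        # pathway in year 3, non-relapsers are healthy for the rest of the
        # horizon
        cost += r * p.stage_costs["palliative"] * df[2]
        qaly += r * p.stage_utilities[TERMINAL_STAGE] * df[2]
        qaly += (1.0 - r) * p.stage_utilities["healthy"] * sum(df[2:])
    return cost, qaly


def _stage_mix_path(p: ScreeningParams, dist: Mapping[str, float]) -> tuple[float, float]:
    cost = qaly = 0.0
    for stage, prop in dist.items():
        c, q = _cancer_path(p, stage)
        cost += prop * c
        qaly += prop * q
    return cost, qaly


def _unscreened_branches(p: ScreeningParams, persons: float, prefix: str) -> list[dict]:
    """Terminal branches for people living under usual care (no blood test):
    a background fraction gets surveillance endoscopy (early detection for
    cancers), the rest present symptomatically (late distribution, diagnostic
    endoscopy at presentation)."""
    b = p.background_endoscopy_rate
    endo = p.stage_costs["endoscopy"]
    early_c, early_q = _stage_mix_path(p, p.stage_distribution_screen)
    late_c, late_q = _stage_mix_path(p, p.stage_distribution_noscreen)
    healthy_c, healthy_q = _healthy_path(p)
    n_cancer = persons * p.cancer_prevalence
    n_healthy = persons - n_cancer
    return [
        {"path": f"{prefix}/cancer/surveillance-endoscopy", "persons": n_cancer * b,
         "cost": n_cancer * b * (endo + early_c), "qalys": n_cancer * b * early_q},
        {"path": f"{prefix}/cancer/symptomatic", "persons": n_cancer * (1 - b),
         "cost": n_cancer * (1 - b) * (endo + late_c), "qalys": n_cancer * (1 - b) * late_q},
        {"path": f"{prefix}/healthy/surveillance-endoscopy", "persons": n_healthy * b,
         "cost": n_healthy * b * (endo + healthy_c), "qalys": n_healthy * b * healthy_q},
        {"path": f"{prefix}/healthy/no-endoscopy", "persons": n_healthy * (1 - b),
         "cost": n_healthy * (1 - b) * healthy_c, "qalys": n_healthy * (1 - b) * healthy_q},
    ]


def run_decision_model(params: ScreeningParams) -> CeaResult:
    """Evaluate both arms of the screening decision tree.

    Persons across the terminal branches of each arm sum exactly to the
    cohort size, and all costs/QALYs scale linearly in it.
    """
    p = params
    p.validate()
    N = p.cohort_size
    endo = p.stage_costs["endoscopy"]
    test = p.stage_costs["test"]
    early_c, early_q = _stage_mix_path(p, p.stage_distribution_screen)
    healthy_c, healthy_q = _healthy_path(p)

    branches: list[dict] = []

    # ----- screening arm -----
    n_comp = N * p.compliance
    branches += _unscreened_branches(p, N - n_comp, "screen/noncompliant")

    n_cancer = n_comp * p.cancer_prevalence
    n_healthy = n_comp - n_cancer
    se, sp = p.test_sensitivity, p.test_specificity

    tp = n_cancer * se
    branches.append({
        "path": "screen/compliant/cancer/test-positive", "persons": tp,
        "cost": tp * (test + endo + early_c), "qalys": tp * early_q,
    })
    # false negatives re-enter usual care: same background surveillance and
    # symptomatic presentation as the comparator arm
    fn = n_cancer * (1 - se)
    for br in _unscreened_branches(replace(p, cancer_prevalence=1.0), fn, "screen/compliant/cancer/test-negative"):
        br["cost"] += br["persons"] * test
        branches.append(br)
    fp = n_healthy * (1 - sp)
    branches.append({
        "path": "screen/compliant/healthy/test-positive", "persons": fp,
        "cost": fp * (test + endo + healthy_c), "qalys": fp * healthy_q,
    })
    tn = n_healthy * sp
    for br in _unscreened_branches(replace(p, cancer_prevalence=0.0), tn, "screen/compliant/healthy/test-negative"):
        br["cost"] += br["persons"] * test
        branches.append(br)
    for br in branches:
        br["arm"] = "screening"

    # ----- no-screening arm -----
    ns_branches = _unscreened_branches(p, N, "noscreen")
    for br in ns_branches:
        br["arm"] = "no-screening"
    branches += ns_branches

    table = pd.DataFrame(branches)[["arm", "path", "persons", "cost", "qalys"]]
    # drop structurally empty sub-branches (e.g. prevalence forced to 0/1)
    table = table[table["persons"] > 0.0].reset_index(drop=True)

    cost_s = float(table.loc[table["arm"] == "screening", "cost"].sum())
    qaly_s = float(table.loc[table["arm"] == "screening", "qalys"].sum())
    cost_n = float(table.loc[table["arm"] == "no-screening", "cost"].sum())
    qaly_n = float(table.loc[table["arm"] == "no-screening", "qalys"].sum())
    dc, dq = cost_s - cost_n, qaly_s - qaly_n
    value, status = icer(dc, dq)
    return CeaResult(
        cost_screen=cost_s,
        qaly_screen=qaly_s,
        cost_noscreen=cost_n,
        qaly_noscreen=qaly_n,
        delta_cost=dc,
        delta_qaly=dq,
        icer=value,
        status=status,
        branches=table,
    )


def _set_nested(params: ScreeningParams, dotted: str, value) -> ScreeningParams:
    parts = dotted.split(".")
    if len(parts) == 1:
        return replace(params, **{parts[0]: value})
    top = parts[0]
    current = getattr(params, top)
    updated = json.loads(json.dumps(current))  # deep copy of plain mappings
    node = updated
    for key in parts[1:-1]:
        node = node[key]
    node[parts[-1]] = value
    return replace(params, **{top: updated})


def one_way_sensitivity(
    params: ScreeningParams,
    ranges: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """Re-run the model at each parameter bound, others held at base case.

    Parameter names may be dotted (e.g. ``stage_costs.palliative``).  The
    output is sorted by the spread of the ICER across each parameter's range
    (tornado-diagram order); dominance outcomes are reported as NaN ICERs.
    """
    base = run_decision_model(params)
    rows = []
    for name, (low, high) in ranges.items():
        entry = {"parameter": name, "low": low, "high": high, "icer_base": base.icer}
        for bound, value in (("icer_low", low), ("icer_high", high)):
            varied = _set_nested(params, name, value)
            try:
                varied.validate()
            except ValueError as exc:
                raise ValueError(f"bound for {name!r} invalid: {exc}") from None
            res = run_decision_model(varied)
            entry[bound] = res.icer
            entry[bound.replace("icer", "status")] = res.status
        lo, hi = entry["icer_low"], entry["icer_high"]
        entry["spread"] = abs((hi if hi is not None else 0.0) - (lo if lo is not None else 0.0))
        rows.append(entry)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("spread", ascending=False, kind="mergesort").reset_index(drop=True)
    return table
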
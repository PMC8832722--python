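"""Synthetic cohort generators with planted ground truth.

Every downstream stage of the pipeline (discovery filtering, qPCR
quantification, risk-score training, evaluation, network enrichment, the
decision model) is testable without any external download by generating

* tissue expression matrices with a shared planted set of upregulated miRNAs
  (additive Gaussian noise on the log2 scale),
* serum qPCR Ct tables with case/control Ct shifts on an 8-miRNA panel,
  stable reference targets, a detection-limit censoring mechanism and
  conventional protein markers calibrated to a target AUC via a binormal
  model, and
* toy interaction tables, gene-set collections and decision-model parameters.

Seeding: a single master seed; each stage derives an independent child seed by
hashing (stage-name, master), so stages are reproducible and independent.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .discovery import ExpressionMatrix

# The 18-candidate tissue panel: the 8 serum signature members, the 4 members
# that drop below the serum detection limit, and 6 further tissue candidates.
SERUM_PANEL_8 = [
    "miR-17", "miR-21", "miR-25", "miR-93",
    "miR-103", "miR-106b", "miR-151", "miR-181a",
]
CENSORED_4 = ["miR-182", "miR-183", "miR-18a", "miR-505"]
TISSUE_PANEL_18 = SERUM_PANEL_8 + CENSORED_4 + [
    "miR-96", "miR-130b", "miR-15b", "miR-301a", "miR-452", "miR-1246",
]

REFERENCE_IDS = ["miR-16", "miR-423", "cel-miR-39"]

STAGES = ["I", "II", "III", "IV", "esophagitis", "LGIN", "HGIN", "healthy"]

# Fraction of the planted case Ct shift expressed by each stage: invasive
# disease carries the full (or graded) shift, high-grade neoplasia a partial
# one, low-grade neoplasia and esophagitis none.
DEFAULT_STAGE_SHIFT_FRACTION = {
    "I": 0.7, "II": 0.85, "III": 1.0, "IV": 1.15,
    "esophagitis": 0.0, "LGIN": 0.0, "HGIN": 0.8, "healthy": 0.0,
}

DEFAULT_CASE_STAGES = {"I": 0.15, "II": 0.22, "III": 0.43, "IV": 0.20}


def child_seed(stage_name: str, master: int) -> int:
    """Deterministic per-stage seed below 2**31 from (stage-name, master)."""
    digest = hashlib.blake2s(f"{stage_name}:{master}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def binormal_case_mean(auc: float) -> float:
    """Case-group mean (unit variances, control mean 0) giving the target AUC.

    Under the equal-variance binormal model AUC = Phi(mu / sqrt(2)), so
    mu = sqrt(2) * Phi^-1(AUC).
    """
    if not 0.5 <= auc <= 1.0:
        raise ValueError("marker_auc values must lie in [0.5, 1.0]")
    return float(np.sqrt(2.0) * norm.ppf(auc))


# ---------------------------------------------------------------------------
# Tissue datasets


@dataclass
class TissueDesign:
    n_tumor: int = 60
    n_normal: int = 60
    n_mirna: int = 300
    planted_ids: Sequence[str] = field(default_factory=lambda: list(TISSUE_PANEL_18))
    planted_log2fc: Mapping[str, float] | float = 2.0
    noise_sd: float = 1.0
    baseline_log2: Mapping[str, float] | None = None  # default assigned at simulation
    dataset_id: str = "sim"
    # dataset-specific distractors: pass all candidate criteria but are unique
    # to this dataset (removed by the overlap), or pass DE but fail abundance
    n_decoy: int = 20
    # must exceed planted + decoys so the abundance median of the DE pool
    # falls in the low tier and the whole planted panel passes the filter
    n_low_abundance_de: int = 60
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumor", "n_normal", "n_mirna"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        n_special = len(self.planted_ids) + self.n_decoy + self.n_low_abundance_de
        if self.n_mirna < n_special:
            raise ValueError("n_mirna smaller than planted + decoy miRNAs")

    def log2fc_of(self, mirna: str) -> float:
        if isinstance(self.planted_log2fc, Mapping):
            return float(self.planted_log2fc.get(mirna, 0.0))
        return float(self.planted_log2fc)


def simulate_tissue_dataset(design: TissueDesign) -> ExpressionMatrix:
    """Simulate one log2 tissue expression matrix with planted tumor signal.

    value(i, s) = baseline_i + log2fc_i * [s is tumor and i planted/distractor]
                  + Normal(0, noise_sd).

    Planted panel miRNAs sit at a high baseline; dataset-specific decoys
    mimic them (and are eliminated only by the multi-dataset overlap), while
    low-abundance differentially expressed miRNAs populate the lower half of
    the abundance distribution so the abundance criterion is exercised.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    ds = design.dataset_id

    planted = list(design.planted_ids)
    decoys = [f"{ds}-decoy-{i:03d}" for i in range(design.n_decoy)]
    low_de = [f"{ds}-lowde-{i:03d}" for i in range(design.n_low_abundance_de)]
    n_null = design.n_mirna - len(planted) - len(decoys) - len(low_de)
    nulls = [f"miR-null-{i:04d}" for i in range(n_null)]
    mirnas = planted + decoys + low_de + nulls

    if design.baseline_log2 is not None:
        baseline = np.array([design.baseline_log2.get(m, 6.0) for m in mirnas])
    else:
        baseline = np.concatenate([
            12.0 + rng.uniform(-0.5, 0.5, len(planted)),
            12.0 + rng.uniform(-0.5, 0.5, len(decoys)),
            4.0 + rng.uniform(-0.5, 0.5, len(low_de)),
            rng.uniform(2.0, 12.0, len(nulls)),
        ])

    effect = np.array(
        [design.log2fc_of(m) if m in set(planted) else 0.0 for m in mirnas]
    )
    effect[len(planted):len(planted) + len(decoys) + len(low_de)] = (
        design.planted_log2fc if not isinstance(design.planted_log2fc, Mapping) else 2.0
    )

    n = design.n_tumor + design.n_normal
    noise = rng.normal(0.0, design.noise_sd, size=(len(mirnas), n))
    values = baseline[:, None] + noise
    values[:, : design.n_tumor] += effect[:, None]

    samples = [f"{ds}_T{i + 1:03d}" for i in range(design.n_tumor)] + [
        f"{ds}_N{i + 1:03d}" for i in range(design.n_normal)
    ]
    labels = pd.Series(
        ["tumor"] * design.n_tumor + ["normal"] * design.n_normal, index=samples
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=mirnas, columns=samples),
        labels=labels,
        dataset_id=ds,
    )


def default_tissue_designs(master_seed: int) -> list[TissueDesign]:
    """Three discovery-style datasets sharing the planted 18-miRNA panel."""
    designs = []
    for i, (ds, n_decoy) in enumerate([("tcga", 20), ("ds55856", 35), ("ds43732", 25)]):
        designs.append(
            TissueDesign(
                dataset_id=ds,
                n_decoy=n_decoy,
                seed=child_seed(f"tissue-{ds}", master_seed),
            )
        )
    return designs


# ---------------------------------------------------------------------------
# Serum cohorts


@dataclass
class SerumDesign:
    n_case: int = 100
    n_control: int = 100
    panel_ids: Sequence[str] = field(default_factory=lambda: list(SERUM_PANEL_8))
    delta_ct_shift: Mapping[str, float] | float = 1.0  # cycles; lower Ct in cases
    ct_sd: float = 1.5
    target_ct_mean: Mapping[str, float] | float = 30.0
    reference_ids: Sequence[str] = field(default_factory=lambda: ["miR-16"])
    reference_ct_mean: Mapping[str, float] | float = 21.0
    reference_ct_sd: float = 0.25
    censor_ids: Sequence[str] = field(default_factory=list)
    censor_ct_mean: float = 37.0
    detection_limit: float = 35.0
    max_cycles: float = 40.0
    undetermined_prob: float = 0.0
    stage_distribution: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "case": dict(DEFAULT_CASE_STAGES),
            "control": {"healthy": 1.0},
        }
    )
    stage_shift_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_SHIFT_FRACTION)
    )
    marker_auc: Mapping[str, float] = field(default_factory=dict)
    cohort_id: str = "serum"
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("cohort sizes must be >= 1")
        overlap = set(self.panel_ids) & set(self.reference_ids)
        if overlap:
            raise ValueError(f"panel/reference identifier collision: {sorted(overlap)}")
        for group, dist in self.stage_distribution.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"stage proportions for {group} sum to {total}, not 1")
            unknown = set(dist) - set(STAGES)
            if unknown:
                raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, auc in self.marker_auc.items():
            if not 0.5 <= auc <= 1.0:
                raise ValueError(f"marker_auc[{name}] must be in [0.5, 1.0]")
        if isinstance(self.delta_ct_shift, Mapping):
            neg = [m for m, s in self.delta_ct_shift.items() if s < 0]
            if neg:
                raise ValueError(f"delta_ct_shift must be >= 0 (upregulated markers): {neg}")
        elif self.delta_ct_shift < 0:
            raise ValueError("delta_ct_shift must be >= 0")

    def shift_of(self, mirna: str) -> float:
        if isinstance(self.delta_ct_shift, Mapping):
            return float(self.delta_ct_shift.get(mirna, 0.0))
        return float(self.delta_ct_shift)

    def base_ct_of(self, mirna: str) -> float:
        if isinstance(self.target_ct_mean, Mapping):
            return float(self.target_ct_mean.get(mirna, 30.0))
        return float(self.target_ct_mean)

    def ref_ct_of(self, ref: str) -> float:
        if isinstance(self.reference_ct_mean, Mapping):
            return float(self.reference_ct_mean.get(ref, 21.0))
        return float(self.reference_ct_mean)


def _draw_stages(rng, dist: Mapping[str, float], n: int) -> np.ndarray:
    names = sorted(dist)
    probs = np.array([dist[s] for s in names], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(names, size=n, p=probs)


def simulate_serum_cohort(design: SerumDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format Ct table and its sample metadata.

    Ct(sample, target) = target mean - shift(target) * stage fraction(sample)
    + Normal(0, ct_sd), clipped to (0, max_cycles].  Censored targets draw
    from a band above the detection limit regardless of group.  Conventional
    markers are drawn from the equal-variance binormal model calibrated to the
    requested AUC (cases N(sqrt(2) Phi^-1(AUC), 1), others N(0, 1)), then
    exponentiated so they resemble concentrations; AUC is rank-based and thus
    unchanged.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    cid = design.cohort_id

    case_ids = [f"{cid}_case_{i + 1:04d}" for i in range(design.n_case)]
    ctrl_ids = [f"{cid}_ctrl_{i + 1:04d}" for i in range(design.n_control)]
    samples = case_ids + ctrl_ids
    groups = np.array(["case"] * design.n_case + ["control"] * design.n_control)

    stages = np.concatenate([
        _draw_stages(rng, design.stage_distribution["case"], design.n_case),
        _draw_stages(rng, design.stage_distribution["control"], design.n_control),
    ])
    frac = np.array([design.stage_shift_fraction.get(s, 0.0) for s in stages])

    records = []
    censored = set(design.censor_ids)
    for target in design.panel_ids:
        if target in censored:
            ct = rng.normal(design.censor_ct_mean, 0.8, len(samples))
            ct = np.clip(ct, design.detection_limit + 0.2, design.max_cycles)
        else:
            mu = design.base_ct_of(target) - design.shift_of(target) * frac
            ct = np.clip(rng.normal(mu, design.ct_sd), 5.0, design.max_cycles)
        records.append(pd.DataFrame({"sample_id": samples, "target_id": target, "ct": ct}))
    for ref in design.reference_ids:
        ct = rng.normal(design.ref_ct_of(ref), design.reference_ct_sd, len(samples))
        records.append(pd.DataFrame({"sample_id": samples, "target_id": ref, "ct": ct}))

    ct_table = pd.concat(records, ignore_index=True)
    ct_table["ct"] = ct_table["ct"].round(4)
    if design.undetermined_prob > 0:
        mask = rng.random(len(ct_table)) < design.undetermined_prob
        ct_table["ct"] = ct_table["ct"].astype(object)
        ct_table.loc[mask, "ct"] = np.nan

    metadata = pd.DataFrame({"sample_id": samples, "group": groups, "stage": stages})
    is_case = groups == "case"
    for marker, auc in design.marker_auc.items():
        mu = binormal_case_mean(auc)
        z = rng.normal(0.0, 1.0, len(samples))
        z[is_case] += mu
        metadata[marker] = np.exp(z).round(6)
    return ct_table, metadata


# ---------------------------------------------------------------------------
# Toy network and decision-model fixtures


def toy_interactions(panel: Sequence[str], rng: np.random.Generator, n_genes: int = 60) -> pd.DataFrame:
    genes = [f"GENE{i:03d}" for i in range(n_genes)]
    rows = []
    for m in panel:
        targets = rng.choice(genes, size=rng.integers(4, 10), replace=False)
        for g in targets:
            rows.append((m, g, "validated"))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "evidence"])
    return df.drop_duplicates(["mirna_id", "gene_id"]).reset_index(drop=True)


def toy_gene_de(genes: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    lfc = rng.normal(0.0, 2.0, len(genes)).round(4)
    p_adj = np.round(10 ** rng.uniform(-6, 0, len(genes)), 6)
    return pd.DataFrame({"gene_id": genes, "log2fc": lfc, "p_adj": p_adj})


def toy_gene_sets(genes: Sequence[str], rng: np.random.Generator, n_sets: int = 8) -> dict[str, list[str]]:
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(5, max(6, len(genes) // 3)))
        members = sorted(rng.choice(genes, size=min(size, len(genes)), replace=False))
        sets[f"PATHWAY_{i:02d}"] = list(members)
    return sets


def default_cea_params() -> dict:
    """Illustrative decision-model parameters for a high-risk screening cohort
    (currency units labelled CNY in fixtures; values are package defaults, not
    published estimates)."""
    return {
        "cohort_size": 100000,
        "cancer_prevalence": 0.01,
        "compliance": 0.45,
        "test_sensitivity": 0.89,
        "test_specificity": 0.84,
        "background_endoscopy_rate": 0.10,
        "followup_years": 3,
        "stage_distribution_screen": {"I": 0.50, "II": 0.30, "III": 0.15, "IV": 0.05},
        "stage_distribution_noscreen": {"I": 0.10, "II": 0.20, "III": 0.40, "IV": 0.30},
        "stage_costs": {
            "test": 150.0,
            "endoscopy": 800.0,
            "treatment": {"I": 60000.0, "II": 90000.0, "III": 120000.0},
            "palliative": 50000.0,
        },
        "stage_utilities": {
            "healthy": 1.0, "I": 0.80, "II": 0.70, "III": 0.60, "IV": 0.30,
        },
        "recurrence_rate": {"I": 0.10, "II": 0.25, "III": 0.45},
        "discount_rate": 0.0,
        "currency": "CNY",
    }


# ---------------------------------------------------------------------------
# Fixture bundle


def default_serum_designs(master_seed: int) -> dict[str, SerumDesign]:
    """Cohort designs mirroring the study roles: an 18-target prioritization
    cohort with 4 censored targets, retrospective training/validation cohorts,
    a prospective cohort with a dual endogenous reference, and a premalignant
    cohort carrying esophagitis/LGIN/HGIN controls."""
    prioritization = SerumDesign(
        cohort_id="prioritization",
        n_case=50, n_control=50,
        panel_ids=list(SERUM_PANEL_8) + CENSORED_4 + TISSUE_PANEL_18[12:],
        censor_ids=list(CENSORED_4),
        seed=child_seed("serum-prioritization", master_seed),
    )
    training = SerumDesign(
        cohort_id="training",
        n_case=280, n_control=128,
        marker_auc={"scc_ag": 0.72, "cea": 0.60},
        seed=child_seed("serum-training", master_seed),
    )
    validation = SerumDesign(
        cohort_id="validation",
        n_case=123, n_control=42,
        marker_auc={"scc_ag": 0.72, "cea": 0.60, "cyfra21_1": 0.65, "ca72_4": 0.55},
        seed=child_seed("serum-validation", master_seed),
    )
    prospective = SerumDesign(
        cohort_id="prospective",
        n_case=89, n_control=96,
        reference_ids=["miR-16", "miR-423", "cel-miR-39"],
        reference_ct_mean={"miR-16": 21.0, "miR-423": 24.0, "cel-miR-39": 22.0},
        marker_auc={"scc_ag": 0.72, "cea": 0.60, "cyfra21_1": 0.65, "ca72_4": 0.55},
        seed=child_seed("serum-prospective", master_seed),
    )
    premalignant = SerumDesign(
        cohort_id="premalignant",
        n_case=60, n_control=67,
        stage_distribution={
            "case": dict(DEFAULT_CASE_STAGES),
            "control": {"healthy": 40 / 67, "esophagitis": 6 / 67, "LGIN": 8 / 67, "HGIN": 13 / 67},
        },
        seed=child_seed("serum-premalignant", master_seed),
    )
    return {
        "prioritization": prioritization,
        "training": training,
        "validation": validation,
        "prospective": prospective,
        "premalignant": premalignant,
    }


def make_fixture_bundle(seed: int, dest: str | Path) -> dict[str, Path]:
    """Write the complete synthetic study to `dest`; byte-identical per seed.

    Contents: three tissue TSV/metadata pairs sharing the planted 18-miRNA
    panel, five serum cohort CSV pairs, a toy miRNA-gene interaction table, a
    toy gene DE table, a toy GMT gene-set file, and decision-model parameters.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for design in default_tissue_designs(seed):
        mat = simulate_tissue_dataset(design)
        mpath = dest / f"tissue_{design.dataset_id}.tsv"
        cpath = dest / f"tissue_{design.dataset_id}_meta.csv"
        mat.to_tsv(mpath, cpath)
        written[f"tissue_{design.dataset_id}"] = mpath
        written[f"tissue_{design.dataset_id}_meta"] = cpath

    for role, design in default_serum_designs(seed).items():
        ct, meta = simulate_serum_cohort(design)
        ct_path = dest / f"serum_{role}_ct.csv"
        meta_path = dest / f"serum_{role}_meta.csv"
        out = ct.copy()
        out["ct"] = out["ct"].map(lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
        out.to_csv(ct_path, index=False)
        meta.to_csv(meta_path, index=False)
        written[f"serum_{role}_ct"] = ct_path
        written[f"serum_{role}_meta"] = meta_path

    rng = np.random.default_rng(child_seed("network", seed))
    inter = toy_interactions(TISSUE_PANEL_18, rng)
    genes = sorted(inter["gene_id"].unique())
    de = toy_gene_de(genes, rng)
    sets = toy_gene_sets(genes, rng)
    inter_path = dest / "interactions.tsv"
    de_path = dest / "gene_de.tsv"
    gmt_path = dest / "gene_sets.gmt"
    inter.to_csv(inter_path, sep="\t", index=False)
    de.to_csv(de_path, sep="\t", index=False)
    with open(gmt_path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + members) + "\n")
    written["interactions"] = inter_path
    written["gene_de"] = de_path
    written["gene_sets"] = gmt_path

    cea_path = dest / "cea_params.json"
    with open(cea_path, "w") as fh:
        json.dump(default_cea_params(), fh, indent=2, sort_keys=True)
    written["cea_params"] = cea_path
    return written
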
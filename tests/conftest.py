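import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirsign import discovery, quantification, signature, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MASTER_SEED = 1


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    dest = tmp_path_factory.mktemp("bundle")
    synthetic.make_fixture_bundle(MASTER_SEED, dest)
    return dest


@pytest.fixture(scope="session")
def tissue_matrices(bundle_dir):
    return {
        ds: discovery.ExpressionMatrix.from_tsv(
            bundle_dir / f"tissue_{ds}.tsv", bundle_dir / f"tissue_{ds}_meta.csv", dataset_id=ds
        )
        for ds in ("tcga", "ds55856", "ds43732")
    }


@pytest.fixture(scope="session")
def overlap_panel(tissue_matrices):
    panels = [
        discovery.filter_candidates(discovery.candidate_stats(mat))
        for mat in tissue_matrices.values()
    ]
    return discovery.intersect_panels(panels)


def _load_cohort(bundle_dir, role, references=("miR-16",)):
    table = quantification.CtTable.from_csv(bundle_dir / f"serum_{role}_ct.csv")
    table, _ = quantification.impute_undetermined(table)
    meta = pd.read_csv(bundle_dir / f"serum_{role}_meta.csv").set_index("sample_id")
    scheme = quantification.NormalizationScheme(reference_ids=list(references))
    expr = quantification.delta_delta_ct(table, scheme, groups=meta["group"].to_dict())
    return expr, meta


@pytest.fixture(scope="session")
def serum_study(bundle_dir):
    """Quantified serum cohorts plus a risk model trained on the training
    cohort over the 8 detectable signature miRNAs."""
    cohorts = {role: _load_cohort(bundle_dir, role) for role in ("training", "validation", "premalignant")}
    train_expr, train_meta = cohorts["training"]
    model = signature.fit_risk_model(
        train_expr, train_meta["group"], synthetic.SERUM_PANEL_8, cohort_id="training"
    )
    frame = signature.scores_frame(signature.score(model, train_expr))
    cutoff, j = signature.youden_cutoff(
        frame["probability"].to_numpy(), train_meta.loc[frame.index, "group"]
    )
    model.cutoff = signature.Cutoff(cutoff, "probability")
    return {"cohorts": cohorts, "model": model, "youden_j": j}


def scores_and_meta(serum_study, role):
    expr, meta = serum_study["cohorts"][role]
    frame = signature.scores_frame(signature.score(serum_study["model"], expr))
    return frame, meta.loc[frame.index]


def auc_by_pairs(cases, controls):
    """Exhaustive pair-enumeration AUC oracle (half credit for ties)."""
    total = 0.0
    for x in cases:
        for y in controls:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(cases) * len(controls))


def delong_variance_by_components(cases, controls):
    """Brute-force structural-components variance oracle (explicit loops)."""
    m, n = len(cases), len(controls)
    psi = [[1.0 if x > y else (0.5 if x == y else 0.0) for y in controls] for x in cases]
    v10 = [sum(row) / n for row in psi]
    v01 = [sum(psi[i][j] for i in range(m)) / m for j in range(n)]
    auc = sum(v10) / m
    s10 = sum((v - auc) ** 2 for v in v10) / (m - 1) if m > 1 else 0.0
    s01 = sum((v - auc) ** 2 for v in v01) / (n - 1) if n > 1 else 0.0
    return s10 / m + s01 / n
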
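"""miRNA-target regulatory network and gene-set over-representation analysis.

Edges come from a table of experimentally validated miRNA->gene interactions,
kept when the miRNA belongs to the candidate panel and the target gene is
strongly differentially expressed.  Over-representation of the resulting
target set in gene-set collections (GMT format) is tested with the one-sided
upper-tail hypergeometric distribution, BH-corrected across sets.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .discovery import MiRNAPanel, benjamini_hochberg


def read_interactions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    req = {"mirna_id", "gene_id"}
    if not req <= set(df.columns):
        raise ValueError(f"interaction table needs columns {sorted(req)}")
    return df.drop_duplicates(["mirna_id", "gene_id"]).reset_index(drop=True)


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a tab-separated gene-set file: name, description, members..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = fields[2:]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def build_network(
    interactions: pd.DataFrame,
    gene_de: pd.DataFrame,
    panel: MiRNAPanel | Sequence[str],
    lfc_min: float = 2.0,
    fdr_max: float = 0.01,
) -> tuple[pd.DataFrame, set[str]]:
    """Filter interactions to panel miRNAs with differentially expressed
    targets (|log2fc| > lfc_min and BH-adjusted p < fdr_max).

    Returns the surviving edge list and the unique target gene set.
    """
    if interactions.empty:
        raise ValueError("empty interaction table")
    de = gene_de.drop_duplicates("gene_id").set_index("gene_id")
    passing = set(de.index[(de["log2fc"].abs() > lfc_min) & (de["p_adj"] < fdr_max)])
    panel_ids = set(panel)
    edges = interactions[
        interactions["mirna_id"].isin(panel_ids) & interactions["gene_id"].isin(passing)
    ]
    edges = edges.drop_duplicates(["mirna_id", "gene_id"]).sort_values(
        ["mirna_id", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    return edges, set(edges["gene_id"])


def hypergeometric_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """One-sided over-representation test per gene set.

    p_raw = P(overlap >= observed) under sampling |query| genes from the
    universe without replacement, where the set is first intersected with the
    universe; sets outside [min_size, max_size] after intersection are
    skipped.  BH correction runs across all tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        k = len(members & query)
        p_raw = float(hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        rows.append({"set_name": name, "set_size": K, "overlap_size": k, "p_raw": min(p_raw, 1.0)})
    table = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap_size", "p_raw"])
    if len(table):
        table["p_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
        table = table.sort_values(["p_adj", "p_raw", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        table["p_adj"] = np.array([], dtype=float)
        table["significant"] = np.array([], dtype=bool)
    return table
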
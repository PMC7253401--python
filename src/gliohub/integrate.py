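"""Result-set integration: the key-gene report, diagnostic AUC and marker
correlations.

The key set is the intersection of the hub screen (A), the confirmed
discovery DEGs (B) and the grade-monotone replication DEGs (D); membership
in the cross-cohort survival set (C) is reported per gene rather than
enforced, so a key gene outside C is flagged, never dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._stats import correlation_pvalues, row_correlations
from .errors import DegenerateInputError, EmptyResultError

log = logging.getLogger(__name__)


def intersect_results(result_a: set[str], result_b: pd.DataFrame,
                      result_c: set[str], result_d: pd.DataFrame,
                      survival_table: pd.DataFrame | None = None,
                      connectivity: pd.Series | None = None) -> pd.DataFrame:
    """Key-gene report over A ∩ B ∩ D with C membership annotated.

    ``result_b``/``result_d`` are the screen frames indexed by gene;
    ``survival_table`` (a survival screen table) supplies RR and survival p
    columns; ``connectivity`` the subnetwork weighted degree. Genes in
    A ∩ B ∩ D but outside C are flagged via ``in_c`` = False.
    """
    set_b = set(result_b.index)
    set_d = set(result_d.index)
    universe = result_a | set_b | result_c | set_d
    if not universe:
        raise EmptyResultError("all result sets are empty")
    key = sorted(result_a & set_b & set_d)
    report = pd.DataFrame(index=pd.Index(key, name="gene"))
    report["in_a"] = True
    report["in_b"] = True
    report["in_c"] = [g in result_c for g in key]
    report["in_d"] = True
    report["direction"] = result_d.loc[key, "direction"]
    for col in ("log2fc_III_vs_II", "log2fc_IV_vs_III"):
        if col in result_d.columns:
            report[col] = result_d.loc[key, col]
    if connectivity is not None:
        report["connectivity"] = connectivity.reindex(key)
    if survival_table is not None:
        cols = survival_table.reindex(key)
        report["rr"] = cols["rr"]
        report["cox_lrt_p"] = cols["cox_lrt_p"]
        report["logrank_p"] = cols["logrank_p"]
    n_outside = int((~report["in_c"]).sum())
    if n_outside:
        log.info("%d key gene(s) fall outside the survival-consistent set C", n_outside)
    if "connectivity" in report.columns:
        report = report.sort_values("connectivity", ascending=False)
    return report


def roc_auc(expr: pd.DataFrame, gene: str, labels: pd.Series,
            positive: str = "tumor") -> float:
    """Diagnostic AUC of one gene for a binary sample label.

    Mann-Whitney formulation: the probability that a positive sample
    outranks a negative one, ties counting one half. Reported
    directionally, so a tumor-down gene can score below 0.5.
    """
    ids = [s for s in expr.columns if pd.notna(labels.get(s))]
    y = (labels.loc[ids] == positive).astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateInputError("both classes must be non-empty")
    return float(roc_auc_score(y, expr.loc[gene, ids].to_numpy(float)))


def marker_correlation(expr: pd.DataFrame, gene_set, marker_set) -> pd.DataFrame:
    """Pairwise Pearson r (and two-sided p) between key genes and markers.

    Returns a long frame (gene, marker, r, p). Missing genes are an error
    naming the absentees.
    """
    genes = list(gene_set)
    markers = list(marker_set)
    missing = [g for g in genes + markers if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from the matrix: {sorted(set(missing))[:10]}")
    n = expr.shape[1]
    r = row_correlations(expr.loc[genes].to_numpy(float),
                         expr.loc[markers].to_numpy(float))
    p = correlation_pvalues(r, n)
    rows = []
    for i, g in enumerate(genes):
        for j, m in enumerate(markers):
            rows.append({"gene": g, "marker": m, "r": float(r[i, j]), "p": float(p[i, j])})
    return pd.DataFrame(rows)
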
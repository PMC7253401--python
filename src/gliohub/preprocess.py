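"""Input handling and matrix preparation.

Reads gene-level expression matrices (genes in rows, samples in columns)
and clinical tables, quantile-normalizes across samples, removes
near-silent genes/samples, and drops outlier samples by cutting a sample
dendrogram at a height threshold.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError, EmptyResultError, FormatError

log = logging.getLogger(__name__)

VALID_GRADES = {"normal", "I", "II", "III", "IV"}
_GRADE_ALIASES = {
    "normal": "normal", "control": "normal", "n": "normal",
    "i": "I", "1": "I", "ii": "II", "2": "II",
    "iii": "III", "3": "III", "iv": "IV", "4": "IV",
    "who i": "I", "who ii": "II", "who iii": "III", "who iv": "IV",
}


def read_expression(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read an expression matrix (first column gene id, header = sample ids).

    ``dialect`` is "tsv" or "csv"; inferred from the file suffix when None.
    Duplicate gene ids are collapsed by keeping the row with the highest
    mean expression (logged). Non-numeric cells raise :class:`FormatError`
    naming the offending gene and sample.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if dialect == "csv" else "\t"
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # ragged rows, empty file
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"empty expression matrix in {path}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in {path}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        g = bad.any(axis=1).idxmax()
        s = bad.loc[g].idxmax()
        raise FormatError(f"non-numeric cell at gene {g!r}, sample {s!r} in {path}")
    if values.isna().to_numpy().any():
        g = values.isna().any(axis=1).idxmax()
        raise FormatError(f"missing value in row {g!r} of {path}")
    expr = values.astype(float)
    expr.index = expr.index.astype(str)
    expr.index.name = "gene"
    if expr.index.duplicated().any():
        dups = sorted(set(expr.index[expr.index.duplicated()]))
        log.warning("collapsing %d duplicated gene id(s) by max mean expression: %s",
                    len(dups), ", ".join(dups[:10]))
        order = expr.mean(axis=1).to_numpy()
        best: dict[str, tuple[int, float]] = {}
        for pos, (g, m) in enumerate(zip(expr.index, order)):
            if g not in best or m > best[g][1]:
                best[g] = (pos, m)
        expr = expr.iloc[[best[g][0] for g in dict.fromkeys(expr.index)]]
    return expr


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical CSV with columns sample_id, grade[, os_time, os_event, age].

    Grade strings are normalized case-insensitively ("iv" -> "IV",
    "Normal" -> "normal"). A row with os_time but no os_event is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in ("sample_id", "grade"):
        if col not in df.columns:
            raise FormatError(f"clinical table {path} lacks required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in {path}")

    def _norm_grade(g):
        key = str(g).strip().lower()
        if key in _GRADE_ALIASES:
            return _GRADE_ALIASES[key]
        raise FormatError(f"unrecognized grade {g!r} in {path}")

    df["grade"] = df["grade"].map(_norm_grade)
    for col in ("os_time", "os_event", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan
    bad = df["os_time"].notna() & df["os_event"].isna()
    if bad.any():
        sid = df.loc[bad, "sample_id"].iloc[0]
        raise FormatError(f"sample {sid!r} has os_time but no os_event in {path}")
    if (df["os_time"].dropna() < 0).any():
        raise FormatError(f"negative os_time in {path}")
    if not df["os_event"].dropna().isin([0, 1]).all():
        raise FormatError(f"os_event must be 0/1 in {path}")
    return df.reset_index(drop=True)


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common reference distribution.

    The reference is the across-sample mean of each column's sorted values.
    Ties within a sample receive the mean of the reference values their
    rank span covers, so tied inputs stay tied.
    """
    if expr.shape[1] < 2:
        raise DegenerateInputError("quantile normalization needs >= 2 samples")
    x = expr.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise DegenerateInputError("non-finite values in expression matrix")
    n_genes = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    # cumulative reference sums give O(1) means over any rank span
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        ranks = np.empty(n_genes, dtype=float)
        i = 0
        while i < n_genes:
            k = i
            while k + 1 < n_genes and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            ranks[order[i:k + 1]] = (csum[k + 1] - csum[i]) / (k + 1 - i)
            i = k + 1
        out[:, j] = ranks
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def clean_genes_samples(expr: pd.DataFrame, min_mean: float = 0.5,
                        min_variance: float = 1e-8):
    """Drop near-silent genes and samples.

    Removes genes with mean < ``min_mean`` or variance < ``min_variance``
    and samples with mean < ``min_mean``. Returns the reduced matrix plus
    the removed gene and sample id lists.
    """
    if min_mean < 0 or min_variance < 0:
        raise ValueError("thresholds must be >= 0")
    gene_mean = expr.mean(axis=1)
    gene_var = expr.var(axis=1, ddof=1)
    drop_genes = expr.index[(gene_mean < min_mean) | (gene_var < min_variance)]
    kept = expr.drop(index=drop_genes)
    if kept.shape[0] == 0:
        raise EmptyResultError("all genes removed by cleaning thresholds")
    sample_mean = kept.mean(axis=0)
    drop_samples = kept.columns[sample_mean < min_mean]
    kept = kept.drop(columns=drop_samples)
    if kept.shape[1] == 0:
        raise EmptyResultError("all samples removed by cleaning thresholds")
    if len(drop_genes) or len(drop_samples):
        log.info("cleaning removed %d gene(s) and %d sample(s)",
                 len(drop_genes), len(drop_samples))
    return kept, list(drop_genes), list(drop_samples)


def remove_outlier_samples(expr: pd.DataFrame, height_threshold: float,
                           linkage_method: str = "average"):
    """Drop samples outside the largest cluster of the sample dendrogram.

    Samples are clustered on Euclidean distance between expression profiles
    with the given linkage; cutting at ``height_threshold`` defines flat
    clusters, and everything outside the largest one is removed.
    """
    if height_threshold <= 0:
        raise ValueError("height_threshold must be > 0")
    if expr.shape[1] < 3:
        raise DegenerateInputError("outlier removal needs >= 3 samples")
    d = pdist(expr.to_numpy(dtype=float).T, metric="euclidean")
    z = hierarchy.linkage(d, method=linkage_method)
    labels = hierarchy.fcluster(z, t=height_threshold, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    if sizes.max() == 1:
        raise DegenerateInputError(
            "every sample is its own cluster at this height; raise height_threshold")
    keep_label = sizes.idxmax()
    removed = [s for s, lab in zip(expr.columns, labels) if lab != keep_label]
    if removed:
        log.info("outlier removal dropped %d sample(s): %s",
                 len(removed), ", ".join(map(str, removed[:10])))
    return expr.drop(columns=removed), removed


def align_samples(expr: pd.DataFrame, clinical: pd.DataFrame):
    """Restrict both tables to their shared sample ids (order of ``expr``).

    Dropped ids from either side are logged and returned.
    """
    clin_ids = set(clinical["sample_id"])
    shared = [s for s in expr.columns if s in clin_ids]
    if not shared:
        raise EmptyResultError("no shared sample ids between expression and clinical tables")
    dropped_expr = [s for s in expr.columns if s not in clin_ids]
    dropped_clin = [s for s in clinical["sample_id"] if s not in set(expr.columns)]
    if dropped_expr or dropped_clin:
        log.info("alignment dropped %d expression and %d clinical sample(s)",
                 len(dropped_expr), len(dropped_clin))
    clin = clinical.set_index("sample_id").loc[shared].reset_index()
    return expr[shared], clin, {"expression_only": dropped_expr, "clinical_only": dropped_clin}
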
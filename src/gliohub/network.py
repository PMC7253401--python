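"""Weighted gene co-expression network construction and module analysis.

Implements the classic weighted-network workflow: correlation similarity,
soft-threshold power selection by scale-free topology fit, topological
overlap, hierarchical module detection on 1-TOM, module eigengenes,
module-trait correlation, module membership (MM) / trait significance (GS)
scoring, hub selection by intersecting top-MM and top-GS genes, and
extraction of a key-gene subnetwork from the strongest edges.

Similarity conventions: unsigned ``S_ij = |cor(x_i, x_j)|`` and signed
``S_ij = cor(x_i, x_j)/2 + 0.5``. Adjacency is the elementwise power
``A = S^beta``; the topological overlap of genes i and j is

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_u a_iu * a_uj   (u != i, j),

with unit diagonal, so genes sharing many strong neighbours score high
even when their direct edge is modest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import correlation_pvalues, row_correlations, standardize_rows
from .errors import DegenerateInputError, NoQualifyingPowerError

log = logging.getLogger(__name__)

# module label palette in assignment order (largest module first); "grey"
# is reserved for unassigned genes
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
GREY = "grey"


def similarity(expr: pd.DataFrame, mode: str = "unsigned") -> pd.DataFrame:
    """Correlation similarity matrix of genes (rows of ``expr``)."""
    if mode not in ("unsigned", "signed"):
        raise ValueError(f"unknown similarity mode {mode!r}")
    if expr.shape[1] < 3:
        raise DegenerateInputError("similarity needs >= 3 samples")
    sd = expr.std(axis=1, ddof=1)
    if (sd == 0).any():
        gene = sd.index[(sd == 0).to_numpy()][0]
        raise DegenerateInputError(f"gene {gene!r} is constant: correlation undefined")
    r = row_correlations(expr.to_numpy(float), expr.to_numpy(float))
    s = np.abs(r) if mode == "unsigned" else r / 2.0 + 0.5
    np.fill_diagonal(s, 1.0)
    out = pd.DataFrame(s, index=expr.index, columns=expr.index)
    out.attrs["mode"] = mode
    return out


def adjacency(sim: pd.DataFrame, power: int) -> pd.DataFrame:
    """Soft-thresholded adjacency ``A = S^power`` (elementwise)."""
    if power < 1:
        raise ValueError("power must be >= 1")
    a = sim.to_numpy(float) ** power
    out = pd.DataFrame(a, index=sim.index, columns=sim.columns)
    out.attrs["power"] = int(power)
    return out


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Weighted degree k_i = sum_{j != i} A_ij."""
    a = adj.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    return pd.Series(a.sum(axis=1), index=adj.index, name="k")


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of the connectivity distribution.

    Connectivities are histogrammed into ``n_bins`` equal-width bins;
    log10(frequency) is regressed on log10(mean connectivity) over
    non-empty bins. Returns (R^2 * -sign(slope), slope): a power-law-like
    decreasing degree distribution scores near +1.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    k = connectivity(adj).to_numpy()
    if np.unique(k).size < 2:
        raise DegenerateInputError("all connectivities identical: scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        in_bin = which == b
        freq = in_bin.sum()
        if freq == 0:
            continue
        mean_k = k[in_bin].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq / k.size))
    if len(xs) < 2:
        raise DegenerateInputError("fewer than 2 usable connectivity bins")
    fit = stats.linregress(xs, ys)
    signed_r2 = fit.rvalue ** 2 * (-np.sign(fit.slope) if fit.slope != 0 else 0.0)
    return float(signed_r2), float(fit.slope)


def soft_threshold_scan(expr: pd.DataFrame, candidate_powers=range(1, 21),
                        mode: str = "unsigned", n_bins: int = 10) -> pd.DataFrame:
    """Scale-free fit and connectivity summary per candidate power."""
    sim = similarity(expr, mode=mode)
    rows = []
    for p in candidate_powers:
        adj = adjacency(sim, p)
        k = connectivity(adj)
        r2, slope = scale_free_fit(adj, n_bins=n_bins)
        rows.append({"power": int(p), "r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(k.median())})
    return pd.DataFrame(rows)


def pick_power(expr: pd.DataFrame, candidate_powers=range(1, 21),
               r2_min: float = 0.9, mode: str = "unsigned",
               n_bins: int = 10) -> tuple[int, pd.DataFrame]:
    """Choose the soft threshold: among powers whose signed fit reaches
    ``r2_min``, the one with the largest mean connectivity (the smallest
    qualifying power, since mean connectivity falls monotonically).
    """
    powers = list(candidate_powers)
    if not powers or sorted(powers) != powers:
        raise ValueError("candidate_powers must be non-empty and ascending")
    scan = soft_threshold_scan(expr, powers, mode=mode, n_bins=n_bins)
    ok = scan[scan["r2"] >= r2_min]
    if ok.empty:
        raise NoQualifyingPowerError(
            f"no candidate power reaches scale-free fit R^2 >= {r2_min}", scan=scan)
    best = ok.loc[ok["mean_k"].idxmax()]
    return int(best["power"]), scan


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency (unit diagonal)."""
    a = adj.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # l_ij: diagonal of a is 0, so u = i, j contribute nothing
    denom = np.minimum.outer(k, k) + 1.0 - a
    omega = (shared + a) / denom
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(omega, index=adj.index, columns=adj.columns)


@dataclass
class ModuleAssignment:
    """Gene -> module label map; ``grey`` marks unassigned genes."""

    labels: pd.Series

    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    mapping = {}
    for rank, old in enumerate(sizes.index):
        mapping[old] = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) \
            else f"module_{rank + 1}"
    return labels.map(lambda m: mapping.get(m, GREY))


def _select_cut_height(z: np.ndarray, min_module_size: int) -> float:
    """Pick the tree-cut height that maximizes usable module structure.

    Candidate heights are quantiles of the merge heights; the height
    forming the most clusters of at least ``min_module_size`` wins, ties
    broken by genes covered by such clusters and then by the larger
    height. Absolute 1-TOM heights vary strongly with the soft power, so
    a data-driven height is far more stable than a fixed fraction of the
    root height.
    """
    heights = z[:, 2]
    cands = np.unique(np.quantile(heights, np.linspace(0.5, 0.999, 40)))
    best_score, best_h = None, None
    for h in cands:
        raw = hierarchy.fcluster(z, t=h, criterion="distance")
        sizes = np.bincount(raw)
        big = sizes[sizes >= min_module_size]
        score = (len(big), int(big.sum()), h)
        if best_score is None or score > best_score:
            best_score, best_h = score, h
    return float(best_h)


def detect_modules(tom_matrix: pd.DataFrame, min_module_size: int = 30,
                   merge_cut: float = 0.25, expr: pd.DataFrame | None = None,
                   cut_height_frac: float | None = None,
                   reassign_kme_min: float = 0.3,
                   linkage_method: str = "average") -> ModuleAssignment:
    """Cluster genes on 1-TOM dissimilarity into modules.

    Average-linkage hierarchical clustering of ``1 - TOM``; the tree is
    cut either at a data-driven height (default: the candidate height
    yielding the most clusters of at least ``min_module_size``) or, when
    ``cut_height_frac`` is given, at that fraction of the maximum merge
    height. Clusters below ``min_module_size`` are relabelled grey; when
    ``expr`` is supplied, modules whose eigengenes are closer than
    ``merge_cut`` (dissimilarity ``1 - cor``) are merged iteratively, and
    every gene is then reassigned to the module whose eigengene it
    correlates with most (|kME|), staying grey below
    ``reassign_kme_min``. Labels are assigned by decreasing module size
    from the standard colour palette.
    """
    genes = tom_matrix.index
    if len(genes) < 2 * min_module_size:
        raise DegenerateInputError("need at least 2 * min_module_size genes")
    d = 1.0 - tom_matrix.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    dvec = squareform(d, checks=False)
    if np.allclose(dvec, dvec[0]):
        log.warning("degenerate TOM (all dissimilarities equal): single module")
        return ModuleAssignment(pd.Series(MODULE_COLORS[0], index=genes, name="module"))
    z = hierarchy.linkage(dvec, method=linkage_method)
    if cut_height_frac is not None:
        cut = cut_height_frac * z[:, 2].max()
    else:
        cut = _select_cut_height(z, min_module_size)
    raw = hierarchy.fcluster(z, t=cut, criterion="distance")
    labels = pd.Series([f"c{c}" for c in raw], index=genes, name="module")
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = GREY
    if (labels == GREY).all():
        log.warning("no cluster reached min_module_size=%d; all genes grey", min_module_size)
        return ModuleAssignment(labels)
    if expr is not None and merge_cut > 0:
        labels = _merge_close_modules(expr, labels, merge_cut)
    if expr is not None and reassign_kme_min is not None:
        labels = _reassign_by_kme(expr, labels, reassign_kme_min)
        # a cluster that melts below the size floor under reassignment was
        # never a real module
        sizes = labels.value_counts()
        labels[labels.isin(sizes.index[sizes < min_module_size])] = GREY
    return ModuleAssignment(_relabel_by_size(labels))


def _reassign_by_kme(expr: pd.DataFrame, labels: pd.Series,
                     kme_min: float) -> pd.Series:
    """Assign each gene to the module whose eigengene it tracks best.

    Genes whose best |kME| falls below ``kme_min`` are left grey. This
    rescues genuinely co-expressed genes that a hard tree cut strands in
    grey, while uncorrelated genes stay unassigned.
    """
    asg = ModuleAssignment(labels)
    if not asg.modules():
        return labels
    me = module_eigengenes(expr, asg)
    kme = np.abs(row_correlations(expr.to_numpy(float), me.to_numpy(float).T))
    best = kme.argmax(axis=1)
    best_val = kme.max(axis=1)
    mods = np.array(list(me.columns), dtype=object)
    new = np.where(best_val >= kme_min, mods[best], GREY)
    moved = int((new != labels.to_numpy()).sum())
    if moved:
        log.info("kME reassignment moved %d gene(s)", moved)
    return pd.Series(new, index=labels.index, name="module")


def _merge_close_modules(expr: pd.DataFrame, labels: pd.Series,
                         merge_cut: float) -> pd.Series:
    """Iteratively merge the closest eigengene pair while 1 - cor < merge_cut."""
    labels = labels.copy()
    while True:
        mods = [m for m in labels.unique() if m != GREY]
        if len(mods) < 2:
            return labels
        me = module_eigengenes(expr, ModuleAssignment(labels))
        e = me.to_numpy(float).T  # modules x samples
        r = row_correlations(e, e)
        diss = 1.0 - r
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            return labels
        keep, absorb = me.columns[i], me.columns[j]
        log.info("merging module %s into %s (eigengene dissimilarity %.3f)",
                 absorb, keep, diss[i, j])
        labels[labels == absorb] = keep


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Returns a samples x modules frame of unit-norm eigengenes, each sign-
    oriented so the summed correlation with its member genes is positive.
    """
    cols = {}
    for m in assignment.modules():
        members = assignment.members(m)
        if len(members) < 2:
            raise DegenerateInputError(f"module {m!r} has fewer than 2 genes")
        sub = standardize_rows(expr.loc[members].to_numpy(float))
        # first right-singular vector spans the dominant sample-space trend
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        if row_correlations(sub, e[None, :]).sum() < 0:
            e = -e
        cols[m] = e
    return pd.DataFrame(cols, index=expr.columns)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p for every module x trait pair.

    Missing trait values are dropped pairwise; a trait constant over the
    complete pairs is an error.
    """
    rows = []
    for m in eigengenes.columns:
        for t in traits.columns:
            e = eigengenes[m].to_numpy(float)
            v = traits[t].to_numpy(float)
            mask = np.isfinite(v)
            if mask.sum() < 3:
                raise DegenerateInputError(f"trait {t!r} has fewer than 3 complete pairs")
            if np.std(v[mask]) == 0:
                raise DegenerateInputError(f"trait {t!r} is constant")
            r = float(np.corrcoef(e[mask], v[mask])[0, 1])
            p = float(correlation_pvalues(np.array(r), int(mask.sum())))
            rows.append({"module": m, "trait": t, "r": r, "p": p, "n": int(mask.sum())})
    return pd.DataFrame(rows)


def membership_and_significance(expr: pd.DataFrame, eigengenes: pd.DataFrame,
                                trait: pd.Series) -> dict[str, pd.DataFrame]:
    """Module membership (MM) and trait significance (GS) per gene.

    MM_m = cor(gene, eigengene_m); GS = cor(gene, trait); all Pearson with
    t-based two-sided p-values. Returns {"mm", "mm_p", "gs"}: MM frames are
    genes x modules, the GS frame has columns (gs, p).
    """
    x = expr.to_numpy(float)
    n = x.shape[1]
    mm = row_correlations(x, eigengenes.to_numpy(float).T)
    mm_p = correlation_pvalues(mm, n)
    t = trait.to_numpy(float)
    if np.std(t) == 0:
        raise DegenerateInputError("trait is constant")
    gs = row_correlations(x, t[None, :]).ravel()
    gs_p = correlation_pvalues(gs, n).ravel()
    mods = list(eigengenes.columns)
    return {
        "mm": pd.DataFrame(mm, index=expr.index, columns=mods),
        "mm_p": pd.DataFrame(mm_p, index=expr.index, columns=mods),
        "gs": pd.DataFrame({"gs": gs, "p": gs_p}, index=expr.index),
    }


def pick_trait_modules(module_trait: pd.DataFrame, trait: str,
                       n_top: int = 4, p_max: float = 0.05) -> list[str]:
    """Top modules by |r| with a trait, keeping only p < p_max (grey excluded).

    Ties in |r| break by smaller p, then label order. Returns fewer than
    ``n_top`` (logged) when fewer qualify.
    """
    sub = module_trait[(module_trait["trait"] == trait)
                       & (module_trait["module"] != GREY)].copy()
    sub = sub[sub["p"] < p_max]
    sub["abs_r"] = sub["r"].abs()
    sub = sub.sort_values(["abs_r", "p", "module"],
                          ascending=[False, True, True], kind="mergesort")
    chosen = list(sub["module"].head(n_top))
    if len(chosen) < n_top:
        log.info("only %d of %d requested modules significant for trait %r",
                 len(chosen), n_top, trait)
    return chosen


def select_module_hubs(scores: dict[str, pd.DataFrame], assignment: ModuleAssignment,
                       chosen_modules: list[str], top_frac: float = 0.2) -> set[str]:
    """Hub genes: per module, intersect the top |MM| and top |GS| fractions.

    For each chosen module the top ``ceil(top_frac * size)`` members by
    |MM| in that module are intersected with the top same-count members by
    |GS|; the union over modules is returned. Absolute values are ranked so
    down-regulated hubs are selectable symmetrically.
    """
    if not chosen_modules:
        raise ValueError("chosen_modules must be non-empty")
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    hubs: set[str] = set()
    for m in chosen_modules:
        members = assignment.members(m)
        if len(members) == 0:
            raise KeyError(f"module {m!r} absent from assignment")
        n_top = int(np.ceil(top_frac * len(members)))
        mm_rank = scores["mm"].loc[members, m].abs().sort_values(ascending=False)
        gs_rank = scores["gs"].loc[members, "gs"].abs().sort_values(ascending=False)
        top_mm = set(mm_rank.index[:n_top])
        top_gs = set(gs_rank.index[:n_top])
        hubs |= top_mm & top_gs
    return hubs


def extract_subnetwork(tom_matrix: pd.DataFrame, seed_genes, edge_top_frac: float = 0.01,
                       node_top_frac: float = 0.3):
    """Key-gene subnetwork from the globally strongest TOM edges.

    Keeps the top ``edge_top_frac`` of all edges by weight, restricts to the
    seeds plus their neighbours in the kept graph, ranks those nodes by
    within-subgraph weighted degree and keeps the top ``node_top_frac``.
    Returns (edge table among kept nodes, connectivity of subgraph nodes).
    """
    genes = list(tom_matrix.index)
    seed_genes = list(seed_genes)
    missing = [g for g in seed_genes if g not in set(genes)]
    if missing:
        raise KeyError(f"seed genes not in network: {missing[:5]}")
    w = tom_matrix.to_numpy(float)
    iu, ju = np.triu_indices(len(genes), k=1)
    weights = w[iu, ju]
    n_keep = int(np.ceil(edge_top_frac * weights.size))
    order = np.argsort(-weights, kind="mergesort")[:n_keep]
    kept = pd.DataFrame({
        "gene_a": [genes[i] for i in iu[order]],
        "gene_b": [genes[j] for j in ju[order]],
        "weight": weights[order],
    })
    seeds = set(seed_genes)
    touches = kept["gene_a"].isin(seeds) | kept["gene_b"].isin(seeds)
    if not touches.any():
        log.warning("no kept edge touches a seed gene; empty subnetwork")
        return kept.iloc[:0], pd.Series(dtype=float, name="connectivity")
    neighbours = set(kept.loc[touches, "gene_a"]) | set(kept.loc[touches, "gene_b"])
    nodes = seeds | neighbours
    sub = kept[kept["gene_a"].isin(nodes) & kept["gene_b"].isin(nodes)]
    conn = pd.Series(0.0, index=sorted(nodes), name="connectivity")
    for a, b, wt in sub.itertuples(index=False):
        conn[a] += wt
        conn[b] += wt
    n_nodes = int(np.ceil(node_top_frac * len(conn)))
    top_nodes = set(conn.sort_values(ascending=False).index[:n_nodes])
    edges = sub[sub["gene_a"].isin(top_nodes) & sub["gene_b"].isin(top_nodes)]
    return edges.reset_index(drop=True), conn.sort_values(ascending=False)
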
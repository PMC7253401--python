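"""Differential expression: moderated t-tests, trend filters and the
grade chi-square confirmation.

The two-group test is an empirical-Bayes moderated t: per-gene pooled
variances are shrunk toward a common prior whose scale ``s0^2`` and
degrees of freedom ``d0`` are estimated by moment matching of the log
variances (digamma/trigamma inversion). The moderated statistic

    t_g = (mean2 - mean1) / (s_tilde_g * sqrt(1/n1 + 1/n2)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

is referred to a t distribution on ``d0 + d_g`` degrees of freedom. With
``d0 = 0`` the test reduces to the ordinary pooled two-sample t; with
``d0`` infinite every gene is tested against the common variance.

Screens follow the study design for grade-structured cohorts: a discovery
contrast set (tumor vs normal, high vs low grade) with a grade chi-square
confirmation, and a replication contrast set (III vs II, IV vs III)
without one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateInputError

log = logging.getLogger(__name__)

HIGH_GRADES = ("III", "IV")
LOW_GRADES = ("I", "II")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moment matching of log s^2: under the hierarchical model the residuals
    ``e_g = log s_g^2 - digamma(df/2) + log(df/2)`` have variance
    ``trigamma(df/2) + trigamma(d0/2)``; the excess over ``trigamma(df/2)``
    is inverted through the trigamma function. A non-positive excess means
    the variances are effectively exchangeable and ``d0`` is infinite.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if not ok.any():
        raise DegenerateInputError("all gene variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    if e.size < 2:
        return np.inf, float(np.exp(emean))
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_ttest(expr: pd.DataFrame, groups: pd.Series,
                    group1: str, group2: str,
                    d0_override: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per gene.

    ``groups`` maps sample id -> label; log2FC is group2 minus group1.
    ``d0_override`` pins the prior degrees of freedom (0 recovers the
    classical pooled t; ``inf`` tests against the common variance).
    Returns a frame with columns log2fc, t, p, direction.
    """
    ids1 = [s for s in expr.columns if groups.get(s) == group1]
    ids2 = [s for s in expr.columns if groups.get(s) == group2]
    n1, n2 = len(ids1), len(ids2)
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError(
            f"need >= 2 samples per group (got {group1}: {n1}, {group2}: {n2})")
    x1 = expr[ids1].to_numpy(float)
    x2 = expr[ids2].to_numpy(float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    s2 = ss / df
    if d0_override is None:
        d0, s0_sq = fit_variance_prior(s2, df)
    elif np.isinf(d0_override):
        d0, (_, s0_sq) = np.inf, fit_variance_prior(s2, df)
    else:
        d0, s0_sq = float(d0_override), np.nan
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    if (s2_post == 0).all():
        raise DegenerateInputError("all genes have zero variance")
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / se
    df_total = d0 + df
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    out = pd.DataFrame({"log2fc": m2 - m1, "t": t, "p": p}, index=expr.index)
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out.attrs.update({"d0": float(d0), "s0_sq": float(s0_sq) if np.isfinite(d0) or d0_override is None else float(s0_sq),
                      "df_residual": float(df), "n1": n1, "n2": n2,
                      "contrast": f"{group2} vs {group1}"})
    return out


def filter_degs(table: pd.DataFrame, p_max: float = 0.001,
                lfc_min: float = 1.0) -> tuple[set[str], set[str]]:
    """Split a DE table into (up, down) gene sets at strict thresholds.

    A gene qualifies with p strictly below ``p_max`` and |log2FC| strictly
    above ``lfc_min``; boundary equality is excluded.
    """
    if p_max <= 0 or lfc_min <= 0:
        raise ValueError("thresholds must be > 0")
    sig = table["p"] < p_max
    up = set(table.index[sig & (table["log2fc"] > lfc_min)])
    down = set(table.index[sig & (table["log2fc"] < -lfc_min)])
    return up, down


def consistent_trend(degs_a: tuple[set[str], set[str]],
                     degs_b: tuple[set[str], set[str]]) -> tuple[set[str], set[str]]:
    """Genes moving the same way in two contrasts: (up & up, down & down).

    Genes significant in both but with opposite trends are counted and
    logged, mirroring the raw-intersection vs consistent-trend distinction.
    """
    up = degs_a[0] & degs_b[0]
    down = degs_a[1] & degs_b[1]
    opposite = (degs_a[0] & degs_b[1]) | (degs_a[1] & degs_b[0])
    if opposite:
        log.info("dropped %d gene(s) with opposite trends between contrasts", len(opposite))
    return up, down


def grade_chisq(expr: pd.DataFrame, gene: str, grade_groups: pd.Series,
                n_bins: int = 3) -> tuple[float, float]:
    """Chi-square of expression tertile (equal-width bins) vs grade group.

    The gene's expression range [min, max] is divided into ``n_bins``
    equal-width intervals (right-open except the last); the resulting
    bins x {high, low} contingency table is tested by Pearson chi-square
    without continuity correction. Empty bin rows are dropped with the
    degrees of freedom adjusted (logged).
    """
    labelled = [s for s in expr.columns if pd.notna(grade_groups.get(s))]
    if len(labelled) < 6:
        raise DegenerateInputError("need >= 6 labelled samples")
    x = expr.loc[gene, labelled].to_numpy(float)
    g = grade_groups.loc[labelled].to_numpy()
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise DegenerateInputError(f"gene {gene!r} has constant expression")
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise DegenerateInputError("grade_groups must have exactly 2 levels")
    table = np.zeros((n_bins, 2))
    for b, lab in zip(bins, g):
        table[b, levels.index(lab)] += 1
    empty = table.sum(axis=1) == 0
    if empty.any():
        log.info("gene %s: dropped %d empty expression bin(s)", gene, int(empty.sum()))
        table = table[~empty]
    if table.shape[0] < 2:
        raise DegenerateInputError(f"gene {gene!r}: fewer than 2 occupied bins")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def make_screen_groups(clinical: pd.DataFrame) -> dict[str, pd.Series]:
    """Sample -> group labels for the standard grade contrasts.

    Contrasts: tumor vs normal, high (III/IV) vs low (I/II) among tumors,
    III vs II, IV vs III. Samples outside a contrast carry NaN.
    """
    g = clinical.set_index("sample_id")["grade"]
    tumor_normal = g.map(lambda x: "normal" if x == "normal" else "tumor")
    high_low = g.map(lambda x: "high" if x in HIGH_GRADES
                     else ("low" if x in LOW_GRADES else np.nan))
    iii_ii = g.map(lambda x: x if x in ("II", "III") else np.nan)
    iv_iii = g.map(lambda x: x if x in ("III", "IV") else np.nan)
    return {"tumor_vs_normal": tumor_normal, "high_vs_low": high_low,
            "III_vs_II": iii_ii, "IV_vs_III": iv_iii}


def build_result_b(expr: pd.DataFrame, clinical: pd.DataFrame,
                   p_max: float = 0.001, lfc_min: float = 1.0,
                   n_bins: int = 3) -> pd.DataFrame:
    """Discovery-cohort screen: trend-consistent DEGs confirmed by the
    grade chi-square.

    Intersects DEG(tumor vs normal) with DEG(high vs low) requiring the
    same direction, then keeps genes whose equal-width-tertile chi-square
    against high/low grade reaches p < ``p_max``. Returns a frame indexed
    by gene with columns direction, chisq, chisq_p.
    """
    groups = make_screen_groups(clinical)
    if (groups["tumor_vs_normal"] == "normal").sum() == 0:
        raise DegenerateInputError("discovery screen needs normal samples")
    deg_tn = moderated_ttest(expr, groups["tumor_vs_normal"], "normal", "tumor")
    deg_hl = moderated_ttest(expr, groups["high_vs_low"], "low", "high")
    up, down = consistent_trend(filter_degs(deg_tn, p_max, lfc_min),
                                filter_degs(deg_hl, p_max, lfc_min))
    rows = []
    for gene in sorted(up | down):
        stat, p = grade_chisq(expr, gene, groups["high_vs_low"], n_bins=n_bins)
        if p < p_max:
            rows.append({"gene": gene, "direction": "up" if gene in up else "down",
                         "chisq": stat, "chisq_p": p})
    out = pd.DataFrame(rows, columns=["gene", "direction", "chisq", "chisq_p"])
    out = out.set_index("gene")
    out.attrs["n_trend_consistent"] = len(up | down)
    return out


def build_result_d(expr: pd.DataFrame, clinical: pd.DataFrame,
                   p_max: float = 0.001, lfc_min: float = 1.0) -> pd.DataFrame:
    """Replication-cohort screen: grade-monotone DEGs, no chi-square stage.

    Intersects DEG(III vs II) with DEG(IV vs III) requiring the same
    direction. Returns a frame indexed by gene with the two log2FCs.
    """
    groups = make_screen_groups(clinical)
    for grade in ("II", "III", "IV"):
        if (clinical["grade"] == grade).sum() == 0:
            raise DegenerateInputError(f"replication screen needs grade {grade} samples")
    deg_32 = moderated_ttest(expr, groups["III_vs_II"], "II", "III")
    deg_43 = moderated_ttest(expr, groups["IV_vs_III"], "III", "IV")
    up, down = consistent_trend(filter_degs(deg_32, p_max, lfc_min),
                                filter_degs(deg_43, p_max, lfc_min))
    genes = sorted(up | down)
    out = pd.DataFrame({
        "direction": ["up" if g in up else "down" for g in genes],
        "log2fc_III_vs_II": deg_32.loc[genes, "log2fc"],
        "log2fc_IV_vs_III": deg_43.loc[genes, "log2fc"],
    }, index=pd.Index(genes, name="gene"))
    return out
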
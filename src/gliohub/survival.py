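"""Expression-stratified survival screen.

Each gene splits the cohort into a low-expression group (bottom 30% by
default) and a high-expression group (the rest); the groups are compared
by the two-group log-rank test, a single-covariate Cox likelihood-ratio
test, a 2x2 death/alive chi-square, and the mortality-ratio relative risk

    RR = (deaths_high / n_high) / (deaths_low / n_low),

with RR > 1 read as high expression promoting death. A gene is carried
forward when significant, with the same RR direction, in two independent
cohorts.

The log-rank and Cox routines are written directly on the risk-set
algebra (hypergeometric moments per event time; Breslow partial
likelihood with Newton-Raphson) so a screen over thousands of genes stays
cheap; they are cross-checked against standard survival libraries in the
test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

log = logging.getLogger(__name__)


def split_high_low(expr: pd.DataFrame, gene: str, low_frac: float = 0.3) -> pd.Series:
    """Label samples 'low' (bottom ``floor(low_frac * n)`` by expression)
    or 'high'; ties at the boundary break by sample id for determinism."""
    if not 0 < low_frac < 1:
        raise ValueError("low_frac must lie in (0, 1)")
    values = expr.loc[gene]
    if values.nunique() == 1:
        raise DegenerateInputError(f"gene {gene!r} has constant expression: split undefined")
    order = sorted(values.index, key=lambda s: (values[s], str(s)))
    n_low = int(math.floor(low_frac * len(order)))
    labels = pd.Series("high", index=values.index, name="group")
    labels[order[:n_low]] = "low"
    return labels


def _two_group_arrays(time, event, groups):
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    g = np.asarray(groups)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise DegenerateInputError(f"need exactly 2 groups, got {levels}")
    if set(levels) == {"high", "low"}:
        levels = ["low", "high"]  # beta > 0 means high expression raises hazard
    x = (g == levels[1]).astype(float)  # indicator of the second level
    if event.sum() == 0:
        raise DegenerateInputError("no events observed")
    return time, event, x, levels


def logrank(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic on 1 df, p).

    At each distinct event time the observed events in group one are
    compared with their hypergeometric expectation given the risk sets;
    the squared standardized sum is referred to chi-square with 1 df.
    """
    time, event, x, _ = _two_group_arrays(time, event, groups)
    order = np.argsort(time, kind="mergesort")
    time, event, x = time[order], event[order], x[order]
    n = len(time)
    event_times = np.unique(time[event == 1])
    obs_minus_exp = 0.0
    var_sum = 0.0
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        n1_t = x[at_risk].sum()
        dying = (time == t) & (event == 1)
        d_t = dying.sum()
        d1_t = x[dying].sum()
        obs_minus_exp += d1_t - d_t * n1_t / n_t
        if n_t > 1:
            var_sum += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    if var_sum == 0:
        return 0.0, 1.0
    stat = obs_minus_exp ** 2 / var_sum
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _breslow_loglik(beta: float, d1, d_tot, n0_risk, n1_risk) -> tuple[float, float, float]:
    """Breslow partial log-likelihood and derivatives for one binary covariate.

    Arrays are per distinct event time: events in group one, total events,
    and risk-set counts per group.
    """
    eb = np.exp(beta)
    denom = n0_risk + n1_risk * eb
    loglik = float(np.sum(beta * d1 - d_tot * np.log(denom)))
    mu = n1_risk * eb / denom           # expected covariate in risk set
    grad = float(np.sum(d1 - d_tot * mu))
    hess = float(-np.sum(d_tot * mu * (1 - mu)))
    return loglik, grad, hess


def cox_group_lrt(time, event, groups, max_iter: int = 50,
                  tol: float = 1e-8) -> tuple[float, float, float, bool]:
    """Cox proportional hazards for one binary covariate (Breslow ties).

    Returns (beta, LRT statistic, p, converged). The likelihood-ratio
    statistic 2*(l(beta_hat) - l(0)) is referred to chi-square on 1 df.
    Monotone likelihoods (e.g. complete separation) are flagged as
    non-converged and evaluated at the last iterate, logged.
    """
    time, event, x, _ = _two_group_arrays(time, event, groups)
    event_times = np.unique(time[event == 1])
    d1 = np.empty(event_times.size)
    d_tot = np.empty(event_times.size)
    n0_risk = np.empty(event_times.size)
    n1_risk = np.empty(event_times.size)
    for i, t in enumerate(event_times):
        at_risk = time >= t
        dying = (time == t) & (event == 1)
        n1_risk[i] = x[at_risk].sum()
        n0_risk[i] = at_risk.sum() - n1_risk[i]
        d1[i] = x[dying].sum()
        d_tot[i] = dying.sum()
    ll0, _, _ = _breslow_loglik(0.0, d1, d_tot, n0_risk, n1_risk)
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik(beta, d1, d_tot, n0_risk, n1_risk)
        if abs(grad) < tol:
            converged = True
            break
        if hess >= 0:  # flat direction; cannot step
            break
        step = grad / hess
        new_beta = beta - step
        if abs(new_beta) > 25:  # monotone likelihood guard
            beta = float(np.clip(new_beta, -25, 25))
            break
        beta = new_beta
    if abs(beta) > 10:  # effectively monotone likelihood (separation)
        converged = False
    ll_hat, _, _ = _breslow_loglik(beta, d1, d_tot, n0_risk, n1_risk)
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    if not converged:
        log.info("Cox fit did not converge (monotone likelihood?); beta=%.3f at last iterate", beta)
    return float(beta), float(lrt), p, converged


def relative_risk(event, groups) -> tuple[float, str]:
    """Mortality-ratio RR of the high- over the low-expression group.

    RR = (deaths_high/n_high) / (deaths_low/n_low). A zero low-group
    mortality gives an undefined RR, reported as +inf with a warning and a
    direction label of 'undefined'. Returns (rr, direction) with direction
    in {'high_risk', 'low_risk', 'null', 'undefined'}.
    """
    event = np.asarray(event, float)
    g = np.asarray(groups)
    for lab in ("low", "high"):
        if (g == lab).sum() == 0:
            raise DegenerateInputError(f"empty {lab!r} group")
    mort_high = event[g == "high"].mean()
    mort_low = event[g == "low"].mean()
    if mort_low == 0:
        log.warning("zero low-group mortality: RR undefined")
        return float("inf"), "undefined"
    rr = mort_high / mort_low
    direction = "high_risk" if rr > 1 else ("low_risk" if rr < 1 else "null")
    return float(rr), direction


def death_chisq(event, groups) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) of the 2x2
    expression-group x death/alive table."""
    event = np.asarray(event, float)
    g = np.asarray(groups)
    table = np.array([
        [((g == "low") & (event == 0)).sum(), ((g == "low") & (event == 1)).sum()],
        [((g == "high") & (event == 0)).sum(), ((g == "high") & (event == 1)).sum()],
    ], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("death chi-square needs positive margins")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


@dataclass
class SurvivalScreen:
    """Per-gene survival screen results plus the settings that made them."""

    table: pd.DataFrame
    low_frac: float
    p_max: float
    test: str


def screen_survival(expr: pd.DataFrame, clinical: pd.DataFrame,
                    low_frac: float = 0.3, p_max: float = 0.001,
                    test: str = "logrank") -> SurvivalScreen:
    """Run the 30/70 split survival screen over every gene.

    ``test`` ('logrank' or 'cox') chooses which p-value gates the
    ``significant`` flag. Samples lacking survival data are dropped; genes
    with undefined splits (constant expression) are skipped and logged.
    """
    if test not in ("logrank", "cox"):
        raise ValueError("test must be 'logrank' or 'cox'")
    clin = clinical.dropna(subset=["os_time", "os_event"])
    usable = [s for s in expr.columns if s in set(clin["sample_id"])]
    if len(usable) < 10:
        raise DegenerateInputError("survival screen needs >= 10 samples with follow-up")
    sub = expr[usable]
    meta = clin.set_index("sample_id").loc[usable]
    time = meta["os_time"].to_numpy(float)
    event = meta["os_event"].to_numpy(float)
    rows = []
    skipped = []
    for gene in sub.index:
        try:
            labels = split_high_low(sub, gene, low_frac=low_frac)
        except DegenerateInputError:
            skipped.append(gene)
            continue
        g = labels.loc[usable].to_numpy()
        lr_stat, lr_p = logrank(time, event, g)
        beta, _, cox_p, _ = cox_group_lrt(time, event, g)
        rr, rr_dir = relative_risk(event, g)
        try:
            chi, chi_p = death_chisq(event, g)
        except DegenerateInputError:
            chi, chi_p = np.nan, np.nan
        rows.append({
            "gene": gene,
            "n_low": int((g == "low").sum()), "n_high": int((g == "high").sum()),
            "deaths_low": int(event[g == "low"].sum()),
            "deaths_high": int(event[g == "high"].sum()),
            "rr": rr, "rr_direction": rr_dir, "cox_beta": beta,
            "logrank_p": lr_p, "cox_lrt_p": cox_p, "death_chisq_p": chi_p,
        })
    if skipped:
        log.info("survival screen skipped %d gene(s) with undefined splits", len(skipped))
    table = pd.DataFrame(rows).set_index("gene")
    gate = table["logrank_p"] if test == "logrank" else table["cox_lrt_p"]
    table["significant"] = gate < p_max
    return SurvivalScreen(table=table, low_frac=low_frac, p_max=p_max, test=test)


def cross_dataset_consistent(screen_x: SurvivalScreen, screen_y: SurvivalScreen,
                             p_max: float = 0.001,
                             chisq_p_max: float = 0.001) -> set[str]:
    """Genes prognostic in both cohorts with the same risk direction.

    Requires the gating test's p < ``p_max`` in both screens, the
    death/alive chi-square p < ``chisq_p_max`` in both, and matching RR
    direction (both > 1 or both < 1). Undefined-RR and opposite-direction
    genes are excluded and counted in the log.
    """
    shared = screen_x.table.index.intersection(screen_y.table.index)
    tx = screen_x.table.loc[shared]
    ty = screen_y.table.loc[shared]
    gx = tx["logrank_p"] if screen_x.test == "logrank" else tx["cox_lrt_p"]
    gy = ty["logrank_p"] if screen_y.test == "logrank" else ty["cox_lrt_p"]
    sig = (gx < p_max) & (gy < p_max) \
        & (tx["death_chisq_p"] < chisq_p_max) & (ty["death_chisq_p"] < chisq_p_max)
    defined = tx["rr_direction"].isin(["high_risk", "low_risk"]) \
        & ty["rr_direction"].isin(["high_risk", "low_risk"])
    same_dir = tx["rr_direction"] == ty["rr_direction"]
    n_opposite = int((sig & defined & ~same_dir).sum())
    if n_opposite:
        log.info("%d gene(s) significant in both cohorts but with opposite RR directions",
                 n_opposite)
    return set(shared[sig & defined & same_dir])
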
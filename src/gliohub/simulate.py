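"""Synthetic glioma cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream screen
assumes: gene modules driven by shared latent factors, module activity that
tracks WHO grade, grade-linked mean shifts on the log2 scale, and survival
times whose hazard depends on grade and on one prognostic module.

Model, per cohort:

* Each sample carries a WHO grade (``normal``, ``II``, ``III``, ``IV``)
  with numeric codes 0/2/3/4 and ordinal "steps" 0/1/2/3.
* Module ``m`` has a latent factor ``f_m = alpha_m * z + sqrt(1-alpha_m^2) * eps``
  where ``z`` is the standardized grade code and ``alpha_m`` the planted
  module-grade correlation.
* A gene of module ``m`` with loading ``lam`` and per-gene expression
  scale ``s`` is
  ``x = baseline + s * (lam * f_m + nuisance + noise) + delta_g * steps``.
  Grade response rides almost entirely on the factor: a module with grade
  correlation ``alpha_m`` shifts its genes by ``lam * alpha_m``
  standardized-grade units per step, which the gene scale converts to
  log2 units. Hub genes of grade-linked modules carry a larger scale
  (``deg_gene_scale``, default 2.3 — strong fold-change genes in log
  intensity data are high-amplitude genes) plus a small additive top-up
  ``delta_g`` that lands their total planted per-step log2 fold change in
  a target band (default 1.7-2.0, direction = sign(alpha_m)). Non-hub
  genes keep unit scale and only the factor-mediated trend (at most
  ~0.7 log2 per step), so "planted differential gene" is a crisply
  separated set rather than a knife-edge around the fold-change
  threshold, and the shared additive trend stays too weak to distort the
  correlation structure the network stage sees.
* Every gene additionally loads on a small set of grade-independent
  nuisance factors (shared technical/compositional variation). Each gene
  gives a fraction ``tau`` of its residual standard deviation to a random
  direction in nuisance-factor space, with ``tau`` drawn from a
  decreasing-density law (``tau = lo + (hi - lo) * U^2``). This emulates
  the pervasive weak correlation of real transcriptomes; without it the
  connectivity distribution of the co-expression network is artificially
  bimodal (structured genes vs exact-zero background) and nothing like a
  measured cohort's.
* Background genes are baseline plus nuisance plus noise.
* Tumor samples get an exponential survival time with hazard
  ``h0 * exp(beta_grade * z_t + gamma * f_prog)`` (``z_t`` standardized over
  tumors only, since normals carry no survival record), administratively
  censored at ``censoring_time``.

Hub genes are planted explicitly: a fixed fraction of each module draws its
loading from a high band separated by a gap from the rest, so "the module's
hubs" is a well-defined planted set rather than an accident of sampling
noise near a quantile boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

GRADE_CODE = {"normal": 0, "I": 1, "II": 2, "III": 3, "IV": 4}
GRADE_STEPS = {"normal": 0, "I": 0, "II": 1, "III": 2, "IV": 3}

_DEFAULT_ALPHAS = (0.75, -0.7, 0.65, -0.6, 0.25, 0.0)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults describe a mid-sized study: a 200-sample discovery cohort
    spanning normal brain plus WHO II-IV, 300-sample tumor-only
    replication cohorts, 6 modules of 150 genes plus 300 background genes
    (1200 genes), four modules linked to grade, hub fold changes planted
    at 1.7-2.0 log2 units per grade step, and exponential survival over a
    60-month follow-up window.
    """

    n_normal: int = 20
    n_grade2: int = 60
    n_grade3: int = 60
    n_grade4: int = 60
    n_rep_grade2: int = 100
    n_rep_grade3: int = 100
    n_rep_grade4: int = 100
    n_modules: int = 6
    genes_per_module: int = 150
    n_background_genes: int = 300
    module_grade_cor: tuple[float, ...] = _DEFAULT_ALPHAS
    loading_range: tuple[float, float] = (0.4, 0.95)
    hub_frac: float = 0.2
    hub_loading_min: float = 0.8
    nonhub_loading_max: float = 0.7
    deg_lfc_range: tuple[float, float] = (1.7, 2.0)  # planted per-step log2FC band for hubs
    deg_gene_scale: float = 2.3       # expression scale of grade-linked hub genes
    grade_link_min: float = 0.5       # |alpha| >= this marks a grade-linked module
    n_nuisance_factors: int = 8
    nuisance_share_range: tuple[float, float] = (0.1, 0.8)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    baseline_hazard: float = 0.02     # events per month
    grade_log_hazard: float = 0.7
    prognostic_log_hazard: float = 0.5
    prognostic_module: int = 0
    censoring_time: float = 60.0      # months
    seed: int = 0

    def __post_init__(self):
        for name in ("module_grade_cor", "loading_range", "deg_lfc_range",
                     "nuisance_share_range"):
            value = getattr(self, name)
            if isinstance(value, list):
                object.__setattr__(self, name, tuple(value))
        counts = (self.n_normal, self.n_grade2, self.n_grade3, self.n_grade4,
                  self.n_rep_grade2, self.n_rep_grade3, self.n_rep_grade4,
                  self.n_modules, self.genes_per_module, self.n_background_genes)
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_samples < 4:
            raise ConfigurationError("need at least 4 samples in total")
        if self.n_genes < 2:
            raise ConfigurationError("need at least 2 genes in total")
        lo, hi = self.loading_range
        if not (0 < lo < hi < 1):
            raise ConfigurationError("loading_range must satisfy 0 < lo < hi < 1")
        if not (lo <= self.nonhub_loading_max < self.hub_loading_min <= hi):
            raise ConfigurationError(
                "need loading_range[0] <= nonhub_loading_max < hub_loading_min <= loading_range[1]")
        if len(self.module_grade_cor) != self.n_modules:
            raise ConfigurationError("module_grade_cor length must equal n_modules")
        if any(abs(a) > 1 for a in self.module_grade_cor):
            raise ConfigurationError("module-grade correlations must lie in [-1, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censoring_time <= 0:
            raise ConfigurationError("censoring_time must be > 0")
        if not 0 < self.hub_frac <= 1:
            raise ConfigurationError("hub_frac must lie in (0, 1]")
        if self.n_nuisance_factors < 0:
            raise ConfigurationError("n_nuisance_factors must be >= 0")
        if not 0 <= self.deg_lfc_range[0] <= self.deg_lfc_range[1]:
            raise ConfigurationError("deg_lfc_range must satisfy 0 <= lo <= hi")
        if self.deg_gene_scale <= 0:
            raise ConfigurationError("deg_gene_scale must be > 0")
        nlo, nhi = self.nuisance_share_range
        if not (0 <= nlo <= nhi < 1):
            raise ConfigurationError("nuisance_share_range must satisfy 0 <= lo <= hi < 1")

    @property
    def n_samples(self) -> int:
        return self.n_normal + self.n_grade2 + self.n_grade3 + self.n_grade4

    @property
    def n_genes(self) -> int:
        return self.n_modules * self.genes_per_module + self.n_background_genes

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study, shared by paired cohorts."""

    module_of: pd.Series          # gene -> "M1".."Mk" or "background"
    loading: pd.Series            # gene -> factor loading (0 for background)
    lfc_direction: pd.Series      # gene -> grade-trend sign (+1/-1/0)
    gene_scale: pd.Series         # gene -> expression scale (log2 sd multiplier)
    step_shift: pd.Series         # gene -> additive per-step shift (signed, log2)
    planted_step_lfc: pd.Series   # gene -> total planted per-step log2FC (signed)
    baseline: pd.Series           # gene -> baseline log2 expression
    module_grade_cor: dict[str, float]
    hub_genes: frozenset[str]
    nuisance_loadings: np.ndarray     # genes x n_nuisance_factors
    prognostic_module: str
    prognostic_direction: int     # sign of the prognostic module's log hazard
    config: SynthConfig

    @property
    def genes(self) -> pd.Index:
        return self.module_of.index

    def grade_linked_modules(self) -> list[str]:
        thr = self.config.grade_link_min
        return [m for m, a in self.module_grade_cor.items() if abs(a) >= thr]

    def planted_deg_genes(self, lfc_min: float = 1.0) -> set[str]:
        """Genes whose planted per-step log2FC exceeds the cutoff."""
        return set(self.genes[self.planted_step_lfc.abs() > lfc_min])

    def planted_key_genes(self, lfc_min: float = 1.0) -> set[str]:
        """Genes planted as simultaneously hub, differential and prognostic.

        With a positive grade log-hazard every grade-linked gene carries a
        marginal survival association, so the planted key set is the hubs of
        grade-linked modules whose planted shift clears the fold-change bar.
        """
        linked = set(self.grade_linked_modules())
        in_linked = set(self.genes[self.module_of.isin(linked)])
        return set(self.hub_genes) & in_linked & self.planted_deg_genes(lfc_min)


def _tumor_step_scale(cfg: SynthConfig) -> float:
    """Standardized-grade-code change per one grade step in a tumor-only
    replication cohort (the scale on which factor-mediated fold changes
    are planted; the replication cohorts host the adjacent-grade
    contrasts)."""
    codes = np.repeat([2.0, 3.0, 4.0],
                      [cfg.n_rep_grade2, cfg.n_rep_grade3, cfg.n_rep_grade4])
    sd = codes.std() if codes.size else 0.0
    return 1.0 / sd if sd > 0 else 0.0


def _draw_truth(cfg: SynthConfig, rng: np.random.Generator) -> GroundTruth:
    gene_ids, modules, loadings, dirs = [], [], [], []
    scales, shifts, planted = [], [], []
    gpm = cfg.genes_per_module
    n_hub = int(np.ceil(cfg.hub_frac * gpm)) if gpm else 0
    hubs: list[str] = []
    dz = _tumor_step_scale(cfg)
    for m in range(cfg.n_modules):
        label = f"M{m + 1}"
        alpha = cfg.module_grade_cor[m]
        linked = abs(alpha) >= cfg.grade_link_min
        direction = int(np.sign(alpha)) if linked else 0
        ids = [f"gene_{m * gpm + g + 1:04d}" for g in range(gpm)]
        lam = np.empty(gpm)
        lam[:n_hub] = rng.uniform(cfg.hub_loading_min, cfg.loading_range[1], n_hub)
        lam[n_hub:] = rng.uniform(cfg.loading_range[0], cfg.nonhub_loading_max, gpm - n_hub)
        scale = np.ones(gpm)
        if linked:
            scale[:n_hub] = cfg.deg_gene_scale
        factor_lfc = lam * alpha * dz * scale   # factor-mediated per-step log2FC
        shift = np.zeros(gpm)
        if linked and n_hub:
            # small additive top-up so hub fold changes land in the target band
            target = rng.uniform(*cfg.deg_lfc_range, n_hub)
            shift[:n_hub] = direction * np.maximum(0.0, target - np.abs(factor_lfc[:n_hub]))
        hubs.extend(ids[:n_hub])
        gene_ids.extend(ids)
        modules.extend([label] * gpm)
        loadings.extend(lam.tolist())
        dirs.extend([direction] * gpm)
        scales.extend(scale.tolist())
        shifts.extend(shift.tolist())
        planted.extend((factor_lfc + shift).tolist())
    offset = cfg.n_modules * gpm
    for b in range(cfg.n_background_genes):
        gene_ids.append(f"gene_{offset + b + 1:04d}")
        modules.append("background")
        loadings.append(0.0)
        dirs.append(0)
        scales.append(1.0)
        shifts.append(0.0)
        planted.append(0.0)
    idx = pd.Index(gene_ids, name="gene")
    baseline = pd.Series(rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(idx)), index=idx)
    n_genes = len(idx)
    lam_arr = np.asarray(loadings)
    resid_sd = np.sqrt(1.0 - lam_arr ** 2)
    k = cfg.n_nuisance_factors
    if k > 0:
        nlo, nhi = cfg.nuisance_share_range
        tau = nlo + (nhi - nlo) * rng.uniform(0, 1, n_genes) ** 2
        ndir = rng.standard_normal((n_genes, k))
        ndir /= np.linalg.norm(ndir, axis=1, keepdims=True)
        nuisance = ndir * (tau * resid_sd)[:, None]
    else:
        nuisance = np.zeros((n_genes, 0))
    return GroundTruth(
        module_of=pd.Series(modules, index=idx, name="module"),
        loading=pd.Series(loadings, index=idx, name="loading"),
        lfc_direction=pd.Series(dirs, index=idx, name="lfc_direction"),
        gene_scale=pd.Series(scales, index=idx, name="gene_scale"),
        step_shift=pd.Series(shifts, index=idx, name="step_shift"),
        planted_step_lfc=pd.Series(planted, index=idx, name="planted_step_lfc"),
        baseline=baseline,
        module_grade_cor={f"M{m + 1}": cfg.module_grade_cor[m] for m in range(cfg.n_modules)},
        hub_genes=frozenset(hubs),
        nuisance_loadings=nuisance,
        prognostic_module=f"M{cfg.prognostic_module + 1}",
        prognostic_direction=int(np.sign(cfg.prognostic_log_hazard)) or 1,
        config=cfg,
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _sample_cohort(truth: GroundTruth, cfg: SynthConfig, rng: np.random.Generator,
                   prefix: str, include_normals: bool = True,
                   replication: bool = False):
    grades = []
    if include_normals:
        grades += ["normal"] * cfg.n_normal
    if replication:
        counts = (cfg.n_rep_grade2, cfg.n_rep_grade3, cfg.n_rep_grade4)
    else:
        counts = (cfg.n_grade2, cfg.n_grade3, cfg.n_grade4)
    grades += ["II"] * counts[0] + ["III"] * counts[1] + ["IV"] * counts[2]
    n = len(grades)
    if n < 4:
        raise ConfigurationError("cohort needs at least 4 samples")
    sample_ids = [f"{prefix}S{i + 1:04d}" for i in range(n)]
    code = np.array([GRADE_CODE[g] for g in grades], dtype=float)
    steps = np.array([GRADE_STEPS[g] for g in grades], dtype=float)
    z = _standardize(code)

    alphas = np.array(cfg.module_grade_cor)
    factors = alphas[:, None] * z[None, :] + \
        np.sqrt(1 - alphas[:, None] ** 2) * rng.standard_normal((cfg.n_modules, n))

    lam = truth.loading.to_numpy()
    step_shift = truth.step_shift.to_numpy()
    base = truth.baseline.to_numpy()
    mod_index = np.full(len(truth.genes), -1)
    for m in range(cfg.n_modules):
        mod_index[truth.module_of.to_numpy() == f"M{m + 1}"] = m

    g_load = truth.nuisance_loadings
    scale = truth.gene_scale.to_numpy()
    nuisance_var = (g_load ** 2).sum(axis=1)
    noise_sd = np.sqrt(np.maximum(1.0 - lam ** 2 - nuisance_var, 0.0))
    noise = rng.standard_normal((len(truth.genes), n))
    stoch = noise_sd[:, None] * noise
    in_module = mod_index >= 0
    stoch[in_module] += lam[in_module, None] * factors[mod_index[in_module]]
    if g_load.shape[1]:
        u = rng.standard_normal((g_load.shape[1], n))
        stoch += g_load @ u
    x = base[:, None] + scale[:, None] * stoch + step_shift[:, None] * steps[None, :]
    expr = pd.DataFrame(x, index=truth.genes.copy(), columns=sample_ids)

    tumor = code > 0
    os_time = np.full(n, np.nan)
    os_event = np.full(n, np.nan)
    if tumor.any():
        zt = np.full(n, np.nan)
        zt[tumor] = _standardize(code[tumor])
        f_prog = factors[cfg.prognostic_module]
        hazard = cfg.baseline_hazard * np.exp(
            cfg.grade_log_hazard * zt[tumor] + cfg.prognostic_log_hazard * f_prog[tumor])
        t_raw = rng.exponential(1.0 / hazard)
        os_event[tumor] = (t_raw <= cfg.censoring_time).astype(float)
        os_time[tumor] = np.minimum(t_raw, cfg.censoring_time)
    age = np.clip(rng.normal(55, 12, n), 18, 90).round(1)
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "grade": grades,
        "os_time": np.round(os_time, 4),
        "os_event": os_event,
        "age": age,
    })
    return expr, clinical


def generate_cohort(config: SynthConfig, seed: int | None = None):
    """Generate one cohort: (expression genes x samples, clinical, truth).

    Same config and seed give bit-identical outputs.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = _draw_truth(config, rng)
    expr, clinical = _sample_cohort(truth, config, rng, prefix="")
    return expr, clinical, truth


def generate_paired_cohorts(config: SynthConfig, seed: int | None = None):
    """Two cohorts with independent noise drawn from one shared ground truth.

    Emulates replication across two tumor banks: sample ids are disjoint
    (prefixes ``A_`` and ``B_``) and neither cohort contains normals, as in
    tumor-only registries with survival follow-up.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = _draw_truth(config, rng)
    expr_a, clin_a = _sample_cohort(truth, config, rng, prefix="A_",
                                    include_normals=False, replication=True)
    expr_b, clin_b = _sample_cohort(truth, config, rng, prefix="B_",
                                    include_normals=False, replication=True)
    return (expr_a, clin_a), (expr_b, clin_b), truth


def generate_study(config: SynthConfig, seed: int | None = None):
    """Three-cohort study design: one discovery cohort with normal samples
    and two tumor-only replication cohorts, all sharing one ground truth.

    Mirrors the typical multi-registry layout: a discovery set containing
    normal brain tissue (used for the network and tumor-vs-normal contrast)
    and two independent tumor cohorts with survival follow-up.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    truth = _draw_truth(config, rng)
    disc = _sample_cohort(truth, config, rng, prefix="D_", include_normals=True)
    rep1 = _sample_cohort(truth, config, rng, prefix="A_",
                          include_normals=False, replication=True)
    rep2 = _sample_cohort(truth, config, rng, prefix="B_",
                          include_normals=False, replication=True)
    return disc, rep1, rep2, truth


def write_cohort(outdir: str | Path, expr: pd.DataFrame, clinical: pd.DataFrame,
                 truth: GroundTruth | None = None, stem: str = "cohort") -> dict[str, Path]:
    """Persist a cohort: expression TSV, clinical CSV, optional truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / f"{stem}_expression.tsv"
    expr.to_csv(p, sep="\t", float_format="%.6g")
    paths["expression"] = p
    p = outdir / f"{stem}_clinical.csv"
    clinical.to_csv(p, index=False, float_format="%.6g")
    paths["clinical"] = p
    if truth is not None:
        p = outdir / f"{stem}_truth.csv"
        df = pd.DataFrame({
            "module": truth.module_of,
            "loading": truth.loading,
            "lfc_direction": truth.lfc_direction,
            "planted_step_lfc": truth.planted_step_lfc,
            "is_hub": truth.module_of.index.isin(truth.hub_genes).astype(int),
        })
        df.to_csv(p, float_format="%.6g")
        paths["truth"] = p
    return paths
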
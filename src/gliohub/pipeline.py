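"""End-to-end orchestration: preparation, network, differential and
survival screens, and the final intersection, with every artifact written
to an output directory.

The pipeline expects a three-cohort study: a discovery cohort containing
normal samples (network + discovery DEG screen) and two tumor-only
replication cohorts with survival follow-up (replication DEG screen +
cross-cohort survival screen). Cohorts come either from files named in
the config or from the synthetic generator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, integrate, network, preprocess, simulate, survival
from .errors import GliohubError, NoQualifyingPowerError, PipelineStageError
from .simulate import SynthConfig

log = logging.getLogger(__name__)

GRADE_VALUE = {"normal": 0, "I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class PipelineConfig:
    """All thresholds of the screen, with the study's values as defaults."""

    outdir: str = "gliohub_run"
    seed: int = 0
    # preparation
    quantile_normalize: bool = True
    min_mean: float = 0.5
    min_variance: float = 1e-8
    outlier_height: float | None = None   # None: skip outlier removal
    outlier_linkage: str = "average"
    # network
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    r2_min: float = 0.9
    fallback_power: int = 6               # used (logged) when no power qualifies
    network_mode: str = "unsigned"
    min_module_size: int = 30
    merge_cut: float = 0.25
    cut_height_frac: float | None = None  # None: data-driven cut height
    reassign_kme_min: float = 0.3
    n_top_modules: int = 4
    top_frac: float = 0.2
    edge_top_frac: float = 0.01
    node_top_frac: float = 0.3
    # differential expression
    p_max: float = 0.001
    lfc_min: float = 1.0
    chisq_bins: int = 3
    # survival
    low_frac: float = 0.3
    survival_test: str = "logrank"
    # inputs: either synthetic, or three cohorts from disk
    synthetic: SynthConfig | None = None
    discovery_expression: str | None = None
    discovery_clinical: str | None = None
    replication1_expression: str | None = None
    replication1_clinical: str | None = None
    replication2_expression: str | None = None
    replication2_clinical: str | None = None

    def __post_init__(self):
        if isinstance(self.candidate_powers, list):
            self.candidate_powers = tuple(self.candidate_powers)
        if isinstance(self.synthetic, dict):
            self.synthetic = SynthConfig(**self.synthetic)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        # plain JSON/YAML types only (tuples become lists)
        return json.loads(json.dumps(d, default=list))


def _load_cohort(expr_path, clin_path, stage):
    if expr_path is None or clin_path is None:
        raise PipelineStageError(stage, "cohort paths missing from config")
    expr = preprocess.read_expression(expr_path)
    clinical = preprocess.read_clinical(clin_path)
    return expr, clinical


def _prepare(expr, clinical, cfg: PipelineConfig, normalize: bool):
    if normalize and cfg.quantile_normalize:
        expr = preprocess.quantile_normalize(expr)
    expr, _, _ = preprocess.clean_genes_samples(expr, cfg.min_mean, cfg.min_variance)
    if cfg.outlier_height is not None:
        expr, _ = preprocess.remove_outlier_samples(expr, cfg.outlier_height,
                                                    cfg.outlier_linkage)
    expr, clinical, _ = preprocess.align_samples(expr, clinical)
    return expr, clinical


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screen and write artifacts under ``config.outdir``.

    Returns the machine-readable run summary (also written as
    ``summary.json``): per-result-set counts, chosen power, module count
    and the final key genes. Any stage failure raises
    :class:`PipelineStageError` naming the stage, with the partial
    artifact manifest attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _write(df: pd.DataFrame, name: str, **kw):
        path = outdir / name
        sep = "\t" if name.endswith(".tsv") else ","
        df.to_csv(path, sep=sep, float_format="%.6g", **kw)
        manifest.append(name)
        return path

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                log.info("stage: %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, str(exc), manifest) from exc
        return _Ctx()

    truth = None
    with _stage("inputs"):
        if config.synthetic is not None:
            disc, rep1, rep2, truth = simulate.generate_study(config.synthetic,
                                                              seed=config.seed)
            expr_disc, clin_disc = disc
            expr_r1, clin_r1 = rep1
            expr_r2, clin_r2 = rep2
            simulate.write_cohort(outdir / "inputs", expr_disc, clin_disc, truth,
                                  stem="discovery")
            simulate.write_cohort(outdir / "inputs", expr_r1, clin_r1, stem="replication1")
            simulate.write_cohort(outdir / "inputs", expr_r2, clin_r2, stem="replication2")
        else:
            expr_disc, clin_disc = _load_cohort(config.discovery_expression,
                                                config.discovery_clinical, "inputs")
            expr_r1, clin_r1 = _load_cohort(config.replication1_expression,
                                            config.replication1_clinical, "inputs")
            expr_r2, clin_r2 = _load_cohort(config.replication2_expression,
                                            config.replication2_clinical, "inputs")
        for clin, label in ((clin_r1, "replication1"), (clin_r2, "replication2")):
            if clin["os_time"].notna().sum() == 0:
                raise GliohubError(f"{label} cohort has no survival records")

    with _stage("prep"):
        expr_disc, clin_disc = _prepare(expr_disc, clin_disc, config, normalize=True)
        expr_r1, clin_r1 = _prepare(expr_r1, clin_r1, config, normalize=False)
        expr_r2, clin_r2 = _prepare(expr_r2, clin_r2, config, normalize=True)

    with _stage("network"):
        try:
            power, scan = network.pick_power(expr_disc, config.candidate_powers,
                                             r2_min=config.r2_min, mode=config.network_mode)
        except NoQualifyingPowerError as exc:
            scan = exc.scan
            power = int(scan.loc[scan["r2"].idxmax(), "power"]) \
                if scan["r2"].max() > 0 else config.fallback_power
            log.warning("no power reached R^2 >= %.2f; relaxing to best fit "
                        "(power %d, R^2 %.3f)", config.r2_min, power, scan["r2"].max())
        _write(scan, "soft_threshold_scan.csv", index=False)
        sim = network.similarity(expr_disc, mode=config.network_mode)
        adj = network.adjacency(sim, power)
        tom = network.tom(adj)
        assignment = network.detect_modules(
            tom, min_module_size=config.min_module_size, merge_cut=config.merge_cut,
            expr=expr_disc, cut_height_frac=config.cut_height_frac,
            reassign_kme_min=config.reassign_kme_min)
        _write(assignment.labels.to_frame("module"), "module_assignment.csv")
        eigengenes = network.module_eigengenes(expr_disc, assignment)
        grade_value = clin_disc.set_index("sample_id")["grade"].map(GRADE_VALUE)
        traits = pd.DataFrame({
            "who_grade": grade_value.reindex(expr_disc.columns).astype(float),
            "age": clin_disc.set_index("sample_id")["age"].reindex(expr_disc.columns),
        })
        mod_trait = network.module_trait_correlation(eigengenes, traits)
        _write(mod_trait, "module_trait_correlation.csv", index=False)
        chosen = network.pick_trait_modules(mod_trait, "who_grade",
                                            n_top=config.n_top_modules)
        scores = network.membership_and_significance(
            expr_disc, eigengenes,
            traits["who_grade"].reindex(expr_disc.columns))
        result_a = network.select_module_hubs(scores, assignment, chosen,
                                              top_frac=config.top_frac)
        _write(pd.DataFrame({"gene": sorted(result_a)}), "result_a.csv", index=False)

    with _stage("deg"):
        result_b = diffexpr.build_result_b(expr_disc, clin_disc,
                                           p_max=config.p_max, lfc_min=config.lfc_min,
                                           n_bins=config.chisq_bins)
        _write(result_b, "result_b.csv")
        result_d = diffexpr.build_result_d(expr_r1, clin_r1,
                                           p_max=config.p_max, lfc_min=config.lfc_min)
        _write(result_d, "result_d.csv")

    with _stage("survival"):
        screen1 = survival.screen_survival(expr_r1, clin_r1, low_frac=config.low_frac,
                                           p_max=config.p_max, test=config.survival_test)
        screen2 = survival.screen_survival(expr_r2, clin_r2, low_frac=config.low_frac,
                                           p_max=config.p_max, test=config.survival_test)
        _write(screen1.table, "survival_screen_replication1.csv")
        _write(screen2.table, "survival_screen_replication2.csv")
        result_c = survival.cross_dataset_consistent(screen1, screen2,
                                                     p_max=config.p_max)
        _write(pd.DataFrame({"gene": sorted(result_c)}), "result_c.csv", index=False)

    with _stage("integrate"):
        key_candidates = result_a & set(result_b.index) & set(result_d.index)
        edges, conn = network.extract_subnetwork(
            tom, sorted(key_candidates & set(tom.index)),
            edge_top_frac=config.edge_top_frac,
            node_top_frac=config.node_top_frac) if key_candidates else (None, None)
        report = integrate.intersect_results(
            result_a, result_b, result_c, result_d,
            survival_table=screen1.table, connectivity=conn)
        if edges is not None:
            _write(edges, "subnetwork_edges.tsv", index=False)
        tumor_normal = clin_disc.set_index("sample_id")["grade"].map(
            lambda g: "normal" if g == "normal" else "tumor")
        aucs = {}
        for gene in report.index:
            if gene in expr_disc.index and (tumor_normal == "normal").any():
                aucs[gene] = integrate.roc_auc(expr_disc, gene, tumor_normal)
        report["auc_tumor_vs_normal"] = pd.Series(aucs).reindex(report.index)
        _write(report, "key_genes.csv")

    summary = {
        "seed": config.seed,
        "soft_power": int(power),
        "n_modules": len(assignment.modules()),
        "chosen_modules": chosen,
        "n_result_a": len(result_a),
        "n_result_b": int(result_b.shape[0]),
        "n_result_c": len(result_c),
        "n_result_d": int(result_d.shape[0]),
        "n_key_genes": int(report.shape[0]),
        "key_genes": sorted(report.index),
        "n_key_in_c": int(report["in_c"].sum()),
        "thresholds": {k: config.to_dict()[k] for k in
                       ("p_max", "lfc_min", "low_frac", "top_frac", "r2_min",
                        "edge_top_frac", "node_top_frac", "n_top_modules")},
    }
    if truth is not None:
        planted = truth.planted_key_genes(lfc_min=config.lfc_min)
        found = set(report.index)
        summary["planted_key_genes"] = len(planted)
        summary["planted_recovered"] = len(planted & found)
        summary["non_planted_in_key"] = len(found - planted)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.append("summary.json")
    (outdir / "run_log.txt").write_text(
        "gliohub run\n" + json.dumps(config.to_dict(), indent=2, default=str) + "\n")
    summary["manifest"] = manifest
    return summary
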
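"""End-to-end orchestration: simulate/load -> filter -> train -> score ->
stratify -> differential -> network -> survival, with a run report.

Every intermediate result is written as a TSV (with the seed recorded in a
header comment line) so stages compose with external tools, and rerunning
with the same configuration and seed reproduces all TSV outputs
byte-identically. Stage timings live only in the JSON run report.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import io as sio
from . import network as net
from . import simulate as sim
from . import stemness as stem
from . import survival as surv

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated configuration of a full run (see ``from_yaml``)."""

    outdir: str = "splicestem_run"
    seed: int = 0
    mode: str = "simulate"
    simulate: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    files: dict = field(default_factory=dict)
    min_observed_frac: float = 0.8
    min_mean_psi: float = 0.05
    oclr_lambda: float | None = None
    oclr_l1: float = 0.0
    orientation: str = "stem_low"
    stratify_frac: float = 0.10
    kase_min_delta_psi: float = 0.1
    sase_min_delta_psi: float = 0.2
    min_abs_log2fc: float = 1.0
    max_fdr: float = 0.05
    min_abs_rho: float = 0.6
    horizons_years: tuple = surv.DEFAULT_HORIZONS_YEARS
    max_covariates: int = 15
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise PipelineConfigError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if not 0 < self.min_observed_frac <= 1 or not 0 <= self.min_mean_psi <= 1:
            raise PipelineConfigError("filter thresholds out of range")
        if not 0 < self.stratify_frac <= 0.5:
            raise PipelineConfigError("stratify_frac must be in (0, 0.5]")
        if self.orientation not in ("stem_low", "stem_high"):
            raise PipelineConfigError(f"unknown orientation {self.orientation!r}")
        for k in ("kase_min_delta_psi", "sase_min_delta_psi"):
            if not 0 <= getattr(self, k) < 1:
                raise PipelineConfigError(f"{k} out of range")
        if not 0 < self.max_fdr <= 1 or not 0 <= self.min_abs_rho < 1:
            raise PipelineConfigError("correlation thresholds out of range")
        if self.mode == "files":
            required = ("psi", "expression_tumor", "expression_training",
                        "training_labels", "clinical")
            for key in required:
                if key not in self.files:
                    raise PipelineConfigError(f"files mode requires a {key!r} path")
                if not Path(self.files[key]).exists():
                    raise PipelineConfigError(f"missing input file: {self.files[key]}")
        self.simulate.seed = self.seed
        self.simulate.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_block = d.pop("simulate", {}) or {}
        known_sim = {f for f in sim.SimulationConfig.__dataclass_fields__}
        bad = set(sim_block) - known_sim
        if bad:
            raise PipelineConfigError(f"unknown simulate keys: {sorted(bad)}")
        cfg_fields = set(cls.__dataclass_fields__)
        bad = set(d) - cfg_fields
        if bad:
            raise PipelineConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**d)
        cfg.simulate = sim.SimulationConfig(**sim_block)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "stages": self.stages, "counts": self.counts,
             "timings_s": {k: round(v, 3) for k, v in self.timings_s.items()}},
            indent=2, sort_keys=True)


class _Stage:
    def __init__(self, report: RunReport, name: str):
        self.report, self.name = report, name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        self.t0 = _time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report.timings_s[self.name] = _time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s failed: %s", self.name, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done (%.2fs)", self.name, self.report.timings_s[self.name])
        return False


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run all stages in dependency order; outputs land in ``config.outdir``."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    seed = config.seed
    truth = None

    with _Stage(report, "inputs"):
        if config.mode == "simulate":
            train_expr, train_labels, _ = sim.simulate_training_cohort(config.simulate)
            psi, tumor_expr, clinical, truth = sim.simulate_tumor_cohort(config.simulate)
            sf_ids = list(truth.sf_target_map)
            sio.write_psi_table(psi, out / "psi.tsv", seed=seed)
            sio.write_expression_table(tumor_expr, out / "expression_tumor.tsv", seed=seed)
            sio.write_expression_table(train_expr, out / "expression_training.tsv", seed=seed)
            sio.write_clinical_table(clinical, out / "clinical.tsv", seed=seed)
            train_labels.to_frame().to_csv(out / "training_labels.tsv", sep="\t")
            sim.write_ground_truth(truth, out / "ground_truth_events.tsv",
                                   out / "ground_truth_summary.json")
        else:
            psi = sio.read_psi_table(config.files["psi"])
            tumor_expr = sio.read_expression_table(config.files["expression_tumor"])
            train_expr = sio.read_expression_table(config.files["expression_training"])
            train_labels = pd.read_csv(config.files["training_labels"], sep="\t",
                                       comment="#", index_col=0).iloc[:, 0]
            clinical = sio.read_clinical_table(config.files["clinical"])
            sf_ids = []
            if "splicing_factors" in config.files:
                sf_ids = [l.strip() for l in open(config.files["splicing_factors"])
                          if l.strip() and not l.startswith("#")]
        report.stages["inputs"] = {"n_events": psi.shape[0], "n_samples": psi.shape[1]}

    tumor_ids = [s for s in psi.sample_ids
                 if clinical.loc[s, "tissue_type"] == "tumor"] if "tissue_type" in clinical \
                 else list(psi.sample_ids)
    normal_ids = [s for s in psi.sample_ids if s not in set(tumor_ids)]

    with _Stage(report, "filter"):
        filtered, freport = sio.filter_events(
            psi, config.min_observed_frac, config.min_mean_psi)
        freport.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        sio.write_psi_table(filtered, out / "psi_filtered.tsv", seed=seed)
        _, upset = sio.splice_mode_membership(filtered)
        upset.to_csv(out / "splice_mode_upset.tsv", sep="\t", index=False)
        report.counts["events_input"] = freport.n_input
        report.counts["events_filtered"] = freport.n_kept

    with _Stage(report, "train"):
        spliced_genes = pd.Index(sorted({e.gene_symbol for e in filtered.events}))
        features = spliced_genes[spliced_genes.isin(train_expr.gene_ids)]
        stem_ids = train_labels.index[train_labels == "stem"]
        model = stem.train_oclr(train_expr, stem_ids, lambda_=config.oclr_lambda,
                                features=features, l1=config.oclr_l1,
                                orientation=config.orientation)
        report.stages["train"] = {"n_features": len(model.feature_ids),
                                  "n_stem_samples": len(stem_ids)}

    with _Stage(report, "score"):
        tumor_only = sio.ExpressionMatrix(tumor_expr.values[tumor_ids], tumor_expr.is_log)
        scores = stem.score_samples(model, tumor_only)
        scores = stem.stratify_by_stemness(scores, config.stratify_frac, config.orientation)
        sio._write_tsv(scores.to_frame(), out / "stemness_scores.tsv", seed=seed)
        weights, meta = model.to_frames()
        sio._write_tsv(weights, out / "stemness_model.tsv", seed=seed)
        (out / "stemness_model_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        tsc = list(scores.stratum[scores.stratum == "TSC"].index)
        usc = list(scores.stratum[scores.stratum == "USC"].index)
        report.counts["n_tsc"] = len(tsc)
        report.counts["n_usc"] = len(usc)

    with _Stage(report, "diff"):
        kase_preset = diff.ThresholdPreset("KASE", config.min_abs_log2fc, config.max_fdr,
                                           config.kase_min_delta_psi, paired=True)
        sase_preset = diff.ThresholdPreset("SASE", config.min_abs_log2fc, config.max_fdr,
                                           config.sase_min_delta_psi, paired=False)
        kase = None
        if normal_ids and "paired_with" in clinical.columns:
            pairing = {s: clinical.loc[s, "paired_with"] for s in tumor_ids
                       if clinical.loc[s, "paired_with"] in set(normal_ids)}
            if len(pairing) >= 2:
                kase = diff.differential_events(filtered, list(pairing), normal_ids,
                                                kase_preset, pairing=pairing)
                sio._write_tsv(kase, out / "kase.tsv", seed=seed)
                report.counts["n_kase"] = int(kase["significant"].sum())
        sase = diff.differential_events(filtered.subset_samples(tumor_ids), tsc, usc,
                                        sase_preset)
        sio._write_tsv(sase, out / "sase.tsv", seed=seed)
        report.counts["n_sase"] = int(sase["significant"].sum())
        deg = diff.differential_expression(tumor_only, tsc, usc)
        sio._write_tsv(deg, out / "deg.tsv", seed=seed)
        report.counts["n_deg"] = int(deg["significant"].sum())
        if kase is not None:
            overlap = diff.overlap_sets(kase, sase)
            overlap["per_gene_events"].to_csv(out / "overlap_per_gene.tsv", sep="\t",
                                              index=False)
            summary = {k: v for k, v in overlap.items() if k != "per_gene_events"}
            (out / "overlap_summary.json").write_text(
                json.dumps({k: len(v) for k, v in summary.items()}, indent=2, sort_keys=True))
            report.counts["events_kase_and_sase"] = len(overlap["events_both"])

    sase_ids = list(diff.significant_ids(sase))
    sase_psi = filtered.subset_events(sase_ids).subset_samples(tumor_ids)

    with _Stage(report, "network"):
        stem_corr = net.correlate_stemness_with_events(
            scores, filtered.subset_samples(tumor_ids),
            min_abs_rho=config.min_abs_rho, max_fdr=config.max_fdr)
        sio._write_tsv(stem_corr.set_index("target"), out / "stemness_event_correlation.tsv",
                       seed=seed)
        report.counts["n_stemness_correlated_events"] = int(stem_corr["kept"].sum())
        sf_present = [s for s in sf_ids if s in tumor_only.gene_ids]
        if sf_present:
            sf_expr = sio.ExpressionMatrix(tumor_only.values.loc[sf_present],
                                           tumor_only.is_log)
            edges, nodes = net.splicing_factor_network(
                sf_expr, sase_psi, min_abs_rho=config.min_abs_rho, max_fdr=config.max_fdr)
            sio._write_tsv(edges.set_index("source"), out / "sf_network_edges.tsv", seed=seed)
            nodes.to_csv(out / "sf_network_nodes.tsv", sep="\t", index=False)
            report.counts["n_network_edges"] = int(edges["kept"].sum())
        for variable in ("stage", "gender", "smoking_history"):
            if variable in clinical.columns:
                comp = net.group_composition(scores, clinical.loc[tumor_ids], variable)
                comp.to_csv(out / f"composition_{variable}.tsv", sep="\t", index=False)

    with _Stage(report, "survival"):
        clin_t = clinical.loc[tumor_ids]
        screen = surv.sase_survival_screen(clin_t, sase_psi.psi)
        sio._write_tsv(screen, out / "sase_survival_univariate.tsv", seed=seed)
        report.counts["n_sase_prognostic"] = int((screen["p"] < 0.05).sum()) if len(screen) else 0
        model_summary: dict = {}
        if len(screen):
            candidates = list(screen[screen["fdr"] < 0.05].index)
            if len(candidates) >= 2:
                cov = sase_psi.psi.T[candidates]
                selected = surv.backward_select_aic(clin_t, cov,
                                                    max_covariates=config.max_covariates)
                mv = surv.cox_multivariate(clin_t, cov[selected],
                                           horizons_years=config.horizons_years)
                sio._write_tsv(mv.hazard_ratios, out / "cox_multivariate.tsv", seed=seed)
                model_summary = {
                    "covariates": mv.covariate_ids,
                    "global_p": mv.global_p,
                    "c_index": mv.c_index,
                    "time_auc_years": {str(k): v for k, v in mv.time_auc.items()},
                }
                report.counts["n_multivariate_covariates"] = len(mv.covariate_ids)
                report.stages["survival"] = {"c_index": mv.c_index,
                                             "global_p": mv.global_p,
                                             "time_auc": model_summary["time_auc_years"]}
                top = screen.sort_values("p").index[0]
                groups = surv.dichotomize_by_median(sase_psi.psi.loc[top])
                curves, lr_p = surv.kaplan_meier_logrank(clin_t.loc[groups.index], groups)
                sio._write_tsv(curves.set_index("group"), out / "km_top_sase.tsv", seed=seed)
                model_summary["top_sase"] = {"event_id": str(top), "logrank_p": lr_p}
        (out / "survival_model_summary.json").write_text(
            json.dumps(model_summary, indent=2, sort_keys=True))

    (out / "run_report.json").write_text(report.to_json())
    return report
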
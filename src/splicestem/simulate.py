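"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Two cohorts are generated. A *training* cohort mimics a stem / non-stem
reference panel: a planted set of signature genes is shifted upward (log2
scale) in the stem samples. A *tumor* cohort carries a latent per-sample
stemness variable in [0, 1] that drives (i) the PSI of a planted subset of
splicing events (the true stemness-associated events), (ii) the expression of
the signature genes (stem-like tumors resemble stem cells), (iii) splicing-
factor expression through the PSI of their target events, and (iv) an
exponential proportional-hazards survival time. Matched normal samples shift
the PSI of a planted cancer-specific event subset, so paired differential
calling has a ground truth as well.

The generative laws are the simplest ones satisfying every downstream
assumption: Beta-distributed PSI with a linear stemness effect on the mean,
log-normal expression, exponential survival with uniform censoring. Ground-
truth labels are returned so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PsiMatrix, SpliceEvent, SPLICE_TYPES

# Splice-mode frequencies used when assigning event types (exon skip dominates,
# mutually exclusive exons are rare, mirroring bulk SpliceSeq tables).
_TYPE_PROBS = {"ES": 0.39, "AP": 0.18, "AT": 0.17, "AA": 0.09, "AD": 0.08, "RI": 0.08, "ME": 0.01}

# Log2-scale upward shift of signature genes in stem samples, and the slope
# linking tumor latent stemness to signature-gene log2 expression. Stem marker
# genes are typically several-fold elevated in pluripotent samples; a 2.0 log2
# shift (4-fold) is a realistic planted effect.
_SIGNATURE_SHIFT = 2.0
_TUMOR_SIGNATURE_SLOPE = 2.0

# Gaussian noise (PSI scale) added to splicing-factor expression on top of the
# signed PSI of the factor's target event.
_SF_NOISE_SD = 0.12

# Base PSI mean ranges: planted differential events sit in a range where both
# the |delta PSI| and the |log2FC| >= 1 criteria are attainable at the default
# effect size; null events span nearly the whole unit interval.
_TRUE_MU_RANGE = (0.20, 0.35)
_KASE_MU_RANGE = (0.15, 0.28)
_NULL_MU_RANGE = (0.05, 0.95)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass
class SimulationConfig:
    """Cohort sizes and effect sizes for the synthetic generator.

    Defaults mirror a stem-cell reference panel of 93 pluripotent (ESC+iPSC)
    and 160 differentiated samples, and a tumor cohort of 200 patients with
    39 matched normals.
    """

    seed: int = 0
    n_stem: int = 93
    n_nonstem: int = 160
    n_tumor: int = 200
    n_normal_paired: int = 39
    n_genes: int = 2000
    n_events: int = 5000
    n_signature_genes: int = 200
    n_true_sase: int = 60
    n_true_kase: int = 300
    n_splicing_factors: int = 30
    effect_dpsi: float = 0.3
    log_hr_stemness: float = 1.0
    psi_concentration: float = 30.0
    missing_rate: float = 0.05

    def validate(self) -> None:
        for name in ("n_stem", "n_nonstem", "n_tumor", "n_normal_paired"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2, got {getattr(self, name)}")
        for name in ("n_genes", "n_events"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("n_signature_genes", "n_true_sase", "n_true_kase", "n_splicing_factors"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_signature_genes > self.n_genes:
            raise ConfigurationError("n_signature_genes exceeds n_genes")
        if self.n_true_sase > self.n_events:
            raise ConfigurationError("n_true_sase exceeds n_events")
        if self.n_true_kase > self.n_events:
            raise ConfigurationError("n_true_kase exceeds n_events")
        if not 0.0 < self.effect_dpsi < 1.0:
            raise ConfigurationError(f"effect_dpsi must be in (0, 1), got {self.effect_dpsi}")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ConfigurationError(f"missing_rate must be in [0, 0.5], got {self.missing_rate}")
        if self.psi_concentration <= 0:
            raise ConfigurationError("psi_concentration must be > 0")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery scoring."""

    signature_gene_ids: frozenset[str] = frozenset()
    true_sase_ids: frozenset[str] = frozenset()
    true_kase_ids: frozenset[str] = frozenset()
    sase_direction: dict[str, int] = field(default_factory=dict)
    sf_target_map: dict[str, dict[str, int]] = field(default_factory=dict)
    latent_stemness: pd.Series | None = None
    true_log_hr: float = 0.0

    def to_event_frame(self) -> pd.DataFrame:
        """Event-level truth table (event_id, is_true_sase, direction, is_true_kase)."""
        ids = sorted(self.true_sase_ids | self.true_kase_ids)
        return pd.DataFrame(
            {
                "event_id": ids,
                "is_true_sase": [e in self.true_sase_ids for e in ids],
                "direction": [self.sase_direction.get(e, 0) for e in ids],
                "is_true_kase": [e in self.true_kase_ids for e in ids],
            }
        ).set_index("event_id")

    def summary_json(self) -> str:
        d = {
            "n_signature_genes": len(self.signature_gene_ids),
            "n_true_sase": len(self.true_sase_ids),
            "n_true_kase": len(self.true_kase_ids),
            "n_splicing_factors": len(self.sf_target_map),
            "true_log_hr": self.true_log_hr,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _rng(config_seed: int, stage: int) -> np.random.Generator:
    # one global seed fans out to per-stage substreams so stages re-run
    # independently and reproducibly
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), stage]))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _signature_idx(config: SimulationConfig) -> np.ndarray:
    # drawn from a dedicated substream so the training and tumor cohorts
    # plant the same signature gene set
    rng = _rng(config.seed, 0)
    return rng.choice(config.n_genes, config.n_signature_genes, replace=False)


def simulate_training_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Stem / non-stem expression panel with planted signature genes.

    Returns the linear-scale expression matrix, a sample->label Series with
    values ``"stem"`` / ``"non-stem"``, and the ground truth. Signature genes
    are shifted upward on the log2 scale in stem samples; all other genes are
    exchangeable between groups.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    genes = _gene_ids(config.n_genes)
    n = config.n_stem + config.n_nonstem
    samples = [f"TRAIN{i:03d}" for i in range(n)]
    labels = pd.Series(
        ["stem"] * config.n_stem + ["non-stem"] * config.n_nonstem,
        index=samples,
        name="group",
    )
    base = rng.uniform(2.0, 8.0, config.n_genes)
    log2x = base[:, None] + rng.normal(0.0, 1.0, (config.n_genes, n))
    sig_idx = _signature_idx(config)
    log2x[np.ix_(sig_idx, np.arange(config.n_stem))] += _SIGNATURE_SHIFT
    values = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    truth = GroundTruth(
        signature_gene_ids=frozenset(genes[i] for i in sig_idx),
        true_log_hr=config.log_hr_stemness,
    )
    return ExpressionMatrix(values), labels, truth


def _assign_events(rng: np.random.Generator, config: SimulationConfig) -> list[SpliceEvent]:
    genes = _gene_ids(config.n_genes)
    gene_idx = rng.integers(0, config.n_genes, config.n_events)
    types = rng.choice(list(_TYPE_PROBS), p=list(_TYPE_PROBS.values()), size=config.n_events)
    return [
        SpliceEvent(genes[g], t, 10000 + i)
        for i, (g, t) in enumerate(zip(gene_idx, types))
    ]


def simulate_tumor_cohort(
    config: SimulationConfig,
) -> tuple[PsiMatrix, ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Tumor cohort: PSI matrix (tumors + matched normals), expression
    (signature genes + splicing factors), clinical table, ground truth.

    Each tumor sample draws latent_stemness ~ Uniform(0, 1). True stemness-
    associated events shift their Beta-mean PSI by
    ``direction * effect_dpsi * (latent - 0.5)``; cancer-specific events shift
    their mean in matched normals; splicing-factor expression follows the
    signed PSI of one target event plus noise; survival is exponential with
    linear predictor ``log_hr_stemness * latent`` and uniform censoring.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    events = _assign_events(rng, config)
    event_ids = [e.event_id for e in events]
    n_t, n_n = config.n_tumor, config.n_normal_paired
    tumor_ids = [f"TUMOR{i:03d}" for i in range(n_t)]
    normal_ids = [f"NORMAL{i:03d}" for i in range(n_n)]
    latent = rng.uniform(0.0, 1.0, n_t)

    # planted event categories: SASE-true, KASE-true (overlapping subsets)
    perm = rng.permutation(config.n_events)
    sase_idx = perm[: config.n_true_sase]
    n_shared = min(config.n_true_kase, config.n_true_sase) // 2
    kase_from_sase = sase_idx[:n_shared]
    rest = perm[config.n_true_sase:]
    kase_idx = np.concatenate([kase_from_sase, rest[: config.n_true_kase - n_shared]]).astype(int)

    mu0 = rng.uniform(*_NULL_MU_RANGE, config.n_events)
    mu0[kase_idx] = rng.uniform(*_KASE_MU_RANGE, len(kase_idx))
    mu0[sase_idx] = rng.uniform(*_TRUE_MU_RANGE, len(sase_idx))
    sase_sign = np.zeros(config.n_events, dtype=int)
    sase_sign[sase_idx] = rng.choice([-1, 1], len(sase_idx))
    kase_sign = np.zeros(config.n_events, dtype=int)
    kase_sign[kase_idx] = rng.choice([-1, 1], len(kase_idx))

    conc = config.psi_concentration
    tumor_mean = np.clip(
        mu0[:, None] + sase_sign[:, None] * config.effect_dpsi * (latent[None, :] - 0.5),
        0.01, 0.99,
    )
    psi_tumor = rng.beta(tumor_mean * conc, (1.0 - tumor_mean) * conc)
    normal_mean = np.clip(
        (mu0 - kase_sign * config.effect_dpsi)[:, None] * np.ones((1, n_n)), 0.01, 0.99
    )
    psi_normal = rng.beta(normal_mean * conc, (1.0 - normal_mean) * conc)
    psi = np.concatenate([psi_tumor, psi_normal], axis=1)
    if config.missing_rate > 0:
        mask = rng.random(psi.shape) < config.missing_rate
        psi = np.where(mask, np.nan, psi)
    psi_df = pd.DataFrame(psi, index=event_ids, columns=tumor_ids + normal_ids)
    psi_matrix = PsiMatrix(psi_df, events)

    # expression: all genes, signature genes increase with latent stemness
    genes = _gene_ids(config.n_genes)
    base = rng.uniform(2.0, 8.0, config.n_genes)
    log2x = base[:, None] + rng.normal(0.0, 1.0, (config.n_genes, n_t))
    sig_idx = _signature_idx(config)
    log2x[sig_idx] += _TUMOR_SIGNATURE_SLOPE * (latent[None, :] - 0.5)

    # splicing factors: log2 expression affine in the signed PSI of one target
    sf_ids = [f"SF{i:02d}" for i in range(config.n_splicing_factors)]
    sf_target_map: dict[str, dict[str, int]] = {}
    sf_rows = []
    if config.n_splicing_factors and len(sase_idx):
        targets = rng.choice(sase_idx, config.n_splicing_factors, replace=True)
        signs = rng.choice([-1, 1], config.n_splicing_factors)
        target_psi = np.nan_to_num(psi_tumor[targets], nan=0.5)
        drive = signs[:, None] * target_psi + rng.normal(
            0.0, _SF_NOISE_SD, (config.n_splicing_factors, n_t)
        )
        sf_rows = 5.0 + 4.0 * drive
        for sf, t, s in zip(sf_ids, targets, signs):
            sf_target_map[sf] = {event_ids[int(t)]: int(s)}
    expr_log2 = pd.DataFrame(log2x, index=genes, columns=tumor_ids)
    if len(sf_rows):
        expr_log2 = pd.concat(
            [expr_log2, pd.DataFrame(sf_rows, index=sf_ids, columns=tumor_ids)]
        )
    expression = ExpressionMatrix(np.exp2(expr_log2), is_log=False)

    clinical = _simulate_clinical(rng, config, tumor_ids, normal_ids, latent)

    truth = GroundTruth(
        signature_gene_ids=frozenset(genes[i] for i in sig_idx),
        true_sase_ids=frozenset(event_ids[int(i)] for i in sase_idx),
        true_kase_ids=frozenset(event_ids[int(i)] for i in kase_idx),
        sase_direction={event_ids[int(i)]: int(sase_sign[i]) for i in sase_idx},
        sf_target_map=sf_target_map,
        latent_stemness=pd.Series(latent, index=tumor_ids, name="latent_stemness"),
        true_log_hr=config.log_hr_stemness,
    )
    return psi_matrix, expression, clinical, truth


def _ordinal_from_latent(
    rng: np.random.Generator, latent: np.ndarray, levels: list[str], noise: float = 0.3
) -> np.ndarray:
    """Categorical covariate whose level increases stochastically with latent."""
    z = latent + rng.normal(0.0, noise, len(latent))
    cuts = np.quantile(z, np.linspace(0, 1, len(levels) + 1)[1:-1])
    return np.asarray(levels)[np.searchsorted(cuts, z)]


def _simulate_clinical(
    rng: np.random.Generator,
    config: SimulationConfig,
    tumor_ids: list[str],
    normal_ids: list[str],
    latent: np.ndarray,
) -> pd.DataFrame:
    n_t = len(tumor_ids)
    # exponential PH survival: baseline median ~5 years, uniform censoring
    rate = np.log(2) / 1825.0 * np.exp(config.log_hr_stemness * (latent - 0.5))
    t_event = rng.exponential(1.0 / rate)
    censor = rng.uniform(180.0, 2920.0, n_t)
    os_time = np.maximum(np.minimum(t_event, censor), 1.0)
    os_event = (t_event <= censor).astype(int)
    stage = _ordinal_from_latent(rng, latent, ["I", "II", "III", "IV"])
    t_stage = _ordinal_from_latent(rng, latent, ["T1", "T2", "T3", "T4"])
    n_stage = _ordinal_from_latent(rng, latent, ["N0", "N1"], noise=0.5)
    m_stage = _ordinal_from_latent(rng, latent, ["M0", "M1"], noise=0.5)
    gender = np.where(rng.random(n_t) < 0.45 + 0.3 * latent, "male", "female")
    smoking = _ordinal_from_latent(rng, latent, ["never", "short", "long"], noise=0.5)
    tumor = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "tissue_type": "tumor",
            "stage": stage,
            "T": t_stage,
            "N": n_stage,
            "M": m_stage,
            "gender": gender,
            "smoking_history": smoking,
            "os_time": np.round(os_time, 1),
            "os_event": os_event,
            "paired_with": [normal_ids[i] if i < len(normal_ids) else "" for i in range(n_t)],
        }
    )
    normal = pd.DataFrame(
        {
            "sample_id": normal_ids,
            "tissue_type": "normal",
            "paired_with": tumor_ids[: len(normal_ids)],
        }
    )
    return (
        pd.concat([tumor, normal], ignore_index=True)
        .set_index("sample_id")
        .fillna("")
    )


def simulate_counts(
    n_events: int,
    n_samples: int,
    depth: float,
    psi_truth: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Inclusion/exclusion read counts around a true PSI matrix.

    Per event and sample the total count is Poisson(depth) and the inclusion
    count Binomial(total, psi_truth); ``compute_psi`` on the output recovers
    ``psi_truth`` up to binomial error.
    """
    if depth <= 0:
        raise ConfigurationError(f"depth must be > 0, got {depth}")
    psi_truth = np.broadcast_to(np.asarray(psi_truth, dtype=float), (n_events, n_samples))
    if (psi_truth < 0).any() or (psi_truth > 1).any():
        raise ConfigurationError("psi_truth must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    total = rng.poisson(depth, (n_events, n_samples))
    inclusion = rng.binomial(total, psi_truth)
    return inclusion, total - inclusion


def write_ground_truth(truth: GroundTruth, event_path, summary_path) -> None:
    truth.to_event_frame().to_csv(event_path, sep="\t")
    with open(summary_path, "w") as fh:
        fh.write(truth.summary_json() + "\n")
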
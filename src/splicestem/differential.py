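"""Differential splicing and expression calling with BH-FDR control.

Three presets mirror the study design:

* ``KASE`` — cancer-specific events: paired t-test of tumor vs matched
  normal PSI, |log2FC| >= 1, FDR < 0.05, |delta PSI| > 0.1.
* ``SASE`` — stemness-associated events: Welch t-test of TSC vs USC PSI,
  |log2FC| >= 1, FDR < 0.05, |delta PSI| > 0.2.
* ``DEG``  — differentially expressed genes: Welch t-test on log2(x+1)
  expression, |log2FC| >= 1, FDR < 0.05 (no delta-PSI term).

log2FC of PSI uses a pseudocount of 1e-3 on the ratio of group means. The BH
family in each call is the set of events that pass the per-event missingness
precondition (>= 2 values per group, or >= 2 complete pairs when paired);
untested events are reported with ``tested = False`` and never enter the
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, PsiMatrix, SpliceEvent

#: pseudocount guarding log2 fold change of PSI group means
LOG2FC_EPS = 1e-3


@dataclass(frozen=True)
class ThresholdPreset:
    """Significance thresholds for one class of differential call."""

    name: str
    min_abs_log2fc: float = 1.0
    max_fdr: float = 0.05
    min_delta_psi: float | None = None
    paired: bool = False

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0 or not 0 < self.max_fdr <= 1:
            raise ValueError("thresholds must be positive (max_fdr in (0, 1])")
        if self.min_delta_psi is not None and self.min_delta_psi < 0:
            raise ValueError("min_delta_psi must be >= 0")


KASE_PRESET = ThresholdPreset("KASE", min_delta_psi=0.1, paired=True)
SASE_PRESET = ThresholdPreset("SASE", min_delta_psi=0.2, paired=False)
DEG_PRESET = ThresholdPreset("DEG", min_delta_psi=None, paired=False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def _group_arrays(m: PsiMatrix, group_a, group_b, pairing) -> tuple[np.ndarray, np.ndarray]:
    group_a, group_b = pd.Index(group_a), pd.Index(group_b)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("empty sample group")
    if len(group_a.intersection(group_b)):
        raise ValueError("sample groups overlap")
    if pairing is not None:
        group_a = pd.Index([a for a in group_a if a in pairing])
        group_b = pd.Index([pairing[a] for a in group_a])
    a = m.psi.loc[:, group_a].to_numpy(float)
    b = m.psi.loc[:, group_b].to_numpy(float)
    return a, b


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    return np.asarray(res.pvalue, dtype=float)


def _paired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # scipy's ttest_rel omit-policy drops pairs; do it explicitly per event
    p = np.full(a.shape[0], np.nan)
    for i in range(a.shape[0]):
        ok = np.isfinite(a[i]) & np.isfinite(b[i])
        if ok.sum() >= 2:
            d = a[i, ok] - b[i, ok]
            if np.allclose(d, d[0]):
                p[i] = 1.0 if np.allclose(d, 0) else 0.0
                continue
            p[i] = stats.ttest_rel(a[i, ok], b[i, ok]).pvalue
    return p


def _differential_frame(
    ids,
    a: np.ndarray,
    b: np.ndarray,
    preset: ThresholdPreset,
    pairing,
    genes=None,
) -> pd.DataFrame:
    na = np.isfinite(a).sum(axis=1)
    nb = np.isfinite(b).sum(axis=1)
    if preset.paired and pairing is not None:
        complete = (np.isfinite(a) & np.isfinite(b)).sum(axis=1)
        tested = complete >= 2
    else:
        tested = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore"):
        mean_a = np.where(na > 0, np.nanmean(a, axis=1), np.nan)
        mean_b = np.where(nb > 0, np.nanmean(b, axis=1), np.nan)
    delta = np.abs(mean_a - mean_b)
    log2fc = np.log2((mean_a + LOG2FC_EPS) / (mean_b + LOG2FC_EPS))

    p = np.full(len(ids), np.nan)
    if tested.any():
        if preset.paired and pairing is not None:
            p[tested] = _paired_t(a[tested], b[tested])
        else:
            p[tested] = _welch_t(a[tested], b[tested])
    tested = tested & np.isfinite(p)  # zero-variance events yield NaN p: untested
    fdr = np.full(len(ids), np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p[tested])

    significant = (
        tested
        & (np.abs(log2fc) >= preset.min_abs_log2fc)
        & (fdr < preset.max_fdr)
    )
    if preset.min_delta_psi is not None:
        significant &= delta > preset.min_delta_psi
    df = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_psi": delta,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "tested": tested,
            "significant": significant,
        },
        index=pd.Index(ids, name="id"),
    )
    if genes is not None:
        df.insert(0, "gene", genes)
    return df


def differential_events(
    m: PsiMatrix,
    group_a,
    group_b,
    preset: ThresholdPreset = SASE_PRESET,
    pairing: dict | None = None,
) -> pd.DataFrame:
    """Per-event differential PSI between two sample groups.

    ``pairing`` maps group-a sample ids to their matched group-b sample; when
    given together with a paired preset, a paired t-test on complete pairs is
    used, otherwise a two-sided Welch t-test on non-missing values.
    Events with insufficient data are reported with ``tested = False`` and
    excluded from the BH family.
    """
    a, b = _group_arrays(m, group_a, group_b, pairing if preset.paired else None)
    genes = [e.gene_symbol for e in m.events]
    return _differential_frame(m.event_ids, a, b, preset, pairing, genes=genes)


def differential_expression(
    e: ExpressionMatrix,
    group_a,
    group_b,
    preset: ThresholdPreset = DEG_PRESET,
) -> pd.DataFrame:
    """Per-gene differential expression (Welch t on log2(x+1) values).

    ``log2fc`` is the difference of group means on the log2 scale; the
    ``delta_psi`` column holds its absolute value for interface uniformity
    but no delta threshold applies under the DEG preset.
    """
    log2x = e.log2p()
    group_a, group_b = pd.Index(group_a), pd.Index(group_b)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("empty sample group")
    if len(group_a.intersection(group_b)):
        raise ValueError("sample groups overlap")
    a = log2x.loc[:, group_a].to_numpy(float)
    b = log2x.loc[:, group_b].to_numpy(float)
    na = np.isfinite(a).sum(axis=1)
    nb = np.isfinite(b).sum(axis=1)
    tested = (na >= 2) & (nb >= 2)
    mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
    mean_b = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
    log2fc = mean_a - mean_b
    p = np.full(len(log2x), np.nan)
    if tested.any():
        p[tested] = _welch_t(a[tested], b[tested])
    tested = tested & np.isfinite(p)
    fdr = np.full(len(log2x), np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(p[tested])
    significant = tested & (np.abs(log2fc) >= preset.min_abs_log2fc) & (fdr < preset.max_fdr)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_psi": np.abs(log2fc),
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "tested": tested,
            "significant": significant,
        },
        index=pd.Index(log2x.index, name="id"),
    )


def significant_ids(result: pd.DataFrame) -> pd.Index:
    return result.index[result["significant"]]


def overlap_sets(kase: pd.DataFrame, sase: pd.DataFrame) -> dict:
    """Set overlaps of significant KASE and SASE calls.

    Returns event-level and gene-level intersections plus, for each gene with
    at least one significant event in either call set, the classification of
    all its events into {both, kase_only, sase_only, not_significant}.
    """
    kase_ids = set(significant_ids(kase))
    sase_ids = set(significant_ids(sase))
    both = kase_ids & sase_ids
    kase_genes = {SpliceEvent.from_event_id(e).gene_symbol for e in kase_ids}
    sase_genes = {SpliceEvent.from_event_id(e).gene_symbol for e in sase_ids}
    shared_genes = kase_genes & sase_genes

    all_ids = set(kase.index) | set(sase.index)
    rows = []
    for eid in sorted(all_ids):
        gene = SpliceEvent.from_event_id(eid).gene_symbol
        if gene not in shared_genes:
            continue
        if eid in both:
            cls = "both"
        elif eid in kase_ids:
            cls = "kase_only"
        elif eid in sase_ids:
            cls = "sase_only"
        else:
            cls = "not_significant"
        rows.append({"event_id": eid, "gene": gene, "class": cls})
    per_gene = pd.DataFrame(rows, columns=["event_id", "gene", "class"])
    return {
        "events_both": sorted(both),
        "events_kase_only": sorted(kase_ids - sase_ids),
        "events_sase_only": sorted(sase_ids - kase_ids),
        "genes_both": sorted(shared_genes),
        "genes_kase_only": sorted(kase_genes - sase_genes),
        "genes_sase_only": sorted(sase_genes - kase_genes),
        "per_gene_events": per_gene,
    }
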
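"""Stemness / splicing-factor correlation analyses and clinical composition.

Spearman rank correlation (mid-ranks for ties, p from the t-approximation
with n-2 degrees of freedom) links the mRNAsi and splicing-factor expression
to event PSI. Edges are retained at FDR < 0.05 and |rho| > 0.6 by default;
the BH family of the factor-event network is the full set of factor x event
pairs tested in the call. The resulting network is bipartite by
construction: sources are factors (or "mRNAsi"), targets are events.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io import ExpressionMatrix, PsiMatrix
from .stemness import StemnessScores

logger = logging.getLogger(__name__)

DEFAULT_MIN_ABS_RHO = 0.6
DEFAULT_MAX_FDR = 0.05
_MIN_PAIRS = 4


def spearman_correlate(x, y) -> tuple[float, float, int]:
    """Spearman rho, t-approximation p-value and the pair count used.

    Pairs with a missing value on either side are removed first; a constant
    vector after removal yields ``(nan, nan, n)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < _MIN_PAIRS:
        raise ValueError(f"need >= {_MIN_PAIRS} complete pairs, got {n}")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        warnings.warn("constant vector in Spearman correlation; result undefined")
        return float("nan"), float("nan"), n
    res = stats.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue), n


def _edge_frame(rows: list[dict], min_abs_rho: float, max_fdr: float) -> pd.DataFrame:
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p", "n_pairs"])
    if len(edges):
        tested = np.isfinite(edges["p"].to_numpy())
        fdr = np.full(len(edges), np.nan)
        fdr[tested] = bh_adjust(edges.loc[tested, "p"])
        edges["fdr"] = fdr
        edges["kept"] = tested & (edges["fdr"] < max_fdr) & (edges["rho"].abs() > min_abs_rho)
    else:
        edges["fdr"] = []
        edges["kept"] = []
    return edges


def correlate_stemness_with_events(
    scores: StemnessScores,
    m: PsiMatrix,
    min_abs_rho: float = DEFAULT_MIN_ABS_RHO,
    max_fdr: float = DEFAULT_MAX_FDR,
) -> pd.DataFrame:
    """Spearman correlation of the mRNAsi with each event's PSI.

    One test per event, BH over all tested events; the returned frame has one
    row per event with ``kept`` marking retained associations, and the
    positive/negative sign split is logged.
    """
    shared = m.sample_ids.intersection(scores.sample_ids)
    if len(shared) < _MIN_PAIRS:
        raise ValueError("no (or too few) shared samples between scores and PSI matrix")
    mr = pd.Series(scores.mrnasi, index=scores.sample_ids)[shared].to_numpy(float)
    psi = m.psi[shared].to_numpy(float)
    rows = []
    for i, eid in enumerate(m.event_ids):
        ok = np.isfinite(psi[i]) & np.isfinite(mr)
        if ok.sum() < _MIN_PAIRS:
            rows.append({"source": "mRNAsi", "target": eid, "rho": np.nan, "p": np.nan,
                         "n_pairs": int(ok.sum())})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p, n = spearman_correlate(mr, psi[i])
        rows.append({"source": "mRNAsi", "target": eid, "rho": rho, "p": p, "n_pairs": n})
    edges = _edge_frame(rows, min_abs_rho, max_fdr)
    kept = edges[edges["kept"]]
    logger.info(
        "stemness-event correlation: %d retained (%d negative, %d positive)",
        len(kept), int((kept["rho"] < 0).sum()), int((kept["rho"] > 0).sum()),
    )
    return edges


def splicing_factor_network(
    sf_expression: ExpressionMatrix,
    sase: PsiMatrix,
    min_abs_rho: float = DEFAULT_MIN_ABS_RHO,
    max_fdr: float = DEFAULT_MAX_FDR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All factor x event Spearman tests; BH over the full pair set.

    Returns ``(edges, nodes)``: the edge table with ``kept`` flags, and a
    node table (id, type, degree) counting retained edges per node. An empty
    event set yields an empty network.
    """
    if len(sf_expression.gene_ids) == 0:
        raise ValueError("empty splicing-factor list")
    if len(sase.events) == 0:
        logger.info("empty SASE set: returning empty network")
        empty = _edge_frame([], min_abs_rho, max_fdr)
        return empty, pd.DataFrame(columns=["id", "type", "degree"])
    shared = sase.sample_ids.intersection(sf_expression.sample_ids)
    if len(shared) < _MIN_PAIRS:
        raise ValueError("too few shared samples between factors and events")
    expr = sf_expression.log2p()[shared].to_numpy(float)
    psi = sase.psi[shared].to_numpy(float)
    rows = []
    for i, sf in enumerate(sf_expression.gene_ids):
        for j, eid in enumerate(sase.event_ids):
            ok = np.isfinite(expr[i]) & np.isfinite(psi[j])
            if ok.sum() < _MIN_PAIRS:
                rows.append({"source": sf, "target": eid, "rho": np.nan, "p": np.nan,
                             "n_pairs": int(ok.sum())})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, p, n = spearman_correlate(expr[i], psi[j])
            rows.append({"source": sf, "target": eid, "rho": rho, "p": p, "n_pairs": n})
    edges = _edge_frame(rows, min_abs_rho, max_fdr)
    kept = edges[edges["kept"]]
    deg_sf = kept.groupby("source").size()
    deg_ev = kept.groupby("target").size()
    nodes = pd.DataFrame(
        [{"id": sf, "type": "splicing_factor", "degree": int(deg_sf.get(sf, 0))}
         for sf in sf_expression.gene_ids]
        + [{"id": e, "type": "event", "degree": int(deg_ev.get(e, 0))}
           for e in sase.event_ids]
    )
    return edges, nodes


def group_composition(
    scores: StemnessScores,
    clinical: pd.DataFrame,
    variable: str,
) -> pd.DataFrame:
    """TSC vs USC composition across the categories of a clinical variable.

    MID samples are excluded. Returns one row per category with TSC/USC
    counts and proportions, plus the table-wide chi-square (or Fisher exact
    for 2x2 tables with any expected count < 5) p-value in every row.
    """
    if variable not in clinical.columns:
        raise KeyError(f"variable {variable!r} not in clinical table")
    if scores.stratum is None:
        raise ValueError("scores have no strata; run stratify_by_stemness first")
    strat = scores.stratum[scores.stratum.isin(["TSC", "USC"])]
    if (strat == "TSC").sum() < 1 or (strat == "USC").sum() < 1:
        raise ValueError("need at least one TSC and one USC sample")
    sub = clinical.loc[clinical.index.intersection(strat.index), [variable]].copy()
    sub = sub[sub[variable].astype(str).str.len() > 0]
    sub["stratum"] = strat[sub.index]
    table = pd.crosstab(sub[variable], sub["stratum"]).reindex(columns=["TSC", "USC"], fill_value=0)
    counts = table.to_numpy(float)
    counts = counts[counts.sum(axis=1) > 0]
    if counts.shape == (2, 2) and (stats.contingency.expected_freq(counts) <= 5).any():
        p = float(stats.fisher_exact(counts)[1])
        method = "fisher"
    else:
        p = float(stats.chi2_contingency(counts)[1]) if counts.shape[0] > 1 else float("nan")
        method = "chi2"
    out = table.copy()
    totals = table.sum(axis=1)
    out["prop_tsc"] = table["TSC"] / totals
    out["prop_usc"] = table["USC"] / totals
    out["p"] = p
    out["test"] = method
    out.index.name = variable
    return out.reset_index()
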
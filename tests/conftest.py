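import numpy as np
import pandas as pd
import pytest

import splicestem as st


def small_config(seed: int = 0, **overrides) -> st.SimulationConfig:
    """Reduced cohort sizes for fast unit tests (defaults stay untouched)."""
    base = dict(
        seed=seed, n_stem=30, n_nonstem=40, n_tumor=80, n_normal_paired=15,
        n_genes=300, n_events=600, n_signature_genes=60, n_true_sase=30,
        n_true_kase=60, n_splicing_factors=10,
    )
    base.update(overrides)
    return st.SimulationConfig(**base)


def run_stemness(config: st.SimulationConfig, holdout_frac: float = 1 / 3):
    """Train on part of the stem samples, score the tumor cohort and the
    held-out training samples; return everything recovery tests need."""
    expr, labels, _ = st.simulate_training_cohort(config)
    psi, tumor_expr, clinical, truth = st.simulate_tumor_cohort(config)
    filtered, _ = st.filter_events(psi)
    genes = pd.Index(sorted({e.gene_symbol for e in filtered.events}))
    features = genes[genes.isin(expr.gene_ids)]
    stem_ids = labels.index[labels == "stem"]
    n_hold = int(np.floor(holdout_frac * len(stem_ids)))
    train_ids = stem_ids[n_hold:]
    holdout_ids = list(stem_ids[:n_hold]) + list(labels.index[labels == "non-stem"])
    model = st.train_oclr(expr, train_ids, features=features)

    tumor_ids = list(truth.latent_stemness.index)
    tumor_only = st.ExpressionMatrix(tumor_expr.values[tumor_ids], tumor_expr.is_log)
    scores = st.stratify_by_stemness(st.score_samples(model, tumor_only))

    hold_expr = st.ExpressionMatrix(expr.values[holdout_ids], expr.is_log)
    hold_model = st.StemnessModel(  # fresh anchors for the held-out cohort
        model.feature_ids, model.w, model.lambda_, model.center, model.orientation)
    hold_scores = st.score_samples(hold_model, hold_expr)
    hold_labels = (labels[holdout_ids] == "stem").to_numpy()
    return dict(
        model=model, scores=scores, truth=truth, filtered=filtered,
        tumor_only=tumor_only, clinical=clinical, tumor_ids=tumor_ids,
        holdout_scores=hold_scores, holdout_is_stem=hold_labels, labels=labels,
        expr=expr,
    )


def call_sases(run: dict) -> pd.DataFrame:
    scores = run["scores"]
    tsc = list(scores.stratum[scores.stratum == "TSC"].index)
    usc = list(scores.stratum[scores.stratum == "USC"].index)
    return st.differential_events(
        run["filtered"].subset_samples(run["tumor_ids"]), tsc, usc, st.SASE_PRESET)


@pytest.fixture(scope="session")
def default_run():
    """One full default-size cohort analysis shared across tests."""
    return run_stemness(st.SimulationConfig(seed=11))


@pytest.fixture
def toy_psi():
    """3 events x 5 samples, designed so only event A survives the filters."""
    psi = pd.DataFrame(
        {
            "S1": [0.5, 0.2, 0.04],
            "S2": [0.6, np.nan, 0.05],
            "S3": [0.4, np.nan, 0.03],
            "S4": [0.5, 0.3, 0.04],
            "S5": [0.5, 0.1, 0.04],
        },
        index=["GA_ES_1", "GB_AP_2", "GC_RI_3"],
    )
    return st.PsiMatrix(psi)
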
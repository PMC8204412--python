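"""Train the OCLR stemness signature, score a tumor cohort to mRNAsi and
stratify it into TSC / MID / USC deciles.

Under the default stem_low orientation, more stem-like samples receive a
LOWER mRNAsi, so TSC (the most stem-like decile) is the lowest-mRNAsi 10%.
"""
import pandas as pd
from scipy.stats import spearmanr
import splicestem as st

config = st.SimulationConfig(seed=7)
train_expr, labels, _ = st.simulate_training_cohort(config)
psi, tumor_expr, clinical, truth = st.simulate_tumor_cohort(config)

filtered, _ = st.filter_events(psi)
spliced_genes = pd.Index(sorted({e.gene_symbol for e in filtered.events}))
model = st.train_oclr(train_expr, labels.index[labels == "stem"],
                      features=spliced_genes[spliced_genes.isin(train_expr.gene_ids)])

# separation on the reference panel (stem-likeness = 1 - mRNAsi)
ref_scores = st.score_samples(
    st.StemnessModel(model.feature_ids, model.w, model.lambda_, model.center),
    train_expr)
auc = st.evaluate_separation(1.0 - ref_scores.mrnasi, (labels == "stem").to_numpy())
print(f"stem vs non-stem AUC on the reference panel: {auc:.3f} (1.0 = perfect)")

tumor_ids = list(truth.latent_stemness.index)
tumor_only = st.ExpressionMatrix(tumor_expr.values[tumor_ids], tumor_expr.is_log)
scores = st.stratify_by_stemness(st.score_samples(model, tumor_only))
rho = spearmanr(scores.mrnasi, truth.latent_stemness[tumor_ids]).statistic
print(f"Spearman(mRNAsi, latent stemness) on tumors: {rho:.3f} "
      "(negative: lower mRNAsi = more stem-like)")
counts = scores.stratum.value_counts()
print(f"strata: {counts['TSC']} TSC / {counts['MID']} MID / {counts['USC']} USC")
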
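"""Generate a synthetic stem-cell reference panel and tumor cohort.

The tumor cohort carries a latent per-sample stemness in [0, 1] that drives a
planted subset of splicing events, the stem signature genes, splicing-factor
expression and survival; ground-truth labels let every downstream result be
scored exactly.
"""
import splicestem as st

config = st.SimulationConfig(seed=7)
train_expr, labels, _ = st.simulate_training_cohort(config)
psi, tumor_expr, clinical, truth = st.simulate_tumor_cohort(config)

print(f"training panel : {train_expr.values.shape[0]} genes x "
      f"{train_expr.values.shape[1]} samples "
      f"({(labels == 'stem').sum()} stem / {(labels == 'non-stem').sum()} non-stem)")
print(f"tumor cohort   : {psi.shape[0]} events x {psi.shape[1]} samples "
      f"({len(truth.latent_stemness)} tumors + "
      f"{psi.shape[1] - len(truth.latent_stemness)} matched normals)")
print(f"missing PSI    : {psi.psi.isna().to_numpy().mean():.3f} "
      f"(requested {config.missing_rate})")
print(truth.summary_json())
# The planted counts above are the recovery targets for the later stages:
# 60 stemness-associated events, 300 cancer-specific events, 30 factors.
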
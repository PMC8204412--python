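"""Relate splicing events and stemness to overall survival: median-split
Kaplan-Meier with log-rank, univariate and multivariate Cox, Harrell's
C-index and IPCW time-dependent AUC.
"""
import pandas as pd
import splicestem as st
from splicestem.survival import backward_select_aic, sase_survival_screen

config = st.SimulationConfig(seed=1)
psi, tumor_expr, clinical, truth = st.simulate_tumor_cohort(config)
filtered, _ = st.filter_events(psi)
tumor_ids = list(truth.latent_stemness.index)
clin = clinical.loc[tumor_ids]

# the latent driver itself recovers the planted log hazard ratio of 1.0
res = st.cox_univariate(clin, truth.latent_stemness)
print(f"Cox on latent stemness: log HR = {res.coef:.3f} "
      f"(planted 1.0), 95% CI on HR [{res.ci_low:.2f}, {res.ci_high:.2f}]")

# screen the planted stemness-associated events
sase_psi = filtered.subset_events(sorted(truth.true_sase_ids)) \
    .subset_samples(tumor_ids)
screen = sase_survival_screen(clin, sase_psi.psi)
print(f"univariate screen: {(screen['p'] < 0.05).sum()}/{len(screen)} events "
      "prognostic at p < 0.05")

candidates = screen[screen["fdr"] < 0.05].index
if len(candidates) < 2:  # small cohorts can leave the FDR screen empty
    candidates = screen[screen["p"] < 0.05].index
cov = sase_psi.psi.T[list(candidates)]
selected = backward_select_aic(clin, cov, max_covariates=10)
model = st.cox_multivariate(clin, cov[selected])
print(f"multivariate Cox on {len(selected)} events: global p = {model.global_p:.2e}, "
      f"C-index = {model.c_index:.3f}")
print("time-dependent AUC:",
      {f"{h:g}y": round(a, 3) for h, a in model.time_auc.items()})

top = screen.sort_values("p").index[0]
groups = st.dichotomize_by_median(sase_psi.psi.loc[top])
curves, p = st.kaplan_meier_logrank(clin.loc[groups.index], groups)
print(f"KM median split of {top}: log-rank p = {p:.2e}")
# A C-index ~0.65-0.7 reflects the moderate share of the hazard carried by
# each event's PSI; the latent driver itself is not observable in real data.
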
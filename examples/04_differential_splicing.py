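"""Call cancer-specific (KASE) and stemness-associated (SASE) splicing events
and intersect them.

KASE: paired t-test, tumor vs matched normal, |dPSI| > 0.1.
SASE: Welch t-test, TSC vs USC tumors, |dPSI| > 0.2.
Both additionally require |log2FC| >= 1 and BH-FDR < 0.05.
"""
import pandas as pd
import splicestem as st

config = st.SimulationConfig(seed=7)
train_expr, labels, _ = st.simulate_training_cohort(config)
psi, tumor_expr, clinical, truth = st.simulate_tumor_cohort(config)
filtered, _ = st.filter_events(psi)

spliced = pd.Index(sorted({e.gene_symbol for e in filtered.events}))
model = st.train_oclr(train_expr, labels.index[labels == "stem"],
                      features=spliced[spliced.isin(train_expr.gene_ids)])
tumor_ids = list(truth.latent_stemness.index)
tumor_only = st.ExpressionMatrix(tumor_expr.values[tumor_ids], tumor_expr.is_log)
scores = st.stratify_by_stemness(st.score_samples(model, tumor_only))
tsc = list(scores.stratum[scores.stratum == "TSC"].index)
usc = list(scores.stratum[scores.stratum == "USC"].index)

pairing = {t: clinical.loc[t, "paired_with"] for t in tumor_ids
           if clinical.loc[t, "paired_with"]}
kase = st.differential_events(filtered, list(pairing), list(pairing.values()),
                              st.KASE_PRESET, pairing=pairing)
sase = st.differential_events(filtered.subset_samples(tumor_ids), tsc, usc,
                              st.SASE_PRESET)
called_sase = set(sase.index[sase["significant"]])
print(f"KASE: {int(kase['significant'].sum())} significant "
      f"(of {len(truth.true_kase_ids)} planted cancer-specific events)")
print(f"SASE: {len(called_sase)} significant "
      f"(of {len(truth.true_sase_ids)} planted stemness-associated events)")
print(f"SASE sensitivity: {len(called_sase & truth.true_sase_ids) / len(truth.true_sase_ids):.2f}, "
      f"false calls: {len(called_sase - truth.true_sase_ids)}")

overlap = st.overlap_sets(kase, sase)
print(f"events in both call sets: {len(overlap['events_both'])}; "
      f"genes shared: {len(overlap['genes_both'])}")
# Events unique to the SASE set differ only between stemness extremes of the
# tumors - the signature of intratumor-heterogeneity splicing.
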
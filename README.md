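# splicestem

Stemness-index and alternative-splicing analysis for bulk tumor cohorts.

Dedifferentiated, stem-like tumors behave more aggressively, and shifts in
alternative splicing accompany the acquisition of stemness. `splicestem` is a
reusable, tested implementation of the full analysis chain that connects the
two in a renal-carcinoma-style cohort design:

1. **Stemness signature (OCLR).** A one-class logistic regression

   L(w) = (1/n) Σᵢ −log σ(wᵀxᵢ) + (λ/2)‖w‖²

   is fitted to stem-cell expression profiles (log2, feature-centered over
   the full stem + non-stem reference). Cohorts are scored by the Spearman
   correlation between w and each sample's profile, min–max scaled to the
   **mRNAsi** ∈ [0, 1] — oriented so that more stem-like samples score
   *lower* — and stratified into the most stem-like decile (**TSC**), the
   least stem-like decile (**USC**) and the remainder (MID).
2. **Differential splicing** on SpliceSeq-style PSI tables (PSI =
   inclusion/(inclusion+exclusion) ∈ [0, 1]; seven splice modes AA, AD, AP,
   AT, ES, ME, RI; 80%-observed and mean-PSI ≥ 0.05 filters):
   cancer-specific events (**KASE**, paired tumor vs matched normal,
   |ΔPSI| > 0.1), stemness-associated events (**SASE**, TSC vs USC,
   |ΔPSI| > 0.2), both with |log2FC| ≥ 1 and BH-FDR < 0.05, plus their set
   overlaps.
3. **Splicing-factor network.** Spearman correlations (FDR < 0.05,
   |ρ| > 0.6) between factor expression and SASE PSI form a bipartite
   regulatory network; the mRNAsi itself is correlated against every event.
4. **Survival.** Median-split Kaplan–Meier with log-rank tests, univariate
   and multivariate Cox (Efron ties, backward-AIC selection), Harrell's
   C-index and IPCW time-dependent ROC at 3/4.5/5 years.

Because the original cohorts (TCGA, PCBC, GEO) cannot ship with a package,
`splicestem` includes a first-class **synthetic-cohort generator**: a latent
per-sample stemness variable drives a planted subset of events,
signature-gene and splicing-factor expression, and an exponential
proportional-hazards survival time — with ground-truth labels, so every
stage's recovery is measurable exactly. See `docs/methods.md` for the model
and its assumptions.

## Worked example

```python
import pandas as pd
from scipy.stats import spearmanr
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
print(spearmanr(scores.mrnasi, truth.latent_stemness[tumor_ids]).statistic)
```

Running `examples/03_stemness_index.py` (which adds the reference-panel AUC)
prints:

```
stem vs non-stem AUC on the reference panel: 1.000 (1.0 = perfect)
Spearman(mRNAsi, latent stemness) on tumors: -0.963 (negative: lower mRNAsi = more stem-like)
strata: 20 TSC / 160 MID / 20 USC
```

The signature separates stem from non-stem samples perfectly, and on tumors
the mRNAsi is a near-monotone (negative) readout of the planted latent
stemness, so the TSC decile really is the most stem-like tenth of the
cohort. Continuing with `examples/04_differential_splicing.py`:

```
KASE: 289 significant (of 300 planted cancer-specific events)
SASE: 60 significant (of 60 planted stemness-associated events)
SASE sensitivity: 1.00, false calls: 0
events in both call sets: 22; genes shared: 26
```

The `examples/` directory holds one short script per capability (simulation,
PSI from counts, stemness index, differential calling, factor network,
survival models, full pipeline).

## Command line

A thin CLI wraps the library; every intermediate is a documented TSV so
stages compose with external tools:

```bash
splicestem run-all --seed 7 --outdir results/run      # whole pipeline
splicestem simulate --seed 7 --outdir data/           # cohorts only
splicestem filter data/psi.tsv --out data/filtered.tsv
```

`run-all` accepts a YAML config (`--config`) mirroring
`splicestem.PipelineConfig`; rerunning with the same seed reproduces all TSV
outputs byte-identically.

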
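"""Run the whole pipeline (simulate -> filter -> train -> score -> stratify
-> differential -> network -> survival) from one configuration and inspect
the run report. All intermediates are TSVs under the output directory; the
same seed reproduces them byte-identically.
"""
import splicestem as st

config = st.PipelineConfig(outdir="scratch/example_run", seed=7)
report = st.run_pipeline(config)
print(report.to_json())
# counts: events surviving the filter, KASE/SASE/DEG calls, their overlap,
# mRNAsi-correlated events, network edges and the multivariate survival model.
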
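"""Simulate one complete GC-MS batch for a SNAT2-like symporter experiment.

Twelve pooled oocytes per sample, three replicates, 0 and 4 h timepoints in
biomimetic L-15 medium, rendered with the alkane ladder, ribitol internal
standard, pooled-QC injections every 8 samples, blanks, standard mixes and
calibration series. The batch is written as plain CSV peak lists plus a
manifest — the format the profiling pipeline consumes.
"""

from oocyteflux import PipelineConfig, run_simulate
import pandas as pd

cfg = PipelineConfig(transporter="SNAT2-like", seed=1)
outdir = run_simulate(cfg, "scratch_example_batch")

manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
print(f"batch written to {outdir}: {len(manifest)} injections")
print(manifest["role"].value_counts().to_string())
qc = manifest.loc[manifest.role == "qc_pool", "injection_order"].tolist()
print(f"pooled-QC injections at positions {qc} (start, then every 8)")
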
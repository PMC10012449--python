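"""One-command synthetic end-to-end run with manifest and report.

Equivalent to `smokewas run-all --outdir scratch/demo --seed 7`.
All stage outputs land as TSV next to a JSON manifest recording seeds,
parameters and row counts; the same seed reproduces every file byte for
byte.
"""
from smokewas.pipeline import PipelineConfig, run_pipeline, summarize

config = PipelineConfig(seed=7)
bundle = run_pipeline(config, "scratch/demo")
print(summarize(bundle))
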
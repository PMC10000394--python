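"""One-call end-to-end run: simulate -> gate -> quantify -> proximity ->
survival -> report. Equivalent to `tmacyto run` on the command line.

All intermediates (cells, thresholds, calls, summaries, profiles, KM curves,
Cox forest table, report.md) are written under the output directory, and the
run is fully determined by (config, seed).
"""

from pathlib import Path

from tmacyto import RunConfig, run_pipeline

cfg = RunConfig(preset="pdac-like", n_patients=20, seed=5,
                outdir="scratch/example_run")
results = run_pipeline(cfg)

out = Path(cfg.outdir)
print("artifacts:", sorted(p.name for p in out.iterdir())[:8], "...")
print()
print((out / "report.md").read_text())
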
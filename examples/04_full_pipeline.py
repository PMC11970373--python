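"""End-to-end pipeline run from files on disk.

Writes a synthetic dataset to a temporary directory, then drives the
whole analysis (normalize, subtract, call, union, cluster, enrich) from
the file-based interface and prints the summary the pipeline writes.
"""

import json
import tempfile
from pathlib import Path

from k9diff import (
    EnrichmentConfig,
    PeakCallConfig,
    PipelineConfig,
    SimulationConfig,
    run_pipeline,
    simulate_dataset,
    write_dataset,
)

workdir = Path(tempfile.mkdtemp(prefix="k9diff_demo_"))
config = SimulationConfig(seed=7)
repeats, truth, tracks = simulate_dataset(config)
paths = write_dataset(config.genome_model(), repeats, truth, tracks, workdir)
print(f"dataset written to {workdir} ({len(paths)} files)")

pipeline = PipelineConfig(
    genome_path=str(paths["chrom_sizes"]),
    sample_sheet=[{"sample_id": s.sample_id, "role": s.role,
                   "condition": s.condition,
                   "bedgraph": str(workdir / f"{s.sample_id}.bedgraph")}
                  for s in tracks],
    repeat_bed=str(paths["repeats"]),
    peak=PeakCallConfig(peak_cutoff=30, link_cutoff=15, min_peak_length=400),
    enrichment=EnrichmentConfig(n_shuffles=3),
    out_dir=str(workdir / "out"),
    seed=7,
)
result = run_pipeline(pipeline)
print(json.dumps(result.summary, indent=2, sort_keys=True))
print(f"outputs in {result.out_dir}")
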
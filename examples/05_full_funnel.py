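"""Run the complete screening funnel end-to-end on synthetic inputs.

`simulate_study` generates everything a real screen would need — query and
library SDF files, a pocket PDB, two pose files with planted interaction
profiles, and two docking-style score tables — then `run_pipeline` executes
shape screening, drug-likeness filtering, two-program top-N consensus and
pose-criteria evaluation, writing auditable per-stage artifacts.
"""

import tempfile
from pathlib import Path

from vsfunnel import PipelineConfig, run_pipeline, simulate_study

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = simulate_study(seed=7, n_compounds=20, out_dir=tmp)
    report = run_pipeline(PipelineConfig.from_yaml(cfg_path))
    print(report.to_text())
    print("Artifacts written to", Path(tmp) / "results")
    print(
        "\nCounts shrink monotonically through the funnel; the final selection "
        "contains only compounds whose poses from both programs satisfy the "
        "visual-inspection criteria."
    )
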
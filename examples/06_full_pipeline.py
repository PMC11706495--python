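"""The whole pipeline on disk, as the CLI runs it.

Simulates a study bundle (hypnogram/arousal/environment CSVs + metadata),
then runs score -> reliability -> equivalence -> compare -> report and
lists the result tables.  Equivalent shell usage:

    psgequiv simulate --config cfg.yaml
    psgequiv score --config cfg.yaml
    ...
"""

import json
import tempfile
from pathlib import Path

from psgequiv.pipeline import (RunConfig, cmd_compare, cmd_equivalence,
                               cmd_reliability, cmd_report, cmd_score,
                               cmd_simulate)

workdir = Path(tempfile.mkdtemp(prefix="psgequiv_demo_"))
cfg = RunConfig(study_dir=str(workdir / "study"),
                out_dir=str(workdir / "results"),
                seed=1, n_subjects=8, variables=["pct_n3", "tst_min"])

for stage in (cmd_simulate, cmd_score, cmd_reliability, cmd_equivalence,
              cmd_compare, cmd_report):
    stage(cfg)
    print(f"ran {stage.__name__}")

report = json.loads((Path(cfg.out_dir) / "report.json").read_text())
print("\nICC by variable and comparison:")
print(json.dumps(report["icc_by_variable"], indent=1))
print(f"\nfraction of equivalence verdicts: "
      f"{report['equivalent_fraction']:.2f}")
print(f"results in {cfg.out_dir}")
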
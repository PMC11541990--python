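"""End-to-end pipeline: simulate -> detect -> classify -> summarize.

Runs the full driver on a small synthetic cohort and prints where each
output table landed plus the detected driver-mCA screening performance.
Outputs are reproducible byte-for-byte from the seed in the manifest.
"""

import json
import tempfile
from pathlib import Path

from mcakit import ArraySimConfig, CohortConfig, DetectConfig, PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = PipelineConfig(
        out_dir=str(Path(tmp) / "run"),
        cohort=CohortConfig(
            group_sizes={"none": 120, "lc_mbl": 40, "hc_mbl": 30, "cll": 15, "sll": 5},
            seed=21,
        ),
        array=ArraySimConfig(n_sites=800, seed=21),
        detect=DetectConfig(n_boot=20),
        chromosomes=("6", "8", "11", "12", "13", "17"),
        cv_folds=5,
        seed=21,
    )
    manifest = run_pipeline(config)
    stats = json.loads((Path(config.out_dir) / "stats.json").read_text())

    print("outputs:", ", ".join(manifest["outputs"]))
    print("\ndetected canonical-mCA prevalence by group:")
    for row in stats["prevalence"]["has_canonical"]:
        print(f"  {row['group']:8s} {row['carriers']:3d}/{row['n']:3d} = {row['percent']}%")
    screen = stats["screening"]["driver_for_hc_mbl"]
    print(f"\ndriver-mCA screen for HC-MBL: sensitivity {screen['sensitivity']}%, "
          f"specificity {screen['specificity']}%")
    print("\nAt this probe density (800 sites/chromosome) focal events such as a")
    print("3 Mb del(13q) fall below the minimum-het threshold, so detected")
    print("prevalence sits below the injected truth rates while specificity")
    print("stays at ~100%.")
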
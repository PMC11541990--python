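"""Detect a mosaic event from simulated phased SNP-array signals.

Injects a copy-neutral LOH clone on 13q at a 20% cell fraction, runs the
CUSUM segmentation detector, and compares the called boundaries, type,
and estimated cell fraction with the injected truth.
"""

from mcakit import (
    ArraySimConfig,
    DetectConfig,
    MosaicEvent,
    SampleQC,
    detect_sample,
    simulate_array_signals,
)

truth = MosaicEvent("13", 30_000_000, 80_000_000, "cnn_loh", cell_fraction=0.20)
sites = simulate_array_signals(
    [truth],
    ArraySimConfig(n_sites=4000, baf_sd=0.03, phase_switch_rate=0.0, seed=5),
)
calls = detect_sample(
    sites, config=DetectConfig(), sample_qc=SampleQC(call_rate=1.0, baf_baseline=0.0),
    seed=1,
)

print(f"injected: {truth.type} {truth.chrom}:{truth.start}-{truth.end} f={truth.cell_fraction}")
for c in calls:
    print(
        f"called:   {c.type} {c.chrom}:{c.start}-{c.end} "
        f"dBAF={c.dbaf:.4f} LRR={c.mean_lrr:+.3f} f={c.cell_fraction:.3f} "
        f"z={c.quality:.1f} ({c.n_hets} hets)"
    )
print("\nThe phased BAF deviation (dBAF ~ f/2 for CNN-LOH) recovers the cell")
print("fraction; the near-zero mean LRR is what marks the event copy-neutral.")
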
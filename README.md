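# mcakit

Mosaic chromosomal alterations (mCAs) — clonally expanded gains, losses,
and copy-neutral loss-of-heterozygosity (CNN-LOH) of large DNA segments —
are a form of clonal hematopoiesis detectable from SNP-array data, and the
CLL-associated subset of them is tightly linked to monoclonal B-cell
lymphocytosis (MBL), the precursor state of chronic lymphocytic leukemia
(CLL). `mcakit` is a Python library for the full inference chain connecting
the two:

* **detection** of mCAs from phased B-allele frequency (BAF) and log R
  ratio (LRR) signals, with cell-fraction estimation;
* **taxonomy** of calls into canonical CLL-associated, CLL-driver, and
  lymphoid categories by genomic-interval rules;
* **lineage inference** comparing mCA cell fractions to flow-cytometric
  B-cell fractions;
* **concordance** of calls against clinical FISH results;
* **cohort statistics**: MBL classification, prevalence cross-tabs, crude
  and covariate-adjusted odds ratios, Mann–Whitney clone-size comparisons,
  screening sensitivity/specificity, polygenic-score computation, and
  cross-validated prediction AUCs;
* a **synthetic-data generator** producing cohorts and per-individual
  phased array signals with injected mosaic events, so every stage runs
  and is tested without access to patient data.

It is aimed at methodologists and analysts working on clonal hematopoiesis
and CLL precursor conditions who want a transparent, fully testable
implementation of this analysis chain.

## The model

A mosaic event of type *t* present in a fraction *f* of cells perturbs the
two array signals. At heterozygous sites, the BAF deviates from ½ by

| type | ΔBAF(f) | mixture copy number |
|---|---|---|
| loss | f / (2(2 − f)) | 2 − f |
| CNN-LOH | f / 2 | 2 |
| gain | f / (2(2 + f)) | 2 + f |

with LRR = log₂(copy number / 2). The direction of the BAF shift at each
het is set by which parental haplotype carries the event, so the *signed
phased deviation* hap·(BAF − ½) has mean +ΔBAF across the event and
averaging over many hets detects clones at cell fractions near 1%
(expected z ≈ 0.005/(0.03/√10⁴) ≈ 16.7 for a 1% CNN-LOH clone over
10,000 hets at per-site noise 0.03). Detection is CUSUM-style recursive
binary segmentation of the signed deviation followed by a z-threshold;
boundaries are refined by bootstrap; type comes from the mean LRR; the
cell fraction inverts the ΔBAF formulas above.

## Worked example

```python
from mcakit import (ArraySimConfig, DetectConfig, MosaicEvent, SampleQC,
                    detect_sample, simulate_array_signals)

truth = MosaicEvent("13", 30_000_000, 80_000_000, "cnn_loh", cell_fraction=0.20)
sites = simulate_array_signals([truth], ArraySimConfig(n_sites=4000, baf_sd=0.03,
                                                       phase_switch_rate=0.0, seed=5))
calls = detect_sample(sites, config=DetectConfig(),
                      sample_qc=SampleQC(call_rate=1.0, baf_baseline=0.0), seed=1)
for c in calls:
    print(c.type, f"{c.chrom}:{c.start}-{c.end}", round(c.cell_fraction, 3))
```

prints

```
cnn_loh 13:30097307-79930660 0.199
```

— the detector recovers the injected CNN-LOH boundaries to within a few
probe spacings and the 20% cell fraction from ΔBAF ≈ 0.099 ≈ f/2. The
`examples/` directory has one short narrative script per capability
(simulation, detection, taxonomy + lineage, cohort statistics, and the
end-to-end pipeline); each prints the numbers it computes and a line on
what they mean. A thin CLI (`mcakit simulate|detect|classify|lineage|
concordance|stats|run`) wraps the same functions for shell use.

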
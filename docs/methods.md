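# Methods

## Signal model and cell-fraction algebra

All inference rests on a two-population mixture: a diploid background and
a clone at cell fraction f carrying a single-copy change. For a
heterozygous SNP the B-allele frequency (BAF) is the B-copy count over
the total copy count of the mixture, which gives

* loss: ΔBAF = f / (2(2 − f)), copy number 2 − f
* CNN-LOH: ΔBAF = f / 2, copy number 2
* gain (one extra copy): ΔBAF = f / (2(2 + f)), copy number 2 + f

and LRR = log₂(copy number / 2). The inverse maps are exact:
f = 4d/(1 + 2d) (loss), 2d (CNN-LOH), 4d/(1 − 2d) capped at 1 (gain;
the single-extra-copy model saturates at d = 1/6, and larger deviations
are attributed to f = 1 rather than to multi-copy states, which are out
of scope). ΔBAF is strictly increasing in f for each type, and at equal
f a loss produces a larger deviation than a gain — both properties are
asserted by tests. The simulator and the detector import the same two
functions, so parameter-recovery tests exercise a genuine shared
contract rather than two parallel formulas.

The sign of the per-site BAF shift depends on which parental haplotype
carries the event. With phased genotypes, the signed phased deviation
y = hap·(BAF − ½) has mean +ΔBAF over the event regardless of allele
labels; its z statistic ΔBAF/(sd/√n) is the detection statistic. This is
what buys sensitivity at ~1% cell fraction: at per-site noise 0.03 and
10⁴ hets, a 1% CNN-LOH clone (ΔBAF = 0.005) has expected z ≈ 16.7.

## Detection

Detection is deliberately simple: recursive binary segmentation of the
signed-deviation sequence using the standardized CUSUM change-point
statistic (two-sample z of left vs right means), recursing while the
best split exceeds `split_z` and both children retain `min_hets` sites;
final segments whose mean-vs-zero z exceeds `z_threshold` become
candidates. A hidden Markov model over copy states (the approach used by
production mCA callers) would be more sensitive for fragmented or
low-density data; the segmentation detector is easier to reason about,
fully testable, and sufficient at the simulated probe densities. This is
a documented fidelity limitation, not an oversight.

Defaults: `min_hets = 25`, `z_threshold = split_z = 5`, `lrr_margin =
0.05`. The z = 5 threshold puts the per-chromosome false-positive rate
well below the nominal `fwer = 0.01` at realistic noise (the null-
calibration test measures 0 calls in 500 event-free chromosomes); ties
in the CUSUM maximum break toward the smaller index for determinism.

Boundary refinement bootstraps het sites (with replacement) in a window
of `refine_window` hets around each raw boundary, re-localizes the
change point per resample, and reports the per-boundary median.
`n_boot = 1` is defined as the plain fit on the original data, so the
degenerate case is deterministic. Because a given het can be absent from
a particular resample, individual resamples can land one or two sites
off even on noiseless data; the median is exact there, which is what the
tests assert.

Type classification thresholds the mean LRR of the refined interval at
±`lrr_margin`: below → loss, above → gain, inside with positive ΔBAF →
CNN-LOH, otherwise undetermined. Undetermined calls receive a cell
fraction via the copy-neutral formula (2·ΔBAF) so that downstream
invariants (cell fraction in [0, 1]) hold; it is a lower-bound style
guess and flagged by the type label itself.

Call filters mirror standard mCA quality control: sample call rate,
genome-wide BAF baseline deviation, phase quality (fraction of hets
whose deviation sign matches the segment consensus; random phase gives
0.5), and a germline check — a call whose ΔBAF and LRR both sit at their
constitutional (f = 1) values is a germline CNV or homozygosity run, not
a mosaic event. Threshold values are configuration defaults, not
published constants.

Phase-switch errors are injected by the simulator but deliberately not
corrected by the detector (no local re-phasing). A switch inside an
event flips the sign of the deviation from that point on, so the
detector splits such an event into adjacent opposite-phase segments;
each piece still carries the correct ΔBAF and cell fraction. At the
default switch rate (0.002 per adjacent het pair) this affects a small
minority of events and is accepted as attenuation.

Sex-chromosome loss (LoY in males, LoX in females) has no het BAF to
lean on, so it is called from the median LRR alone:
f = 2(1 − 2^median LRR), clipped to [0, 1], emitted when the LRR shift
is significant and f exceeds a floor (default 0.05).

## Taxonomy

Intervals are 0-based half-open throughout (BED convention). The
canonical list encodes the CLL clinical FISH panel: del 6q, del 11q,
trisomy 12, del 13q, del 17p, plus CNN-LOH on 13q required to contain
the MIR16-1 anchor locus. Matching rules where the underlying definitions
are genuinely underspecified were fixed as: an arm entry matches on ≥1 bp
overlap with matching type (a fractional-overlap option exists per
entry); trisomy 12 requires a gain covering ≥80% of the chromosome —
an arm-level gain of 12p alone is not trisomy. A driver call must
*fully contain* a candidate driver region of exactly matching type
(large mCAs span focal drivers, not the reverse); CNN-LOH is not
interchangeable with loss for containment. Categories are OR-aggregated
flags, never a partition — canonical ⊆ driver by construction, and a
call can be canonical and lymphoid at once.

The shipped driver-candidate and lymphoid lists are small illustrative
examples with hg38-approximate coordinates (including the MIR16-1
anchor); faithful replication of published analyses requires supplying
the full published region lists, which are not distributed here.

## Lineage and concordance

For each individual and category, the mCA cell fraction is the maximum
over that category's autosomal calls (the largest clone is the
informative one), 0 when absent. `exceeds` uses strict inequality — a
tie does not count as evidence of origin before B-cell commitment, the
conservative direction. The comparison is cleanly interpretable only
when DNA and flow cytometry share a sample source, hence the PBMC
restriction option. Both cell-fraction estimates are imprecise; the
module computes the comparison and makes no stronger claim.

FISH concordance cross-tabulates array calls against FISH truth at the
five panel loci over individuals present in both assays; 13q FISH
positives may be matched by a CNN-LOH call containing the anchor
(toggleable), since the deletion probes detect the lesion in both
forms. Zero denominators report None rather than 0.

## Cohort statistics

Percentages round half-up to one decimal, the convention that
reproduces printed cohort tables (52.108 → 52.1, 99.865 → 99.9,
14.976 → 15.0, 1.665 → 1.7, 57.228 → 57.2, 98.540 → 98.5). MBL
classification implements both the relative rule (clone ≥85% of B cells
→ high-count) and the absolute rule (<500 cells/µL low-count, 500–5000
high-count; above 5000 exceeds the MBL definition and raises rather
than silently binning). Crude odds ratios use the cross-product with
Woolf CIs and optional Haldane–Anscombe correction; adjusted odds
ratios come from an IRLS logistic fit (deviance tolerance 1e-8, ≤100
iterations) with Wald CIs, and quasi-separation — a binary exposure
absent from one outcome arm, or a diverging coefficient — is reported
as a flag instead of a silently huge OR. With no covariates the
logistic OR equals the crude OR; a test enforces this equivalence. The
clone-size comparison is the two-sided Mann–Whitney U with tie and
continuity corrections (completely tied data returns p = 1); no
multiple-testing correction is applied anywhere, matching the raw-p
reporting style of cohort tables. The polygenic score is the weighted
average Σwᵢdᵢ/Σwᵢ over allele dosages with mean imputation for missing
entries. Prediction uses stratified 10-fold cross-validation with
pooled out-of-fold probabilities (lower variance than averaging
per-fold AUCs) and the rank-statistic AUC; the four predictor sets are
ALC alone, driver-mCA alone, demographics + mCA + PRS, and all four
combined.

## Synthetic cohorts

The generator's defaults encode the study conditions the analysis
assumes: groups none / LC-MBL / HC-MBL / CLL / SLL with sizes 2971 /
728 / 332 / 497 / 104, and per-group prevalences of six event
categories (canonical, extra driver, extra lymphoid, other autosomal,
LoY, LoX) matching the observed carrier fractions (canonical: 52.1% in
HC-MBL, 1.1% in LC-MBL, 0.135% in unaffected). Canonical events are
drawn uniformly from six locus templates (del 6q/11q/13q/17p, trisomy
12, CNN-LOH 13q); the non-canonical categories each have one fixed
template chosen to exercise exactly one taxonomy rule.

Distribution families are stand-ins where no empirical distribution is
published: clonal B-cell % is Beta scaled to (0, 85) for LC-MBL and
Uniform(85, 100) for HC-MBL; B-cell fraction is Beta per group; ALC is
lognormal (medians ≈1800 cells/µL unaffected, ≈3000 HC-MBL, ≈12,000
CLL); the PRS is standard normal with per-group mean shifts; the event
cell fraction is Beta(1.5, 3). Clone-size and cell-fraction
distributions in particular are placeholders, not calibrated claims —
cohort-level quantities computed from them (e.g. the fraction of
carriers whose clone exceeds the B-cell fraction, or the synthetic
prediction AUCs) characterize the pipeline under these conditions, not
the real cohort. The generator omits linkage disequilibrium, germline
CNVs, raw intensity artifacts, probe-density variation, and batch-
dependent noise, so passing tests demonstrate correctness of the
inference chain, not performance on real arrays.

BAF noise is truncated (not resampled) to [0, 1], keeping the noise
model monotone in `baf_sd`; phase labels carry cumulative switch errors
(a realistic long-range decay of phasing quality).

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen as the package's
own defaults: 200 replicates of 10⁴ hets for the detection limit, 500
event-free chromosomes of 2000 sites for null calibration, cohorts of
n = 3000 over 100 seeds per effect size for odds-ratio coverage, and
the full default synthetic cohort (4632 individuals) for the prediction
AUCs. All randomness flows through numpy Generators seeded from a
single integer; reruns are byte-identical (the pipeline manifest
records output SHA-256 digests to make this checkable). Degenerate
inputs are defined, not left to chance: zero-variance windows give
z = 0 when the mean is zero and +inf otherwise; empty candidate driver
lists make driver classification canonical-only with a warning; zero
denominators yield None.

## Known limitations

No HMM detection, no multi-copy gains or subclonal mixtures, no
re-phasing, no genotype QC or ancestry estimation, no immunophenotype
logic beyond a stored label, and illustrative rather than published
region lists. The detector's sensitivity at low probe density is
materially below that of production callers for focal events (a 3 Mb
del(13q) needs ≥25 hets to be callable at all).
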
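"""Detector unit and property tests: cell-fraction algebra, phased deviation
statistics, CUSUM segmentation, boundary refinement, classification, filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcakit.detect import (
    DetectConfig,
    SampleQC,
    SegmentCall,
    apply_filters,
    cf_to_dbaf,
    classify_event_type,
    dbaf_to_cf,
    detect_sex_chrom_loss,
    expected_lrr,
    refine_boundaries,
    segment_scan,
    signed_phased_deviation,
)
from mcakit.errors import ConfigurationError, InputError
from mcakit.simulate import ArraySimConfig, MosaicEvent, simulate_array_signals


# ---------------------------------------------------------------------------
# cell-fraction algebra
# ---------------------------------------------------------------------------

@given(
    st.sampled_from(["loss", "gain", "cnn_loh"]),
    st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
)
def test_cf_dbaf_round_trip_identity(etype, f):
    """cf -> dBAF -> cf is the identity to 1e-12 for all event types."""
    assert dbaf_to_cf(etype, cf_to_dbaf(etype, f)) == pytest.approx(f, abs=1e-12)


@pytest.mark.parametrize(
    "etype,dbaf,expected_f",
    [
        ("cnn_loh", 0.5, 1.0),
        ("cnn_loh", 0.25, 0.5),
        ("loss", 0.5, 1.0),
    ],
)
def test_dbaf_to_cf_closed_forms(etype, dbaf, expected_f):
    assert dbaf_to_cf(etype, dbaf) == pytest.approx(expected_f, abs=1e-12)


def test_gain_dbaf_saturates_at_one_sixth():
    """A fully clonal single-copy gain gives dBAF = 1/(2*3); beyond that f caps at 1."""
    assert cf_to_dbaf("gain", 1.0) == pytest.approx(1.0 / 6.0, abs=1e-12)
    assert dbaf_to_cf("gain", 0.2) == 1.0


def test_dbaf_monotone_in_f_and_loss_exceeds_gain():
    fs = np.linspace(0.01, 0.99, 50)
    for etype in ("loss", "gain", "cnn_loh"):
        d = [cf_to_dbaf(etype, f) for f in fs]
        assert np.all(np.diff(d) > 0)
    for f in fs:
        assert cf_to_dbaf("loss", f) > cf_to_dbaf("gain", f)


def test_algebra_input_validation():
    with pytest.raises(InputError):
        cf_to_dbaf("loss", 1.5)
    with pytest.raises(InputError):
        dbaf_to_cf("loss", 0.6)
    with pytest.raises(InputError):
        dbaf_to_cf("deletion", 0.1)


# ---------------------------------------------------------------------------
# signed phased deviation
# ---------------------------------------------------------------------------

def test_signed_deviation_zero_on_balanced_baf():
    baf = np.full(100, 0.5)
    hap = np.ones(100)
    dbaf, z = signed_phased_deviation(baf, hap)
    assert dbaf == 0.0 and z == 0.0


def test_signed_deviation_exact_quarter_shift():
    """1000 hets with hap*(baf-0.5) = +0.25 exactly (noiseless CNN-LOH at f=0.5)."""
    hap = np.where(np.arange(1000) % 2 == 0, 1.0, -1.0)
    baf = 0.5 + hap * 0.25
    dbaf, z = signed_phased_deviation(baf, hap)
    assert dbaf == pytest.approx(0.25, abs=1e-12)
    assert math.isinf(z)  # zero variance, nonzero mean


def test_signed_deviation_no_call_below_min_hets():
    assert signed_phased_deviation(np.full(10, 0.5), np.ones(10), min_hets=25) is None


def test_z_statistic_detects_one_percent_clone(rng):
    """CNN-LOH at f=0.01 over 10,000 hets with baf_sd=0.03: expected z ~ 16.7."""
    n, d, sd = 10_000, 0.005, 0.03
    zs = []
    for _ in range(30):
        hap = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        baf = 0.5 + hap * d + rng.normal(0, sd, n)
        _, z = signed_phased_deviation(baf, hap)
        zs.append(z)
    assert np.mean(zs) == pytest.approx(16.7, rel=0.15)
    assert all(z > 3 for z in zs)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _sim_sites(events, n_sites, seed, het_fraction=0.5, baf_sd=0.03, switch=0.0):
    cfg = ArraySimConfig(
        n_sites=n_sites, het_fraction=het_fraction, baf_sd=baf_sd,
        lrr_sd=0.2, phase_switch_rate=switch, seed=seed,
    )
    return simulate_array_signals(events, cfg, chromosomes=["13"])


def test_segment_scan_null_no_candidates():
    """Pure-noise chromosomes yield zero candidates at the default z threshold."""
    n_fp = 0
    for seed in range(20):
        sites = _sim_sites([], 2000, seed)
        n_fp += len(segment_scan(sites, DetectConfig()))
    assert n_fp == 0


def test_segment_scan_recovers_injected_event():
    """One injected CNN-LOH at f=0.3 gives exactly one candidate, Jaccard >= 0.9."""
    ev = MosaicEvent("13", 30_000_000, 70_000_000, "cnn_loh", 0.3)
    sites = _sim_sites([ev], 10_000, seed=7)
    cands = segment_scan(sites, DetectConfig())
    assert len(cands) == 1
    c = cands[0]
    inter = min(c["end"], ev.end) - max(c["start"], ev.start)
    union = max(c["end"], ev.end) - min(c["start"], ev.start)
    assert inter / union >= 0.9


def test_segment_scan_whole_chromosome_event():
    ev = MosaicEvent("13", 0, 114_364_328, "cnn_loh", 0.4)
    sites = _sim_sites([ev], 3000, seed=3)
    cands = segment_scan(sites, DetectConfig())
    assert len(cands) == 1
    n_hets = int((sites["genotype"] == "AB").sum())
    assert cands[0]["j"] - cands[0]["i"] == n_hets


def test_segment_scan_rejects_unsorted_input():
    sites = _sim_sites([], 500, seed=0)
    shuffled = sites.sample(frac=1, random_state=1).reset_index(drop=True)
    with pytest.raises(InputError):
        segment_scan(shuffled, DetectConfig())


# ---------------------------------------------------------------------------
# boundary refinement
# ---------------------------------------------------------------------------

def _step_sites(n, lo, hi, d=0.2):
    """Noiseless het-only chromosome with a mean step on [lo, hi) (het indices)."""
    pos = np.arange(n) * 1000
    hap = np.ones(n)
    baf = np.full(n, 0.5)
    baf[lo:hi] += d
    return pd.DataFrame(
        {"chrom": "13", "pos": pos, "genotype": "AB", "hap": hap.astype(int),
         "baf": baf, "lrr": 0.0}
    )


def test_refine_boundaries_noiseless_step():
    sites = _step_sites(1000, 300, 700)
    seg = {"i": 290, "j": 710}
    start, end = refine_boundaries(sites, seg, n_boot=50, seed=0)
    assert start == 300 * 1000
    assert end == 699 * 1000 + 1


def test_refine_n_boot_one_is_plain_cusum_fit():
    sites = _step_sites(1000, 300, 700)
    seg = {"i": 250, "j": 750}
    assert refine_boundaries(sites, seg, n_boot=1, seed=0) == refine_boundaries(
        sites, seg, n_boot=1, seed=99
    )


def test_refine_boundaries_noisy_within_50_hets():
    """Injected event at f=0.2, baf_sd=0.03: boundary medians within 50 hets of truth."""
    ev = MosaicEvent("13", 30_000_000, 70_000_000, "cnn_loh", 0.2)
    sites = _sim_sites([ev], 8000, seed=11)
    cands = segment_scan(sites, DetectConfig())
    assert len(cands) == 1
    start, end = refine_boundaries(sites, cands[0], n_boot=100, seed=5)
    het_pos = sites.loc[sites["genotype"] == "AB", "pos"].to_numpy()
    spacing = np.median(np.diff(het_pos))
    assert abs(start - ev.start) <= 50 * spacing
    assert abs(end - ev.end) <= 50 * spacing


def test_refine_rejects_bad_n_boot():
    sites = _step_sites(100, 40, 60)
    with pytest.raises(ConfigurationError):
        refine_boundaries(sites, {"i": 40, "j": 60}, n_boot=0)


# ---------------------------------------------------------------------------
# type classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dbaf,lrr,expected",
    [
        (0.25, 0.0, "cnn_loh"),
        (0.4 / (2 * 1.6), math.log2(1.6 / 2), "loss"),   # f=0.4 loss: lrr ~ -0.32
        (0.4 / (2 * 2.4), math.log2(2.4 / 2), "gain"),   # f=0.4 gain: lrr ~ +0.26
        (0.0, 0.0, "undetermined"),
    ],
)
def test_classify_event_type(dbaf, lrr, expected):
    assert classify_event_type(dbaf, lrr, lrr_margin=0.05) == expected


def test_classify_rejects_negative_dbaf():
    with pytest.raises(InputError):
        classify_event_type(-0.1, 0.0)


# ---------------------------------------------------------------------------
# detection power is monotone in f and n_hets
# ---------------------------------------------------------------------------

def test_power_monotone_in_f_and_n_hets(rng):
    """z-based detection power is non-decreasing along both axes of a 3x3 grid."""
    fs = [0.01, 0.05, 0.2]
    ns = [100, 400, 1600]
    power = np.zeros((3, 3))
    for i, f in enumerate(fs):
        d = cf_to_dbaf("cnn_loh", f)
        for j, n in enumerate(ns):
            hits = 0
            for _ in range(40):
                hap = np.where(rng.random(n) < 0.5, 1.0, -1.0)
                baf = 0.5 + hap * d + rng.normal(0, 0.03, n)
                _, z = signed_phased_deviation(baf, hap)
                hits += z > 5
            power[i, j] = hits / 40
    assert np.all(np.diff(power, axis=0) >= 0)
    assert np.all(np.diff(power, axis=1) >= 0)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _call(**kw):
    base = dict(
        chrom="13", start=0, end=10_000_000, type="loss", dbaf=0.1,
        mean_lrr=-0.1, cell_fraction=0.35, n_hets=200, quality=12.0,
        phase_concordance=0.95,
    )
    base.update(kw)
    return SegmentCall(**base)


def test_filters_flag_constitutional_deletion():
    """dBAF = 0.5 with LRR = -1 is the f=1 limit of a loss: germline, not mosaic."""
    call = _call(dbaf=0.5, mean_lrr=-1.0, cell_fraction=1.0)
    passed, flagged = apply_filters([call], SampleQC(1.0, 0.0))
    assert passed == []
    assert "germline" in flagged[0].filter_flags


def test_filters_retain_nominal_call():
    passed, _ = apply_filters([_call()], SampleQC(call_rate=1.0, baf_baseline=0.0))
    assert len(passed) == 1 and passed[0].filter_flags == ()


def test_filters_drop_random_phase():
    call = _call(phase_concordance=0.5)
    cfg = DetectConfig(min_phase_concordance=0.6)
    passed, flagged = apply_filters([call], SampleQC(1.0, 0.0), cfg)
    assert passed == [] and "low_phase_quality" in flagged[0].filter_flags


def test_filters_drop_low_call_rate_sample():
    passed, flagged = apply_filters([_call()], SampleQC(call_rate=0.90, baf_baseline=0.0))
    assert passed == [] and "low_call_rate" in flagged[0].filter_flags


def test_filters_error_names_missing_metric():
    with pytest.raises(InputError, match="baf_baseline"):
        apply_filters([_call()], SampleQC(call_rate=1.0, baf_baseline=None))


# ---------------------------------------------------------------------------
# sex-chromosome loss
# ---------------------------------------------------------------------------

def _sex_sites(chrom, median_lrr, n=500, sd=0.15, seed=0):
    r = np.random.default_rng(seed)
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(n) * 10_000, "genotype": "AA",
         "hap": 0, "baf": 0.0, "lrr": median_lrr + r.normal(0, sd, n)}
    )


def test_no_loy_call_without_lrr_shift():
    assert detect_sex_chrom_loss(_sex_sites("Y", 0.0), "male") is None


def test_complete_loss_gives_f_one():
    call = detect_sex_chrom_loss(_sex_sites("Y", -1.0), "male")
    assert call is not None
    assert call.cell_fraction == pytest.approx(1.0, abs=0.05)


def test_loy_cell_fraction_recovery():
    """LoY at f=0.3 implies median LRR = log2(0.85); f recovered within 0.05."""
    call = detect_sex_chrom_loss(_sex_sites("Y", math.log2(0.85), seed=4), "male")
    assert call is not None
    assert call.cell_fraction == pytest.approx(0.3, abs=0.05)


def test_sex_chrom_loss_wrong_chromosome_errors():
    with pytest.raises(InputError):
        detect_sex_chrom_loss(_sex_sites("X", -1.0), "male")
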
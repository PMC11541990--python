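"""Mosaic chromosomal alteration detection from phased SNP-array signals.

A mosaic event present in a fraction ``f`` of cells perturbs two array
signals: at heterozygous sites the B-allele frequency (BAF) departs from
0.5 by a type-dependent amount dBAF(type, f), with the direction of the
departure set by which parental haplotype carries the event; and the log R
ratio (LRR, log2 of total intensity relative to diploid) shifts according
to the mixture copy number.  Phasing makes the tiny per-site BAF shifts
coherent: the *signed phased deviation* ``hap * (baf - 0.5)`` has mean
+dBAF across the event regardless of which allele is the B allele, so
averaging over many heterozygous sites detects cell fractions far below
per-site noise.

Under a two-population mixture (diploid cells plus event-carrying cells at
fraction f, single-copy change):

=========  ====================  ==========================
type       dBAF(f)               mixture copy number
=========  ====================  ==========================
loss       f / (2 (2 - f))       2 - f
cnn_loh    f / 2                 2
gain       f / (2 (2 + f))       2 + f
=========  ====================  ==========================

and LRR = log2(copy number / 2).  Inverting dBAF gives the cell-fraction
estimators ``dbaf_to_cf``.

Detection is CUSUM-style recursive binary segmentation on the signed
phased deviation sequence followed by a z-threshold on candidate
segments, bootstrap boundary refinement, LRR-based type classification,
and the call-level filters (sample call rate, BAF baseline, phase
quality, germline likelihood).  This is a deliberately simple detector —
no hidden Markov model, no multi-copy states, no subclone deconvolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

EVENT_TYPES = ("loss", "gain", "cnn_loh")

#: mixture copy number contributed by one event-carrying cell
_EVENT_COPIES = {"loss": 1.0, "cnn_loh": 2.0, "gain": 3.0}


# ---------------------------------------------------------------------------
# cell-fraction algebra (shared contract with the signal simulator)
# ---------------------------------------------------------------------------

def cf_to_dbaf(event_type: str, f: float) -> float:
    """Expected het-site BAF deviation |BAF - 0.5| for an event at cell fraction *f*."""
    if event_type not in EVENT_TYPES:
        raise InputError(f"unknown event type {event_type!r}")
    if not 0.0 <= f <= 1.0:
        raise InputError(f"cell fraction must be in [0, 1], got {f}")
    if event_type == "cnn_loh":
        return f / 2.0
    if event_type == "loss":
        return f / (2.0 * (2.0 - f))
    return f / (2.0 * (2.0 + f))


def dbaf_to_cf(event_type: str, dbaf: float) -> float:
    """Invert :func:`cf_to_dbaf`: estimate cell fraction from a BAF deviation.

    For gains the single-extra-copy model saturates at dbaf = 1/6; larger
    deviations are capped at f = 1.
    """
    if event_type not in EVENT_TYPES:
        raise InputError(f"unknown event type {event_type!r}")
    if not 0.0 <= dbaf <= 0.5:
        raise InputError(f"dbaf must be in [0, 0.5], got {dbaf}")
    if event_type == "cnn_loh":
        return 2.0 * dbaf
    if event_type == "loss":
        return 4.0 * dbaf / (1.0 + 2.0 * dbaf)
    return min(4.0 * dbaf / (1.0 - 2.0 * dbaf), 1.0) if dbaf < 0.5 else 1.0


def expected_lrr(event_type: str, f: float) -> float:
    """Expected log R ratio for an event at cell fraction *f*."""
    c = _EVENT_COPIES[event_type]
    return math.log2(((1.0 - f) * 2.0 + f * c) / 2.0)


# ---------------------------------------------------------------------------
# configuration and call container
# ---------------------------------------------------------------------------

@dataclass
class DetectConfig:
    """Tunables of the segmentation detector and call filters.

    Defaults are set so that event-free chromosomes at realistic array
    noise produce false-positive calls at a family-wise rate below
    ``fwer`` (see the null-calibration tests).
    """

    min_hets: int = 25            # minimum heterozygous sites per segment
    z_threshold: float = 5.0      # emit a candidate when |mean|/SE exceeds this
    split_z: float = 5.0          # recurse on a change point when the two-sample z exceeds this
    lrr_margin: float = 0.05      # |mean LRR| band for copy-neutral classification
    n_boot: int = 100             # bootstrap resamples for boundary refinement
    refine_window: int = 300      # hets searched either side of a raw boundary
    fwer: float = 0.01            # nominal per-chromosome false-positive rate at these settings
    # call filters
    min_call_rate: float = 0.97
    max_baf_baseline: float = 0.05
    min_phase_concordance: float = 0.6
    germline_dbaf_tol: float = 0.02
    germline_lrr_tol: float = 0.10
    # sex-chromosome loss
    sex_loss_min_cf: float = 0.05
    sex_loss_z: float = 5.0


@dataclass
class SegmentCall:
    """One called mosaic segment (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    type: str                     # loss | gain | cnn_loh | undetermined
    dbaf: float
    mean_lrr: float
    cell_fraction: float
    n_hets: int
    quality: float                # detection z statistic
    phase_concordance: float = float("nan")
    filter_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"segment start {self.start} >= end {self.end}")


@dataclass
class SampleQC:
    """Per-sample quality metrics consumed by :func:`apply_filters`."""

    call_rate: float | None = None
    baf_baseline: float | None = None   # |median het BAF - 0.5| genome-wide


# ---------------------------------------------------------------------------
# detection statistics
# ---------------------------------------------------------------------------

def signed_phased_deviation(
    baf: np.ndarray, hap: np.ndarray, min_hets: int = 1
) -> tuple[float, float] | None:
    """Phased BAF-deviation estimate and its z statistic over a het window.

    Returns ``(dbaf, z)`` where ``dbaf = |mean(hap * (baf - 0.5))|`` and
    ``z = dbaf / (sd / sqrt(n))`` with the sample standard deviation of
    the signed deviations.  Returns ``None`` (no-call) with fewer than
    *min_hets* sites; a zero-variance window with zero mean gives z = 0.
    """
    baf = np.asarray(baf, dtype=float)
    hap = np.asarray(hap, dtype=float)
    if baf.shape != hap.shape:
        raise InputError("baf and hap must have equal length")
    n = baf.size
    if n < min_hets:
        return None
    y = hap * (baf - 0.5)
    dbaf = abs(float(np.mean(y)))
    sd = float(np.std(y, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        z = 0.0 if dbaf == 0.0 else float("inf")
    else:
        z = dbaf / (sd / math.sqrt(n))
    return dbaf, z


def _best_split(y: np.ndarray, min_len: int) -> tuple[int, float]:
    """Best single change point of the mean of *y* (two-sample z, CUSUM form).

    Returns ``(k, stat)`` where the split is between indices k-1 and k.
    Ties break toward the smaller index (np.argmax convention).  Returns
    ``(-1, 0.0)`` when no admissible split exists.
    """
    n = y.size
    if n < 2 * min_len:
        return -1, 0.0
    s = np.cumsum(y)
    k = np.arange(min_len, n - min_len + 1)
    mean_l = s[k - 1] / k
    mean_r = (s[-1] - s[k - 1]) / (n - k)
    sd = float(np.std(y, ddof=1))
    diff = np.abs(mean_l - mean_r)
    if sd == 0.0:
        stat = np.where(diff > 0, np.inf, 0.0)
    else:
        stat = diff / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    i = int(np.argmax(stat))
    return int(k[i]), float(stat[i])


def _binary_segment(y: np.ndarray, config: DetectConfig) -> list[tuple[int, int]]:
    """Recursive binary segmentation; returns half-open het-index intervals."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        k, stat = _best_split(y[lo:hi], config.min_hets)
        if k >= 0 and stat > config.split_z:
            recurse(lo, lo + k)
            recurse(lo + k, hi)
        else:
            out.append((lo, hi))

    if y.size:
        recurse(0, y.size)
    return out


def segment_scan(sites: pd.DataFrame, config: DetectConfig | None = None) -> list[dict]:
    """Scan one chromosome for candidate mosaic segments.

    *sites* must be sorted by ``pos`` and contain columns ``pos``,
    ``genotype``, ``hap``, ``baf``.  Returns candidate dictionaries with
    het-index bounds (``i``, ``j`` into the het subset), bp bounds, the
    deviation estimate and z statistic.  Candidates are the segments from
    recursive binary segmentation whose z exceeds ``config.z_threshold``.
    """
    config = config or DetectConfig()
    pos = np.asarray(sites["pos"], dtype=np.int64)
    if np.any(np.diff(pos) < 0):
        raise InputError("sites must be sorted by position")
    het_mask = np.asarray(sites["genotype"] == "AB")
    het_pos = pos[het_mask]
    baf = np.asarray(sites.loc[het_mask, "baf"], dtype=float)
    hap = np.asarray(sites.loc[het_mask, "hap"], dtype=float)
    y = hap * (baf - 0.5)
    if y.size < config.min_hets:
        return []
    candidates = []
    for lo, hi in _binary_segment(y, config):
        res = signed_phased_deviation(baf[lo:hi], hap[lo:hi], config.min_hets)
        if res is None:
            continue
        dbaf, z = res
        if z > config.z_threshold:
            signed_mean = float(np.mean(y[lo:hi]))
            concord = float(np.mean(np.sign(y[lo:hi]) == np.sign(signed_mean)))
            candidates.append(
                {
                    "i": lo,
                    "j": hi,
                    "start": int(het_pos[lo]),
                    "end": int(het_pos[hi - 1]) + 1,
                    "dbaf": dbaf,
                    "z": z,
                    "phase_concordance": concord,
                }
            )
    return candidates


def refine_boundaries(
    sites: pd.DataFrame,
    segment: dict,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
    config: DetectConfig | None = None,
) -> tuple[int, int]:
    """Bootstrap point estimates of a candidate segment's boundaries (bp).

    Each boundary is re-localized by maximizing the CUSUM change-point
    statistic of the signed phased deviation within a window around the
    raw boundary; with ``n_boot > 1`` het sites are resampled with
    replacement and the per-boundary median across resamples is returned.
    ``n_boot == 1`` is the plain fit on the original data (degenerate
    resampling).
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    config = config or DetectConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    het = sites[sites["genotype"] == "AB"]
    het_pos = np.asarray(het["pos"], dtype=np.int64)
    y = np.asarray(het["hap"], dtype=float) * (np.asarray(het["baf"], dtype=float) - 0.5)
    n = y.size
    i, j = segment["i"], segment["j"]
    w = config.refine_window
    mid = (i + j) // 2

    def localize(win_lo: int, win_hi: int) -> int:
        """Het index of the change point within [win_lo, win_hi)."""
        win = np.arange(win_lo, win_hi)
        if win.size < 4:
            return win_lo
        ests = []
        for b in range(n_boot):
            if n_boot == 1:
                idx = win
            else:
                idx = np.sort(rng.choice(win, size=win.size, replace=True))
            k, _ = _best_split(y[idx], 1)
            ests.append(int(idx[k]) if k >= 0 else int(idx[0]))
        return int(np.median(ests))

    left = localize(max(0, i - w), min(mid, i + w))
    right = localize(max(mid, j - w), min(n, j + w))
    if right <= left:
        right = left + 1
    start = int(het_pos[left])
    end = int(het_pos[min(right, n) - 1]) + 1
    return start, end


def classify_event_type(dbaf: float, mean_lrr: float, lrr_margin: float = 0.05) -> str:
    """Assign loss / gain / cnn_loh / undetermined from ΔBAF and mean LRR."""
    if dbaf < 0:
        raise InputError("dbaf must be >= 0")
    if mean_lrr < -lrr_margin:
        return "loss"
    if mean_lrr > lrr_margin:
        return "gain"
    if dbaf > 0:
        return "cnn_loh"
    return "undetermined"


def detect_chromosome(
    sites: pd.DataFrame,
    config: DetectConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SegmentCall]:
    """Full single-chromosome detection: scan, refine, classify, estimate f."""
    config = config or DetectConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom = str(sites["chrom"].iloc[0]) if len(sites) else ""
    candidates = segment_scan(sites, config)
    calls: list[SegmentCall] = []
    for cand in candidates:
        start, end = refine_boundaries(sites, cand, config.n_boot, rng, config)
        span = sites[(sites["pos"] >= start) & (sites["pos"] < end)]
        het = span[span["genotype"] == "AB"]
        res = signed_phased_deviation(
            np.asarray(het["baf"], dtype=float),
            np.asarray(het["hap"], dtype=float),
            config.min_hets,
        )
        if res is None:
            continue
        dbaf, z = res
        mean_lrr = float(np.mean(span["lrr"]))
        etype = classify_event_type(dbaf, mean_lrr, config.lrr_margin)
        d = min(dbaf, 0.5)
        cf = dbaf_to_cf(etype, d) if etype != "undetermined" else min(2.0 * d, 1.0)
        y = np.asarray(het["hap"], dtype=float) * (np.asarray(het["baf"], dtype=float) - 0.5)
        signed_mean = float(np.mean(y))
        concord = float(np.mean(np.sign(y) == np.sign(signed_mean))) if y.size else float("nan")
        calls.append(
            SegmentCall(
                chrom=chrom,
                start=start,
                end=end,
                type=etype,
                dbaf=d,
                mean_lrr=mean_lrr,
                cell_fraction=cf,
                n_hets=int(len(het)),
                quality=z,
                phase_concordance=concord,
            )
        )
    return calls


def detect_sex_chrom_loss(
    sites: pd.DataFrame, sex: str, config: DetectConfig | None = None
) -> SegmentCall | None:
    """Call mosaic loss of Y (males) or X (females) from the median LRR shift.

    Het BAF is uninformative on the male X/Y, so the cell fraction comes
    from the LRR alone: for a single-copy loss at fraction f the mixture
    copy number is ``c = 2 - f`` on a nominally two-copy scale, i.e.
    ``f = 2 (1 - 2**median_lrr)``, clipped to [0, 1].  A call is emitted
    when the shift is significant (one-sample z) and f exceeds the
    configured floor.
    """
    config = config or DetectConfig()
    if len(sites) == 0:
        return None
    chrom = str(sites["chrom"].iloc[0]).removeprefix("chr")
    expected = "Y" if sex == "male" else "X"
    if chrom != expected:
        raise InputError(
            f"sex-chromosome loss for sex={sex!r} expects chromosome {expected}, got {chrom!r}"
        )
    lrr = np.asarray(sites["lrr"], dtype=float)
    med = float(np.median(lrr))
    f = float(np.clip(2.0 * (1.0 - 2.0 ** med), 0.0, 1.0))
    sd = float(np.std(lrr, ddof=1)) if lrr.size > 1 else 0.0
    z = 0.0 if sd == 0.0 else (-float(np.mean(lrr))) / (sd / math.sqrt(lrr.size))
    if f < config.sex_loss_min_cf or z < config.sex_loss_z:
        return None
    pos = np.asarray(sites["pos"], dtype=np.int64)
    return SegmentCall(
        chrom=chrom,
        start=int(pos.min()),
        end=int(pos.max()) + 1,
        type="loss",
        dbaf=0.0,
        mean_lrr=med,
        cell_fraction=f,
        n_hets=0,
        quality=z,
    )


def apply_filters(
    calls: Sequence[SegmentCall],
    sample_qc: SampleQC,
    config: DetectConfig | None = None,
) -> tuple[list[SegmentCall], list[SegmentCall]]:
    """Apply the call-level filters; returns ``(passed, all_flagged)``.

    Filters: sample call rate below threshold; high BAF baseline
    deviation; low phase quality (fraction of sign-consistent hets);
    germline likelihood — a deviation at the constitutional (f = 1) value
    with LRR matching the integer copy number is flagged ``germline``.
    Sex-chromosome LRR-only calls (n_hets = 0) are exempt from the phase
    and germline ΔBAF checks.
    """
    config = config or DetectConfig()
    for name in ("call_rate", "baf_baseline"):
        if getattr(sample_qc, name) is None:
            raise InputError(f"sample QC metric {name!r} is missing")
    passed: list[SegmentCall] = []
    flagged: list[SegmentCall] = []
    for call in calls:
        flags: list[str] = []
        if sample_qc.call_rate < config.min_call_rate:
            flags.append("low_call_rate")
        if sample_qc.baf_baseline > config.max_baf_baseline:
            flags.append("high_baf")
        if call.n_hets > 0:
            if (
                not math.isnan(call.phase_concordance)
                and call.phase_concordance < config.min_phase_concordance
            ):
                flags.append("low_phase_quality")
            if call.type in EVENT_TYPES:
                d1 = cf_to_dbaf(call.type, 1.0)
                l1 = expected_lrr(call.type, 1.0)
                if (
                    abs(call.dbaf - d1) <= config.germline_dbaf_tol
                    and abs(call.mean_lrr - l1) <= config.germline_lrr_tol
                ):
                    flags.append("germline")
        out = replace(call, filter_flags=tuple(flags))
        flagged.append(out)
        if not flags:
            passed.append(out)
    return passed, flagged


def detect_sample(
    sites: pd.DataFrame,
    sex: str | None = None,
    config: DetectConfig | None = None,
    sample_qc: SampleQC | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SegmentCall]:
    """Detect mosaic events across all chromosomes of one sample's site table."""
    config = config or DetectConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls: list[SegmentCall] = []
    for chrom, chrom_sites in sites.groupby("chrom", sort=False):
        name = str(chrom).removeprefix("chr")
        if name in ("X", "Y"):
            if sex is None:
                continue
            if (name == "Y" and sex == "male") or (name == "X" and sex == "female"):
                call = detect_sex_chrom_loss(chrom_sites, sex, config)
                if call is not None:
                    calls.append(call)
            continue
        calls.extend(detect_chromosome(chrom_sites.reset_index(drop=True), config, rng))
    if sample_qc is not None:
        calls, _ = apply_filters(calls, sample_qc, config)
    return calls
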
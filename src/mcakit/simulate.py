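"""Synthetic cohorts and phased SNP-array signals with injected mosaic events.

The generator emulates the statistical structure a flow-cytometry-screened
MBL/CLL cohort presents to the analysis: five clinical groups (no MBL,
low-count MBL, high-count MBL, CLL, SLL), per-group prevalences of mCA
categories, clone-size and B-cell-fraction distributions, lymphocyte
counts, a polygenic risk score, and — per individual — phased BAF/LRR
site tables carrying the injected mosaic events.

The BAF/LRR signal model is shared with :mod:`mcakit.detect`
(:func:`~mcakit.detect.cf_to_dbaf`, :func:`~mcakit.detect.expected_lrr`),
so cell fractions injected here are recoverable by the detector's
estimators up to Monte-Carlo error.  Outside events, heterozygous BAF is
Normal(0.5, baf_sd) truncated to [0, 1] and LRR is Normal(0, lrr_sd);
inside an event of type t at fraction f the het BAF mean is
0.5 + hap * dBAF(t, f) (sign set by the carrier haplotype) and the LRR
mean is log2(((1-f)*2 + f*c)/2) with c = 1 (loss), 2 (cnn_loh),
3 (gain).  Phase labels carry switch errors that flip cumulatively along
the chromosome.

Default parameters are the study conditions: group sizes 2971 / 728 /
332 / 497 / 104 and per-group category prevalences matching the observed
carrier fractions (e.g. canonical CLL-associated mCAs in 52.1% of
HC-MBL, 1.1% of LC-MBL, 0.13% of unaffected individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .detect import cf_to_dbaf, expected_lrr, EVENT_TYPES
from .errors import ConfigurationError, InputError
from .resources import load_region_lists_dict

GROUPS = ("none", "lc_mbl", "hc_mbl", "cll", "sll")
CATEGORIES = ("canonical", "driver_extra", "lymphoid_extra", "autosomal_other", "loy", "lox")


@dataclass(frozen=True)
class MosaicEvent:
    """A mosaic chromosomal alteration (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    type: str
    cell_fraction: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"event start {self.start} >= end {self.end}")
        if self.type not in EVENT_TYPES:
            raise InputError(f"event type must be one of {EVENT_TYPES}, got {self.type!r}")
        if not 0.0 < self.cell_fraction <= 1.0:
            raise InputError(f"cell fraction must be in (0, 1], got {self.cell_fraction}")


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------

def draw_dist(spec: Mapping, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw from a small declarative distribution spec.

    Supported families: ``constant`` (value), ``uniform`` (low, high),
    ``beta`` (a, b, optional loc/scale), ``lognormal`` (mean_log,
    sd_log), ``normal`` (mean, sd, optional clip_low/clip_high).
    """
    try:
        dist = spec["dist"]
        if dist == "constant":
            return np.full(size, float(spec["value"]))
        if dist == "uniform":
            return rng.uniform(float(spec["low"]), float(spec["high"]), size)
        if dist == "beta":
            x = rng.beta(float(spec["a"]), float(spec["b"]), size)
            return float(spec.get("loc", 0.0)) + float(spec.get("scale", 1.0)) * x
        if dist == "lognormal":
            return rng.lognormal(float(spec["mean_log"]), float(spec["sd_log"]), size)
        if dist == "normal":
            x = rng.normal(float(spec["mean"]), float(spec["sd"]), size)
            lo, hi = spec.get("clip_low"), spec.get("clip_high")
            if lo is not None or hi is not None:
                x = np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
            return x
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid distribution spec {spec!r}: {exc}") from exc
    raise ConfigurationError(f"unknown distribution family {spec.get('dist')!r}")


# ---------------------------------------------------------------------------
# cohort configuration (defaults are the study conditions)
# ---------------------------------------------------------------------------

def _default_group_sizes() -> dict:
    return {"none": 2971, "lc_mbl": 728, "hc_mbl": 332, "cll": 497, "sll": 104}


def _default_category_prevalence() -> dict:
    common = {"autosomal_other": 0.10, "loy": 0.15, "lox": 0.017}
    return {
        "none": {"canonical": 0.00135, "driver_extra": 0.011, "lymphoid_extra": 0.003, **common},
        "lc_mbl": {"canonical": 0.011, "driver_extra": 0.012, "lymphoid_extra": 0.005, **common},
        "hc_mbl": {"canonical": 0.521, "driver_extra": 0.037, "lymphoid_extra": 0.02, **common},
        "cll": {"canonical": 0.671, "driver_extra": 0.073, "lymphoid_extra": 0.02, **common},
        "sll": {"canonical": 0.452, "driver_extra": 0.106, "lymphoid_extra": 0.056, **common},
    }


def _default_clone_pct() -> dict:
    return {
        "none": {"dist": "constant", "value": 0.0},
        "lc_mbl": {"dist": "beta", "a": 2.0, "b": 5.0, "scale": 85.0},
        "hc_mbl": {"dist": "uniform", "low": 85.0, "high": 100.0},
        "cll": {"dist": "uniform", "low": 90.0, "high": 100.0},
        "sll": {"dist": "uniform", "low": 85.0, "high": 100.0},
    }


def _default_bcell_fraction() -> dict:
    return {
        "none": {"dist": "beta", "a": 2.0, "b": 18.0},
        "lc_mbl": {"dist": "beta", "a": 2.0, "b": 18.0},
        "hc_mbl": {"dist": "beta", "a": 4.0, "b": 12.0},
        "cll": {"dist": "beta", "a": 10.0, "b": 5.0},
        "sll": {"dist": "beta", "a": 3.0, "b": 12.0},
    }


def _default_alc() -> dict:
    return {
        "none": {"dist": "lognormal", "mean_log": 7.50, "sd_log": 0.30},
        "lc_mbl": {"dist": "lognormal", "mean_log": 7.55, "sd_log": 0.30},
        "hc_mbl": {"dist": "lognormal", "mean_log": 8.00, "sd_log": 0.35},
        "cll": {"dist": "lognormal", "mean_log": 9.40, "sd_log": 0.70},
        "sll": {"dist": "lognormal", "mean_log": 7.80, "sd_log": 0.40},
    }


def _default_age() -> dict:
    return {
        "none": {"dist": "normal", "mean": 65.0, "sd": 10.0, "clip_low": 40, "clip_high": 95},
        "lc_mbl": {"dist": "normal", "mean": 72.0, "sd": 9.0, "clip_low": 40, "clip_high": 95},
        "hc_mbl": {"dist": "normal", "mean": 70.0, "sd": 9.0, "clip_low": 40, "clip_high": 95},
        "cll": {"dist": "normal", "mean": 70.0, "sd": 10.0, "clip_low": 40, "clip_high": 95},
        "sll": {"dist": "normal", "mean": 69.0, "sd": 10.0, "clip_low": 40, "clip_high": 95},
    }


def _default_prs_shift() -> dict:
    return {"none": 0.0, "lc_mbl": 0.25, "hc_mbl": 0.5, "cll": 0.6, "sll": 0.6}


def _default_male_fraction() -> dict:
    return {"none": 0.401, "lc_mbl": 0.45, "hc_mbl": 0.60, "cll": 0.717, "sll": 0.65}


def _default_pbmc_fraction() -> dict:
    return {"none": 0.0, "lc_mbl": 0.003, "hc_mbl": 0.10, "cll": 0.05, "sll": 0.01}


@dataclass
class CohortConfig:
    """Generative parameters of the synthetic cohort."""

    group_sizes: dict = field(default_factory=_default_group_sizes)
    category_prevalence: dict = field(default_factory=_default_category_prevalence)
    clone_pct_dist: dict = field(default_factory=_default_clone_pct)
    bcell_fraction_dist: dict = field(default_factory=_default_bcell_fraction)
    alc_dist: dict = field(default_factory=_default_alc)
    age_dist: dict = field(default_factory=_default_age)
    prs_shift: dict = field(default_factory=_default_prs_shift)
    male_fraction: dict = field(default_factory=_default_male_fraction)
    pbmc_fraction: dict = field(default_factory=_default_pbmc_fraction)
    cf_dist: dict = field(default_factory=lambda: {"dist": "beta", "a": 1.5, "b": 3.0})
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigurationError(f"group size for {g!r} must be >= 0")
        for g, cats in self.category_prevalence.items():
            for c, p in cats.items():
                if c not in CATEGORIES:
                    raise ConfigurationError(f"unknown mCA category {c!r}")
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"prevalence {g}/{c} = {p} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ArraySimConfig:
    """Noise and density parameters of the simulated SNP array."""

    n_sites: int = 2000          # probes per chromosome
    het_fraction: float = 0.33   # probability a probe is heterozygous
    baf_sd: float = 0.03
    lrr_sd: float = 0.20
    phase_switch_rate: float = 0.002  # per adjacent het pair
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baf_sd <= 0 or self.lrr_sd <= 0:
            raise ConfigurationError("baf_sd and lrr_sd must be > 0")
        if not 0.0 <= self.phase_switch_rate < 0.5:
            raise ConfigurationError("phase_switch_rate must be in [0, 0.5)")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ConfigurationError("het_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ArraySimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# event templates: where each mCA category is injected
# ---------------------------------------------------------------------------

def _genome_lengths() -> dict:
    arm = load_region_lists_dict()["arm_table"]
    return {c: int(v["length"]) for c, v in arm.items()}

_LEN = _genome_lengths()

#: canonical CLL-associated loci (CLL FISH panel)
CANONICAL_TEMPLATES: tuple[tuple[str, str, int, int, str], ...] = (
    ("del6q", "6", 80_000_000, 140_000_000, "loss"),
    ("del11q", "11", 95_000_000, 115_000_000, "loss"),
    ("tri12", "12", 0, _LEN["12"], "gain"),
    ("del13q", "13", 49_000_000, 52_000_000, "loss"),
    ("del17p", "17", 100_000, 20_000_000, "loss"),
    ("cnnloh13q", "13", 30_000_000, 114_000_000, "cnn_loh"),
)

#: one template per non-canonical category
EXTRA_TEMPLATES: dict[str, tuple[str, str, int, int, str]] = {
    "driver_extra": ("del8p", "8", 100_000, 32_000_000, "loss"),
    "lymphoid_extra": ("del22q", "22", 20_000_000, 40_000_000, "loss"),
    "autosomal_other": ("del5p_prox", "5", 10_000_000, 40_000_000, "loss"),
    "loy": ("loy", "Y", 100_000, _LEN["Y"], "loss"),
    "lox": ("lox", "X", 100_000, _LEN["X"], "loss"),
}


def generate_cohort(config: CohortConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort and its per-individual truth events.

    Returns ``(cohort, truth_events)``: the cohort table has one row per
    individual (phenotypes plus truth mCA-category flags); the truth
    table has one row per injected event (individual_id, chrom, start,
    end, type, cell_fraction, category, label).  Fully reproducible from
    ``config.seed``.
    """
    from . import taxonomy  # deferred: avoid import cycle at module load

    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    lists = taxonomy.RegionLists.default()

    rows = []
    events = []
    for group in GROUPS:
        n = int(config.group_sizes.get(group, 0))
        if n == 0:
            continue
        prev = config.category_prevalence.get(group, {})
        clone_pct = draw_dist(config.clone_pct_dist[group], rng, n)
        bfrac = np.clip(draw_dist(config.bcell_fraction_dist[group], rng, n), 0.0, 1.0)
        alc = draw_dist(config.alc_dist[group], rng, n)
        age = draw_dist(config.age_dist[group], rng, n)
        prs = rng.normal(config.prs_shift.get(group, 0.0), 1.0, n)
        male = rng.random(n) < config.male_fraction.get(group, 0.5)
        pbmc = rng.random(n) < config.pbmc_fraction.get(group, 0.0)
        array_type = rng.choice(["omniexpress", "gsa"], n)
        batch = rng.choice(["b1", "b2", "b3", "b4"], n)

        for i in range(n):
            iid = f"{group}_{i:05d}"
            indiv_events: list[tuple[str, str, MosaicEvent]] = []
            for cat in CATEGORIES:
                p = prev.get(cat, 0.0)
                if p <= 0.0 or rng.random() >= p:
                    continue
                if cat == "loy" and not male[i]:
                    continue
                if cat == "lox" and male[i]:
                    continue
                if cat == "canonical":
                    label, chrom, start, end, etype = CANONICAL_TEMPLATES[
                        rng.integers(len(CANONICAL_TEMPLATES))
                    ]
                else:
                    label, chrom, start, end, etype = EXTRA_TEMPLATES[cat]
                cf = float(np.clip(draw_dist(config.cf_dist, rng, 1)[0], 1e-3, 1.0))
                indiv_events.append(
                    (cat, label, MosaicEvent(chrom, int(start), int(end), etype, cf))
                )
            flags = taxonomy.summarize_individual([e for _, _, e in indiv_events], lists)
            clonal_count = alc[i] * bfrac[i] * clone_pct[i] / 100.0
            rows.append(
                {
                    "individual_id": iid,
                    "group": group,
                    "sex": "male" if male[i] else "female",
                    "age": float(age[i]),
                    "clonal_b_pct": float(clone_pct[i]),
                    "clonal_b_count": float(clonal_count),
                    "bcell_fraction": float(bfrac[i]),
                    "alc": float(alc[i]),
                    "prs": float(prs[i]),
                    "dna_source": "pbmc" if pbmc[i] else "whole_blood",
                    "array_type": array_type[i],
                    "batch": batch[i],
                    "has_canonical": flags.has_canonical,
                    "has_driver": flags.has_driver,
                    "has_lymphoid": flags.has_lymphoid,
                    "has_autosomal": flags.has_autosomal,
                    "has_autosomal_without_driver_or_lymphoid":
                        flags.has_autosomal_without_driver_or_lymphoid,
                    "has_loy": flags.has_loy,
                    "has_lox": flags.has_lox,
                    "n_autosomal": flags.n_autosomal,
                    "max_driver_cf": flags.max_driver_cf,
                }
            )
            for cat, label, ev in indiv_events:
                events.append(
                    {
                        "chrom": ev.chrom,
                        "start": ev.start,
                        "end": ev.end,
                        "type": ev.type,
                        "cell_fraction": ev.cell_fraction,
                        "individual_id": iid,
                        "category": cat,
                        "label": label,
                    }
                )
    cohort = pd.DataFrame(rows)
    truth = pd.DataFrame(
        events,
        columns=["chrom", "start", "end", "type", "cell_fraction",
                 "individual_id", "category", "label"],
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# array signal simulation
# ---------------------------------------------------------------------------

def simulate_array_signals(
    events: Sequence[MosaicEvent],
    config: ArraySimConfig | None = None,
    chromosomes: Sequence[str] | None = None,
    genome: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a phased SNP-array site table carrying the given mosaic events.

    Chromosomes simulated are *chromosomes* if given, else the
    chromosomes the events lie on.  Events on one chromosome must not
    overlap.  Returns a table with columns ``chrom, pos, genotype, hap,
    baf, lrr`` (``hap`` is +1/-1 at heterozygous sites, 0 elsewhere).
    """
    config = config or ArraySimConfig()
    genome = dict(genome) if genome is not None else _genome_lengths()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    by_chrom: dict[str, list[MosaicEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs.sort(key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end:
                raise InputError(f"overlapping events on chromosome {chrom}")

    if chromosomes is None:
        chromosomes = sorted(by_chrom)
    if not chromosomes:
        raise InputError("no chromosomes to simulate (no events and no chromosome list)")

    frames = []
    for chrom in chromosomes:
        length = genome.get(chrom)
        if length is None:
            raise InputError(f"chromosome {chrom!r} missing from genome table")
        n = config.n_sites
        pos = np.sort(rng.integers(0, length, n))
        is_het = rng.random(n) < config.het_fraction
        hom_b = rng.random(n) < 0.5
        genotype = np.where(is_het, "AB", np.where(hom_b, "BB", "AA"))
        hap_true = np.where(rng.random(n) < 0.5, 1, -1)

        # per-site event signal
        baf_mean = np.where(is_het, 0.5, np.where(hom_b, 1.0, 0.0))
        lrr_mean = np.zeros(n)
        for ev in by_chrom.get(chrom, []):
            inside = (pos >= ev.start) & (pos < ev.end)
            d = cf_to_dbaf(ev.type, ev.cell_fraction)
            baf_mean = np.where(
                inside & is_het, 0.5 + hap_true * d, baf_mean
            )
            lrr_mean = np.where(inside, expected_lrr(ev.type, ev.cell_fraction), lrr_mean)

        baf = np.clip(baf_mean + rng.normal(0.0, config.baf_sd, n), 0.0, 1.0)
        lrr = lrr_mean + rng.normal(0.0, config.lrr_sd, n)

        # phase labels: truth flipped by cumulative switch errors
        hap = np.zeros(n, dtype=int)
        het_idx = np.flatnonzero(is_het)
        if het_idx.size:
            flips = rng.random(het_idx.size - 1) < config.phase_switch_rate
            state = np.concatenate([[1], np.cumprod(np.where(flips, -1, 1))])
            hap[het_idx] = hap_true[het_idx] * state

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "genotype": genotype,
                    "hap": hap,
                    "baf": baf,
                    "lrr": lrr,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# case-control cohorts with a known exposure odds ratio
# ---------------------------------------------------------------------------

def simulate_association_cohort(
    n: int,
    exposure_or: float,
    seed: int = 0,
    exposure_prev: float = 0.2,
    base_rate: float = 0.15,
    age_beta: float = 0.3,
    sex_beta: float = 0.2,
) -> pd.DataFrame:
    """Cohort with a binary exposure whose true outcome odds ratio is known.

    The outcome follows a logistic model with the exposure log-odds-ratio
    ``log(exposure_or)`` plus mild age and sex effects, for parameter-
    recovery checks of :func:`mcakit.stats.adjusted_or`.
    """
    if exposure_or <= 0:
        raise ConfigurationError("exposure_or must be > 0")
    rng = np.random.default_rng(seed)
    exposure = (rng.random(n) < exposure_prev).astype(int)
    age = rng.normal(0.0, 1.0, n)
    sex = (rng.random(n) < 0.5).astype(int)
    b0 = float(np.log(base_rate / (1.0 - base_rate)))
    logit = b0 + np.log(exposure_or) * exposure + age_beta * age + sex_beta * sex
    p = 1.0 / (1.0 + np.exp(-logit))
    outcome = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {"outcome": outcome, "exposure": exposure, "age": age, "sex": sex}
    )
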
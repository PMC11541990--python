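"""Genomic-interval taxonomy of mCA calls.

Classifies each called segment into three (overlapping) category
systems used in CLL precursor studies:

* **canonical CLL-associated** — the clinical CLL FISH panel loci:
  del 6q, del 11q, trisomy 12, del 13q, del 17p, plus copy-neutral LOH
  on 13q when the call contains the MIR16-1 anchor locus;
* **CLL-driver** — canonical, or fully containing a candidate driver
  region of matching type from large CLL sequencing studies;
* **lymphoid** — matching an entry from a list of mCAs associated with
  lymphoid (versus myeloid) malignancy risk.

Matching rules: an arm entry matches when at least 1 bp of the call
lies on that arm and the type matches (a stricter fractional overlap is
configurable per entry via ``min_overlap``); "trisomy"-style whole-
chromosome entries require the call to cover at least ``min_fraction``
of the chromosome (default 0.8); anchor entries additionally require
the call interval to contain the anchor interval.  The categories are
OR-aggregated flags, never a partition — one call can be canonical and
lymphoid at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import InputError
from .resources import load_region_lists_dict

AUTOSOMES = {str(i) for i in range(1, 23)}


def _norm_chrom(chrom) -> str:
    return str(chrom).removeprefix("chr")


@dataclass
class RegionLists:
    """Region definitions driving the taxonomy (all intervals half-open)."""

    canonical: list[dict]
    driver_candidates: list[dict]
    lymphoid: list[dict]
    arm_table: dict
    genome_build: str = "unspecified"

    @classmethod
    def default(cls) -> "RegionLists":
        return cls.from_dict(load_region_lists_dict())

    @classmethod
    def from_dict(cls, data: Mapping) -> "RegionLists":
        return cls(
            canonical=list(data.get("canonical", [])),
            driver_candidates=list(data.get("driver_candidates", [])),
            lymphoid=list(data.get("lymphoid", [])),
            arm_table={_norm_chrom(k): dict(v) for k, v in data.get("arm_table", {}).items()},
            genome_build=data.get("genome_build", "unspecified"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RegionLists":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def arm_interval(self, chrom: str, arm: str) -> tuple[int, int]:
        chrom = _norm_chrom(chrom)
        info = self.arm_table.get(chrom)
        if info is None:
            raise InputError(f"chromosome {chrom!r} missing from arm table")
        cen, length = int(info["centromere"]), int(info["length"])
        if arm == "p":
            return 0, cen
        if arm == "q":
            return cen, length
        if arm == "whole":
            return 0, length
        raise InputError(f"unknown arm {arm!r}")


@dataclass(frozen=True)
class IndividualFlags:
    """Per-individual OR-aggregated mCA category flags."""

    has_canonical: bool = False
    has_driver: bool = False
    has_lymphoid: bool = False
    has_autosomal: bool = False
    has_autosomal_without_driver_or_lymphoid: bool = False
    has_loy: bool = False
    has_lox: bool = False
    n_autosomal: int = 0
    max_driver_cf: float = 0.0


def _matches_entry(call, entry: Mapping, lists: RegionLists) -> bool:
    """Arm/whole-chromosome entry match (shared by canonical and lymphoid rules)."""
    if call.type != entry["type"]:
        return False
    if _norm_chrom(call.chrom) != _norm_chrom(entry["chrom"]):
        return False
    arm = entry.get("arm", "whole")
    lo, hi = lists.arm_interval(call.chrom, arm)
    overlap = min(call.end, hi) - max(call.start, lo)
    if overlap <= 0:
        return False
    if arm == "whole":
        frac = overlap / (hi - lo)
        if frac < float(entry.get("min_fraction", 0.8)):
            return False
    else:
        min_ov = entry.get("min_overlap")
        if min_ov is not None and overlap / (hi - lo) < float(min_ov):
            return False
    anchor = entry.get("anchor")
    if anchor is not None:
        a_lo, a_hi = int(anchor[0]), int(anchor[1])
        if not (call.start <= a_lo and call.end >= a_hi):
            return False
    return True


def is_canonical(call, lists: RegionLists) -> bool:
    """True when the call matches a canonical CLL-associated (FISH panel) entry."""
    return any(_matches_entry(call, e, lists) for e in lists.canonical)


def is_cll_driver(call, lists: RegionLists) -> bool:
    """True when canonical, or the call fully contains a driver candidate of its type."""
    if is_canonical(call, lists):
        return True
    if not lists.driver_candidates:
        warnings.warn(
            "driver classification with an empty candidate list is canonical-only",
            stacklevel=2,
        )
        return False
    chrom = _norm_chrom(call.chrom)
    for cand in lists.driver_candidates:
        if cand["type"] != call.type or _norm_chrom(cand["chrom"]) != chrom:
            continue
        if call.start <= int(cand["start"]) and int(cand["end"]) <= call.end:
            return True
    return False


def is_lymphoid(call, lists: RegionLists) -> bool:
    """True when the call matches an entry of the lymphoid-malignancy list."""
    return any(_matches_entry(call, e, lists) for e in lists.lymphoid)


def classify_call(call, lists: RegionLists) -> dict:
    """Category booleans for one call."""
    return {
        "is_canonical": is_canonical(call, lists),
        "is_cll_driver": is_cll_driver(call, lists),
        "is_lymphoid": is_lymphoid(call, lists),
    }


def summarize_individual(calls: Sequence, lists: RegionLists) -> IndividualFlags:
    """Roll one individual's calls up into OR-aggregated category flags.

    Autosomal means chromosomes 1–22; LoY/LoX are whole-chromosome-scale
    losses on Y/X.  ``max_driver_cf`` is the largest cell fraction among
    driver calls (0 when there are none).  Duplicate calls (same
    chromosome, interval, and type) raise :class:`InputError`.
    """
    seen = set()
    for call in calls:
        key = (_norm_chrom(call.chrom), call.start, call.end, call.type)
        if key in seen:
            raise InputError(f"duplicate call {key}")
        seen.add(key)

    has_canonical = has_driver = has_lymphoid = False
    has_loy = has_lox = False
    n_autosomal = 0
    max_driver_cf = 0.0
    for call in calls:
        chrom = _norm_chrom(call.chrom)
        if chrom == "Y" and call.type == "loss":
            has_loy = True
            continue
        if chrom == "X" and call.type == "loss":
            has_lox = True
            continue
        if chrom not in AUTOSOMES:
            continue
        n_autosomal += 1
        canon = is_canonical(call, lists)
        driver = canon or is_cll_driver(call, lists)
        lymph = is_lymphoid(call, lists)
        has_canonical |= canon
        has_driver |= driver
        has_lymphoid |= lymph
        if driver:
            max_driver_cf = max(max_driver_cf, float(call.cell_fraction))
    has_autosomal = n_autosomal > 0
    return IndividualFlags(
        has_canonical=has_canonical,
        has_driver=has_driver,
        has_lymphoid=has_lymphoid,
        has_autosomal=has_autosomal,
        has_autosomal_without_driver_or_lymphoid=(
            has_autosomal and not (has_driver or has_lymphoid)
        ),
        has_loy=has_loy,
        has_lox=has_lox,
        n_autosomal=n_autosomal,
        max_driver_cf=max_driver_cf,
    )
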
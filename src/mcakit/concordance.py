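"""Per-locus concordance of array mCA calls with clinical FISH results.

FISH is the orthogonal clinical truth assay at the canonical CLL panel
loci (6q, 11q, 12, 13q, 17p).  For each locus, individuals with both a
FISH result and array data are cross-tabulated (array call positive /
negative vs FISH positive / negative) and per-locus sensitivity and
specificity are reported; a locus with a zero denominator reports None.
13q FISH positives may be matched by either a 13q loss or a CNN-LOH
call containing the MIR16-1 anchor (toggleable): CNN-LOH removes the
FISH probe target's heterozygosity without copy loss, and clinical
del(13q) probes detect the lesion in both forms.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import taxonomy
from .errors import InputError

FISH_LOCI = ("6q", "11q", "12", "13q", "17p")

#: locus -> (chrom, arm, type) of the matching array call
_LOCUS_RULES = {
    "6q": ("6", "q", "loss"),
    "11q": ("11", "q", "loss"),
    "12": ("12", "whole", "gain"),
    "13q": ("13", "q", "loss"),
    "17p": ("17", "p", "loss"),
}


def _call_positive_at_locus(
    calls: Sequence, locus: str, lists: taxonomy.RegionLists, cnnloh_13q: bool
) -> bool:
    chrom, arm, etype = _LOCUS_RULES[locus]
    entry = {"chrom": chrom, "arm": arm, "type": etype}
    if arm == "whole":
        entry["min_fraction"] = 0.8
    for call in calls:
        if taxonomy._matches_entry(call, entry, lists):
            return True
    if locus == "13q" and cnnloh_13q:
        anchor_entries = [
            e for e in lists.canonical if e.get("type") == "cnn_loh" and "anchor" in e
        ]
        for call in calls:
            if any(taxonomy._matches_entry(call, e, lists) for e in anchor_entries):
                return True
    return False


def fish_concordance(
    calls_by_individual: Mapping[str, Sequence],
    fish: pd.DataFrame,
    lists: taxonomy.RegionLists | None = None,
    match_cnnloh_13q: bool = True,
) -> pd.DataFrame:
    """Per-locus 2x2 agreement of array calls with FISH.

    *fish* needs columns ``individual_id``, ``locus`` (one of 6q, 11q,
    12, 13q, 17p), ``positive`` (boolean).  Only individuals present in
    *calls_by_individual* (the array-assayed universe) contribute.
    Returns one row per locus with tp/fp/fn/tn, sensitivity, and
    specificity.
    """
    lists = lists or taxonomy.RegionLists.default()
    bad = set(fish["locus"].astype(str)) - set(FISH_LOCI)
    if bad:
        raise InputError(f"unknown FISH locus labels: {sorted(bad)}")
    rows = []
    for locus in FISH_LOCI:
        sub = fish[fish["locus"].astype(str) == locus]
        tp = fp = fn = tn = 0
        for _, rec in sub.iterrows():
            iid = rec["individual_id"]
            if iid not in calls_by_individual:
                continue
            truth = bool(rec["positive"])
            pred = _call_positive_at_locus(
                calls_by_individual[iid], locus, lists, match_cnnloh_13q
            )
            if truth and pred:
                tp += 1
            elif truth:
                fn += 1
            elif pred:
                fp += 1
            else:
                tn += 1
        sens = tp / (tp + fn) if (tp + fn) > 0 else None
        spec = tn / (tn + fp) if (tn + fp) > 0 else None
        rows.append(
            {
                "locus": locus,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
    return pd.DataFrame(rows)
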
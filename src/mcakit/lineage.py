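"""Blood-cell lineage inference for mCAs.

If an mCA were confined to the B-cell lineage, the fraction of cells
carrying it could not exceed the B-cell fraction of the assayed sample.
This module computes that comparison per individual and mCA category:
``exceeds`` is true when the (maximum) mCA cell fraction strictly
exceeds the flow-cytometric B-cell fraction, pointing to a cell of
origin before B-cell lineage commitment.  Ties count as *not*
exceeding (conservative).  The comparison is only cleanly interpretable
when DNA and flow cytometry come from the same sample source, hence the
optional restriction to PBMC-derived DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import taxonomy

CATEGORIES = ("canonical", "driver", "lymphoid")

_CATEGORY_PREDICATE = {
    "canonical": taxonomy.is_canonical,
    "driver": taxonomy.is_cll_driver,
    "lymphoid": taxonomy.is_lymphoid,
}


@dataclass(frozen=True)
class LineageAssessment:
    individual_id: str
    category: str
    mca_cf: float
    bcell_fraction: float
    exceeds: bool
    dna_source: str


def assess_lineage(
    calls_by_individual: Mapping[str, Sequence],
    phenotype: pd.DataFrame,
    lists: taxonomy.RegionLists | None = None,
) -> pd.DataFrame:
    """Compare per-category mCA cell fraction to the B-cell fraction.

    *calls_by_individual* maps individual_id to that individual's calls
    (the keys define who was array-assayed); *phenotype* needs columns
    ``individual_id``, ``bcell_fraction``, ``dna_source``.  For each
    individual and category the mCA cell fraction is the maximum over
    calls in the category, 0 when the category was not detected.
    Individuals with a missing B-cell fraction are skipped with a
    warning.
    """
    lists = lists or taxonomy.RegionLists.default()
    pheno = phenotype.set_index("individual_id")
    rows = []
    for iid, calls in calls_by_individual.items():
        if iid not in pheno.index:
            continue
        b = pheno.at[iid, "bcell_fraction"]
        if pd.isna(b):
            warnings.warn(f"individual {iid}: missing bcell_fraction, skipped", stacklevel=2)
            continue
        b = float(b)
        dna = str(pheno.at[iid, "dna_source"]) if "dna_source" in pheno.columns else "whole_blood"
        autosomal = [c for c in calls if taxonomy._norm_chrom(c.chrom) in taxonomy.AUTOSOMES]
        for cat in CATEGORIES:
            pred = _CATEGORY_PREDICATE[cat]
            cfs = [float(c.cell_fraction) for c in autosomal if pred(c, lists)]
            cf = max(cfs, default=0.0)
            rows.append(
                {
                    "individual_id": iid,
                    "category": cat,
                    "mca_cf": cf,
                    "bcell_fraction": b,
                    "exceeds": cf > b,
                    "dna_source": dna,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["individual_id", "category", "mca_cf", "bcell_fraction", "exceeds", "dna_source"],
    )


def lineage_summary(
    assessments: pd.DataFrame, restrict_dna_source: str | None = None
) -> pd.DataFrame:
    """Counts of carriers and of carriers whose clone exceeds the B-cell fraction.

    Carriers are rows with ``mca_cf > 0``; optionally restricted to one
    DNA source (e.g. ``"pbmc"``).  Returns one row per category with
    ``n_carriers`` and ``n_exceeds``.
    """
    df = assessments
    if restrict_dna_source is not None:
        df = df[df["dna_source"] == restrict_dna_source]
    rows = []
    for cat in CATEGORIES:
        sub = df[(df["category"] == cat) & (df["mca_cf"] > 0)]
        rows.append(
            {
                "category": cat,
                "n_carriers": int(len(sub)),
                "n_exceeds": int(sub["exceeds"].sum()),
            }
        )
    return pd.DataFrame(rows)
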
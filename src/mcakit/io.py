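"""Tabular I/O and the end-to-end pipeline driver.

All tables are TSV with headers; interval columns are BED-compatible
(0-based half-open ``chrom, start, end`` first).  ``read_calls`` can
shift 1-based inclusive input to the internal convention.  The pipeline
driver chains simulation, detection, taxonomy, lineage, and cohort
statistics, and writes a manifest (seeds, parameters, output digests)
from which a run is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import lineage as lineage_mod
from . import stats as stats_mod
from . import taxonomy
from .detect import DetectConfig, SampleQC, SegmentCall, detect_sample
from .errors import InputError
from .simulate import ArraySimConfig, CohortConfig, MosaicEvent, generate_cohort, simulate_array_signals

CALL_COLUMNS = [
    "chrom", "start", "end", "type", "dbaf", "mean_lrr",
    "cell_fraction", "n_hets", "quality", "filter_flags",
]
SITE_COLUMNS = ["chrom", "pos", "genotype", "hap", "baf", "lrr"]
EVENT_COLUMNS = ["chrom", "start", "end", "type", "cell_fraction", "individual_id"]

_CALL_NUMERIC = {
    "start": "int", "end": "int", "dbaf": "float", "mean_lrr": "float",
    "cell_fraction": "float", "n_hets": "int", "quality": "float",
}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")


def _coerce_numeric(df: pd.DataFrame, spec: dict, path) -> pd.DataFrame:
    for col, kind in spec.items():
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise InputError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced.astype(np.int64 if kind == "int" else float)
    return df


def write_sites(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False, columns=SITE_COLUMNS, float_format="%.17g")


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    _require_columns(df, SITE_COLUMNS, path)
    return _coerce_numeric(df, {"pos": "int", "hap": "int", "baf": "float", "lrr": "float"}, path)


def calls_to_frame(calls: Sequence[SegmentCall], individual_id: str | None = None) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "chrom": c.chrom, "start": c.start, "end": c.end, "type": c.type,
            "dbaf": c.dbaf, "mean_lrr": c.mean_lrr, "cell_fraction": c.cell_fraction,
            "n_hets": c.n_hets, "quality": c.quality,
            "filter_flags": ";".join(c.filter_flags) if c.filter_flags else "PASS",
        }
        if individual_id is not None:
            row["individual_id"] = individual_id
        rows.append(row)
    cols = CALL_COLUMNS + (["individual_id"] if individual_id is not None else [])
    return pd.DataFrame(rows, columns=cols)


def frame_to_calls(df: pd.DataFrame) -> list[SegmentCall]:
    calls = []
    for _, r in df.iterrows():
        flags = () if r.get("filter_flags", "PASS") in ("PASS", "", ".") else tuple(
            str(r["filter_flags"]).split(";")
        )
        calls.append(
            SegmentCall(
                chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]),
                type=str(r["type"]), dbaf=float(r["dbaf"]), mean_lrr=float(r["mean_lrr"]),
                cell_fraction=float(r["cell_fraction"]), n_hets=int(r["n_hets"]),
                quality=float(r["quality"]), filter_flags=flags,
            )
        )
    return calls


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_calls(path, one_based: bool = False) -> pd.DataFrame:
    """Read a call table; ``one_based`` shifts start coordinates by -1 on read."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    _require_columns(df, CALL_COLUMNS, path)
    df = _coerce_numeric(df, _CALL_NUMERIC, path)
    if one_based:
        df["start"] = df["start"] - 1
    if (df["start"] >= df["end"]).any():
        line = int((df["start"] >= df["end"]).idxmax()) + 2
        raise InputError(f"{path}: start >= end at line {line}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    _require_columns(df, EVENT_COLUMNS, path)
    return _coerce_numeric(df, {"start": "int", "end": "int", "cell_fraction": "float"}, path)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["individual_id"], path)
    return df


def read_fish(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["individual_id", "locus", "positive"], path)
    if df["positive"].dtype == object:
        df["positive"] = df["positive"].astype(str).str.lower().isin(["true", "1", "yes"])
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulation through cohort statistics)."""

    out_dir: str = "mcakit_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    array: ArraySimConfig = field(default_factory=ArraySimConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    chromosomes: tuple[str, ...] = ("5", "6", "8", "11", "12", "13", "17", "22")
    detect_sex_chroms: bool = True
    cv_folds: int = 10
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, detect, classify, and summarize; returns the manifest dict.

    Writes cohort.tsv, truth_events.tsv, calls.tsv, flags.tsv,
    lineage.tsv, lineage_summary.tsv, stats.json, and manifest.json into
    ``config.out_dir``.  Deterministic given the configured seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lists = taxonomy.RegionLists.default()

    cohort, truth = generate_cohort(config.cohort)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    write_events(truth, out / "truth_events.tsv")

    truth_by_iid = {iid: g for iid, g in truth.groupby("individual_id")}
    call_frames = []
    calls_by_iid: dict[str, list[SegmentCall]] = {}
    qc = SampleQC(call_rate=1.0, baf_baseline=0.0)
    for i, row in enumerate(cohort.itertuples()):
        iid = row.individual_id
        events = []
        for _, ev in truth_by_iid.get(iid, pd.DataFrame(columns=EVENT_COLUMNS)).iterrows():
            events.append(
                MosaicEvent(str(ev["chrom"]), int(ev["start"]), int(ev["end"]),
                            str(ev["type"]), float(ev["cell_fraction"]))
            )
        chroms = list(config.chromosomes)
        if config.detect_sex_chroms:
            chroms.append("Y" if row.sex == "male" else "X")
        rng = np.random.default_rng([config.seed, i])
        sites = simulate_array_signals(
            events, config.array, chromosomes=chroms, seed=rng.integers(2**31)
        )
        calls = detect_sample(
            sites, sex=row.sex, config=config.detect, sample_qc=qc, seed=rng
        )
        calls_by_iid[iid] = calls
        call_frames.append(calls_to_frame(calls, individual_id=iid))
    call_frames = [f for f in call_frames if len(f)]
    calls_df = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(columns=CALL_COLUMNS + ["individual_id"])
    )
    write_calls(calls_df, out / "calls.tsv")

    flag_rows = []
    for iid, calls in calls_by_iid.items():
        flags = taxonomy.summarize_individual(calls, lists)
        flag_rows.append({"individual_id": iid, **dataclasses.asdict(flags)})
    flags_df = pd.DataFrame(flag_rows)
    flags_df.to_csv(out / "flags.tsv", sep="\t", index=False)

    assessments = lineage_mod.assess_lineage(calls_by_iid, cohort, lists)
    assessments.to_csv(out / "lineage.tsv", sep="\t", index=False)
    lin_summary = lineage_mod.lineage_summary(assessments, restrict_dna_source="pbmc")
    lin_summary.to_csv(out / "lineage_summary.tsv", sep="\t", index=False)

    merged = cohort.drop(
        columns=[c for c in flags_df.columns if c != "individual_id" and c in cohort.columns]
    ).merge(flags_df, on="individual_id")
    stats_out: dict = {"prevalence": {}, "screening": {}}
    for cat in ("has_canonical", "has_driver", "has_lymphoid", "has_autosomal"):
        tab = stats_mod.prevalence_table(merged, cat)
        stats_out["prevalence"][cat] = tab.to_dict(orient="records")
    screen_pop = merged[merged["group"].isin(["none", "lc_mbl", "hc_mbl"])]
    is_hc = screen_pop["group"] == "hc_mbl"
    pred = screen_pop["has_driver"].astype(bool)
    t = stats_mod.Screen2x2(
        tp=int((is_hc & pred).sum()), fp=int((~is_hc & pred).sum()),
        fn=int((is_hc & ~pred).sum()), tn=int((~is_hc & ~pred).sum()),
    )
    stats_out["screening"]["driver_for_hc_mbl"] = {
        **dataclasses.asdict(t), **stats_mod.screening_metrics(t)
    }
    try:
        aucs = stats_mod.hc_mbl_prediction_aucs(merged, k=config.cv_folds, seed=config.seed)
        stats_out["cv_auc"] = aucs
    except InputError as exc:  # e.g. no HC-MBL detected in a tiny run
        stats_out["cv_auc"] = {"error": str(exc)}
    (out / "stats.json").write_text(json.dumps(stats_out, indent=2, default=float))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            "cohort": dataclasses.asdict(config.cohort),
            "array": dataclasses.asdict(config.array),
            "detect": dataclasses.asdict(config.detect),
            "chromosomes": list(config.chromosomes),
            "cv_folds": config.cv_folds,
        },
        "outputs": {
            name: _sha256(out / name)
            for name in [
                "cohort.tsv", "truth_events.tsv", "calls.tsv", "flags.tsv",
                "lineage.tsv", "lineage_summary.tsv", "stats.json",
            ]
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
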
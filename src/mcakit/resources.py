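"""Access to packaged data files (default region lists, published cohort counts)."""

from __future__ import annotations

import json
from importlib import resources

import yaml


def load_region_lists_dict() -> dict:
    """Raw dictionary form of the default region-list configuration."""
    with resources.files("mcakit.data").joinpath("region_lists.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_cohort_counts() -> dict:
    """Published cross-tabulated cohort counts (group sizes, carrier counts)."""
    with resources.files("mcakit.data").joinpath("cohort_counts.json").open() as fh:
        return json.load(fh)
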
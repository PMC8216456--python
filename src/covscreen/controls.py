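"""Positive-control set manifest.

The screen's candidate criteria were tuned on a panel of 80 known
structural RNA genes: 29 H/ACA box snoRNAs, the 5S and 5.8S rRNAs, 39
tRNAs (one per anticodon), five spliceosomal RNAs, and five singleton
RNAs (U3, Telomerase RNA, RNase MRP, RNase P, SRP RNA).  The packaged
manifest records that composition for bookkeeping; it holds names and
counts only, not sequences.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["positive_control_manifest", "positive_control_count"]


def positive_control_manifest() -> dict:
    """The packaged positive-control composition (categories, counts, members)."""
    ref = resources.files("covscreen").joinpath("data/positive_controls.json")
    data = json.loads(ref.read_text())
    for name, cat in data["categories"].items():
        if len(cat["members"]) != cat["count"]:
            raise ValueError(f"manifest category {name!r} count mismatch")
    return data


def positive_control_count() -> int:
    """Total number of RNAs in the positive-control set (sums the categories)."""
    data = positive_control_manifest()
    return sum(cat["count"] for cat in data["categories"].values())
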
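"""Classification of MS-PAVs against external pQTL summary statistics.

Each variant is looked up in a platform's (variant, target, p-value) table
and classed as *cis* (its own protein shows an association below
0.05 / n_variants), *trans_only* (no cis, but some other protein passes the
stricter 0.05 / n_variants / n_assayed_proteins bound), *not_assayed* (the
variant's own protein is not on the platform) or *none*. Matching is by
exact variant identifier; linkage-based expansion is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASSES = ("cis", "trans_only", "none", "not_assayed")


class OverlapError(ValueError):
    pass


@dataclass
class ExternalSummaryTable:
    """A platform's pQTL summary statistics restricted to queried variants."""

    platform: str
    n_assayed_proteins: int
    rows: pd.DataFrame  # columns: variant_id, target_id, p
    assayed_targets: Optional[set] = None

    def __post_init__(self) -> None:
        required = {"variant_id", "target_id", "p"}
        missing = required - set(self.rows.columns)
        if missing:
            raise OverlapError(f"summary table missing columns: {sorted(missing)}")
        p = self.rows["p"].to_numpy(dtype=float)
        if len(p) and ((p <= 0) | (p > 1)).any():
            raise OverlapError("p-values must lie in (0, 1]")
        targets = set(self.rows["target_id"])
        if self.assayed_targets is None:
            self.assayed_targets = targets
        if self.n_assayed_proteins < len(self.assayed_targets):
            raise OverlapError(
                "n_assayed_proteins smaller than the number of distinct targets"
            )


def classify_overlap(
    mspavs: pd.DataFrame,
    external: ExternalSummaryTable,
    n_variants: Optional[int] = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify each MS-PAV against one platform; emit the count summary.

    ``mspavs`` needs columns ``variant_id`` and ``target_id`` (the variant's
    own protein key, harmonized with the platform's target identifiers).
    ``n_variants`` defaults to the number of queried MS-PAVs and sets the
    cis threshold 0.05 / n_variants; the trans threshold divides further by
    the platform's assayed-protein count. Variants absent from the summary
    table carry no association rows and fall to ``none``/``not_assayed`` by
    assay status.
    """
    required = {"variant_id", "target_id"}
    missing = required - set(mspavs.columns)
    if missing:
        raise OverlapError(f"mspavs table missing columns: {sorted(missing)}")
    if n_variants is None:
        n_variants = mspavs["variant_id"].nunique()
    if n_variants < 1:
        raise OverlapError("n_variants must be >= 1")
    cis_threshold = 0.05 / n_variants
    trans_threshold = cis_threshold / external.n_assayed_proteins

    by_variant = dict(tuple(external.rows.groupby("variant_id")))
    rows = []
    for _, rec in mspavs.drop_duplicates("variant_id").iterrows():
        vid, own = rec["variant_id"], rec["target_id"]
        assayed = own in external.assayed_targets
        hits = by_variant.get(vid)
        if hits is None:
            logger.info("variant %s absent from %s summary statistics", vid, external.platform)
            cls = "none" if assayed else "not_assayed"
        else:
            own_p = hits.loc[hits["target_id"] == own, "p"]
            other_p = hits.loc[hits["target_id"] != own, "p"]
            if assayed and len(own_p) and (own_p < cis_threshold).any():
                cls = "cis"
            elif len(other_p) and (other_p < trans_threshold).any():
                cls = "trans_only"
            elif not assayed:
                cls = "not_assayed"
            else:
                cls = "none"
        rows.append(
            {
                "variant_id": vid,
                "target_id": own,
                "platform": external.platform,
                "assayed": assayed,
                "overlap_class": cls,
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "platform": external.platform,
        "n_variants": len(table),
        "cis_threshold": cis_threshold,
        "trans_threshold": trans_threshold,
        "assayed": int(table["assayed"].sum()),
        "not_assayed": int((~table["assayed"]).sum()),
        "cis": int((table["overlap_class"] == "cis").sum()),
        "trans_not_cis": int((table["overlap_class"] == "trans_only").sum()),
        "any_overlap": int(table["overlap_class"].isin(["cis", "trans_only"]).sum()),
        "no_overlap": int(table["overlap_class"].isin(["none", "not_assayed"]).sum()),
    }
    return table, summary


def combine_overlap(per_platform: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate class across platforms: cis beats trans_only beats none/not_assayed."""
    if not per_platform:
        return pd.DataFrame()
    merged = pd.concat(per_platform, ignore_index=True)
    order = {"cis": 0, "trans_only": 1, "none": 2, "not_assayed": 3}
    best = (
        merged.assign(rank=merged["overlap_class"].map(order))
        .sort_values("rank")
        .drop_duplicates("variant_id")
        .drop(columns=["rank", "platform", "assayed"])
        .rename(columns={"overlap_class": "aggregate_class"})
        .reset_index(drop=True)
    )
    return best
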
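"""Mapping PTM sites onto region classes; count and share statistics.

The count table is modification-type x region-class, with the
coiled-coil subclass folded into the disorder-with-SS column, matching
the published layout for the spliceosomal proteome.  Shares are kept
unrounded internally; report writers round to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .records import (
    ModType,
    PTMSite,
    Region,
    RegionClass,
    ValidationError,
)

#: Column order of the count table; coiled-coil folds into disorder_with_SS.
TABLE_CLASSES: list[RegionClass] = [
    RegionClass.STRUCTURAL_ORDER,
    RegionClass.DISORDER_WITH_SS,
    RegionClass.RS_LIKE,
    RegionClass.POLY_PQ,
    RegionClass.HNRNP_G_RICH,
    RegionClass.NONCHARGED_BIASED,
    RegionClass.CHARGED_BIASED,
    RegionClass.OTHER_DISORDER,
]

MOD_ORDER: list[ModType] = list(ModType)


def _table_class(region_class: RegionClass) -> RegionClass:
    if region_class is RegionClass.DISORDER_WITH_COILED_COIL:
        return RegionClass.DISORDER_WITH_SS
    return region_class


def build_count_table(sites: Sequence[PTMSite], regions: Sequence[Region]) -> pd.DataFrame:
    """Count sites per (mod_type, region class).  Regions must tile every
    protein carrying sites; a site not covered by any region is an error.

    Returns a DataFrame indexed by mod_type value with one column per
    class value plus a ``total`` column.
    """
    by_protein: dict[str, list[Region]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    for regs in by_protein.values():
        regs.sort(key=lambda r: r.start)

    table = pd.DataFrame(
        0,
        index=[m.value for m in MOD_ORDER],
        columns=[c.value for c in TABLE_CLASSES],
        dtype=int,
    )
    for site in sites:
        regs = by_protein.get(site.protein_id)
        hit = None
        if regs is not None:
            for r in regs:
                if r.start <= site.position <= r.end:
                    hit = r
                    break
        if hit is None:
            raise ValidationError(
                f"PTM site {site.protein_id}@{site.position} not covered by any region"
            )
        table.loc[site.mod_type.value, _table_class(hit.region_class).value] += 1
    table["total"] = table.sum(axis=1)
    return table


def class_lengths(regions: Sequence[Region]) -> dict[str, int]:
    """Total residues per (folded) region class across the proteome."""
    out = {c.value: 0 for c in TABLE_CLASSES}
    for r in regions:
        out[_table_class(r.region_class).value] += r.length
    return out


@dataclass(frozen=True)
class ShareReport:
    """Unrounded share statistics derived from a count table."""

    mod_share_of_all: Mapping[str, float]  # % of all PTMs per mod_type
    class_share_of_mod: pd.DataFrame  # % of each mod_type's sites per class
    class_share_of_length: Mapping[str, float]  # % of combined length per class
    enrichment: pd.DataFrame  # site share / length share
    grand_total: int


def ptm_share_stats(
    table: pd.DataFrame,
    lengths: Mapping[str, int] | None = None,
) -> ShareReport:
    """Percentage shares and length-normalised enrichments from a count table.

    ``lengths`` maps class value -> total residues; when omitted, the
    length-share and enrichment fields are empty.
    """
    counts = table[[c.value for c in TABLE_CLASSES]]
    grand_total = int(counts.to_numpy().sum())
    if grand_total == 0:
        raise ValidationError("count table is empty (grand total 0)")
    row_totals = counts.sum(axis=1)

    mod_share = {m: 100.0 * row_totals[m] / grand_total for m in counts.index}
    safe_totals = row_totals.astype(float).replace(0.0, float("nan"))
    class_share = (counts.div(safe_totals, axis=0) * 100.0).astype(float)

    if lengths:
        total_len = sum(lengths.values())
        if total_len == 0:
            raise ValidationError("total proteome length is zero")
        len_share = {c: 100.0 * lengths.get(c, 0) / total_len for c in counts.columns}
        enrich = class_share.copy()
        for c in counts.columns:
            if len_share[c] > 0:
                enrich[c] = class_share[c] / len_share[c]
            else:
                enrich[c] = float("nan")
    else:
        len_share = {}
        enrich = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)

    return ShareReport(mod_share, class_share, len_share, enrich, grand_total)


def share_report_frame(report: ShareReport) -> pd.DataFrame:
    """One-decimal display table mirroring the published layout."""
    df = report.class_share_of_mod.round(1).copy()
    df["percent_of_all_ptms"] = pd.Series(report.mod_share_of_all).round(1)
    return df
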
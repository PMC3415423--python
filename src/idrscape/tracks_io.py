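"""Readers and writers for the pipeline's external formats.

Sequences come in as FASTA (via Biopython), everything else as long-form
TSV so that heterogeneous per-residue categories share one reader.  All
files use 1-based inclusive coordinates; every reader validates against
the proteome and raises :class:`ValidationError` naming the offending
record rather than dropping it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .records import (
    Abundance,
    ModType,
    PredictorTrack,
    ProteinRecord,
    PTMSite,
    PtmStatus,
    Region,
    RegionClass,
    RnaRecord,
    TrackCategory,
    ValidationError,
)

_BINARY_CATEGORIES = {
    TrackCategory.COILED_COIL,
    TrackCategory.BURIAL,
    TrackCategory.HOMOLOGY_SUPPORT,
}


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a protein metadata TSV (protein_id, group, abundance, copy_number)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise ValidationError(f"{path}: metadata table lacks a protein_id column")
    return df


def read_fasta(path: str | Path, metadata: Optional[pd.DataFrame] = None) -> list[ProteinRecord]:
    """Parse a FASTA proteome, optionally joining group/abundance/copy metadata.

    Raises on duplicate ids, empty sequences or non-amino-acid letters
    (other than X), naming the offending record.
    """
    meta: dict[str, dict] = {}
    if metadata is not None:
        for row in metadata.to_dict("records"):
            meta[str(row["protein_id"])] = row

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValidationError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        row = meta.get(pid, {})
        abundance = row.get("abundance")
        group = row.get("group")
        if isinstance(group, float) and pd.isna(group):
            group = None
        copy_number = row.get("copy_number", 1)
        if pd.isna(copy_number):
            copy_number = 1
        records.append(
            ProteinRecord(
                protein_id=pid,
                sequence=str(entry.seq).upper(),
                group=group,
                abundance=Abundance(abundance) if isinstance(abundance, str) else Abundance.UNSPECIFIED,
                copy_number=int(copy_number),
            )
        )
    if not records:
        raise ValidationError(f"{path}: no FASTA entries found")
    return records


def write_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def _proteome_index(proteome: Sequence[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {p.protein_id: p for p in proteome}


def read_tracks(path: str | Path, proteome: Sequence[ProteinRecord]) -> list[PredictorTrack]:
    """Read a long-form track TSV: protein_id, predictor_id, category, position, value.

    Every (protein, predictor) pair must cover positions 1..L exactly once.
    """
    index = _proteome_index(proteome)
    df = pd.read_csv(
        path, sep="\t", dtype={"protein_id": str, "predictor_id": str, "category": str, "value": str}
    )
    required = {"protein_id", "predictor_id", "category", "position", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    tracks: list[PredictorTrack] = []
    for (pid, pred, cat), sub in df.groupby(["protein_id", "predictor_id", "category"], sort=True):
        if pid not in index:
            raise ValidationError(f"{path}: unknown protein_id {pid!r}")
        try:
            category = TrackCategory(cat)
        except ValueError as exc:
            raise ValidationError(f"{path}: unknown track category {cat!r}") from exc
        length = len(index[pid])
        positions = sub["position"].astype(int)
        expected = set(range(1, length + 1))
        got = set(positions)
        gaps = sorted(expected - got)
        if gaps or len(positions) != length:
            detail = f"missing positions {gaps[:10]}" if gaps else "duplicate positions"
            raise ValidationError(f"{path}: track {pid}/{pred}/{cat}: {detail}")
        ordered = sub.sort_values("position")["value"]
        if category is TrackCategory.DISORDER:
            values = tuple(float(v) for v in ordered)
        elif category is TrackCategory.SECONDARY_STRUCTURE:
            values = tuple(str(v) for v in ordered)
        else:
            values = tuple(int(float(v)) for v in ordered)
        tracks.append(PredictorTrack(pid, pred, category, values))
    return tracks


def write_tracks(tracks: Sequence[PredictorTrack], path: str | Path) -> None:
    rows = []
    for t in sorted(tracks, key=lambda t: (t.protein_id, t.predictor_id, t.category.value)):
        for i, v in enumerate(t.values, start=1):
            rows.append((t.protein_id, t.predictor_id, t.category.value, i, v))
    pd.DataFrame(
        rows, columns=["protein_id", "predictor_id", "category", "position", "value"]
    ).to_csv(path, sep="\t", index=False)


def read_ptm_table(
    path: str | Path,
    proteome: Sequence[ProteinRecord],
    exclude_unverified: bool = False,
) -> list[PTMSite]:
    """Read a PTM site TSV and validate each site against the sequences.

    ``exclude_unverified=True`` drops sites whose status is by_similarity or
    potential_or_probable; by default all sites are kept, which the source
    annotations support (removing them does not change overall statistics).
    """
    index = _proteome_index(proteome)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    sites: list[PTMSite] = []
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid not in index:
            raise ValidationError(f"{path}: unknown protein_id {pid!r}")
        try:
            mod = ModType(row.mod_type)
        except ValueError as exc:
            raise ValidationError(f"{path}: unknown mod_type {row.mod_type!r}") from exc
        try:
            status = PtmStatus(row.status)
        except ValueError as exc:
            raise ValidationError(f"{path}: unknown status {row.status!r}") from exc
        pos = int(row.position)
        seq = index[pid].sequence
        if not (1 <= pos <= len(seq)):
            raise ValidationError(f"{path}: site {pid}@{pos} outside protein (length {len(seq)})")
        if seq[pos - 1] != row.residue:
            raise ValidationError(
                f"{path}: site {pid}@{pos} annotated {row.residue} but sequence has {seq[pos - 1]}"
            )
        site = PTMSite(pid, pos, row.residue, mod, status)
        if exclude_unverified and status is not PtmStatus.EXPERIMENTAL:
            continue
        sites.append(site)
    return sites


def write_ptm_table(sites: Sequence[PTMSite], path: str | Path) -> None:
    rows = [
        (s.protein_id, s.position, s.residue, s.mod_type.value, s.status.value)
        for s in sorted(sites, key=lambda s: (s.protein_id, s.position, s.mod_type.value))
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "position", "residue", "mod_type", "status"]
    ).to_csv(path, sep="\t", index=False)


def read_rna_table(path: str | Path) -> list[RnaRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"rna_id": str})
    out = []
    for row in df.itertuples(index=False):
        copy_number = int(getattr(row, "copy_number", 1))
        out.append(RnaRecord(row.rna_id, int(row.length_nt), copy_number))
    return out


def write_region_table(regions: Sequence[Region], path: str | Path) -> None:
    """Write regions as TSV sorted by (protein_id, start); overlap is an error."""
    ordered = sorted(regions, key=lambda r: (r.protein_id, r.start))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.protein_id == prev.protein_id and cur.start <= prev.end:
            raise ValidationError(
                f"overlapping regions on {cur.protein_id}: "
                f"[{prev.start},{prev.end}] and [{cur.start},{cur.end}]"
            )
    rows = [
        (
            r.protein_id,
            r.start,
            r.end,
            r.region_class.value,
            ",".join(sorted(r.overrep)),
            r.grich_length_class or "",
            r.length,
        )
        for r in ordered
    ]
    pd.DataFrame(
        rows,
        columns=["protein_id", "start", "end", "region_class", "overrep", "grich_length_class", "length"],
    ).to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> list[Region]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "overrep": str, "grich_length_class": str})
    regions = []
    for row in df.itertuples(index=False):
        overrep = frozenset(str(row.overrep).split(",")) if isinstance(row.overrep, str) and row.overrep else frozenset()
        glc = row.grich_length_class if isinstance(row.grich_length_class, str) and row.grich_length_class else None
        regions.append(
            Region(
                protein_id=row.protein_id,
                start=int(row.start),
                end=int(row.end),
                region_class=RegionClass(row.region_class),
                overrep=overrep,
                grich_length_class=glc,
            )
        )
    return regions
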
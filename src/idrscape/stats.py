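"""Proteome- and group-level disorder summaries.

Two averaging conventions are kept distinct throughout:

* *per-residue* mean — all disordered residues in a group divided by the
  total length of the group's proteins (length-weighted);
* *per-protein* mean — each protein's disordered fraction computed first,
  then averaged unweighted.

An *IDR* for length statistics is a maximal run of non-ordered residues:
contiguous disorder regions of different classes merge into one IDR,
since segment lengths predate classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .records import (
    DISORDER_CLASSES,
    ProteinRecord,
    Region,
    RegionClass,
    RnaRecord,
    ValidationError,
    merge_adjacent,
)

#: Average residue masses in daltons (monomer minus water).
AA_MASSES: dict[str, float] = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
    "X": 110.0,  # unresolved residue: average placeholder mass
}

#: Average RNA nucleotide-monophosphate residue mass in daltons.
NT_MASS_DEFAULT: float = 321.0

_SS_CLASSES = {RegionClass.DISORDER_WITH_SS, RegionClass.DISORDER_WITH_COILED_COIL}


@dataclass(frozen=True)
class GroupStats:
    group: str
    n_proteins: int
    per_residue_disorder: float
    per_protein_disorder: float
    n_with_idr_ge30: int
    n_with_idr_ge70: int
    mean_idr_length: float
    n_idrs: int
    ss_disorder_share: float  # fraction of disordered residues in SS classes
    n_nonss_idr_ge70: int


def _regions_by_protein(regions: Sequence[Region]) -> dict[str, list[Region]]:
    out: dict[str, list[Region]] = {}
    for r in regions:
        out.setdefault(r.protein_id, []).append(r)
    for v in out.values():
        v.sort(key=lambda r: r.start)
    return out


def _disordered_residues(regs: Sequence[Region]) -> int:
    return sum(r.length for r in regs if r.region_class in DISORDER_CLASSES)


def _idr_intervals(regs: Sequence[Region]) -> list[tuple[int, int]]:
    """Maximal runs of non-ordered residues (class-agnostic merge)."""
    return merge_adjacent(regs, DISORDER_CLASSES)


def disorder_fractions(
    proteins: Sequence[ProteinRecord],
    regions: Sequence[Region],
    group_by: str = "group",
) -> list[GroupStats]:
    """Per-group disorder statistics under both averaging conventions.

    ``group_by`` is "group" (metadata label; proteins without one fall
    into "unassigned") or "all" (a single group of every protein).
    Duplicate-protein policy: each ProteinRecord counts once here,
    regardless of copy_number (copy numbers only weight mass fractions).
    """
    by_protein = _regions_by_protein(regions)
    groups: dict[str, list[ProteinRecord]] = {}
    for p in proteins:
        key = "all" if group_by == "all" else (p.group or "unassigned")
        groups.setdefault(key, []).append(p)

    out: list[GroupStats] = []
    for label in sorted(groups):
        members = groups[label]
        if not members:
            raise ValidationError(f"empty group {label!r}")
        total_len = 0
        total_dis = 0
        per_protein_fracs = []
        n_ge30 = n_ge70 = 0
        idr_lengths: list[int] = []
        ss_dis = 0
        n_nonss_ge70 = 0
        for p in members:
            regs = by_protein.get(p.protein_id, [])
            dis = _disordered_residues(regs)
            total_len += len(p)
            total_dis += dis
            per_protein_fracs.append(dis / len(p))
            idrs = _idr_intervals(regs)
            lens = [e - s + 1 for s, e in idrs]
            idr_lengths.extend(lens)
            if any(l >= 30 for l in lens):
                n_ge30 += 1
            if any(l >= 70 for l in lens):
                n_ge70 += 1
            ss_dis += sum(r.length for r in regs if r.region_class in _SS_CLASSES)
            n_nonss_ge70 += sum(
                1
                for r in regs
                if r.region_class in (DISORDER_CLASSES - _SS_CLASSES) and r.length >= 70
            )
        out.append(
            GroupStats(
                group=label,
                n_proteins=len(members),
                per_residue_disorder=total_dis / total_len,
                per_protein_disorder=sum(per_protein_fracs) / len(per_protein_fracs),
                n_with_idr_ge30=n_ge30,
                n_with_idr_ge70=n_ge70,
                mean_idr_length=(sum(idr_lengths) / len(idr_lengths)) if idr_lengths else 0.0,
                n_idrs=len(idr_lengths),
                ss_disorder_share=(ss_dis / total_dis) if total_dis else 0.0,
                n_nonss_idr_ge70=n_nonss_ge70,
            )
        )
    return out


@dataclass(frozen=True)
class IdrLengthSummary:
    mean_idr_length: float
    n_idrs: int
    n_proteins_with_idr_ge: Mapping[int, int]
    n_nonss_idrs_ge70: int


def idr_length_stats(
    regions: Sequence[Region],
    thresholds: Sequence[int] = (30, 70),
) -> IdrLengthSummary:
    """IDR length summary over a region table (IDR = merged non-ordered run).

    The mean averages over IDRs, not proteins; with no IDRs anywhere the
    mean is reported as 0.0 alongside ``n_idrs == 0``.
    """
    by_protein = _regions_by_protein(regions)
    all_lens: list[int] = []
    per_thresh = {t: 0 for t in thresholds}
    n_nonss_ge70 = 0
    for regs in by_protein.values():
        lens = [e - s + 1 for s, e in _idr_intervals(regs)]
        all_lens.extend(lens)
        for t in thresholds:
            if any(l >= t for l in lens):
                per_thresh[t] += 1
        n_nonss_ge70 += sum(
            1
            for r in regs
            if r.region_class in (DISORDER_CLASSES - _SS_CLASSES) and r.length >= 70
        )
    mean = (sum(all_lens) / len(all_lens)) if all_lens else 0.0
    return IdrLengthSummary(mean, len(all_lens), per_thresh, n_nonss_ge70)


@dataclass(frozen=True)
class MassReport:
    protein_mass: float
    rna_mass: float
    rna_fraction: float  # of total mass, in [0, 1]
    class_mass_fractions: Mapping[str, float]  # of total (protein+RNA) mass


def protein_mass(protein: ProteinRecord, aa_masses: Mapping[str, float]) -> float:
    try:
        return sum(aa_masses[c] for c in protein.sequence)
    except KeyError as exc:
        raise ValidationError(
            f"{protein.protein_id}: residue {exc.args[0]!r} missing from mass table"
        ) from exc


def mass_fractions(
    proteins: Sequence[ProteinRecord],
    rnas: Sequence[RnaRecord],
    regions: Sequence[Region] = (),
    aa_masses: Optional[Mapping[str, float]] = None,
    nt_mass: float = NT_MASS_DEFAULT,
) -> MassReport:
    """Mass composition of the complex.  Copy numbers weight every chain
    (stoichiometric repeats, e.g. ring proteins present in several snRNPs,
    count each copy toward the weight)."""
    aa_masses = AA_MASSES if aa_masses is None else aa_masses
    p_mass = sum(p.copy_number * protein_mass(p, aa_masses) for p in proteins)
    r_mass = sum(r.copy_number * r.length_nt * nt_mass for r in rnas)
    total = p_mass + r_mass
    if total == 0:
        raise ValidationError("total mass is zero")

    class_mass: dict[str, float] = {}
    if regions:
        index = {p.protein_id: p for p in proteins}
        for r in regions:
            p = index.get(r.protein_id)
            if p is None:
                continue
            seg_mass = p.copy_number * sum(
                aa_masses[c] for c in p.sequence[r.start - 1 : r.end]
            )
            key = r.region_class.value
            class_mass[key] = class_mass.get(key, 0.0) + seg_mass
        class_mass = {k: v / total for k, v in sorted(class_mass.items())}

    return MassReport(p_mass, r_mass, r_mass / total, class_mass)
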
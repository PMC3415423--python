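"""Core domain records shared across the pipeline.

All coordinates are 1-based and inclusive on both ends, matching UniProt
feature-table usage ("residues 333-342").  Helpers to convert to 0-based
half-open slices live at the I/O boundary only (:func:`to_slice`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
#: Sequences may carry 'X' for unresolved residues; excluded from composition.
SEQ_LETTERS = AA_LETTERS | {"X"}

CHARGED = frozenset("RKDE")
#: Table of noncharged residues used by the noncharged-bias subclass.
NONCHARGED_CLASS_SET = frozenset("PQMGVWA")


class Abundance(str, enum.Enum):
    ABUNDANT = "abundant"
    NON_ABUNDANT = "non_abundant"
    UNSPECIFIED = "unspecified"


class TrackCategory(str, enum.Enum):
    DISORDER = "disorder"
    SECONDARY_STRUCTURE = "secondary_structure"
    COILED_COIL = "coiled_coil"
    BURIAL = "burial"
    HOMOLOGY_SUPPORT = "homology_support"


class ModType(str, enum.Enum):
    PHOSPHORYLATION = "phosphorylation"
    LYSINE_N_ACETYLATION = "lysine_N_acetylation"
    OTHER_N_ACETYLATION = "other_N_acetylation"
    ARGININE_METHYLATION = "arginine_methylation"
    LYSINE_METHYLATION = "lysine_methylation"
    CYSTEINE_METHYL_ESTER = "cysteine_methyl_ester"


class PtmStatus(str, enum.Enum):
    EXPERIMENTAL = "experimental"
    BY_SIMILARITY = "by_similarity"
    POTENTIAL_OR_PROBABLE = "potential_or_probable"


class RegionClass(str, enum.Enum):
    STRUCTURAL_ORDER = "structural_order"
    DISORDER_WITH_SS = "disorder_with_SS"
    DISORDER_WITH_COILED_COIL = "disorder_with_coiled_coil"
    RS_LIKE = "RS_like"
    POLY_PQ = "polyPQ"
    HNRNP_G_RICH = "hnRNP_G_rich"
    NONCHARGED_BIASED = "noncharged_biased"
    CHARGED_BIASED = "charged_biased"
    OTHER_DISORDER = "other_disorder"


#: The five compositionally biased subclasses gated at >=25 residues.
BIASED_CLASSES = frozenset(
    {
        RegionClass.RS_LIKE,
        RegionClass.POLY_PQ,
        RegionClass.HNRNP_G_RICH,
        RegionClass.NONCHARGED_BIASED,
        RegionClass.CHARGED_BIASED,
    }
)

#: Classes counted as disordered (everything except structural order).
DISORDER_CLASSES = frozenset(set(RegionClass) - {RegionClass.STRUCTURAL_ORDER})


class ValidationError(ValueError):
    """Raised whenever an input file or record violates an invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    group: Optional[str] = None
    abundance: Abundance = Abundance.UNSPECIFIED
    copy_number: int = 1

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValidationError(f"{self.protein_id}: sequence must be uppercase")
        bad = set(self.sequence) - SEQ_LETTERS
        if bad:
            raise ValidationError(
                f"{self.protein_id}: non-amino-acid characters {sorted(bad)}"
            )
        if self.copy_number < 1:
            raise ValidationError(f"{self.protein_id}: copy_number must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RnaRecord:
    rna_id: str
    length_nt: int
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValidationError(f"{self.rna_id}: length_nt must be >= 1")
        if self.copy_number < 1:
            raise ValidationError(f"{self.rna_id}: copy_number must be >= 1")


@dataclass(frozen=True)
class PredictorTrack:
    """One predictor's per-residue values for one protein.

    ``values`` is a tuple: floats in [0,1] or 0/1 ints for disorder;
    'H'/'E'/'C' labels for secondary structure; 0/1 for coiled-coil,
    burial and homology support.
    """

    protein_id: str
    predictor_id: str
    category: TrackCategory
    values: tuple

    def __post_init__(self) -> None:
        if self.category is TrackCategory.DISORDER:
            for v in self.values:
                if not (0.0 <= float(v) <= 1.0):
                    raise ValidationError(
                        f"{self.protein_id}/{self.predictor_id}: disorder value "
                        f"{v!r} outside [0, 1]"
                    )
        elif self.category is TrackCategory.SECONDARY_STRUCTURE:
            bad = set(self.values) - {"H", "E", "C"}
            if bad:
                raise ValidationError(
                    f"{self.protein_id}/{self.predictor_id}: SS labels must be "
                    f"H/E/C, got {sorted(bad)}"
                )
        else:
            bad = {v for v in self.values if int(v) not in (0, 1)}
            if bad:
                raise ValidationError(
                    f"{self.protein_id}/{self.predictor_id}: binary track with "
                    f"non-binary values {sorted(map(repr, bad))}"
                )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PTMSite:
    protein_id: str
    position: int
    residue: str
    mod_type: ModType
    status: PtmStatus = PtmStatus.EXPERIMENTAL

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.protein_id}: PTM position {self.position} is not 1-based"
            )
        if self.residue not in SEQ_LETTERS:
            raise ValidationError(
                f"{self.protein_id}@{self.position}: residue {self.residue!r} "
                "is not an amino-acid letter"
            )


@dataclass(frozen=True)
class Region:
    """A classified interval on one protein, 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    region_class: RegionClass
    overrep: frozenset = frozenset()
    grich_length_class: Optional[str] = None  # "short" | "long"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"{self.protein_id}: bad region bounds [{self.start}, {self.end}]"
            )
        if self.grich_length_class not in (None, "short", "long"):
            raise ValidationError(
                f"{self.protein_id}: grich_length_class "
                f"{self.grich_length_class!r} invalid"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __len__(self) -> int:
        return self.length


def to_slice(start: int, end: int) -> slice:
    """1-based inclusive interval -> Python slice (0-based half-open)."""
    return slice(start - 1, end)


def check_tiling(regions: Sequence[Region], protein_length: int) -> None:
    """Assert that ``regions`` tile [1, L] without gaps or overlap."""
    if not regions:
        raise ValidationError("no regions supplied")
    ordered = sorted(regions, key=lambda r: r.start)
    pid = ordered[0].protein_id
    cursor = 1
    for r in ordered:
        if r.protein_id != pid:
            raise ValidationError("regions from multiple proteins")
        if r.start != cursor:
            raise ValidationError(
                f"{pid}: gap or overlap at position {cursor} (next region "
                f"starts at {r.start})"
            )
        cursor = r.end + 1
    if cursor != protein_length + 1:
        raise ValidationError(
            f"{pid}: regions end at {cursor - 1}, protein length {protein_length}"
        )


def merge_adjacent(regions: Iterable[Region], classes: frozenset) -> list[tuple[int, int]]:
    """Merge sorted same-protein regions whose class is in ``classes`` into
    maximal contiguous intervals (start, end)."""
    merged: list[tuple[int, int]] = []
    for r in sorted(regions, key=lambda r: r.start):
        if r.region_class not in classes:
            continue
        if merged and r.start == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], r.end)
        else:
            merged.append((r.start, r.end))
    return merged
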
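"""Compositional-bias detection and subclass assignment for SS-free IDRs.

A region is *compositionally biased* when at least one residue type occurs
at a frequency above ``region_thresh`` (20%) or above ``region_fold`` (5x)
times its background frequency; within a biased region a residue type is
*overrepresented* when its frequency exceeds ``residue_thresh`` (20%) or
``residue_fold`` (3x) background.  Biased stretches of >= 25 residues are
assigned to one of five subclasses (RS-like, hnRNP-like G-rich, poly-P/Q,
charged, noncharged) in specific-to-generic precedence; everything else
is "other disorder".

Background frequencies default to a packaged vertebrate average
composition (after King & Jukes); they are a documented default, loadable
from a user table, not a claim about any particular proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .consensus import ConsensusAnnotation, segment_protein
from .motifs import MotifMatch, find_pq_runs, scan_pattern
from .records import (
    AA_LETTERS,
    CHARGED,
    NONCHARGED_CLASS_SET,
    ProteinRecord,
    Region,
    RegionClass,
    ValidationError,
)

#: Average amino-acid composition of vertebrate proteins (fractions),
#: after King & Jukes.  Packaged default; override via a two-column TSV.
VERTEBRATE_AA_FREQS: dict[str, float] = {
    "A": 0.074, "R": 0.042, "N": 0.044, "D": 0.059, "C": 0.033,
    "E": 0.058, "Q": 0.037, "G": 0.074, "H": 0.029, "I": 0.038,
    "L": 0.076, "K": 0.072, "M": 0.018, "F": 0.040, "P": 0.050,
    "S": 0.081, "T": 0.062, "W": 0.013, "Y": 0.033, "V": 0.068,
}


@dataclass(frozen=True)
class BackgroundFrequencies:
    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = AA_LETTERS - set(self.freqs)
        if missing:
            raise ValidationError(f"background lacks residues {sorted(missing)}")
        total = sum(self.freqs[a] for a in AA_LETTERS)
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"background frequencies sum to {total}, not 1")
        if any(self.freqs[a] <= 0 for a in AA_LETTERS):
            raise ValidationError("background frequencies must all be positive")

    def __getitem__(self, aa: str) -> float:
        return self.freqs[aa]

    @classmethod
    def vertebrate_default(cls) -> "BackgroundFrequencies":
        total = sum(VERTEBRATE_AA_FREQS.values())
        return cls({k: v / total for k, v in VERTEBRATE_AA_FREQS.items()})

    @classmethod
    def from_table(cls, path: str | Path) -> "BackgroundFrequencies":
        df = pd.read_csv(path, sep="\t", dtype={"residue": str})
        freqs = dict(zip(df["residue"], df["frequency"].astype(float)))
        total = sum(freqs.values())
        return cls({k: v / total for k, v in freqs.items()})


@dataclass(frozen=True)
class BiasVerdict:
    region_biased: bool
    overrep: frozenset
    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.overrep and not self.region_biased:
            raise ValidationError("overrep nonempty but region not biased")


def residue_frequencies(seq: str) -> dict[str, float]:
    """Residue frequencies over the 20 standard letters; X excluded from
    both numerator and denominator."""
    effective = [c for c in seq if c in AA_LETTERS]
    if not effective:
        raise ValidationError("sequence has no standard residues (all X?)")
    n = len(effective)
    out = {aa: 0.0 for aa in AA_LETTERS}
    for c in effective:
        out[c] += 1
    return {aa: cnt / n for aa, cnt in out.items()}


def overrepresented_residues(
    seq: str,
    bg: BackgroundFrequencies,
    region_thresh: float = 0.20,
    region_fold: float = 5.0,
    residue_thresh: float = 0.20,
    residue_fold: float = 3.0,
) -> BiasVerdict:
    """Two-tier bias call: the region is biased if any residue passes the
    stringent region criterion (>20% or >5x background); overrepresented
    residues are then those passing the laxer residue criterion
    (>20% or >3x background)."""
    freqs = residue_frequencies(seq)
    biased = any(
        f > region_thresh or f > region_fold * bg[aa] for aa, f in freqs.items()
    )
    if not biased:
        return BiasVerdict(False, frozenset(), freqs)
    overrep = frozenset(
        aa
        for aa, f in freqs.items()
        if f > residue_thresh or f > residue_fold * bg[aa]
    )
    return BiasVerdict(True, overrep, freqs)


def _grich_coverage(seq: str) -> float:
    """Fraction of the stretch covered by G-rich repeat pattern matches."""
    covered = set()
    for name in ("GRICH_A", "GRICH_B"):
        for m in scan_pattern(seq, name):
            covered.update(range(m.start, m.end + 1))
    return len(covered) / len(seq) if seq else 0.0


def classify_region(
    protein_id: str,
    start: int,
    end: int,
    seq: str,
    verdict: BiasVerdict,
    min_biased_len: int = 25,
    grich_cover: float = 0.5,
    grich_short_max: int = 100,
    pq_homopolymer_only: bool = False,
) -> Region:
    """Assign one SS-free disordered stretch to a compositional subclass.

    ``seq`` is the stretch's own sequence (length end-start+1).  Stretches
    below ``min_biased_len`` or without a bias verdict are other_disorder.
    Precedence is specific-to-generic: RS-like > G-rich > poly-P/Q >
    charged > noncharged.
    """
    length = end - start + 1
    if len(seq) != length:
        raise ValidationError(
            f"{protein_id}: stretch sequence length {len(seq)} != span {length}"
        )

    def region(cls: RegionClass, glc: Optional[str] = None) -> Region:
        keep = verdict.overrep if cls in {
            RegionClass.RS_LIKE,
            RegionClass.POLY_PQ,
            RegionClass.HNRNP_G_RICH,
            RegionClass.NONCHARGED_BIASED,
            RegionClass.CHARGED_BIASED,
        } else frozenset()
        return Region(protein_id, start, end, cls, overrep=keep, grich_length_class=glc)

    if length < min_biased_len or not verdict.region_biased:
        return region(RegionClass.OTHER_DISORDER)

    overrep = verdict.overrep
    if "R" in overrep and "S" in overrep:
        return region(RegionClass.RS_LIKE)
    if _grich_coverage(seq) >= grich_cover:
        glc = "short" if length <= grich_short_max else "long"
        return region(RegionClass.HNRNP_G_RICH, glc)
    has_pq_run = bool(find_pq_runs(seq, n_min=3, homopolymer_only=pq_homopolymer_only))
    if overrep and not (overrep & CHARGED) and has_pq_run:
        return region(RegionClass.POLY_PQ)
    if overrep and overrep <= CHARGED:
        return region(RegionClass.CHARGED_BIASED)
    if overrep and overrep <= NONCHARGED_CLASS_SET:
        return region(RegionClass.NONCHARGED_BIASED)
    return region(RegionClass.OTHER_DISORDER)


def classify_proteome(
    proteins: Sequence[ProteinRecord],
    consensus: Mapping[str, ConsensusAnnotation],
    bg: Optional[BackgroundFrequencies] = None,
    merge_gap: int = 20,
    min_helix: int = 4,
    min_strand: int = 3,
    min_biased_len: int = 25,
    grich_cover: float = 0.5,
    pq_homopolymer_only: bool = False,
) -> list[Region]:
    """Segment and classify every protein; the result tiles each protein.

    Deterministic in the inputs: output is sorted by (protein_id, start)
    and independent of the input ordering of ``proteins``.
    """
    if bg is None:
        bg = BackgroundFrequencies.vertebrate_default()
    regions: list[Region] = []
    for protein in sorted(proteins, key=lambda p: p.protein_id):
        cons = consensus[protein.protein_id]
        if len(cons) != len(protein):
            raise ValidationError(
                f"{protein.protein_id}: consensus length {len(cons)} != protein "
                f"length {len(protein)}"
            )
        base, stretches = segment_protein(cons, merge_gap, min_helix, min_strand)
        regions.extend(base)
        for s, e in stretches:
            seq = protein.sequence[s - 1 : e]
            try:
                verdict = overrepresented_residues(seq, bg)
            except ValidationError:
                # all-X stretch: no composition signal
                verdict = BiasVerdict(False, frozenset(), {})
            regions.append(
                classify_region(
                    protein.protein_id,
                    s,
                    e,
                    seq,
                    verdict,
                    min_biased_len=min_biased_len,
                    grich_cover=grich_cover,
                    pq_homopolymer_only=pq_homopolymer_only,
                )
            )
    return sorted(regions, key=lambda r: (r.protein_id, r.start))
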
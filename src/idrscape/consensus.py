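"""Per-residue consensus over predictor ensembles and IDR segmentation.

A residue is called disordered iff strictly more than half of the disorder
predictors call it disordered (probability tracks are binarised at a cutoff
first).  Ties therefore fall to order — the conservative reading, which
biases the pipeline the same way the downstream globular override does.

The globular override recasts a curation step as a deterministic rule:
a long disordered run that is mostly buried, mostly covered by secondary
structure and (optionally) supported by homology to known globular folds
is flipped to order wholesale.

Segmentation then splits each maximal disorder run into disorder-with-SS
spans (clusters of secondary-structure elements whose connecting loops are
shorter than ``merge_gap``) and SS-free stretches handed to the
composition classifier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .records import (
    PredictorTrack,
    Region,
    RegionClass,
    TrackCategory,
    ValidationError,
)


@dataclass(frozen=True)
class ConsensusAnnotation:
    protein_id: str
    disorder: tuple  # bool per residue
    ss_label: tuple  # 'H' | 'E' | 'C' per residue
    coiled_coil: tuple  # bool per residue
    overridden: tuple  # bool per residue; True where override flipped D->O

    def __post_init__(self) -> None:
        n = len(self.disorder)
        if not (len(self.ss_label) == len(self.coiled_coil) == len(self.overridden) == n):
            raise ValidationError(f"{self.protein_id}: consensus vectors of unequal length")
        for ov, dis in zip(self.overridden, self.disorder):
            if ov and dis:
                raise ValidationError(
                    f"{self.protein_id}: overridden residue still marked disordered"
                )

    def __len__(self) -> int:
        return len(self.disorder)


@dataclass(frozen=True)
class SsElement:
    start: int  # 1-based inclusive
    end: int
    kind: str  # "helix" | "strand"


def consensus_tracks(
    tracks: Sequence[PredictorTrack],
    disorder_cutoff: float = 0.5,
) -> ConsensusAnnotation:
    """Vote per-residue consensus for one protein's predictor tracks.

    disorder: strict majority of disorder tracks (>= cutoff counts as a
    disorder call); ss_label: plurality over SS tracks, ties -> 'C';
    coiled_coil: strict majority of coiled-coil tracks.
    """
    if not tracks:
        raise ValidationError("no tracks supplied")
    pids = {t.protein_id for t in tracks}
    if len(pids) != 1:
        raise ValidationError(f"tracks from multiple proteins: {sorted(pids)}")
    pid = tracks[0].protein_id
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValidationError(f"{pid}: tracks of unequal length {sorted(lengths)}")
    n = lengths.pop()

    dis_tracks = [t for t in tracks if t.category is TrackCategory.DISORDER]
    if not dis_tracks:
        raise ValidationError(f"{pid}: no disorder tracks")
    ss_tracks = [t for t in tracks if t.category is TrackCategory.SECONDARY_STRUCTURE]
    cc_tracks = [t for t in tracks if t.category is TrackCategory.COILED_COIL]

    calls = np.array([[float(v) >= disorder_cutoff for v in t.values] for t in dis_tracks])
    disorder = tuple(bool(x) for x in (calls.sum(axis=0) * 2 > len(dis_tracks)))

    if ss_tracks:
        ss_label = []
        for i in range(n):
            votes = Counter(t.values[i] for t in ss_tracks)
            top = max(votes.values())
            winners = sorted(k for k, v in votes.items() if v == top)
            ss_label.append(winners[0] if len(winners) == 1 else "C")
        ss_label = tuple(ss_label)
    else:
        ss_label = tuple("C") * n

    if cc_tracks:
        cc = np.array([[int(v) for v in t.values] for t in cc_tracks])
        coiled = tuple(bool(x) for x in (cc.sum(axis=0) * 2 > len(cc_tracks)))
    else:
        coiled = (False,) * n

    return ConsensusAnnotation(pid, disorder, ss_label, coiled, (False,) * n)


def _runs(mask: Sequence[bool]) -> list[tuple[int, int]]:
    """Maximal True-runs as 1-based inclusive (start, end) intervals."""
    runs = []
    start = None
    for i, v in enumerate(mask, start=1):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def apply_globular_override(
    cons: ConsensusAnnotation,
    burial_track: Optional[PredictorTrack],
    homology_track: Optional[PredictorTrack] = None,
    min_window: int = 30,
    burial_frac: float = 0.5,
    require_homology: bool = True,
) -> ConsensusAnnotation:
    """Flip long, buried, SS-covered (and homology-supported) disorder runs
    to order.  Idempotent; a no-op when no run meets all conditions.

    With ``require_homology=True`` and no homology track, nothing flips;
    set it False to waive the homology condition when the track is absent.
    """
    if burial_track is None:
        return cons
    if len(burial_track) != len(cons):
        raise ValidationError(f"{cons.protein_id}: burial track length mismatch")
    if homology_track is not None and len(homology_track) != len(cons):
        raise ValidationError(f"{cons.protein_id}: homology track length mismatch")

    disorder = list(cons.disorder)
    overridden = list(cons.overridden)
    for start, end in _runs(cons.disorder):
        width = end - start + 1
        if width < min_window:
            continue
        sl = slice(start - 1, end)
        buried = sum(int(v) for v in burial_track.values[sl]) / width
        if buried < burial_frac:
            continue
        ss_cover = sum(1 for lab in cons.ss_label[sl] if lab in ("H", "E")) / width
        if ss_cover < 0.5:
            continue
        if homology_track is not None:
            if not all(int(v) for v in homology_track.values[sl]):
                continue
        elif require_homology:
            continue
        for i in range(start - 1, end):
            disorder[i] = False
            overridden[i] = True
    return replace(cons, disorder=tuple(disorder), overridden=tuple(overridden))


def extract_idrs(cons: ConsensusAnnotation, min_report_len: int = 1) -> list[tuple[int, int]]:
    """Maximal disordered runs of length >= min_report_len, 1-based inclusive."""
    return [(s, e) for s, e in _runs(cons.disorder) if e - s + 1 >= min_report_len]


def find_ss_elements(
    cons: ConsensusAnnotation,
    start: int,
    end: int,
    min_helix: int = 4,
    min_strand: int = 3,
) -> list[SsElement]:
    """Secondary-structure elements inside [start, end] meeting length minima."""
    elements: list[SsElement] = []
    labels = cons.ss_label[start - 1 : end]
    run_start = None
    run_label = None
    for offset, lab in enumerate(list(labels) + ["C"]):
        if lab == run_label:
            continue
        if run_label in ("H", "E"):
            s, e = start + run_start, start + offset - 1
            width = e - s + 1
            if run_label == "H" and width >= min_helix:
                elements.append(SsElement(s, e, "helix"))
            elif run_label == "E" and width >= min_strand:
                elements.append(SsElement(s, e, "strand"))
        run_label = lab
        run_start = offset
    return elements


def partition_idr_by_ss(
    idr: tuple[int, int],
    cons: ConsensusAnnotation,
    merge_gap: int = 20,
    min_helix: int = 4,
    min_strand: int = 3,
) -> tuple[list[Region], list[tuple[int, int]]]:
    """Split one IDR into disorder-with-SS regions and SS-free stretches.

    SS elements whose separating loops are shorter than ``merge_gap`` are
    clustered; each cluster's span (first element start to last element end)
    becomes one region — disorder_with_coiled_coil if any helix in the
    cluster overlaps coiled-coil consensus.  Returns (regions, stretches);
    stretches are the intervals of the IDR outside cluster spans.
    """
    start, end = idr
    if start < 1 or end > len(cons) or start > end:
        raise ValidationError(f"{cons.protein_id}: IDR [{start},{end}] out of bounds")
    elements = find_ss_elements(cons, start, end, min_helix, min_strand)

    clusters: list[list[SsElement]] = []
    for el in elements:
        if clusters and el.start - clusters[-1][-1].end - 1 < merge_gap:
            clusters[-1].append(el)
        else:
            clusters.append([el])

    regions: list[Region] = []
    stretches: list[tuple[int, int]] = []
    cursor = start
    for cluster in clusters:
        span = (cluster[0].start, cluster[-1].end)
        has_cc_helix = any(
            el.kind == "helix" and any(cons.coiled_coil[el.start - 1 : el.end])
            for el in cluster
        )
        cls = (
            RegionClass.DISORDER_WITH_COILED_COIL
            if has_cc_helix
            else RegionClass.DISORDER_WITH_SS
        )
        if span[0] > cursor:
            stretches.append((cursor, span[0] - 1))
        regions.append(Region(cons.protein_id, span[0], span[1], cls))
        cursor = span[1] + 1
    if cursor <= end:
        stretches.append((cursor, end))
    return regions, stretches


def segment_protein(
    cons: ConsensusAnnotation,
    merge_gap: int = 20,
    min_helix: int = 4,
    min_strand: int = 3,
) -> tuple[list[Region], list[tuple[int, int]]]:
    """Full segmentation of one protein: ordered regions + SS regions +
    SS-free disordered stretches (returned separately for composition)."""
    regions: list[Region] = []
    stretches: list[tuple[int, int]] = []
    disorder = cons.disorder
    for s, e in _runs([not d for d in disorder]):
        regions.append(Region(cons.protein_id, s, e, RegionClass.STRUCTURAL_ORDER))
    for idr in extract_idrs(cons):
        ss_regions, free = partition_idr_by_ss(idr, cons, merge_gap, min_helix, min_strand)
        regions.extend(ss_regions)
        stretches.extend(free)
    return regions, stretches
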
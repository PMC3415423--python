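"""Linear-motif scanning: ULM, G-rich repeat patterns, and P/Q runs.

Patterns (x = any amino acid):

* ``ULM``     — [RK]{1,}  [RK]  x{0,1}  [RK]{1,}  x{0,1}  W  x{0,2}  [DE]{1,}
  (tryptophan-centred basic motif bound by U2AF-homology-motif domains;
  the stringent consensus chosen to limit false positives)
* ``ULM_LENIENT`` — [KR]{1,4} [KR] x{0,1} [KR]W x{0,1}
  (the more permissive literature variant, available as a named alternate)
* ``GRICH_A`` — [RSY]GG x{1,50} [RSY]GG x{1,50} [RSY]GG
* ``GRICH_B`` — R[AGT][AGTFIVR] x{1,25} RGG x{1,25} R[AGT][AGTFIVR]
* ``PQ_RUN``  — maximal runs over {P, Q} of length >= 3 (config-switchable
  to homopolymer-only runs)

Matches are reported non-overlapping with leftmost-then-longest
resolution: at the leftmost position where any match starts, the longest
match there is taken and scanning resumes after its end.  Python's `re`
engine is leftmost-*greedy*, which is not guaranteed longest, so the
scanner searches explicitly for the longest end at each start.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .records import Region, RegionClass, ValidationError


class DisorderContext(str, enum.Enum):
    ORDERED = "ordered"
    DISORDERED = "disordered"
    MIXED = "mixed"
    UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    motif_name: str
    start: int  # 1-based inclusive
    end: int
    matched_seq: str
    disorder_context: DisorderContext = DisorderContext.UNANNOTATED


PATTERNS: dict[str, str] = {
    "ULM": r"[RK]+[RK].?[RK]+.?W.{0,2}[DE]+",
    "ULM_LENIENT": r"[KR]{1,4}[KR].?[KR]W.?",
    "GRICH_A": r"[RSY]GG.{1,50}[RSY]GG.{1,50}[RSY]GG",
    "GRICH_B": r"R[AGT][AGTFIVR].{1,25}RGG.{1,25}R[AGT][AGTFIVR]",
}

_COMPILED = {name: re.compile(pat) for name, pat in PATTERNS.items()}
_COMPILED_FULL = {name: re.compile(pat + r"\Z") for name, pat in PATTERNS.items()}


def _longest_match_at(pattern_name: str, seq: str, start0: int) -> Optional[int]:
    """Longest end (0-based exclusive) of a match starting exactly at start0."""
    rx = _COMPILED[pattern_name]
    m = rx.match(seq, start0)
    if m is None:
        return None
    best = m.end()
    full = _COMPILED_FULL[pattern_name]
    # A greedy match is not necessarily the longest; probe longer ends.
    for end0 in range(len(seq), best, -1):
        if full.match(seq, start0, end0):
            return end0
    return best


def scan_pattern(
    seq: str,
    motif_name: str,
    protein_id: str = "",
    allow_overlap: bool = False,
) -> list[MotifMatch]:
    """All matches of a named pattern, non-overlapping leftmost-then-longest.

    With ``allow_overlap=True`` the longest match starting at *every*
    position is reported (sensitivity-analysis mode).
    """
    if motif_name not in PATTERNS:
        raise ValidationError(f"unknown motif {motif_name!r}")
    matches: list[MotifMatch] = []
    pos = 0
    n = len(seq)
    while pos < n:
        end0 = _longest_match_at(motif_name, seq, pos)
        if end0 is None:
            pos += 1
            continue
        matches.append(
            MotifMatch(protein_id, motif_name, pos + 1, end0, seq[pos:end0])
        )
        pos = pos + 1 if allow_overlap else end0
    return matches


def find_pq_runs(
    seq: str,
    n_min: int = 3,
    protein_id: str = "",
    homopolymer_only: bool = False,
) -> list[MotifMatch]:
    """Maximal runs over {P, Q} (or pure-P / pure-Q runs) of length >= n_min."""
    if n_min < 1:
        raise ValidationError("n_min must be >= 1")
    alphabet = "PQ"
    rx = (
        re.compile(r"P+|Q+")
        if homopolymer_only
        else re.compile(rf"[{alphabet}]+")
    )
    return [
        MotifMatch(protein_id, "PQ_RUN", m.start() + 1, m.end(), m.group())
        for m in rx.finditer(seq)
        if m.end() - m.start() >= n_min
    ]


def annotate_matches_with_regions(
    matches: Sequence[MotifMatch],
    regions: Sequence[Region],
) -> list[MotifMatch]:
    """Tag each match ordered / disordered / mixed against the region tiling.

    A match wholly inside non-structural_order regions is ``disordered``,
    wholly inside structural_order is ``ordered``, otherwise ``mixed``;
    matches on proteins absent from ``regions`` stay ``unannotated``.
    """
    by_protein: dict[str, list[Region]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    for regs in by_protein.values():
        regs.sort(key=lambda r: r.start)

    out: list[MotifMatch] = []
    for m in matches:
        regs = by_protein.get(m.protein_id)
        if regs is None:
            out.append(replace(m, disorder_context=DisorderContext.UNANNOTATED))
            continue
        length = regs[-1].end
        if m.start < 1 or m.end > length:
            raise ValidationError(
                f"match {m.protein_id}[{m.start},{m.end}] outside protein bounds"
            )
        ordered_res = 0
        disordered_res = 0
        for r in regs:
            lo, hi = max(r.start, m.start), min(r.end, m.end)
            if lo > hi:
                continue
            if r.region_class is RegionClass.STRUCTURAL_ORDER:
                ordered_res += hi - lo + 1
            else:
                disordered_res += hi - lo + 1
        total = m.end - m.start + 1
        if disordered_res == total:
            ctx = DisorderContext.DISORDERED
        elif ordered_res == total:
            ctx = DisorderContext.ORDERED
        else:
            ctx = DisorderContext.MIXED
        out.append(replace(m, disorder_context=ctx))
    return out


def brute_force_scan(seq: str, motif_name: str, protein_id: str = "") -> list[MotifMatch]:
    """Independent oracle: test every substring against the pattern grammar,
    then resolve non-overlapping leftmost-then-longest.  Quadratic; meant
    for verification on short sequences only."""
    if motif_name not in PATTERNS:
        raise ValidationError(f"unknown motif {motif_name!r}")
    full = _COMPILED_FULL[motif_name]
    n = len(seq)
    matches: list[MotifMatch] = []
    pos = 0
    while pos < n:
        best_end = None
        for end0 in range(pos + 1, n + 1):
            if full.match(seq, pos, end0):
                best_end = end0
        if best_end is None:
            pos += 1
            continue
        matches.append(MotifMatch(protein_id, motif_name, pos + 1, best_end, seq[pos:best_end]))
        pos = best_end
    return matches
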
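"""End-to-end orchestration: consensus -> override -> segmentation ->
composition classes -> motifs -> PTM tables -> group statistics.

Each stage writes a TSV so the CLI subcommands are independently
runnable; ``run_full`` composes them and emits a manifest with input
digests for reproducibility.  Analytical outputs are deterministic in
the inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .composition import BackgroundFrequencies, classify_proteome
from .consensus import (
    ConsensusAnnotation,
    apply_globular_override,
    consensus_tracks,
)
from .motifs import annotate_matches_with_regions, find_pq_runs, scan_pattern
from .ptm import build_count_table, class_lengths, ptm_share_stats, share_report_frame
from .records import (
    PredictorTrack,
    ProteinRecord,
    PTMSite,
    Region,
    TrackCategory,
    ValidationError,
    check_tiling,
)
from .stats import disorder_fractions, idr_length_stats
from . import tracks_io

log = logging.getLogger("idrscape")

DEFAULT_PARAMS: dict = {
    "disorder_cutoff": 0.5,
    "merge_gap": 20,
    "min_helix": 4,
    "min_strand": 3,
    "min_biased_len": 25,
    "grich_cover": 0.5,
    "pq_homopolymer_only": False,
    "exclude_unverified_ptms": False,
    "override": {"min_window": 30, "burial_frac": 0.5, "require_homology": True},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = {**DEFAULT_PARAMS, **cfg}
    merged["override"] = {**DEFAULT_PARAMS["override"], **(cfg.get("override") or {})}
    return merged


def build_consensus(
    proteins: Sequence[ProteinRecord],
    tracks: Sequence[PredictorTrack],
    disorder_cutoff: float = 0.5,
    override_params: Optional[Mapping] = None,
) -> dict[str, ConsensusAnnotation]:
    """Vote consensus per protein, then apply the globular override."""
    override_params = dict(override_params or DEFAULT_PARAMS["override"])
    by_protein: dict[str, list[PredictorTrack]] = {}
    for t in tracks:
        by_protein.setdefault(t.protein_id, []).append(t)
    out: dict[str, ConsensusAnnotation] = {}
    for p in proteins:
        ptracks = by_protein.get(p.protein_id)
        if not ptracks:
            raise ValidationError(f"{p.protein_id}: no tracks supplied")
        vote_tracks = [
            t
            for t in ptracks
            if t.category
            in (
                TrackCategory.DISORDER,
                TrackCategory.SECONDARY_STRUCTURE,
                TrackCategory.COILED_COIL,
            )
        ]
        cons = consensus_tracks(vote_tracks, disorder_cutoff)
        burial = next(
            (t for t in ptracks if t.category is TrackCategory.BURIAL), None
        )
        homology = next(
            (t for t in ptracks if t.category is TrackCategory.HOMOLOGY_SUPPORT), None
        )
        cons = apply_globular_override(
            cons,
            burial,
            homology,
            min_window=int(override_params.get("min_window", 30)),
            burial_frac=float(override_params.get("burial_frac", 0.5)),
            require_homology=bool(override_params.get("require_homology", True)),
        )
        out[p.protein_id] = cons
    return out


@dataclass
class PipelineResult:
    proteins: list
    consensus: dict
    regions: list
    motif_frame: pd.DataFrame
    count_table: Optional[pd.DataFrame]
    share_frame: Optional[pd.DataFrame]
    group_stats_frame: pd.DataFrame


def scan_all_motifs(
    proteins: Sequence[ProteinRecord],
    regions: Sequence[Region],
    motifs: Sequence[str] = ("ULM", "GRICH_A", "GRICH_B"),
    pq_homopolymer_only: bool = False,
) -> pd.DataFrame:
    rows = []
    for p in sorted(proteins, key=lambda p: p.protein_id):
        matches = []
        for name in motifs:
            matches.extend(scan_pattern(p.sequence, name, p.protein_id))
        matches.extend(
            find_pq_runs(p.sequence, 3, p.protein_id, pq_homopolymer_only)
        )
        for m in annotate_matches_with_regions(matches, regions):
            rows.append(
                (
                    m.protein_id,
                    m.motif_name,
                    m.start,
                    m.end,
                    m.matched_seq,
                    m.disorder_context.value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "motif_name", "start", "end", "matched_seq", "disorder_context"],
    ).sort_values(["protein_id", "start", "motif_name"], kind="mergesort").reset_index(drop=True)


def analyze(
    proteins: Sequence[ProteinRecord],
    tracks: Sequence[PredictorTrack],
    sites: Sequence[PTMSite] = (),
    params: Optional[Mapping] = None,
) -> PipelineResult:
    """Run the full in-memory analysis with the given parameter mapping."""
    p = {**DEFAULT_PARAMS, **(params or {})}
    p["override"] = {**DEFAULT_PARAMS["override"], **((params or {}).get("override") or {})}

    consensus = build_consensus(
        proteins, tracks, p["disorder_cutoff"], p["override"]
    )
    log.info("consensus: %d proteins", len(consensus))

    bg = (
        BackgroundFrequencies.from_table(p["background_freqs"])
        if p.get("background_freqs")
        else BackgroundFrequencies.vertebrate_default()
    )
    regions = classify_proteome(
        proteins,
        consensus,
        bg,
        merge_gap=p["merge_gap"],
        min_helix=p["min_helix"],
        min_strand=p["min_strand"],
        min_biased_len=p["min_biased_len"],
        grich_cover=p["grich_cover"],
        pq_homopolymer_only=p["pq_homopolymer_only"],
    )
    by_protein: dict[str, list[Region]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    for protein in proteins:
        check_tiling(by_protein[protein.protein_id], len(protein))
    log.info("regions: %d across %d proteins", len(regions), len(by_protein))

    motif_frame = scan_all_motifs(
        proteins, regions, pq_homopolymer_only=p["pq_homopolymer_only"]
    )
    log.info("motif matches: %d", len(motif_frame))

    count_table = share_frame = None
    if sites:
        count_table = build_count_table(sites, regions)
        report = ptm_share_stats(count_table, class_lengths(regions))
        share_frame = share_report_frame(report)
        log.info("PTM sites mapped: %d", report.grand_total)

    stats = disorder_fractions(proteins, regions, group_by="group")
    stats_all = disorder_fractions(proteins, regions, group_by="all")
    frame = pd.DataFrame([s.__dict__ for s in stats + stats_all])
    return PipelineResult(
        list(proteins), consensus, regions, motif_frame, count_table, share_frame, frame
    )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(config_path: str | Path, out_dir: Optional[str | Path] = None) -> Path:
    """Run every stage from a YAML config; returns the bundle directory.

    The bundle holds regions.tsv, motifs.tsv, ptm_counts.tsv /
    ptm_shares.tsv (when sites are supplied), group_stats.tsv and
    manifest.json.  Any stage error aborts with the stage name.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.get("out_dir") or "idrscape_out")
    out.mkdir(parents=True, exist_ok=True)

    stage = "tracks_io"
    try:
        metadata = (
            tracks_io.read_metadata(cfg["metadata"]) if cfg.get("metadata") else None
        )
        proteins = tracks_io.read_fasta(cfg["fasta"], metadata)
        tracks = tracks_io.read_tracks(cfg["tracks"], proteins)
        sites = (
            tracks_io.read_ptm_table(
                cfg["ptm_sites"], proteins, cfg["exclude_unverified_ptms"]
            )
            if cfg.get("ptm_sites")
            else []
        )
        stage = "analysis"
        result = analyze(proteins, tracks, sites, cfg)
        stage = "write"
        tracks_io.write_region_table(result.regions, out / "regions.tsv")
        result.motif_frame.to_csv(out / "motifs.tsv", sep="\t", index=False)
        if result.count_table is not None:
            result.count_table.to_csv(out / "ptm_counts.tsv", sep="\t")
            result.share_frame.to_csv(out / "ptm_shares.tsv", sep="\t")
        result.group_stats_frame.to_csv(out / "group_stats.tsv", sep="\t", index=False)
    except Exception as exc:
        raise ValidationError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "software": f"idrscape {__version__}",
        "config": {k: v for k, v in cfg.items() if not isinstance(v, Path)},
        "inputs": {
            key: {"path": str(cfg[key]), "sha256": _digest(Path(cfg[key]))}
            for key in ("fasta", "tracks", "ptm_sites", "metadata")
            if cfg.get(key)
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("bundle written to %s", out)
    return out
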
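"""Seeded synthetic proteomes with planted region classes, tracks and PTMs.

Proteins are concatenations of segments: ordered globular segments
alternate with disordered segments drawn from class-specific residue
composition models (RS-rich, poly-P/Q, G-rich with planted repeat units,
charged, noncharged, unbiased "other" disorder, and disorder-with-SS
with planted helix elements).  Every biased segment is rejection-sampled
until its sequence satisfies its class's defining thresholds, and every
"other disorder" segment until it is verifiably unbiased, so the planted
truth is recoverable by construction, not by luck.

Pseudo-predictor tracks equal the planted truth with independent
per-residue errors at rate ``epsilon`` (disorder/coiled-coil calls flip;
secondary-structure labels are replaced by one of the two other labels).
Under majority voting over K predictors the per-residue consensus error
is the upper tail of Binomial(K, epsilon).

PTM sites are planted on chemically compatible residues with
class-dependent rates: phosphorylation (S/T/Y) enriched in RS-like
segments, arginine methylation (R) in G-rich segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .composition import (
    BackgroundFrequencies,
    classify_region,
    overrepresented_residues,
)
from .records import (
    ModType,
    PredictorTrack,
    ProteinRecord,
    PTMSite,
    PtmStatus,
    Region,
    RegionClass,
    TrackCategory,
    ValidationError,
)

# -- class-specific residue composition models --------------------------------

COMPOSITION_MODELS: dict[RegionClass, dict[str, float]] = {
    RegionClass.RS_LIKE: {
        "R": 0.35, "S": 0.35, "G": 0.04, "E": 0.03, "P": 0.04, "K": 0.03,
        "D": 0.03, "A": 0.03, "L": 0.03, "T": 0.04, "V": 0.03,
    },
    RegionClass.POLY_PQ: {
        "P": 0.28, "Q": 0.18, "A": 0.15, "M": 0.05, "V": 0.12, "T": 0.10,
        "N": 0.07, "S": 0.05,
    },
    RegionClass.CHARGED_BIASED: {
        "E": 0.25, "R": 0.15, "K": 0.14, "D": 0.14, "G": 0.05, "S": 0.05,
        "T": 0.07, "A": 0.07, "L": 0.05, "N": 0.03,
    },
    RegionClass.NONCHARGED_BIASED: {
        "V": 0.25, "M": 0.10, "A": 0.18, "G": 0.10, "T": 0.12, "L": 0.10,
        "I": 0.08, "F": 0.07,
    },
    RegionClass.OTHER_DISORDER: {
        aa: 0.1 for aa in "ARDEGLKSTV"
    },
    # ordered / disorder-with-SS segments draw from a generic composition
    RegionClass.STRUCTURAL_ORDER: {
        "A": 0.09, "L": 0.10, "V": 0.08, "I": 0.06, "F": 0.05, "G": 0.07,
        "E": 0.07, "K": 0.06, "D": 0.06, "S": 0.07, "T": 0.06, "R": 0.05,
        "N": 0.04, "Q": 0.04, "P": 0.04, "H": 0.02, "Y": 0.03, "W": 0.01,
        "M": 0.02, "C": 0.04,
    },
}
COMPOSITION_MODELS[RegionClass.DISORDER_WITH_SS] = COMPOSITION_MODELS[
    RegionClass.STRUCTURAL_ORDER
]
COMPOSITION_MODELS[RegionClass.DISORDER_WITH_COILED_COIL] = COMPOSITION_MODELS[
    RegionClass.STRUCTURAL_ORDER
]

#: Spacer alphabet for G-rich repeat units (no serine: keeps the RS rule out).
_GRICH_SPACER = ("G", "Y", "A", "N", "F")
_GRICH_SPACER_P = (0.5, 0.15, 0.15, 0.1, 0.1)

#: Default per-compatible-residue PTM planting probabilities by class.
DEFAULT_PTM_RATES: dict[ModType, dict[RegionClass, float]] = {
    ModType.PHOSPHORYLATION: {
        RegionClass.RS_LIKE: 0.25,
        RegionClass.STRUCTURAL_ORDER: 0.02,
    },
    ModType.ARGININE_METHYLATION: {
        RegionClass.HNRNP_G_RICH: 0.30,
    },
    ModType.LYSINE_N_ACETYLATION: {},
    ModType.LYSINE_METHYLATION: {},
    ModType.CYSTEINE_METHYL_ESTER: {},
}
_PTM_BASE_RATES: dict[ModType, float] = {
    ModType.PHOSPHORYLATION: 0.05,
    ModType.ARGININE_METHYLATION: 0.01,
    ModType.LYSINE_N_ACETYLATION: 0.05,
    ModType.LYSINE_METHYLATION: 0.01,
    ModType.CYSTEINE_METHYL_ESTER: 0.002,
}
PTM_COMPATIBLE: dict[ModType, str] = {
    ModType.PHOSPHORYLATION: "STY",
    ModType.LYSINE_N_ACETYLATION: "K",
    ModType.ARGININE_METHYLATION: "R",
    ModType.LYSINE_METHYLATION: "K",
    ModType.CYSTEINE_METHYL_ESTER: "C",
}
_NTERM_ACETYL_RESIDUES = set("MGASTV")
_NTERM_ACETYL_RATE = 0.6

#: Disordered segment classes sampled by the default grammar, with weights.
DEFAULT_CLASS_WEIGHTS: dict[RegionClass, float] = {
    RegionClass.DISORDER_WITH_SS: 0.20,
    RegionClass.DISORDER_WITH_COILED_COIL: 0.08,
    RegionClass.RS_LIKE: 0.16,
    RegionClass.POLY_PQ: 0.12,
    RegionClass.HNRNP_G_RICH: 0.12,
    RegionClass.NONCHARGED_BIASED: 0.10,
    RegionClass.CHARGED_BIASED: 0.10,
    RegionClass.OTHER_DISORDER: 0.12,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 50
    k_disorder_predictors: int = 5
    k_ss_predictors: int = 3
    epsilon: float = 0.0
    seed: int = 0
    min_segments: int = 1  # disordered segments per protein
    max_segments: int = 3
    ordered_len: tuple[int, int] = (30, 80)
    disordered_len: tuple[int, int] = (30, 120)
    class_weights: Mapping[RegionClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    ptm_rates: Mapping[ModType, Mapping[RegionClass, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_PTM_RATES.items()}
    )
    max_rejection_tries: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.5):
            raise ValidationError("epsilon must be in [0, 0.5)")
        if self.n_proteins < 1 or self.k_disorder_predictors < 1:
            raise ValidationError("need at least one protein and one predictor")
        for bounds in (self.ordered_len, self.disordered_len):
            if bounds[0] < 1 or bounds[1] < bounds[0]:
                raise ValidationError(f"bad length bounds {bounds}")


@dataclass(frozen=True)
class SyntheticTruth:
    regions: list  # planted Region records, tiling every protein
    disorder: dict  # protein_id -> tuple of bool
    ss_label: dict  # protein_id -> tuple of 'H'/'E'/'C'
    coiled_coil: dict  # protein_id -> tuple of bool
    sites: list  # planted PTMSite records


def _sample_seq(rng: np.random.Generator, model: Mapping[str, float], n: int) -> str:
    letters = sorted(model)
    probs = np.array([model[a] for a in letters], dtype=float)
    probs /= probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


def _grich_seq(rng: np.random.Generator, n: int) -> str:
    parts: list[str] = []
    total = 0
    while total < n:
        spacer_len = int(rng.integers(2, 6))
        spacer = "".join(
            rng.choice(_GRICH_SPACER, size=spacer_len, p=_GRICH_SPACER_P)
        )
        unit = "RGG" + spacer
        parts.append(unit)
        total += len(unit)
    return "".join(parts)[:n]


def _helix_layout(n: int, helix_len: int = 6, loop_len: int = 12) -> list[str]:
    """SS labels with helices covering both ends and loops < 20 between."""
    labels = ["C"] * n
    step = helix_len + loop_len
    for start in range(0, n - helix_len + 1, step):
        for i in range(start, start + helix_len):
            labels[i] = "H"
    for i in range(max(0, n - helix_len), n):  # force coverage of the segment end
        labels[i] = "H"
    return labels


def _ordered_ss_layout(rng: np.random.Generator, n: int) -> list[str]:
    labels: list[str] = []
    while len(labels) < n:
        kind = rng.choice(["H", "E", "C"])
        run = int(rng.integers(3, 10))
        labels.extend([kind] * run)
    return labels[:n]


def _segment_sequence(
    rng: np.random.Generator,
    cls: RegionClass,
    n: int,
    bg: BackgroundFrequencies,
    max_tries: int,
) -> str:
    """Draw a segment sequence; biased classes (and unbiased "other") are
    rejection-sampled against the classifier's own thresholds."""
    needs_check = cls in {
        RegionClass.RS_LIKE,
        RegionClass.POLY_PQ,
        RegionClass.HNRNP_G_RICH,
        RegionClass.NONCHARGED_BIASED,
        RegionClass.CHARGED_BIASED,
        RegionClass.OTHER_DISORDER,
    }
    for _ in range(max_tries):
        if cls is RegionClass.HNRNP_G_RICH:
            seq = _grich_seq(rng, n)
        else:
            seq = _sample_seq(rng, COMPOSITION_MODELS[cls], n)
            if cls is RegionClass.POLY_PQ:
                # plant one explicit P/Q run so the run criterion always holds
                run = "".join(rng.choice(["P", "Q"], size=4))
                pos = int(rng.integers(0, n - 4 + 1))
                seq = seq[:pos] + run + seq[pos + 4 :]
        if not needs_check:
            return seq
        verdict = overrepresented_residues(seq, bg)
        got = classify_region("chk", 1, n, seq, verdict).region_class
        if got is cls:
            return seq
    raise ValidationError(
        f"composition model for {cls.value} cannot satisfy its class "
        f"thresholds at length {n} (exhausted {max_tries} tries)"
    )


def generate_proteome(
    cfg: SyntheticConfig,
) -> tuple[list[ProteinRecord], list[PredictorTrack], list[PTMSite], SyntheticTruth]:
    """Generate a seeded proteome with planted truth.

    Returns (proteins, tracks, ptm_sites, truth); identical config and
    seed give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    bg = BackgroundFrequencies.vertebrate_default()
    weights = {RegionClass(k): v for k, v in cfg.class_weights.items()}
    classes = sorted(weights, key=lambda c: c.value)
    probs = np.array([weights[c] for c in classes], dtype=float)
    probs /= probs.sum()

    proteins: list[ProteinRecord] = []
    tracks: list[PredictorTrack] = []
    sites: list[PTMSite] = []
    truth_regions: list[Region] = []
    truth_dis: dict[str, tuple] = {}
    truth_ss: dict[str, tuple] = {}
    truth_cc: dict[str, tuple] = {}

    for idx in range(cfg.n_proteins):
        pid = f"syn{idx:04d}"
        n_dis = int(rng.integers(cfg.min_segments, cfg.max_segments + 1))
        seq_parts: list[str] = []
        dis_vec: list[bool] = []
        ss_vec: list[str] = []
        cc_vec: list[bool] = []
        regions: list[Region] = []
        cursor = 1

        def add_segment(cls: RegionClass, length: int) -> None:
            nonlocal cursor
            seq = _segment_sequence(rng, cls, length, bg, cfg.max_rejection_tries)
            seq_parts.append(seq)
            disordered = cls is not RegionClass.STRUCTURAL_ORDER
            dis_vec.extend([disordered] * length)
            if cls is RegionClass.STRUCTURAL_ORDER:
                ss_vec.extend(_ordered_ss_layout(rng, length))
                cc_vec.extend([False] * length)
            elif cls in (
                RegionClass.DISORDER_WITH_SS,
                RegionClass.DISORDER_WITH_COILED_COIL,
            ):
                ss_vec.extend(_helix_layout(length))
                cc_vec.extend(
                    [cls is RegionClass.DISORDER_WITH_COILED_COIL] * length
                )
            else:
                ss_vec.extend(["C"] * length)
                cc_vec.extend([False] * length)
            overrep = frozenset()
            glc = None
            if cls in {
                RegionClass.RS_LIKE,
                RegionClass.POLY_PQ,
                RegionClass.HNRNP_G_RICH,
                RegionClass.NONCHARGED_BIASED,
                RegionClass.CHARGED_BIASED,
            }:
                overrep = overrepresented_residues(seq, bg).overrep
                if cls is RegionClass.HNRNP_G_RICH:
                    glc = "short" if length <= 100 else "long"
            regions.append(
                Region(pid, cursor, cursor + length - 1, cls, overrep, glc)
            )
            cursor += length

        for _seg in range(n_dis):
            add_segment(
                RegionClass.STRUCTURAL_ORDER,
                int(rng.integers(cfg.ordered_len[0], cfg.ordered_len[1] + 1)),
            )
            cls = classes[int(rng.choice(len(classes), p=probs))]
            add_segment(
                cls,
                int(rng.integers(cfg.disordered_len[0], cfg.disordered_len[1] + 1)),
            )
        add_segment(
            RegionClass.STRUCTURAL_ORDER,
            int(rng.integers(cfg.ordered_len[0], cfg.ordered_len[1] + 1)),
        )

        sequence = "".join(seq_parts)
        n = len(sequence)
        proteins.append(ProteinRecord(pid, sequence))
        truth_regions.extend(regions)
        truth_dis[pid] = tuple(dis_vec)
        truth_ss[pid] = tuple(ss_vec)
        truth_cc[pid] = tuple(cc_vec)

        dis_arr = np.array(dis_vec, dtype=bool)
        for k in range(cfg.k_disorder_predictors):
            flips = rng.random(n) < cfg.epsilon
            vals = np.where(flips, ~dis_arr, dis_arr)
            tracks.append(
                PredictorTrack(
                    pid, f"dis{k}", TrackCategory.DISORDER, tuple(int(v) for v in vals)
                )
            )
        others = {"H": ("E", "C"), "E": ("H", "C"), "C": ("H", "E")}
        for k in range(cfg.k_ss_predictors):
            flips = rng.random(n) < cfg.epsilon
            picks = rng.integers(0, 2, size=n)
            vals = tuple(
                others[lab][picks[i]] if flips[i] else lab
                for i, lab in enumerate(ss_vec)
            )
            tracks.append(
                PredictorTrack(pid, f"ss{k}", TrackCategory.SECONDARY_STRUCTURE, vals)
            )
        cc_arr = np.array(cc_vec, dtype=bool)
        for k in range(cfg.k_ss_predictors):
            flips = rng.random(n) < cfg.epsilon
            vals = np.where(flips, ~cc_arr, cc_arr)
            tracks.append(
                PredictorTrack(
                    pid, f"cc{k}", TrackCategory.COILED_COIL, tuple(int(v) for v in vals)
                )
            )
        burial = tuple(0 if d else 1 for d in dis_vec)
        tracks.append(PredictorTrack(pid, "burial", TrackCategory.BURIAL, burial))
        tracks.append(
            PredictorTrack(
                pid, "homology", TrackCategory.HOMOLOGY_SUPPORT, burial
            )
        )

        # plant PTM sites on compatible residues with class-dependent rates
        for region in regions:
            for mod, compatible in PTM_COMPATIBLE.items():
                class_rates = cfg.ptm_rates.get(mod, {})
                rate = class_rates.get(region.region_class, _PTM_BASE_RATES[mod])
                for pos in range(region.start, region.end + 1):
                    aa = sequence[pos - 1]
                    if aa in compatible and rng.random() < rate:
                        status = _sample_status(rng)
                        sites.append(PTMSite(pid, pos, aa, mod, status))
        if sequence[0] in _NTERM_ACETYL_RESIDUES and rng.random() < _NTERM_ACETYL_RATE:
            sites.append(
                PTMSite(
                    pid, 1, sequence[0], ModType.OTHER_N_ACETYLATION, _sample_status(rng)
                )
            )

    truth = SyntheticTruth(truth_regions, truth_dis, truth_ss, truth_cc, sites)
    return proteins, tracks, sites, truth


def _sample_status(rng: np.random.Generator) -> PtmStatus:
    u = rng.random()
    if u < 0.93:
        return PtmStatus.EXPERIMENTAL
    if u < 0.99:
        return PtmStatus.BY_SIMILARITY
    return PtmStatus.POTENTIAL_OR_PROBABLE


@dataclass(frozen=True)
class RecoveryReport:
    confusion: pd.DataFrame  # truth class (rows) x predicted class (cols), residues
    accuracy: float
    per_class_precision: Mapping[str, float]
    per_class_recall: Mapping[str, float]


def _class_vector(regions: Sequence[Region], length: int) -> list[str]:
    vec = [None] * length
    for r in regions:
        for i in range(r.start - 1, r.end):
            vec[i] = r.region_class.value
    if any(v is None for v in vec):
        raise ValidationError("regions do not tile the protein")
    return vec


def evaluate_recovery(predicted: Sequence[Region], truth: SyntheticTruth) -> RecoveryReport:
    """Residue-level confusion matrix and accuracy of predicted vs planted
    region classes."""
    pred_by: dict[str, list[Region]] = {}
    true_by: dict[str, list[Region]] = {}
    for r in predicted:
        pred_by.setdefault(r.protein_id, []).append(r)
    for r in truth.regions:
        true_by.setdefault(r.protein_id, []).append(r)
    if set(pred_by) != set(true_by):
        raise ValidationError(
            "predicted and truth cover different proteins: "
            f"{sorted(set(pred_by) ^ set(true_by))[:5]}"
        )

    labels = [c.value for c in RegionClass]
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for pid, true_regs in true_by.items():
        length = max(r.end for r in true_regs)
        tv = _class_vector(true_regs, length)
        pv = _class_vector(pred_by[pid], length)
        for t, p in zip(tv, pv):
            confusion.loc[t, p] += 1

    total = int(confusion.to_numpy().sum())
    correct = int(np.trace(confusion.to_numpy()))
    accuracy = correct / total if total else 0.0
    precision = {}
    recall = {}
    for lab in labels:
        col = int(confusion[lab].sum())
        row = int(confusion.loc[lab].sum())
        diag = int(confusion.loc[lab, lab])
        precision[lab] = diag / col if col else float("nan")
        recall[lab] = diag / row if row else float("nan")
    return RecoveryReport(confusion, accuracy, precision, recall)
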
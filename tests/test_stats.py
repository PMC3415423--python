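"""Proteome-level disorder, IDR-length and mass statistics."""

import numpy as np
import pytest

from idrscape.records import (
    ProteinRecord,
    Region,
    RegionClass,
    RnaRecord,
    ValidationError,
)
from idrscape.stats import (
    disorder_fractions,
    idr_length_stats,
    mass_fractions,
    protein_mass,
)


def tile(pid, spans):
    return [Region(pid, s, e, cls) for s, e, cls in spans]


class TestDisorderFractions:
    def test_per_protein_vs_per_residue_conventions(self):
        proteins = [
            ProteinRecord("a", "A" * 100),
            ProteinRecord("b", "A" * 300),
        ]
        regions = tile("a", [(1, 50, RegionClass.OTHER_DISORDER), (51, 100, RegionClass.STRUCTURAL_ORDER)])
        regions += tile("b", [(1, 30, RegionClass.OTHER_DISORDER), (31, 300, RegionClass.STRUCTURAL_ORDER)])
        (stats,) = disorder_fractions(proteins, regions, group_by="all")
        assert stats.per_protein_disorder == pytest.approx(0.30)
        assert stats.per_residue_disorder == pytest.approx(80 / 400)

    def test_single_protein_conventions_coincide(self):
        proteins = [ProteinRecord("a", "A" * 100)]
        regions = tile("a", [(1, 40, RegionClass.RS_LIKE), (41, 100, RegionClass.STRUCTURAL_ORDER)])
        (stats,) = disorder_fractions(proteins, regions, group_by="all")
        assert stats.per_protein_disorder == stats.per_residue_disorder

    def test_per_residue_matches_popcount_oracle(self):
        rng = np.random.default_rng(3)
        proteins, regions, bits = [], [], []
        for i in range(20):
            n = int(rng.integers(20, 120))
            mask = rng.random(n) < 0.4
            proteins.append(ProteinRecord(f"p{i}", "A" * n))
            pos = 1
            # convert the random mask into alternating region runs
            for val, run in _runs(mask):
                cls = RegionClass.OTHER_DISORDER if val else RegionClass.STRUCTURAL_ORDER
                regions.append(Region(f"p{i}", pos, pos + run - 1, cls))
                pos += run
            bits.append(mask)
        (stats,) = disorder_fractions(proteins, regions, group_by="all")
        oracle = np.concatenate(bits)
        assert stats.per_residue_disorder == pytest.approx(oracle.sum() / oracle.size)

    def test_group_of_all_is_length_weighted_mean_of_subgroups(self):
        proteins = [
            ProteinRecord("a", "A" * 100, group="g1"),
            ProteinRecord("b", "A" * 300, group="g2"),
        ]
        regions = tile("a", [(1, 50, RegionClass.OTHER_DISORDER), (51, 100, RegionClass.STRUCTURAL_ORDER)])
        regions += tile("b", [(1, 30, RegionClass.OTHER_DISORDER), (31, 300, RegionClass.STRUCTURAL_ORDER)])
        sub = disorder_fractions(proteins, regions, group_by="group")
        (overall,) = disorder_fractions(proteins, regions, group_by="all")
        weighted = (sub[0].per_residue_disorder * 100 + sub[1].per_residue_disorder * 300) / 400
        assert overall.per_residue_disorder == pytest.approx(weighted)


def _runs(mask):
    runs = []
    current, count = bool(mask[0]), 0
    for v in mask:
        if bool(v) == current:
            count += 1
        else:
            runs.append((current, count))
            current, count = bool(v), 1
    runs.append((current, count))
    return runs


class TestIdrLengthStats:
    def test_counts_and_mean(self):
        regions = tile(
            "a",
            [
                (1, 10, RegionClass.OTHER_DISORDER),
                (11, 30, RegionClass.STRUCTURAL_ORDER),
                (31, 100, RegionClass.DISORDER_WITH_SS),
            ],
        )
        summary = idr_length_stats(regions)
        assert summary.mean_idr_length == pytest.approx(40.0)
        assert summary.n_proteins_with_idr_ge[30] == 1
        assert summary.n_proteins_with_idr_ge[70] == 1

    def test_adjacent_disorder_classes_merge_into_one_idr(self):
        regions = tile(
            "a",
            [
                (1, 30, RegionClass.RS_LIKE),
                (31, 50, RegionClass.OTHER_DISORDER),
                (51, 60, RegionClass.STRUCTURAL_ORDER),
            ],
        )
        summary = idr_length_stats(regions)
        assert summary.n_idrs == 1
        assert summary.mean_idr_length == pytest.approx(50.0)

    def test_no_disorder_degenerate(self):
        regions = tile("a", [(1, 50, RegionClass.STRUCTURAL_ORDER)])
        summary = idr_length_stats(regions)
        assert summary.n_idrs == 0 and summary.mean_idr_length == 0.0

    def test_nonss_idr_ge70_counts_only_ss_free_classes(self):
        regions = tile(
            "a",
            [
                (1, 80, RegionClass.DISORDER_WITH_SS),
                (81, 160, RegionClass.RS_LIKE),
                (161, 200, RegionClass.STRUCTURAL_ORDER),
            ],
        )
        assert idr_length_stats(regions).n_nonss_idrs_ge70 == 1


class TestMassFractions:
    def test_rna_share_uniform_masses(self):
        proteins = [ProteinRecord("a", "A" * 10)]
        rnas = [RnaRecord("u1", 10)]
        aa = {"A": 110.0}
        report = mass_fractions(proteins, rnas, aa_masses=aa, nt_mass=330.0)
        assert report.rna_fraction == pytest.approx(3300 / 4400)

    def test_copy_number_weights_protein_mass(self):
        proteins = [ProteinRecord("a", "A" * 10, copy_number=4)]
        rnas = [RnaRecord("u1", 10)]
        report = mass_fractions(proteins, rnas, aa_masses={"A": 110.0}, nt_mass=330.0)
        assert report.rna_fraction == pytest.approx(3300 / (4 * 1100 + 3300))

    def test_no_rna_zero_fraction(self):
        proteins = [ProteinRecord("a", "MKR")]
        assert mass_fractions(proteins, []).rna_fraction == 0.0

    def test_missing_residue_mass_error(self):
        with pytest.raises(ValidationError, match="missing from mass table"):
            protein_mass(ProteinRecord("a", "MKR"), {"M": 131.19})

    def test_class_mass_fractions_partition_protein_mass(self):
        proteins = [ProteinRecord("a", "A" * 100, copy_number=2)]
        regions = tile(
            "a", [(1, 40, RegionClass.RS_LIKE), (41, 100, RegionClass.STRUCTURAL_ORDER)]
        )
        report = mass_fractions(proteins, [], regions=regions, aa_masses={"A": 100.0})
        assert sum(report.class_mass_fractions.values()) == pytest.approx(1.0)
        assert report.class_mass_fractions["RS_like"] == pytest.approx(0.4)
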
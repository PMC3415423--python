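"""I/O round trips and total validation of malformed inputs."""

import pandas as pd
import pytest

from idrscape import tracks_io
from idrscape.records import (
    Abundance,
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


def write(path, text):
    path.write_text(text)
    return path


class TestReadFasta:
    def test_parses_entries_and_lengths(self, tmp_path):
        fa = write(tmp_path / "p.fa", ">p1\nMKR\n>p2\nGGS\n")
        records = tracks_io.read_fasta(fa)
        assert [(r.protein_id, len(r)) for r in records] == [("p1", 3), ("p2", 3)]

    def test_metadata_join_and_default_copy_number(self, tmp_path):
        fa = write(tmp_path / "p.fa", ">p1\nMKR\n>p2\nGGS\n")
        meta = pd.DataFrame(
            [{"protein_id": "p1", "group": "U1 snRNP", "abundance": "abundant", "copy_number": 4}]
        )
        records = tracks_io.read_fasta(fa, meta)
        assert records[0].group == "U1 snRNP"
        assert records[0].abundance is Abundance.ABUNDANT
        assert records[0].copy_number == 4
        assert records[1].group is None and records[1].copy_number == 1

    def test_duplicate_ids_rejected(self, tmp_path):
        fa = write(tmp_path / "p.fa", ">p1\nMKR\n>p1\nGGS\n")
        with pytest.raises(ValidationError, match="duplicate"):
            tracks_io.read_fasta(fa)

    def test_non_amino_acid_letters_rejected(self, tmp_path):
        fa = write(tmp_path / "p.fa", ">p1\nMK1R\n")
        with pytest.raises(ValidationError, match="p1"):
            tracks_io.read_fasta(fa)

    def test_x_residues_allowed(self, tmp_path):
        fa = write(tmp_path / "p.fa", ">p1\nMXKR\n")
        assert tracks_io.read_fasta(fa)[0].sequence == "MXKR"


class TestReadTracks:
    def track_tsv(self, tmp_path, rows):
        head = "protein_id\tpredictor_id\tcategory\tposition\tvalue\n"
        return write(tmp_path / "t.tsv", head + "".join(
            "\t".join(map(str, r)) + "\n" for r in rows
        ))

    def test_assembles_track(self, tmp_path, tiny_proteome):
        path = self.track_tsv(
            tmp_path,
            [("p1", "d1", "disorder", i, v) for i, v in [(1, 0.9), (2, 0.8), (3, 0.1)]],
        )
        tracks = tracks_io.read_tracks(path, tiny_proteome)
        assert len(tracks) == 1 and tracks[0].values == (0.9, 0.8, 0.1)

    def test_gap_reported(self, tmp_path, tiny_proteome):
        path = self.track_tsv(
            tmp_path, [("p1", "d1", "disorder", 1, 0.9), ("p1", "d1", "disorder", 2, 0.8)]
        )
        with pytest.raises(ValidationError, match=r"missing positions \[3\]"):
            tracks_io.read_tracks(path, tiny_proteome)

    def test_out_of_range_probability(self, tmp_path, tiny_proteome):
        path = self.track_tsv(
            tmp_path, [("p1", "d1", "disorder", i, v) for i, v in [(1, 1.5), (2, 0.1), (3, 0.1)]]
        )
        with pytest.raises(ValidationError, match="outside"):
            tracks_io.read_tracks(path, tiny_proteome)

    def test_unknown_protein(self, tmp_path, tiny_proteome):
        path = self.track_tsv(tmp_path, [("zz", "d1", "disorder", 1, 0.5)])
        with pytest.raises(ValidationError, match="zz"):
            tracks_io.read_tracks(path, tiny_proteome)

    def test_round_trip(self, tmp_path, tiny_proteome):
        tracks = [
            PredictorTrack("p1", "d1", TrackCategory.DISORDER, (0.25, 0.5, 1.0)),
            PredictorTrack("p2", "s1", TrackCategory.SECONDARY_STRUCTURE, tuple("HECC")),
            PredictorTrack("p2", "b1", TrackCategory.BURIAL, (1, 0, 1, 1)),
        ]
        path = tmp_path / "t.tsv"
        tracks_io.write_tracks(tracks, path)
        assert sorted(tracks_io.read_tracks(path, tiny_proteome), key=repr) == sorted(
            tracks, key=repr
        )


class TestReadPtmTable:
    def ptm_tsv(self, tmp_path, rows):
        head = "protein_id\tposition\tresidue\tmod_type\tstatus\n"
        return write(tmp_path / "ptm.tsv", head + "".join(
            "\t".join(map(str, r)) + "\n" for r in rows
        ))

    def test_valid_site(self, tmp_path, tiny_proteome):
        path = self.ptm_tsv(
            tmp_path, [("p1", 2, "K", "lysine_N_acetylation", "experimental")]
        )
        sites = tracks_io.read_ptm_table(path, tiny_proteome)
        assert sites == [
            PTMSite("p1", 2, "K", ModType.LYSINE_N_ACETYLATION, PtmStatus.EXPERIMENTAL)
        ]

    def test_residue_mismatch_names_site(self, tmp_path, tiny_proteome):
        path = self.ptm_tsv(tmp_path, [("p1", 2, "S", "phosphorylation", "experimental")])
        with pytest.raises(ValidationError, match="p1@2"):
            tracks_io.read_ptm_table(path, tiny_proteome)

    def test_unknown_mod_type(self, tmp_path, tiny_proteome):
        path = self.ptm_tsv(tmp_path, [("p1", 2, "K", "sumoylation", "experimental")])
        with pytest.raises(ValidationError, match="sumoylation"):
            tracks_io.read_ptm_table(path, tiny_proteome)

    def test_exclusion_flag_keeps_experimental_only(self, tmp_path, tiny_proteome):
        path = self.ptm_tsv(
            tmp_path,
            [
                ("p1", 2, "K", "lysine_N_acetylation", "experimental"),
                ("p1", 3, "R", "arginine_methylation", "by_similarity"),
                ("p2", 3, "S", "phosphorylation", "potential_or_probable"),
            ],
        )
        assert len(tracks_io.read_ptm_table(path, tiny_proteome)) == 3
        kept = tracks_io.read_ptm_table(path, tiny_proteome, exclude_unverified=True)
        assert [s.status for s in kept] == [PtmStatus.EXPERIMENTAL]


class TestRegionTable:
    def test_round_trip_and_length_column(self, tmp_path, simple_regions):
        path = tmp_path / "r.tsv"
        tracks_io.write_region_table(simple_regions, path)
        df = pd.read_csv(path, sep="\t")
        assert df.loc[1, "length"] == 30
        assert tracks_io.read_region_table(path) == sorted(
            simple_regions, key=lambda r: (r.protein_id, r.start)
        )

    def test_overlap_rejected(self, tmp_path):
        regions = [
            Region("p1", 1, 10, RegionClass.STRUCTURAL_ORDER),
            Region("p1", 5, 20, RegionClass.OTHER_DISORDER),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            tracks_io.write_region_table(regions, tmp_path / "r.tsv")


def test_ptm_round_trip(tmp_path, small_bundle):
    _, _, sites, _ = small_bundle
    path = tmp_path / "ptm.tsv"
    tracks_io.write_ptm_table(sites, path)
    df = pd.read_csv(path, sep="\t")
    assert len(df) == len(sites)
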
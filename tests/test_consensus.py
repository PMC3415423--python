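"""Consensus voting, the globular override, and IDR segmentation."""

import pytest
from hypothesis import given, settings, strategies as st

from idrscape.consensus import (
    ConsensusAnnotation,
    apply_globular_override,
    consensus_tracks,
    extract_idrs,
    partition_idr_by_ss,
    segment_protein,
)
from idrscape.records import (
    PredictorTrack,
    RegionClass,
    TrackCategory,
    ValidationError,
    check_tiling,
)

from conftest import binary_track, disorder_track, ss_track


def make_cons(disorder, ss=None, cc=None):
    n = len(disorder)
    return ConsensusAnnotation(
        "p",
        tuple(bool(d) for d in disorder),
        tuple(ss) if ss else ("C",) * n,
        tuple(bool(c) for c in cc) if cc else (False,) * n,
        (False,) * n,
    )


class TestConsensusTracks:
    def test_majority_of_three_is_disordered(self):
        tracks = [disorder_track("p", [1], f"d{i}") for i in range(2)]
        tracks.append(disorder_track("p", [0], "d2"))
        assert consensus_tracks(tracks).disorder == (True,)

    def test_even_tie_falls_to_order(self):
        tracks = [disorder_track("p", [v], f"d{i}") for i, v in enumerate([1, 1, 0, 0])]
        assert consensus_tracks(tracks).disorder == (False,)

    def test_unanimous_tracks_reproduce_truth(self):
        truth = [1, 1, 0, 1, 0, 0, 1]
        tracks = [disorder_track("p", truth, f"d{i}") for i in range(3)]
        assert consensus_tracks(tracks).disorder == tuple(bool(v) for v in truth)

    def test_probability_binarisation_at_cutoff(self):
        tracks = [disorder_track("p", [0.49, 0.5, 0.9])]
        assert consensus_tracks(tracks).disorder == (False, True, True)

    def test_ss_plurality_with_tie_to_coil(self):
        tracks = [
            disorder_track("p", [1, 1]),
            ss_track("p", "HH", "s0"),
            ss_track("p", "HE", "s1"),
            ss_track("p", "EE", "s2"),
        ]
        # position 1: H=2,E=1 -> H; position 2: H=1,E=2 -> E
        assert consensus_tracks(tracks).ss_label == ("H", "E")

    def test_no_disorder_tracks_error(self):
        with pytest.raises(ValidationError, match="no disorder tracks"):
            consensus_tracks([ss_track("p", "H")])

    def test_unequal_lengths_error(self):
        with pytest.raises(ValidationError, match="unequal length"):
            consensus_tracks([disorder_track("p", [1]), disorder_track("p", [1, 0], "d1")])

    def test_raising_cutoff_never_adds_disorder(self):
        values = [i / 10 for i in range(11)]
        tracks = [disorder_track("p", values)]
        previous = None
        for cutoff in (0.2, 0.5, 0.8):
            dis = consensus_tracks(tracks, disorder_cutoff=cutoff).disorder
            n = sum(dis)
            if previous is not None:
                assert n <= previous
            previous = n


class TestGlobularOverride:
    def window(self, n=40, buried_frac=1.0, ss="H", homology=1):
        cons = make_cons([1] * n, ss=ss * n)
        n_buried = int(buried_frac * n)
        burial = binary_track("p", TrackCategory.BURIAL, [1] * n_buried + [0] * (n - n_buried))
        hom = binary_track("p", TrackCategory.HOMOLOGY_SUPPORT, [homology] * n, "h")
        return cons, burial, hom

    def test_qualifying_window_flipped(self):
        cons, burial, hom = self.window(buried_frac=0.8)
        out = apply_globular_override(cons, burial, hom)
        assert not any(out.disorder)
        assert all(out.overridden)

    def test_low_burial_unchanged(self):
        cons, burial, hom = self.window(buried_frac=0.1)
        out = apply_globular_override(cons, burial, hom)
        assert out == cons

    def test_fully_ordered_protein_is_identity(self):
        cons = make_cons([0] * 50)
        burial = binary_track("p", TrackCategory.BURIAL, [1] * 50)
        assert apply_globular_override(cons, burial, None, require_homology=False) == cons

    def test_short_window_not_flipped(self):
        cons, burial, hom = self.window(n=20)
        assert apply_globular_override(cons, burial, hom, min_window=30) == cons

    def test_missing_homology_waivable(self):
        cons, burial, _ = self.window()
        assert any(
            apply_globular_override(cons, burial, None, require_homology=False).overridden
        )
        assert apply_globular_override(cons, burial, None, require_homology=True) == cons

    def test_idempotent(self):
        cons, burial, hom = self.window(n=60, buried_frac=0.7)
        once = apply_globular_override(cons, burial, hom)
        twice = apply_globular_override(once, burial, hom)
        assert once == twice


class TestExtractIdrs:
    def test_single_interval(self):
        cons = make_cons([0] * 5 + [1] * 30 + [0] * 5)
        assert extract_idrs(cons) == [(6, 35)]

    def test_all_ordered_empty(self):
        assert extract_idrs(make_cons([0] * 10)) == []

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_interval_lengths_conserve_popcount(self, bits):
        cons = make_cons(bits)
        intervals = extract_idrs(cons)
        assert sum(e - s + 1 for s, e in intervals) == sum(bits)
        # intervals are maximal: flanked by order or sequence ends
        for s, e in intervals:
            assert s == 1 or not bits[s - 2]
            assert e == len(bits) or not bits[e]


class TestPartitionByNearbySs:
    def idr_cons(self, helices, n=100, cc_at=()):
        ss = ["C"] * n
        for s, e in helices:
            for i in range(s - 1, e):
                ss[i] = "H"
        cc = [False] * n
        for i in cc_at:
            cc[i - 1] = True
        return make_cons([1] * n, ss=ss, cc=cc)

    def test_close_elements_merge_into_one_region(self):
        cons = self.idr_cons([(10, 20), (35, 45)])  # gap 14 < 20
        regions, stretches = partition_idr_by_ss((1, 100), cons)
        assert [(r.start, r.end, r.region_class) for r in regions] == [
            (10, 45, RegionClass.DISORDER_WITH_SS)
        ]
        assert stretches == [(1, 9), (46, 100)]

    def test_distant_elements_stay_separate(self):
        cons = self.idr_cons([(10, 20), (50, 60)])  # gap 29 >= 20
        regions, stretches = partition_idr_by_ss((1, 100), cons)
        assert [(r.start, r.end) for r in regions] == [(10, 20), (50, 60)]
        assert stretches == [(1, 9), (21, 49), (61, 100)]

    def test_gap_of_exactly_merge_gap_separates(self):
        cons = self.idr_cons([(10, 20), (41, 50)])  # gap exactly 20
        regions, _ = partition_idr_by_ss((1, 100), cons)
        assert len(regions) == 2

    def test_subminimal_elements_ignored(self):
        cons = self.idr_cons([(10, 12)])  # 3-residue helix < min_helix
        regions, stretches = partition_idr_by_ss((1, 100), cons)
        assert regions == [] and stretches == [(1, 100)]

    def test_coiled_coil_subclass(self):
        cons = self.idr_cons([(10, 20)], cc_at=range(10, 21))
        regions, _ = partition_idr_by_ss((1, 100), cons)
        assert regions[0].region_class is RegionClass.DISORDER_WITH_COILED_COIL


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.booleans(), min_size=1, max_size=80),
    st.lists(st.sampled_from("HEC"), min_size=1, max_size=80),
)
def test_segmentation_tiles_protein(disorder, ss):
    n = min(len(disorder), len(ss))
    cons = make_cons(disorder[:n], ss=ss[:n])
    regions, stretches = segment_protein(cons)
    from idrscape.records import Region

    tiles = list(regions) + [
        Region("p", s, e, RegionClass.OTHER_DISORDER) for s, e in stretches
    ]
    check_tiling(tiles, n)
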
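import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import preyfield as pf
from preyfield.annotations import SIZE_EXCLUDED_SUBTYPES
from tests.conftest import make_record

SIMPLE_HEADER = "image_id,object_id,imaged_length_px,resolvability,subtype\n"


def write(tmp_path, text, name="ann.csv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestSimpleDialect:
    def test_three_rows_parse(self, tmp_path):
        p = write(
            tmp_path,
            SIMPLE_HEADER
            + "i1,a,72,resolvable,plain\n"
            + "i1,b,40,resolvable,bent\n"
            + "i2,c,15,unresolvable,plain\n",
        )
        aset = pf.read_annotations(p)
        assert len(aset) == 3
        assert aset.n_images == 2
        assert [r.imaged_length_px for r in aset] == [72.0, 40.0, 15.0]

    def test_header_only_gives_empty_set(self, tmp_path):
        aset = pf.read_annotations(write(tmp_path, SIMPLE_HEADER))
        assert len(aset) == 0 and aset.n_images == 0

    def test_nonpositive_length_cites_row(self, tmp_path):
        p = write(tmp_path, SIMPLE_HEADER + "i1,a,-3,resolvable,plain\n")
        with pytest.raises(pf.ValidationError, match="row 2"):
            pf.read_annotations(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = write(tmp_path, "image_id,object_id,resolvability,subtype\ni1,a,resolvable,plain\n")
        with pytest.raises(pf.FormatError, match="imaged_length_px"):
            pf.read_annotations(p)

    def test_unknown_subtype_rejected(self, tmp_path):
        p = write(tmp_path, SIMPLE_HEADER + "i1,a,30,resolvable,squashed\n")
        with pytest.raises(pf.ValidationError, match="subtype"):
            pf.read_annotations(p)


class TestViameDialect:
    VIAME = (
        "# 1: Detection or Track-id,2: Image Identifier,3: Frame,4-7: bbox,8: conf,9: length,10-11: class pairs\n"
        "0,frame_000.png,0,10,10,40,50,0.9,-1,resolvable,0.9\n"
        "1,frame_000.png,0,5,5,10,10,0.8,33.5,resolvable_bent,0.8\n"
        "2,frame_001.png,1,0,0,6,8,0.7,-1,unresolvable,0.7\n"
    )

    def test_bbox_diagonal_and_explicit_length(self, tmp_path):
        aset = pf.read_annotations(write(tmp_path, self.VIAME), dialect="viame_csv")
        assert len(aset) == 3 and aset.n_images == 2
        assert aset.records[0].imaged_length_px == pytest.approx(math.hypot(30, 40))
        assert aset.records[1].imaged_length_px == 33.5  # explicit length wins
        assert aset.records[1].subtype == "bent"
        assert aset.records[2].resolvability == "unresolvable"
        assert aset.records[2].imaged_length_px == pytest.approx(10.0)

    def test_unknown_label_rejected(self, tmp_path):
        bad = "0,f.png,0,0,0,3,4,0.9,-1,seaweed,0.9\n"
        with pytest.raises(pf.FormatError, match="label"):
            pf.read_annotations(write(tmp_path, bad), dialect="viame_csv")


def test_unresolvable_cannot_carry_presentation_subtype():
    with pytest.raises(pf.ValidationError, match="subtype"):
        pf.ObjectRecord("i", "o", 20.0, "unresolvable", "bent")


records_strategy = st.lists(
    st.builds(
        pf.ObjectRecord,
        image_id=st.sampled_from(["a", "b", "c"]),
        object_id=st.uuids().map(str),
        imaged_length_px=st.floats(0.5, 500, allow_nan=False),
        resolvability=st.just("resolvable"),
        subtype=st.sampled_from(
            ["plain", "bent", "partial", "axial", "motion_blurred", "packed_aggregation"]
        ),
        timestamp_s=st.one_of(st.none(), st.floats(0, 1e6, allow_nan=False)),
    )
    | st.builds(
        pf.ObjectRecord,
        image_id=st.sampled_from(["a", "b"]),
        object_id=st.uuids().map(str),
        imaged_length_px=st.floats(0.5, 500, allow_nan=False),
        resolvability=st.just("unresolvable"),
        subtype=st.sampled_from(["plain", "none"]),
    ),
    max_size=30,
)


@settings(max_examples=25, deadline=None)
@given(records=records_strategy)
def test_write_read_round_trip_is_lossless(tmp_path_factory, records):
    aset = pf.AnnotationSet(tuple(records))
    path = tmp_path_factory.mktemp("rt") / "out.csv"
    pf.write_annotations(path, aset)
    assert pf.read_annotations(path).records == aset.records


class TestBoundaryFitSubset:
    def test_excludes_partial_and_packed(self, small_set):
        pairs = pf.boundary_fit_subset(small_set)
        assert pairs == [(72.0, 1), (15.0, 0), (33.0, 0)]

    def test_identity_when_all_plain(self):
        aset = pf.AnnotationSet(tuple(make_record(i, length=10.0 + i) for i in range(4)))
        assert len(pf.boundary_fit_subset(aset)) == 4

    @settings(max_examples=25, deadline=None)
    @given(records=records_strategy.filter(lambda rs: len(rs) > 0))
    def test_filter_matches_brute_force_recount_and_is_idempotent(self, records):
        aset = pf.AnnotationSet(tuple(records))
        expected = sum(1 for r in records if r.subtype not in SIZE_EXCLUDED_SUBTYPES)
        if expected == 0:
            with pytest.raises(pf.ValidationError):
                pf.boundary_fit_subset(aset)
            return
        pairs = pf.boundary_fit_subset(aset)
        assert len(pairs) == expected
        # applying the same subtype filter to an already-filtered set changes nothing:
        # pairs carry no subtype, so rebuild a plain-subtype set from them
        refiltered = pf.AnnotationSet(
            tuple(
                pf.ObjectRecord("x", str(i), L, "resolvable" if y else "unresolvable")
                for i, (L, y) in enumerate(pairs)
            )
        )
        assert [p[0] for p in pf.boundary_fit_subset(refiltered)] == [p[0] for p in pairs]

    def test_all_excluded_raises(self):
        aset = pf.AnnotationSet(
            (make_record(0, subtype="partial"), make_record(1, subtype="packed_aggregation"))
        )
        with pytest.raises(pf.ValidationError, match="excluded"):
            pf.boundary_fit_subset(aset)


class TestCountablePerImage:
    def test_reported_totals_give_mean_28_73(self, reported_class_totals_set):
        counts = pf.countable_per_image(reported_class_totals_set)
        assert len(counts) == 124
        assert counts["count"].sum() == 3079 + 154 + 193 + 12 + 125
        assert counts["count"].mean() == pytest.approx(28.734, abs=0.001)

    def test_single_image_two_resolvable(self):
        aset = pf.AnnotationSet((make_record(0), make_record(1)))
        counts = pf.countable_per_image(aset)
        assert counts["count"].tolist() == [2]

    def test_all_unresolvable_image_appears_with_zero(self):
        aset = pf.AnnotationSet(
            (make_record(0, "a"), make_record(1, "b", resolvability="unresolvable"))
        )
        counts = pf.countable_per_image(aset).set_index("image_id")["count"]
        assert counts["a"] == 1 and counts["b"] == 0

    @settings(max_examples=25, deadline=None)
    @given(records=records_strategy.filter(lambda rs: len(rs) > 0))
    def test_counts_sum_to_resolvable_records(self, records):
        aset = pf.AnnotationSet(tuple(records))
        counts = pf.countable_per_image(aset)
        assert counts["count"].sum() == sum(r.resolvability == "resolvable" for r in records)
        assert len(counts) == aset.n_images


def test_dive_events_round_trip(tmp_path):
    p = tmp_path / "ev.csv"
    p.write_text(
        "time_s,depth_m,kind\n0,0,dive_start\n5,12,strike\n9,19,strike\n20,0,dive_end\n",
        encoding="utf-8",
    )
    events = pf.read_dive_events(p)
    assert [e.kind for e in events] == ["dive_start", "strike", "strike", "dive_end"]
    assert events[2].depth_m == 19.0
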
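"""Subject I/O: XML round-trips, record validation, and the soma-size
inclusion rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lxml import etree

from icnsmap.core_io import (
    ContourTrace,
    MarkerRecordError,
    NeuronMarker,
    SubjectMap,
    SubjectValidationError,
    apply_inclusion_filter,
    markers_to_dataframe,
    read_subject,
    write_subject,
)


def _subject():
    markers = [
        NeuronMarker("m0", [100.0, 200.0, 12.5], 2, 15.2, 28.4, cluster_label=3,
                     roi_labels={"pv_hilum"}),
        NeuronMarker("m1", [-5.25, 0.125, 62.0], 12),
        NeuronMarker("m2", [1e4 / 3, 0.1, 7.0], 1, 13.0, 23.0),
    ]
    contours = [
        ContourTrace("left_atrium", [[0, 0, 60], [10, 0, 60], [10, 10, 60]], 12,
                     closed=True),
        ContourTrace("väßel_ünknown", [[0, 0, 5], [1, 1, 5]], 1, recognized=False),
    ]
    return SubjectMap("S1", "male", 5.0, markers, contours, provenance="test run")


def _assert_subjects_equal(a: SubjectMap, b: SubjectMap, rtol=1e-6):
    assert a.subject_id == b.subject_id
    assert a.sex == b.sex
    assert a.section_thickness == pytest.approx(b.section_thickness, rel=rtol)
    assert len(a.markers) == len(b.markers)
    for ma, mb in zip(a.markers, b.markers):
        assert ma.id == mb.id
        assert ma.section_index == mb.section_index
        np.testing.assert_allclose(ma.position, mb.position, rtol=rtol)
        for attr in ("soma_short_axis", "soma_long_axis", "cluster_label"):
            va, vb = getattr(ma, attr), getattr(mb, attr)
            assert (va is None) == (vb is None)
            if va is not None:
                assert va == pytest.approx(vb, rel=rtol)
        assert ma.roi_labels == mb.roi_labels
    assert len(a.contours) == len(b.contours)
    for ca, cb in zip(a.contours, b.contours):
        assert ca.structure_name == cb.structure_name
        assert ca.section_index == cb.section_index
        assert ca.closed == cb.closed
        np.testing.assert_allclose(ca.points, cb.points, rtol=rtol)


class TestRoundTrip:
    def test_counts_preserved(self, tmp_path):
        subject = _subject()
        path = tmp_path / "s.xml"
        write_subject(subject, path)
        back = read_subject(path)
        assert len(back.markers) == 3
        assert len(back.contours) == 2

    def test_field_wise_identity(self, tmp_path):
        subject = _subject()
        path = tmp_path / "s.xml"
        with pytest.warns(UserWarning, match="unknown structure"):
            write_subject(subject, path)
            back = read_subject(path)
        _assert_subjects_equal(subject, back)

    def test_unicode_structure_name_preserved(self, tmp_path):
        subject = _subject()
        path = tmp_path / "s.xml"
        write_subject(subject, path)
        with pytest.warns(UserWarning):
            back = read_subject(path)
        assert back.contours[1].structure_name == "väßel_ünknown"
        assert not back.contours[1].recognized

    def test_empty_subject(self, tmp_path):
        path = tmp_path / "empty.xml"
        write_subject(SubjectMap("E", "female"), path)
        back = read_subject(path)
        assert back.markers == [] and back.contours == []
        assert back.sex == "female"

    def test_large_synthetic_round_trip(self, tmp_path, template):
        from icnsmap.synthetic import sample_icns, male_profile

        markers, _ = sample_icns(
            template, male_profile(total_neurons_mean=1000), 3
        )
        subject = SubjectMap("big", "male", markers=markers)
        path = tmp_path / "big.xml"
        write_subject(subject, path)
        _assert_subjects_equal(subject, read_subject(path))


class TestReadValidation:
    def test_section_index_from_z(self, tmp_path):
        # z = 12.5 µm at 5 µm thickness -> section floor(12.5/5) = 2
        xml = (
            '<subject id="s" section_thickness="5">'
            '<markers><marker id="a"><point x="0" y="0" z="12.5"/></marker>'
            "</markers></subject>"
        )
        p = tmp_path / "s.xml"
        p.write_text(xml)
        assert read_subject(p).markers[0].section_index == 2

    def test_marker_missing_position_lists_id(self, tmp_path):
        xml = (
            '<subject id="s"><markers><marker id="bad1"/>'
            '<marker id="ok"><point x="0" y="0" z="0"/></marker>'
            '<marker id="bad2"/></markers></subject>'
        )
        p = tmp_path / "s.xml"
        p.write_text(xml)
        with pytest.raises(MarkerRecordError, match=r"bad1.*bad2"):
            read_subject(p)

    def test_duplicate_marker_id(self, tmp_path):
        xml = (
            '<subject id="s"><markers>'
            '<marker id="a"><point x="0" y="0" z="0"/></marker>'
            '<marker id="a"><point x="1" y="0" z="0"/></marker>'
            "</markers></subject>"
        )
        p = tmp_path / "s.xml"
        p.write_text(xml)
        with pytest.raises(SubjectValidationError, match="duplicate"):
            read_subject(p)

    def test_malformed_markup_names_line(self, tmp_path):
        p = tmp_path / "s.xml"
        p.write_text('<subject id="s">\n<markers>\n</subject>')
        with pytest.raises(etree.XMLSyntaxError, match="line"):
            read_subject(p)

    def test_unknown_elements_ignored(self, tmp_path):
        xml = (
            '<subject id="s"><exotic attr="1"/><markers>'
            '<marker id="a" mystery="yes"><point x="0" y="0" z="0"/>'
            "<extra/></marker></markers></subject>"
        )
        p = tmp_path / "s.xml"
        p.write_text(xml)
        assert len(read_subject(p).markers) == 1

    def test_contour_z_as_section_index(self, tmp_path):
        xml = (
            '<subject id="s" section_thickness="5"><contours>'
            '<contour name="left_atrium" section="3">'
            '<point x="0" y="0" z="3"/><point x="1" y="0" z="3"/>'
            "</contour></contours></subject>"
        )
        p = tmp_path / "s.xml"
        p.write_text(xml)
        c = read_subject(p, contour_z_mode="section").contours[0]
        assert c.points[0, 2] == pytest.approx(15.0)


class TestInvariants:
    def test_long_axis_shorter_than_short_rejected(self):
        with pytest.raises(SubjectValidationError):
            NeuronMarker("m", [0, 0, 0], 0, soma_short_axis=20, soma_long_axis=10)

    def test_closed_contour_needs_three_points(self):
        with pytest.raises(SubjectValidationError):
            ContourTrace("aorta", [[0, 0, 0], [1, 0, 0]], 0, closed=True)

    def test_contour_multiple_z_rejected(self):
        with pytest.raises(SubjectValidationError, match="z"):
            ContourTrace("aorta", [[0, 0, 0], [1, 0, 5]], 0)

    def test_section_consistency_check(self):
        m = NeuronMarker("m", [0, 0, 12.5], 2)
        m.validate_section(5.0)  # |12.5 - 10| = 2.5 <= 2.5
        bad = NeuronMarker("m", [0, 0, 20.0], 2)
        with pytest.raises(SubjectValidationError):
            bad.validate_section(5.0)


class TestInclusionFilter:
    def test_boundary_is_inclusive(self):
        kept = apply_inclusion_filter(
            [NeuronMarker("m", [0, 0, 0], 0, 13.0, 23.0)], 13.0, 23.0
        )
        assert len(kept) == 1

    def test_fails_short_axis(self):
        kept = apply_inclusion_filter(
            [NeuronMarker("m", [0, 0, 0], 0, 12.9, 30.0)], 13.0, 23.0
        )
        assert kept == []

    def test_missing_axes_retained_and_flagged(self):
        m = NeuronMarker("m", [0, 0, 0], 0)
        kept = apply_inclusion_filter([m], 13.0, 23.0)
        assert kept == [m]
        assert "size_unverified" in m.flags

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_inclusion_filter([], -1.0, 23.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        axes=st.lists(
            st.tuples(
                st.floats(5.0, 40.0, allow_nan=False),
                st.floats(0.0, 30.0, allow_nan=False),
            ),
            min_size=1,
            max_size=100,
        )
    )
    def test_matches_per_record_brute_force(self, axes):
        markers = [
            NeuronMarker(f"m{i}", [0, 0, 0], 0, s, s + d)
            for i, (s, d) in enumerate(axes)
        ]
        kept = apply_inclusion_filter(list(markers), 13.0, 23.0)
        expected = [
            m
            for m in markers
            if m.soma_short_axis >= 13.0 and m.soma_long_axis >= 23.0
        ]
        assert [m.id for m in kept] == [m.id for m in expected]
        # idempotent and order-preserving
        again = apply_inclusion_filter(list(kept), 13.0, 23.0)
        assert [m.id for m in again] == [m.id for m in kept]

    def test_synthetic_markers_brute_force(self, small_markers):
        markers, _ = small_markers
        kept = apply_inclusion_filter(list(markers), 13.0, 23.0)
        brute = [
            m
            for m in markers
            if m.soma_short_axis >= 13.0 and m.soma_long_axis >= 23.0
        ]
        assert [m.id for m in kept] == [m.id for m in brute]


def test_markers_dataframe_columns():
    df = markers_to_dataframe(_subject())
    assert list(df.columns) == ["id", "x", "y", "z", "section", "cluster", "rois"]
    assert df.loc[0, "rois"] == "pv_hilum"
    assert df.loc[1, "cluster"] == -1
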
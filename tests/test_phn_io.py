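import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonealign.phn_io import (
    PhnParseError,
    UnusablePhnError,
    annotation_to_segments,
    export_textgrid,
    read_bundle,
    read_phn,
    read_textgrid,
    rescale_phn,
    write_bundle,
    write_phn,
)
from phonealign.types import FrontendBundle, LabeledSegment, PhoneticAnnotation


def _write(tmp_path, text, name="x.phn"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPhn:
    def test_single_entry_seconds(self, tmp_path):
        ann = read_phn(_write(tmp_path, "0 1600 sh\n"), 16000)
        assert ann.entries == ((0, 1600, "sh"),)
        assert annotation_to_segments(ann) == [LabeledSegment("sh", 0.0, 0.1)]

    def test_contiguous_entries(self, tmp_path):
        ann = read_phn(_write(tmp_path, "0 800 h#\n800 1600 aa\n"), 16000)
        assert len(ann) == 2
        assert ann.entries[0][1] == ann.entries[1][0]

    def test_unsorted_input_is_sorted(self, tmp_path):
        ann = read_phn(_write(tmp_path, "800 1600 aa\n0 800 h#\n"), 16000)
        assert [e[2] for e in ann.entries] == ["h#", "aa"]

    @pytest.mark.parametrize("content", ["", "xxx", ".jpg", "  xxx  \n"])
    def test_placeholder_files_rejected(self, tmp_path, content):
        with pytest.raises(UnusablePhnError):
            read_phn(_write(tmp_path, content), 16000)

    @pytest.mark.parametrize(
        "content", ["0 800\n", "0 abc sh\n", "800 800 sh\n", "900 800 sh\n"]
    )
    def test_malformed_lines_rejected(self, tmp_path, content):
        with pytest.raises(PhnParseError):
            read_phn(_write(tmp_path, content), 16000)

    def test_parse_error_carries_line_number(self, tmp_path):
        with pytest.raises(PhnParseError, match=":2:"):
            read_phn(_write(tmp_path, "0 800 sh\nbroken line here extra\n"), 16000)


class TestRescale:
    def test_downsample_44k_to_16k(self):
        ann = PhoneticAnnotation(((0, 44100, "aa"), (88200, 132300, "iy")), 44100)
        out = rescale_phn(ann, 44100, 16000)
        assert out.entries == ((0, 16000, "aa"), (32000, 48000, "iy"))
        assert out.sampling_rate == 16000

    def test_identity_when_rates_equal(self):
        ann = PhoneticAnnotation(((0, 100, "t"),), 16000)
        assert rescale_phn(ann, 16000, 16000).entries == ann.entries

    def test_degenerate_result_rejected(self):
        ann = PhoneticAnnotation(((10, 11, "t"),), 44100)
        with pytest.raises(ValueError, match="degenerate"):
            rescale_phn(ann, 44100, 16000)

    def test_round_trip_44k_within_two_samples(self):
        ann = PhoneticAnnotation(
            ((0, 1234, "t"), (1234, 9999, "aa"), (10000, 54321, "iy")), 16000
        )
        back = rescale_phn(rescale_phn(ann, 16000, 44100), 44100, 16000)
        for (b0, e0, _), (b1, e1, _) in zip(ann.entries, back.entries):
            assert abs(b0 - b1) <= 2 and abs(e0 - e1) <= 2


entry_st = st.tuples(
    st.integers(0, 10**6), st.integers(1, 2000), st.text("abcxyz#", min_size=1, max_size=3)
)


@settings(derandomize=True, max_examples=50)
@given(st.lists(entry_st, min_size=1, max_size=12), st.sampled_from([8000, 16000, 44100]))
def test_phn_round_trip_identity(tmp_path_factory, raw, rate):
    """Arbitrary valid annotations survive write -> read unchanged."""
    cursor = 0
    entries = []
    for gap, length, phone in raw:
        begin = cursor + gap
        entries.append((begin, begin + length, phone))
        cursor = begin + length
    ann = PhoneticAnnotation(tuple(entries), rate)
    path = tmp_path_factory.mktemp("phn") / "rt.phn"
    write_phn(ann, path)
    assert read_phn(path, rate) == ann


def test_write_empty_annotation_refused(tmp_path):
    with pytest.raises(ValueError):
        write_phn(PhoneticAnnotation((), 16000), tmp_path / "e.phn")


class TestTextGrid:
    def test_full_coverage_two_intervals(self, tmp_path):
        path = tmp_path / "a.TextGrid"
        export_textgrid(
            [LabeledSegment("sh", 0.0, 1.0), LabeledSegment("iy", 1.0, 2.0)], 2.0, path
        )
        text = path.read_text()
        assert "intervals: size = 2" in text
        assert read_textgrid(path) == [
            LabeledSegment("sh", 0.0, 1.0),
            LabeledSegment("iy", 1.0, 2.0),
        ]

    def test_gaps_filled_with_empty_intervals(self, tmp_path):
        path = tmp_path / "b.TextGrid"
        export_textgrid([LabeledSegment("aa", 0.5, 1.0)], 2.0, path)
        assert "intervals: size = 3" in path.read_text()
        assert read_textgrid(path) == [LabeledSegment("aa", 0.5, 1.0)]

    def test_empty_segment_list_single_interval(self, tmp_path):
        path = tmp_path / "c.TextGrid"
        export_textgrid([], 2.0, path)
        assert "intervals: size = 1" in path.read_text()

    def test_overlapping_segments_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_textgrid(
                [LabeledSegment("a", 0.0, 1.0), LabeledSegment("b", 0.5, 1.5)],
                2.0,
                tmp_path / "d.TextGrid",
            )


class TestBundleInterchange:
    def test_round_trip(self, tmp_path):
        bundle = FrontendBundle(
            frame_labels=("[pad]", "sh", "[pad]", "iy"),
            n_samples=32000,
            sampling_rate=16000,
            boundaries_s=(0.5, 1.2),
            audio_path="x.wav",
        )
        path = tmp_path / "b.json"
        write_bundle(bundle, path)
        assert read_bundle(path) == bundle

    def test_missing_key_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"frame_labels": ["sh"]}')
        with pytest.raises(ValueError, match="missing interchange key"):
            read_bundle(path)

    def test_boundary_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            FrontendBundle(("sh",), 16000, 16000, boundaries_s=(1.5,))
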
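"""Record loading, Z-scoring, segmentation, fixed-length preparation."""

import struct

import numpy as np
import pytest

from lraecg.ecg_io import (
    BeatAnnotation,
    ECGRecord,
    load_record,
    prepare_fixed_length,
    segment_beats,
    write_fixture_record,
    zscore,
)


def make_record(signal, fs=360.0, record_id="rec1"):
    return ECGRecord(signal=np.asarray(signal, float), fs=fs, lead_names=["MLII"], record_id=record_id)


class TestZscore:
    def test_constant_signal_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = zscore(np.array([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_closed_form_three_points(self):
        np.testing.assert_allclose(
            zscore(np.array([1.0, 2.0, 3.0])),
            [-np.sqrt(1.5), 0.0, np.sqrt(1.5)],
            atol=1e-12,
        )  # mu=2, population sigma=sqrt(2/3)

    def test_long_noise_vector_standardized(self, rng):
        x = rng.normal(loc=3.0, scale=7.0, size=1000)
        z = zscore(x)
        # two-pass oracle
        mu = sum(x) / len(x)
        var = sum((v - mu) ** 2 for v in x) / len(x)
        np.testing.assert_allclose(z, (x - mu) / np.sqrt(var), atol=1e-9)
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1.0) < 1e-9

    def test_idempotent_up_to_tolerance(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_allclose(zscore(zscore(x)), zscore(x), atol=1e-9)

    def test_sample_std_switch(self):
        z = zscore(np.array([1.0, 2.0, 3.0]), ddof=1)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            zscore(np.array([]))


class TestSegmentBeats:
    def test_window_near_start_dropped(self, rng):
        rec = make_record(rng.normal(size=500))
        ds = segment_beats(rec, [BeatAnnotation(10, "N")], window=(100, 150))
        assert len(ds) == 0 and ds.n_boundary_dropped == 1

    def test_counts_two_interior_beats(self, rng):
        rec = make_record(rng.normal(size=1000))
        anns = [BeatAnnotation(300, "N"), BeatAnnotation(700, "V")]
        ds = segment_beats(rec, anns, window=(100, 150))
        assert ds.segments.shape == (2, 250)
        assert list(ds.labels) == [0, 3]

    def test_off_target_symbols_filtered(self, rng):
        rec = make_record(rng.normal(size=2000))
        anns = [BeatAnnotation(i, s) for i, s in
                [(300, "N"), (600, "L"), (900, "A"), (1200, "R"), (1500, "V")]]
        ds = segment_beats(rec, anns, window=(100, 150))
        assert len(ds) == 4 and ds.n_symbol_filtered == 1

    def test_row_count_identity(self, rng):
        rec = make_record(rng.normal(size=1500))
        anns = [BeatAnnotation(i, "N") for i in (50, 400, 800, 1450)]
        ds = segment_beats(rec, anns, window=(100, 150))
        assert len(ds) == 4 - ds.n_boundary_dropped
        assert ds.n_boundary_dropped == 2  # 50 and 1450 exit the record

    def test_segments_cut_from_record_level_zscore(self, rng):
        raw = rng.normal(loc=4.0, scale=2.0, size=1000)
        rec = make_record(raw)
        ds = segment_beats(rec, [BeatAnnotation(500, "N")], window=(100, 150))
        np.testing.assert_allclose(ds.segments[0], zscore(raw)[400:650], atol=1e-12)

    def test_annotation_at_last_sample_dropped(self, rng):
        rec = make_record(rng.normal(size=1000))
        ds = segment_beats(rec, [BeatAnnotation(999, "N")], window=(100, 150))
        assert len(ds) == 0 and ds.n_boundary_dropped == 1

    def test_empty_usable_set_warns_not_crashes(self, rng):
        rec = make_record(rng.normal(size=1000))
        with pytest.warns(UserWarning, match="no usable beats"):
            ds = segment_beats(rec, [BeatAnnotation(500, "A")], window=(100, 150))
        assert len(ds) == 0


class TestPrepareFixedLength:
    def test_exact_length_passthrough(self, rng):
        rec = make_record(rng.normal(size=9000), fs=300)
        out = prepare_fixed_length(rec, 9000)
        np.testing.assert_allclose(out, zscore(rec.signal[0]), atol=1e-12)

    def test_long_record_truncated_from_start(self, rng):
        rec = make_record(rng.normal(size=12000), fs=300)
        out = prepare_fixed_length(rec, 9000)
        np.testing.assert_allclose(out, zscore(rec.signal[0])[:9000], atol=1e-12)

    def test_short_record_zero_padded_after_zscore(self, rng):
        rec = make_record(rng.normal(size=6000), fs=300)
        out = prepare_fixed_length(rec, 9000)
        assert np.all(out[6000:] == 0.0)
        np.testing.assert_allclose(out[:6000], zscore(rec.signal[0]), atol=1e-12)


class TestCsvFixtureDialect:
    def test_round_trip(self, tmp_path, rng):
        rec = make_record(rng.normal(size=300), fs=360, record_id="fx1")
        anns = [BeatAnnotation(100, "N"), BeatAnnotation(200, "V")]
        write_fixture_record(rec, anns, tmp_path)
        loaded, loaded_anns = load_record(tmp_path / "fx1.csv", dialect="csv_fixture")
        np.testing.assert_allclose(loaded.signal, rec.signal, atol=0)
        assert loaded.fs == 360 and loaded.lead_names == ["MLII"]
        assert loaded_anns == anns

    def test_missing_annotation_file_raises(self, tmp_path, rng):
        rec = make_record(rng.normal(size=10), record_id="fx2")
        write_fixture_record(rec, [], tmp_path)
        (tmp_path / "fx2.ann.csv").unlink()
        with pytest.raises(FileNotFoundError, match="annotation"):
            load_record(tmp_path / "fx2.csv")

    def test_malformed_annotation_reports_line(self, tmp_path, rng):
        rec = make_record(rng.normal(size=10), record_id="fx3")
        write_fixture_record(rec, [BeatAnnotation(3, "N")], tmp_path)
        (tmp_path / "fx3.ann.csv").write_text("sample_index,symbol\n3,N\nnot-a-number,Q\n")
        with pytest.raises(ValueError, match=":3"):
            load_record(tmp_path / "fx3.csv")

    def test_boundary_annotation_loads_then_drops_in_segmentation(self, tmp_path, rng):
        rec = make_record(rng.normal(size=400), record_id="fx4")
        anns = [BeatAnnotation(399, "N"), BeatAnnotation(200, "N")]
        write_fixture_record(rec, sorted(anns, key=lambda a: a.sample_index), tmp_path)
        loaded, loaded_anns = load_record(tmp_path / "fx4.csv")
        assert len(loaded_anns) == 2
        ds = segment_beats(loaded, loaded_anns, window=(100, 150))
        assert len(ds) == 1 and ds.n_boundary_dropped == 1


def encode_212(values):
    """Independent byte-level encoder for WFDB format 212 (test oracle)."""
    out = bytearray()
    vals = list(values)
    if len(vals) % 2:
        vals.append(0)
    for a, b in zip(vals[0::2], vals[1::2]):
        a &= 0xFFF
        b &= 0xFFF
        out.append(a & 0xFF)
        out.append(((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4))
        out.append(b & 0xFF)
    return bytes(out)


def encode_atr(entries):
    """Independent MIT-annotation encoder: (delta, code) words + EOF."""
    out = bytearray()
    for delta, code in entries:
        out += struct.pack("<H", (code << 10) | delta)
    out += struct.pack("<H", 0)
    return bytes(out)


class TestWfdbDialect:
    SYMBOL_CODES = {"N": 1, "L": 2, "R": 3, "V": 5}

    def write_wfdb(self, tmp_path, adc, fs=360, gain=200, baseline=1024, anns=()):
        n = len(adc)
        (tmp_path / "r1.hea").write_text(
            f"r1 1 {fs} {n}\n"
            f"r1.dat 212 {gain}({baseline})/mV 12 {baseline} {adc[0]} 0 0 MLII\n"
        )
        (tmp_path / "r1.dat").write_bytes(encode_212(adc))
        (tmp_path / "r1.atr").write_bytes(
            encode_atr([(d, self.SYMBOL_CODES[s]) for d, s in anns])
        )

    def test_signal_decoding_and_physical_units(self, tmp_path):
        adc = [1024, 1224, 824, 1024, 2047, -2048 & 0xFFF]
        self.write_wfdb(tmp_path, adc)
        rec, _ = load_record(tmp_path / "r1", dialect="wfdb")
        assert rec.fs == 360 and rec.lead_names == ["MLII"]
        expected = (np.array([1024, 1224, 824, 1024, 2047, -2048]) - 1024) / 200.0
        np.testing.assert_allclose(rec.signal[0], expected, atol=1e-12)

    def test_annotation_times_accumulate_deltas(self, tmp_path):
        adc = [1024] * 600
        self.write_wfdb(tmp_path, adc, anns=[(100, "N"), (150, "V"), (200, "L")])
        _, anns = load_record(tmp_path / "r1", dialect="wfdb")
        assert [(a.sample_index, a.symbol) for a in anns] == [
            (100, "N"), (250, "V"), (450, "L"),
        ]

    def test_skip_word_extends_time(self, tmp_path):
        adc = [1024] * 10
        self.write_wfdb(tmp_path, adc)
        raw = bytearray()
        raw += struct.pack("<H", (59 << 10))  # SKIP
        raw += struct.pack("<H", 0)  # high word
        raw += struct.pack("<H", 70000 & 0xFFFF)  # low word -> overflows 16 bits
        raw += struct.pack("<H", 1)  # high word carries the rest
        raw = bytearray()
        raw += struct.pack("<H", (59 << 10))
        raw += struct.pack("<H", (70000 >> 16) & 0xFFFF)
        raw += struct.pack("<H", 70000 & 0xFFFF)
        raw += struct.pack("<H", (1 << 10) | 5)  # N at +5
        raw += struct.pack("<H", 0)
        (tmp_path / "r1.atr").write_bytes(bytes(raw))
        _, anns = load_record(tmp_path / "r1", dialect="wfdb")
        assert [(a.sample_index, a.symbol) for a in anns] == [(70005, "N")]

    def test_missing_header_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="header"):
            load_record(tmp_path / "nope", dialect="wfdb")
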
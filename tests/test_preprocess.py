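"""I/O and the preprocessing chain: resampling, filtering, epoching,
rejection, average reference and sensor neighborhoods."""

import numpy as np
import pytest
from scipy import signal as sps

from eegcomplex import (
    EpochSet,
    FormatError,
    InvalidArgumentError,
    Montage,
    Recording,
    average_reference,
    bandpass,
    build_neighborhood,
    read_recording,
    reject_epochs,
    resample,
    segment,
    write_recording,
)
from eegcomplex.preprocess import read_layout, write_layout


def _rec(data, sfreq=500.0, names=None):
    data = np.atleast_2d(np.asarray(data, float))
    n = data.shape[0]
    names = names or tuple(f"E{i + 1}" for i in range(n))
    pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return Recording(data, sfreq, Montage(tuple(names), pos))


def _sine(freq, sfreq, dur, amp=1.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    return amp * np.sin(2 * np.pi * freq * t)


class TestIO:
    def test_delimited_round_trip(self, tmp_path, rng):
        rec = _rec(rng.standard_normal((3, 1000)) * 20)
        path = tmp_path / "rec.tsv"
        write_recording(path, rec)
        back = read_recording(path, "delimited", rec.montage)
        np.testing.assert_allclose(back.data, rec.data, rtol=1e-6, atol=1e-5)
        assert back.sfreq == rec.sfreq

    def test_edf_round_trip(self, tmp_path, rng):
        rec = _rec(rng.standard_normal((3, 1500)) * 50)
        path = tmp_path / "rec.edf"
        write_recording(path, rec, format="edf")
        back = read_recording(path, "edf", rec.montage)
        assert back.sfreq == rec.sfreq
        assert back.montage.channel_names == rec.montage.channel_names
        # 16-bit quantization over a ±~200 μV span
        np.testing.assert_allclose(
            back.data[:, : rec.n_samples], rec.data, atol=0.02
        )

    def test_layout_mismatch_is_format_error(self, tmp_path, rng):
        rec = _rec(rng.standard_normal((3, 100)))
        path = tmp_path / "rec.tsv"
        write_recording(path, rec)
        two = Montage(("E1", "E2"), np.array([[0.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(FormatError):
            read_recording(path, "delimited", two)

    def test_non_numeric_cell_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# sfreq=500\nE1\tE2\n1.0\toops\n")
        m = Montage(("E1", "E2"), np.zeros((2, 2)))
        with pytest.raises(FormatError):
            read_recording(path, "delimited", m)

    def test_layout_round_trip(self, tmp_path, small_montage):
        path = tmp_path / "layout.csv"
        write_layout(path, small_montage)
        back = read_layout(path)
        assert back.channel_names == small_montage.channel_names
        np.testing.assert_allclose(back.positions, small_montage.positions)


class TestResample:
    def test_same_rate_is_identity(self, rng):
        rec = _rec(rng.standard_normal((2, 1000)))
        np.testing.assert_array_equal(resample(rec, 500.0).data, rec.data)

    def test_downsampling_preserves_dominant_frequency(self):
        rec = _rec(_sine(10, 1000, 4.0), sfreq=1000.0)
        out = resample(rec, 500.0)
        assert out.sfreq == 500.0
        f, p = sps.periodogram(out.data[0], fs=out.sfreq)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.3)
        assert abs(out.duration - rec.duration) <= 1 / 500.0

    def test_upsampling_doubles_length(self, rng):
        rec = _rec(rng.standard_normal((1, 777)), sfreq=250.0)
        out = resample(rec, 500.0)
        assert abs(out.n_samples - 2 * 777) <= 1


class TestBandpass:
    def test_stopband_sine_attenuated(self):
        rec = _rec(_sine(60, 500, 30.0))
        out = bandpass(rec, 0.5, 45.0)
        assert np.sqrt((out.data**2).mean()) < 0.1 * np.sqrt((rec.data**2).mean())

    def test_passband_sine_preserved(self):
        rec = _rec(_sine(10, 500, 10.0))
        out = bandpass(rec, 0.5, 45.0)
        ratio = np.sqrt((out.data**2).mean() / (rec.data**2).mean())
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_zero_in_zero_out(self):
        rec = _rec(np.zeros((2, 2000)))
        np.testing.assert_allclose(bandpass(rec, 1.0, 40.0).data, 0.0, atol=1e-12)

    def test_attenuation_contract_at_half_lo(self):
        # two-pass response ≥ 20 dB down at lo/2 and at min(2·hi, 0.95·Nyquist)
        from eegcomplex.preprocess import _fir_bandpass

        lo, hi, fs = 0.5, 45.0, 500.0
        taps = _fir_bandpass(lo, hi, fs, min(max(lo / 2, 2.0), lo))
        w, h = sps.freqz(taps, worN=[lo / 2, min(2 * hi, 0.475 * fs)], fs=fs)
        two_pass_db = 40 * np.log10(np.abs(h) + 1e-300)
        assert np.all(two_pass_db <= -20.0)

    def test_hi_at_nyquist_rejected(self):
        rec = _rec(np.zeros((1, 1000)))
        with pytest.raises(InvalidArgumentError):
            bandpass(rec, 1.0, 250.0)


class TestSegmentRejectReference:
    def test_segment_arithmetic(self, rng):
        rec = _rec(rng.standard_normal((3, 180_000)))  # 360 s at 500 Hz
        ep = segment(rec, 2.0)
        assert (ep.n_epochs, ep.n_channels, ep.n_samples) == (180, 3, 1000)

    @pytest.mark.parametrize("dur_s, epoch_s, n", [(61, 60, 1), (1, 2, 0)])
    def test_segment_remainder(self, rng, dur_s, epoch_s, n):
        rec = _rec(rng.standard_normal((1, dur_s * 500)))
        assert segment(rec, epoch_s).n_epochs == n

    def test_reject_drops_only_spiking_epoch(self, rng):
        data = rng.uniform(-99, 99, size=(5, 2, 1000))
        data[2, 1, 17] = 150.0
        ep = EpochSet(data, 500.0, 2.0, _rec(np.zeros((2, 10))).montage)
        kept = reject_epochs(ep, 100.0)
        assert kept.n_epochs == 4
        np.testing.assert_array_equal(kept.data, data[[0, 1, 3, 4]])

    def test_reject_all_warns_and_empties(self, rng):
        ep = EpochSet(
            rng.standard_normal((3, 2, 100)), 50.0, 2.0,
            _rec(np.zeros((2, 10))).montage,
        )
        with pytest.warns(UserWarning):
            out = reject_epochs(ep, 0.001)
        assert out.n_epochs == 0

    def test_average_reference_two_channel_closed_form(self, rng):
        a, b = rng.standard_normal((2, 500))
        out = average_reference(_rec(np.vstack([a, b])))
        np.testing.assert_allclose(out.data[0], (a - b) / 2)
        np.testing.assert_allclose(out.data[1], (b - a) / 2)

    def test_average_reference_idempotent_and_zero_mean(self, rng):
        rec = _rec(rng.standard_normal((4, 300)))
        once = average_reference(rec)
        assert np.abs(once.data.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(average_reference(once).data, once.data)

    def test_average_reference_commutes_with_segmentation(self, rng):
        rec = _rec(rng.standard_normal((3, 6000)))
        a = segment(average_reference(rec), 2.0)
        b = average_reference(segment(rec, 2.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidArgumentError):
            average_reference(_rec(np.zeros((1, 100))))


class TestNeighborhood:
    def test_collinear_chain(self):
        m = Montage(("a", "b", "c"), np.array([[0.0, 0], [1.0, 0], [2.0, 0]]))
        g = build_neighborhood(m, "distance", radius=1.0)
        assert g.adjacency.sum(axis=1).tolist() == [1, 2, 1]

    def test_large_radius_complete_graph(self, small_montage):
        g = build_neighborhood(small_montage, "distance", radius=100.0)
        n = small_montage.n_channels
        assert g.adjacency.sum() == n * (n - 1)
        assert not np.any(np.diag(g.adjacency))

    def test_delaunay_convex_quad_degrees(self):
        m = Montage(
            ("a", "b", "c", "d"),
            np.array([[0.0, 0], [1.0, 0], [1.0, 1], [0.0, 1]]),
        )
        g = build_neighborhood(m, "delaunay")
        degrees = g.adjacency.sum(axis=1)
        assert np.all(degrees >= 2)
        assert np.array_equal(g.adjacency, g.adjacency.T)

    def test_bad_radius_rejected(self, small_montage):
        with pytest.raises(InvalidArgumentError):
            build_neighborhood(small_montage, "distance", radius=-1.0)
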
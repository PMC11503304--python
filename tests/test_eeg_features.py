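import numpy as np
import pytest

from stresspipe import eeg_features as ef
from stresspipe.errors import (
    ChannelMismatchError,
    DegenerateSignalError,
    NyquistError,
)
from stresspipe.io_core import (
    BlockWindow,
    EEGRecording,
    EXPECTED_CHANNELS,
    SessionManifest,
    Task,
)

from oracles import higuchi_fd_oracle, sample_entropy_oracle

FS = 250.0


def recording(channel_data: dict[str, np.ndarray], fs=FS) -> EEGRecording:
    data = np.vstack([channel_data[c] for c in EXPECTED_CHANNELS])
    return EEGRecording(EXPECTED_CHANNELS, data, fs)


def sine(freq, dur=10.0, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(0, dur, 1 / fs))


class TestBandpass:
    def _filter_one(self, x, fs=FS):
        rec = recording({c: x.copy() for c in EXPECTED_CHANNELS}, fs)
        return ef.bandpass(rec).samples[0]

    def test_stopband_sine_attenuated(self):
        x = sine(50, dur=60.0)
        y = self._filter_one(x)
        interior = slice(int(10 * FS), -int(10 * FS))  # past filtfilt edges
        assert y[interior].std() / x[interior].std() < 0.05

    def test_passband_sine_preserved(self):
        x = sine(10, dur=60.0)
        y = self._filter_one(x)
        interior = slice(int(10 * FS), -int(10 * FS))
        assert y[interior].std() / x[interior].std() == pytest.approx(1.0, abs=0.05)

    def test_dc_rejected(self):
        y = self._filter_one(np.full(2500, 7.3))
        assert abs(y.mean()) < 1e-8

    def test_edge_at_nyquist_rejected(self):
        rec = recording({c: np.zeros(1000) for c in EXPECTED_CHANNELS}, fs=81.0)
        with pytest.raises(NyquistError):
            ef.bandpass(rec, hi=40.5)


class TestDeriveBipolar:
    def test_identical_electrodes_cancel(self, rng):
        x = rng.standard_normal(1000)
        rec = recording({"Fp1": rng.standard_normal(1000), "Fp2": x,
                         "T9": rng.standard_normal(1000), "T10": x})
        pair = ef.derive_bipolar(rec)
        np.testing.assert_allclose(pair.ch1, 0.0, atol=1e-12)

    def test_constant_offset_survives(self, rng):
        base = rng.standard_normal(1000)
        rec = recording({"Fp1": base, "Fp2": np.zeros(1000),
                         "T9": base + 5.0, "T10": np.zeros(1000)})
        np.testing.assert_allclose(ef.derive_bipolar(rec).ch2, 5.0)

    def test_label_driven_not_order_driven(self, rng):
        chans = {c: rng.standard_normal(500) for c in EXPECTED_CHANNELS}
        rec1 = recording(chans)
        shuffled_order = ("T9", "Fp2", "T10", "Fp1")
        rec2 = EEGRecording(shuffled_order,
                            np.vstack([chans[c] for c in shuffled_order]), FS)
        p1, p2 = ef.derive_bipolar(rec1), ef.derive_bipolar(rec2)
        np.testing.assert_array_equal(p1.ch1, p2.ch1)
        np.testing.assert_array_equal(p1.ch2, p2.ch2)

    def test_missing_channel_rejected(self, rng):
        rec = EEGRecording(("Fp1", "Fp2", "T9"), rng.standard_normal((3, 500)), FS)
        with pytest.raises(ChannelMismatchError):
            ef.derive_bipolar(rec)


class TestFlatlineDetection:
    def test_all_zero_signal_excludes_session(self):
        pair = ef.BipolarPair(np.zeros(5000), np.zeros(5000), FS)
        mask, excluded = ef.detect_flatline(pair)
        assert mask.all() and excluded

    def test_clean_noise_has_no_flat_windows(self, rng):
        pair = ef.BipolarPair(10 * rng.standard_normal(5000),
                              10 * rng.standard_normal(5000), FS)
        mask, excluded = ef.detect_flatline(pair)
        assert not mask.any() and not excluded

    def test_thirty_percent_zeroed_stretch_triggers_exclusion(self, rng):
        x = 10 * rng.standard_normal(10000)
        y = 10 * rng.standard_normal(10000)
        x[:3000] = 0.0
        mask, excluded = ef.detect_flatline(ef.BipolarPair(x, y, FS))
        assert excluded and mask[:5].all()


def manifest_for(blocks):
    return SessionManifest("P001", Task.CVT,
                           tuple(BlockWindow(i, a, b)
                                 for i, (a, b) in enumerate(blocks)))


class TestEpoching:
    def _pair(self, rng, dur=200.0):
        n = int(dur * FS)
        return ef.BipolarPair(10 * rng.standard_normal(n),
                              10 * rng.standard_normal(n), FS)

    def test_floor_division_of_block_length(self, rng):
        man = manifest_for([(0.0, 90.0)])
        epochs = ef.epoch_signal(self._pair(rng), man, window_s=2.0)
        assert len(epochs) == 45 * 2  # 45 epochs x 2 channels
        assert {e[2] for e in epochs} == {"ch1", "ch2"}

    def test_short_block_keeps_only_full_windows(self, rng):
        man = manifest_for([(0.0, 3.9)])
        epochs = ef.epoch_signal(self._pair(rng, dur=10.0), man, window_s=2.0)
        assert len(epochs) == 1 * 2

    def test_sub_window_block_yields_zero_epochs(self, rng):
        man = manifest_for([(0.0, 1.5)])
        assert ef.epoch_signal(self._pair(rng, dur=10.0), man) == []

    def test_flat_window_dropped(self, rng):
        pair = self._pair(rng, dur=92.0)
        flat = slice(int(10 * FS), int(12 * FS))
        pair.ch1[flat] = 0.0
        man = manifest_for([(0.0, 90.0)])
        epochs = ef.epoch_signal(pair, man, window_s=2.0)
        assert len(epochs) == 44 * 2


class TestBandPowers:
    def test_pure_alpha_tone_concentrates(self):
        a, r = ef.band_powers(sine(10, dur=2.0), FS)
        assert r["alpha"] > 0.95
        assert all(v < 0.05 for b, v in r.items() if b != "alpha")
        # cross-check absolute alpha power against a direct periodogram
        x = sine(10, dur=2.0)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / FS)
        direct = spec[(freqs >= 8) & (freqs < 13)].sum() / spec[freqs >= 0.5].sum()
        assert direct > 0.95

    def test_white_noise_tracks_band_widths(self):
        widths = {b: hi - lo for b, (lo, hi) in ef.BANDS.items()}
        total_width = sum(widths.values())
        sums = {b: 0.0 for b in ef.BANDS}
        n_seeds = 100
        for seed in range(n_seeds):
            x = np.random.default_rng(seed).standard_normal(int(2 * FS))
            a, _ = ef.band_powers(x, FS)
            tot = sum(a[b] * widths[b] for b in a)
            for b in a:
                sums[b] += a[b] * widths[b] / tot
        for b in ef.BANDS:
            expect = widths[b] / total_width
            assert sums[b] / n_seeds == pytest.approx(expect, rel=0.5), b

    def test_relative_powers_normalized(self, rng):
        _, r = ef.band_powers(rng.standard_normal(500), FS)
        assert sum(r.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            ef.band_powers(np.zeros(500), FS)


class TestSampleEntropy:
    def test_constant_signal_is_perfectly_regular(self):
        assert ef.sample_entropy(np.ones(200)) == 0.0

    def test_matches_brute_force_template_counting(self, rng):
        for n in (80, 200, 500, 1000):
            x = rng.uniform(size=n)
            got = ef.sample_entropy(x)
            want = sample_entropy_oracle(x)
            assert got == pytest.approx(want, abs=1e-12)

    def test_noise_more_entropic_than_sine(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(500)
            tone = sine(7, dur=2.0)
            tone = (tone - tone.mean()) / tone.std()
            assert ef.sample_entropy(tone) < ef.sample_entropy(noise)


class TestHiguchiFD:
    def test_straight_line_has_dimension_one(self):
        assert ef.higuchi_fd(np.arange(500.0)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_near_two(self, rng):
        fd = ef.higuchi_fd(rng.standard_normal(2000))
        assert 1.85 <= fd <= 2.05

    def test_matches_plain_loop_oracle(self, rng):
        x = rng.standard_normal(700)
        assert ef.higuchi_fd(x) == pytest.approx(higuchi_fd_oracle(x), abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(600)
        assert ef.higuchi_fd(3.7 * x - 11) == pytest.approx(ef.higuchi_fd(x),
                                                            abs=1e-9)

    def test_constant_signal_undefined(self):
        with pytest.raises(DegenerateSignalError):
            ef.higuchi_fd(np.zeros(500))


class TestHjorth:
    def test_constant_signal_undefined(self):
        with pytest.raises(DegenerateSignalError):
            ef.hjorth(np.full(100, 3.0))

    def test_unit_sine_activity_is_half(self):
        act, _, _ = ef.hjorth(sine(10, dur=10.0))
        assert act == pytest.approx(0.5, rel=0.02)

    def test_complexity_is_squared_mobility(self, rng):
        for _ in range(10):
            x = rng.standard_normal(300)
            _, mob, comp = ef.hjorth(x)
            assert comp == pytest.approx(mob ** 2, rel=1e-12)

    def test_scaling_behaviour(self, rng):
        x = rng.standard_normal(400)
        a1, m1, c1 = ef.hjorth(x)
        a2, m2, c2 = ef.hjorth(5.0 * x)
        assert a2 == pytest.approx(25 * a1, rel=1e-9)
        assert m2 == pytest.approx(m1, rel=1e-9)
        assert c2 == pytest.approx(c1, rel=1e-9)


@pytest.fixture(scope="module")
def session():
    rng = np.random.default_rng(11)
    n = int(130 * FS)
    chans = {c: 10 * rng.standard_normal(n) + 5 * sine(10, 130.0)
             for c in EXPECTED_CHANNELS}
    rec = recording(chans)
    man = manifest_for([(0.0, 60.0), (65.0, 125.0)])
    return rec, man


class TestExtractEpochFeatures:

    def test_row_count_contract(self, session):
        rec, man = session
        rows = ef.extract_epoch_features(rec, man)
        assert len(rows) == 2 * 30 * 2  # blocks x epochs x channels

    def test_rows_satisfy_invariants(self, session):
        rec, man = session
        for row in ef.extract_epoch_features(rec, man):
            f = row.features
            rel = [f[f"rel_{b}"] for b in ef.BANDS]
            assert all(0 <= v <= 1 for v in rel)
            assert sum(rel) == pytest.approx(1.0, abs=1e-6)
            assert f["hjorth_activity"] >= 0
            assert 0.9 <= f["higuchi_fd"] <= 2.1
            assert f["hjorth_complexity"] == pytest.approx(
                f["hjorth_mobility"] ** 2, rel=1e-9)

    def test_deterministic(self, session):
        rec, man = session
        df1 = ef.extract_epoch_features(rec, man)
        df2 = ef.extract_epoch_features(rec, man)
        for r1, r2 in zip(df1, df2):
            assert r1.features == r2.features
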
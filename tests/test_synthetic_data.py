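import filecmp

import numpy as np
import pytest

from stresspipe import ecg_hrv, io_core
from stresspipe.eeg_features import bandpass, band_powers, derive_bipolar
from stresspipe.io_core import BlockWindow, RROrigin, RRSeries
from stresspipe.pipeline import session_eeg_features, session_hrv_features
from stresspipe.synthetic_data import (
    GeneratorConfig,
    SubjectProfile,
    _draw_profile,
    generate_cohort,
    generate_eeg,
    generate_rr,
    generate_stress_trajectory,
)


def tiny_config(**kw):
    base = dict(n_participants=2, n_blocks=6, task="CVT", seed=42)
    base.update(kw)
    return GeneratorConfig(**base)


def two_block_windows(block_s=30.0):
    return [BlockWindow(0, 0.0, block_s), BlockWindow(1, block_s + 3.0,
                                                      2 * block_s + 3.0)]


class TestTrajectory:
    def test_linear_five_blocks(self):
        cfg = tiny_config(n_blocks=5, stress_ramp="linear")
        np.testing.assert_allclose(generate_stress_trajectory(cfg),
                                   [0, 0.25, 0.5, 0.75, 1.0])

    @pytest.mark.parametrize("ramp,center", [
        ("linear", 0.5), ("sigmoid", 0.5), ("sigmoid", 0.8),
    ])
    def test_endpoints_and_monotonicity(self, ramp, center):
        cfg = tiny_config(n_blocks=20, stress_ramp=ramp, ramp_center=center)
        traj = generate_stress_trajectory(cfg)
        assert traj[0] == 0.0 and traj[-1] == pytest.approx(1.0)
        assert (np.diff(traj) >= 0).all()

    def test_late_sigmoid_concentrates_effect_in_terminal_blocks(self):
        cfg = tiny_config(n_blocks=20, stress_ramp="sigmoid",
                          ramp_center=0.8, ramp_steepness=25.0)
        traj = generate_stress_trajectory(cfg)
        assert traj[9] < 0.05       # mid-session still near baseline
        assert traj[-3] > 0.5       # stress confined to the end


def _first_last_rel_power(cfg, seed, band):
    rng = np.random.default_rng(seed)
    windows = two_block_windows()
    profile = _draw_profile(rng, cfg)
    rec = generate_eeg(cfg, np.array([0.0, 1.0]), windows, rng, profile)
    pair = derive_bipolar(bandpass(rec))
    out = []
    for w in windows:
        seg = pair.ch1[int(w.start_s * cfg.fs): int(w.end_s * cfg.fs)]
        _, rel = band_powers(seg, cfg.fs)
        out.append(rel[band])
    return out


class TestGenerateEEG:
    def test_stress_raises_relative_beta(self):
        cfg = tiny_config(stress_effect_eeg=0.5)
        wins = sum(
            _first_last_rel_power(cfg, seed, "beta")[1]
            > _first_last_rel_power(cfg, seed, "beta")[0]
            for seed in range(40)
        )
        assert wins >= 36  # >= 90% of seeds show the injected direction

    def test_null_effect_leaves_alpha_balanced(self):
        cfg = tiny_config(stress_effect_eeg=0.0)
        diffs = []
        for seed in range(40):
            first, last = _first_last_rel_power(cfg, seed, "alpha")
            diffs.append(last - first)
        assert abs(np.mean(diffs)) < 0.02

    def test_fixed_seed_reproducible(self):
        cfg = tiny_config()
        wins = two_block_windows()
        traj = np.array([0.0, 1.0])
        r1 = generate_eeg(cfg, traj, wins, np.random.default_rng(1),
                          _draw_profile(np.random.default_rng(9), cfg))
        r2 = generate_eeg(cfg, traj, wins, np.random.default_rng(1),
                          _draw_profile(np.random.default_rng(9), cfg))
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_flatline_injection_produces_zero_windows(self):
        cfg = tiny_config(flatline_rate=0.3)
        rec = generate_eeg(cfg, np.array([0.0, 1.0]), two_block_windows(),
                           np.random.default_rng(3),
                           _draw_profile(np.random.default_rng(3), cfg))
        win = int(2 * cfg.fs)
        n_windows = rec.n_samples // win
        flat = sum(
            rec.samples[:, w * win:(w + 1) * win].std() == 0.0
            for w in range(n_windows)
        )
        assert flat > 0


class TestGenerateRR:
    def test_nan_injection_rate_within_binomial_band(self):
        cfg = tiny_config(nan_rate=0.05)
        counts = []
        windows = [BlockWindow(0, 0.0, 400.0), BlockWindow(1, 403.0, 803.0)]
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rr, _ = generate_rr(cfg, np.array([0.0, 1.0]), windows, rng,
                                _draw_profile(rng, cfg))
            n = rr.intervals_ms.size
            sigma = np.sqrt(n * 0.05 * 0.95)
            assert abs(rr.n_missing - 0.05 * n) < 3 * sigma
            counts.append(rr.n_missing)
        assert sum(counts) > 0

    def test_stress_shrinks_cleaned_sdnn(self):
        cfg = tiny_config(stress_effect_hrv=0.5)
        windows = [BlockWindow(0, 0.0, 120.0), BlockWindow(1, 123.0, 243.0)]
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            rr, times = generate_rr(cfg, np.array([0.0, 1.0]), windows, rng,
                                    _draw_profile(rng, cfg))
            clean = ecg_hrv.preprocess_rr(rr)
            sdnn = []
            for w in windows:
                sel = (times >= w.start_s) & (times < w.end_s)
                sdnn.append(RRSeries(clean.intervals_ms[sel],
                                     origin=RROrigin.NN))
            f0 = ecg_hrv.compute_hrv_features(sdnn[0]).sdnn
            f1 = ecg_hrv.compute_hrv_features(sdnn[1]).sdnn
            wins += f1 < f0
        assert wins >= 36

    def test_null_series_is_stationary(self):
        cfg = tiny_config(stress_effect_hrv=0.0, nan_rate=0.0,
                          ectopic_rate=0.0)
        windows = [BlockWindow(0, 0.0, 300.0), BlockWindow(1, 303.0, 603.0)]
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rr, times = generate_rr(cfg, np.array([0.0, 1.0]), windows, rng,
                                    _draw_profile(rng, cfg))
            sd = []
            for w in windows:
                sel = (times >= w.start_s) & (times < w.end_s)
                sd.append(rr.intervals_ms[sel].std())
            diffs.append((sd[1] - sd[0]) / sd[0])
        assert abs(np.mean(diffs)) < 0.1


class TestCohort:
    def test_on_disk_layout_complete(self, tmp_path):
        cfg = tiny_config(n_participants=3, n_blocks=4)
        generate_cohort(cfg, out_dir=tmp_path / "cohort")
        dirs = sorted(p.name for p in (tmp_path / "cohort").iterdir())
        assert dirs == ["P001", "P002", "P003"]
        for d in dirs:
            files = {p.name for p in (tmp_path / "cohort" / d).iterdir()}
            assert {"eeg.csv", "rr.txt", "manifest.json", "events.csv",
                    "ground_truth.csv"} <= files

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = tiny_config(n_participants=2, n_blocks=4)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        for sub in ("P001/eeg.csv", "P001/rr.txt", "P001/manifest.json",
                    "P002/events.csv", "P002/ground_truth.csv"):
            assert filecmp.cmp(tmp_path / "a" / sub, tmp_path / "b" / sub,
                               shallow=False), sub

    def test_written_files_parse_through_readers(self, tmp_path):
        cfg = tiny_config(n_participants=1, n_blocks=4)
        sessions = generate_cohort(cfg, out_dir=tmp_path)
        pdir = tmp_path / "P001"
        rr = io_core.read_rr_file(pdir / "rr.txt")
        assert rr.intervals_ms.size == sessions[0].rr.intervals_ms.size
        rec = io_core.read_eeg(pdir / "eeg.csv", "csv")
        assert rec.fs == pytest.approx(cfg.fs)
        man = io_core.read_manifest(pdir / "manifest.json")
        assert man.n_blocks == 4

    def test_sessions_flow_through_both_feature_pipelines(self, small_cohort):
        _, sessions = small_cohort
        eeg = session_eeg_features(sessions[0])
        hrv = session_hrv_features(sessions[0])
        assert not eeg.empty and not hrv.empty
        assert set(eeg["block"]) == set(range(10))
        assert hrv["sdnn"].gt(0).all()
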
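"""Synthetic participant sessions with a controllable stress effect.

The generator emulates the statistical structure the analysis assumes: a
session of task blocks over which the participant drifts from a
"non-stress" regime (block 1) to a "stress" regime (final block). Stress
is encoded as

* EEG — relative beta and gamma band amplitude scaled by
  ``1 + s * stress_effect_eeg`` and alpha by ``1 - s * stress_effect_eeg``,
  plus a broadband noise admixture that grows with stress so signal
  irregularity (sample entropy) rises;
* heart rhythm — R-R variability (SD) scaled by
  ``1 - s * stress_effect_hrv`` and the mean interval mildly shortened
  (heart rate up).

Realistic nuisance structure is injected on top: per-participant baseline
offsets (band profile, amplitude, resting heart rate) so that subject
identity is a strong confound, NaN dropouts and ectopic beats in the R-R
export, and occasional EEG flatline stretches. MMIT sessions get variable
block durations from the closed-loop difficulty controller driven by a
simulated responder; CVT sessions have fixed trial timing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_core import (
    BlockWindow,
    EEGRecording,
    EXPECTED_CHANNELS,
    RRSeries,
    SessionManifest,
    Task,
    write_eeg_csv,
    write_manifest,
    write_rr_file,
)
from .task_engine import SimulatedResponder, events_to_frame, run_session

log = logging.getLogger("stresspipe")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study layout: ~30 blocks of roughly a
    minute each per session, 4-channel forehead EEG, chest-strap R-R
    export with a few percent of dropouts and ectopic beats.
    """

    n_participants: int = 12
    task: str = "MMIT"
    n_blocks: int = 30
    fs: float = 125.0
    stress_effect_eeg: float = 0.5
    stress_effect_hrv: float = 0.5
    stress_ramp: str = "linear"          # "linear" | "sigmoid"
    ramp_center: float = 0.5             # sigmoid midpoint, fraction of session
    ramp_steepness: float = 10.0
    nan_rate: float = 0.02
    ectopic_rate: float = 0.02
    flatline_rate: float = 0.005
    subject_spread: float = 0.2          # lognormal sigma of per-subject offsets
    inter_trial_gap_s: float = 3.0
    inter_block_gap_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nan_rate", "ectopic_rate", "flatline_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_blocks < 4:
            raise ValueError("need at least 4 blocks per session")
        if not (np.isfinite(self.stress_effect_eeg)
                and np.isfinite(self.stress_effect_hrv)):
            raise ValueError("stress effects must be finite")
        if self.stress_ramp not in ("linear", "sigmoid"):
            raise ValueError(f"unknown ramp {self.stress_ramp!r}")


@dataclass
class SubjectProfile:
    """Per-participant baseline offsets (the between-subject confound)."""

    band_mult: dict[str, float]
    amplitude_mult: float
    mean_rr_ms: float
    rr_sd_ms: float
    responder: SimulatedResponder


@dataclass
class SessionData:
    """One complete synthetic participant-task session."""

    participant_id: str
    manifest: SessionManifest
    eeg: EEGRecording
    rr: RRSeries
    rr_times_s: np.ndarray
    events: pd.DataFrame
    trajectory: np.ndarray       # ground-truth per-block stress in [0, 1]
    block_durations_s: list[int] = field(default_factory=list)


#: Baseline band amplitudes in µV RMS before subject/stress modulation.
BASE_BAND_AMPLITUDE = {
    "delta": 10.0, "theta": 6.0, "alpha": 8.0, "beta": 4.0, "gamma": 2.0,
}
BAND_EDGES = {
    "delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0), "gamma": (30.0, 40.0),
}
PINK_AMPLITUDE = 3.0
REGULARITY_NOISE_AMPLITUDE = 1.5   # broadband admixture; scales up with stress
SENSOR_NOISE_AMPLITUDE = 1.0       # independent per-electrode noise


def generate_stress_trajectory(config: GeneratorConfig) -> np.ndarray:
    """Monotone per-block stress level rising from 0 (block 1) to 1 (last).

    Linear ramps are uniform in block index; sigmoid ramps concentrate
    the transition around ``ramp_center`` (so a late, steep ramp confines
    the stress effect to the terminal blocks)."""
    t = np.linspace(0.0, 1.0, config.n_blocks)
    if config.stress_ramp == "linear":
        return t
    raw = 1.0 / (1.0 + np.exp(-config.ramp_steepness * (t - config.ramp_center)))
    return (raw - raw[0]) / (raw[-1] - raw[0])


def _stress_per_sample(
    trajectory: np.ndarray, windows: list[BlockWindow], n: int, fs: float
) -> np.ndarray:
    """Interpolate the block-level stress trajectory onto the sample clock."""
    t = np.arange(n) / fs
    centers = np.array([(w.start_s + w.end_s) / 2 for w in windows])
    return np.interp(t, centers, trajectory)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    sos = sps.butter(4, [lo, min(hi, 0.99 * fs / 2)], btype="bandpass",
                     fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f background via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return (x - x.mean()) / x.std()


def _draw_profile(rng: np.random.Generator, config: GeneratorConfig) -> SubjectProfile:
    s = config.subject_spread
    return SubjectProfile(
        band_mult={b: float(rng.lognormal(0.0, s)) for b in BAND_EDGES},
        amplitude_mult=float(rng.lognormal(0.0, s)),
        mean_rr_ms=float(np.clip(rng.normal(800.0, 80.0), 600.0, 1100.0)),
        rr_sd_ms=float(np.clip(rng.normal(50.0, 10.0), 25.0, 90.0)),
        responder=SimulatedResponder(
            median_rt_s=float(rng.lognormal(np.log(1.5), 0.25)),
            rt_sigma=0.35,
        ),
    )


def generate_eeg(
    config: GeneratorConfig,
    trajectory: np.ndarray,
    windows: list[BlockWindow],
    rng: np.random.Generator,
    profile: SubjectProfile,
    participant_id: str = "",
) -> EEGRecording:
    """Four-channel synthetic EEG whose spectral profile tracks stress.

    The two bipolar derivations (T10-Fp2, T9-Fp1) each carry an
    independent band-structured source; the frontal electrodes carry
    shared reference noise that the bipolar subtraction removes.
    Flatline (signal-loss) stretches are zeroed on all channels at
    ``flatline_rate`` of 2 s windows.
    """
    duration = windows[-1].end_s + 1.0
    n = int(round(duration * config.fs))
    s = _stress_per_sample(trajectory, windows, n, config.fs)
    eff = config.stress_effect_eeg

    sources = []
    for _ in range(2):
        x = np.zeros(n)
        for band, (lo, hi) in BAND_EDGES.items():
            amp = BASE_BAND_AMPLITUDE[band] * profile.band_mult[band]
            if band in ("beta", "gamma"):
                envelope = amp * (1.0 + s * eff)
            elif band == "alpha":
                envelope = amp * np.clip(1.0 - s * eff, 0.05, None)
            else:
                envelope = amp * np.ones(n)
            x += envelope * _band_noise(rng, n, config.fs, lo, hi)
        x += PINK_AMPLITUDE * _pink_noise(rng, n)
        # irregularity channel: broadband noise admixture grows with stress
        x += (REGULARITY_NOISE_AMPLITUDE * (1.0 + 2.0 * s * eff)
              * rng.standard_normal(n))
        sources.append(x * profile.amplitude_mult)

    ref1 = SENSOR_NOISE_AMPLITUDE * rng.standard_normal(n)  # Fp1
    ref2 = SENSOR_NOISE_AMPLITUDE * rng.standard_normal(n)  # Fp2
    channels = {
        "Fp1": ref1,
        "Fp2": ref2,
        "T9": ref1 + sources[1],   # ch2 = T9 - Fp1
        "T10": ref2 + sources[0],  # ch1 = T10 - Fp2
    }
    data = np.vstack([channels[c] for c in EXPECTED_CHANNELS])

    if config.flatline_rate > 0:
        win = int(round(2.0 * config.fs))
        n_windows = n // win
        flat = rng.random(n_windows) < config.flatline_rate
        for w in np.nonzero(flat)[0]:
            data[:, w * win:(w + 1) * win] = 0.0
    return EEGRecording(EXPECTED_CHANNELS, data, config.fs, participant_id)


def generate_rr(
    config: GeneratorConfig,
    trajectory: np.ndarray,
    windows: list[BlockWindow],
    rng: np.random.Generator,
    profile: SubjectProfile,
    participant_id: str = "",
) -> tuple[RRSeries, np.ndarray]:
    """Beat-by-beat R-R series whose variability shrinks under stress.

    Variability combines respiratory (0.25 Hz) and low-frequency (0.1 Hz)
    oscillations with beat-to-beat noise; its SD scales by
    ``1 - s * stress_effect_hrv`` and the mean interval shortens by up to
    10% at full stress. Dropouts (NaN) and ectopic excursions (±30-50% of
    one interval) are injected at the configured rates. Returns the raw
    series and the true time of each interval's terminating beat.
    """
    duration = windows[-1].end_s + 1.0
    centers = np.array([(w.start_s + w.end_s) / 2 for w in windows])
    eff = config.stress_effect_hrv

    intervals: list[float] = []
    times: list[float] = []
    t = 0.0
    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_hf = rng.uniform(0, 2 * np.pi)
    while t < duration:
        s = float(np.interp(t, centers, trajectory))
        mean_nn = profile.mean_rr_ms * (1.0 - 0.10 * s)
        sd = profile.rr_sd_ms * max(1.0 - eff * s, 0.05)
        osc = (0.5 * np.sin(2 * np.pi * 0.25 * t + phase_hf)
               + 0.35 * np.sin(2 * np.pi * 0.10 * t + phase_lf))
        nn = mean_nn + sd * (osc + 0.7 * rng.standard_normal())
        nn = float(np.clip(nn, 350.0, 1900.0))
        recorded = nn
        if rng.random() < config.ectopic_rate:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            recorded = nn * (1.0 + sign * rng.uniform(0.3, 0.5))
        t += nn / 1000.0
        if rng.random() < config.nan_rate:
            recorded = np.nan
        intervals.append(recorded)
        times.append(t)
    rr = RRSeries(np.array(intervals), source_id=participant_id or "synthetic")
    return rr, np.array(times)


def generate_session(
    config: GeneratorConfig,
    participant_id: str,
    seed_seq: np.random.SeedSequence,
) -> SessionData:
    """One complete session: task run, manifest, EEG, R-R, ground truth."""
    rng = np.random.default_rng(seed_seq)
    profile = _draw_profile(rng, config)
    events, raw_windows, durations = run_session(
        config.task, config.n_blocks, rng, responder=profile.responder,
        inter_block_gap_s=config.inter_block_gap_s,
        inter_trial_gap_s=config.inter_trial_gap_s,
    )
    windows = [BlockWindow(i, a, b) for i, (a, b) in enumerate(raw_windows)]
    manifest = SessionManifest(
        participant_id=participant_id, task=Task(config.task), blocks=tuple(windows),
    )
    trajectory = generate_stress_trajectory(config)
    eeg = generate_eeg(config, trajectory, windows, rng, profile, participant_id)
    rr, rr_times = generate_rr(config, trajectory, windows, rng, profile,
                               participant_id)
    return SessionData(
        participant_id=participant_id,
        manifest=manifest,
        eeg=eeg,
        rr=rr,
        rr_times_s=rr_times,
        events=events_to_frame(events),
        trajectory=trajectory,
        block_durations_s=durations,
    )


def generate_cohort(
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
) -> list[SessionData]:
    """Generate the full cohort; optionally write it to disk.

    Each participant gets an independent child of the master seed, so the
    cohort is reproducible as a whole and per participant. With
    ``out_dir`` set, each participant directory receives ``eeg.csv``,
    ``rr.txt``, ``manifest.json``, ``events.csv`` and
    ``ground_truth.csv``, all in the formats the readers consume.
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_participants)
    sessions = []
    for i, child in enumerate(children):
        pid = f"P{i + 1:03d}"
        sessions.append(generate_session(config, pid, child))
    if out_dir is not None:
        write_cohort(sessions, out_dir)
    return sessions


def write_cohort(sessions: list[SessionData], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    for sess in sessions:
        pdir = out_dir / sess.participant_id
        pdir.mkdir(parents=True, exist_ok=True)
        write_eeg_csv(sess.eeg, pdir / "eeg.csv")
        write_rr_file(sess.rr, pdir / "rr.txt")
        write_manifest(sess.manifest, pdir / "manifest.json")
        sess.events.to_csv(pdir / "events.csv", index=False)
        pd.DataFrame({
            "block": np.arange(len(sess.trajectory)),
            "stress_level": np.round(sess.trajectory, 6),
        }).to_csv(pdir / "ground_truth.csv", index=False)
        np.savetxt(pdir / "rr_times_s.txt", sess.rr_times_s, fmt="%.6f")
    log.info("wrote %d participant directories under %s", len(sessions), out_dir)
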
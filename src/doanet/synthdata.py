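"""Synthetic anesthesia "patients" for exercising the index pipeline.

No public recordings exist for this kind of intraoperative dataset, so
this module generates patients with the statistical structure the
pipeline assumes: a latent consciousness trajectory on a 0.2 Hz grid
(100 = fully awake, 0 = deepest anesthesia) that drives

* a 125 Hz single-channel EEG whose per-window irregularity (sample
  entropy) increases with consciousness — awake EEG is modelled as
  band-limited (0.8-32 Hz) noise, deep anesthesia as a slow 1-3 Hz
  oscillation, with a mixing weight linear in the latent state;
* six vital-sign channels (EMG, HR, pulse, SBP, DBP, SQI) at 0.2 Hz,
  each baseline + gain x state + Gaussian noise, clipped to
  physiological ranges — the per-channel gains are the ground truth for
  sensitivity-recovery experiments;
* five noisy clinician ("rater") consciousness scores at 0.2 Hz;
* optional electrosurgical-style artifact bursts: broadband
  high-amplitude interference above the EEG band.

All randomness flows from one per-patient seed expanded into per-stream
``SeedSequence`` children, so adding a channel never perturbs another
and identical seeds give bit-identical patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "LatentTrajectory",
    "SyntheticPatient",
    "ChannelEffect",
    "DEFAULT_EFFECT_PROFILE",
    "generate_trajectory",
    "generate_eeg",
    "generate_vitals",
    "generate_rater_scores",
    "inject_artifact",
    "generate_patient",
    "write_patient_dir",
    "load_patient_dir",
]

FS_EEG = 125.0
WINDOW_S = 5.0
SAMPLES_PER_WINDOW = int(FS_EEG * WINDOW_S)  # 625

VITAL_CHANNELS = ("emg", "hr", "pulse", "sbp", "dbp", "sqi")

# baseline value and physiological clipping range per channel
_CHANNEL_BASELINE = {
    "emg": 5.0,
    "hr": 55.0,
    "pulse": 55.0,
    "sbp": 95.0,
    "dbp": 55.0,
    "sqi": 80.0,
}
_CHANNEL_CLIP = {
    "emg": (0.0, np.inf),
    "hr": (30.0, 180.0),
    "pulse": (30.0, 180.0),
    "sbp": (60.0, 220.0),
    "dbp": (30.0, 130.0),
    "sqi": (0.0, 100.0),
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent substream ``stream`` of the patient seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class LatentTrajectory:
    """Latent consciousness level on the 0.2 Hz grid, in [0, 100]."""

    times: np.ndarray  # seconds, window-end convention (5, 10, ...)
    state: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.state.shape:
            raise ValueError("times and state must have equal length")
        if np.any(self.state < 0) or np.any(self.state > 100):
            raise ValueError("latent state must lie in [0, 100]")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ChannelEffect:
    """Linear effect of the latent state on one vital channel."""

    gain: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# EMG dominant (gain ratio 16x): the study condition for ranking recovery
DEFAULT_EFFECT_PROFILE: dict[str, ChannelEffect] = {
    "emg": ChannelEffect(gain=0.8, noise_sd=2.0),
    "hr": ChannelEffect(gain=0.05, noise_sd=2.0),
    "pulse": ChannelEffect(gain=0.05, noise_sd=2.0),
    "sbp": ChannelEffect(gain=0.05, noise_sd=3.0),
    "dbp": ChannelEffect(gain=0.05, noise_sd=2.0),
    "sqi": ChannelEffect(gain=0.05, noise_sd=3.0),
}


def generate_trajectory(duration_s: float, seed: int) -> LatentTrajectory:
    """Piecewise-smooth consciousness trajectory over a surgical case.

    Awake plateau (>= 80) -> smooth induction ramp -> anesthetized
    maintenance plateau (<= 40) with slow wander -> emergence ramp back
    up.  Needs at least 50 s (10 windows of 5 s).
    """
    if duration_s < 50:
        raise ValueError("duration_s must be >= 50 (at least 10 windows)")
    rng = _rng(seed, 0)
    n = int(duration_s // WINDOW_S)
    t = np.arange(1, n + 1) * WINDOW_S
    u = t / duration_s  # normalized time in (0, 1]

    awake = rng.uniform(85.0, 95.0)
    deep = rng.uniform(15.0, 32.0)
    t_induct = rng.uniform(0.10, 0.20)  # induction midpoint (fraction)
    t_emerge = rng.uniform(0.80, 0.90)  # emergence midpoint
    width = rng.uniform(0.02, 0.04)  # transition half-width

    down = 1.0 / (1.0 + np.exp((u - t_induct) / width))  # 1 awake -> 0 deep
    up = 1.0 / (1.0 + np.exp(-(u - t_emerge) / width))
    level = deep + (awake - deep) * np.clip(down + up, 0.0, 1.0)

    # slow wander on the maintenance plateau: smoothed random walk,
    # damped near the awake segments so plateau guarantees hold
    walk = np.cumsum(rng.normal(0.0, 0.8, size=n))
    kernel = np.ones(7) / 7.0
    wander = np.convolve(walk - walk.mean(), kernel, mode="same")
    wander = 3.0 * wander / max(1.0, np.abs(wander).max())
    level = level + wander * (1.0 - np.clip(down + up, 0.0, 1.0))

    return LatentTrajectory(times=t, state=np.clip(level, 0.0, 100.0))


def _bandpass_sos(low: float, high: float, fs: float = FS_EEG):
    return butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


SLOW_WAVE_MAX_AMPLITUDE = 3.0  # slow-wave RMS at state 0, rel. broadband
HF_FLOOR_AMPLITUDE = 0.4  # above-band noise RMS, rel. broadband
HF_FLOOR_CORNER_HZ = 50.0


def generate_eeg(latent: LatentTrajectory, seed: int) -> np.ndarray:
    """125 Hz EEG whose windowed irregularity tracks the latent state.

    Three components, summed with fixed broadband reference amplitude:

    * broadband: white noise band-passed to 0.8-32 Hz, unit RMS — the
      irregular cortical background;
    * slow wave: a 1-3 Hz oscillation whose amplitude grows linearly as
      consciousness falls, ``3 * (1 - state/100)`` — large regular delta
      activity dominates the record (and the SampEn tolerance, which
      scales with window SD) under deep anesthesia;
    * above-band floor: white noise high-passed at 50 Hz, 0.4 RMS —
      the muscle/instrument noise that occupies IMF 1 in raw
      intraoperative EEG and is the reason the band reconstruction
      starts at IMF 2.

    The floor keeps the IMF index ladder aligned between clean and
    artifact-contaminated windows (an electrosurgical burst joins IMF 1
    instead of inserting a new fastest scale), and guarantees a finite,
    non-silent signal at any state.  Output length is 625 x n windows,
    ~30 uV scale.
    """
    rng = _rng(seed, 1)
    n_win = latent.n
    n_samp = n_win * SAMPLES_PER_WINDOW

    # broadband component generated whole-record so windows join smoothly
    broadband = sosfiltfilt(_bandpass_sos(0.8, 32.0), rng.standard_normal(n_samp))
    broadband /= broadband.std()

    # slow oscillation: per-window frequency 1-3 Hz, continuous phase
    freqs = rng.uniform(1.0, 3.0, size=n_win)
    phase0 = rng.uniform(0.0, 2 * np.pi)
    inst_f = np.repeat(freqs, SAMPLES_PER_WINDOW)
    phase = phase0 + 2 * np.pi * np.cumsum(inst_f) / FS_EEG
    slow = np.sqrt(2.0) * np.sin(phase)  # unit RMS

    hf_sos = butter(4, HF_FLOOR_CORNER_HZ, btype="highpass", fs=FS_EEG, output="sos")
    floor = sosfiltfilt(hf_sos, rng.standard_normal(n_samp))
    floor /= floor.std()

    depth = 1.0 - np.clip(latent.state / 100.0, 0.0, 1.0)
    amp = np.repeat(SLOW_WAVE_MAX_AMPLITUDE * depth, SAMPLES_PER_WINDOW)
    return 30.0 * (broadband + amp * slow + HF_FLOOR_AMPLITUDE * floor)


def generate_vitals(
    latent: LatentTrajectory,
    seed: int,
    effect_profile: dict[str, ChannelEffect] | None = None,
) -> pd.DataFrame:
    """0.2 Hz vital-sign table: baseline + gain x state + noise, clipped.

    ``effect_profile`` must assign a :class:`ChannelEffect` to each of
    EMG, HR, pulse, SBP, DBP, SQI; out-of-range excursions saturate at
    the physiological clip bounds rather than erroring.
    """
    profile = effect_profile if effect_profile is not None else DEFAULT_EFFECT_PROFILE
    missing = set(VITAL_CHANNELS) - set(profile)
    if missing:
        raise ValueError(f"effect_profile missing channels: {sorted(missing)}")
    data = {"time_s": latent.times}
    for k, ch in enumerate(VITAL_CHANNELS):
        eff = profile[ch]
        rng = _rng(seed, 10 + k)  # one substream per channel
        raw = (
            _CHANNEL_BASELINE[ch]
            + eff.gain * latent.state
            + rng.normal(0.0, eff.noise_sd, size=latent.n)
        )
        lo, hi = _CHANNEL_CLIP[ch]
        data[ch] = np.clip(raw, lo, hi)
    return pd.DataFrame(data)


def generate_rater_scores(
    latent: LatentTrajectory,
    seed: int,
    n_raters: int = 5,
    noise_sd: float = 5.0,
) -> pd.DataFrame:
    """Noisy clinician scores: latent + independent N(0, sd), clipped to
    [0, 100]; columns r1..r{n_raters}."""
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    data = {"time_s": latent.times}
    for j in range(n_raters):
        rng = _rng(seed, 100 + j)
        data[f"r{j + 1}"] = np.clip(
            latent.state + rng.normal(0.0, noise_sd, size=latent.n), 0.0, 100.0
        )
    return pd.DataFrame(data)


def inject_artifact(
    eeg: np.ndarray,
    windows: list[int] | np.ndarray,
    amplitude: float = 15.0,
    seed: int = 0,
) -> np.ndarray:
    """Add electrosurgical-style bursts to selected 5 s windows.

    Electrosurgical units switch at hundreds of kHz, far above the EEG
    band; in a 125 Hz-sampled record the interference that survives the
    front end shows up as high-amplitude broadband noise at the top of
    the digital band.  The burst is therefore white noise high-passed
    above 55 Hz (near Nyquist, well outside the 0.8-32 Hz band kept by
    the IMF 2-6 reconstruction), scaled to ``amplitude`` times the clean
    window RMS (>= 10 required).  Untouched windows are bit-identical to
    the input.
    """
    eeg = np.asarray(eeg, dtype=float)
    n_win = eeg.size // SAMPLES_PER_WINDOW
    windows = np.asarray(windows, dtype=int)
    if windows.size and (windows.min() < 0 or windows.max() >= n_win):
        raise IndexError("window index out of range")
    if amplitude < 10.0:
        raise ValueError("amplitude must be >= 10x clean RMS")
    sos = butter(4, 55.0, btype="highpass", fs=FS_EEG, output="sos")
    out = eeg.copy()
    for w in windows:
        rng = _rng(seed, 1000 + int(w))
        burst = sosfiltfilt(sos, rng.standard_normal(SAMPLES_PER_WINDOW))
        burst /= burst.std()
        sl = slice(w * SAMPLES_PER_WINDOW, (w + 1) * SAMPLES_PER_WINDOW)
        clean_rms = float(np.sqrt(np.mean(eeg[sl] ** 2)))
        out[sl] = eeg[sl] + amplitude * clean_rms * burst
    return out


@dataclass
class SyntheticPatient:
    """One generated patient: EEG, vitals, rater scores, latent truth."""

    eeg: np.ndarray
    vitals: pd.DataFrame
    rater_scores: pd.DataFrame
    latent: LatentTrajectory
    seed: int
    artifact_windows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.eeg.size != self.latent.n * SAMPLES_PER_WINDOW:
            raise ValueError("eeg length must be 625 x number of 0.2 Hz samples")


def generate_patient(
    duration_s: float,
    seed: int,
    effect_profile: dict[str, ChannelEffect] | None = None,
    n_raters: int = 5,
    rater_noise_sd: float = 5.0,
    artifact_windows: list[int] | None = None,
    artifact_amplitude: float = 15.0,
) -> SyntheticPatient:
    """Generate a full patient; deterministic given identical arguments."""
    latent = generate_trajectory(duration_s, seed)
    eeg = generate_eeg(latent, seed)
    if artifact_windows:
        eeg = inject_artifact(eeg, artifact_windows, artifact_amplitude, seed)
    return SyntheticPatient(
        eeg=eeg,
        vitals=generate_vitals(latent, seed, effect_profile),
        rater_scores=generate_rater_scores(latent, seed, n_raters, rater_noise_sd),
        latent=latent,
        seed=seed,
        artifact_windows=list(artifact_windows or []),
    )


def write_patient_dir(patient: SyntheticPatient, out_dir: str | Path) -> Path:
    """Write eeg.csv, vitals.csv, raters.csv and meta.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "eeg.csv", patient.eeg, fmt="%.8g")
    patient.vitals.to_csv(out / "vitals.csv", index=False, float_format="%.6f")
    patient.rater_scores.to_csv(out / "raters.csv", index=False, float_format="%.6f")
    meta = {
        "seed": patient.seed,
        "n_windows": patient.latent.n,
        "artifact_windows": patient.artifact_windows,
        "latent_state": [round(float(v), 6) for v in patient.latent.state],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def load_patient_dir(path: str | Path) -> SyntheticPatient:
    """Load a patient previously written by :func:`write_patient_dir`."""
    p = Path(path)
    eeg = np.loadtxt(p / "eeg.csv")
    vitals = pd.read_csv(p / "vitals.csv")
    raters = pd.read_csv(p / "raters.csv")
    meta = json.loads((p / "meta.json").read_text())
    latent = LatentTrajectory(
        times=vitals["time_s"].to_numpy(),
        state=np.asarray(meta["latent_state"], dtype=float),
    )
    return SyntheticPatient(
        eeg=eeg,
        vitals=vitals,
        rater_scores=raters,
        latent=latent,
        seed=int(meta["seed"]),
        artifact_windows=list(meta.get("artifact_windows", [])),
    )
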
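"""Synthetic multichannel EEG with the statistical structure seizure
detection from cross-power features relies on.

Three ingredients are emulated:

* background: per-channel pink (1/f-shaped) broadband noise plus a small
  common-mode component shared by all channels, so baseline cross-power is
  nonzero;
* seizure activity: a band-limited oscillation with slowly drifting
  frequency, added coherently (identical waveform up to a small per-channel
  phase jitter) to a subset of channels — the excessive cross-channel
  synchronization that marks ictal EEG;
* EMG-like artifacts: rare, short, high-amplitude high-pass-shaped bursts on
  one to three channels, which produce impulsive outliers in the cross-power
  matrix.  Bursts are injected into both classes at the same rate, so they
  carry no label information — they are pure nuisance, the regime the
  correntropy loss is built for.

Physiological realism (dipole sources, realistic artifact taxonomy) is out
of scope; only the second-order structure the pipeline consumes is modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rsae.io import NONSEIZURE, SEIZURE, Recording, Segment

#: low-frequency floor of the 1/f shaping filter, Hz (keeps variance finite)
_PINK_FLOOR_HZ = 1.0
#: common-mode amplitude as a fraction of background_amp
_COMMON_MODE_FRAC = 0.2


@dataclass
class SynthConfig:
    """Generator settings.

    Amplitudes are RMS microvolts.  ``seizure_band`` bounds the drifting
    oscillation frequency; ``coupled_fraction`` of the channels carry it.
    ``artifact_rate`` is the expected number of EMG bursts per minute, each
    lasting ``artifact_dur_s`` seconds with peak amplitude
    ``artifact_amp_mult * background_amp`` on 1-3 random channels.
    """

    n_channels: int = 8
    fs: float = 256.0
    background_amp: float = 20.0
    seizure_band: tuple[float, float] = (8.0, 13.0)
    seizure_amp: float = 30.0
    coupled_fraction: float = 0.75
    artifact_rate: float = 3.0
    artifact_amp_mult: float = 20.0
    artifact_dur_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lb, ub = self.seizure_band
        if not (0.0 < lb < ub < self.fs / 2.0):
            raise ValueError(f"seizure_band {self.seizure_band} must satisfy 0 < lb < ub < fs/2")
        if self.background_amp < 0 or self.seizure_amp < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not (0.0 < self.coupled_fraction <= 1.0):
            raise ValueError("coupled_fraction must be in (0, 1]")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")


def _pink_batch(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int, fs: float) -> np.ndarray:
    """Unit-RMS pink noise, shape ``shape + (n_samples,)``, via spectral shaping."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = 1.0 / np.sqrt(np.maximum(freqs, _PINK_FLOOR_HZ))
    gain[0] = 0.0  # remove DC
    x = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _background_batch(config: SynthConfig, n_segments: int, n_samples: int,
                      rng: np.random.Generator) -> np.ndarray:
    """(n_segments, n_channels, n_samples) pink background + common mode."""
    x = _pink_batch(rng, (n_segments, config.n_channels), n_samples, config.fs)
    common = _pink_batch(rng, (n_segments, 1), n_samples, config.fs)
    return config.background_amp * (x + _COMMON_MODE_FRAC * common)


def gen_background(config: SynthConfig, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Background EEG: per-channel pink noise at ``background_amp`` RMS plus
    a shared common-mode component, as a channels x samples matrix."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = round(duration_s * config.fs)
    return _background_batch(config, 1, n, rng)[0]


def _seizure_batch(config: SynthConfig, n_segments: int, n_samples: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Background plus a coherent drifting in-band oscillation per segment."""
    out = _background_batch(config, n_segments, n_samples, rng)
    lb, ub = config.seizure_band
    bw = ub - lb
    t = np.arange(n_samples) / config.fs
    n_coupled = math.ceil(config.coupled_fraction * config.n_channels)
    for k in range(n_segments):
        # slow sinusoidal frequency drift confined to the band
        f_center = rng.uniform(lb + 0.3 * bw, ub - 0.3 * bw)
        drift_rate = rng.uniform(0.05, 0.3)            # Hz of the drift itself
        drift_phase = rng.uniform(0, 2 * np.pi)
        f_inst = f_center + 0.25 * bw * np.sin(2 * np.pi * drift_rate * t + drift_phase)
        phase = 2 * np.pi * np.cumsum(f_inst) / config.fs + rng.uniform(0, 2 * np.pi)
        channels = rng.choice(config.n_channels, size=n_coupled, replace=False)
        jitter = rng.normal(0.0, 0.05, size=n_coupled)  # radians
        wave = np.sin(phase[None, :] + jitter[:, None])
        out[k, channels, :] += config.seizure_amp * math.sqrt(2.0) * wave
    return out


def gen_seizure_activity(config: SynthConfig, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Seizure-like signal: background plus a coherent oscillation of
    ``seizure_amp`` RMS whose frequency drifts slowly inside
    ``seizure_band``, on ``ceil(coupled_fraction * n_channels)`` channels
    with identical phase up to small per-channel jitter."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = round(duration_s * config.fs)
    return _seizure_batch(config, 1, n, rng)[0]


def inject_emg_artifacts(
    data: np.ndarray, config: SynthConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Add Poisson-arriving EMG-like bursts to a copy of ``data``.

    Each burst is high-pass-shaped noise (white noise high-passed at 15 Hz,
    broadband like surface EMG, so it contaminates beta-band cross-power)
    under a Hann envelope, peak-normalized to
    ``artifact_amp_mult * background_amp`` and added to 1-3 randomly chosen
    channels.  Returns the modified copy and a log of events for test
    introspection.
    """
    from scipy import signal as _signal
    data = np.array(data, dtype=float)
    n_channels, n_samples = data.shape
    duration_s = n_samples / config.fs
    n_events = rng.poisson(config.artifact_rate * duration_s / 60.0)
    burst_len = max(4, round(config.artifact_dur_s * config.fs))
    log: list[dict] = []
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, n_samples - burst_len)))
        n_hit = int(rng.integers(1, min(3, n_channels) + 1))
        channels = rng.choice(n_channels, size=n_hit, replace=False)
        amp = config.artifact_amp_mult * config.background_amp
        sos = _signal.butter(4, 15.0, btype="highpass", fs=config.fs, output="sos")
        # one source waveform per event: the same burst couples into every
        # hit channel (per-channel gain), so burst cross-power is coherent
        noise = _signal.sosfiltfilt(sos, rng.standard_normal(burst_len))
        noise *= np.hanning(burst_len)
        peak = np.max(np.abs(noise))
        if peak > 0:
            noise *= amp / peak
        gains = rng.uniform(0.7, 1.0, size=n_hit)
        for ch, gain in zip(channels, gains):
            data[ch, start:start + burst_len] += gain * noise
        log.append({"start_sample": start, "n_samples": burst_len,
                    "channels": sorted(int(c) for c in channels), "amplitude": amp})
    return data, log


def make_labeled_dataset(
    config: SynthConfig,
    n_seizure: int = 1000,
    n_nonseizure: int = 4000,
    window_s: float = 5.0,
    chunk: int = 500,
) -> list[Segment]:
    """Generate exactly ``n_seizure`` + ``n_nonseizure`` labeled windows.

    Seizure windows come from :func:`gen_seizure_activity`, nonseizure from
    :func:`gen_background`; both classes receive EMG bursts at the same
    ``artifact_rate``, so bursts alone carry no class signal.  The list is
    shuffled deterministically from ``config.seed``.
    """
    if n_seizure <= 0 or n_nonseizure <= 0:
        raise ValueError("requested segment counts must be positive")
    rng = np.random.default_rng(config.seed)
    L = round(window_s * config.fs)
    segments: list[Segment] = []
    for label, count, batch_fn in ((SEIZURE, n_seizure, _seizure_batch),
                                   (NONSEIZURE, n_nonseizure, _background_batch)):
        done = 0
        while done < count:
            b = min(chunk, count - done)
            block = batch_fn(config, b, L, rng)
            for k in range(b):
                data = block[k]
                if config.artifact_rate > 0:
                    data, _ = inject_emg_artifacts(data, config, rng)
                segments.append(Segment(data=data, label=label, start_s=0.0))
            done += b
    order = rng.permutation(len(segments))
    return [segments[i] for i in order]


def gen_recording(
    config: SynthConfig,
    duration_s: float,
    seizure_intervals: Sequence[tuple[float, float]],
    rng: np.random.Generator | None = None,
) -> Recording:
    """One continuous annotated recording: background everywhere, seizure
    oscillation inside the given intervals, artifacts throughout."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    data = gen_background(config, duration_s, rng)
    for a, b in seizure_intervals:
        seg = gen_seizure_activity(config, b - a, rng)
        i0, i1 = round(a * config.fs), round(a * config.fs) + seg.shape[1]
        data[:, i0:i1] = seg
    if config.artifact_rate > 0:
        data, _ = inject_emg_artifacts(data, config, rng)
    return Recording(data=data, fs=config.fs,
                     seizure_intervals=[tuple(iv) for iv in seizure_intervals])


def config_to_text(config: SynthConfig) -> str:
    """Serialize a SynthConfig as a flat key=value block."""
    lines = []
    for key, val in vars(config).items():
        if isinstance(val, tuple):
            val = ",".join(str(v) for v in val)
        lines.append(f"{key}={val}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> SynthConfig:
    kwargs: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        val = val.strip()
        if key == "seizure_band":
            lb, ub = val.split(",")
            kwargs[key] = (float(lb), float(ub))
        elif key in ("n_channels", "seed"):
            kwargs[key] = int(val)
        else:
            kwargs[key] = float(val)
    return SynthConfig(**kwargs)
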
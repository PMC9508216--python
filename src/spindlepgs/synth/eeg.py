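"""Synthetic NREM EEG: 1/f background noise with Hann-windowed sigma bursts.

The generator plants spindle-like oscillatory bursts of known onset,
duration, frequency and amplitude into coloured noise, so detector output can
be scored against an exact event list. Bursts are Hann-tapered sinusoids — a
smooth waxing/waning envelope resembling real spindle morphology — placed by
rejection sampling with a 1-s refractory gap so ground-truth events never
merge. Background is 1/f (alpha = 1) noise plus a white floor, the standard
EEG surrogate, which puts realistic low-frequency power under the sigma band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import EPOCH_LENGTH_S, EEGRecording, Hypnogram

#: Canonical sigma sub-bands (Hz): slow and fast spindles.
BANDS: dict[str, tuple[float, float]] = {"slow": (9.0, 12.0), "fast": (12.0, 15.0)}

#: Event-duration limits (s) shared with the detector.
MIN_DURATION_S = 0.5
MAX_DURATION_S = 3.0

REFRACTORY_GAP_S = 1.0


@dataclass
class SpindleGroundTruth:
    """Planted events: (onset_s, duration_s, frequency_hz, amplitude_uv)."""

    events: list[tuple[float, float, float, float]]
    target_density: float  # events per 30-s epoch

    def __post_init__(self) -> None:
        for onset, dur, freq, amp in self.events:
            if not (MIN_DURATION_S <= dur <= MAX_DURATION_S):
                raise ValueError(f"duration {dur} outside [0.5, 3.0] s")
            if amp <= 0:
                raise ValueError("amplitude must be positive")
        ends = sorted((o, o + d) for o, d, _, _ in self.events)
        for (_, e1), (o2, _) in zip(ends, ends[1:]):
            if o2 < e1:
                raise ValueError("ground-truth events overlap")

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class NoiseProfile:
    """Background composition (RMS microvolts per component)."""

    pink_rms_uv: float = 10.0
    white_rms_uv: float = 2.0

    def __post_init__(self) -> None:
        if self.pink_rms_uv < 0 or self.white_rms_uv < 0:
            raise ValueError("noise levels must be non-negative")
        if self.pink_rms_uv == 0 and self.white_rms_uv == 0:
            raise ValueError("at least one noise component must be positive")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^1 (power) noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid div-by-zero at DC; DC amplitude irrelevant
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _place_events(
    duration_s: float,
    durations: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Rejection-sample non-overlapping onsets with a refractory gap."""
    onsets: list[float] = []
    intervals: list[tuple[float, float]] = []
    for dur in durations:
        for _ in range(max_tries):
            onset = rng.uniform(0.0, duration_s - dur)
            lo, hi = onset - REFRACTORY_GAP_S, onset + dur + REFRACTORY_GAP_S
            if all(hi <= a or lo >= b for a, b in intervals):
                onsets.append(onset)
                intervals.append((onset, onset + dur))
                break
        else:
            raise ValueError(
                "could not place events without overlap; density too high"
            )
    return np.asarray(onsets)


def simulate_eeg(
    duration_s: float,
    sampling_rate_hz: float = 256.0,
    band: str = "fast",
    truth_density: float = 2.22,
    amplitude_uv: float = 27.56,
    noise_profile: NoiseProfile | None = None,
    seed: int = 0,
    duration_mean_s: float = 0.82,
    duration_sd_s: float = 0.05,
    frequency_sd_hz: float = 0.25,
    stages: list[str] | None = None,
    artifact_flags: np.ndarray | None = None,
) -> tuple[EEGRecording, Hypnogram, SpindleGroundTruth]:
    """Generate one NREM recording with planted spindles.

    Parameters mirror the population the detector is meant for: 256 Hz
    sampling, fast (12-15 Hz) or slow (9-12 Hz) sigma band, burst durations
    around 0.82 s, densities around 2.2 per 30-s epoch, peak amplitudes
    around 28 microvolts. Event count is Poisson with mean
    ``truth_density * n_epochs``; events are Hann-windowed sinusoids at a
    band-internal frequency.

    Returns the recording, a hypnogram (all N2 unless ``stages`` given), and
    the exact ground-truth event list.
    """
    if duration_s <= 0 or duration_s % EPOCH_LENGTH_S != 0:
        raise ValueError("duration must be a positive multiple of 30 s")
    if band not in BANDS:
        raise ValueError(f"band must be one of {sorted(BANDS)}")
    if amplitude_uv <= 0:
        raise ValueError("amplitude must be positive")
    if truth_density < 0:
        raise ValueError("density must be non-negative")
    noise_profile = noise_profile or NoiseProfile()

    rng = np.random.default_rng(seed)
    n_epochs = int(duration_s / EPOCH_LENGTH_S)
    n_samples = int(round(duration_s * sampling_rate_hz))
    lo, hi = BANDS[band]
    center = 13.46 if band == "fast" else 10.84  # typical cohort peaks

    signal = noise_profile.pink_rms_uv * _pink_noise(n_samples, rng)
    if noise_profile.white_rms_uv > 0:
        signal = signal + noise_profile.white_rms_uv * rng.standard_normal(n_samples)

    n_events = int(rng.poisson(truth_density * n_epochs))
    events: list[tuple[float, float, float, float]] = []
    if n_events > 0:
        durs = np.clip(
            rng.normal(duration_mean_s, duration_sd_s, n_events),
            MIN_DURATION_S,
            MAX_DURATION_S,
        )
        # sanity bound before rejection sampling
        if np.sum(durs + REFRACTORY_GAP_S) > 0.8 * duration_s:
            raise ValueError("density too high: events cannot fit without overlap")
        freqs = np.clip(
            rng.normal(center, frequency_sd_hz, n_events), lo + 0.1, hi - 0.1
        )
        amps = amplitude_uv * np.exp(rng.normal(0.0, 0.05, n_events))
        onsets = _place_events(duration_s, durs, rng)
        order = np.argsort(onsets)
        for k in order:
            onset, dur, freq, amp = onsets[k], durs[k], freqs[k], amps[k]
            i0 = int(round(onset * sampling_rate_hz))
            n_burst = int(round(dur * sampling_rate_hz))
            t = np.arange(n_burst) / sampling_rate_hz
            burst = amp * np.hanning(n_burst) * np.sin(
                2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
            )
            signal[i0 : i0 + n_burst] += burst
            events.append((float(onset), float(dur), float(freq), float(amp)))

    rec = EEGRecording(signal, sampling_rate_hz)
    if stages is None:
        stages = ["N2"] * n_epochs
    if artifact_flags is None:
        artifact_flags = np.zeros(n_epochs, dtype=bool)
    hyp = Hypnogram(stages, artifact_flags)
    truth = SpindleGroundTruth(events, truth_density)
    return rec, hyp, truth
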
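"""Individually-adapted sleep spindle detection from NREM EEG.

The detector follows the peak-adaptive scheme used in quantitative sleep
EEG work:

1. Average the power spectrum over all artifact-free N2/N3 epochs.
2. Locate the subject's own spindle peak within the fast (12-15 Hz) or slow
   (9-12 Hz) sigma band as the most prominent local maximum of the smoothed
   spectrum above a fitted 1/f background. Subjects without a detectable
   peak (common for the slow band) are *excluded* from that band's analysis
   rather than scored as zero.
3. Band-pass filter +/- 1.5 Hz around the individual peak (zero-phase
   Butterworth), compute the RMS of the filtered signal in consecutive
   200-ms windows, and call an event wherever the RMS exceeds 1.5 standard
   deviations of the filtered signal for 0.5-3 s.

Density is events per included 30-s epoch; duration is the interval between
threshold crossings (the RMS series is a step function, so durations are
multiples of the RMS window); amplitude is the maximal absolute filtered
voltage within the event.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth.eeg import BANDS
from .types import (
    EPOCH_LENGTH_S,
    EEGRecording,
    Hypnogram,
    SpindleEvent,
    SpindlePeak,
    SpindleSummary,
)


class NoNREMDataError(ValueError):
    """Raised when a recording has no artifact-free N2/N3 epochs."""


class AbsentPeakError(ValueError):
    """Raised when event detection is attempted without a spectral peak."""


def _epoch_slices(hypnogram: Hypnogram, fs: float) -> list[tuple[int, int, int]]:
    spe = int(round(EPOCH_LENGTH_S * fs))
    return [(e, e * spe, (e + 1) * spe) for e in hypnogram.included_epochs()]


def nrem_power_spectrum(
    recording: EEGRecording, hypnogram: Hypnogram, resolution_hz: float = 0.25
) -> pd.DataFrame:
    """Welch power spectral density averaged over included N2/N3 epochs.

    Returns a DataFrame with columns ``frequency`` (Hz, resolution
    <= ``resolution_hz``) and ``power`` (uV^2/Hz), covering 0 to Nyquist.
    """
    fs = recording.sampling_rate
    slices = _epoch_slices(hypnogram, fs)
    if not slices:
        raise NoNREMDataError("no artifact-free N2/N3 epochs in recording")
    n_available = min(e - s for _, s, e in slices)
    nperseg = min(int(round(fs / resolution_hz)), n_available)
    psds = []
    for _, s, e in slices:
        f, pxx = sps.welch(recording.samples[s:e], fs=fs, nperseg=nperseg)
        psds.append(pxx)
    return pd.DataFrame({"frequency": f, "power": np.mean(psds, axis=0)})


def find_spindle_peak(
    spectrum: pd.DataFrame,
    band: str,
    prominence_ratio: float = 1.10,
    smooth_hz: float = 0.5,
    fit_range_hz: tuple[float, float] = (4.0, 20.0),
) -> SpindlePeak:
    """Locate the individual spindle peak within a sigma sub-band.

    The smoothed spectrum is compared against a log-log linear (1/f-like)
    background fitted over ``fit_range_hz`` excluding the sigma band; the
    most prominent in-band local maximum whose power exceeds
    ``prominence_ratio`` times the background is returned. An absent peak is
    a legal outcome (``peak_frequency_hz is None``).
    """
    if band not in BANDS:
        raise ValueError(f"band must be one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    f = spectrum["frequency"].to_numpy()
    p = spectrum["power"].to_numpy()
    if f.min() > lo - 1.0 or f.max() < hi + 1.0:
        raise ValueError("spectrum does not cover the band plus margins")

    df = np.median(np.diff(f))
    win = max(1, int(round(smooth_hz / df)))
    kernel = np.ones(win) / win
    p_smooth = np.convolve(p, kernel, mode="same")

    # log-log background fit outside all sigma bands
    fit_lo, fit_hi = fit_range_hz
    sigma_lo, sigma_hi = 9.0, 16.0
    mask = (f >= fit_lo) & (f <= fit_hi) & ((f < sigma_lo) | (f > sigma_hi)) & (f > 0)
    if mask.sum() < 4:
        raise ValueError("spectrum too short to fit a background")
    slope, intercept = np.polyfit(np.log(f[mask]), np.log(p_smooth[mask]), 1)
    background = np.exp(intercept + slope * np.log(np.maximum(f, df)))

    in_band = (f >= lo) & (f <= hi)
    ratio = np.where(background > 0, p_smooth / background, 0.0)
    idx = np.flatnonzero(in_band)
    # local maxima of the smoothed spectrum inside the band
    peaks, _ = sps.find_peaks(p_smooth[idx[0] - 1 : idx[-1] + 2])
    peaks = peaks + idx[0] - 1
    peaks = [k for k in peaks if in_band[k] and ratio[k] >= prominence_ratio]
    if not peaks:
        return SpindlePeak(band, None, float(ratio[in_band].max()))
    best = max(peaks, key=lambda k: ratio[k])
    return SpindlePeak(band, float(f[best]), float(ratio[best]))


def bandpass_filter(
    samples: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (filtfilt; order per pass)."""
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, samples)


def rms_series(
    samples: np.ndarray, fs: float, window_s: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """RMS over consecutive non-overlapping windows.

    Window boundaries are placed at ``round(i * fs * window_s)`` samples so
    the grid exactly tiles the recording even when ``fs * window_s`` is not
    an integer (e.g. 51.2 samples at 256 Hz). Returns (rms, onset_times_s).
    """
    n = samples.size
    n_win = int(np.floor(n / (fs * window_s) + 1e-9))
    bounds = np.round(np.arange(n_win + 1) * fs * window_s).astype(int)
    rms = np.array(
        [np.sqrt(np.mean(samples[bounds[i] : bounds[i + 1]] ** 2)) for i in range(n_win)]
    )
    return rms, bounds[:-1] / fs


def detect_spindle_events(
    recording: EEGRecording,
    hypnogram: Hypnogram,
    peak: SpindlePeak,
    halfwidth_hz: float = 1.5,
    rms_window_s: float = 0.2,
    threshold_sd: float = 1.5,
    min_dur_s: float = 0.5,
    max_dur_s: float = 3.0,
    threshold_on: str = "filtered",
) -> list[SpindleEvent]:
    """Detect spindle events around an individual's spectral peak.

    ``threshold_on`` selects what the 1.5-SD threshold is computed from:
    ``"filtered"`` (default) uses the SD of the band-passed signal over
    included epochs; ``"rms"`` uses mean + SD of the RMS series instead.
    Runs longer than ``max_dur_s`` are discarded entirely, and events whose
    span touches an excluded epoch are dropped.
    """
    if not peak.present:
        raise AbsentPeakError(
            f"no {peak.band} spindle peak; subject excluded from this band"
        )
    if not (halfwidth_hz > 0 and rms_window_s > 0 and threshold_sd > 0):
        raise ValueError("detector parameters must be positive")
    if not (0 < min_dur_s < max_dur_s):
        raise ValueError("need 0 < min_dur_s < max_dur_s")
    fs = recording.sampling_rate
    if recording.samples.size < int(round(EPOCH_LENGTH_S * fs)):
        raise ValueError("recording shorter than one 30-s epoch")
    slices = _epoch_slices(hypnogram, fs)
    if not slices:
        raise NoNREMDataError("no artifact-free N2/N3 epochs in recording")

    filt = bandpass_filter(
        recording.samples, fs, peak.peak_frequency_hz - halfwidth_hz,
        peak.peak_frequency_hz + halfwidth_hz,
    )
    included_mask = np.zeros(recording.samples.size, dtype=bool)
    for _, s, e in slices:
        included_mask[s:e] = True

    rms, t_win = rms_series(filt, fs, rms_window_s)
    if threshold_on == "filtered":
        threshold = threshold_sd * filt[included_mask].std()
    elif threshold_on == "rms":
        rin = rms[np.isin(
            np.floor(t_win / EPOCH_LENGTH_S).astype(int),
            hypnogram.included_epochs(),
        )]
        threshold = rin.mean() + threshold_sd * rin.std()
    else:
        raise ValueError("threshold_on must be 'filtered' or 'rms'")

    events = events_from_rms(
        rms, t_win, filt, fs, threshold, hypnogram,
        rms_window_s=rms_window_s, min_dur_s=min_dur_s, max_dur_s=max_dur_s,
    )
    return events


def events_from_rms(
    rms: np.ndarray,
    t_win: np.ndarray,
    filt: np.ndarray,
    fs: float,
    threshold: float,
    hypnogram: Hypnogram,
    rms_window_s: float = 0.2,
    min_dur_s: float = 0.5,
    max_dur_s: float = 3.0,
) -> list[SpindleEvent]:
    """Turn a supra-threshold RMS step function into spindle events.

    A run of consecutive windows with RMS > threshold becomes an event if
    its step-function duration lies in [min_dur_s, max_dur_s]; longer runs
    are discarded. The event belongs to the epoch containing its onset, and
    every epoch it touches must be an included N2/N3 artifact-free epoch.
    """
    included = set(hypnogram.included_epochs().tolist())
    above = rms > threshold
    events: list[SpindleEvent] = []
    # run-length boundaries of the boolean series
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    for s_win, e_win in zip(starts, ends):
        onset = t_win[s_win]
        duration = (e_win - s_win) * rms_window_s
        if duration < min_dur_s or duration > max_dur_s:
            continue
        # each RMS window lies entirely within one epoch (the window grid
        # tiles each 30-s epoch exactly), so the touched epochs are those of
        # the run's member windows
        touched = {int(t_win[k] // EPOCH_LENGTH_S) for k in range(s_win, e_win)}
        first_epoch = min(touched)
        if any(e not in included for e in touched):
            continue
        i0 = int(round(onset * fs))
        i1 = int(round((onset + duration) * fs))
        amplitude = float(np.abs(filt[i0:i1]).max())
        events.append(
            SpindleEvent(
                onset_s=float(onset),
                duration_s=float(duration),
                amplitude_uv=amplitude,
                epoch_index=first_epoch,
            )
        )
    return events


def summarize_spindles(
    events: list[SpindleEvent],
    hypnogram: Hypnogram,
    peak: SpindlePeak | None = None,
) -> SpindleSummary:
    """Per-subject density and morphology over included epochs."""
    n_included = int(hypnogram.included_epochs().size)
    if n_included == 0:
        raise NoNREMDataError("zero included epochs; density undefined")
    n_events = len(events)
    return SpindleSummary(
        density=n_events / n_included,
        mean_duration_s=(
            float(np.mean([e.duration_s for e in events])) if n_events else None
        ),
        mean_amplitude_uv=(
            float(np.mean([e.amplitude_uv for e in events])) if n_events else None
        ),
        peak_frequency_hz=peak.peak_frequency_hz if peak is not None else None,
        n_epochs_included=n_included,
        n_events=n_events,
    )


def events_to_frame(events: list[SpindleEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_s": [e.onset_s for e in events],
            "duration_s": [e.duration_s for e in events],
            "amplitude_uv": [e.amplitude_uv for e in events],
            "epoch_index": [e.epoch_index for e in events],
        }
    )
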
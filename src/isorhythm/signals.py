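"""Preprocessing chains that turn field recordings into tempo spectrograms.

Two pipelines, mirroring how the firefly and cricket recordings are
processed:

* flash counts (video-derived, 29.97 frames/s): Savitzky-Golay smoothing
  (order 2, frame 9), mean subtraction, spectrogram;
* audio: high-pass filter (5 kHz cutoff), analytic-signal magnitude with a
  sliding-window peak envelope (3,000 samples ~ 68 ms at 44.1 kHz), mean
  subtraction, down-sampling, spectrogram.

The dominant tempo is the frequency of maximal time-averaged spectral
power within a band of interest (default 0.25-10 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.io import wavfile

__all__ = [
    "SampledSeries",
    "SpectrogramResult",
    "preprocess_flash_counts",
    "preprocess_audio",
    "spectrogram",
    "dominant_tempo",
    "downsample",
    "flash_series_tempo",
    "audio_series_tempo",
    "read_wav",
    "write_wav",
]

VIDEO_FPS = 29.97


@dataclass(frozen=True)
class SampledSeries:
    """A uniformly sampled real-valued signal."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a nonempty 1-d array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "values", values)

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass(frozen=True)
class SpectrogramResult:
    """Short-time power spectrum: ``power[t, f]`` in dB/Hz."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.times), len(self.freqs)):
            raise ValueError("power must be time x freq")
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0:
            raise ValueError("freqs must be nonnegative ascending")


def preprocess_flash_counts(series: SampledSeries, window: int = 9, order: int = 2) -> SampledSeries:
    """Savitzky-Golay smoothing followed by mean subtraction.

    The order-2, frame-9 filter leaves locally quadratic structure intact
    while knocking down frame noise in the summed flash counts.
    """
    if series.values.size < window:
        raise ValueError(f"series shorter than the {window}-sample filter frame")
    smoothed = signal.savgol_filter(series.values, window_length=window, polyorder=order)
    return SampledSeries(values=smoothed - smoothed.mean(), rate=series.rate)


def preprocess_audio(
    series: SampledSeries, cutoff: float = 5000.0, env_window: int = 3000
) -> SampledSeries:
    """High-pass, analytic-signal magnitude, sliding peak envelope, mean removal.

    The high-pass isolates the call's carrier band; the envelope tracks its
    slow amplitude modulation, which carries the tempo.  A 4th-order
    Butterworth filter is applied forward-backward (zero phase).
    """
    if series.rate <= 2 * cutoff:
        raise ValueError(
            f"sample rate {series.rate} too low for a {cutoff} Hz high-pass"
        )
    if series.values.size <= env_window:
        raise ValueError("series must be longer than the envelope window")
    sos = signal.butter(4, cutoff, btype="highpass", fs=series.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, series.values)
    magnitude = np.abs(signal.hilbert(filtered))
    envelope = ndimage.maximum_filter1d(magnitude, size=env_window, mode="nearest")
    return SampledSeries(values=envelope - envelope.mean(), rate=series.rate)


def downsample(series: SampledSeries, target_rate: float = 150.0) -> SampledSeries:
    """Polyphase down-sampling to at most ``target_rate`` samples/s.

    Keeps the 0-10 Hz tempo band well resolved while making the tempo
    spectrogram cheap; no-op when the series is already slow enough.
    """
    factor = int(series.rate // target_rate)
    if factor <= 1:
        return series
    values = signal.resample_poly(series.values, 1, factor)
    return SampledSeries(values=values, rate=series.rate / factor)


def spectrogram(series: SampledSeries, window_samples: int) -> SpectrogramResult:
    """One-sided short-time power spectrum in dB (Hann window, 50% overlap)."""
    if window_samples > series.values.size:
        raise ValueError("window longer than the series")
    freqs, times, sxx = signal.spectrogram(
        series.values,
        fs=series.rate,
        window="hann",
        nperseg=window_samples,
        noverlap=window_samples // 2,
        scaling="density",
        mode="psd",
    )
    power_db = 10.0 * np.log10(sxx + np.finfo(float).tiny)
    return SpectrogramResult(times=times, freqs=freqs, power=power_db.T)


def dominant_tempo(spec: SpectrogramResult, band: tuple[float, float] = (0.25, 10.0)) -> float:
    """Frequency of maximal time-averaged power within ``band`` (Hz).

    Powers are averaged in linear units before the maximum is taken.
    """
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the frequency axis")
    linear = 10.0 ** (spec.power / 10.0)
    mean_power = linear.mean(axis=0)
    band_freqs = spec.freqs[mask]
    return float(band_freqs[int(np.argmax(mean_power[mask]))])


def flash_series_tempo(
    series: SampledSeries,
    window_samples: int = 100,
    band: tuple[float, float] = (0.25, 10.0),
) -> float:
    """Dominant tempo of a flash-count series after the standard chain.

    The default 100-sample window is 3.34 s at 29.97 frames/s, giving a
    ~0.3 Hz frequency resolution.
    """
    pre = preprocess_flash_counts(series)
    return dominant_tempo(spectrogram(pre, window_samples), band)


def audio_series_tempo(
    series: SampledSeries,
    cutoff: float = 5000.0,
    env_window: int = 3000,
    window_seconds: float = 8.0,
    band: tuple[float, float] = (0.25, 10.0),
) -> float:
    """Dominant chirp tempo of an audio recording after the standard chain."""
    env = downsample(preprocess_audio(series, cutoff, env_window))
    window = min(int(round(window_seconds * env.rate)), env.values.size)
    return dominant_tempo(spectrogram(env, window), band)


def read_wav(path) -> SampledSeries:
    """Read a PCM or float WAV file into a mono SampledSeries."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return SampledSeries(values=data.astype(float), rate=float(rate))


def write_wav(path, series: SampledSeries) -> None:
    wavfile.write(path, int(round(series.rate)), series.values.astype(np.float32))
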
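"""Seeded generators for every input the analysis consumes.

These emulate, with controllable statistics, the kinds of data the
pipelines were designed for: near-isochronous event trains with Gaussian
IOI jitter, cross-species tempo samples from the fitted log-normal,
group-level firefly flash-count series at video frame rate, and
amplitude-modulated high-carrier audio mimicking cricket chirps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import SampledSeries, VIDEO_FPS
from .tempo_stats import EventTrain

__all__ = [
    "EventTrainSpec",
    "generate_event_train",
    "sample_tempos",
    "synth_flash_series",
    "synth_chirp_audio",
    "write_event_csv",
    "write_flash_csv",
]


@dataclass(frozen=True)
class EventTrainSpec:
    """Specification of a jittered isochronous event train.

    ``jitter_cv`` is the coefficient of variation of the IOIs: intervals
    are drawn i.i.d. Normal(1/tempo, (jitter_cv/tempo)^2), truncated to
    positive values.
    """

    tempo: float
    n_events: int
    jitter_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tempo <= 0:
            raise ValueError("tempo must be positive")
        if self.n_events < 2:
            raise ValueError("need at least two events")
        if not 0 <= self.jitter_cv < 1:
            raise ValueError("jitter_cv must be in [0, 1)")


def generate_event_train(spec: EventTrainSpec) -> EventTrain:
    """Event train with Gaussian-jittered IOIs around 1/tempo, seeded."""
    rng = np.random.default_rng(spec.seed)
    mean = 1.0 / spec.tempo
    sd = spec.jitter_cv * mean
    n_iois = spec.n_events - 1
    if sd == 0:
        iois = np.full(n_iois, mean)
    else:
        iois = rng.normal(mean, sd, size=n_iois)
        while np.any(iois <= 0):  # truncate to positive by redrawing
            bad = iois <= 0
            iois[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    onsets = np.concatenate([[0.0], np.cumsum(iois)])
    return EventTrain(onsets=onsets)


def sample_tempos(
    n: int, mu_ln: float = 1.1, sigma_ln: float = 0.90, seed: int = 0
) -> np.ndarray:
    """Log-normally distributed tempo sample: exp of Normal(mu_ln, sigma_ln^2) draws.

    Defaults are the fitted cross-species parameters (median exp(1.1) ~ 3 Hz).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(mu_ln, sigma_ln, size=n))


def synth_flash_series(
    tempo: float,
    duration: float,
    fps: float = VIDEO_FPS,
    n_individuals: int = 21,
    noise_sd: float = 0.2,
    flash_frames: int = 2,
    phase_jitter_s: float = 0.05,
    seed: int = 0,
) -> SampledSeries:
    """Per-frame flash counts of a group of synchronously flashing individuals.

    Each individual flashes periodically at the common tempo for
    ``flash_frames`` frames per cycle, offset from the group phase by a
    Gaussian timing scatter (sd ``phase_jitter_s``) — the emulated swarm is
    synchronized, so offsets are small rather than uniform over the cycle.
    Counts are the sum over individuals plus Gaussian noise, clipped at 0.
    """
    n_frames = int(round(duration * fps))
    period = 1.0 / tempo
    if n_frames < 2 * period * fps:
        raise ValueError("duration must cover at least two flash periods")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    flash_len = flash_frames / fps
    counts = np.zeros(n_frames)
    offsets = rng.normal(0.0, phase_jitter_s, size=n_individuals)
    for off in offsets:
        counts += (np.mod(t - off, period) < flash_len).astype(float)
    if noise_sd > 0:
        counts += rng.normal(0.0, noise_sd, size=n_frames)
    return SampledSeries(values=np.clip(counts, 0.0, None), rate=fps)


def synth_chirp_audio(
    tempo: float,
    duration: float,
    carrier: float = 8000.0,
    rate: float = 44100.0,
    duty: float = 0.3,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SampledSeries:
    """Carrier tone gated on/off at the chirp tempo, plus broadband noise.

    ``duty`` is the on fraction of each chirp cycle; ``duty=1`` degenerates
    to an unmodulated tone.
    """
    if rate <= 2 * carrier:
        raise ValueError("carrier must be below the Nyquist frequency")
    if not 0 < duty <= 1:
        raise ValueError("duty must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    gate = np.mod(t, 1.0 / tempo) < duty / tempo
    values = gate * np.sin(2.0 * np.pi * carrier * t)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    return SampledSeries(values=values, rate=rate)


def write_event_csv(path, train: EventTrain) -> None:
    df = pd.DataFrame({"onset_s": train.onsets})
    if train.label is not None:
        df["label"] = train.label
    df.to_csv(path, index=False)


def write_flash_csv(path, series: SampledSeries) -> None:
    """Flash counts as (frame, count) rows; the frame rate goes in a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={series.rate}\n")
        pd.DataFrame(
            {"frame": np.arange(series.values.size), "count": series.values}
        ).to_csv(fh, index=False)
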
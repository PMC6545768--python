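"""Synthetic two-session, two-class motor-imagery EEG.

The generator emulates the statistical structure the downstream analysis
relies on: every channel carries 1/f^beta background activity plus a
narrowband sensorimotor-rhythm oscillation, and on a designated subset of
channels the oscillation is attenuated for class-1 trials — an
event-related desynchronization (ERD).  A second session reproduces the
between-day nonstationarity of real recordings through an overall amplitude
change, a raised broadband noise floor, and a small shift of the rhythm's
peak frequency.

Defaults mirror the public motor-imagery competition recordings the
pipeline is designed for: 22 channels at 250 Hz, 3 s trials, and
2 sessions x 6 runs x 12 trials per class (72 trials per class per
session).  Identical configuration and seed give bit-identical output;
every (session, trial) pair draws from its own counter-keyed substream, so
subsets are reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft
from scipy.signal import welch

from .dataio import TrialSet

__all__ = ["SyntheticConfig", "generate_study", "band_power_contrast"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-generation parameters.

    Parameters
    ----------
    n_channels, fs, trial_seconds, trials_per_class_per_session
        Recording geometry; defaults match the emulated data set
        (22 channels, 250 Hz, 3 s trials, 6 runs x 12 trials = 72 per class
        and session).
    erd_band : (low, high) Hz
        Band of the class-dependent rhythm; the oscillation center is the
        band midpoint.  Default (8, 12) Hz, the mu band.
    erd_channels : channel indices
        Channels carrying the class effect (a small sensorimotor subset).
    erd_depth : float in [0, 1]
        Fractional amplitude reduction of the rhythm in class-1 trials on
        ``erd_channels``; 0 removes the class difference entirely.
    osc_amplitude : float
        Rhythm amplitude relative to the unit-variance background.
    background_exponent : float
        Spectral slope beta of the 1/f^beta background.
    session_gain, session_noise_sd, session_freq_shift
        Between-day drift applied to session 2 only: multiplicative
        amplitude factor, additive white-noise standard deviation, and a
        shift (Hz) of the oscillation center frequency.  Session 1 is the
        reference (gain 1, no extra noise, no shift).
    seed : int
        Master seed; expands to per-(session, trial) substreams.
    """

    n_channels: int = 22
    fs: float = 250.0
    trial_seconds: float = 3.0
    trials_per_class_per_session: int = 72
    erd_band: tuple[float, float] = (8.0, 12.0)
    erd_channels: tuple[int, ...] = (7, 9, 11)
    erd_depth: float = 0.6
    osc_amplitude: float = 0.5
    background_exponent: float = 1.0
    session_gain: float = 0.85
    session_noise_sd: float = 0.3
    session_freq_shift: float = 0.5
    seed: int = 0

    def __post_init__(self):
        low, high = self.erd_band
        if not (0.0 < low < high < self.fs / 2):
            raise ValueError(
                f"erd_band must satisfy 0 < low < high < fs/2 = {self.fs / 2}; got {self.erd_band}"
            )
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError(f"erd_depth must lie in [0, 1]; got {self.erd_depth}")
        if self.trials_per_class_per_session < 1:
            raise ValueError("trials_per_class_per_session must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        bad = [c for c in self.erd_channels if not (0 <= int(c) < self.n_channels)]
        if bad:
            raise ValueError(
                f"erd_channels indices {bad} out of range for {self.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))


def _background(rng: np.random.Generator, n_channels: int, n_samples: int,
                beta: float) -> np.ndarray:
    """Unit-variance 1/f^beta noise, independent across channels."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)  # shape only matters up to scale
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    shaped = irfft(spectrum * shaping, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _trial(cfg: SyntheticConfig, session_idx: int, trial_idx: int, label: int) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(session_idx, trial_idx))
    )
    n, fs = cfg.n_samples, cfg.fs
    bg = _background(rng, cfg.n_channels, n, cfg.background_exponent)

    center = 0.5 * (cfg.erd_band[0] + cfg.erd_band[1])
    if session_idx == 1:
        center += cfg.session_freq_shift
    t = np.arange(n) / fs
    envelope = np.hanning(n)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_channels)
    amplitude = np.full(cfg.n_channels, cfg.osc_amplitude)
    if label == 1 and cfg.erd_channels:
        amplitude[list(cfg.erd_channels)] *= 1.0 - cfg.erd_depth
    osc = amplitude[:, None] * envelope * np.sin(2.0 * np.pi * center * t + phases[:, None])

    gain = 1.0 if session_idx == 0 else cfg.session_gain
    noise_sd = 0.0 if session_idx == 0 else cfg.session_noise_sd
    x = gain * (bg + osc)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


def generate_study(cfg: SyntheticConfig) -> tuple[TrialSet, TrialSet]:
    """Generate the two-session study ``(day1, day2)``.

    Each session holds ``2 * trials_per_class_per_session`` trials (class 0
    first, then class 1), with the class difference planted as an ERD of
    ``erd_depth`` on ``erd_channels`` and session-2 drift applied as
    configured.  Identical ``cfg`` (including seed) reproduces the arrays
    bit-for-bit.
    """
    n_per = cfg.trials_per_class_per_session
    labels = np.repeat([0, 1], n_per)
    sessions = []
    for s, name in enumerate(("day1", "day2")):
        data = np.empty((2 * n_per, cfg.n_channels, cfg.n_samples))
        for t_idx, label in enumerate(labels):
            data[t_idx] = _trial(cfg, s, t_idx, int(label))
        sessions.append(
            TrialSet(data=data, labels=labels.copy(), session_id=name, fs=cfg.fs)
        )
    return sessions[0], sessions[1]


def band_power_contrast(ts: TrialSet, band: tuple[float, float]) -> np.ndarray:
    """Standardized per-channel class difference in Welch band power.

    Returns one value per channel: the Welch-t statistic of mean band power
    between the two classes, positive when class 0 exceeds class 1 (the sign
    an ERD in class 1 produces on affected channels).
    """
    low, high = band
    if not (0.0 < low < high < ts.fs / 2):
        raise ValueError(f"band must lie inside (0, {ts.fs / 2}) Hz; got {band}")
    ts.require_two_classes()
    freqs, psd = welch(ts.data, fs=ts.fs, nperseg=min(256, ts.n_samples), axis=-1)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValueError(f"band {band} Hz contains no spectral estimate bins")
    power = psd[..., mask].mean(axis=-1)  # (trials, channels)
    c0, c1 = ts.classes
    p0, p1 = power[ts.labels == c0], power[ts.labels == c1]
    n0, n1 = p0.shape[0], p1.shape[0]
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least two trials for a contrast")
    se = np.sqrt(p0.var(axis=0, ddof=1) / n0 + p1.var(axis=0, ddof=1) / n1)
    se[se == 0] = np.finfo(float).tiny
    return (p0.mean(axis=0) - p1.mean(axis=0)) / se
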
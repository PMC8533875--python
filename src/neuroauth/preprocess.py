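"""Band-pass filtering, downsampling, and epoching of raw sessions.

The pipeline order is filter -> resample -> epoch: the whole continuous
session is filtered (zero-phase, so the 3-s task window is not shifted by
group delay) and decimated before the per-trial windows are cut out, which
avoids per-epoch edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .synth import RawSession, ValidationError

__all__ = ["PreprocessConfig", "Epoch", "bandpass_filter",
           "resample_to_target", "extract_epochs", "butter_sos",
           "filtfilt_gain"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Defaults: fourth-order Butterworth band-pass 1-30 Hz, decimation to
    100 Hz, 3-s epochs (300 samples)."""

    filter_order: int = 4
    band: tuple[float, float] = (1.0, 30.0)
    target_rate: float = 100.0
    epoch_s: float = 3.0

    def validate(self) -> None:
        low, high = self.band
        if not 0 < low < high < self.target_rate / 2:
            raise ValidationError(
                "band must satisfy 0 < low < high < target_rate/2")
        if self.filter_order <= 0 or self.filter_order % 2 != 0:
            raise ValidationError("filter_order must be even and positive")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_s * self.target_rate))


@dataclass
class Epoch:
    """One 3-s trial after filtering and decimation (channels x time)."""

    subject_id: int
    day_index: int
    task: str
    arm: str
    samples: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...] = ()


def butter_sos(cfg: PreprocessConfig, rate: float) -> np.ndarray:
    """Second-order sections of the band-pass filter.

    ``filter_order`` counts the overall band-pass order (a band-pass of
    order 2N comes from an order-N low/high prototype pair), matching the
    usual "fourth-order Butterworth band-pass" reading.
    """
    cfg.validate()
    if rate <= 2 * cfg.band[1]:
        raise ValidationError(
            f"sampling rate {rate} too low for band {cfg.band}")
    return signal.butter(cfg.filter_order // 2, cfg.band,
                         btype="bandpass", fs=rate, output="sos")


def filtfilt_gain(cfg: PreprocessConfig, rate: float,
                  freqs: np.ndarray) -> np.ndarray:
    """Analytic amplitude response of the zero-phase (forward-backward)
    filter at ``freqs``: |H(f)|^2 of the one-pass Butterworth design."""
    sos = butter_sos(cfg, rate)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=rate)
    return np.abs(h) ** 2


def bandpass_filter(samples: np.ndarray, rate: float,
                    cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase band-pass along the time axis (last axis)."""
    sos = butter_sos(cfg, rate)
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float), axis=-1)


def resample_to_target(samples: np.ndarray, rate: float,
                       cfg: PreprocessConfig) -> np.ndarray:
    """Polyphase resampling to ``cfg.target_rate`` (Kaiser anti-alias FIR).

    250 -> 100 Hz is the rational change 2/5; arbitrary rates are reduced to
    a fraction first.  A no-op when the rates already match.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[-1] == 0:
        raise ValidationError("cannot resample zero-length input")
    if rate == cfg.target_rate:
        return samples
    frac = Fraction(cfg.target_rate / rate).limit_denominator(1000)
    return signal.resample_poly(samples, frac.numerator, frac.denominator,
                                axis=-1)


def extract_epochs(session: RawSession, cfg: PreprocessConfig) -> list[Epoch]:
    """Filter and resample the continuous session, then cut one epoch per
    event.  Event order is preserved; metadata is copied through."""
    cfg.validate()
    session.validate()
    if not session.events:
        return []
    filtered = bandpass_filter(session.samples, session.sampling_rate, cfg)
    resampled = resample_to_target(filtered, session.sampling_rate, cfg)
    ratio = cfg.target_rate / session.sampling_rate
    n_t = cfg.epoch_samples
    epochs = []
    for k, ev in enumerate(session.events):
        start = int(round(ev.onset_sample * ratio))
        stop = start + n_t
        if stop > resampled.shape[-1]:
            raise ValidationError(
                f"event {k} (onset {ev.onset_sample}) window exceeds "
                "resampled recording")
        epochs.append(Epoch(
            subject_id=session.subject_id, day_index=session.day_index,
            task=ev.task, arm=ev.arm,
            samples=resampled[:, start:stop].copy(),
            sampling_rate=cfg.target_rate,
            channel_names=session.channel_names))
    return epochs
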
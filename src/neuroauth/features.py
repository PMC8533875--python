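"""STFT spectrogram, dB power, sub-band grouping, and feature assembly.

Each 300-sample epoch channel is zero-padded symmetrically to 330 samples,
sliced into 128-point Hann-tapered segments with a 3-sample hop (125-sample
overlap, ~97.7%), and transformed one-sidedly, giving a 65 x 68 complex
spectrogram with 100/128 = 0.78125 Hz frequency resolution.  Power in dB is
20*log10|X| (with a small floor so silent bins stay finite); bins are then
grouped into five sub-bands spanning the mu (7-11 Hz) and beta (11-30 Hz)
ranges by averaging the dB values of the bins whose center frequency falls in
the half-open interval [low, high).  Stacking the per-channel 5 x 68 blocks
row-wise yields the feature matrix: 25 x 68 for the five central/midline
electrodes (``paper_literal`` mode) or 40 x 68 for all eight
(``all_channels``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .preprocess import Epoch
from .synth import SUBBANDS, ValidationError

__all__ = ["StftConfig", "Spectrogram", "SubbandScheme", "FeatureMatrix",
           "stft", "power_db", "subband_matrix", "assemble_features",
           "n_frames_for", "LITERAL_CHANNELS", "DB_FLOOR"]

#: Central/midline subset used by ``paper_literal`` feature assembly.
LITERAL_CHANNELS = ("Fz", "C3", "Cz", "C4", "Pz")

DB_FLOOR = 1e-12


@dataclass(frozen=True)
class StftConfig:
    """Spectrogram dialect.

    A literal 98% overlap of 128 samples would need a fractional hop of
    2.56 samples; the realizable hop of 3 (overlap 125/128 ~ 97.7%) is used
    instead, and the 300-sample epoch is zero-padded symmetrically to
    ``pad_to`` = 330 so that exactly floor((330-128)/3)+1 = 68 frames result.
    """

    n_fft: int = 128
    window: str = "hann"
    overlap_fraction: float = 0.98
    pad_to: int = 330
    hop: int = 3

    def validate(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValidationError("overlap_fraction must lie in [0, 1)")
        if self.hop < 1 or self.n_fft < self.hop:
            raise ValidationError("need 1 <= hop <= n_fft")
        if self.pad_to < self.n_fft:
            raise ValidationError("pad_to must be >= n_fft")


@dataclass
class Spectrogram:
    """One-sided complex STFT: rows are frequencies, columns time frames."""

    X: np.ndarray          # (n_freq, n_frames) complex
    freqs: np.ndarray      # Hz per row, spacing fs / n_fft
    frame_times: np.ndarray  # s per column (frame centers, epoch-relative)


@dataclass(frozen=True)
class SubbandScheme:
    """Sub-band edges; membership is half-open [low, high) on bin centers so
    shared edges (11, 16, 21, 25 Hz) are never double-counted."""

    bands: tuple[tuple[float, float], ...] = SUBBANDS

    def validate(self) -> None:
        prev_high = 0.0
        for low, high in self.bands:
            if not low < high:
                raise ValidationError(f"band ({low}, {high}) inverted")
            if low < prev_high:
                raise ValidationError("bands must be ordered, non-overlapping")
            prev_high = high


@dataclass
class FeatureMatrix:
    """dB sub-band power sequence: (channels x bands) rows, frame columns."""

    P: np.ndarray  # (n_rows, n_frames), dB
    row_labels: list  # (channel_name, (low, high)) per row
    mode: str      # "paper_literal" | "all_channels"


def n_frames_for(length: int, cfg: StftConfig) -> int:
    """Number of STFT frames for a ``length``-sample input after padding."""
    padded = max(length, cfg.pad_to)
    return (padded - cfg.n_fft) // cfg.hop + 1


def _pad_symmetric(x: np.ndarray, target: int) -> np.ndarray:
    if x.size >= target:
        return x
    total = target - x.size
    left = total // 2
    return np.pad(x, (left, total - left))


def stft(epoch_channel: np.ndarray, fs: float, cfg: StftConfig) -> Spectrogram:
    """One-sided STFT of a single-channel epoch.

    With the defaults and a 300-sample input at 100 Hz the result is
    65 rows x 68 frames at k * 0.78125 Hz.
    """
    cfg.validate()
    x = np.asarray(epoch_channel, dtype=float).ravel()
    if x.size < cfg.n_fft:
        raise ValidationError(
            f"input length {x.size} shorter than n_fft={cfg.n_fft}; "
            "padding only aligns frame counts, it cannot rescue short input")
    x = _pad_symmetric(x, cfg.pad_to)
    if cfg.window != "hann":
        raise ValidationError(f"unsupported window '{cfg.window}'")
    win = hann(cfg.n_fft, sym=False)
    frames = np.lib.stride_tricks.sliding_window_view(
        x, cfg.n_fft)[:: cfg.hop]
    X = np.fft.rfft(frames * win, n=cfg.n_fft, axis=1).T
    freqs = np.fft.rfftfreq(cfg.n_fft, d=1.0 / fs)
    pad_left = (max(x.size, cfg.pad_to) - len(epoch_channel)) // 2
    starts = np.arange(frames.shape[0]) * cfg.hop
    frame_times = (starts + cfg.n_fft / 2.0 - pad_left) / fs
    return Spectrogram(X=X, freqs=freqs, frame_times=frame_times)


def power_db(X: np.ndarray, floor: float = DB_FLOOR) -> np.ndarray:
    """Elementwise power in dB: 20*log10(max(|X|, floor))."""
    return 20.0 * np.log10(np.maximum(np.abs(X), floor))


def subband_matrix(spec: Spectrogram, scheme: SubbandScheme | None = None
                   ) -> np.ndarray:
    """Mean dB power per sub-band per frame: (n_bands x n_frames)."""
    scheme = scheme or SubbandScheme()
    scheme.validate()
    P = power_db(spec.X)
    rows = []
    for low, high in scheme.bands:
        members = (spec.freqs >= low) & (spec.freqs < high)
        if not members.any():
            raise ValidationError(
                f"sub-band ({low}, {high}) Hz has no member bins")
        rows.append(P[members].mean(axis=0))
    return np.vstack(rows)


def assemble_features(epoch: Epoch, cfg: StftConfig | None = None,
                      scheme: SubbandScheme | None = None,
                      mode: str = "all_channels",
                      channel_names: tuple[str, ...] | None = None
                      ) -> FeatureMatrix:
    """Stack per-channel sub-band matrices row-wise into the feature matrix.

    ``paper_literal`` uses the five central/midline electrodes (25 rows with
    default bands); ``all_channels`` uses every channel (40 rows for the
    8-channel montage).
    """
    cfg = cfg or StftConfig()
    scheme = scheme or SubbandScheme()
    if channel_names is None:
        channel_names = epoch.channel_names
    if not channel_names:
        channel_names = tuple(
            f"ch{i}" for i in range(epoch.samples.shape[0]))
    if mode == "paper_literal":
        missing = [c for c in LITERAL_CHANNELS if c not in channel_names]
        if missing:
            raise ValidationError(
                f"paper_literal mode needs channels {missing} "
                "absent from this montage")
        picks = [channel_names.index(c) for c in LITERAL_CHANNELS]
        picked_names = LITERAL_CHANNELS
    elif mode == "all_channels":
        picks = list(range(epoch.samples.shape[0]))
        picked_names = tuple(channel_names)
    else:
        raise ValidationError(f"unknown feature mode '{mode}'")

    blocks, labels = [], []
    for idx, name in zip(picks, picked_names):
        spec = stft(epoch.samples[idx], epoch.sampling_rate, cfg)
        blocks.append(subband_matrix(spec, scheme))
        labels.extend((name, band) for band in scheme.bands)
    return FeatureMatrix(P=np.vstack(blocks), row_labels=labels, mode=mode)
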
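"""Seeded synthetic chronic EEG cohort generator.

Emulates a multi-subject, multi-day motor/imagery study: each subject
contributes several sessions recorded on different days, each session holding
a block of performed-movement trials followed by a block of motor-imagery
trials, half left arm and half right arm, with 3-s task epochs marked by
events.

Subjects are given a spectral identity (per-channel, per-sub-band power
gains) that persists across days; day-to-day variability enters through
per-channel gain jitter, a small channel-leakage mixing matrix (a surrogate
for electrode re-placement), and a noise-level multiplier.  Motor tasks are
expressed as event-related desynchronization (ERD): multiplicative
suppression of mu- and beta-band power on the central channel contralateral
to the cued arm, confined to the task window.

The background is 1/f-shaped Gaussian noise, band-limited well below half of
the downstream target rate so that decimation is alias-safe.  All randomness
derives from a single cohort seed via keyed ``numpy.random.SeedSequence``
streams, so identical specs produce bit-identical cohorts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "SUBBANDS",
    "CohortSpec",
    "SubjectFingerprint",
    "DayEffect",
    "Event",
    "RawSession",
    "generate_cohort",
    "generate_session",
    "make_fingerprint",
    "make_day_effect",
    "write_session_csv",
    "read_session_csv",
    "SessionParseError",
]

#: The five sub-bands (Hz) used throughout the pipeline: mu (7-11) plus four
#: beta sub-bands covering 11-30 Hz.
SUBBANDS: tuple[tuple[float, float], ...] = (
    (7.0, 11.0),
    (11.0, 16.0),
    (16.0, 21.0),
    (21.0, 25.0),
    (25.0, 30.0),
)

TASKS = ("performed", "imagined")
ARMS = ("left", "right")

# Base oscillation amplitude (uV std) per sub-band before subject gain; mildly
# decreasing with frequency like real sensorimotor rhythms.
_BAND_BASE_AMP = (4.0, 3.2, 2.6, 2.2, 1.8)
# Fraction of the ERD depth applied to each sub-band on the contralateral
# channel: full on mu, none on the 11-16 Hz transition band, partial on beta.
_BAND_ERD_WEIGHT = (1.0, 0.0, 0.6, 0.6, 0.6)

_BG_LOW = (1.0, 7.0)    # delta/theta background, uV std 4 * noise_scale
_BG_HIGH = (30.0, 45.0)  # gamma-side background, band-limited below 50 Hz
_BG_LOW_AMP = 4.0
_BG_HIGH_AMP = 1.0
_WHITE_AMP = 0.5

_ERD_RAMP_S = 0.15  # cosine ramp at ERD window edges, avoids spectral splatter


class ValidationError(ValueError):
    """Raised when a spec or session violates a documented invariant."""


@dataclass(frozen=True)
class CohortSpec:
    """Design of the synthetic cohort.

    Defaults mirror the emulated study: 15 subjects, 5 daily sessions each,
    10 performed + 10 imagined trials per session (5 left / 5 right arm),
    8 dry electrodes sampled at 250 Hz, 3-s task epochs.
    """

    n_subjects: int = 15
    n_days: int = 5
    trials_per_task: int = 10
    sampling_rate: float = 250.0
    n_channels: int = 8
    channel_names: tuple[str, ...] = (
        "Fz", "C3", "Cz", "C4", "Pz", "PO7", "Oz", "PO8")
    epoch_s: float = 3.0
    seed: int = 0
    # Generator physiology/variability parameters (not part of the emulated
    # study design; defaults documented in docs/methods.md).
    band_gain_dispersion: float = 0.6
    erd_depth: float = 0.4
    imagined_erd_factor: float = 0.7
    background_exponent: float = 1.0
    day_gain_sigma: float = 0.08
    day_mixing_offdiag: float = 0.05
    day_noise_sigma: float = 0.10
    rest_s: float = 4.0

    def validate(self) -> None:
        for name in ("n_subjects", "n_days", "trials_per_task", "n_channels"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.trials_per_task % 2 != 0:
            raise ValidationError(
                "trials_per_task must be even (equal left/right split)")
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                "channel_names length must equal n_channels")
        if self.sampling_rate < 2.0 * _BG_HIGH[1]:
            raise ValidationError(
                "sampling_rate must be at least twice the highest "
                f"synthesized frequency ({_BG_HIGH[1]} Hz)")
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be strictly positive")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValidationError("erd_depth must lie in [0, 1]")
        if not 0.0 <= self.day_mixing_offdiag < 1.0:
            raise ValidationError("day_mixing_offdiag must lie in [0, 1)")


@dataclass(frozen=True)
class SubjectFingerprint:
    """A subject's persistent spectral identity."""

    subject_id: int
    band_gains: np.ndarray  # (n_channels, 5) strictly positive multipliers
    erd_depth: dict  # (arm, task) -> suppression fraction in [0, 1]
    background_exponent: float

    def validate(self) -> None:
        if not np.all(self.band_gains > 0):
            raise ValidationError("band_gains must be strictly positive")
        for depth in self.erd_depth.values():
            if not 0.0 <= depth <= 1.0:
                raise ValidationError("erd_depth values must lie in [0, 1]")


@dataclass(frozen=True)
class DayEffect:
    """Session-to-session nuisance variability for one subject-day."""

    gain_jitter: np.ndarray  # (n_channels,) multiplicative
    mixing: np.ndarray       # (n_channels, n_channels), rows sum to 1
    noise_scale: float

    def validate(self, offdiag_bound: float) -> None:
        rowsum = self.mixing.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValidationError("mixing rows must sum to 1")
        offdiag = self.mixing - np.diag(np.diag(self.mixing))
        if np.any(offdiag.sum(axis=1) > offdiag_bound + 1e-9):
            raise ValidationError("mixing off-diagonal mass exceeds bound")


class Event(NamedTuple):
    onset_sample: int
    task: str  # "performed" | "imagined"
    arm: str   # "left" | "right"


@dataclass
class RawSession:
    """Continuous multi-channel recording for one subject-day."""

    subject_id: int
    day_index: int
    samples: np.ndarray  # (n_channels, n_samples), uV
    sampling_rate: float
    channel_names: tuple[str, ...]
    events: list[Event] = field(default_factory=list)
    epoch_s: float = 3.0

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def validate(self) -> None:
        win = int(round(self.epoch_s * self.sampling_rate))
        prev_end = -1
        for ev in self.events:
            if ev.onset_sample <= prev_end:
                raise ValidationError(
                    "events must be non-overlapping and ordered by onset")
            if ev.onset_sample < 0 or ev.onset_sample + win > self.n_samples:
                raise ValidationError(
                    f"event at sample {ev.onset_sample} exceeds recording")
            if ev.task not in TASKS or ev.arm not in ARMS:
                raise ValidationError(f"unknown task/arm in event {ev}")
            prev_end = ev.onset_sample + win - 1


# ---------------------------------------------------------------------------
# Seed derivation: keyed SeedSequence streams.  Stream (seed, kind, *key)
# gives every subject/day an independent, reproducible generator.

_KIND_FINGERPRINT = 1
_KIND_DAY = 2
_KIND_SESSION = 3


def _rng(seed: int, kind: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, kind, *key]))


def make_fingerprint(spec: CohortSpec, subject_id: int) -> SubjectFingerprint:
    """Draw the persistent spectral identity of one subject."""
    rng = _rng(spec.seed, _KIND_FINGERPRINT, subject_id)
    gains = np.exp(rng.normal(
        0.0, spec.band_gain_dispersion, size=(spec.n_channels, len(SUBBANDS))))
    depths = {}
    for arm in ARMS:
        depths[(arm, "performed")] = spec.erd_depth
        depths[(arm, "imagined")] = spec.erd_depth * spec.imagined_erd_factor
    fp = SubjectFingerprint(
        subject_id=subject_id, band_gains=gains, erd_depth=depths,
        background_exponent=spec.background_exponent)
    fp.validate()
    return fp


def make_day_effect(spec: CohortSpec, subject_id: int, day: int) -> DayEffect:
    rng = _rng(spec.seed, _KIND_DAY, subject_id, day)
    n = spec.n_channels
    gain = np.exp(rng.normal(0.0, spec.day_gain_sigma, size=n))
    off = spec.day_mixing_offdiag
    mixing = np.eye(n) * (1.0 - off)
    for i in range(n):
        w = rng.dirichlet(np.ones(n - 1)) * off
        mixing[i, np.arange(n) != i] = w
    noise = float(np.exp(rng.normal(0.0, spec.day_noise_sigma)))
    eff = DayEffect(gain_jitter=gain, mixing=mixing, noise_scale=noise)
    eff.validate(off)
    return eff


# ---------------------------------------------------------------------------
# Signal synthesis


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float], exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with 1/f^exponent power confined to band."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs < band[1])
    coeffs = np.zeros(freqs.size, dtype=complex)
    k = int(mask.sum())
    if k == 0:
        raise ValidationError(f"band {band} empty at fs={fs}, n={n}")
    amp = freqs[mask] ** (-exponent / 2.0)
    coeffs[mask] = (rng.standard_normal(k) + 1j * rng.standard_normal(k)) * amp
    x = np.fft.irfft(coeffs, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _erd_envelope(n: int, fs: float, windows: list[tuple[int, int]],
                  depth: np.ndarray) -> np.ndarray:
    """Amplitude envelope: 1 at rest, sqrt(1-depth_i) inside window i,
    cosine-ramped over ``_ERD_RAMP_S`` at the edges."""
    env = np.ones(n)
    ramp = max(1, int(round(_ERD_RAMP_S * fs)))
    up = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, ramp)))
    for (a, b), d in zip(windows, depth):
        lo = np.sqrt(max(0.0, 1.0 - d))
        a0, b0 = max(0, a), min(n, b)
        env[a0:b0] = lo
        k = min(ramp, a0)
        if k > 0:  # ramp down into the window: 1 -> lo
            env[a0 - k:a0] = 1.0 + (lo - 1.0) * up[ramp - k:]
        k = min(ramp, n - b0)
        if k > 0:  # ramp back out: lo -> 1
            env[b0:b0 + k] = lo + (1.0 - lo) * up[:k]
    return env


def _session_layout(spec: CohortSpec, rng: np.random.Generator
                    ) -> tuple[list[Event], int]:
    """Trial order and onsets: performed block then imagined block, arms
    shuffled within each block, epoch_s task + rest_s rest per trial."""
    fs = spec.sampling_rate
    pre = int(round(2.0 * fs))
    step = int(round((spec.epoch_s + spec.rest_s) * fs))
    win = int(round(spec.epoch_s * fs))
    events: list[Event] = []
    onset = pre
    for task in TASKS:
        arms = [a for a in ARMS for _ in range(spec.trials_per_task // 2)]
        rng.shuffle(arms)
        for arm in arms:
            events.append(Event(onset, task, arm))
            onset += step
    total = onset - step + win + int(round(2.0 * fs))
    return events, total


def generate_session(spec: CohortSpec, fingerprint: SubjectFingerprint,
                     day_effect: DayEffect, day_index: int) -> RawSession:
    """Synthesize one continuous subject-day recording with event markers."""
    fs = spec.sampling_rate
    rng = _rng(spec.seed, _KIND_SESSION, fingerprint.subject_id, day_index)
    events, n = _session_layout(spec, rng)
    win = int(round(spec.epoch_s * fs))
    exp = fingerprint.background_exponent

    name_to_idx = {c: i for i, c in enumerate(spec.channel_names)}
    # contralateral central channel per cued arm (skip if montage lacks it)
    contra = {"right": name_to_idx.get("C3"), "left": name_to_idx.get("C4")}

    sig = np.zeros((spec.n_channels, n))
    for ch in range(spec.n_channels):
        for b, band in enumerate(SUBBANDS):
            comp = _bandlimited_noise(rng, n, fs, band, exp)
            amp = _BAND_BASE_AMP[b] * np.sqrt(fingerprint.band_gains[ch, b])
            windows, depths = [], []
            for ev in events:
                if contra.get(ev.arm) == ch and _BAND_ERD_WEIGHT[b] > 0:
                    d = fingerprint.erd_depth[(ev.arm, ev.task)]
                    windows.append((ev.onset_sample, ev.onset_sample + win))
                    depths.append(d * _BAND_ERD_WEIGHT[b])
            if windows:
                comp = comp * _erd_envelope(n, fs, windows, np.asarray(depths))
            sig[ch] += amp * comp
        bg = (_BG_LOW_AMP * _bandlimited_noise(rng, n, fs, _BG_LOW, exp)
              + _BG_HIGH_AMP * _bandlimited_noise(rng, n, fs, _BG_HIGH, exp)
              + _WHITE_AMP * rng.standard_normal(n))
        sig[ch] += day_effect.noise_scale * bg

    sig = day_effect.mixing @ sig
    sig *= day_effect.gain_jitter[:, None]

    session = RawSession(
        subject_id=fingerprint.subject_id, day_index=day_index,
        samples=sig, sampling_rate=fs, channel_names=spec.channel_names,
        events=events, epoch_s=spec.epoch_s)
    session.validate()
    return session


def generate_cohort(spec: CohortSpec) -> list[RawSession]:
    """Generate the full cohort: ``n_subjects x n_days`` sessions.

    Identical spec (including seed) yields bit-identical output.
    """
    spec.validate()
    sessions = []
    for s in range(spec.n_subjects):
        fp = make_fingerprint(spec, s)
        for d in range(spec.n_days):
            eff = make_day_effect(spec, s, d)
            sessions.append(generate_session(spec, fp, eff, d))
    return sessions


# ---------------------------------------------------------------------------
# CSV dialect
#
# Data file: `# subject=`, `# day=`, `# fs=`, `# epoch_s=`, `# channels=`
# header lines, then one row per time sample with one column per channel
# (UTF-8, '.' decimal, LF).  Events live in a sibling file
# `<stem>.events.csv` with header `onset_sample,task,arm`.

_FLOAT_FMT = "%.5f"
_FLOAT_ATOL = 5e-6  # round-trip precision implied by _FLOAT_FMT


class SessionParseError(ValueError):
    """Malformed session/events CSV; message carries the offending line."""


def events_path_for(path: Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".events.csv")


def write_session_csv(session: RawSession, path) -> None:
    """Write a session (and its events) in the documented CSV dialect."""
    session.validate()
    path = Path(path)
    with io.open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# subject={session.subject_id}\n")
        fh.write(f"# day={session.day_index}\n")
        fh.write(f"# fs={session.sampling_rate:g}\n")
        fh.write(f"# epoch_s={session.epoch_s:g}\n")
        fh.write("# channels=" + ",".join(session.channel_names) + "\n")
        np.savetxt(fh, session.samples.T, fmt=_FLOAT_FMT, delimiter=",")
    with io.open(events_path_for(path), "w", encoding="utf-8",
                 newline="\n") as fh:
        fh.write("onset_sample,task,arm\n")
        for ev in session.events:
            fh.write(f"{ev.onset_sample},{ev.task},{ev.arm}\n")


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for i, line in enumerate(lines, start=1):
        if not line.startswith("# "):
            raise SessionParseError(f"line {i}: malformed header '{line}'")
        key, _, value = line[2:].partition("=")
        meta[key.strip()] = value.strip()
    for key in ("subject", "day", "fs", "channels"):
        if key not in meta:
            raise SessionParseError(f"missing header key '{key}'")
    return meta


def read_session_csv(path) -> RawSession:
    """Read a session written by :func:`write_session_csv`.

    Raises :class:`SessionParseError` (with a line number) on malformed
    headers, inconsistent channel counts, or out-of-range event onsets.
    """
    path = Path(path)
    with io.open(path, "r", encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    n_header = 0
    while n_header < len(raw) and raw[n_header].startswith("#"):
        n_header += 1
    meta = _parse_header(raw[:n_header])
    channels = tuple(c.strip() for c in meta["channels"].split(","))
    rows = []
    for i, line in enumerate(raw[n_header:], start=n_header + 1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(channels):
            raise SessionParseError(
                f"line {i}: expected {len(channels)} columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise SessionParseError(f"line {i}: {exc}") from None
    samples = np.asarray(rows, dtype=float).T
    if samples.size == 0:
        samples = samples.reshape(len(channels), 0)

    events = []
    ev_path = events_path_for(path)
    with io.open(ev_path, "r", encoding="utf-8") as fh:
        ev_lines = fh.read().splitlines()
    if not ev_lines or ev_lines[0].strip() != "onset_sample,task,arm":
        raise SessionParseError(f"{ev_path.name} line 1: bad events header")
    for i, line in enumerate(ev_lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise SessionParseError(
                f"{ev_path.name} line {i}: expected 3 columns")
        try:
            onset = int(parts[0])
        except ValueError:
            raise SessionParseError(
                f"{ev_path.name} line {i}: non-integer onset") from None
        events.append(Event(onset, parts[1], parts[2]))

    session = RawSession(
        subject_id=int(meta["subject"]), day_index=int(meta["day"]),
        samples=samples, sampling_rate=float(meta["fs"]),
        channel_names=channels, events=events,
        epoch_s=float(meta.get("epoch_s", 3.0)))
    try:
        session.validate()
    except ValidationError as exc:
        raise SessionParseError(f"{ev_path.name}: {exc}") from None
    return session


def sessions_equal(a: RawSession, b: RawSession,
                   atol: float = _FLOAT_ATOL) -> bool:
    """Field-wise equality up to the CSV float precision."""
    return (a.subject_id == b.subject_id and a.day_index == b.day_index
            and a.sampling_rate == b.sampling_rate
            and a.channel_names == b.channel_names
            and a.events == b.events
            and a.samples.shape == b.samples.shape
            and np.allclose(a.samples, b.samples, atol=atol, rtol=0.0))
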
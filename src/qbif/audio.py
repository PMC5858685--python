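"""Stimulus signal chain.

Target speech and masker are mixed at a requested broadband TMR, passed
through a bank of octave-wide Butterworth band-pass filters (edges at
center/sqrt(2) and center*sqrt(2), 36 dB/oct roll-off at each edge), and
the mixture is reconstructed from a subset of the band outputs.  All
stages are linear.  Filters default to zero-phase (forward-backward)
application so that reconstruction does not suffer band-dependent group
delay; a flag switches to causal single-pass filtering.

Also provides WAV I/O and seeded synthetic fixtures (white noise,
speech-shaped noise, band-center tone complexes) for testing without any
speech corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfilt, sosfiltfilt

from .errors import InvalidArgumentError
from .sii_core import BandGrid, StimulusSpec

__all__ = [
    "AudioBuffer",
    "rms",
    "mix_at_tmr",
    "octave_filterbank",
    "reconstruct_subset",
    "make_trial_stimulus",
    "read_wav",
    "write_wav",
    "white_noise",
    "speech_shaped_noise",
    "tone_complex",
]

DEFAULT_SAMPLE_RATE_HZ = 44100

#: Band-pass Butterworth order per edge: 6th order -> 36 dB/oct roll-off.
FILTER_ORDER = 6


@dataclass(frozen=True)
class AudioBuffer:
    """A single-channel signal with its sample rate."""

    samples: np.ndarray
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise InvalidArgumentError("audio must be single-channel (1-D)")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("audio samples must be finite")
        if self.sample_rate_hz <= 0:
            raise InvalidArgumentError("sample rate must be positive")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return len(self.samples)


def rms(buf: AudioBuffer) -> float:
    return float(np.sqrt(np.mean(buf.samples**2)))


def _match_length(
    masker: AudioBuffer, n: int, rng: np.random.Generator | None
) -> np.ndarray:
    m = masker.samples
    if len(m) >= n:
        return m[:n]
    # wrap-around looping with a random circular offset
    offset = int(rng.integers(len(m))) if rng is not None else 0
    reps = int(np.ceil((n + offset) / len(m)))
    return np.tile(m, reps)[offset : offset + n]


def mix_at_tmr(
    target: AudioBuffer,
    masker: AudioBuffer,
    tmr_db: float,
    rng: np.random.Generator | None = None,
) -> AudioBuffer:
    """Scale the masker so the broadband target-to-masker RMS ratio equals
    ``tmr_db`` and return the sum.  A masker shorter than the target is
    looped with a circular offset drawn from ``rng`` (offset 0 if None)."""
    if target.sample_rate_hz != masker.sample_rate_hz:
        raise InvalidArgumentError("target and masker sample rates differ")
    m = _match_length(masker, len(target), rng)
    m_rms = float(np.sqrt(np.mean(m**2)))
    if m_rms == 0.0:
        raise InvalidArgumentError("masker is silent; cannot set a TMR")
    scale = rms(target) / (m_rms * 10.0 ** (tmr_db / 20.0))
    return AudioBuffer(target.samples + scale * m, target.sample_rate_hz)


def _band_sos(center_hz: float, fs: float):
    lo = center_hz / np.sqrt(2.0)
    hi = center_hz * np.sqrt(2.0)
    if hi >= fs / 2.0:
        raise InvalidArgumentError(
            f"band edge {hi:.0f} Hz at or above Nyquist ({fs / 2:.0f} Hz)"
        )
    return butter(FILTER_ORDER, [lo, hi], btype="bandpass", fs=fs, output="sos")


def octave_filterbank(
    signal: AudioBuffer, grid: BandGrid, zero_phase: bool = True
) -> list[AudioBuffer]:
    """Split a signal into octave-wide bands, one per grid center."""
    fs = signal.sample_rate_hz
    out = []
    for c in grid.center_frequencies_hz:
        sos = _band_sos(c, fs)
        filt = sosfiltfilt if zero_phase else sosfilt
        out.append(AudioBuffer(filt(sos, signal.samples), fs))
    return out


def reconstruct_subset(bands: list[AudioBuffer], mask) -> AudioBuffer:
    """Sample-wise sum of the band signals where ``mask`` is true."""
    mask = tuple(bool(b) for b in mask)
    if len(mask) != len(bands):
        raise InvalidArgumentError("mask length does not match band count")
    lengths = {len(b) for b in bands}
    rates = {b.sample_rate_hz for b in bands}
    if len(lengths) != 1 or len(rates) != 1:
        raise InvalidArgumentError("bands must share length and sample rate")
    n = lengths.pop()
    total = np.zeros(n)
    for keep, band in zip(mask, bands):
        if keep:
            total += band.samples
    return AudioBuffer(total, rates.pop())


def make_trial_stimulus(
    target: AudioBuffer,
    masker: AudioBuffer,
    stimulus: StimulusSpec,
    grid: BandGrid,
    zero_phase: bool = True,
    rng: np.random.Generator | None = None,
) -> AudioBuffer:
    """Full chain for one trial: mix at the stimulus TMR, filter into
    octave bands, reconstruct keeping only the masked-in bands."""
    if len(stimulus.band_mask) != grid.n_band:
        raise InvalidArgumentError("stimulus mask does not match band grid")
    mixed = mix_at_tmr(target, masker, stimulus.tmr_db, rng=rng)
    bands = octave_filterbank(mixed, grid, zero_phase=zero_phase)
    return reconstruct_subset(bands, stimulus.band_mask)


# --- WAV I/O -----------------------------------------------------------


def read_wav(path) -> AudioBuffer:
    """Read a WAV file (PCM or float); multi-channel input is averaged to
    mono, integer formats are scaled to [-1, 1]."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioBuffer(data, int(fs))


def write_wav(path, buf: AudioBuffer, pcm16: bool = False) -> None:
    """Write float32 WAV by default, or 16-bit PCM (clipped to full scale)."""
    if pcm16:
        clipped = np.clip(buf.samples, -1.0, 1.0)
        wavfile.write(path, buf.sample_rate_hz, (clipped * 32767).astype(np.int16))
    else:
        wavfile.write(path, buf.sample_rate_hz, buf.samples.astype(np.float32))


# --- synthetic fixtures -------------------------------------------------


def white_noise(
    duration_s: float,
    rng: np.random.Generator,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
) -> AudioBuffer:
    n = int(round(duration_s * sample_rate_hz))
    return AudioBuffer(rng.standard_normal(n), sample_rate_hz)


def speech_shaped_noise(
    duration_s: float,
    rng: np.random.Generator,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
    corner_hz: float = 500.0,
) -> AudioBuffer:
    """Gaussian noise with a flat spectrum up to ``corner_hz`` and a
    -6 dB/oct slope above it (first-order low-pass), a crude stand-in for
    the long-term average speech spectrum."""
    noise = white_noise(duration_s, rng, sample_rate_hz)
    sos = butter(1, corner_hz, btype="lowpass", fs=sample_rate_hz, output="sos")
    return AudioBuffer(sosfilt(sos, noise.samples), sample_rate_hz)


def tone_complex(
    duration_s: float,
    grid: BandGrid,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE_HZ,
) -> AudioBuffer:
    """Equal-amplitude sum of pure tones at the band centers."""
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    total = np.zeros(n)
    for c in grid.center_frequencies_hz:
        total += np.sin(2 * np.pi * c * t)
    return AudioBuffer(total / grid.n_band, sample_rate_hz)
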
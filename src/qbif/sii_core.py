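"""The Speech Intelligibility Index (SII) model.

The SII expresses the proportion of speech information available to a
listener as a weighted sum of per-band audibilities,

    SII = sum_i w_i * A_i,

where the spectral weights ``w_i`` (the band importance function, summing
to 1) describe how much each frequency band contributes to intelligibility
and the band audibility ``A_i`` in [0, 1] describes how much of the speech
in band i is audible.  This module holds the band grid, the audibility map,
the weighted SII, the two link functions relating SII to probability of
correct keyword recognition, and summary metrics of a weight vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import InvalidArgumentError

__all__ = [
    "BandGrid",
    "SpectralWeights",
    "LinkParams",
    "StimulusSpec",
    "band_audibility",
    "compute_sii",
    "logistic_link",
    "traditional_link",
    "spectral_centroid",
    "DEFAULT_CENTERS_HZ",
]

#: Octave-band centers used throughout: 250 Hz to 8 kHz.
DEFAULT_CENTERS_HZ = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)

#: Audibility is a linear map of the band target-to-masker ratio clamped to
#: this symmetric range (dB).
AUDIBILITY_RANGE_DB = 15.0


@dataclass(frozen=True)
class BandGrid:
    """An ascending grid of band center frequencies (Hz)."""

    center_frequencies_hz: tuple[float, ...] = DEFAULT_CENTERS_HZ

    def __post_init__(self):
        centers = tuple(float(c) for c in self.center_frequencies_hz)
        object.__setattr__(self, "center_frequencies_hz", centers)
        if len(centers) < 2:
            raise InvalidArgumentError("band grid needs at least 2 bands")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise InvalidArgumentError("band centers must be strictly increasing")

    @property
    def n_band(self) -> int:
        return len(self.center_frequencies_hz)

    @classmethod
    def octave(cls, n_band: int, start_hz: float = 250.0) -> "BandGrid":
        """Octave-spaced grid of ``n_band`` centers starting at ``start_hz``."""
        return cls(tuple(start_hz * 2.0**i for i in range(n_band)))


@dataclass(frozen=True)
class SpectralWeights:
    """A band importance function: non-negative weights summing to 1."""

    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(v < 0 for v in vals):
            raise InvalidArgumentError("spectral weights must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"spectral weights must sum to 1 (got {sum(vals):.12g})"
            )

    def __len__(self) -> int:
        return len(self.values)

    def asarray(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def uniform(cls, n_band: int) -> "SpectralWeights":
        return cls(tuple(1.0 / n_band for _ in range(n_band)))

    @classmethod
    def from_raw(cls, raw) -> "SpectralWeights":
        """Clip negatives to zero and renormalize (the reported form)."""
        arr = np.clip(np.asarray(raw, dtype=float), 0.0, None)
        total = arr.sum()
        if total <= 0:
            raise InvalidArgumentError("raw weights have no positive mass")
        return cls(tuple(arr / total))


@dataclass(frozen=True)
class LinkParams:
    """Logistic link parameters: SRT (dB, the TMR at 50% correct) and
    slope beta (1/dB, > 0)."""

    srt_db: float
    beta: float

    def __post_init__(self):
        if not (self.beta > 0):
            raise InvalidArgumentError("beta must be > 0")


@dataclass(frozen=True)
class StimulusSpec:
    """One trial's stimulus: a broadband TMR and a band presence mask.

    ``in_quiet`` marks a speech-in-quiet presentation (no masker); presented
    bands are then fully audible regardless of ``tmr_db``.
    """

    tmr_db: float
    band_mask: tuple[bool, ...]
    in_quiet: bool = False

    def __post_init__(self):
        object.__setattr__(self, "band_mask", tuple(bool(b) for b in self.band_mask))
        if not math.isfinite(self.tmr_db):
            raise InvalidArgumentError("tmr_db must be finite")

    @property
    def n_band(self) -> int:
        return len(self.band_mask)

    @property
    def n_presented(self) -> int:
        return sum(self.band_mask)

    def mask_string(self) -> str:
        return "".join("1" if b else "0" for b in self.band_mask)


def band_audibility(tmr_prime_db):
    """Proportion of speech information audible in a band at the given
    band TMR: ``(clamp(TMR', -15, 15) + 15) / 30``.

    Accepts scalars or arrays; always in [0, 1].
    """
    arr = np.asarray(tmr_prime_db, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("band TMR must be finite")
    a = (np.clip(arr, -AUDIBILITY_RANGE_DB, AUDIBILITY_RANGE_DB) + AUDIBILITY_RANGE_DB) / (
        2 * AUDIBILITY_RANGE_DB
    )
    return a if arr.ndim else float(a)


def compute_sii(weights: SpectralWeights, stimulus: StimulusSpec) -> float:
    """Weighted band-audibility sum for one stimulus.

    Omitted bands contribute zero audibility; every presented band carries
    the broadband mixing TMR (target and masker are mixed at one TMR before
    filtering), or full audibility for in-quiet stimuli.
    """
    if len(weights) != stimulus.n_band:
        raise InvalidArgumentError(
            f"weights ({len(weights)}) and mask ({stimulus.n_band}) lengths differ"
        )
    a = 1.0 if stimulus.in_quiet else band_audibility(stimulus.tmr_db)
    mask = np.asarray(stimulus.band_mask, dtype=float)
    return float(np.dot(weights.asarray(), mask) * a)


def logistic_link(sii, params: LinkParams):
    """Probability of correct recognition under the symmetric logistic link.

    The SII is rescaled to the +/-15 dB audibility axis via ``30*SII - 15``
    so that the threshold parameter is a TMR in dB:

        p = 1 / (1 + exp(-beta * (30*SII - 15 - SRT)))

    Computed with :func:`scipy.special.expit`, which is overflow-safe for
    arbitrarily steep slopes.
    """
    sii_arr = np.asarray(sii, dtype=float)
    p = expit(params.beta * (30.0 * sii_arr - 15.0 - params.srt_db))
    return p if sii_arr.ndim else float(p)


def traditional_link(sii, P: float, Q: float, N: float):
    """The classical asymmetric SII-to-score transfer function

        p = (1 - 10**(-SII * P / Q)) ** N

    with proficiency ``P``, fitting constant ``Q`` and redundancy exponent
    ``N``.  Unlike the logistic link it is asymmetric about its midpoint.
    """
    if not Q > 0:
        raise InvalidArgumentError("Q must be > 0")
    if not N > 0:
        raise InvalidArgumentError("N must be > 0")
    sii_arr = np.asarray(sii, dtype=float)
    # -expm1(-x*ln10) = 1 - 10**-x, accurate for small arguments
    base = -np.expm1(-sii_arr * P / Q * np.log(10.0))
    p = base**N
    return p if sii_arr.ndim else float(p)


def spectral_centroid(weights: SpectralWeights, grid: BandGrid) -> float:
    """Weight-averaged deviation of band centers from 1 kHz, in octaves:
    ``sum_i w_i * log2(f_i / 1000)``.

    Summarizes where along the spectrum a band importance function puts its
    mass; 0 means centered on the 1-kHz band.
    """
    if len(weights) != grid.n_band:
        raise InvalidArgumentError("weights and grid lengths differ")
    offsets = np.log2(np.asarray(grid.center_frequencies_hz) / 1000.0)
    return float(np.dot(weights.asarray(), offsets))
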
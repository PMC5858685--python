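"""Non-adaptive baseline sampling strategies.

Both baselines present speech in quiet (no masker), so a presented band is
fully audible; stimuli therefore differ only in which bands carry speech.
Neither schedule depends on responses: each is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .sii_core import StimulusSpec

__all__ = ["ScheduleConfig", "compound_schedule", "random_schedule"]

#: In-quiet stimuli carry the top of the default TMR grid; the quiet flag,
#: not this value, is what forces full audibility.
QUIET_TMR_DB = 15.0


@dataclass(frozen=True)
class ScheduleConfig:
    n_band: int
    total_trials: int
    rng_seed: int

    def __post_init__(self):
        if self.total_trials < 1:
            raise InvalidArgumentError("total_trials must be >= 1")


def _quiet(mask) -> StimulusSpec:
    return StimulusSpec(tmr_db=QUIET_TMR_DB, band_mask=tuple(mask), in_quiet=True)


def compound_schedule(config: ScheduleConfig) -> list[StimulusSpec]:
    """Paired-trial target-band design.

    Each band serves as the target in turn (band 1 to band n, repeating).
    Per target, every pair of *context* bands drawn from the remaining
    bands appears once, in shuffled order; each context pair contributes
    two consecutive trials — context plus target, then context alone — so
    the pair isolates the target band's contribution.  The sequence is
    truncated at ``total_trials`` (possibly mid-pair).
    """
    n = config.n_band
    if n < 3:
        raise InvalidArgumentError("compound schedule needs at least 3 bands")
    rng = np.random.default_rng(config.rng_seed)
    out: list[StimulusSpec] = []
    for target in itertools.cycle(range(n)):
        pairs = list(itertools.combinations([b for b in range(n) if b != target], 2))
        order = rng.permutation(len(pairs))
        for idx in order:
            ctx = pairs[idx]
            with_target = [False] * n
            without_target = [False] * n
            for b in ctx:
                with_target[b] = True
                without_target[b] = True
            with_target[target] = True
            out.append(_quiet(with_target))
            out.append(_quiet(without_target))
            if len(out) >= config.total_trials:
                return out[: config.total_trials]
    raise AssertionError("unreachable")


def random_schedule(config: ScheduleConfig) -> list[StimulusSpec]:
    """Shuffled exhaustive passes over every admissible band subset.

    All masks with 2..(n_band-1) presented bands are shuffled, presented
    once each, reshuffled, and repeated until ``total_trials``.
    """
    n = config.n_band
    if n < 2:
        raise InvalidArgumentError("random schedule needs at least 2 bands")
    rng = np.random.default_rng(config.rng_seed)
    masks = []
    for k in range(2, n):
        for idx in itertools.combinations(range(n), k):
            mask = [False] * n
            for i in idx:
                mask[i] = True
            masks.append(tuple(mask))
    out: list[StimulusSpec] = []
    while len(out) < config.total_trials:
        order = rng.permutation(len(masks))
        out.extend(_quiet(masks[i]) for i in order)
    return out[: config.total_trials]
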
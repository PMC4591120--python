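"""Molecular-clock dating of duplication events from component median Ks.

Two duplicated lineages each accumulate synonymous substitutions at rate r
per synonymous site per year, so a pair diverging T years ago shows
Ks = 2 r T, and T = Ks / (2 r).  The default rate is the angiosperm
average r = 6.1e-9 substitutions per synonymous site per year.
"""

from __future__ import annotations

import dataclasses

DEFAULT_RATE = 6.1e-9


@dataclasses.dataclass
class ClockConfig:
    rate_r: float = DEFAULT_RATE          # subst. per synonymous site per year
    report_decimals: int = 1              # rounding of Mya in reports

    def __post_init__(self):
        if self.rate_r <= 0:
            raise ValueError("substitution rate must be positive")


def date_event(median_ks: float, clock: ClockConfig | None = None) -> float:
    """Divergence time in Mya: T = Ks / (2 r) / 1e6, unrounded."""
    if clock is None:
        clock = ClockConfig()
    if median_ks <= 0:
        raise ValueError("median Ks must be positive to date an event")
    return median_ks / (2.0 * clock.rate_r) / 1e6


def format_mya(mya: float, clock: ClockConfig | None = None) -> float:
    clock = clock or ClockConfig()
    return round(mya, clock.report_decimals)
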
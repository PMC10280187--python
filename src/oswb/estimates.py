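"""Closed-form estimate of the Russian-communication-language population.

Census-style sources give the number of Russian *speakers* worldwide and
in Russia.  Survey estimates put the share of speakers who use Russian
as their language of communication at 95.76% inside Russia and 45.54%
outside.  Combining the two gives, per year,

    russia_comm = 0.9576 * russia
    world_comm  = russia_comm + 0.4554 * (world - russia)

and the share of communication-language speakers living in Russia,
``100 * russia_comm / world_comm``.  The chain is computed in full
precision and rounded half-away-from-zero to 2 decimals on output only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SpeakerEstimateParams:
    within_russia_rate: float = 0.9576
    outside_russia_rate: float = 0.4554

    def __post_init__(self) -> None:
        for r in (self.within_russia_rate, self.outside_russia_rate):
            if not 0 <= r <= 1:
                raise ValueError("communication rates must lie in [0, 1]")


@dataclass(frozen=True)
class SpeakerYearRow:
    year: int
    world_speakers: float       # millions
    russia_speakers: float      # millions
    russia_comm: float          # millions, derived
    world_comm: float           # millions, derived
    speaker_share: float        # % of speakers living in Russia
    comm_share: float           # % of communication-language speakers in Russia


def estimate_row(year: int, world: float, russia: float,
                 params: SpeakerEstimateParams | None = None) -> SpeakerYearRow:
    """One year's derived row; all outputs rounded to 2 decimals."""
    params = params or SpeakerEstimateParams()
    if not 0 < russia <= world:
        raise ValueError("need 0 < russia <= world")
    russia_comm = params.within_russia_rate * russia
    world_comm = russia_comm + params.outside_russia_rate * (world - russia)
    return SpeakerYearRow(
        year=year,
        world_speakers=world,
        russia_speakers=russia,
        russia_comm=round2(russia_comm),
        world_comm=round2(world_comm),
        speaker_share=round2(100.0 * russia / world),
        comm_share=round2(100.0 * russia_comm / world_comm),
    )


def estimate_table(rows: list[tuple[int, float, float]],
                   params: SpeakerEstimateParams | None = None) -> pd.DataFrame:
    """Apply estimate_row to (year, world, russia) triples."""
    return pd.DataFrame([estimate_row(*r, params=params).__dict__
                         for r in rows])
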
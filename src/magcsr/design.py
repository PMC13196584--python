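"""Disturbance-gradient experimental designs.

A design describes an ordered set of disturbance levels (increasing event
frequency), the ecological regime each level belongs to (undisturbed,
intermediate, or press disturbance), and the replication per level. The
default instance mirrors a sequencing-batch-reactor microcosm layout: six
levels at frequencies 0, 1/8, 1/6, 1/4, 1/2 and 1 events per day, five
replicates each, sampled on day 42.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import pandas as pd

REGIMES = ("undisturbed", "intermediate", "press")

DEFAULT_FREQUENCIES = (
    Fraction(0),
    Fraction(1, 8),
    Fraction(1, 6),
    Fraction(1, 4),
    Fraction(1, 2),
    Fraction(1),
)

#: Level -> regime mapping used throughout: the never-disturbed level is the
#: undisturbed regime, the daily-disturbed level is the press regime, and
#: every pulsed level in between is intermediate.
DEFAULT_REGIME_OF_LEVEL = {
    0: "undisturbed",
    1: "intermediate",
    2: "intermediate",
    3: "intermediate",
    4: "intermediate",
    5: "press",
}


@dataclass(frozen=True)
class DisturbanceDesign:
    """Replicated disturbance-frequency design.

    Parameters
    ----------
    frequencies
        Disturbance frequency per level (events/day), non-decreasing with
        level id. Level ids are implicitly ``0..len(frequencies)-1``.
    regime_of_level
        Mapping level id -> regime name (one of ``REGIMES``).
    replicates
        Number of independent replicate reactors per level.
    day
        Integer day label of the sampling point.
    """

    frequencies: Sequence[Fraction] = DEFAULT_FREQUENCIES
    regime_of_level: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_REGIME_OF_LEVEL)
    )
    replicates: int = 5
    day: int = 42

    def __post_init__(self) -> None:
        freqs = [Fraction(f) for f in self.frequencies]
        if any(b < a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("frequencies must be non-decreasing with level id")
        for lvl in self.level_ids:
            regime = self.regime_of_level.get(lvl)
            if regime not in REGIMES:
                raise ValueError(
                    f"level {lvl} must map to exactly one regime in {REGIMES}, "
                    f"got {regime!r}"
                )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def level_ids(self) -> list[int]:
        return list(range(len(self.frequencies)))

    @property
    def n_levels(self) -> int:
        return len(self.frequencies)

    @property
    def n_samples(self) -> int:
        return self.n_levels * self.replicates

    def sample_ids(self) -> list[str]:
        return [f"L{lvl}R{rep}" for lvl in self.level_ids
                for rep in range(1, self.replicates + 1)]

    def metadata(self) -> pd.DataFrame:
        """One row per sample: level, frequency, regime, replicate, day."""
        rows = []
        for lvl in self.level_ids:
            for rep in range(1, self.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"L{lvl}R{rep}",
                        "level": lvl,
                        "frequency": float(self.frequencies[lvl]),
                        "regime": self.regime_of_level[lvl],
                        "replicate": rep,
                        "day": self.day,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")

    def regime_of_sample(self) -> pd.Series:
        meta = self.metadata()
        return meta["regime"]


def default_design() -> DisturbanceDesign:
    """The 6-level x 5-replicate day-42 design."""
    return DisturbanceDesign()
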
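"""Scale presets: the study's population structure at different sizes.

``full`` is the structure the study states: a 1000-founder historical
population grown to 10,000 over 1000 generations and shrunk to 4,000 by
generation 2020 (the last generation produced as 500 males + 3,500 females),
a 10-generation expansion at 5 offspring/dam, and a 50-sire x 3,500-dam
recent phase of 10 generations.

The smaller presets shrink the historical census sizes *and* historical
generation counts by a common factor (drift operates on a timescale of N
generations, so a miniature with both scaled preserves the equilibrium and
bottleneck shape), and shrink female counts in the expansion/recent phases
by the same factor.  ``desk`` keeps the full-scale 50 recent-phase sires —
recent effective size, the quantity the mating designs act on, is dominated
by the rare sex.  ``micro`` and ``mini`` shrink further (including sire
counts) and are intended for ordering/directional checks, not for
magnitude-level reproduction.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError
from .popsim_historical import DEFAULT_MUTATION_RATE, SizeSchedule


@dataclass(frozen=True)
class ScalePreset:
    name: str
    hist_anchors: tuple
    expand_sires: int
    expand_dams: int
    recent_sires: int
    recent_dams: int
    expand_generations: int = 10
    recent_generations: int = 10
    litter: int = 5
    dam_growth_cap: float = 2.0
    mutation_rate: float = DEFAULT_MUTATION_RATE

    @property
    def schedule(self) -> SizeSchedule:
        return SizeSchedule(self.hist_anchors)

    @property
    def final_sex_split(self) -> tuple[int, int]:
        # last historical generation is produced with exactly the sex split
        # the expansion phase draws
        return (self.expand_sires, self.expand_dams)


FULL = ScalePreset(
    name="full",
    hist_anchors=((0, 1000), (1000, 10000), (2020, 4000)),
    expand_sires=500, expand_dams=3500,
    recent_sires=50, recent_dams=3500,
)

DESK = ScalePreset(
    name="desk",
    hist_anchors=((0, 100), (100, 1000), (202, 400)),
    expand_sires=50, expand_dams=350,
    recent_sires=50, recent_dams=350,
)

MICRO = ScalePreset(
    name="micro",
    hist_anchors=((0, 50), (50, 500), (101, 160)),
    expand_sires=20, expand_dams=140,
    recent_sires=20, recent_dams=140,
)

MINI = ScalePreset(
    name="mini",
    hist_anchors=((0, 25), (25, 250), (50, 80)),
    expand_sires=10, expand_dams=70,
    recent_sires=10, recent_dams=70,
)

_PRESETS = {p.name: p for p in (FULL, DESK, MICRO, MINI)}


def get_preset(name) -> ScalePreset:
    if isinstance(name, ScalePreset):
        return name
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
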
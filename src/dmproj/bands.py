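"""Age bands and age grids.

The model is stratified by sex and age.  Rates and reporting tables live on
coarse *age bands* (``25-34`` ... ``75+``), while the projection engine can
run on an arbitrary :class:`AgeGrid` of cells — either the bands themselves
or single years of age grouped back into bands for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

SEXES = ("M", "F")

#: index of each sex in engine arrays
SEX_INDEX = {s: i for i, s in enumerate(SEXES)}


@dataclass(frozen=True, order=True)
class AgeBand:
    """A half-open age interval ``[lower, upper)``; ``upper=None`` means open-ended."""

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"age band must have lower < upper, got {self.lower}..{self.upper}")

    @property
    def width(self) -> float:
        return math.inf if self.upper is None else self.upper - self.lower

    @property
    def open_ended(self) -> bool:
        return self.upper is None

    @property
    def label(self) -> str:
        if self.upper is None:
            return f"{self.lower}+"
        return f"{self.lower}-{self.upper - 1}"

    @classmethod
    def parse(cls, text: str) -> "AgeBand":
        """Parse labels like ``"25-34"`` or ``"75+"`` (inclusive upper bound)."""
        text = str(text).strip()
        if text.endswith("+"):
            return cls(int(text[:-1]), None)
        lo, hi = text.split("-")
        return cls(int(lo), int(hi) + 1)

    def contains(self, age: float) -> bool:
        return age >= self.lower and (self.upper is None or age < self.upper)


#: reporting bands used by the core model (adults 25 and over)
CORE_BANDS: tuple[AgeBand, ...] = (
    AgeBand(25, 35),
    AgeBand(35, 45),
    AgeBand(45, 55),
    AgeBand(55, 65),
    AgeBand(65, 75),
    AgeBand(75, None),
)

#: the 20-79 comparison view: 20-24 extension, 75+ split into 75-79 (80+ dropped)
IDF_BANDS: tuple[AgeBand, ...] = (
    AgeBand(20, 25),
    AgeBand(25, 35),
    AgeBand(35, 45),
    AgeBand(45, 55),
    AgeBand(55, 65),
    AgeBand(65, 75),
    AgeBand(75, 80),
)


def check_tiling(bands: Sequence[AgeBand]) -> None:
    """Require bands to tile an age range without gaps or overlap."""
    ordered = sorted(bands)
    for a, b in zip(ordered, ordered[1:]):
        if a.upper is None:
            raise ValueError("open-ended band must be last")
        if a.upper != b.lower:
            raise ValueError(f"bands {a.label} and {b.label} do not tile contiguously")


class AgeGrid:
    """Cells the engine actually steps over, each assigned to a reporting band.

    A cell of width ``w`` passes a fraction ``1/w`` of each living compartment
    on to the next cell per annual cycle; with single-year cells this is exact
    cohort aging, with band-wide cells it is the usual exponential-sojourn
    approximation.  The last cell may be open-ended (no aging out).
    """

    def __init__(self, lowers: Sequence[int], uppers: Sequence[int | None], bands: Sequence[AgeBand]):
        check_tiling(bands)
        self.lowers = tuple(int(x) for x in lowers)
        self.uppers = tuple(uppers)
        self.bands = tuple(bands)
        self.n_cells = len(self.lowers)
        self.widths = tuple(
            math.inf if u is None else u - l for l, u in zip(self.lowers, self.uppers)
        )
        self.cell_band: tuple[int, ...] = tuple(
            self._band_of(lo) for lo in self.lowers
        )

    def _band_of(self, age: int) -> int:
        for i, b in enumerate(self.bands):
            if b.contains(age):
                return i
        raise ValueError(f"age {age} not covered by reporting bands")

    @classmethod
    def from_bands(cls, bands: Sequence[AgeBand]) -> "AgeGrid":
        """One cell per band (the coarse 1/w-aging variant)."""
        return cls([b.lower for b in bands], [b.upper for b in bands], bands)

    @classmethod
    def single_year(cls, bands: Sequence[AgeBand], top_age: int = 99) -> "AgeGrid":
        """Single-year cells from the youngest band bound up to ``top_age``+ (open)."""
        lo = min(b.lower for b in bands)
        lowers = list(range(lo, top_age + 1))
        uppers: list[int | None] = [a + 1 for a in range(lo, top_age)] + [None]
        return cls(lowers, uppers, bands)

    def cells_in_band(self, band_idx: int) -> list[int]:
        return [c for c in range(self.n_cells) if self.cell_band[c] == band_idx]

    def band_labels(self) -> list[str]:
        return [b.label for b in self.bands]
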
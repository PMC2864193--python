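"""Polytene cytogenetic band coordinates (e.g. ``89B7``) and band intervals.

Drosophila polytene maps address positions by a numbered division (1-102),
a lettered band (A-F) and an optional numbered sub-band.  Introgression
endpoints and gene positions in this package are all expressed in these
coordinates, ordered lexicographically on (division, letter, sub-band)
within a single chromosome arm.  Coordinates are taken exactly as given in
the input tables; no rearrangement relative to another species' map is
applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering
from typing import Optional, Tuple

__all__ = ["CytoBand", "CytoInterval", "parse_band", "parse_interval", "BandError"]

_BAND_RE = re.compile(r"^\s*(\d+)([A-F])(\d+)?\s*$")

# Sort sentinel for a missing sub-band used as an interval *end*: "84B" as an
# end means "anywhere in 84B", i.e. up to the largest sub-band.
_SUB_MAX = 10**6


class BandError(ValueError):
    """Raised for malformed band strings or inverted intervals."""


@total_ordering
@dataclass(frozen=True)
class CytoBand:
    """One cytogenetic map position: division, band letter, optional sub-band."""

    division: int
    letter: str
    subband: Optional[int] = None

    def __post_init__(self) -> None:
        if self.division < 1:
            raise BandError(f"division must be >= 1, got {self.division}")
        if self.letter not in "ABCDEF":
            raise BandError(f"band letter must be A-F, got {self.letter!r}")
        if self.subband is not None and self.subband < 1:
            raise BandError(f"sub-band must be >= 1, got {self.subband}")

    def key_start(self) -> Tuple[int, str, int]:
        """Sort key when this band opens an interval (missing sub-band -> 1)."""
        return (self.division, self.letter, self.subband if self.subband is not None else 1)

    def key_end(self) -> Tuple[int, str, int]:
        """Sort key when this band closes an interval (missing sub-band -> max)."""
        return (self.division, self.letter, self.subband if self.subband is not None else _SUB_MAX)

    def __str__(self) -> str:
        sub = "" if self.subband is None else str(self.subband)
        return f"{self.division}{self.letter}{sub}"

    def __lt__(self, other: "CytoBand") -> bool:
        return self.key_start() < other.key_start()


def parse_band(text: str) -> CytoBand:
    """Parse a band string like ``"89B20"`` or ``"77B"`` into a :class:`CytoBand`."""
    m = _BAND_RE.match(str(text))
    if not m:
        raise BandError(f"malformed cytogenetic band: {text!r}")
    division, letter, sub = m.groups()
    return CytoBand(int(division), letter, int(sub) if sub is not None else None)


@dataclass(frozen=True)
class CytoInterval:
    """A contiguous band range, inclusive at both ends (``77B`` to ``84B``)."""

    start: CytoBand
    end: CytoBand

    def __post_init__(self) -> None:
        if self.start.key_start() > self.end.key_end():
            raise BandError(f"inverted interval: {self.start} > {self.end}")

    def contains_band(self, band: CytoBand) -> bool:
        """True iff ``band`` lies inside the interval (inclusive ends).

        A band without a sub-band is treated as the whole lettered band, so
        it is contained as soon as any part of it falls in the interval's
        closed range (e.g. ``84B`` is inside ``77B..84B``).
        """
        return (self.start.key_start() <= band.key_end()
                and band.key_start() <= self.end.key_end())

    def contains_interval(self, other: "CytoInterval") -> bool:
        return (self.start.key_start() <= other.start.key_start()
                and other.end.key_end() <= self.end.key_end())

    def overlaps(self, other: "CytoInterval") -> bool:
        return (self.start.key_start() <= other.end.key_end()
                and other.start.key_start() <= self.end.key_end())

    def __str__(self) -> str:
        return f"{self.start}:{self.end}"


def parse_interval(text: str) -> CytoInterval:
    """Parse ``"77B:84B"`` (also accepts ``-`` or ``..`` separators)."""
    for sep in (":", "..", "-"):
        if sep in text:
            a, b = text.split(sep, 1)
            return CytoInterval(parse_band(a), parse_band(b))
    raise BandError(f"malformed interval (expected START:END): {text!r}")
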
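"""Time periods of the postglacial range chronology.

Three successive intervals are distinguished: ``holocene`` (11,700 BP to
AD 1900), ``historical`` (AD 1900 to AD 2000) and ``modern`` (post AD 2000).
Ranges are reconstructed cumulatively backwards in time, so the periods
carry a strict temporal order.
"""

from __future__ import annotations

import enum
import functools


@functools.total_ordering
class TimePeriod(enum.Enum):
    """One of the three analysis periods, ordered oldest-first."""

    HOLOCENE = "holocene"
    HISTORICAL = "historical"
    MODERN = "modern"

    @property
    def bounds(self) -> str:
        return _BOUNDS[self]

    def __lt__(self, other: "TimePeriod") -> bool:
        if not isinstance(other, TimePeriod):
            return NotImplemented
        return _ORDER[self] < _ORDER[other]

    @classmethod
    def parse(cls, text: str) -> "TimePeriod":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown time period {text!r}; expected one of "
                f"{[p.value for p in cls]}"
            ) from None


_ORDER = {TimePeriod.HOLOCENE: 0, TimePeriod.HISTORICAL: 1, TimePeriod.MODERN: 2}
_BOUNDS = {
    TimePeriod.HOLOCENE: "11,700 BP - AD 1900",
    TimePeriod.HISTORICAL: "AD 1900 - AD 2000",
    TimePeriod.MODERN: "post AD 2000",
}

#: The two intervals between successive periods plus the overall interval.
INTERVALS = (
    (TimePeriod.HOLOCENE, TimePeriod.HISTORICAL),
    (TimePeriod.HISTORICAL, TimePeriod.MODERN),
    (TimePeriod.HOLOCENE, TimePeriod.MODERN),
)
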
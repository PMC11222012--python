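"""Canonical EEG frequency bands.

Band edges follow the conventional rhythm definitions: delta 0.5-4 Hz,
theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz.  Edges are treated as
half-open intervals [lo, hi) so that the shared boundaries at 4, 8 and
13 Hz belong to exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-open support [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got lo={self.lo}, hi={self.hi}"
            )

    def contains(self, freq: float) -> bool:
        return self.lo <= freq < self.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo


CANONICAL_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta")


def get_band(name: str) -> BandDefinition:
    try:
        return CANONICAL_BANDS[name]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; known bands: {sorted(CANONICAL_BANDS)}"
        ) from None
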
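"""EEG frequency band definitions.

The five bands used throughout the package partition the analysed
[0, 30) Hz range with half-open edges ``[lo, hi)`` so every spectral bin
belongs to exactly one band: very-low [0, 0.1), delta [0.1, 4),
theta [4, 8), alpha [8, 12) and beta [12, 30) Hz.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(
                f"band {self.name!r}: lower edge {self.lo} must be < upper edge {self.hi}"
            )
        if self.lo < 0:
            raise ValueError(f"band {self.name!r}: negative lower edge {self.lo}")

    def contains(self, freq: float) -> bool:
        return self.lo <= freq < self.hi


VERY_LOW = BandDefinition("very_low", 0.0, 0.1)
DELTA = BandDefinition("delta", 0.1, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 12.0, 30.0)

#: The standard five-band partition of [0, 30) Hz, in ascending order.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (VERY_LOW, DELTA, THETA, ALPHA, BETA)

#: Total analysed range (Hz); the five default bands partition it exactly.
TOTAL_RANGE: tuple[float, float] = (0.0, 30.0)

#: Bands pooled as "low frequency" for stun classification.
LOW_FREQ_BANDS: tuple[str, str] = ("delta", "theta")


def check_partition(bands: tuple[BandDefinition, ...], lo: float, hi: float) -> None:
    """Raise if *bands* do not partition ``[lo, hi)`` without gap or overlap."""
    ordered = sorted(bands, key=lambda b: b.lo)
    edge = lo
    for band in ordered:
        if abs(band.lo - edge) > 1e-12:
            raise ValueError(f"bands do not partition [{lo}, {hi}): gap/overlap at {band.lo}")
        edge = band.hi
    if abs(edge - hi) > 1e-12:
        raise ValueError(f"bands do not partition [{lo}, {hi}): end at {edge}")
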
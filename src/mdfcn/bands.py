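"""Frequency band schemes for band-split parcel signals.

The pipeline operates on signals that have already been separated into a
small set of physiologically motivated frequency bands. The default scheme
is the neonatal EEG convention: low-delta, high-delta, theta, alpha, beta.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandScheme:
    """Ordered set of named, non-overlapping frequency bands.

    Parameters
    ----------
    bands
        Ordered list of ``(name, low_hz, high_hz)`` tuples. Edges must be
        strictly increasing within each band and bands must not overlap
        (touching edges are allowed, e.g. 1.5/1.5).
    """

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band scheme must contain at least one band")
        prev_high = 0.0
        for name, low, high in self.bands:
            if not (0.0 < low < high):
                raise ValueError(f"band {name!r}: need 0 < low < high, got [{low}, {high}]")
            if low < prev_high:
                raise ValueError(f"band {name!r} overlaps the previous band")
            prev_high = high

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def edges(self, index: int) -> tuple[float, float]:
        _, low, high = self.bands[index]
        return low, high

    def validate_nyquist(self, fs: float) -> None:
        """Raise if any band edge is at or above the Nyquist frequency."""
        for name, low, high in self.bands:
            if high >= fs / 2:
                raise ValueError(
                    f"band {name!r} upper edge {high} Hz is not below Nyquist ({fs / 2} Hz)"
                )

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def default_band_scheme() -> BandScheme:
    """Neonatal five-band scheme: low-d, high-d, theta, alpha, beta (Hz)."""
    return BandScheme(
        (
            ("low-delta", 0.4, 1.5),
            ("high-delta", 1.5, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 13.0),
            ("beta", 13.0, 22.0),
        )
    )
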
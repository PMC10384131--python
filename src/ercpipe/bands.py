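"""EEG frequency-band definitions.

The four oscillatory bands analysed by the pipeline, with their nominal
edges in Hz.  Band limits in the EEG literature are conventional; these
are the ranges used throughout this package:

* Theta: 3-7 Hz
* Alpha: 8-12 Hz
* Beta:  13-29 Hz
* Gamma: 30-69 Hz

At the 128 samples/s rate of consumer headsets the Gamma upper edge
exceeds the 64 Hz Nyquist frequency, so effective edges are capped at
``NYQUIST_MARGIN`` times Nyquist (a realizability constraint, logged when
it bites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: Fraction of Nyquist above which band edges are not allowed.
NYQUIST_MARGIN = 0.95


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with nominal edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"invalid band edges for {self.name!r}: "
                f"({self.low_hz}, {self.high_hz})"
            )

    def effective_edges(self, fs: float) -> tuple[float, float]:
        """Band edges usable at sampling rate ``fs``, capping at Nyquist.

        Raises ``ValueError`` if the band lies entirely above the
        realizable range.
        """
        cap = NYQUIST_MARGIN * fs / 2.0
        if self.low_hz >= cap:
            raise ValueError(
                f"band {self.name!r} ({self.low_hz}-{self.high_hz} Hz) lies "
                f"above the realizable limit {cap:.1f} Hz at fs={fs} Hz"
            )
        high = self.high_hz
        if high > cap:
            logger.info(
                "capping %s upper edge %.1f Hz to %.1f Hz (Nyquist limit at fs=%g)",
                self.name, high, cap, fs,
            )
            high = cap
        return self.low_hz, high


THETA = BandDefinition("Theta", 3.0, 7.0)
ALPHA = BandDefinition("Alpha", 8.0, 12.0)
BETA = BandDefinition("Beta", 13.0, 29.0)
GAMMA = BandDefinition("Gamma", 30.0, 69.0)

#: The analysis bands, keyed by name, in canonical order.
BANDS: dict[str, BandDefinition] = {
    b.name: b for b in (THETA, ALPHA, BETA, GAMMA)
}

BAND_NAMES = tuple(BANDS)


def get_band(name: str) -> BandDefinition:
    """Look up a band by (case-sensitive) name."""
    try:
        return BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; expected one of {list(BANDS)}"
        ) from None
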
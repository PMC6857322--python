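"""Canonical BOLD oscillation frequency bands.

The resting-state BOLD spectrum sampled at TR = 2 s (Nyquist 0.25 Hz) is
divided into the slow-6..slow-2 oscillation bands.  Connectomes are built
within slow-5, slow-4 and slow-3; slow-6 is dominated by scanner drift and
slow-2 by high-frequency physiological noise, so neither is analysed.  A
conventional broadband window (0.01-0.1 Hz) is kept as a control band.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BandDefinition",
    "SLOW5",
    "SLOW4",
    "SLOW3",
    "CONTROL_BAND",
    "ANALYSIS_BANDS",
    "full_partition",
    "nyquist_frequency",
]


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [low_hz, high_hz) in hertz.

    The half-open convention makes adjacent bands partition DFT bins
    exactly; the top band of a partition additionally absorbs the Nyquist
    bin (see :func:`oscnet.preprocess.bandpass_ideal`).
    """

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.name!r}: need 0 <= low < high, "
                f"got [{self.low_hz}, {self.high_hz})"
            )

    def validate_against_tr(self, tr_seconds: float) -> None:
        nyq = nyquist_frequency(tr_seconds)
        if self.low_hz >= nyq:
            raise ValueError(
                f"band {self.name!r} lies entirely above the Nyquist "
                f"frequency {nyq:g} Hz for TR={tr_seconds:g} s"
            )

    @property
    def width_hz(self) -> float:
        return self.high_hz - self.low_hz


def nyquist_frequency(tr_seconds: float) -> float:
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return 1.0 / (2.0 * tr_seconds)


SLOW5 = BandDefinition("slow-5", 0.01, 0.027)
SLOW4 = BandDefinition("slow-4", 0.027, 0.073)
SLOW3 = BandDefinition("slow-3", 0.073, 0.198)
CONTROL_BAND = BandDefinition("control-0.01-0.1", 0.01, 0.1)

#: The three bands in which connectomes are constructed.
ANALYSIS_BANDS: tuple[BandDefinition, ...] = (SLOW5, SLOW4, SLOW3)


def full_partition(tr_seconds: float) -> tuple[BandDefinition, ...]:
    """Five bands (slow-6 .. slow-2) that partition [0, Nyquist].

    slow-6 starts at 0 (DC included) and slow-2 runs up to the Nyquist
    frequency inclusive, so summing the five band-filtered signals
    reconstructs the input exactly.
    """
    nyq = nyquist_frequency(tr_seconds)
    if nyq <= SLOW3.high_hz:
        raise ValueError(
            f"TR={tr_seconds:g} s gives Nyquist {nyq:g} Hz <= {SLOW3.high_hz} Hz; "
            "the canonical five-band partition needs a faster sampling rate"
        )
    return (
        BandDefinition("slow-6", 0.0, SLOW5.low_hz),
        SLOW5,
        SLOW4,
        SLOW3,
        BandDefinition("slow-2", SLOW3.high_hz, nyq),
    )
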
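"""ROI-level ALFF and fractional ALFF per oscillation band.

ALFF of a band is the sum of single-sided DFT amplitudes over the band's
bins; fALFF divides that by the amplitude sum over the entire detectable
range (0, Nyquist], making it a scale-free spectral fraction.  The DC bin
is excluded everywhere.  fALFF values are z-standardized across ROIs
within subject before parametric group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import ANALYSIS_BANDS, BandDefinition, nyquist_frequency
from .preprocess import TimeSeriesMatrix

__all__ = [
    "SpectralProfile",
    "amplitude_spectrum",
    "alff",
    "falff",
    "zscore_across_rois",
    "falff_table",
]


@dataclass
class SpectralProfile:
    """Single-sided amplitude spectrum per ROI (DC bin excluded)."""

    frequencies: np.ndarray
    amplitudes: np.ndarray  # roi x frequency
    tr_seconds: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape[1] != self.frequencies.size:
            raise ValueError("amplitude columns must match the frequency grid")
        if not np.isfinite(self.amplitudes).all():
            raise ValueError("amplitudes contain non-finite values")


def amplitude_spectrum(ts: TimeSeriesMatrix) -> SpectralProfile:
    """Single-sided DFT amplitude per ROI from a broadband series.

    A band-filtered input is rejected: the fALFF denominator requires the
    full detectable spectrum.
    """
    if ts.band != "broadband":
        raise ValueError(
            f"fALFF requires a broadband series; got band {ts.band!r}"
        )
    spec = np.fft.rfft(ts.values, axis=1)
    freqs = np.fft.rfftfreq(ts.n_timepoints, d=ts.tr_seconds)
    amp = np.abs(spec)[:, 1:]  # drop DC
    return SpectralProfile(frequencies=freqs[1:], amplitudes=amp, tr_seconds=ts.tr_seconds)


def _band_columns(profile: SpectralProfile, band: BandDefinition) -> np.ndarray:
    nyq = nyquist_frequency(profile.tr_seconds)
    mask = (profile.frequencies >= band.low_hz) & (profile.frequencies < band.high_hz)
    if band.high_hz >= nyq * (1 - 1e-12):
        mask |= np.isclose(profile.frequencies, nyq)
    return mask


def alff(profile: SpectralProfile, band: BandDefinition) -> np.ndarray:
    """Sum of amplitudes over the band's bins, per ROI."""
    mask = _band_columns(profile, band)
    if not mask.any():
        raise ValueError(
            f"band {band.name!r} contains no DFT bins at this series length"
        )
    return profile.amplitudes[:, mask].sum(axis=1)


def falff(profile: SpectralProfile, band: BandDefinition) -> np.ndarray:
    """Band amplitude sum as a fraction of the full-range amplitude sum."""
    total = profile.amplitudes.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total spectral amplitude for at least one ROI")
    return alff(profile, band) / total


def zscore_across_rois(values: np.ndarray) -> np.ndarray:
    """Standardize a per-ROI vector to mean 0, sd 1 (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 ROIs to z-score")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across ROIs; z-score undefined")
    return (v - v.mean()) / sd


def falff_table(
    ts: TimeSeriesMatrix,
    bands: tuple[BandDefinition, ...] = ANALYSIS_BANDS,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Long-format per-ROI fALFF (raw and z-standardized) for each band."""
    profile = amplitude_spectrum(ts)
    labels = ts.roi_labels or [f"roi{i}" for i in range(ts.n_rois)]
    rows = []
    for band in bands:
        f = falff(profile, band)
        z = zscore_across_rois(f)
        for i in range(ts.n_rois):
            rows.append(
                {
                    "subject": subject_id,
                    "band": band.name,
                    "node": i,
                    "roi": labels[i],
                    "falff": f[i],
                    "falff_z": z[i],
                }
            )
    return pd.DataFrame(rows)
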
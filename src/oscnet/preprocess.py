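"""Time-series level preprocessing of ROI BOLD matrices.

The stages, applied in this order, mirror a conventional resting-state
pipeline operating after image-space registration: discard of initial
volumes, nuisance regression (Friston-24 motion expansion plus white-matter
and CSF signals), linear detrending, motion scrubbing by framewise
displacement, and ideal band-pass decomposition into oscillation bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import BandDefinition, nyquist_frequency

__all__ = [
    "TimeSeriesMatrix",
    "NuisanceDesign",
    "ScrubMask",
    "discard_initial_volumes",
    "regress_nuisance",
    "detrend_linear",
    "compute_fd_and_scrub",
    "apply_scrub",
    "bandpass_ideal",
    "friston24",
    "build_nuisance_design",
    "HEAD_RADIUS_MM",
]

#: Rotation-to-displacement conversion radius (Power's framewise displacement).
HEAD_RADIUS_MM = 50.0


@dataclass
class TimeSeriesMatrix:
    """An ROI x time matrix with its sampling interval and band provenance."""

    values: np.ndarray
    tr_seconds: float
    band: str = "broadband"
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D ROI x time matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 time points")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.roi_labels is not None and len(self.roi_labels) != self.values.shape[0]:
            raise ValueError("roi_labels length does not match the ROI dimension")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, band: str | None = None) -> "TimeSeriesMatrix":
        return replace(self, values=values, band=self.band if band is None else band)


@dataclass
class NuisanceDesign:
    """time x regressor design matrix for nuisance regression."""

    columns: np.ndarray
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("design must be 2-D (time x regressor)")
        if not self.column_names:
            self.column_names = [f"x{i}" for i in range(self.columns.shape[1])]
        if len(self.column_names) != self.columns.shape[1]:
            raise ValueError("column_names length mismatch")


@dataclass
class ScrubMask:
    """Per-frame bad/good flags derived from framewise displacement."""

    flags: np.ndarray
    fd_series: np.ndarray
    threshold_mm: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.fd_series = np.asarray(self.fd_series, dtype=float)
        if self.flags.shape != self.fd_series.shape:
            raise ValueError("flags and fd_series must have equal length")

    @property
    def fraction_bad(self) -> float:
        return float(self.flags.mean())


def discard_initial_volumes(ts: TimeSeriesMatrix, k: int) -> TimeSeriesMatrix:
    """Drop the first ``k`` time points (initial signal instability)."""
    if not 0 <= k < ts.n_timepoints:
        raise ValueError(
            f"cannot discard {k} volumes from a series of length {ts.n_timepoints}"
        )
    return ts.with_values(ts.values[:, k:])


def regress_nuisance(ts: TimeSeriesMatrix, design: NuisanceDesign) -> TimeSeriesMatrix:
    """Replace each ROI series by its least-squares residual against the design.

    An intercept column is appended if the design does not already span it.
    Near-duplicate columns are pruned before fitting; a design that is still
    rank deficient raises with the offending columns named.
    """
    X = design.columns
    names = list(design.column_names)
    if X.shape[0] != ts.n_timepoints:
        raise ValueError(
            f"design has {X.shape[0]} rows but the series has {ts.n_timepoints} time points"
        )
    ones = np.ones((X.shape[0], 1))
    X = np.hstack([ones, X])
    names = ["intercept"] + names

    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    X = X[:, keep]
    if X.shape[1] < 1 or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"nuisance design rank deficient; collinear columns: {dropped}")

    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values.T - X @ beta
    return ts.with_values(resid.T)


def detrend_linear(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Remove the per-ROI best-fit line (intercept + slope)."""
    if ts.n_timepoints < 3:
        raise ValueError("linear detrend needs at least 3 time points")
    t = np.arange(ts.n_timepoints, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    return ts.with_values((ts.values.T - X @ beta).T)


def framewise_displacement(motion_params: np.ndarray) -> np.ndarray:
    """Power's FD: sum of |backward differences| of the six rigid-body
    parameters, rotations (radians) converted to arc length on a 50 mm
    sphere.  The first frame has FD = 0 by convention."""
    P = np.asarray(motion_params, dtype=float)
    if P.ndim != 2 or P.shape[1] != 6:
        raise ValueError("motion_params must be time x 6 (3 translations mm, 3 rotations rad)")
    if P.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute framewise displacement")
    d = np.abs(np.diff(P, axis=0))
    d[:, 3:] *= HEAD_RADIUS_MM
    fd = np.zeros(P.shape[0])
    fd[1:] = d.sum(axis=1)
    return fd


def compute_fd_and_scrub(
    motion_params: np.ndarray,
    threshold_mm: float = 0.5,
    augment_policy: str = "none",
) -> ScrubMask:
    """Flag frames whose framewise displacement exceeds ``threshold_mm``.

    ``augment_policy="1back2fwd"`` additionally flags one frame before and
    two after each offender; the default flags the offending frame only.
    """
    fd = framewise_displacement(motion_params)
    flags = fd > threshold_mm
    if augment_policy == "1back2fwd":
        base = np.flatnonzero(flags)
        for t in base:
            flags[max(t - 1, 0) : min(t + 3, flags.size)] = True
    elif augment_policy != "none":
        raise ValueError(f"unknown augment_policy {augment_policy!r}")
    return ScrubMask(flags=flags, fd_series=fd, threshold_mm=threshold_mm)


def apply_scrub(
    ts: TimeSeriesMatrix, mask: ScrubMask, mode: str = "delete"
) -> tuple[TimeSeriesMatrix, dict]:
    """Delete flagged frames.  Returns the censored series and a report with
    the retained count and the fraction removed (the >1/3 subject-exclusion
    decision is taken upstream, not here)."""
    if mask.flags.size != ts.n_timepoints:
        raise ValueError("scrub mask length does not match the series")
    if mode != "delete":
        raise ValueError(f"unsupported scrub mode {mode!r}")
    good = ~mask.flags
    if not good.any():
        raise ValueError("all frames flagged bad; nothing to retain")
    report = {
        "n_retained": int(good.sum()),
        "n_removed": int(mask.flags.sum()),
        "fraction_removed": float(mask.flags.mean()),
    }
    return ts.with_values(ts.values[:, good]), report


def _band_bin_mask(n_timepoints: int, tr_seconds: float, band: BandDefinition) -> np.ndarray:
    """Boolean mask over rfft bins kept by the ideal filter.

    Bins with low <= f < high are kept; a band starting at 0 keeps DC and a
    band whose upper edge reaches the Nyquist frequency keeps the Nyquist
    bin, so a partition of [0, Nyquist] covers every bin exactly once.
    """
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    nyq = nyquist_frequency(tr_seconds)
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    if band.high_hz >= nyq * (1 - 1e-12):
        mask |= np.isclose(freqs, nyq)
    return mask


def bandpass_ideal(ts: TimeSeriesMatrix, band: BandDefinition) -> TimeSeriesMatrix:
    """Ideal (rectangular) Fourier band-pass filter, per ROI.

    DFT coefficients outside the half-open interval [low, high) are zeroed
    and the signal inverse-transformed; no taper is applied, so disjoint
    bands sum exactly to the unfiltered signal.
    """
    band.validate_against_tr(ts.tr_seconds)
    mask = _band_bin_mask(ts.n_timepoints, ts.tr_seconds, band)
    spec = np.fft.rfft(ts.values, axis=1)
    spec[:, ~mask] = 0.0
    out = np.fft.irfft(spec, n=ts.n_timepoints, axis=1)
    return ts.with_values(out, band=band.name)


def friston24(motion_params: np.ndarray) -> np.ndarray:
    """Friston's 24-parameter motion expansion.

    The six rigid-body parameters, their one-frame lags, and the squares of
    both (the lagged row for frame 0 is zero).
    """
    P = np.asarray(motion_params, dtype=float)
    if P.ndim != 2 or P.shape[1] != 6:
        raise ValueError("motion_params must be time x 6")
    lag = np.vstack([np.zeros((1, 6)), P[:-1]])
    return np.hstack([P, lag, P**2, lag**2])


def build_nuisance_design(
    motion_params: np.ndarray,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> NuisanceDesign:
    """Assemble the standard nuisance design: Friston-24 motion expansion
    plus white-matter and CSF mean signals (intercept added at fit time)."""
    cols = [friston24(motion_params)]
    names = (
        [f"motion{i+1}" for i in range(6)]
        + [f"motion{i+1}_lag" for i in range(6)]
        + [f"motion{i+1}_sq" for i in range(6)]
        + [f"motion{i+1}_lag_sq" for i in range(6)]
    )
    for sig, name in ((wm_signal, "wm"), (csf_signal, "csf")):
        if sig is not None:
            sig = np.asarray(sig, dtype=float).reshape(-1, 1)
            cols.append(sig)
            names.append(name)
    return NuisanceDesign(columns=np.hstack(cols), column_names=names)
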
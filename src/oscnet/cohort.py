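"""Synthetic resting-state cohorts with plantable band-specific hub effects.

The generator emulates a three-group study (early-stage parkinsonian EPD,
middle-stage MPD, and normal controls NC): 112 ROI time series of 205
volumes at TR = 2 s per subject, six rigid-body motion parameters,
white-matter/CSF nuisance signals, and a clinical metadata table (age,
sex, education, MMSE, UPDRS motor items, head motion).

Signal model, per subject and oscillation band: every ROI is a mixture of
a global band-limited factor (baseline inter-regional correlation c0),
optional planted-effect factors, and idiosyncratic band-limited noise.  A
:class:`HubEffect` with sign="increase" couples its hub nodes to a partner
community through a shared latent factor (raising hub-partner latent
correlation by ``connectivity_delta`` in that band only); one with
sign="decrease" detunes its hub nodes from the band's global factor
(lowering their correlation with all nodes by the same amount).
Broadband white measurement
noise, linear drift, and motion/WM/CSF leakage are added on top, so the
preprocessing stages have real work to do.

Group-level covariate distributions default to values typical of an
early-to-middle-stage Parkinson cohort; a :class:`MotorLink` can tie a
motor subscale to the per-subject strength of a planted effect so that
clinical correlation analyses have a recoverable planted association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import N_NODES, atlas_labels, index_of
from .bands import BandDefinition, full_partition
from .preprocess import TimeSeriesMatrix, bandpass_ideal, framewise_displacement

__all__ = [
    "HubEffect",
    "MotorLink",
    "GroupCovariates",
    "CovariateModel",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "compute_updrs_subscales",
    "apply_qc_filters",
    "default_parkinson_effects",
    "MMSE_THRESHOLDS",
    "GROUPS",
    "save_cohort",
    "read_timeseries_tsv",
]

GROUPS = ("EPD", "MPD", "NC")

#: Education-weighted MMSE cutoffs; a score at or below the cutoff for the
#: subject's literacy class marks potential cognitive impairment (excluded).
MMSE_THRESHOLDS = {
    "illiterate": 17,
    "grade-school": 20,
    "junior-high-or-higher": 23,
}

_TREMOR_ITEMS = (20, 21)
_AR_ITEMS = (22, 23, 24, 25, 26, 27, 31)
_OTHER_MOTOR_ITEMS = (18, 19, 28, 29, 30)
ALL_MOTOR_ITEMS = tuple(range(18, 32))


@dataclass(frozen=True)
class HubEffect:
    """A band-specific shift of hub-node connectivity in selected groups.

    sign="increase": hubs in ``node_ids`` are coupled to a ``partner_ids``
    community through a shared latent factor, raising each hub-partner
    latent correlation by ``connectivity_delta`` within ``band`` only
    (when ``partner_ids`` is None a deterministic community of
    ``n_partners`` non-hub nodes is used).

    sign="decrease": hubs are detuned from the band's global background
    factor instead, lowering their latent correlation with every other
    node by ``connectivity_delta`` (no partner community involved); the
    decrease cannot exceed the baseline correlation.
    """

    node_ids: tuple[int, ...]
    band: str
    groups_affected: tuple[str, ...]
    connectivity_delta: float
    sign: str = "increase"
    partner_ids: tuple[int, ...] | None = None
    n_partners: int = 70
    partner_loading: float = 0.35

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        object.__setattr__(self, "groups_affected", tuple(self.groups_affected))
        if self.partner_ids is not None:
            object.__setattr__(self, "partner_ids", tuple(self.partner_ids))
        if self.sign not in ("increase", "decrease"):
            raise ValueError("sign must be 'increase' or 'decrease'")
        if self.connectivity_delta < 0:
            raise ValueError("connectivity_delta must be non-negative; use sign")
        unknown = set(self.groups_affected) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if not 0 < self.partner_loading < 1:
            raise ValueError("partner_loading must lie in (0, 1)")

    @property
    def signed_delta(self) -> float:
        return self.connectivity_delta if self.sign == "increase" else -self.connectivity_delta

    def resolve_partners(self, n_rois: int) -> tuple[int, ...]:
        if any(not 0 <= i < n_rois for i in self.node_ids):
            raise ValueError(f"node_ids out of range [0, {n_rois})")
        if self.partner_ids is not None:
            if any(not 0 <= i < n_rois for i in self.partner_ids):
                raise ValueError(f"partner_ids out of range [0, {n_rois})")
            return self.partner_ids
        pool = [i for i in range(n_rois) if i not in self.node_ids]
        if self.n_partners > len(pool):
            raise ValueError("n_partners exceeds the number of non-hub nodes")
        # evenly spread over the atlas for a deterministic community
        idx = np.linspace(0, len(pool) - 1, self.n_partners).round().astype(int)
        return tuple(pool[i] for i in idx)

    def hub_loading(self) -> float:
        return self.connectivity_delta / self.partner_loading


@dataclass(frozen=True)
class MotorLink:
    """Ties a UPDRS motor subscale to a planted effect's per-subject strength.

    For affected subjects the subscale target becomes
    ``group mean + slope * (m_s - 1) + noise`` where ``m_s`` is the
    subject's effect multiplier (mean 1).  A positive slope on a
    "decrease" effect yields a negative metric-score correlation.
    """

    effect_index: int
    subscale: str  # "akinesia_rigidity" or "tremor"
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.subscale not in ("akinesia_rigidity", "tremor"):
            raise ValueError("subscale must be 'akinesia_rigidity' or 'tremor'")


@dataclass(frozen=True)
class GroupCovariates:
    """Mean/SD parameters of one group's clinical covariates."""

    age: tuple[float, float]
    education: tuple[float, float]
    mmse: tuple[float, float]
    head_motion: tuple[float, float]
    updrs_motor: tuple[float, float]
    akinesia_rigidity: tuple[float, float]
    tremor: tuple[float, float]
    p_female: float
    duration: tuple[float, float] | None = None
    hoehn_yahr: tuple[float, ...] = (0.0,)


def _default_group_covariates() -> dict[str, GroupCovariates]:
    # typical early/middle-stage parkinsonian cohort demographics
    return {
        "EPD": GroupCovariates(
            age=(56.5, 8.2),
            education=(10.0, 4.1),
            mmse=(28.1, 1.9),
            head_motion=(0.121, 0.077),
            updrs_motor=(14.8, 6.1),
            akinesia_rigidity=(8.9, 3.9),
            tremor=(2.5, 1.8),
            p_female=18 / 39,
            duration=(3.4, 3.6),
            hoehn_yahr=(1.0, 1.5),
        ),
        "MPD": GroupCovariates(
            age=(62.3, 8.9),
            education=(7.0, 5.0),
            mmse=(26.5, 2.8),
            head_motion=(0.134, 0.077),
            updrs_motor=(32.6, 12.6),
            akinesia_rigidity=(21.6, 8.9),
            tremor=(5.2, 4.7),
            p_female=20 / 49,
            duration=(4.0, 3.1),
            hoehn_yahr=(2.0, 2.5),
        ),
        "NC": GroupCovariates(
            age=(58.1, 8.1),
            education=(11.2, 3.6),
            mmse=(28.7, 1.7),
            head_motion=(0.129, 0.065),
            updrs_motor=(0.6, 1.1),
            akinesia_rigidity=(0.3, 0.6),
            tremor=(0.2, 0.5),
            p_female=20 / 36,
        ),
    }


@dataclass(frozen=True)
class CovariateModel:
    """Clinical covariate distributions and their link to planted effects."""

    groups: Mapping[str, GroupCovariates] = field(default_factory=_default_group_covariates)
    motor_link: MotorLink | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"EPD": 39, "MPD": 49, "NC": 36}
    )
    n_rois: int = N_NODES
    n_timepoints: int = 205
    tr_seconds: float = 2.0
    planted_effects: tuple[HubEffect, ...] = ()
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0
    baseline_correlation: float = 0.2
    baseline_correlation_jitter: float = 0.03
    band_power: Mapping[str, float] = field(
        default_factory=lambda: {"slow-6": 0.0, "slow-5": 1.0, "slow-4": 1.0, "slow-3": 1.0, "slow-2": 0.25}
    )
    white_noise_sd: float = 0.6
    drift_sd: float = 0.7
    effect_variability: float = 0.2
    motion_spike_prob: float = 0.015
    nuisance_leak_sd: float = 0.12
    #: frames of unstable initial signal prepended to the band-aligned core
    #: (the downstream initial-volume discard removes exactly these)
    n_burnin: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError(f"need at least 2 subjects per group, got {n} for {g}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_timepoints <= self.n_burnin:
            raise ValueError("n_timepoints must exceed the burn-in/discard count")
        if not 0 < self.baseline_correlation < 1:
            raise ValueError("baseline_correlation must lie in (0, 1)")
        band_names = {b.name for b in full_partition(self.tr_seconds)}
        for eff in self.planted_effects:
            if eff.band not in band_names:
                raise ValueError(f"effect band {eff.band!r} not a canonical band")
            eff.resolve_partners(self.n_rois)
        self.validate_feasibility()

    def validate_feasibility(self) -> None:
        """Reject planted effects whose latent correlations leave (-1, 1)
        or whose factor loadings exceed unit node variance."""
        c0 = self.baseline_correlation + 3 * self.baseline_correlation_jitter
        load2 = {b.name: np.full(self.n_rois, c0) for b in full_partition(self.tr_seconds)}
        for eff in self.planted_effects:
            hub_corr = c0 + eff.signed_delta
            if not -1.0 < hub_corr < 1.0:
                raise ValueError(
                    f"infeasible connectivity_delta {eff.connectivity_delta}: "
                    f"latent hub correlation {hub_corr:.3f} outside (-1, 1)"
                )
            if eff.sign == "decrease":
                if eff.connectivity_delta > self.baseline_correlation:
                    raise ValueError(
                        f"infeasible connectivity_delta {eff.connectivity_delta}: "
                        f"a decrease cannot exceed the baseline latent correlation "
                        f"{self.baseline_correlation}"
                    )
                continue
            beta = eff.hub_loading()
            sq = load2[eff.band].copy()
            for i in eff.node_ids:
                sq[i] += beta**2
            for i in eff.resolve_partners(self.n_rois):
                sq[i] += eff.partner_loading**2
            if (sq >= 1.0).any():
                raise ValueError(
                    f"infeasible connectivity_delta {eff.connectivity_delta}: "
                    f"factor loadings in band {eff.band} exceed unit variance "
                    f"(reduce delta or raise partner_loading)"
                )
            load2[eff.band] = sq


def default_parkinson_effects(
    delta_basal_ganglia: float = 0.25,
    delta_occipital: float = 0.15,
    ar_slope: float = 25.0,
    ar_noise_sd: float = 3.0,
) -> tuple[tuple[HubEffect, ...], MotorLink]:
    """The default planted scenario: slow-5 basal-ganglia hyperconnectivity
    in the middle-stage group, and a slow-3 occipital disruption whose
    per-subject severity drives the akinesia/rigidity score."""
    effects = (
        HubEffect(
            node_ids=(index_of("Putamen", "L"), index_of("Putamen", "R")),
            band="slow-5",
            groups_affected=("MPD",),
            connectivity_delta=delta_basal_ganglia,
            sign="increase",
        ),
        HubEffect(
            node_ids=(
                index_of("Occipital Pole", "L"),
                index_of("Occipital Pole", "R"),
                index_of("Lateral Occipital Cortex, superior division", "L"),
                index_of("Lateral Occipital Cortex, superior division", "R"),
            ),
            band="slow-3",
            groups_affected=("MPD",),
            connectivity_delta=delta_occipital,
            sign="decrease",
        ),
    )
    link = MotorLink(
        effect_index=1, subscale="akinesia_rigidity", slope=ar_slope, noise_sd=ar_noise_sd
    )
    return effects, link


@dataclass
class Cohort:
    """A generated cohort: per-subject broadband series and metadata."""

    spec: CohortSpec
    timeseries: dict[str, TimeSeriesMatrix]
    motion: dict[str, np.ndarray]
    nuisance: dict[str, dict[str, np.ndarray]]
    table: pd.DataFrame

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])


def compute_updrs_subscales(updrs_items: Mapping[int, int]) -> tuple[int, int]:
    """(tremor, akinesia/rigidity) motor subscales.

    tremor = items 20 + 21; akinesia/rigidity = items 22-27 plus 31.
    """
    for item in _TREMOR_ITEMS + _AR_ITEMS:
        if item not in updrs_items:
            raise KeyError(f"UPDRS item {item} missing; cannot compute subscales")
    tremor = sum(int(updrs_items[i]) for i in _TREMOR_ITEMS)
    ar = sum(int(updrs_items[i]) for i in _AR_ITEMS)
    return tremor, ar


def _literacy_class(education_years: int) -> str:
    if education_years <= 0:
        return "illiterate"
    if education_years <= 6:
        return "grade-school"
    return "junior-high-or-higher"


def _distribute_score(rng: np.random.Generator, total: int, items: Sequence[int], cap: int = 4) -> dict[int, int]:
    """Spread an integer score across items, each capped at ``cap``."""
    scores = {i: 0 for i in items}
    capacity = cap * len(items)
    remaining = min(int(round(total)), capacity)
    open_items = list(items)
    while remaining > 0 and open_items:
        i = open_items[rng.integers(len(open_items))]
        scores[i] += 1
        remaining -= 1
        if scores[i] >= cap:
            open_items.remove(i)
    return scores


def _truncated_normal(rng, mu, sd, lo=None, hi=None):
    x = rng.normal(mu, sd)
    if lo is not None:
        x = max(x, lo)
    if hi is not None:
        x = min(x, hi)
    return x


def _motion_trace(rng: np.random.Generator, T: int, target_fd: float, spike_prob: float) -> np.ndarray:
    """Random-walk rigid-body parameters calibrated to a mean FD target,
    with occasional single-frame spikes that scrubbing should catch."""
    # mean FD of a random walk: (3*s_t + 3*50*s_r) * sqrt(2/pi)
    s_t = target_fd / (6.0 * np.sqrt(2.0 / np.pi))
    s_r = s_t / 50.0
    steps = rng.normal(0.0, 1.0, size=(T - 1, 6))
    steps[:, :3] *= s_t
    steps[:, 3:] *= s_r
    P = np.vstack([np.zeros((1, 6)), np.cumsum(steps, axis=0)])
    spikes = rng.random(T) < spike_prob
    spikes[0] = False
    for t in np.flatnonzero(spikes):
        axis = rng.integers(3)
        P[t, axis] += rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.4)
    return P


def _band_fraction(T: int, tr: float, band: BandDefinition) -> float:
    from .preprocess import _band_bin_mask

    mask = _band_bin_mask(T, tr, band)
    freqs = np.fft.rfftfreq(T, d=tr)
    # power fraction kept by the filter for unit white noise
    weight = np.ones_like(freqs)
    weight[0] = 0.5
    if T % 2 == 0:
        weight[-1] = 0.5
    return float(weight[mask].sum() / weight.sum())


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a deterministic cohort from a :class:`CohortSpec`.

    The same spec (including seed) always yields identical arrays and
    metadata.  Returns broadband, unpreprocessed series (initial-volume
    discard, nuisance regression, scrubbing and band-splitting are the
    preprocessing stages' job).
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_timepoints
    Tb = spec.n_burnin
    Tc = T - Tb  # band-aligned core length (what survives the discard)
    tr = spec.tr_seconds
    n = spec.n_rois
    labels = atlas_labels() if n == N_NODES else [f"roi{i}" for i in range(n)]
    bands = full_partition(tr)
    fracs = {b.name: _band_fraction(Tc, tr, b) for b in bands}
    partners = {e: e.resolve_partners(n) for e in spec.planted_effects}

    # per-ROI leakage loadings, shared across subjects
    wm_load = rng.normal(0.0, spec.nuisance_leak_sd, size=n)
    csf_load = rng.normal(0.0, spec.nuisance_leak_sd, size=n)
    motion_load = rng.normal(0.0, spec.nuisance_leak_sd / 2.0, size=(6, n))

    timeseries: dict[str, TimeSeriesMatrix] = {}
    motion: dict[str, np.ndarray] = {}
    nuisance: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    link = spec.covariate_model.motor_link

    counter = 0
    for group in GROUPS:
        n_g = spec.n_per_group.get(group, 0)
        gc = spec.covariate_model.groups[group]
        for _ in range(n_g):
            counter += 1
            sid = f"sub-{counter:03d}"
            age = round(_truncated_normal(rng, *gc.age, lo=30, hi=90), 1)
            sex = "F" if rng.random() < gc.p_female else "M"
            education = int(round(_truncated_normal(rng, *gc.education, lo=0, hi=22)))
            mmse = int(round(_truncated_normal(rng, *gc.mmse, lo=0, hi=30)))
            target_fd = _truncated_normal(rng, *gc.head_motion, lo=0.02)
            duration = (
                round(_truncated_normal(rng, *gc.duration, lo=0.1), 1)
                if gc.duration
                else 0.0
            )
            hy = float(rng.choice(np.asarray(gc.hoehn_yahr)))

            # per-subject effect strength multipliers (mean 1, clipped to
            # keep factor loadings feasible)
            multipliers: dict[HubEffect, float] = {}
            c0 = float(
                np.clip(
                    rng.normal(spec.baseline_correlation, spec.baseline_correlation_jitter),
                    0.05,
                    0.6,
                )
            )
            for eff in spec.planted_effects:
                m = max(0.0, rng.normal(1.0, spec.effect_variability))
                if eff.sign == "decrease":
                    m_max = c0 / max(eff.connectivity_delta, 1e-12)
                else:
                    m_max = eff.partner_loading * np.sqrt(
                        max(1 - c0 - 1e-3, 0.0)
                    ) / max(eff.connectivity_delta, 1e-12)
                multipliers[eff] = float(min(m, m_max))

            # clinical motor scores, optionally linked to an effect
            tremor_target = _truncated_normal(rng, *gc.tremor, lo=0)
            ar_target = _truncated_normal(rng, *gc.akinesia_rigidity, lo=0)
            if link is not None:
                eff = spec.planted_effects[link.effect_index]
                if group in eff.groups_affected:
                    shift = link.slope * (multipliers[eff] - 1.0) + rng.normal(
                        0.0, link.noise_sd
                    )
                    if link.subscale == "akinesia_rigidity":
                        ar_target = max(0.0, gc.akinesia_rigidity[0] + shift)
                    else:
                        tremor_target = max(0.0, gc.tremor[0] + shift)

            items = _distribute_score(rng, int(round(tremor_target)), _TREMOR_ITEMS)
            items.update(_distribute_score(rng, int(round(ar_target)), _AR_ITEMS))
            tremor_score, ar_score = compute_updrs_subscales(items)
            other_target = max(
                0.0, _truncated_normal(rng, *gc.updrs_motor, lo=0) - tremor_score - ar_score
            )
            items.update(
                _distribute_score(rng, int(round(other_target)), _OTHER_MOTOR_ITEMS)
            )
            updrs_motor = sum(items.values())

            # ---- BOLD signal assembly -------------------------------------
            # the neural component is built on the post-discard grid so the
            # planted band structure aligns exactly with the analysis bins
            X = np.zeros((n, Tc))
            for band in bands:
                w = spec.band_power.get(band.name, 0.0)
                if w <= 0:
                    continue
                # global-factor loadings; a "decrease" effect detunes its hub
                # nodes from the background factor so every edge touching
                # them drops by delta * m_s
                a = np.full(n, np.sqrt(c0))
                factors = []
                for eff in spec.planted_effects:
                    if eff.band != band.name or group not in eff.groups_affected:
                        continue
                    m_s = multipliers[eff]
                    if eff.sign == "decrease":
                        kappa = eff.connectivity_delta * m_s / np.sqrt(c0)
                        for i in eff.node_ids:
                            a[i] = max(a[i] - kappa, 0.0)
                    else:
                        # an "increase" effect couples hubs to a partner
                        # community through a shared factor: hub-partner
                        # latent correlation rises by delta * m_s
                        lam_e = np.zeros(n)
                        beta = eff.connectivity_delta * m_s / eff.partner_loading
                        for i in eff.node_ids:
                            lam_e[i] += beta
                        for i in partners[eff]:
                            lam_e[i] += eff.partner_loading
                        factors.append(lam_e)
                g_t = rng.standard_normal(Tc)
                U = a[:, None] * g_t[None, :]
                sq = a**2
                for lam_e in factors:
                    h_t = rng.standard_normal(Tc)
                    U = U + lam_e[:, None] * h_t[None, :]
                    sq = sq + lam_e**2
                idio = np.sqrt(np.clip(1.0 - sq, 1e-6, None))
                U = U + idio[:, None] * rng.standard_normal((n, Tc))
                comp = bandpass_ideal(
                    TimeSeriesMatrix(U, tr_seconds=tr, band="broadband"), band
                ).values
                X += np.sqrt(w / fracs[band.name]) * comp

            # unstable initial frames: matched-variance noise plus a
            # decaying saturation transient (removed by the volume discard)
            total_sd = float(np.sqrt(sum(
                w for bname, w in spec.band_power.items() if w > 0
            )))
            prefix = total_sd * rng.standard_normal((n, Tb))
            prefix += 2.0 * total_sd * np.exp(-np.arange(Tb) / 3.0)[None, :]
            X = np.hstack([prefix, X])

            X += spec.white_noise_sd * rng.standard_normal((n, T))
            slope = rng.normal(0.0, spec.drift_sd, size=n)
            X += slope[:, None] * np.linspace(-1.0, 1.0, T)[None, :]

            P = _motion_trace(rng, T, target_fd, spec.motion_spike_prob)
            Pz = (P - P.mean(axis=0)) / (P.std(axis=0) + 1e-12)
            X += (Pz @ motion_load).T

            lowpass = BandDefinition("nuis", 0.0, 0.1)
            wm = bandpass_ideal(
                TimeSeriesMatrix(
                    rng.standard_normal((1, T)), tr_seconds=tr, band="broadband"
                ),
                lowpass,
            ).values[0]
            csf = bandpass_ideal(
                TimeSeriesMatrix(
                    rng.standard_normal((1, T)), tr_seconds=tr, band="broadband"
                ),
                lowpass,
            ).values[0]
            X += np.outer(wm_load, wm) + np.outer(csf_load, csf)

            fd = framewise_displacement(P)
            timeseries[sid] = TimeSeriesMatrix(
                X, tr_seconds=tr, band="broadband", roi_labels=labels
            )
            motion[sid] = P
            nuisance[sid] = {"wm": wm, "csf": csf}

            row = {
                "subject_id": sid,
                "group": group,
                "age": age,
                "sex": sex,
                "education_years": education,
                "literacy_class": _literacy_class(education),
                "mmse": mmse,
                "duration_years": duration,
                "hoehn_yahr": hy,
                "updrs_motor": updrs_motor,
                "tremor_score": tremor_score,
                "ar_score": ar_score,
                "head_motion": float(fd.mean()),
                "max_translation_mm": float(np.abs(P[:, :3]).max()),
                "max_rotation_deg": float(np.degrees(np.abs(P[:, 3:]).max())),
                "qc_status": "included",
            }
            for item, score in sorted(items.items()):
                row[f"updrs_item{item}"] = score
            rows.append(row)

    table = pd.DataFrame(rows)
    return Cohort(spec=spec, timeseries=timeseries, motion=motion, nuisance=nuisance, table=table)


def apply_qc_filters(
    table: pd.DataFrame,
    scrub_fractions: Mapping[str, float] | None = None,
    max_translation_mm: Mapping[str, float] | None = None,
    max_rotation_deg: Mapping[str, float] | None = None,
    motion_limit_mm: float = 2.0,
    rotation_limit_deg: float = 2.0,
    scrub_limit: float = 1.0 / 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Flag subjects violating the standard exclusion rules.

    Rules (a subject may trip several; all are recorded):
      * motion   -- max translation > 2 mm or max rotation > 2 degrees
      * cognition -- MMSE at or below the literacy-specific cutoff
      * scrubbing -- more than 1/3 of frames removed by scrubbing

    The function is pure (returns a new table) and each rule is evaluated
    independently, so the filter is idempotent and order-independent.
    """
    table = table.copy()
    reasons: dict[str, list[str]] = {sid: [] for sid in table["subject_id"]}

    def lookup(mapping, sid, column):
        if mapping is not None:
            return mapping.get(sid)
        if column in table.columns:
            return table.set_index("subject_id").at[sid, column]
        return None

    trans = table.set_index("subject_id")
    for sid in table["subject_id"]:
        mt = lookup(max_translation_mm, sid, "max_translation_mm")
        mr = lookup(max_rotation_deg, sid, "max_rotation_deg")
        if (mt is not None and mt > motion_limit_mm) or (
            mr is not None and mr > rotation_limit_deg
        ):
            reasons[sid].append("motion")
        mmse = trans.at[sid, "mmse"]
        lit = trans.at[sid, "literacy_class"]
        if mmse <= MMSE_THRESHOLDS[lit]:
            reasons[sid].append("cognition")
        sf = None if scrub_fractions is None else scrub_fractions.get(sid)
        if sf is not None and sf > scrub_limit:
            reasons[sid].append("scrubbing")

    status = [
        "included" if not r else "excluded:" + "+".join(r)
        for r in (reasons[sid] for sid in table["subject_id"])
    ]
    table["qc_status"] = status
    counts = {"motion": 0, "cognition": 0, "scrubbing": 0}
    for r in reasons.values():
        for rule in r:
            counts[rule] += 1
    log = {
        "n_total": len(table),
        "n_included": int((table["qc_status"] == "included").sum()),
        "counts_per_rule": counts,
        "excluded": {
            sid: r for sid, r in reasons.items() if r
        },
    }
    return table, log


# ---------------------------------------------------------------------------
# plain-text persistence

def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write per-subject TSV time series, motion text files, the metadata
    CSV, and (if QC was applied) an exclusion log."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(parents=True, exist_ok=True)
    for sid, ts in cohort.timeseries.items():
        header = "\t".join(str(t) for t in range(ts.n_timepoints))
        np.savetxt(
            out / "timeseries" / f"{sid}.tsv",
            ts.values,
            delimiter="\t",
            header=header,
            comments="",
            fmt="%.6f",
        )
        np.savetxt(out / "motion" / f"{sid}.txt", cohort.motion[sid], fmt="%.8f")
    cohort.table.to_csv(out / "cohort.csv", index=False)


def read_timeseries_tsv(path: str | Path, tr_seconds: float, roi_labels=None) -> TimeSeriesMatrix:
    values = np.loadtxt(path, delimiter="\t", skiprows=1)
    return TimeSeriesMatrix(values, tr_seconds=tr_seconds, band="broadband", roi_labels=roi_labels)
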
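"""Seeded simulation studies over the full analysis pipeline.

Three replicated experiments characterize the pipeline's statistical
behaviour end-to-end on synthetic cohorts:

* :func:`null_calibration` -- with no planted effects, the mean number of
  nodes passing the 1/N threshold per analysis should be about one (the
  "less than one false positive per analysis" design of the threshold).
* :func:`hub_detection_study` -- a planted slow-5 hub effect must be
  detected in the slow-5 degree-AUC contrast and not leak into slow-4 or
  slow-3 beyond null rates.
* :func:`motor_association_study` -- a planted slow-3 occipital
  disruption whose severity drives the akinesia/rigidity score must be
  recovered as a negative partial correlation with the AR subscale
  (tremor regressed out) and no systematic tremor association.

Replicate counts and group sizes default to desk-scale values; the
per-replicate cohorts follow the generator's standard acquisition
constants (112 ROIs, 205 volumes, TR 2 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import index_of
from .bands import ANALYSIS_BANDS
from .cohort import CohortSpec, CovariateModel, HubEffect, MotorLink
from .inference import significance_threshold
from .model import OscillationNodalModel

__all__ = [
    "NullCalibrationResult",
    "HubDetectionResult",
    "MotorAssociationResult",
    "null_calibration",
    "hub_detection_study",
    "motor_association_study",
]

_COVARIATES = ("age", "sex_indicator", "head_motion")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


@dataclass
class NullCalibrationResult:
    counts: np.ndarray  # cohorts x metrics: significant nodes per analysis
    metrics: tuple[str, ...]
    threshold: float

    @property
    def mean_per_analysis(self) -> float:
        return float(self.counts.mean())

    @property
    def sem_per_analysis(self) -> float:
        per_cohort = self.counts.mean(axis=1)
        return float(per_cohort.std(ddof=1) / np.sqrt(len(per_cohort)))


def null_calibration(
    n_cohorts: int = 50,
    n_per_group: int = 15,
    seed: int = 0,
    metrics: tuple[str, ...] = ("degree", "betweenness", "efficiency"),
    band=ANALYSIS_BANDS[1],
    contrast: tuple[str, str] = ("MPD", "NC"),
) -> NullCalibrationResult:
    """False-positive calibration under the global null.

    Generates cohorts with no planted effects, runs the full pipeline in
    one band, and counts nodes passing the single-contrast 1/N threshold
    for each metric (= one "analysis").
    """
    counts = np.zeros((n_cohorts, len(metrics)))
    thr = None
    for ci, s in enumerate(_child_seeds(seed, n_cohorts)):
        spec = CohortSpec(
            n_per_group={contrast[0]: n_per_group, contrast[1]: n_per_group},
            seed=s,
        )
        model = OscillationNodalModel.from_cohort_spec(spec, bands=(band,))
        res = model.fit(metrics=metrics, compute_falff=False)
        thr = significance_threshold(res.n_nodes, 1)
        for mi, m in enumerate(metrics):
            tab = res.contrast_table(m, band.name, contrast, _COVARIATES)
            counts[ci, mi] = int(tab["significant"].sum())
    return NullCalibrationResult(counts=counts, metrics=tuple(metrics), threshold=thr)


@dataclass
class HubDetectionResult:
    detected_in_band: np.ndarray  # bool per cohort (all hubs significant, right sign)
    detected_off_band: dict[str, np.ndarray]  # per off band: any hub significant
    hub_nodes: tuple[int, ...]

    @property
    def detection_rate(self) -> float:
        return float(self.detected_in_band.mean())

    def off_band_rate(self, band: str) -> float:
        return float(self.detected_off_band[band].mean())


def hub_detection_study(
    n_cohorts: int = 40,
    seed: int = 0,
    n_affected: int = 49,
    n_control: int = 36,
    delta: float = 0.25,
    affected_group: str = "MPD",
) -> HubDetectionResult:
    """Recovery of a planted slow-5 basal-ganglia hub effect.

    Each replicate plants a +delta slow-5 effect at the putamen-analog
    nodes in the affected group only, runs the full pipeline in all three
    bands, and tests the degree-AUC group contrast at the 1/N threshold.
    Detection requires every hub node significant with the planted
    direction in slow-5; off-band detections (any hub significant in
    slow-4/slow-3) estimate leakage.
    """
    hubs = (index_of("Putamen", "L"), index_of("Putamen", "R"))
    effect = HubEffect(
        node_ids=hubs,
        band="slow-5",
        groups_affected=(affected_group,),
        connectivity_delta=delta,
        sign="increase",
    )
    in_band = np.zeros(n_cohorts, dtype=bool)
    off = {b.name: np.zeros(n_cohorts, dtype=bool) for b in ANALYSIS_BANDS[1:]}
    for ci, s in enumerate(_child_seeds(seed, n_cohorts)):
        spec = CohortSpec(
            n_per_group={affected_group: n_affected, "NC": n_control},
            planted_effects=(effect,),
            seed=s,
        )
        model = OscillationNodalModel.from_cohort_spec(spec, bands=ANALYSIS_BANDS)
        res = model.fit(metrics=("degree",), compute_falff=False)
        contrast = (affected_group, "NC")
        tab5 = res.contrast_table("degree", "slow-5", contrast, _COVARIATES)
        hits = tab5.loc[tab5["node"].isin(hubs)]
        in_band[ci] = bool(
            hits["significant"].all() and (hits["t_value"] > 0).all()
        )
        for band in ANALYSIS_BANDS[1:]:
            tab = res.contrast_table("degree", band.name, contrast, _COVARIATES)
            off[band.name][ci] = bool(
                tab.loc[tab["node"].isin(hubs), "significant"].any()
            )
    return HubDetectionResult(detected_in_band=in_band, detected_off_band=off, hub_nodes=hubs)


@dataclass
class MotorAssociationResult:
    ar_negative_significant: np.ndarray  # per cohort
    tremor_nonsignificant: np.ndarray
    ar_r: np.ndarray  # mean partial r at planted nodes per cohort

    @property
    def ar_recovery_rate(self) -> float:
        return float(self.ar_negative_significant.mean())

    @property
    def tremor_specificity_rate(self) -> float:
        return float(self.tremor_nonsignificant.mean())


def motor_association_study(
    n_cohorts: int = 40,
    seed: int = 0,
    n_patients: int = 49,
    delta: float = 0.15,
    ar_slope: float = 25.0,
    ar_noise_sd: float = 3.0,
    severity_sd: float = 0.4,
) -> MotorAssociationResult:
    """Recovery of a planted occipital slow-3 / akinesia-rigidity link.

    The planted effect lowers occipital-analog connectivity in slow-3 with
    per-subject severity; the akinesia/rigidity score is generated from
    that severity.  The screen computes, within patients, the partial
    correlation of each planted node's slow-3 degree AUC with each motor
    subscale (the other subscale and the standard covariates regressed
    out).  Recovery = significantly negative AR partial r (Bonferroni over
    the screened family) at at least one planted node with no planted node
    significant for tremor.
    """
    nodes = (
        index_of("Occipital Pole", "L"),
        index_of("Occipital Pole", "R"),
        index_of("Lateral Occipital Cortex, superior division", "L"),
        index_of("Lateral Occipital Cortex, superior division", "R"),
    )
    effect = HubEffect(
        node_ids=nodes,
        band="slow-3",
        groups_affected=("MPD",),
        connectivity_delta=delta,
        sign="decrease",
    )
    link = MotorLink(
        effect_index=0, subscale="akinesia_rigidity", slope=ar_slope, noise_sd=ar_noise_sd
    )
    ar_ok = np.zeros(n_cohorts, dtype=bool)
    tremor_ok = np.zeros(n_cohorts, dtype=bool)
    ar_rs = np.zeros(n_cohorts)
    band = ANALYSIS_BANDS[2]  # slow-3
    for ci, s in enumerate(_child_seeds(seed, n_cohorts)):
        spec = CohortSpec(
            n_per_group={"MPD": n_patients},
            planted_effects=(effect,),
            covariate_model=CovariateModel(motor_link=link),
            effect_variability=severity_sd,
            seed=s,
        )
        model = OscillationNodalModel.from_cohort_spec(spec, bands=(band,))
        res = model.fit(metrics=("degree",), compute_falff=False)
        screened = [(n, band.name, "degree") for n in nodes]
        tab = res.correlation_screen(screened, groups=("MPD",))
        ar_rows = tab[tab["score"] == "ar_score"]
        tr_rows = tab[tab["score"] == "tremor_score"]
        ar_ok[ci] = bool(((ar_rows["r"] < 0) & ar_rows["significant"]).any())
        tremor_ok[ci] = bool(~tr_rows["significant"].any())
        ar_rs[ci] = float(ar_rows["r"].mean())
    return MotorAssociationResult(
        ar_negative_significant=ar_ok,
        tremor_nonsignificant=tremor_ok,
        ar_r=ar_rs,
    )
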
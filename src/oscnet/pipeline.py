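"""End-to-end pipeline orchestration from a single YAML config.

A :class:`PipelineConfig` names either a synthetic cohort spec or a
directory of real inputs (per-subject ROI time-series TSVs, a metadata
CSV, motion parameter text files).  :func:`run_pipeline` executes the
stages in order -- cohort (generate or ingest), preprocessing, band
connectomes, nodal metrics + fALFF, group inference -- writes all result
tables, and returns a :class:`RunManifest` with checksums for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import atlas_labels
from .bands import ANALYSIS_BANDS, CONTROL_BAND, BandDefinition
from .cohort import (
    Cohort,
    CohortSpec,
    CovariateModel,
    HubEffect,
    MotorLink,
    default_parkinson_effects,
    read_timeseries_tsv,
)
from .model import OscillationNodalModel, PreprocessConfig
from .preprocess import TimeSeriesMatrix

logger = logging.getLogger("oscnet")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "extract_roi_timeseries", "load_config"]

_BAND_LOOKUP = {b.name: b for b in ANALYSIS_BANDS} | {CONTROL_BAND.name: CONTROL_BAND}


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of synthetic/input_dir set."""

    out_dir: str
    seed: int = 0
    synthetic: CohortSpec | None = None
    input_dir: str | None = None
    tr_seconds: float = 2.0
    bands: tuple[str, ...] = tuple(b.name for b in ANALYSIS_BANDS)
    grid: list[float] | None = None
    prep: PreprocessConfig = field(default_factory=PreprocessConfig)
    covariates: tuple[str, ...] = ("age", "sex_indicator", "head_motion")
    contrasts: tuple[tuple[str, str], ...] = (("MPD", "NC"), ("EPD", "NC"), ("MPD", "EPD"))
    metrics: tuple[str, ...] = ("degree", "betweenness", "efficiency")
    compute_falff: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValueError("exactly one of {synthetic spec, input_dir} must be given")
        for b in self.bands:
            if b not in _BAND_LOOKUP:
                raise ValueError(f"unknown band {b!r}; known: {sorted(_BAND_LOOKUP)}")

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(_BAND_LOOKUP[b] for b in self.bands)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    syn = raw.pop("synthetic", None)
    prep = raw.pop("prep", None)
    cfg: dict = dict(raw)
    if syn is not None:
        effects = []
        for e in syn.pop("planted_effects", []) or []:
            effects.append(HubEffect(**e))
        if syn.pop("default_parkinson_scenario", False):
            effects_t, link = default_parkinson_effects()
            syn["covariate_model"] = CovariateModel(motor_link=link)
            effects = list(effects_t) + effects
        link_cfg = syn.pop("motor_link", None)
        if link_cfg is not None:
            syn["covariate_model"] = CovariateModel(motor_link=MotorLink(**link_cfg))
        cfg["synthetic"] = CohortSpec(planted_effects=tuple(effects), **syn)
    if prep is not None:
        cfg["prep"] = PreprocessConfig(**prep)
    if "bands" in cfg:
        cfg["bands"] = tuple(cfg["bands"])
    if "contrasts" in cfg:
        cfg["contrasts"] = tuple(tuple(c) for c in cfg["contrasts"])
    if "metrics" in cfg:
        cfg["metrics"] = tuple(cfg["metrics"])
    if "covariates" in cfg:
        cfg["covariates"] = tuple(cfg["covariates"])
    return PipelineConfig(**cfg)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    software_version: str
    n_subjects_total: int
    n_subjects_included: int
    exclusions: dict
    output_checksums: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_real_cohort(input_dir: str, tr_seconds: float) -> Cohort:
    root = Path(input_dir)
    table = pd.read_csv(root / "cohort.csv")
    labels = atlas_labels()
    timeseries, motion, nuisance = {}, {}, {}
    for sid in table["subject_id"]:
        ts_path = root / "timeseries" / f"{sid}.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing time series for {sid}: {ts_path}")
        ts = read_timeseries_tsv(ts_path, tr_seconds)
        if ts.n_rois == len(labels):
            ts.roi_labels = labels
        timeseries[sid] = ts
        m_path = root / "motion" / f"{sid}.txt"
        if m_path.exists():
            motion[sid] = np.loadtxt(m_path)
    spec = CohortSpec(
        n_per_group={g: int(n) for g, n in table["group"].value_counts().items()},
        n_timepoints=next(iter(timeseries.values())).n_timepoints,
        tr_seconds=tr_seconds,
    )
    return Cohort(spec=spec, timeseries=timeseries, motion=motion, nuisance=nuisance, table=table)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write result tables plus a provenance manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    if config.synthetic is not None:
        spec = config.synthetic
        if spec.seed != config.seed:
            spec = CohortSpec(**{**asdict_shallow(spec), "seed": config.seed})
        logger.info("generating synthetic cohort (seed=%d)", spec.seed)
        model = OscillationNodalModel.from_cohort_spec(
            spec,
            bands=config.band_definitions(),
            grid=config.grid,
            prep=config.prep,
        )
    else:
        logger.info("ingesting cohort from %s", config.input_dir)
        cohort = _load_real_cohort(config.input_dir, config.tr_seconds)
        model = OscillationNodalModel.from_cohort(
            cohort,
            bands=config.band_definitions(),
            grid=config.grid,
            prep=config.prep,
        )

    results = model.fit(metrics=config.metrics, compute_falff=config.compute_falff)
    logger.info("fit complete: %d subjects included", len(results.subject_ids))

    written: dict[str, str] = {}

    auc = results.auc_long()
    auc_path = out / "nodal_auc.csv"
    auc.to_csv(auc_path, index=False)
    written["nodal_auc.csv"] = _sha256(auc_path)

    groups_present = set(results.included_table["group"])
    n_pairwise = sum(
        1 for a, b in config.contrasts if {a, b} <= groups_present
    )
    frames = []
    for metric in config.metrics:
        for band in config.bands:
            for a, b in config.contrasts:
                if not {a, b} <= groups_present:
                    continue
                frames.append(
                    results.contrast_table(
                        metric, band, (a, b), config.covariates,
                        n_pairwise_comparisons=max(n_pairwise, 1),
                    )
                )
    if frames:
        contrasts = pd.concat(frames, ignore_index=True)
        c_path = out / "contrasts.csv"
        contrasts.to_csv(c_path, index=False)
        written["contrasts.csv"] = _sha256(c_path)

    if config.compute_falff and len(results.falff):
        f_path = out / "falff.csv"
        results.falff.to_csv(f_path, index=False)
        written["falff.csv"] = _sha256(f_path)

    t_path = out / "cohort_qc.csv"
    results.cohort_table.to_csv(t_path, index=False)
    written["cohort_qc.csv"] = _sha256(t_path)

    excl_path = out / "exclusions.txt"
    lines = [
        f"{sid}: {'+'.join(reasons)}"
        for sid, reasons in results.qc_log.get("excluded", {}).items()
    ]
    excl_path.write_text("\n".join(lines) + ("\n" if lines else ""))
    written["exclusions.txt"] = _sha256(excl_path)

    summary_path = out / "summary.txt"
    summary_path.write_text(results.summary() + "\n")
    written["summary.txt"] = _sha256(summary_path)

    cfg_repr = repr(config).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_repr).hexdigest(),
        seed=config.seed,
        software_version=__version__,
        n_subjects_total=results.qc_log.get("n_total", len(results.cohort_table)),
        n_subjects_included=len(results.subject_ids),
        exclusions=results.qc_log.get("excluded", {}),
        output_checksums=written,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def asdict_shallow(spec: CohortSpec) -> dict:
    """dataclasses.asdict without recursing into nested dataclasses."""
    import dataclasses

    return {f.name: getattr(spec, f.name) for f in dataclasses.fields(spec)}


def extract_roi_timeseries(image_4d, label_image) -> TimeSeriesMatrix:
    """Mean time course per atlas label from a 4-D NIfTI.

    Accepts nibabel images or paths; labels must be positive integers
    1..K on the same voxel grid (label k -> ROI row k-1).
    """
    import nibabel as nib

    if isinstance(image_4d, (str, Path)):
        image_4d = nib.load(str(image_4d))
    if isinstance(label_image, (str, Path)):
        label_image = nib.load(str(label_image))
    data = np.asarray(image_4d.dataobj, dtype=float)
    labels = np.asarray(label_image.dataobj).astype(int)
    if data.ndim != 4:
        raise ValueError("image_4d must be 4-dimensional (x, y, z, time)")
    if labels.shape != data.shape[:3]:
        raise ValueError("label image grid does not match the 4-D image")
    k_max = labels.max()
    if k_max < 1:
        raise ValueError("label image contains no positive labels")
    tr = float(image_4d.header.get_zooms()[3]) if len(image_4d.header.get_zooms()) > 3 else 1.0
    series = np.zeros((k_max, data.shape[3]))
    for k in range(1, k_max + 1):
        mask = labels == k
        if not mask.any():
            raise ValueError(f"label {k} absent from the label image")
        series[k - 1] = data[mask].mean(axis=0)
    return TimeSeriesMatrix(series, tr_seconds=tr if tr > 0 else 1.0, band="broadband")
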
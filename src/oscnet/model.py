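"""Fitting interface: a model object over a cohort, a results object over
the fitted nodal metrics.

:class:`OscillationNodalModel` holds the per-subject ROI time series and
the cohort metadata; ``fit()`` runs preprocessing, band-resolved
connectome construction and the nodal-metric/AUC pipeline, returning an
:class:`OscillationNodalResults` carrying the AUC tables, fALFF tables
and QC ledger, with methods for the group GLM contrasts, clinical
correlation screening, logistic discrimination, and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import ANALYSIS_BANDS, BandDefinition
from .cohort import Cohort, CohortSpec, apply_qc_filters, generate_cohort
from .connectome import ConnectivityMatrix, correlation_matrix, sparsity_grid
from .falff import falff_table
from .inference import (
    DiscriminationResult,
    correlation_screen,
    logistic_discriminate,
    nodal_contrast_table,
    significance_threshold,
)
from .metrics import METRIC_NAMES, metric_pipeline
from .preprocess import (
    TimeSeriesMatrix,
    bandpass_ideal,
    build_nuisance_design,
    compute_fd_and_scrub,
    detrend_linear,
    discard_initial_volumes,
    regress_nuisance,
)

__all__ = ["PreprocessConfig", "OscillationNodalModel", "OscillationNodalResults"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the subject-level preprocessing chain.

    ``scrub_order`` selects whether flagged frames are deleted from the
    band-filtered series ("after_bandpass", default -- preserves the
    spectral separation of the oscillation bands) or from the broadband
    series before filtering ("before_bandpass").
    """

    n_discard: int = 10
    fd_threshold_mm: float = 0.5
    scrub_augment: str = "none"
    regress_nuisance: bool = True
    detrend: bool = True
    scrub: bool = True
    scrub_order: str = "after_bandpass"

    def __post_init__(self) -> None:
        if self.scrub_order not in ("after_bandpass", "before_bandpass"):
            raise ValueError("scrub_order must be 'after_bandpass' or 'before_bandpass'")


class OscillationNodalModel:
    """Band-resolved nodal-metric model of a resting-state cohort.

    Parameters
    ----------
    timeseries
        Mapping subject id -> broadband :class:`TimeSeriesMatrix`.
    cohort_table
        One row per subject: group label, covariates, UPDRS subscales.
    motion, nuisance
        Optional per-subject motion parameter arrays (time x 6) and
        white-matter/CSF signals used for nuisance regression/scrubbing.
    bands
        Oscillation bands in which connectomes are built.
    grid
        Sparsity grid for binarization (default 5%..50% step 5%).
    """

    def __init__(
        self,
        timeseries: dict[str, TimeSeriesMatrix],
        cohort_table: pd.DataFrame,
        motion: dict[str, np.ndarray] | None = None,
        nuisance: dict[str, dict[str, np.ndarray]] | None = None,
        bands: tuple[BandDefinition, ...] = ANALYSIS_BANDS,
        grid: list[float] | None = None,
        prep: PreprocessConfig = PreprocessConfig(),
    ) -> None:
        self.timeseries = timeseries
        self.cohort_table = cohort_table.copy()
        self.motion = motion or {}
        self.nuisance = nuisance or {}
        self.bands = tuple(bands)
        self.grid = list(grid) if grid is not None else sparsity_grid()
        self.prep = prep

    @classmethod
    def from_cohort_spec(
        cls,
        spec: CohortSpec,
        bands: tuple[BandDefinition, ...] = ANALYSIS_BANDS,
        grid: list[float] | None = None,
        prep: PreprocessConfig = PreprocessConfig(),
    ) -> "OscillationNodalModel":
        """Generate a synthetic cohort from a spec and wrap it as a model."""
        cohort = generate_cohort(spec)
        return cls.from_cohort(cohort, bands=bands, grid=grid, prep=prep)

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        bands: tuple[BandDefinition, ...] = ANALYSIS_BANDS,
        grid: list[float] | None = None,
        prep: PreprocessConfig = PreprocessConfig(),
    ) -> "OscillationNodalModel":
        return cls(
            cohort.timeseries,
            cohort.table,
            motion=cohort.motion,
            nuisance=cohort.nuisance,
            bands=bands,
            grid=grid,
            prep=prep,
        )

    # ------------------------------------------------------------------
    def _preprocess_subject(
        self, sid: str
    ) -> tuple[TimeSeriesMatrix, np.ndarray | None, float, float]:
        """Run the stage chain for one subject.

        Returns (cleaned broadband series, good-frame mask or None, scrub
        fraction, mean FD over retained frames).  Frame deletion itself is
        deferred so it can be applied before or after band filtering.
        """
        cfg = self.prep
        ts = discard_initial_volumes(self.timeseries[sid], cfg.n_discard)
        motion = self.motion.get(sid)
        if motion is not None:
            motion = motion[cfg.n_discard :]
        if cfg.regress_nuisance and motion is not None:
            extra = self.nuisance.get(sid, {})
            wm = extra.get("wm")
            csf = extra.get("csf")
            design = build_nuisance_design(
                motion,
                None if wm is None else wm[cfg.n_discard :],
                None if csf is None else csf[cfg.n_discard :],
            )
            ts = regress_nuisance(ts, design)
        if cfg.detrend:
            ts = detrend_linear(ts)
        good = None
        scrub_fraction = 0.0
        mean_fd = float("nan")
        if motion is not None:
            mask = compute_fd_and_scrub(
                motion, cfg.fd_threshold_mm, cfg.scrub_augment
            )
            if cfg.scrub:
                good = ~mask.flags
                if not good.any():
                    raise ValueError(f"subject {sid}: all frames flagged bad")
                scrub_fraction = float(mask.flags.mean())
                mean_fd = float(mask.fd_series[good].mean())
            else:
                mean_fd = float(mask.fd_series.mean())
        return ts, good, scrub_fraction, mean_fd

    def fit(
        self,
        metrics: tuple[str, ...] = METRIC_NAMES,
        compute_falff: bool = True,
        apply_qc: bool = True,
        keep_connectomes: bool = False,
    ) -> "OscillationNodalResults":
        """Preprocess every subject, build per-band connectomes, compute
        nodal metric AUCs (and fALFF), and apply subject-level QC."""
        cleaned: dict[str, TimeSeriesMatrix] = {}
        good_frames: dict[str, np.ndarray | None] = {}
        scrub_fractions: dict[str, float] = {}
        mean_fd: dict[str, float] = {}
        for sid in self.timeseries:
            ts, good, sf, fd = self._preprocess_subject(sid)
            cleaned[sid] = ts
            good_frames[sid] = good
            scrub_fractions[sid] = sf
            if np.isfinite(fd):
                mean_fd[sid] = fd

        table = self.cohort_table.copy()
        if mean_fd:
            # head-motion covariate = mean FD over retained frames
            prior = (
                table["head_motion"] if "head_motion" in table.columns else pd.Series(np.nan, index=table.index)
            )
            table["head_motion"] = [
                mean_fd.get(sid, prior.iloc[i])
                for i, sid in enumerate(table["subject_id"])
            ]
        if apply_qc:
            table, qc_log = apply_qc_filters(table, scrub_fractions=scrub_fractions)
        else:
            qc_log = {"n_total": len(table), "n_included": len(table)}
        included = [
            sid
            for sid in table.loc[table["qc_status"] == "included", "subject_id"]
            if sid in cleaned
        ]

        n_nodes = next(iter(self.timeseries.values())).n_rois
        grid = np.asarray(self.grid, dtype=float)
        auc: dict[tuple[str, str], np.ndarray] = {
            (b.name, m): np.zeros((len(included), n_nodes))
            for b in self.bands
            for m in metrics
        }
        falff_frames = []
        connectomes: dict[tuple[str, str], ConnectivityMatrix] = {}
        for si, sid in enumerate(included):
            ts = cleaned[sid]
            good = good_frames[sid]
            if good is not None and self.prep.scrub_order == "before_bandpass":
                ts = ts.with_values(ts.values[:, good])
                good = None
            for band in self.bands:
                filtered = bandpass_ideal(ts, band)
                if good is not None:
                    filtered = filtered.with_values(filtered.values[:, good])
                conn = correlation_matrix(filtered)
                conn.subject_id = sid
                if keep_connectomes:
                    connectomes[(sid, band.name)] = conn
                curves = metric_pipeline(conn.z_values, self.grid, metrics)
                for m in metrics:
                    auc[(band.name, m)][si] = curves[m].auc
            if compute_falff:
                ts_f = ts if good is None else ts.with_values(ts.values[:, good])
                falff_frames.append(falff_table(ts_f, subject_id=sid))

        return OscillationNodalResults(
            model=self,
            subject_ids=included,
            cohort_table=table,
            qc_log=qc_log,
            auc=auc,
            grid=grid,
            metrics=tuple(metrics),
            falff=(pd.concat(falff_frames, ignore_index=True) if falff_frames else pd.DataFrame()),
            scrub_fractions=scrub_fractions,
            connectomes=connectomes,
        )


@dataclass
class OscillationNodalResults:
    """Fitted nodal AUCs plus the inference surface over them."""

    model: OscillationNodalModel
    subject_ids: list[str]
    cohort_table: pd.DataFrame
    qc_log: dict
    auc: dict[tuple[str, str], np.ndarray]
    grid: np.ndarray
    metrics: tuple[str, ...]
    falff: pd.DataFrame
    scrub_fractions: dict[str, float] = field(default_factory=dict)
    connectomes: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def included_table(self) -> pd.DataFrame:
        t = self.cohort_table.set_index("subject_id").loc[self.subject_ids].reset_index()
        return t

    @property
    def n_nodes(self) -> int:
        return next(iter(self.auc.values())).shape[1]

    def auc_matrix(self, band: str, metric: str) -> np.ndarray:
        try:
            return self.auc[(band, metric)]
        except KeyError:
            raise KeyError(f"no AUC fitted for band={band!r}, metric={metric!r}") from None

    def auc_long(self) -> pd.DataFrame:
        """Long-format subject x (band, metric, node) AUC table."""
        rows = []
        for (band, metric), M in self.auc.items():
            for si, sid in enumerate(self.subject_ids):
                for node in range(M.shape[1]):
                    rows.append(
                        {
                            "subject_id": sid,
                            "band": band,
                            "metric": metric,
                            "node": node,
                            "auc": M[si, node],
                        }
                    )
        return pd.DataFrame(rows)

    def _covariate_frame(self, covariates: tuple[str, ...]) -> pd.DataFrame:
        t = self.included_table
        cov = pd.DataFrame(index=t.index)
        for c in covariates:
            if c == "sex_indicator":
                cov[c] = (t["sex"] == "F").astype(float)
            else:
                cov[c] = pd.to_numeric(t[c])
        return cov

    def contrast_table(
        self,
        metric: str,
        band: str,
        contrast: tuple[str, str] = ("MPD", "NC"),
        covariates: tuple[str, ...] = ("age", "sex_indicator", "head_motion"),
        n_pairwise_comparisons: int = 1,
    ) -> pd.DataFrame:
        """Per-node covariate-adjusted GLM contrast at the 1/N (optionally
        Bonferroni-shared) significance threshold."""
        thr = significance_threshold(self.n_nodes, n_pairwise_comparisons)
        t = self.included_table
        cov = self._covariate_frame(covariates) if covariates else None
        return nodal_contrast_table(
            self.auc_matrix(band, metric),
            t["group"].to_numpy(),
            cov,
            contrast,
            thr,
            metric=metric,
            band=band,
        )

    def significant_nodes(
        self,
        contrast: tuple[str, str] = ("MPD", "NC"),
        covariates: tuple[str, ...] = ("age", "sex_indicator", "head_motion"),
        n_pairwise_comparisons: int = 1,
        bands: tuple[str, ...] | None = None,
    ) -> list[tuple[int, str, str]]:
        """(node, band, metric) triples passing the nodal threshold."""
        out = []
        for band, metric in self.auc:
            if bands is not None and band not in bands:
                continue
            tab = self.contrast_table(
                metric, band, contrast, covariates, n_pairwise_comparisons
            )
            for node in tab.loc[tab["significant"], "node"]:
                out.append((int(node), band, metric))
        return out

    def correlation_screen(
        self,
        significant_nodes: list[tuple[int, str, str]],
        groups: tuple[str, ...] = ("EPD", "MPD"),
        covariates: tuple[str, ...] = ("age", "sex_indicator", "head_motion"),
    ) -> pd.DataFrame:
        """Partial-correlation screen of nodal AUCs against motor scores
        within the patient groups."""
        t = self.included_table
        keep = t["group"].isin(groups)
        clinical = t.loc[keep].copy()
        clinical["sex_indicator"] = (clinical["sex"] == "F").astype(float)
        auc_long = self.auc_long()
        auc_long = auc_long[auc_long["subject_id"].isin(clinical["subject_id"])]
        return correlation_screen(
            auc_long, clinical, significant_nodes, covariate_columns=covariates
        )

    def discriminate(
        self,
        features: list[tuple[int, str, str]],
        between: tuple[str, str] = ("MPD", "NC"),
        selection_mode: str = "backward",
    ) -> DiscriminationResult:
        """Logistic discrimination between two groups from nodal AUCs."""
        t = self.included_table
        keep = t["group"].isin(between).to_numpy()
        idx = np.flatnonzero(keep)
        cols = {}
        for node, band, metric in features:
            M = self.auc_matrix(band, metric)
            cols[f"{metric}_{band}_n{node}"] = M[idx, node]
        X = pd.DataFrame(cols)
        y = (t["group"].to_numpy()[keep] == between[0]).astype(int)
        return logistic_discriminate(X, y, selection_mode=selection_mode)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary."""
        t = self.included_table
        lines = [
            "Oscillation-resolved nodal network analysis",
            "=" * 46,
            f"nodes: {self.n_nodes}   sparsity grid: "
            f"{self.grid[0]:.2f}..{self.grid[-1]:.2f} ({self.grid.size} points)",
            f"bands: {', '.join(sorted({b for b, _ in self.auc}))}",
            f"metrics: {', '.join(self.metrics)}",
            f"subjects included/total: {len(self.subject_ids)}/{self.qc_log.get('n_total', len(self.subject_ids))}",
        ]
        for g, cnt in t["group"].value_counts().items():
            lines.append(f"  {g}: {cnt}")
        if "counts_per_rule" in self.qc_log:
            lines.append(f"exclusions by rule: {self.qc_log['counts_per_rule']}")
        thr = significance_threshold(self.n_nodes)
        lines.append(f"nodal significance threshold (single contrast): {thr:.3f}")
        return "\n".join(lines)

    def plot_metric_curves(self, band: str, metric: str, nodes, ax=None):
        """Group-mean metric-vs-sparsity curves for selected nodes.

        Plotting is a thin convenience over the AUC arrays; requires
        matplotlib.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        M = self.auc_matrix(band, metric)
        t = self.included_table
        for g in t["group"].unique():
            sel = (t["group"] == g).to_numpy()
            for node in np.atleast_1d(nodes):
                ax.plot(
                    [0], [M[sel, node].mean()], "o", label=f"{g} node {node}"
                )
        ax.set_xlabel("sparsity")
        ax.set_ylabel(f"{metric} AUC ({band})")
        ax.legend()
        return ax

    def plot_roc(self, result: DiscriminationResult, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(result.roc_points[:, 0], result.roc_points[:, 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], "--", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"ROC (AUC = {result.auc:.3f})")
        return ax
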
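"""Muscle normalization, signal-enhancement maps, voxel-wise AUC and perfusion metrics.

This is the model-free analysis chain: intensities are first normalized to
the mean dorsal-muscle signal at each time point (removing scanner scale
drift), then per-voxel signal enhancement SE(t) = S(t)/S(0) is formed
against the pre-injection baseline.  The per-voxel area under the
enhancement curve is computed by trapezoidal integration of SE minus a
reference level:

* ``first-post`` mode (AUC_5–55): the reference is SE at the first
  post-injection sample (≈5 min), so the area is *signed* — positive for
  curves that keep rising after the distribution phase (retention,
  consistent with collagen binding), negative for washout.
* ``baseline`` mode (AUC_0–55): the reference is 1 and integration starts
  at t = 0 with SE(0) = 1, giving the conventional, perfusion-dominated
  area, nonnegative whenever SE ≥ 1.

Perfusion is summarized by Enh5 (enhancement at the first post-injection
time) and PerfVF, the fraction of ROI voxels whose Enh5 strictly exceeds a
pooled-cohort median threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from dceauc.io import DynamicSeries, RoiSet

__all__ = [
    "EnhancementSeries",
    "AUCMap",
    "SpecimenSummary",
    "normalize_to_muscle",
    "muscle_means",
    "enhancement_map",
    "auc_map",
    "mean_over_roi",
    "pooled_perfusion_threshold",
    "perf_vf",
    "summarize_specimen",
    "curve_mean_perfused",
]


@dataclass
class EnhancementSeries:
    """Per-voxel signal enhancement for each post-injection time point.

    ``se`` is indexed (x, y, z, t_post); ``valid`` flags voxels with a
    usable (positive) baseline — invalid voxels are excluded from every
    downstream mean and count rather than propagating infinities.
    """

    se: np.ndarray
    times_post: np.ndarray
    valid: np.ndarray
    specimen_id: str = "unknown"
    norm_constants: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.se.ndim != 4:
            raise ValueError("SE array must be 4D (x,y,z,t_post)")
        if self.se.shape[3] != len(self.times_post):
            raise ValueError("one SE volume per post-injection time required")

    @property
    def enh5(self) -> np.ndarray:
        """Enhancement at the first post-injection time point."""
        return self.se[..., 0]

    @property
    def enh_last(self) -> np.ndarray:
        return self.se[..., -1]


@dataclass
class AUCMap:
    """Per-voxel area under the enhancement curve, AU·min."""

    values: np.ndarray
    mode: Literal["baseline", "first-post"]
    window: tuple[float, float]
    times_used: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class SpecimenSummary:
    """Scalar imaging biomarkers for one specimen's tissue ROI."""

    specimen_id: str
    tissue: str
    auc_5_55: float
    auc_0_55: float
    enh5: float
    enh_last: float
    perf_vf: float
    n_voxels: int
    n_invalid: int


def muscle_means(series: DynamicSeries, rois: RoiSet) -> np.ndarray:
    """Mean signal over the dorsal-muscle ROI at each time point."""
    rois.check_grid(series)
    m = rois.mask("muscle")
    means = series.data[m].mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("muscle reference mean must be positive at every time point")
    return means


def normalize_to_muscle(series: DynamicSeries, rois: RoiSet) -> DynamicSeries:
    """Scale each time point so the mean dorsal-muscle signal equals 1."""
    means = muscle_means(series, rois)
    return DynamicSeries(
        data=series.data / means,
        sample_times=series.sample_times,
        spacing=series.spacing,
        specimen_id=series.specimen_id,
        affine=series.affine,
    )


def enhancement_map(norm: DynamicSeries) -> EnhancementSeries:
    """Per-voxel SE(t) = S(t)/S(0) for each post-injection time point.

    Voxels with nonpositive baseline are flagged invalid (SE set to NaN)
    instead of producing silent infinities.
    """
    if norm.n_post < 1:
        raise ValueError("series has no post-injection volumes")
    baseline = norm.data[..., 0]
    valid = baseline > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = norm.data[..., 1:] / baseline[..., None]
    se[~valid] = np.nan
    return EnhancementSeries(
        se=se,
        times_post=norm.sample_times[1:].copy(),
        valid=valid,
        specimen_id=norm.specimen_id,
    )


def auc_map(
    enh: EnhancementSeries,
    mode: Literal["baseline", "first-post"] = "first-post",
    window: tuple[float, float] = (5.0, 55.0),
) -> AUCMap:
    """Trapezoidal area of SE minus a reference level over a time window.

    Actual acquisition times are used as trapezoid nodes; a window not fully
    covered by the available samples is clipped with a warning.  In
    ``baseline`` mode a node at t = 0 with SE = 1 (enhancement of the
    baseline against itself) starts the integration when the window allows.
    """
    if mode not in ("baseline", "first-post"):
        raise ValueError("mode must be 'baseline' or 'first-post'")
    t_a, t_b = float(window[0]), float(window[1])
    if t_b <= t_a:
        raise ValueError("window must have positive length")
    times = enh.times_post
    if t_a < (0.0 if mode == "baseline" else times[0]) - 1e-9 or t_b > times[-1] + 1e-9:
        warnings.warn(
            f"AUC window [{t_a}, {t_b}] min not fully covered by samples; clipping",
            stacklevel=2,
        )
    sel = (times >= t_a - 1e-9) & (times <= t_b + 1e-9)
    t_nodes = times[sel]
    se_nodes = enh.se[..., sel]
    if mode == "baseline" and t_a <= 1e-9:
        t_nodes = np.concatenate([[0.0], t_nodes])
        se_nodes = np.concatenate([np.ones_like(se_nodes[..., :1]), se_nodes], axis=-1)
    if t_nodes.size < 2:
        raise ValueError("fewer than 2 usable time points inside the AUC window")
    ref = 1.0 if mode == "baseline" else se_nodes[..., 0][..., None]
    values = np.trapezoid(se_nodes - ref, t_nodes, axis=-1)
    values = np.where(enh.valid, values, np.nan)
    return AUCMap(values=values, mode=mode, window=(t_a, t_b), times_used=t_nodes)


def mean_over_roi(
    values: np.ndarray,
    rois: RoiSet,
    label: str,
    valid: np.ndarray | None = None,
) -> tuple[float, int]:
    """Arithmetic mean of a per-voxel map over an ROI, with the voxel count used.

    ``valid`` (or NaNs in the map) excludes flagged voxels from both the
    mean and the count.
    """
    m = rois.mask(label)
    if valid is not None:
        m = m & valid
    vals = np.asarray(values)[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"ROI '{label}' has no usable voxels")
    return float(vals.mean()), int(vals.size)


def pooled_perfusion_threshold(enh5_pools: Iterable[np.ndarray]) -> float:
    """Median Enh5 over all analysed tissue voxels of all specimens, both probe arms.

    Even-count pools use the mean of the two central order statistics.
    """
    pools = [np.asarray(p, dtype=float).ravel() for p in enh5_pools]
    pooled = np.concatenate(pools) if pools else np.array([])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("empty pooled enhancement set")
    return float(np.median(pooled))


def perf_vf(
    enh5: np.ndarray,
    rois: RoiSet,
    label: str,
    threshold: float,
    valid: np.ndarray | None = None,
) -> float:
    """Well-perfused volume fraction: ROI voxels with Enh5 strictly above threshold.

    "Surpassed" is read as strict inequality; ties count as poorly perfused.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    m = rois.mask(label)
    if valid is not None:
        m = m & valid
    vals = np.asarray(enh5)[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"ROI '{label}' has no usable voxels")
    return float(np.count_nonzero(vals > threshold) / vals.size)


def summarize_specimen(
    enh: EnhancementSeries,
    rois: RoiSet,
    tissue_label: str,
    threshold: float,
    windows: Sequence[tuple[float, float]] = ((5.0, 55.0), (0.0, 55.0)),
) -> SpecimenSummary:
    """All scalar biomarkers for one specimen: mean AUCs over the whole tissue
    ROI, mean Enh5 and last-time-point enhancement, PerfVF and voxel counts."""
    w_ref, w_base = windows
    auc_ref = auc_map(enh, mode="first-post", window=w_ref)
    auc_base = auc_map(enh, mode="baseline", window=w_base)
    mean_ref, n_vox = mean_over_roi(auc_ref.values, rois, tissue_label, enh.valid)
    mean_base, _ = mean_over_roi(auc_base.values, rois, tissue_label, enh.valid)
    enh5_mean, _ = mean_over_roi(enh.enh5, rois, tissue_label, enh.valid)
    last_mean, _ = mean_over_roi(enh.enh_last, rois, tissue_label, enh.valid)
    pvf = perf_vf(enh.enh5, rois, tissue_label, threshold, enh.valid)
    n_total = int(rois.mask(tissue_label).sum())
    return SpecimenSummary(
        specimen_id=enh.specimen_id,
        tissue=tissue_label,
        auc_5_55=mean_ref,
        auc_0_55=mean_base,
        enh5=enh5_mean,
        enh_last=last_mean,
        perf_vf=pvf,
        n_voxels=n_vox,
        n_invalid=n_total - n_vox,
    )


def curve_mean_perfused(
    enh: EnhancementSeries,
    rois: RoiSet,
    label: str,
    threshold: float,
) -> np.ndarray:
    """Mean SE time course over the well-perfused voxels of an ROI.

    This is the display convention for cohort time-course curves; whole-ROI
    means are used for the AUC biomarkers themselves.
    """
    m = rois.mask(label) & enh.valid & (enh.enh5 > threshold)
    if not np.any(m):
        raise ValueError(f"no well-perfused voxels in ROI '{label}'")
    return enh.se[m].mean(axis=0)
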
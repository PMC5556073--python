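"""SHG micrograph rendering at MR resolution and rigid slice-to-slice alignment.

Second-harmonic-generation microscopy images fibrillar collagen directly;
to compare its spatial pattern with ex-vivo MR enhancement, a micrograph
z-stack is max-projected, block-averaged down to the MR pixel size
(e.g. 9.18 µm → 250 µm), and rigidly registered (rotation, isotropic
scale, translation) to a user-selected MR slice by maximizing normalized
cross-correlation over a deterministic grid search with local refinement.
Spatial agreement is quantified by Pearson correlation, Dice overlap at
percentile thresholds, and the two directional conditional fractions
P(collagen-rich | MR-enhanced) and P(MR-enhanced | collagen-rich) — the
latter pair captures non-reciprocal overlap (enhanced regions lying inside
larger collagen-rich regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.feature import match_template
from skimage.measure import block_reduce
from skimage.transform import resize, rescale, rotate

__all__ = [
    "Micrograph",
    "RigidTransform2D",
    "max_projection",
    "render_at_mri_resolution",
    "register_rigid",
    "apply_transform",
    "overlap_metrics",
]


@dataclass
class Micrograph:
    """A 2D micrograph or z-stack (z, y, x) with its pixel size in µm."""

    data: np.ndarray
    pixel_size_um: float
    channel: str = "SHG"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.data.ndim not in (2, 3):
            raise ValueError("micrograph must be 2D or a 3D z-stack")
        if self.channel not in ("SHG", "autofluorescence"):
            raise ValueError("channel must be 'SHG' or 'autofluorescence'")


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation (degrees, counter-clockwise), isotropic scale, translation in
    target pixels (row, col offsets of the moving image origin)."""

    rotation_deg: float
    scale: float
    translation: tuple[float, float]
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def max_projection(zstack: Micrograph) -> Micrograph:
    """Per-pixel maximum across the depth axis of a z-stack."""
    if zstack.data.ndim == 2:
        return Micrograph(zstack.data.copy(), zstack.pixel_size_um, zstack.channel)
    if zstack.data.shape[0] < 1:
        raise ValueError("empty z-stack")
    return Micrograph(zstack.data.max(axis=0), zstack.pixel_size_um, zstack.channel)


def render_at_mri_resolution(img: Micrograph, target_pixel_um: float) -> Micrograph:
    """Block-average downsampling of a micrograph to the MR pixel size.

    Mean intensity is conserved (exactly for integer, evenly dividing
    factors; within interpolation tolerance otherwise).  Upsampling is
    refused — the micrograph is always the finer image.
    """
    if img.data.ndim != 2:
        raise ValueError("render expects a 2D image (max-project first)")
    if target_pixel_um < img.pixel_size_um:
        raise ValueError("target pixel size must not be finer than the source")
    factor = target_pixel_um / img.pixel_size_um
    data = img.data
    f_int = int(round(factor))
    if abs(factor - f_int) < 1e-9 and all(s % f_int == 0 for s in data.shape):
        out = block_reduce(data, (f_int, f_int), np.mean)
    else:
        new_shape = tuple(max(1, int(round(s / factor))) for s in data.shape)
        out = resize(data, new_shape, order=1, anti_aliasing=True, preserve_range=True)
    return Micrograph(out, target_pixel_um, img.channel)


def _transform(moving: np.ndarray, rotation_deg: float, scale: float) -> np.ndarray:
    """Scale then rotate with bicubic interpolation, expanding the canvas."""
    out = moving
    if scale != 1.0:
        out = rescale(out, scale, order=3, anti_aliasing=scale < 1.0, preserve_range=True)
    if rotation_deg != 0.0:
        out = rotate(out, rotation_deg, resize=True, order=3, preserve_range=True)
    return out


def _ncc_best_translation(fixed: np.ndarray, template: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Max NCC over translations and the offset achieving it."""
    if template.shape[0] > fixed.shape[0] or template.shape[1] > fixed.shape[1]:
        pad = (
            max(0, template.shape[0] - fixed.shape[0]),
            max(0, template.shape[1] - fixed.shape[1]),
        )
        fixed = np.pad(fixed, ((0, pad[0]), (0, pad[1])))
    ncc = match_template(fixed, template, pad_input=True)
    idx = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    return float(ncc[idx]), (int(idx[0]), int(idx[1]))


def register_rigid(
    moving: Micrograph | np.ndarray,
    fixed: np.ndarray,
    rotations_deg: Sequence[float] = tuple(np.arange(-30.0, 30.5, 2.0)),
    scales: Sequence[float] = tuple(np.round(np.arange(0.8, 1.21, 0.05), 3)),
    refine: bool = True,
    refine_levels: int = 2,
) -> RigidTransform2D:
    """Find the rigid transform maximizing positive NCC against the fixed slice.

    A full grid over rotation × scale is searched (translations via the NCC
    map), then the best cell is refined on successively quartered grid steps.
    Deterministic for fixed inputs and search specification.
    """
    mov = moving.data if isinstance(moving, Micrograph) else np.asarray(moving, float)
    fix = np.asarray(fixed, dtype=float)
    if mov.ndim != 2 or fix.ndim != 2:
        raise ValueError("registration operates on 2D images")
    if mov.std() == 0 or fix.std() == 0:
        raise ValueError("cannot register constant images")
    rotations = np.asarray(list(rotations_deg), float)
    scale_grid = np.asarray(list(scales), float)
    if rotations.size == 0 or scale_grid.size == 0:
        raise ValueError("empty search range")

    def evaluate(rot: float, sc: float):
        t = _transform(mov, rot, sc)
        score, off = _ncc_best_translation(fix, t)
        return score, off

    best = (-np.inf, 0.0, 1.0, (0, 0))
    for rot in rotations:
        for sc in scale_grid:
            score, off = evaluate(rot, sc)
            if score > best[0]:
                best = (score, float(rot), float(sc), off)

    d_rot = float(np.min(np.diff(np.sort(rotations)))) if rotations.size > 1 else 1.0
    d_sc = float(np.min(np.diff(np.sort(scale_grid)))) if scale_grid.size > 1 else 0.05
    if refine:
        for _ in range(refine_levels):
            d_rot /= 4.0
            d_sc /= 4.0
            center_rot, center_sc = best[1], best[2]
            for rot in center_rot + d_rot * np.arange(-2, 3):
                for sc in center_sc + d_sc * np.arange(-2, 3):
                    if sc <= 0:
                        continue
                    score, off = evaluate(float(rot), float(sc))
                    if score > best[0]:
                        best = (score, float(rot), float(sc), off)

    score, rot, sc, off = best
    return RigidTransform2D(rotation_deg=rot, scale=sc, translation=off, score=score)


def apply_transform(moving: Micrograph | np.ndarray, transform: RigidTransform2D) -> np.ndarray:
    """Resample the moving image under a registration result (before translation)."""
    mov = moving.data if isinstance(moving, Micrograph) else np.asarray(moving, float)
    return _transform(mov, transform.rotation_deg, transform.scale)


def overlap_metrics(
    mri_map: np.ndarray,
    shg_map: np.ndarray,
    mask: np.ndarray | None = None,
    mri_percentile: float = 75.0,
    shg_percentile: float = 75.0,
    mri_threshold: float | None = None,
    shg_threshold: float | None = None,
) -> dict[str, float]:
    """Spatial agreement between co-registered MR enhancement and SHG collagen maps.

    Thresholds default to each map's 75th percentile within the mask;
    explicit ``*_threshold`` values override the percentiles (useful for
    already-binary maps).  Returns Pearson r, Dice, and the directional
    fractions ``p_shg_given_mri`` = P(collagen-rich | MR-enhanced) and
    ``p_mri_given_shg`` = P(MR-enhanced | collagen-rich).
    """
    mri = np.asarray(mri_map, dtype=float)
    shg = np.asarray(shg_map, dtype=float)
    if mri.shape != shg.shape:
        raise ValueError("maps must be co-registered on the same grid")
    m = np.ones(mri.shape, bool) if mask is None else np.asarray(mask, bool)
    if m.shape != mri.shape:
        raise ValueError("mask grid mismatch")
    x, y = mri[m], shg[m]
    r = float(sps.pearsonr(x, y).statistic) if x.std() > 0 and y.std() > 0 else float("nan")
    thr_x = np.percentile(x, mri_percentile) if mri_threshold is None else mri_threshold
    thr_y = np.percentile(y, shg_percentile) if shg_threshold is None else shg_threshold
    mri_hi = x > thr_x
    shg_hi = y > thr_y
    inter = np.count_nonzero(mri_hi & shg_hi)
    n_mri, n_shg = np.count_nonzero(mri_hi), np.count_nonzero(shg_hi)
    dice = 2.0 * inter / (n_mri + n_shg) if (n_mri + n_shg) else float("nan")
    return {
        "pearson_r": r,
        "dice": float(dice),
        "p_shg_given_mri": float(inter / n_mri) if n_mri else float("nan"),
        "p_mri_given_shg": float(inter / n_shg) if n_shg else float("nan"),
        "n_mri_enhanced": float(n_mri),
        "n_shg_high": float(n_shg),
    }
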
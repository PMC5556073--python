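"""Canonical on-disk formats and validated in-memory containers.

Volumes travel as NIfTI-1 with a JSON sidecar carrying acquisition times in
minutes; ROI masks are integer-labelled NIfTI on the same grid with a JSON
label dictionary; per-specimen assay values (hydroxyproline, gadolinium)
are CSV.  Readers validate rather than coerce: a series whose time axis
disagrees with its sidecar, or a mask on a different grid, is rejected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AssayTable",
    "DynamicSeries",
    "RoiSet",
    "read_assays",
    "read_roiset",
    "read_series",
    "write_assays",
    "write_roiset",
    "write_series",
    "convert_dicom_series",
]

ASSAY_COLUMNS = ["specimen_id", "hydroxyproline_ug_g", "gadolinium_nmol_g", "group"]


@dataclass
class DynamicSeries:
    """A 4D dynamic MR acquisition: one baseline volume plus post-injection volumes.

    ``data`` is indexed (x, y, z, t) in arbitrary signal units;
    ``sample_times`` are minutes post-injection with the baseline at 0.
    """

    data: np.ndarray
    sample_times: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    specimen_id: str = "unknown"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.sample_times = np.asarray(self.sample_times, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.sample_times.ndim != 1 or len(self.sample_times) != self.data.shape[3]:
            raise ValueError(
                f"{len(self.sample_times)} sample times for {self.data.shape[3]} volumes"
            )
        if self.sample_times[0] != 0:
            raise ValueError("first sample time must be 0 (pre-injection baseline)")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("magnitude intensities must be nonnegative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_post(self) -> int:
        return len(self.sample_times) - 1

    def volume(self, i: int) -> np.ndarray:
        return self.data[..., i]


@dataclass
class RoiSet:
    """Integer-labelled voxel masks sharing the series grid.

    ``names`` maps ROI name to label value; label 0 is background and a
    ``muscle`` reference label is mandatory (the normalization target).
    """

    labels: np.ndarray
    names: dict[str, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("ROI label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("ROI labels must be integers")
            self.labels = lab.astype(np.int32)
        if np.any(self.labels < 0):
            raise ValueError("ROI labels must be nonnegative (0 = background)")
        if "muscle" not in self.names:
            raise ValueError("RoiSet requires a 'muscle' reference label")
        vals = list(self.names.values())
        if len(set(vals)) != len(vals):
            raise ValueError("ROI label values must be distinct")
        if 0 in vals:
            raise ValueError("label 0 is reserved for background")
        if not np.any(self.labels == self.names["muscle"]):
            raise ValueError("muscle reference ROI is empty")
        for name, val in self.names.items():
            if name != "muscle" and not np.any(self.labels == val):
                warnings.warn(f"tissue ROI '{name}' is empty", stacklevel=2)

    def mask(self, name: str) -> np.ndarray:
        if name not in self.names:
            raise KeyError(f"unknown ROI '{name}'; have {sorted(self.names)}")
        return self.labels == self.names[name]

    def check_grid(self, series: DynamicSeries) -> None:
        if self.labels.shape != series.shape:
            raise ValueError(
                f"ROI grid {self.labels.shape} does not match series grid {series.shape}"
            )


@dataclass
class AssayTable:
    """Per-specimen wet-tissue assay values.

    Hydroxyproline in µg/g wet tissue (surrogate for total collagen),
    gadolinium in nmol/g wet tissue; empty cells are missing, not zero.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"assay table missing columns {missing}")
        df["specimen_id"] = df["specimen_id"].astype(str)
        for col in ("hydroxyproline_ug_g", "gadolinium_nmol_g"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if (df[col].dropna() < 0).any():
                raise ValueError(f"negative values in {col}")
        if df["specimen_id"].duplicated().any():
            dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
            raise ValueError(f"duplicate specimen ids: {dup}")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def _affine(series: DynamicSeries) -> np.ndarray:
    if series.affine is not None:
        return series.affine
    aff = np.diag([*series.spacing, 1.0])
    return aff


def write_series(series: DynamicSeries, path: str | Path, sidecar_path: str | Path | None = None,
                 **extra) -> Path:
    """Write a 4D NIfTI plus JSON sidecar with acquisition times in minutes."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series))
    img.header.set_zooms((*series.spacing, 1.0))
    nib.save(img, str(path))
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".json")
    meta = {
        "specimen_id": series.specimen_id,
        "sample_times_min": [float(t) for t in series.sample_times],
        "voxel_spacing_mm": list(series.spacing),
    }
    meta.update(extra)
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_series(path: str | Path, sidecar_path: str | Path | None = None) -> DynamicSeries:
    """Read a dynamic series, validating sidecar timing against the volume count."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix("").with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"timing sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "sample_times_min" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks 'sample_times_min'")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    zooms = img.header.get_zooms()
    return DynamicSeries(
        data=data,
        sample_times=np.asarray(meta["sample_times_min"], dtype=float),
        spacing=tuple(float(z) for z in zooms[:3]),
        specimen_id=str(meta.get("specimen_id", path.stem)),
        affine=np.asarray(img.affine),
    )


def write_roiset(rois: RoiSet, path: str | Path, labels_path: str | Path | None = None,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(rois.labels.astype(np.int16), np.diag([*spacing, 1.0]))
    nib.save(img, str(path))
    lp = Path(labels_path) if labels_path else path.with_suffix("").with_suffix(".json")
    lp.write_text(json.dumps({k: int(v) for k, v in rois.names.items()}, indent=1))
    return path


def read_roiset(path: str | Path, labels_path: str | Path | None = None,
                series: DynamicSeries | None = None) -> RoiSet:
    """Read an ROI label volume; optionally validate its grid against a series."""
    path = Path(path)
    lp = Path(labels_path) if labels_path else path.with_suffix("").with_suffix(".json")
    if not lp.exists():
        raise FileNotFoundError(f"ROI label dictionary not found: {lp}")
    names = {str(k): int(v) for k, v in json.loads(lp.read_text()).items()}
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    rois = RoiSet(labels=np.rint(labels).astype(np.int32), names=names)
    if series is not None:
        rois.check_grid(series)
    return rois


def write_assays(assays: AssayTable, path: str | Path) -> Path:
    path = Path(path)
    assays.table.to_csv(path, index=False)
    return path


def read_assays(path: str | Path) -> AssayTable:
    """Read the per-specimen assay CSV (header row required)."""
    df = pd.read_csv(path, header=0)
    return AssayTable(table=df)


def convert_dicom_series(dicom_dir: str | Path, slices_per_volume: int,
                         out_path: str | Path) -> DynamicSeries:
    """Convenience conversion of a single-frame DICOM directory to canonical NIfTI.

    Files are ordered by InstanceNumber and chunked into volumes of
    ``slices_per_volume``; per-volume times come from AcquisitionTime relative
    to the first volume.  The analysis itself only consumes the canonical form.
    """
    import pydicom

    dicom_dir = Path(dicom_dir)
    files = sorted(dicom_dir.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files under {dicom_dir}")
    dsets = [pydicom.dcmread(str(f)) for f in files]
    dsets.sort(key=lambda d: int(d.InstanceNumber))
    if len(dsets) % slices_per_volume:
        raise ValueError(
            f"{len(dsets)} slices is not a multiple of slices_per_volume={slices_per_volume}"
        )
    n_vol = len(dsets) // slices_per_volume
    slices = [np.asarray(d.pixel_array, dtype=np.float64).T for d in dsets]
    vols = [
        np.stack(slices[i * slices_per_volume : (i + 1) * slices_per_volume], axis=-1)
        for i in range(n_vol)
    ]
    data = np.stack(vols, axis=-1)

    def _acq_minutes(d) -> float:
        t = str(getattr(d, "AcquisitionTime", "0"))
        h, m, s = int(t[0:2] or 0), int(t[2:4] or 0), float(t[4:] or 0)
        return h * 60.0 + m + s / 60.0

    t0 = _acq_minutes(dsets[0])
    times = np.array([_acq_minutes(dsets[i * slices_per_volume]) - t0 for i in range(n_vol)])
    px = getattr(dsets[0], "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(dsets[0], "SliceThickness", 1.0))
    series = DynamicSeries(
        data=data,
        sample_times=times,
        spacing=(float(px[0]), float(px[1]), dz),
        specimen_id=str(getattr(dsets[0], "PatientID", "dicom")),
    )
    write_series(series, out_path)
    return series
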
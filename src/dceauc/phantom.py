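"""Digital tumour/pancreas phantoms and simulation of the dynamic acquisition.

The simulator emulates a collagen-targeted gadolinium probe study in a
fibrotic (desmoplastic) tumour model: a monoexponential plasma input
(half-life 19 min for a 10 µmol/kg dose), two-compartment tissue exchange
with reversible second-order binding to collagen sites, a linear relaxivity
model (16.2 mM⁻¹s⁻¹ per tri-Gd molecule), a spoiled-gradient-echo readout
(TR 92.6 ms, flip 35°) sampled at 0/5/20/35/45/55 min, and Rician magnitude
noise.  Ground truth (tissue classes, collagen, binding sites, perfusion,
noiseless concentration curves, endpoint Gd) is emitted alongside the noisy
series so every downstream stage can be tested against a known answer.

Tissue model (per voxel, concentrations in µM, times in min)::

    dCf/dt = (Ktrans/ve)(Cp - Cf) - kon·Cf·(Bmax - Cb) + kon·Kd·Cb
    dCb/dt = kon·Cf·(Bmax - Cb) - kon·Kd·Cb
    Ct     = vp·Cp + ve·Cf + Cb

where Cf is free probe in the extravascular extracellular space, Cb is
collagen-bound probe (per tissue volume), and Bmax = c·Hyp links binding
capacity linearly to hydroxyproline.  With Bmax = 0 this reduces to the
standard two-compartment exchange model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from dceauc.io import DynamicSeries, RoiSet, write_roiset, write_series

__all__ = [
    "PKParams",
    "SequenceParams",
    "TissueClass",
    "PhantomSpec",
    "PhantomTruth",
    "aif",
    "tissue_pk",
    "concentration_to_r1",
    "spgr_signal",
    "add_noise",
    "build_phantom",
    "simulate_study",
    "write_truth",
]

#: ground-truth tissue class labels
CLASS_LABELS = {"tumour": 1, "necrotic": 2, "pancreas": 3, "muscle": 4}
#: analysis ROI labels (tumour ROI includes the necrotic core, as drawn ROIs would)
ROI_LABELS = {"tumour": 1, "pancreas": 2, "muscle": 3}


@dataclass(frozen=True)
class PKParams:
    """Probe kinetics and relaxivity constants.

    Units: dose µmol/kg; injected concentration mM; half-life min;
    initial distribution volume mL/kg; ktrans 1/min; kon 1/(µM·min);
    kd µM; molecular relaxivity mM⁻¹s⁻¹.  koff is always kon·kd and is
    never stored separately.
    """

    dose_per_kg: float = 10.0
    inject_conc: float = 5.0
    plasma_half_life: float = 19.0
    init_dist_volume: float = 100.0
    ktrans: float = 0.1
    ve: float = 0.2
    vp: float = 0.05
    kon: float = 0.0015
    kd: float = 1.8
    r1_molecular: float = 16.2
    n_gd: int = 3

    def __post_init__(self) -> None:
        for name in ("dose_per_kg", "inject_conc", "plasma_half_life", "init_dist_volume",
                     "ktrans", "kon", "kd", "r1_molecular"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.ve <= 1:
            raise ValueError("ve must lie in (0, 1]")
        if not 0 <= self.vp < 1:
            raise ValueError("vp must lie in [0, 1)")
        if self.n_gd < 1:
            raise ValueError("n_gd must be a positive integer")

    @property
    def koff(self) -> float:
        """Dissociation rate, 1/min (kon·kd by definition)."""
        return self.kon * self.kd

    @property
    def cp0(self) -> float:
        """Initial plasma concentration, µM (dose over initial distribution volume)."""
        return self.dose_per_kg / self.init_dist_volume * 1000.0

    @property
    def r1_per_gd(self) -> float:
        """Per-Gd-ion relaxivity, mM⁻¹s⁻¹."""
        return self.r1_molecular / self.n_gd

    @property
    def injection_volume_ul_per_g(self) -> float:
        """Injected solution volume per gram of body weight, µL/g."""
        return self.dose_per_kg / self.inject_conc

    def control(self, affinity_loss: float = 100.0) -> "PKParams":
        """Non-binding stereoisomer: identical except for >=100-fold weaker affinity."""
        if affinity_loss < 100.0:
            raise ValueError("control probe must lose at least 100-fold affinity")
        return replace(self, kd=self.kd * affinity_loss)


@dataclass(frozen=True)
class SequenceParams:
    """Spoiled-gradient-echo readout and sampling schedule.

    TR/TE in ms, flip angle in degrees; sample times in minutes with the
    pre-injection baseline at 0.
    """

    tr: float = 92.6
    te: float = 2.77
    flip: float = 35.0
    sample_times: tuple[float, ...] = (0.0, 5.0, 20.0, 35.0, 45.0, 55.0)
    matrix: tuple[int, int] = (144, 144)
    voxel_size: tuple[float, float, float] = (0.2, 0.2, 1.0)

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.te < 0:
            raise ValueError("TR must be positive and TE nonnegative")
        if not 0 < self.flip <= 90:
            raise ValueError("flip angle must lie in (0, 90] degrees")
        st = np.asarray(self.sample_times, float)
        if st[0] != 0 or np.any(np.diff(st) <= 0):
            raise ValueError("sample times must start at 0 and increase strictly")


@dataclass(frozen=True)
class TissueClass:
    """Per-class generative parameters for the phantom.

    hyp: hydroxyproline mean and spatial SD, µg/g; ktrans mean 1/min with
    log-normal spatial SD; ve extravascular-extracellular fraction;
    vp plasma (vascular) volume fraction; r1_baseline pre-contrast
    longitudinal rate, 1/s.
    """

    hyp_mean: float
    hyp_sd: float
    ktrans_mean: float
    ktrans_sd_log: float
    ve: float
    vp: float
    r1_baseline: float

    def __post_init__(self) -> None:
        if self.hyp_mean < 0 or self.hyp_sd < 0:
            raise ValueError("collagen mean and SD must be nonnegative")
        if self.ktrans_mean <= 0 or self.r1_baseline <= 0:
            raise ValueError("ktrans and baseline R1 must be positive")
        if not 0 < self.ve <= 1:
            raise ValueError("ve must lie in (0, 1]")
        if not 0 <= self.vp < 1:
            raise ValueError("vp must lie in [0, 1)")


def _default_classes() -> dict[str, TissueClass]:
    return {
        # fibrotic tumour rim: collagen-rich, poorly perfused, dense ECM
        "tumour": TissueClass(1224.0, 250.0, 0.10, 0.25, 0.20, 0.04, 0.60),
        # necrotic core: low collagen, nearly unperfused
        "necrotic": TissueClass(300.0, 80.0, 0.01, 0.25, 0.30, 0.01, 0.50),
        # healthy pancreas: normal collagen, well perfused
        "pancreas": TissueClass(523.0, 60.0, 0.50, 0.25, 0.50, 0.15, 0.60),
        # dorsal muscle: the normalization reference
        "muscle": TissueClass(250.0, 30.0, 0.05, 0.15, 0.12, 0.03, 0.75),
    }


@dataclass
class PhantomSpec:
    """Geometry, tissue composition and noise of one synthetic specimen.

    Geometry is parametric (ellipsoids on a regular grid, muscle as a dorsal
    slab); ``collagen_scale`` and ``perfusion_scale`` are specimen-level
    multipliers used to generate between-animal variability in a cohort.
    ``seed`` fixes all randomness in phantom construction.
    """

    shape: tuple[int, int, int] = (64, 64, 10)
    spacing: tuple[float, float, float] = (0.45, 0.45, 1.0)
    tumour_center: tuple[float, float, float] = (21.0, 34.0, 4.5)
    tumour_radii: tuple[float, float, float] = (11.0, 11.0, 4.0)
    necrotic_radii: tuple[float, float, float] = (4.0, 4.0, 1.8)
    pancreas_center: tuple[float, float, float] = (47.0, 34.0, 4.5)
    pancreas_radii: tuple[float, float, float] = (8.0, 8.0, 3.0)
    muscle_rows: int = 5
    classes: dict[str, TissueClass] = field(default_factory=_default_classes)
    smooth_sigma: float = 1.5
    bmax_per_hyp: float = 0.025
    noise_sigma: float = 0.3
    m0: float = 100.0
    collagen_scale: float = 1.0
    perfusion_scale: float = 1.0
    endpoint_time_min: float = 80.0
    specimen_id: str = "phantom"
    seed: int = 0

    def __post_init__(self) -> None:
        required = {"tumour", "necrotic", "pancreas", "muscle"}
        if set(self.classes) != required:
            raise ValueError(f"classes must be exactly {sorted(required)}")
        if self.classes["necrotic"].hyp_mean >= self.classes["tumour"].hyp_mean:
            raise ValueError("necrotic-core collagen mean must be below the tumour mean")
        if self.bmax_per_hyp < 0 or self.noise_sigma < 0:
            raise ValueError("bmax_per_hyp and noise_sigma must be nonnegative")
        if self.collagen_scale <= 0 or self.perfusion_scale <= 0:
            raise ValueError("specimen-level scales must be positive")


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic specimen.

    Concentration curves (µM, noiseless) and the specimen table (true mean
    hydroxyproline plus simulated endpoint Gd in nmol/g assuming tissue
    density 1 g/mL) are filled by :func:`simulate_study`.
    """

    class_map: np.ndarray
    hyp_map: np.ndarray
    bmax_map: np.ndarray
    ktrans_map: np.ndarray
    ve_map: np.ndarray
    vp_map: np.ndarray
    r1_baseline_map: np.ndarray
    specimen_id: str = "phantom"
    conc_times: np.ndarray | None = None
    conc_curves: np.ndarray | None = None  # total tissue concentration, (x,y,z,t)
    specimen_table: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# kinetics


def aif(t, pk: PKParams):
    """Plasma probe concentration (µM) at time t (min): monoexponential decay.

    Cp(t) = Cp(0)·2^(−t/t½) with Cp(0) = dose / initial distribution volume.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return pk.cp0 * 2.0 ** (-t / pk.plasma_half_life)


def tissue_pk(
    cp: Callable[[np.ndarray], np.ndarray],
    ktrans,
    ve,
    vp,
    kon,
    kd,
    bmax,
    t_grid,
    dt: float = 0.02,
):
    """Integrate the two-compartment + reversible-binding model.

    Parameters may be scalars or broadcastable arrays (voxel-wise maps);
    ``cp`` is the plasma input as a callable of time (min) returning µM.
    Integration starts from zero tissue concentration at t = 0 using
    classical fixed-step RK4 with substeps no longer than ``dt`` minutes.

    Returns ``(cf, cb, ct)``, each of shape ``(*param_shape, len(t_grid))``.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if t_grid[0] < 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be nonnegative and strictly increasing")
    ktrans, ve, vp, kon, kd, bmax = (
        np.asarray(a, dtype=float) for a in np.broadcast_arrays(ktrans, ve, vp, kon, kd, bmax)
    )
    if np.any(bmax < 0):
        raise ValueError("Bmax must be nonnegative")
    shape = ktrans.shape
    kep = ktrans / ve
    koff = kon * kd

    def deriv(t, cf, cb):
        cpt = cp(t)
        bind = kon * cf * (bmax - cb) - koff * cb
        return kep * (cpt - cf) - bind, bind

    cf = np.zeros(shape)
    cb = np.zeros(shape)
    out_cf = np.empty(shape + (t_grid.size,))
    out_cb = np.empty(shape + (t_grid.size,))
    t_now = 0.0
    for j, t_next in enumerate(t_grid):
        span = t_next - t_now
        if span > 0:
            n_sub = max(1, int(np.ceil(span / dt)))
            h = span / n_sub
            for _ in range(n_sub):
                k1f, k1b = deriv(t_now, cf, cb)
                k2f, k2b = deriv(t_now + h / 2, cf + h / 2 * k1f, cb + h / 2 * k1b)
                k3f, k3b = deriv(t_now + h / 2, cf + h / 2 * k2f, cb + h / 2 * k2b)
                k4f, k4b = deriv(t_now + h, cf + h * k3f, cb + h * k3b)
                cf = cf + h / 6 * (k1f + 2 * k2f + 2 * k3f + k4f)
                cb = cb + h / 6 * (k1b + 2 * k2b + 2 * k3b + k4b)
                t_now += h
            t_now = t_next
        out_cf[..., j] = cf
        out_cb[..., j] = cb
    # guard against tiny negative round-off
    np.clip(out_cf, 0.0, None, out=out_cf)
    np.clip(out_cb, 0.0, None, out=out_cb)
    ct = vp[..., None] * cp(t_grid) + ve[..., None] * out_cf + out_cb
    return out_cf, out_cb, ct


def concentration_to_r1(ct, r1_molecular: float, r1_baseline):
    """Linear relaxivity model: R1 = R1₀ + r1·[probe], ct in µM, r1 in mM⁻¹s⁻¹."""
    ct = np.asarray(ct, dtype=float)
    if np.any(ct < 0):
        raise ValueError("concentration must be nonnegative")
    return np.asarray(r1_baseline, dtype=float) + r1_molecular * ct / 1000.0


def spgr_signal(r1, seq: SequenceParams, m0=1.0):
    """Steady-state spoiled-gradient-echo signal.

    S = M0·sinθ·(1 − E)/(1 − E·cosθ) with E = exp(−TR·R1).  TE/T2* decay is
    neglected (TE = 2.77 ms is short, and all downstream quantities are
    ratios that cancel multiplicative factors).
    """
    r1 = np.asarray(r1, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if seq.tr <= 0:
        raise ValueError("TR must be positive")
    if np.any(r1 <= 0):
        raise ValueError("R1 must be positive")
    if np.any(m0 < 0):
        raise ValueError("M0 must be nonnegative")
    theta = np.radians(seq.flip)
    e1 = np.exp(-seq.tr / 1000.0 * r1)
    return m0 * np.sin(theta) * (1.0 - e1) / (1.0 - e1 * np.cos(theta))


def add_noise(volume, sigma: float, seed: int):
    """Rician magnitude noise: |signal + n₁ + i·n₂| with n ~ N(0, sigma²)."""
    volume = np.asarray(volume, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    return np.hypot(volume + n1, n2)


# ---------------------------------------------------------------------------
# phantom construction


def _ellipsoid(shape, center, radii):
    idx = np.indices(shape, dtype=float)
    d2 = sum(((idx[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance, zero-mean Gaussian random field with correlation length sigma."""
    w = rng.standard_normal(shape)
    if sigma > 0:
        w = gaussian_filter(w, sigma=sigma, mode="wrap")
    sd = w.std()
    return w / sd if sd > 0 else w


def build_phantom(spec: PhantomSpec) -> tuple[PhantomTruth, RoiSet]:
    """Lay out tissue classes and draw per-voxel collagen and perfusion maps.

    Collagen (hydroxyproline) is a class mean plus a spatially smooth random
    field; perfusion (ktrans) is log-normal around the class mean, so maps
    stay positive.  Binding capacity is the fixed linear conversion
    Bmax = bmax_per_hyp · Hyp.  All randomness derives from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    class_map = np.zeros(shape, dtype=np.int16)
    tum = _ellipsoid(shape, spec.tumour_center, spec.tumour_radii)
    nec = _ellipsoid(shape, spec.tumour_center, spec.necrotic_radii)
    pan = _ellipsoid(shape, spec.pancreas_center, spec.pancreas_radii) & ~tum
    mus = np.zeros(shape, dtype=bool)
    mus[:, : spec.muscle_rows, :] = True
    mus &= ~(tum | pan)
    class_map[mus] = CLASS_LABELS["muscle"]
    class_map[pan] = CLASS_LABELS["pancreas"]
    class_map[tum] = CLASS_LABELS["tumour"]
    class_map[nec & tum] = CLASS_LABELS["necrotic"]

    for name, lab in CLASS_LABELS.items():
        if not np.any(class_map == lab):
            raise ValueError(f"phantom geometry leaves tissue class '{name}' empty")

    hyp_field = _smooth_field(rng, shape, spec.smooth_sigma)
    perf_field = _smooth_field(rng, shape, spec.smooth_sigma)
    hyp = np.zeros(shape)
    ktrans = np.zeros(shape)
    ve = np.zeros(shape)
    vp = np.zeros(shape)
    r1b = np.zeros(shape)
    for name, cls in spec.classes.items():
        m = class_map == CLASS_LABELS[name]
        hyp[m] = cls.hyp_mean * spec.collagen_scale + cls.hyp_sd * hyp_field[m]
        sd = cls.ktrans_sd_log
        ktrans[m] = (
            cls.ktrans_mean * spec.perfusion_scale * np.exp(sd * perf_field[m] - sd**2 / 2)
        )
        ve[m] = cls.ve
        vp[m] = cls.vp
        r1b[m] = cls.r1_baseline
    np.clip(hyp, 0.0, None, out=hyp)

    truth = PhantomTruth(
        class_map=class_map,
        hyp_map=hyp,
        bmax_map=spec.bmax_per_hyp * hyp,
        ktrans_map=ktrans,
        ve_map=ve,
        vp_map=vp,
        r1_baseline_map=r1b,
        specimen_id=spec.specimen_id,
    )
    roi_labels = np.zeros(shape, dtype=np.int16)
    roi_labels[tum] = ROI_LABELS["tumour"]  # drawn tumour ROIs include necrotic areas
    roi_labels[pan] = ROI_LABELS["pancreas"]
    roi_labels[mus] = ROI_LABELS["muscle"]
    rois = RoiSet(labels=roi_labels, names=dict(ROI_LABELS))
    return truth, rois


def simulate_study(
    spec: PhantomSpec,
    pk: PKParams | None = None,
    seq: SequenceParams | None = None,
    probe: Literal["targeted", "control"] = "targeted",
    seed: int | None = None,
) -> tuple[DynamicSeries, RoiSet, PhantomTruth]:
    """Simulate one dynamic study of a phantom specimen.

    The baseline volume contains no probe; each later volume is the SPGR
    signal of the tissue concentration at that sample time with Rician
    noise.  ``probe='control'`` uses the non-binding stereoisomer (100-fold
    weaker affinity, otherwise identical).  ``seed`` (default ``spec.seed``)
    drives the noise stream; phantom construction uses ``spec.seed``.
    """
    pk = pk or PKParams()
    seq = seq or SequenceParams()
    if probe not in ("targeted", "control"):
        raise ValueError("probe must be 'targeted' or 'control'")
    pk_used = pk if probe == "targeted" else pk.control()
    truth, rois = build_phantom(spec)
    body = truth.class_map > 0

    times = np.asarray(seq.sample_times, dtype=float)
    t_eval = np.union1d(times[times > 0], [spec.endpoint_time_min])

    cp = lambda t: aif(t, pk_used)  # noqa: E731
    _, _, ct = tissue_pk(
        cp,
        truth.ktrans_map[body],
        truth.ve_map[body],
        truth.vp_map[body],
        pk_used.kon,
        pk_used.kd,
        truth.bmax_map[body],
        t_eval,
    )

    n_t = times.size
    conc = np.zeros((*spec.shape, n_t))
    for j, t in enumerate(times):
        if t == 0:
            continue
        conc[..., j][body] = ct[..., np.searchsorted(t_eval, t)]
    truth.conc_times = times.copy()
    truth.conc_curves = conc

    r1 = np.where(
        body[..., None],
        concentration_to_r1(conc, pk_used.r1_molecular, truth.r1_baseline_map[..., None]),
        1.0,
    )
    m0 = np.where(body, spec.m0, 0.0)
    signal = spgr_signal(r1, seq, m0[..., None])

    noise_seed = int(np.random.SeedSequence(spec.seed if seed is None else seed).generate_state(1)[0] % (2**31))
    noisy = add_noise(signal, spec.noise_sigma, noise_seed)
    series = DynamicSeries(
        data=noisy,
        sample_times=times,
        spacing=spec.spacing,
        specimen_id=spec.specimen_id,
    )

    # endpoint ground truth: total tissue concentration at the endpoint time,
    # converted to Gd nmol/g assuming tissue density 1 g/mL (µM × n_gd ions)
    ct_end = np.zeros(spec.shape)
    ct_end[body] = ct[..., np.searchsorted(t_eval, spec.endpoint_time_min)]
    rows = []
    for name in ("tumour", "pancreas", "muscle"):
        m = rois.mask(name)
        rows.append(
            {
                "specimen_id": spec.specimen_id,
                "tissue": name,
                "probe": probe,
                "true_hyp_ug_g": float(truth.hyp_map[m].mean()),
                "sim_gd_nmol_g": float(ct_end[m].mean() * pk_used.n_gd),
                "n_voxels": int(m.sum()),
            }
        )
    truth.specimen_table = pd.DataFrame(rows)
    return series, rois, truth


def write_truth(truth: PhantomTruth, out_dir: str | Path) -> Path:
    """Write the per-specimen ground-truth table as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "truth.csv"
    if truth.specimen_table is None:
        raise ValueError("truth has no specimen table; run simulate_study first")
    truth.specimen_table.to_csv(path, index=False)
    return path


def write_study(series: DynamicSeries, rois: RoiSet, truth: PhantomTruth,
                out_dir: str | Path, pk: PKParams, seq: SequenceParams,
                probe: str, seed: int) -> Path:
    """Write one simulated study in the canonical layout (NIfTI + sidecars + CSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_series(
        series,
        out_dir / "series.nii.gz",
        out_dir / "series.json",
        probe=probe,
        seed=seed,
        pk={k: getattr(pk, k) for k in (
            "dose_per_kg", "inject_conc", "plasma_half_life", "init_dist_volume",
            "ktrans", "ve", "vp", "kon", "kd", "r1_molecular", "n_gd")},
        seq={"tr": seq.tr, "te": seq.te, "flip": seq.flip,
             "sample_times": list(seq.sample_times)},
    )
    write_roiset(rois, out_dir / "rois.nii.gz", out_dir / "rois.json", spacing=series.spacing)
    write_truth(truth, out_dir)
    (out_dir / "spec.json").write_text(json.dumps({"specimen_id": series.specimen_id}, indent=1))
    return out_dir
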
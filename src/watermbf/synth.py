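"""Synthetic dynamic oxygen-15-water cardiac PET phantom.

Everything downstream (kinetic fitting, segmentation, the misalignment
study) is testable against this module: it builds a voxelised thick-walled
half-ellipsoidal left ventricle with an adjacent right-ventricular blood
pool, assigns per-territory kinetic truth, generates tissue curves through
the single-tissue-compartment forward model, and adds count-statistics-like
frame noise.  Geometry follows the axis convention +X = patient-left,
+Y = anterior, +Z = caudal; the LV long axis lies along Z with the apex
pointing caudally.

Simulation scope: reconstructed, decay-corrected image space.  No sinograms,
scatter, randoms or intra-scan motion are modelled, and attenuation-
correction errors enter only as the amplitude-bias fields of
:mod:`watermbf.misalign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .frames import (
    FrameSchedule,
    SampledCurve,
    frame_average,
    make_default_frame_schedule,
)
from .kinetics import DEFAULT_V_D, InputFunctions, _convolve_values

__all__ = [
    "AifParams",
    "TruthParams",
    "PhantomSpec",
    "DynamicImage",
    "PhantomGeometry",
    "Phantom",
    "make_aif",
    "make_rv_curve",
    "forward_tac",
    "build_phantom",
    "add_noise",
]

AXIS_CONVENTION = "+X=patient-left, +Y=anterior, +Z=caudal"

TERRITORIES = ("LAD", "RCA", "LCX")
TERRITORY_CODES = {"LAD": 1, "RCA": 2, "LCX": 3}


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth kinetic parameters of a tissue region.

    mbf in mL/g/min, ptf in g/mL, v_a/v_rv unitless blood fractions with
    ``v_a + v_rv <= 1``.
    """

    mbf: float
    ptf: float
    v_a: float
    v_rv: float

    def __post_init__(self) -> None:
        if self.mbf < 0:
            raise ValueError("mbf must be non-negative")
        if not (0 <= self.ptf <= 1.2):
            raise ValueError("ptf must lie in [0, 1.2] g/mL")
        if not (0 <= self.v_a < 1) or not (0 <= self.v_rv < 1):
            raise ValueError("blood fractions must lie in [0, 1)")
        if self.v_a + self.v_rv > 1:
            raise ValueError("v_a + v_rv must not exceed 1")


@dataclass(frozen=True)
class AifParams:
    """Parametric arterial input: gamma-variate bolus + recirculation tail."""

    peak_time_s: float = 25.0
    peak_value: float = 60.0
    recirc_fraction: float = 0.15
    tail_rate_per_s: float = 0.01
    rise_time_s: float = 10.0


def _default_territory_truth() -> dict[str, TruthParams]:
    # Septal sectors (LAD/RCA) see more right-ventricular spill-over than
    # the free lateral wall.
    return {
        "LAD": TruthParams(mbf=2.4, ptf=0.70, v_a=0.15, v_rv=0.08),
        "RCA": TruthParams(mbf=2.0, ptf=0.70, v_a=0.15, v_rv=0.08),
        "LCX": TruthParams(mbf=2.8, ptf=0.70, v_a=0.15, v_rv=0.02),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to build one deterministic phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    lv_outer_semiaxes_mm: tuple[float, float, float] = (30.0, 30.0, 40.0)
    wall_thickness_mm: float = 10.0
    base_cut_mm: float = 10.0
    rv_center_offset_mm: tuple[float, float, float] = (-35.0, -5.0, 0.0)
    rv_semiaxes_mm: tuple[float, float, float] = (12.0, 18.0, 25.0)
    territory_truth: dict[str, TruthParams] = field(
        default_factory=_default_territory_truth
    )
    aif: AifParams = field(default_factory=AifParams)
    rv_lead_time_s: float = 4.0
    rv_dispersion_s: float = 6.0
    fine_dt_s: float = 0.1
    #: calibrated to ~5% relative noise on late wall-curve frames, a level
    #: at which the fitter stays stable (median |MBF| error a few percent)
    noise_scale: float = 0.4
    noise_floor: float = 1.0
    seed: int = 1234
    v_d: float = DEFAULT_V_D

    def __post_init__(self) -> None:
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if set(self.territory_truth) != set(TERRITORIES):
            raise ValueError(f"territory_truth must define exactly {TERRITORIES}")

    def with_global_mbf(self, global_mbf: float) -> "PhantomSpec":
        """Rescale all territory MBFs so their mean equals ``global_mbf``."""
        mean = np.mean([t.mbf for t in self.territory_truth.values()])
        scale = global_mbf / mean
        truth = {
            k: replace(t, mbf=t.mbf * scale) for k, t in self.territory_truth.items()
        }
        return replace(self, territory_truth=truth)


@dataclass(frozen=True)
class DynamicImage:
    """A 4-D dynamic volume (x, y, z, frame) in kBq/mL with its timing."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: float
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise ValueError("dynamic image data must be 4-D (x, y, z, frame)")
        if data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis ({data.shape[3]}) does not match the schedule "
                f"({self.schedule.n_frames} frames)"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("image values must be finite")


@dataclass(frozen=True)
class PhantomGeometry:
    """Geometric description of the phantom heart on its voxel grid."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    lv_center_mm: np.ndarray
    outer_semiaxes_mm: np.ndarray
    inner_semiaxes_mm: np.ndarray
    wall_mask: np.ndarray
    normals: np.ndarray  # (nx, ny, nz, 3) outward unit wall normals
    long_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class Phantom:
    """A built phantom: image, ground truth and bookkeeping masks."""

    image: DynamicImage
    truth_maps: dict[str, np.ndarray]
    labels: np.ndarray
    wall_mask: np.ndarray
    lv_voi: np.ndarray
    rv_voi: np.ndarray
    inputs: InputFunctions
    geometry: PhantomGeometry
    spec: PhantomSpec


def make_aif(
    peak_time_s: float = 25.0,
    peak_value: float = 60.0,
    recirc_fraction: float = 0.15,
    tail_rate: float = 0.01,
    fine_dt_s: float = 0.1,
    duration_s: float = 240.0,
    rise_time_s: float = 10.0,
) -> SampledCurve:
    """Parametric arterial input function on a uniform fine grid.

    A gamma-variate bolus (shape parameter alpha = 2) peaking at
    ``peak_time_s`` with value ``peak_value``, plus a slowly decaying
    recirculation tail ramped in after bolus arrival.  The curve is zero
    before arrival and non-negative everywhere.
    """
    if fine_dt_s <= 0:
        raise ValueError("fine_dt_s must be positive")
    if peak_value <= 0:
        raise ValueError("peak_value must be positive")
    if not (0 <= recirc_fraction < 1):
        raise ValueError("recirc_fraction must lie in [0, 1)")
    if rise_time_s <= 0 or peak_time_s < rise_time_s:
        raise ValueError("need peak_time_s >= rise_time_s > 0")
    t = np.arange(0.0, duration_s + fine_dt_s / 2, fine_dt_s)
    t0 = peak_time_s - rise_time_s
    tau = np.clip(t - t0, 0.0, None)
    u = tau / rise_time_s
    bolus = peak_value * u**2 * np.exp(2.0 * (1.0 - u))
    recirc = (
        recirc_fraction
        * peak_value
        * (1.0 - np.exp(-tau / 20.0))
        * np.exp(-tail_rate * tau)
    )
    values = np.where(tau > 0, bolus + recirc, 0.0)
    return SampledCurve(t, values)


def make_rv_curve(
    aif: SampledCurve, lead_time_s: float = 4.0, dispersion_s: float = 6.0
) -> SampledCurve:
    """Right-ventricular input: the arterial bolus, earlier and dispersed.

    Blood passes the right ventricle before the lungs and left heart, so the
    RV curve leads the arterial one by ``lead_time_s`` and is smoothed by a
    normalised single-exponential dispersion kernel of time constant
    ``dispersion_s`` (0 disables the smoothing).  The time grid is preserved.
    """
    if lead_time_s < 0:
        raise ValueError("lead_time_s must be non-negative")
    if dispersion_s < 0:
        raise ValueError("dispersion_s must be non-negative")
    t = aif.times_s
    shifted = np.interp(t + lead_time_s, t, aif.values, left=0.0)
    if dispersion_s == 0:
        return SampledCurve(t, shifted)
    dt = aif.dt()
    smoothed = _convolve_values(shifted, dt, 1.0 / dispersion_s) / dispersion_s
    return SampledCurve(t, smoothed)


def forward_tac(
    truth: TruthParams,
    inputs: InputFunctions,
    schedule: FrameSchedule,
    v_d: float = DEFAULT_V_D,
) -> SampledCurve:
    """Frame-averaged tissue curve from the forward compartment model.

    Evaluates

        C(t) = (MBF/60) PTF [C_A conv exp(-MBF/(60 V_D) t)](t)
               + V_A C_A(t) + V_RV C_RV(t)

    on the fine input grid (MBF converted from per-minute to per-second),
    then averages within each frame interval to emulate frame binning.
    Returns a curve with one value per frame at the frame midpoints.
    """
    if v_d <= 0:
        raise ValueError("v_d must be positive")
    dt = inputs.c_a.dt()
    lam = truth.mbf / (60.0 * v_d)
    k1 = truth.mbf / 60.0 * truth.ptf
    fine = (
        k1 * _convolve_values(inputs.c_a.values, dt, lam)
        + truth.v_a * inputs.c_a.values
        + truth.v_rv * inputs.c_rv.values
    )
    framed = frame_average(SampledCurve(inputs.times_s, fine), schedule)
    return SampledCurve(schedule.mids_s, framed)


def _grid_coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    axes = [
        (np.arange(n) + 0.5) * spec.voxel_size_mm for n in spec.grid_shape
    ]
    return tuple(np.meshgrid(*axes, indexing="ij"))


def build_phantom(
    spec: PhantomSpec, schedule: Optional[FrameSchedule] = None
) -> Phantom:
    """Build the voxelised phantom and its ground truth.

    The LV wall is the shell between two confocal ellipsoids truncated at a
    basal plane (open towards the cranial side); the cavity inside carries
    the arterial curve, the RV pool the right-ventricular curve, and each
    wall voxel the forward-model curve of its coronary territory.  Noise is
    added per ``spec.noise_scale`` and ``spec.seed``; the construction is
    bit-reproducible for a given spec.
    """
    from .regions import circumferential_territories

    if schedule is None:
        schedule = make_default_frame_schedule()
    outer = np.asarray(spec.lv_outer_semiaxes_mm, dtype=float)
    inner = outer - spec.wall_thickness_mm
    if np.any(inner <= 0):
        raise ValueError("wall thickness exceeds the LV semiaxes")
    if spec.wall_thickness_mm < spec.voxel_size_mm:
        raise ValueError("wall is thinner than one voxel")

    center = 0.5 * spec.voxel_size_mm * np.asarray(spec.grid_shape, dtype=float)
    xx, yy, zz = _grid_coords_mm(spec)
    rel = np.stack([xx - center[0], yy - center[1], zz - center[2]], axis=-1)

    q_outer = np.sum((rel / outer) ** 2, axis=-1)
    q_inner = np.sum((rel / inner) ** 2, axis=-1)
    above_base = rel[..., 2] >= -spec.base_cut_mm
    wall = (q_outer <= 1.0) & (q_inner >= 1.0) & above_base
    lv_cavity = (q_inner < 1.0) & above_base

    rv_center = center + np.asarray(spec.rv_center_offset_mm)
    rv_rel = np.stack(
        [xx - rv_center[0], yy - rv_center[1], zz - rv_center[2]], axis=-1
    )
    q_rv = np.sum((rv_rel / np.asarray(spec.rv_semiaxes_mm)) ** 2, axis=-1)
    rv_cavity = (q_rv <= 1.0) & ~wall & ~lv_cavity

    if not wall.any():
        raise ValueError("phantom wall is empty; check geometry")

    # outward ellipsoid normals (gradient of the quadratic form), unit length
    grad = rel / outer**2
    norm = np.linalg.norm(grad, axis=-1, keepdims=True)
    normals = np.where(norm > 0, grad / np.where(norm > 0, norm, 1.0), 0.0)

    geometry = PhantomGeometry(
        grid_shape=spec.grid_shape,
        voxel_size_mm=spec.voxel_size_mm,
        lv_center_mm=center,
        outer_semiaxes_mm=outer,
        inner_semiaxes_mm=inner,
        wall_mask=wall,
        normals=normals,
    )

    labels = circumferential_territories(wall, center, spec.voxel_size_mm)

    a = spec.aif
    c_a = make_aif(
        peak_time_s=a.peak_time_s,
        peak_value=a.peak_value,
        recirc_fraction=a.recirc_fraction,
        tail_rate=a.tail_rate_per_s,
        fine_dt_s=spec.fine_dt_s,
        duration_s=schedule.total_duration_s,
        rise_time_s=a.rise_time_s,
    )
    c_rv = make_rv_curve(c_a, spec.rv_lead_time_s, spec.rv_dispersion_s)
    inputs = InputFunctions(c_a=c_a, c_rv=c_rv)
    framed_ca = frame_average(c_a, schedule)
    framed_crv = frame_average(c_rv, schedule)

    data = np.zeros(spec.grid_shape + (schedule.n_frames,))
    truth_maps = {
        k: np.zeros(spec.grid_shape) for k in ("mbf", "ptf", "v_a", "v_rv", "mbft")
    }
    for name, code in TERRITORY_CODES.items():
        truth = spec.territory_truth[name]
        region = labels == code
        tac = forward_tac(truth, inputs, schedule, spec.v_d)
        data[region] = tac.values
        truth_maps["mbf"][region] = truth.mbf
        truth_maps["ptf"][region] = truth.ptf
        truth_maps["v_a"][region] = truth.v_a
        truth_maps["v_rv"][region] = truth.v_rv
        truth_maps["mbft"][region] = truth.mbf * truth.ptf / (1.0 - truth.v_a)
    data[lv_cavity] = framed_ca
    data[rv_cavity] = framed_crv

    image = DynamicImage(
        data=data, schedule=schedule, voxel_size_mm=spec.voxel_size_mm
    )
    if spec.noise_scale > 0:
        image = add_noise(image, spec.noise_scale, spec.seed, spec.noise_floor)

    from scipy.ndimage import binary_erosion

    lv_voi = binary_erosion(lv_cavity)
    rv_voi = binary_erosion(rv_cavity)
    if not lv_voi.any():
        lv_voi = lv_cavity
    if not rv_voi.any():
        rv_voi = rv_cavity

    return Phantom(
        image=image,
        truth_maps=truth_maps,
        labels=labels,
        wall_mask=wall,
        lv_voi=lv_voi,
        rv_voi=rv_voi,
        inputs=inputs,
        geometry=geometry,
        spec=spec,
    )


def add_noise(
    img: DynamicImage, noise_scale: float, seed: int, floor: float = 1.0
) -> DynamicImage:
    """Add count-limited-frame noise to a dynamic image.

    Zero-mean Gaussian noise per voxel-frame with standard deviation
    ``noise_scale * sqrt(max(value, floor) / duration_s)`` - variance
    proportional to activity and inversely proportional to frame duration,
    the usual behaviour of reconstructed-image noise.  Reproducible by seed.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    if noise_scale == 0:
        return img
    rng = np.random.default_rng(seed)
    sd = noise_scale * np.sqrt(
        np.maximum(img.data, floor) / img.schedule.durations_s
    )
    noisy = img.data + rng.standard_normal(img.data.shape) * sd
    return DynamicImage(
        data=noisy,
        schedule=img.schedule,
        voxel_size_mm=img.voxel_size_mm,
        axis_convention=img.axis_convention,
    )
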
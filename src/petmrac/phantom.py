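"""Synthetic pediatric head phantoms.

Each phantom is a concentric-ellipsoid head: a soft-tissue scalp shell, a
skull layer whose thickness and peak density scale with age class, a brain
compartment, optional internal air cavities (nasal, mastoid, post-surgical
pocket), and a spherical FET-avid tumor.  From the anatomy we synthesize

* a ground-truth CT in Hounsfield units,
* a co-registered dual-echo UTE pair whose bone signal decays with a
  spatially varying R2* tied to the local bone density (so an R2* -> HU
  mapping exists to be calibrated, as in segmentation-based AC),
* an amino-acid-tracer-like activity map with background uptake ~1 and a
  suprathreshold tumor,
* a background ROI mirrored into the hemisphere opposite the tumor, and an
  exclusion mask covering any extratumoral hot spot.

The skull of an infant is thin and of low density and calcifies rapidly
through childhood; the age-class table below encodes that growth so that the
AC methods are exercised across the anatomical range they must handle.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import Volume, require_same_grid

__all__ = [
    "AGE_CLASSES", "AGE_DEFAULTS", "LABELS", "PhantomSpec", "PhantomCase",
    "build_anatomy", "synthesize_signals", "synthesize_activity",
    "generate_case", "generate_battery", "substream",
]

# tissue label codes
LABELS = {"bg_air": 0, "soft": 1, "bone": 2, "int_air": 3, "brain": 4, "tumor": 5}
BG_AIR, SOFT, BONE, INT_AIR, BRAIN, TUMOR = 0, 1, 2, 3, 4, 5

# seven pediatric age brackets with (skull thickness mm, peak skull HU).
# Values follow the qualitative rule that both thickness and mineral density
# grow quickly over the first years of life; they are plausible defaults, not
# a calibrated growth curve, and are freely overridable per spec.
AGE_CLASSES = ("0-2m", "2m-1y", "1-2y", "2-4y", "4-8y", "8-11y", "11-14y")
AGE_DEFAULTS = {
    "0-2m": (2.0, 400.0),
    "2m-1y": (2.5, 500.0),
    "1-2y": (3.0, 650.0),
    "2-4y": (3.5, 800.0),
    "4-8y": (4.5, 1000.0),
    "8-11y": (5.5, 1200.0),
    "11-14y": (6.0, 1300.0),
}

# UTE echo times (ms)
TE1_MS = 0.07
TE2_MS = 2.46

# per-tissue (S0, R2* s^-1, HU) means; bone handled separately via the
# density field (R2* and HU co-vary with local mineral density)
TISSUE_SIGNALS = {
    BG_AIR: (0.0, 0.0, -1000.0),
    SOFT: (100.0, 30.0, 30.0),
    INT_AIR: (0.0, 0.0, -1000.0),
    BRAIN: (100.0, 20.0, 40.0),
    TUMOR: (100.0, 25.0, 40.0),
}
BONE_S0 = 80.0
BONE_R2_BASE = 400.0   # s^-1 at zero mineral density fraction
BONE_R2_SPAN = 800.0   # s^-1 added at full density
BONE_DENSITY_RANGE = (0.3, 1.0)  # fraction of skull_peak_hu

SCALP_THICKNESS_MM = 5.0
HEAD_FRACTION = 0.85  # outer head semi-axes as a fraction of the half-extent


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible random substream.

    A single study seed fans out to per-stage generators keyed by strings, so
    each stage is reproducible in isolation.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject."""

    age_class: str = "4-8y"
    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    voxel_mm: float = 2.0
    skull_thickness_mm: Optional[float] = None  # None -> age default
    skull_peak_hu: Optional[float] = None       # None -> age default
    tumor_center_mm: Tuple[float, float, float] = (0.0, -8.0, 10.0)
    tumor_radius_mm: float = 8.0
    tumor_to_background_ratio: float = 2.5
    air_nasal: bool = False
    air_mastoid: bool = False
    air_pocket: bool = False
    hot_spot: bool = False
    noise_sigma: float = 0.02  # fraction of soft-tissue S0
    seed: int = 0

    def __post_init__(self):
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"unknown age class {self.age_class!r}")
        if len(self.grid_shape) != 3 or any(int(s) < 32 for s in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 32, got {self.grid_shape}")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be positive")
        if self.tumor_to_background_ratio <= 0:
            raise ValueError("tumor_to_background_ratio must be positive")
        if self.skull_mm < self.voxel_mm:
            raise ValueError(
                f"skull_thickness_mm={self.skull_mm} below one voxel ({self.voxel_mm} mm)")

    @property
    def skull_mm(self) -> float:
        return self.skull_thickness_mm if self.skull_thickness_mm is not None \
            else AGE_DEFAULTS[self.age_class][0]

    @property
    def peak_hu(self) -> float:
        return self.skull_peak_hu if self.skull_peak_hu is not None \
            else AGE_DEFAULTS[self.age_class][1]

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return (self.voxel_mm,) * 3

    @classmethod
    def micro(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """32^3 grid at 3 mm — the scale used by the test battery."""
        kw = dict(grid_shape=(32, 32, 32), voxel_mm=3.0, age_class="4-8y",
                  tumor_radius_mm=8.0, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """96^3 grid at 2 mm."""
        kw = dict(grid_shape=(96, 96, 96), voxel_mm=2.0, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def full(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """192^3 grid at 1.6 mm, the acquisition-matrix scale."""
        kw = dict(grid_shape=(192, 192, 192), voxel_mm=1.6, seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PhantomCase:
    """One synthetic examination: anatomy, CT, UTE echoes, activity, ROIs."""

    labels: Volume            # int labels per LABELS
    ct_hu: Volume             # Hounsfield units
    ute1: Volume              # first-echo magnitude, a.u.
    ute2: Volume              # second-echo magnitude, a.u.
    activity: Volume          # tracer uptake, a.u. (background ~ 1)
    background_roi: Volume    # bool
    exclusion_mask: Volume    # bool
    spec: PhantomSpec
    subject_id: str = "sub-000"
    exam_index: int = 0

    def __post_init__(self):
        require_same_grid(self.labels, self.ct_hu, self.ute1, self.ute2,
                          self.activity, self.background_roi, self.exclusion_mask)
        if np.any(self.background_roi.data & (self.labels.data == TUMOR)):
            raise ValueError("background ROI overlaps the tumor")

    @property
    def seed(self) -> int:
        return self.spec.seed

    def tumor_mask(self) -> np.ndarray:
        return self.labels.data == TUMOR

    def head_mask(self) -> np.ndarray:
        return self.labels.data != BG_AIR


def _grid_mm(spec: PhantomSpec):
    """Voxel-center coordinates in mm relative to the grid center, per axis."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * spec.voxel_mm
        for n in spec.grid_shape
    ]


def _ellipsoid(coords, center, semi) -> np.ndarray:
    z, y, x = coords
    zz = ((z - center[0]) / semi[0]) ** 2
    yy = ((y - center[1]) / semi[1]) ** 2
    xx = ((x - center[2]) / semi[2]) ** 2
    return (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]) <= 1.0


def build_anatomy(spec: PhantomSpec) -> Volume:
    """Deterministic tissue label map for a phantom spec.

    Concentric ellipsoids: soft scalp shell, skull of the requested thickness,
    brain; optional internal-air structures; a spherical tumor that must sit
    entirely inside the brain.
    """
    coords = _grid_mm(spec)
    half_extent = np.array([n * spec.voxel_mm / 2.0 for n in spec.grid_shape])
    outer = HEAD_FRACTION * half_extent          # scalp surface
    skull_out = outer - SCALP_THICKNESS_MM
    skull_in = skull_out - spec.skull_mm
    if np.any(skull_in <= 2 * spec.voxel_mm):
        raise ValueError("grid too small for scalp+skull at this voxel size")

    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    labels[_ellipsoid(coords, (0, 0, 0), outer)] = SOFT
    in_skull_out = _ellipsoid(coords, (0, 0, 0), skull_out)
    in_skull_in = _ellipsoid(coords, (0, 0, 0), skull_in)
    labels[in_skull_out & ~in_skull_in] = BONE
    labels[in_skull_in] = BRAIN

    brain_semi = skull_in
    if spec.air_nasal:
        c = (-0.45 * brain_semi[0], 0.55 * brain_semi[1], 0.0)
        s = (0.18 * brain_semi[0], 0.18 * brain_semi[1], 0.18 * brain_semi[2])
        labels[_ellipsoid(coords, c, s) & (labels == BRAIN)] = INT_AIR
    if spec.air_mastoid:
        r = 0.13 * min(brain_semi)
        for side in (-1.0, 1.0):
            c = (-0.3 * brain_semi[0], -0.55 * brain_semi[1], side * 0.6 * brain_semi[2])
            labels[_ellipsoid(coords, c, (r, r, r)) & (labels == BRAIN)] = INT_AIR
    if spec.air_pocket:
        r = 0.12 * min(brain_semi)
        c = (0.3 * brain_semi[0], 0.4 * brain_semi[1], -0.35 * brain_semi[2])
        labels[_ellipsoid(coords, c, (r, r, r)) & (labels == BRAIN)] = INT_AIR

    rt = spec.tumor_radius_mm
    tumor = _ellipsoid(coords, spec.tumor_center_mm, (rt, rt, rt))
    if not tumor.any():
        raise ValueError("tumor sphere contains no voxels at this resolution")
    if np.any(tumor & ~in_skull_in):
        raise ValueError(
            "tumor extends outside the brain; shrink tumor_radius_mm or move "
            "tumor_center_mm")
    labels[tumor & (labels == BRAIN)] = TUMOR
    # a tumor overlapping a carved air cavity would change its size silently
    if np.any(tumor & (labels == INT_AIR)):
        raise ValueError("tumor overlaps an internal air cavity")

    return Volume(labels, (spec.voxel_mm,) * 3, units="label")


def _bone_density_field(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Smooth mineral-density fraction f in [0.3, 1] over bone voxels.

    The field is anatomy-level (seeded independently of exam noise) so that
    repeat examinations of a subject share the same skull.
    """
    rng = substream(spec.seed, "bone-density")
    white = rng.standard_normal(labels.shape)
    smooth = gaussian_filter(white, sigma=2.0)
    sd = smooth.std()
    g = np.tanh(smooth / sd) if sd > 0 else np.zeros_like(smooth)
    lo, hi = BONE_DENSITY_RANGE
    mid, span = (lo + hi) / 2.0, (hi - lo) / 2.0
    return np.clip(mid + span * g, lo, hi)


def synthesize_signals(labels: Volume, spec: PhantomSpec,
                       exam_index: int = 0) -> tuple[Volume, Volume, Volume]:
    """CT (HU) and dual-echo UTE magnitudes for a label map.

    Echo signals follow S(TE) = S0 * exp(-TE * R2*) with additive Gaussian
    noise of sd ``noise_sigma * S0_soft`` (clipped at zero, magnitudes being
    non-negative).  Bone S0 is low and its R2*/HU co-vary with a smooth
    density field, giving the monotone R2*->HU relation that segmentation AC
    calibrates.  CT noise scales with the same noise_sigma.
    """
    if spec.noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    lab = labels.data
    s0 = np.zeros(lab.shape)
    r2 = np.zeros(lab.shape)
    hu = np.full(lab.shape, -1000.0)
    for code, (s0v, r2v, huv) in TISSUE_SIGNALS.items():
        m = lab == code
        s0[m], r2[m], hu[m] = s0v, r2v, huv

    bone = lab == BONE
    if bone.any():
        f = _bone_density_field(lab, spec)[bone]
        s0[bone] = BONE_S0
        r2[bone] = BONE_R2_BASE + BONE_R2_SPAN * f
        hu[bone] = spec.peak_hu * f

    te1_s, te2_s = TE1_MS * 1e-3, TE2_MS * 1e-3
    e1 = s0 * np.exp(-te1_s * r2)
    e2 = s0 * np.exp(-te2_s * r2)

    if spec.noise_sigma > 0:
        rng = substream(spec.seed, "exam-noise", exam_index)
        sd = spec.noise_sigma * TISSUE_SIGNALS[SOFT][0]
        e1 = np.clip(e1 + rng.normal(0.0, sd, lab.shape), 0.0, None)
        e2 = np.clip(e2 + rng.normal(0.0, sd, lab.shape), 0.0, None)
        hu = hu + rng.normal(0.0, 400.0 * spec.noise_sigma, lab.shape)
    hu = np.clip(hu, -1000.0, 3000.0)

    meta = {"te1_ms": TE1_MS, "te2_ms": TE2_MS}
    sp = (spec.voxel_mm,) * 3
    return (Volume(hu, sp, units="HU"),
            Volume(e1, sp, units="a.u.", meta=dict(meta)),
            Volume(e2, sp, units="a.u.", meta=dict(meta)))


def synthesize_activity(labels: Volume, spec: PhantomSpec,
                        exam_index: int = 0) -> tuple[Volume, Volume, Volume]:
    """Tracer activity map plus background ROI and exclusion mask.

    Background (brain) uptake is ~1 a.u. with mild smooth heterogeneity;
    the tumor peaks at ``ratio`` times the nominal background with an
    internal center-to-rim gradient; an optional extratumoral hot spot
    (e.g. a vascular structure) is covered by the exclusion mask.  The
    background ROI is a small box mirrored left-right from the tumor center.
    """
    if spec.tumor_to_background_ratio <= 1.6:
        warnings.warn("sub-threshold tumor: tumor_to_background_ratio <= 1.6; "
                      "the auto-contour will not detect it", stacklevel=2)
    lab = labels.data
    act = np.zeros(lab.shape)
    act[lab == SOFT] = 0.25
    act[lab == BONE] = 0.05
    act[(lab == BRAIN) | (lab == TUMOR)] = 1.0

    coords = _grid_mm(spec)
    z, y, x = np.meshgrid(*coords, indexing="ij")
    tumor = lab == TUMOR
    if tumor.any():
        cz, cy, cx = spec.tumor_center_mm
        r = np.sqrt((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2)
        # center-to-rim gradient: peak ratio at center, 85% of peak at the rim;
        # rescaled so the voxelwise maximum is exactly ratio x background
        prof = 0.85 + 0.15 * np.clip(1.0 - r / spec.tumor_radius_mm, 0.0, 1.0)
        tprof = prof[tumor]
        act[tumor] = spec.tumor_to_background_ratio * tprof / tprof.max()

    exclusion = np.zeros(lab.shape, dtype=bool)
    if spec.hot_spot:
        # superficial hot structure in scalp tissue, opposite-anterior quadrant
        half_extent = np.array([n * spec.voxel_mm / 2.0 for n in spec.grid_shape])
        outer = HEAD_FRACTION * half_extent
        c = (0.0, 0.75 * outer[1], -0.5 * outer[2])
        spot = _ellipsoid(coords, c, (6.0, 6.0, 6.0)) & (lab == SOFT)
        act[spot] = 2.2
        exclusion |= spot

    if spec.noise_sigma > 0:
        rng = substream(spec.seed, "activity-noise", exam_index)
        hetero = gaussian_filter(rng.standard_normal(lab.shape), sigma=3.0)
        sd = hetero.std()
        if sd > 0:
            brainish = (lab == BRAIN) | (lab == TUMOR)
            act[brainish] *= 1.0 + 2.0 * spec.noise_sigma * (hetero[brainish] / sd)
        act = np.clip(act + rng.normal(0.0, spec.noise_sigma, lab.shape), 0.0, None)

    # mirrored background ROI: reflect the tumor center across the midline
    cz, cy, cx = spec.tumor_center_mm
    mirror = (cz, cy, -cx) if abs(cx) > 1e-9 else (cz, -cy, cx)
    half = 6.0  # mm box half-width
    zb = np.abs(coords[0] - mirror[0]) <= half
    yb = np.abs(coords[1] - mirror[1]) <= half
    xb = np.abs(coords[2] - mirror[2]) <= half
    roi = (zb[:, None, None] & yb[None, :, None] & xb[None, None, :]) & (lab == BRAIN)
    if not roi.any():
        raise ValueError("mirrored background ROI is empty; adjust tumor position")
    if np.any(roi & tumor):
        raise ValueError("background ROI overlaps tumor")

    sp = (spec.voxel_mm,) * 3
    return (Volume(act, sp, units="a.u."),
            Volume(roi, sp, units="mask"),
            Volume(exclusion, sp, units="mask"))


def generate_case(spec: PhantomSpec, subject_id: str = "sub-000",
                  exam_index: int = 0) -> PhantomCase:
    """Build one complete examination from a spec.

    Repeat exams (``exam_index`` > 0) share the anatomy and skull density of
    the subject but redraw all measurement noise.
    """
    labels = build_anatomy(spec)
    ct, e1, e2 = synthesize_signals(labels, spec, exam_index=exam_index)
    act, roi, excl = synthesize_activity(labels, spec, exam_index=exam_index)
    return PhantomCase(labels, ct, e1, e2, act, roi, excl, spec,
                       subject_id=subject_id, exam_index=exam_index)


def generate_battery(n_subjects: int, seed: int, scale: str = "micro",
                     repeat_every: int = 0, **spec_overrides) -> list[PhantomCase]:
    """A battery of subjects with varied age, anatomy and tumor geometry.

    ``repeat_every``: every k-th subject additionally gets a second exam
    (same anatomy, fresh noise), emulating follow-up scans; 0 disables.
    """
    maker = {"micro": PhantomSpec.micro, "desk": PhantomSpec.desk,
             "full": PhantomSpec.full}[scale]
    rng = substream(seed, "battery")
    # micro voxels are 3 mm, so stay in brackets whose skull is >= 1 voxel
    ages = AGE_CLASSES[3:] if scale == "micro" else AGE_CLASSES
    cases = []
    for i in range(n_subjects):
        jitter = rng.uniform(-3.0, 3.0, size=2)
        kw = dict(
            age_class=ages[i % len(ages)],
            tumor_center_mm=(0.0, -8.0 + jitter[0], 10.0 + jitter[1]),
            tumor_radius_mm=float(rng.uniform(6.5, 9.5)),
            air_nasal=bool(i % 2), air_mastoid=bool(i % 3 == 0),
            hot_spot=bool(i % 4 == 0),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        kw.update(spec_overrides)
        spec = maker(**kw)
        sid = f"sub-{i:03d}"
        cases.append(generate_case(spec, subject_id=sid, exam_index=0))
        if repeat_every and i % repeat_every == 0:
            cases.append(generate_case(spec, subject_id=sid, exam_index=1))
    return cases
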
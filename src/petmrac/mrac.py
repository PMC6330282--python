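"""Core scalar transforms shared by all attenuation-correction methods.

* R2* mapping from dual-echo UTE magnitudes,
* the bilinear Hounsfield-unit -> 511 keV linear-attenuation conversion,
* three-class tissue labelling of a CT-like volume (air / soft / bone),
* field-of-view stitching of two attenuation maps.

R2* (= 1/T2*, in s^-1) is the apparent transverse relaxation rate.  Cortical
bone decays so fast that it is dark at conventional echo times but still
visible at an ultrashort first echo; the two-point estimate

    R2* = ln(S1/S2) / (TE2 - TE1)

is therefore the package's bone-density surrogate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume, require_same_grid

__all__ = [
    "MU_WATER_511", "K_BONE_511", "R2StarMap", "MuMap",
    "compute_r2star", "hu_to_mu", "classify_tissue", "stitch_fov",
]

#: water linear attenuation coefficient at 511 keV, cm^-1
MU_WATER_511 = 0.096
#: HU -> mu slope above water, cm^-1 per HU
K_BONE_511 = 5.1e-5

#: default 3-class thresholds on the HU scale
AIR_HU_THRESHOLD = -500.0
BONE_HU_THRESHOLD = 300.0

#: physically plausible ceiling for mu at 511 keV (dense cortical bone ~0.17)
MU_MAX = 0.25

R2STAR_CLAMP_MAX = 3000.0  # s^-1; above this the two-point estimate is noise


@dataclass
class R2StarMap:
    """Apparent transverse relaxation rates in s^-1, clamped to [0, clamp_max]."""
    volume: Volume
    clamp_max: float = R2STAR_CLAMP_MAX


@dataclass
class MuMap:
    """511 keV linear attenuation coefficients (cm^-1) with provenance."""
    volume: Volume
    provenance: str  # CT | RESOLUTE | DEEPUTE | NOBONE | composites

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("MuMap requires a provenance tag")


def compute_r2star(ute1: Volume, ute2: Volume, te1_ms: float, te2_ms: float,
                   clamp_max: float = R2STAR_CLAMP_MAX,
                   eps_frac: float = 1e-6) -> R2StarMap:
    """Two-point R2* estimate from dual-echo magnitudes.

    Voxels where either echo is at/below the signal floor, or where the
    estimate comes out negative (noise making S2 > S1), are set to 0;
    estimates above ``clamp_max`` are clamped.

    Parameters
    ----------
    te1_ms, te2_ms : float
        Echo times in milliseconds; must satisfy 0 < te1 < te2.
    eps_frac : float
        Signal floor as a fraction of the maximum first-echo signal.
    """
    require_same_grid(ute1, ute2)
    if not (0 < te1_ms < te2_ms):
        raise ValueError(f"need 0 < te1 < te2, got {te1_ms}, {te2_ms}")
    s1 = np.asarray(ute1.data, dtype=np.float64)
    s2 = np.asarray(ute2.data, dtype=np.float64)
    dte_s = (te2_ms - te1_ms) * 1e-3
    eps = eps_frac * float(np.max(s1, initial=0.0))
    valid = (s1 > eps) & (s2 > eps)
    r2 = np.zeros_like(s1)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.log(s1[valid] / s2[valid]) / dte_s
    r2[valid] = est
    np.clip(r2, 0.0, clamp_max, out=r2)
    r2[~np.isfinite(r2)] = 0.0
    return R2StarMap(ute1.like(r2, units="s^-1"), clamp_max=clamp_max)


def hu_to_mu(ct: Volume, mu_water: float = MU_WATER_511,
             k_bone: float = K_BONE_511) -> MuMap:
    """Bilinear HU -> 511 keV mu conversion.

    mu = mu_water * (HU + 1000) / 1000          for HU <= 0
    mu = mu_water + k_bone * HU                 for HU >  0

    Continuous and monotone at the water breakpoint; negative results
    (HU < -1000) clamp to 0.
    """
    hu = np.asarray(ct.data, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite HU values in CT input")
    mu = np.where(hu <= 0.0, mu_water * (hu + 1000.0) / 1000.0,
                  mu_water + k_bone * hu)
    np.clip(mu, 0.0, None, out=mu)
    return MuMap(ct.like(mu, units="cm^-1"), provenance="CT")


def classify_tissue(ct_like: Volume, air_hu: float = AIR_HU_THRESHOLD,
                    bone_hu: float = BONE_HU_THRESHOLD) -> Volume:
    """Threshold a CT-like volume into air (0) / soft (1) / bone (2).

    Used to score pseudo-CTs against the reference CT class-by-class.
    """
    hu = np.asarray(ct_like.data, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite HU values")
    labels = np.ones(hu.shape, dtype=np.int8)
    labels[hu < air_hu] = 0
    labels[hu > bone_hu] = 2
    return ct_like.like(labels, units="class")


def stitch_fov(primary: MuMap, fallback: MuMap, fov_mask: Volume) -> MuMap:
    """Compose a mu-map: ``primary`` inside the field-of-view, ``fallback`` outside.

    Mirrors the clinical practice of padding a head-CT-derived map with the
    whole-body MR-derived map beyond the CT axial coverage.
    """
    require_same_grid(primary.volume, fallback.volume, fov_mask)
    mask = np.asarray(fov_mask.data, dtype=bool)
    out = np.where(mask, primary.volume.data, fallback.volume.data)
    return MuMap(primary.volume.like(out),
                 provenance=f"{primary.provenance}+{fallback.provenance}")
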
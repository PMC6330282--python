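"""Segmentation-based continuous-bone attenuation correction.

UTE voxels are classified into air / soft tissue / candidate bone, and bone
voxels get a continuous pseudo-HU through a sigmoid mapping of their R2*
value.  The sigmoid is calibrated against co-registered reference CTs of
*other* subjects (subject-level cross-validation), because a mapping fitted
and evaluated on the same subject would flatter itself.

Also provides the bone-less two-class baseline (air/soft only) that emulates
vendor fat/water AC maps, which famously lack bone.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_erosion, binary_fill_holes
from scipy.optimize import curve_fit

from .folds import FoldSplit, kfold_split
from .mrac import BONE_HU_THRESHOLD, MuMap, compute_r2star, hu_to_mu
from .phantom import TE1_MS, TE2_MS, PhantomCase

__all__ = [
    "SigmoidParams", "sigmoid", "calibrate_bone_sigmoid",
    "build_resolute_map", "build_nobone_map", "resolute_crossval",
]

SOFT_TISSUE_HU = 30.0
#: default R2* cut separating soft tissue (~tens of s^-1, incl. the noise
#: floor of the two-point estimate) from candidate cortical bone (>~400 s^-1)
BONE_R2_THRESHOLD = 300.0
AIR_FLOOR_FRACTION = 0.05   # of the median in-head first-echo signal
SHELL_DEPTH_MM = 15.0       # outer head band searched for bone
MIN_BONE_SAMPLES = 100


@dataclass(frozen=True)
class SigmoidParams:
    """HU(r) = L + (U - L) / (1 + exp(-k (r - r0))).

    L, U are the lower/upper HU asymptotes, r0 the inflection R2* (s^-1),
    k the steepness (s).  rmse/n are fit diagnostics.
    """

    L: float
    U: float
    r0: float
    k: float
    rmse: float = float("nan")
    n: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.L) and np.isfinite(self.U)
                and np.isfinite(self.r0) and np.isfinite(self.k)):
            raise ValueError("sigmoid parameters must be finite")
        if self.U <= self.L:
            raise ValueError(f"need U > L, got L={self.L}, U={self.U}")
        if self.k <= 0:
            raise ValueError(f"need k > 0, got k={self.k}")


def sigmoid(r, p: SigmoidParams):
    r = np.asarray(r, dtype=np.float64)
    return p.L + (p.U - p.L) / (1.0 + np.exp(-p.k * (r - p.r0)))


def _sigmoid_fn(r, L, U, r0, k):
    return L + (U - L) / (1.0 + np.exp(-k * (r - r0)))


def fit_sigmoid(r: np.ndarray, hu: np.ndarray) -> SigmoidParams:
    """Nonlinear least squares fit of the R2*->HU sigmoid.

    Initialization: L=0, U=95th percentile HU, r0=median r, k=1/IQR(r).
    """
    r = np.asarray(r, dtype=np.float64)
    hu = np.asarray(hu, dtype=np.float64)
    if r.size < MIN_BONE_SAMPLES:
        raise ValueError(f"only {r.size} bone samples; need >= {MIN_BONE_SAMPLES}")
    q25, q75 = np.percentile(r, [25, 75])
    iqr = max(q75 - q25, 1e-6)
    p0 = [0.0, float(np.percentile(hu, 95)), float(np.median(r)), 1.0 / iqr]
    lo = [-1000.0, 0.0, 0.0, 1e-6]
    hi = [1000.0, 4000.0, 5000.0, 1.0]
    try:
        popt, _ = curve_fit(_sigmoid_fn, r, hu, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise RuntimeError(
            f"sigmoid calibration did not converge (n={r.size}, "
            f"r range [{r.min():.1f}, {r.max():.1f}] s^-1): {exc}") from exc
    resid = hu - _sigmoid_fn(r, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return SigmoidParams(*map(float, popt), rmse=rmse, n=int(r.size))


def calibrate_bone_sigmoid(cases: Sequence[PhantomCase], folds: FoldSplit,
                           max_samples: int = 20000,
                           seed: int = 0) -> Dict[int, SigmoidParams]:
    """Per-fold sigmoid calibration on pooled bone (R2*, HU) pairs.

    For each fold the fit uses only subjects *outside* the fold, so the
    mapping applied to a subject never saw that subject's own CT.
    Bone voxels are taken from the reference CT (HU > 300).
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to calibrate across folds")
    out: Dict[int, SigmoidParams] = {}
    for fold in range(folds.k):
        train_ids = set(folds.train_subjects(fold))
        rs, hus = [], []
        for case in cases:
            if case.subject_id not in train_ids:
                continue
            r2 = compute_r2star(case.ute1, case.ute2, TE1_MS, TE2_MS).volume.data
            bone = case.ct_hu.data > BONE_HU_THRESHOLD
            rs.append(r2[bone])
            hus.append(case.ct_hu.data[bone])
        r = np.concatenate(rs) if rs else np.empty(0)
        hu = np.concatenate(hus) if hus else np.empty(0)
        if r.size > max_samples:
            idx = np.random.default_rng(seed + fold).choice(r.size, max_samples,
                                                            replace=False)
            r, hu = r[idx], hu[idx]
        out[fold] = fit_sigmoid(r, hu)
    return out


def _signal_floor(ute1: np.ndarray) -> float:
    """Air/tissue signal floor: 5% of the median in-head first-echo signal."""
    strong = ute1 > 0.1 * float(ute1.max(initial=0.0))
    if not strong.any():
        return 0.0
    return AIR_FLOOR_FRACTION * float(np.median(ute1[strong]))


def _segment_air_soft(case: PhantomCase):
    """Shared UTE segmentation: air mask, filled head mask, outer shell band."""
    e1 = case.ute1.data
    e2 = case.ute2.data
    floor = _signal_floor(e1)
    tissue = (e1 > floor) | (e2 > floor)
    head = binary_fill_holes(tissue)
    air = (e1 <= floor) & (e2 <= floor)  # air only where no echo has signal
    depth_vox = max(1, int(round(SHELL_DEPTH_MM / case.ute1.voxel_mm[0])))
    interior = binary_erosion(head, iterations=depth_vox)
    shell = head & ~interior
    return air, head, shell


def build_resolute_map(case: PhantomCase, params: SigmoidParams,
                       bone_r2_threshold: Optional[float] = None,
                       soft_hu: float = SOFT_TISSUE_HU):
    """Continuous-bone pseudo-CT and mu-map from UTE echoes.

    Voxels with no signal in either echo are air (-1000 HU); high-R2* voxels
    inside the outer-head shell band become bone and receive sigmoid(R2*);
    everything else in the head is soft tissue.  The shell band stands in for
    the anatomical regional masks used on real patients: bone is only
    credible near the head surface, which suppresses R2* noise elsewhere.

    Returns (MuMap, pseudo_ct Volume).
    """
    if bone_r2_threshold is None:
        bone_r2_threshold = BONE_R2_THRESHOLD
    r2 = compute_r2star(case.ute1, case.ute2, TE1_MS, TE2_MS).volume.data
    air, head, shell = _segment_air_soft(case)

    pct = np.full(case.ute1.shape, -1000.0)
    soft_mask = head & ~air
    pct[soft_mask] = soft_hu
    bone_mask = soft_mask & shell & (r2 > bone_r2_threshold)
    pct[bone_mask] = np.clip(sigmoid(r2[bone_mask], params), params.L, params.U)

    pct_vol = case.ute1.like(pct, units="HU")
    mu = hu_to_mu(pct_vol)
    return MuMap(mu.volume, provenance="RESOLUTE"), pct_vol


def build_nobone_map(case: PhantomCase, soft_hu: float = SOFT_TISSUE_HU):
    """Two-class (air/soft) baseline mu-map emulating fat/water vendor AC.

    Bone voxels are absorbed into soft tissue, reproducing the systematic
    under-attenuation of bone-less MR-AC.  Returns (MuMap, pseudo_ct Volume).
    """
    air, head, _ = _segment_air_soft(case)
    pct = np.full(case.ute1.shape, -1000.0)
    pct[head & ~air] = soft_hu
    pct_vol = case.ute1.like(pct, units="HU")
    mu = hu_to_mu(pct_vol)
    return MuMap(mu.volume, provenance="NOBONE"), pct_vol


def resolute_crossval(cases: Sequence[PhantomCase], k: int = 2, seed: int = 0):
    """Calibrate with k folds and apply each case's out-of-fold parameters.

    Returns (results, params) where results maps (subject_id, exam_index) ->
    (MuMap, pseudo_ct) and params maps fold -> SigmoidParams.
    """
    folds = kfold_split(cases, k=k, seed=seed)
    params = calibrate_bone_sigmoid(cases, folds, seed=seed)
    results = {}
    for case in cases:
        fold = folds.fold_of(case.subject_id)
        results[(case.subject_id, case.exam_index)] = build_resolute_map(
            case, params[fold])
    return results, params
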
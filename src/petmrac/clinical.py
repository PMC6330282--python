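"""Clinical read-outs: background, BTV auto-contour, T/B ratios, overlap.

These are the diagnostic quantities a reader uses on amino-acid-tracer brain
PET: the mean uptake B in a healthy contralateral background ROI, the
biological tumor volume BTV (all voxels strictly above 1.6 x B, minus
explicitly excluded extratumoral hot structures), the tumor mean/max uptake
and their ratios to B, and per-metric acceptance limits mixing an absolute
and a relative cut-off (a large or very avid tumor tolerates a larger
absolute change).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import numpy as np

from .volume import Volume, require_same_grid

__all__ = [
    "BTV_THRESHOLD_MULTIPLIER", "Delineation", "MetricsRecord", "AcceptanceRule",
    "DEFAULT_RULES", "background_mean", "delineate_btv", "tumor_metrics",
    "jaccard", "acceptance_check", "cohort_filter", "evaluate_activity",
]

BTV_THRESHOLD_MULTIPLIER = 1.6
MIN_COHORT_BTV_ML = 1.0


@dataclass
class Delineation:
    tumor_mask: Volume        # bool
    btv_ml: float
    threshold_used: float     # absolute activity cut (multiplier * B)
    background_mean: float


@dataclass
class MetricsRecord:
    """Per-exam clinical metrics under one AC method."""

    b: float
    t_mean: float
    t_max: float
    tmean_b: float
    tmax_b: float
    btv_ml: float
    ac_method: str
    subject_id: str
    exam_index: int = 0
    valid: bool = True        # False when the tumor was completely missed

    def metric(self, name: str) -> float:
        return {"tmean_b": self.tmean_b, "tmax_b": self.tmax_b,
                "btv_ml": self.btv_ml}[name]


@dataclass(frozen=True)
class AcceptanceRule:
    """Pass iff |delta| <= abs_limit OR |delta|/ref <= rel_limit_pct."""

    metric: str
    abs_limit: float
    rel_limit_pct: float

    def __post_init__(self):
        if self.abs_limit <= 0 or self.rel_limit_pct <= 0:
            raise ValueError("acceptance limits must be positive")


DEFAULT_RULES: Dict[str, AcceptanceRule] = {
    "tmean_b": AcceptanceRule("tmean_b", 0.05, 5.0),
    "tmax_b": AcceptanceRule("tmax_b", 0.10, 5.0),
    "btv_ml": AcceptanceRule("btv_ml", 2.0, 10.0),
}


def background_mean(activity: Volume, roi: Volume) -> float:
    """Arithmetic mean of activity over the background ROI."""
    require_same_grid(activity, roi)
    mask = np.asarray(roi.data, dtype=bool)
    if not mask.any():
        raise ValueError("background ROI is empty")
    return float(activity.data[mask].mean())


def delineate_btv(activity: Volume, b: float,
                  exclusion_mask: Optional[Volume] = None,
                  multiplier: float = BTV_THRESHOLD_MULTIPLIER) -> Delineation:
    """3D auto-contour: voxels strictly above multiplier * B.

    Voxels inside the exclusion mask (extratumoral hot structures such as
    vessels or skin) never count toward the tumor.
    """
    if b <= 0:
        raise ValueError("background mean must be positive")
    threshold = multiplier * b
    mask = activity.data > threshold
    if exclusion_mask is not None:
        require_same_grid(activity, exclusion_mask)
        mask &= ~np.asarray(exclusion_mask.data, dtype=bool)
    btv_ml = float(mask.sum()) * activity.voxel_volume_ml
    return Delineation(activity.like(mask, units="mask"), btv_ml, threshold, b)


def tumor_metrics(activity: Volume, delin: Delineation, b: float,
                  ac_method: str = "", subject_id: str = "",
                  exam_index: int = 0) -> MetricsRecord:
    """Tumor mean/max and their ratios to background.

    An empty delineation (tumor completely missed under this AC method)
    yields a flagged record with NaN tumor statistics; flagged records are
    excluded from ratio summaries downstream.
    """
    mask = np.asarray(delin.tumor_mask.data, dtype=bool)
    if b <= 0:
        raise ValueError("background mean must be positive")
    if not mask.any():
        return MetricsRecord(b, math.nan, math.nan, math.nan, math.nan,
                             0.0, ac_method, subject_id, exam_index, valid=False)
    vals = activity.data[mask]
    t_mean = float(vals.mean())
    t_max = float(vals.max())
    return MetricsRecord(b, t_mean, t_max, t_mean / b, t_max / b,
                         delin.btv_ml, ac_method, subject_id, exam_index)


def jaccard(mask_a: Volume | np.ndarray, mask_b: Volume | np.ndarray) -> float:
    """|A intersect B| / |A union B|; 1.0 when both masks are empty."""
    a = np.asarray(mask_a.data if isinstance(mask_a, Volume) else mask_a, dtype=bool)
    b = np.asarray(mask_b.data if isinstance(mask_b, Volume) else mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def acceptance_check(test: MetricsRecord, ref: MetricsRecord,
                     rules: Mapping[str, AcceptanceRule] = DEFAULT_RULES
                     ) -> Dict[str, bool]:
    """Per-metric pass/fail of a test record against its CT-AC reference.

    A metric passes iff the absolute difference is within the absolute limit
    OR the relative difference is within the relative limit.  With a zero
    reference the relative term is undefined and only the absolute limit
    applies.
    """
    if (test.subject_id, test.exam_index) != (ref.subject_id, ref.exam_index):
        raise ValueError("test and reference records are from different exams")
    out = {}
    for name, rule in rules.items():
        t, r = test.metric(name), ref.metric(name)
        delta = abs(t - r)
        ok = delta <= rule.abs_limit
        if not ok and r != 0:
            ok = delta / abs(r) <= rule.rel_limit_pct / 100.0
        out[name] = bool(ok)
    return out


def cohort_filter(ref_records: Iterable[MetricsRecord],
                  min_btv_ml: float = MIN_COHORT_BTV_ML) -> list[MetricsRecord]:
    """Keep exams whose reference (CT-AC) BTV exceeds the inclusion minimum."""
    return [r for r in ref_records if r.btv_ml > min_btv_ml]


def evaluate_activity(activity: Volume, background_roi: Volume,
                      exclusion_mask: Optional[Volume], ac_method: str,
                      subject_id: str, exam_index: int = 0
                      ) -> tuple[MetricsRecord, Delineation]:
    """Background -> delineation -> metrics for one reconstructed exam."""
    b = background_mean(activity, background_roi)
    delin = delineate_btv(activity, b, exclusion_mask)
    rec = tumor_metrics(activity, delin, b, ac_method, subject_id, exam_index)
    return rec, delin
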
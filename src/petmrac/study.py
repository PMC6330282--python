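"""End-to-end study driver.

Chains phantom generation -> attenuation-map construction (reference CT,
bone-less baseline, segmentation AC with 2-fold calibration, CNN AC with
subject-level cross-validation) -> per-slice PET simulation under the true
mu-map -> reconstruction with each candidate mu-map -> clinical metrics and
cohort agreement statistics, and writes deterministic CSV reports.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .agreement import agreement_report, bland_altman_table, pairs_table
from .clinical import MetricsRecord, cohort_filter, evaluate_activity, jaccard
from .deepute import NetworkSpec, TrainConfig, deepute_crossval
from .mrac import MuMap, hu_to_mu, stitch_fov
from .petsim import project_emission, reconstruct_with_ac
from .phantom import PhantomCase, generate_battery, substream
from .resolute import build_nobone_map, resolute_crossval
from .volume import Volume

__all__ = ["StudyConfig", "StudyResult", "run_study"]

VALID_METHODS = ("ct", "nobone", "resolute", "deepute")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one phantom study."""

    n_subjects: int = 6
    scale: str = "micro"                    # micro | desk | full
    methods: Tuple[str, ...] = VALID_METHODS
    resolute_folds: int = 2
    deepute_folds: int = 4
    deepute_epochs: Optional[int] = None    # None -> scale default
    repeat_every: int = 3                   # every k-th subject gets a 2nd exam
    n_angles: int = 180
    reduced_ct_fov: bool = False            # truncate CT coverage, stitch baseline
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self):
        bad = set(self.methods) - set(VALID_METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")
        if "ct" not in self.methods:
            raise ValueError("the reference method 'ct' is required")
        if self.scale not in ("micro", "desk", "full"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.n_subjects < max(self.resolute_folds, 2):
            raise ValueError("need at least as many subjects as folds")


@dataclass
class StudyResult:
    config: StudyConfig
    cases: list
    mu_maps: Dict[Tuple[str, int, str], MuMap]      # (subject, exam, method)
    recons: Dict[Tuple[str, int, str], Volume]
    records: list                                    # MetricsRecord
    tumor_jaccard: pd.DataFrame
    pairs: pd.DataFrame
    summary: pd.DataFrame
    flags: pd.DataFrame


def _method_tag(m: str) -> str:
    return m.upper()


def _net_spec(scale: str) -> NetworkSpec:
    if scale == "micro":
        return NetworkSpec.micro()
    return NetworkSpec()


def _train_cfg(cfg: StudyConfig) -> TrainConfig:
    if cfg.scale == "micro":
        return TrainConfig.micro(epochs=cfg.deepute_epochs or 10, seed=cfg.seed)
    return TrainConfig(epochs=cfg.deepute_epochs or 100, seed=cfg.seed)


def run_study(cfg: StudyConfig) -> StudyResult:
    seeds = {name: int(substream(cfg.seed, "study", name).integers(2 ** 31))
             for name in ("battery", "resolute", "deepute", "petsim")}
    cases: list[PhantomCase] = generate_battery(
        cfg.n_subjects, seed=seeds["battery"], scale=cfg.scale,
        repeat_every=cfg.repeat_every)
    key = lambda c: (c.subject_id, c.exam_index)  # noqa: E731

    # --- attenuation maps per method -------------------------------------
    mu_maps: Dict[Tuple[str, int, str], MuMap] = {}
    for c in cases:
        mu_maps[key(c) + ("CT",)] = MuMap(hu_to_mu(c.ct_hu).volume, "CT")
    if "nobone" in cfg.methods or cfg.reduced_ct_fov:
        for c in cases:
            mu, _ = build_nobone_map(c)
            mu_maps[key(c) + ("NOBONE",)] = mu
    if "resolute" in cfg.methods:
        res, _params = resolute_crossval(cases, k=cfg.resolute_folds,
                                         seed=seeds["resolute"])
        for k_, (mu, _pct) in res.items():
            mu_maps[k_ + ("RESOLUTE",)] = mu
    if "deepute" in cfg.methods:
        res, _hist = deepute_crossval(cases, k=cfg.deepute_folds,
                                      net_spec=_net_spec(cfg.scale),
                                      cfg=_train_cfg(cfg), seed=seeds["deepute"])
        for k_, (mu, _pct) in res.items():
            mu_maps[k_ + ("DEEPUTE",)] = mu

    if cfg.reduced_ct_fov:
        # emulate CT axial coverage ending above the lowest slices: every
        # method's map falls back to the bone-less baseline outside the FOV
        for c in cases:
            d = c.ct_hu.shape[0]
            fov = np.ones(c.ct_hu.shape, dtype=bool)
            fov[: d // 5] = False
            fov_vol = Volume(fov, c.ct_hu.voxel_mm, "mask")
            fallback = mu_maps[key(c) + ("NOBONE",)]
            for m in cfg.methods:
                tag = _method_tag(m)
                k_ = key(c) + (tag,)
                if k_ in mu_maps and tag != "NOBONE":
                    mu_maps[k_] = stitch_fov(mu_maps[k_], fallback, fov_vol)

    # --- PET simulation ----------------------------------------------------
    angles = np.linspace(0.0, 180.0, cfg.n_angles, endpoint=False)
    recons: Dict[Tuple[str, int, str], Volume] = {}
    for c in cases:
        sino = project_emission(c.activity, mu_maps[key(c) + ("CT",)], angles)
        for m in cfg.methods:
            tag = _method_tag(m)
            recons[key(c) + (tag,)] = reconstruct_with_ac(
                sino, mu_maps[key(c) + (tag,)])

    # --- clinical metrics ----------------------------------------------------
    records: list[MetricsRecord] = []
    delins: Dict[Tuple[str, int, str], Volume] = {}
    for c in cases:
        for m in cfg.methods:
            tag = _method_tag(m)
            rec, delin = evaluate_activity(
                recons[key(c) + (tag,)], c.background_roi, c.exclusion_mask,
                tag, c.subject_id, c.exam_index)
            records.append(rec)
            delins[key(c) + (tag,)] = delin.tumor_mask

    # cohort inclusion: reference BTV above 1 mL
    ct_records = [r for r in records if r.ac_method == "CT"]
    included = {(r.subject_id, r.exam_index) for r in cohort_filter(ct_records)}
    records = [r for r in records if (r.subject_id, r.exam_index) in included]

    jrows = []
    for c in cases:
        if key(c) not in included:
            continue
        ref_mask = delins[key(c) + ("CT",)]
        for m in cfg.methods:
            if m == "ct":
                continue
            tag = _method_tag(m)
            jrows.append({
                "subject_id": c.subject_id, "exam_index": c.exam_index,
                "method": tag,
                "tumor_jaccard": jaccard(delins[key(c) + (tag,)], ref_mask)})
    tumor_j = pd.DataFrame(jrows)

    pairs = pairs_table(records, ref_method="CT")
    summary = agreement_report(pairs)
    flags = bland_altman_table(pairs)

    result = StudyResult(cfg, cases, mu_maps, recons, records, tumor_j,
                         pairs, summary, flags)
    if cfg.out_dir:
        _write_reports(result, Path(cfg.out_dir))
    return result


def _write_reports(result: StudyResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(index=False, float_format="%.8g")
    recs = pd.DataFrame([dataclasses.asdict(r) for r in result.records])
    recs.sort_values(["subject_id", "exam_index", "ac_method"]).to_csv(
        out / "records.csv", **fmt)
    result.pairs.to_csv(out / "pairs.csv", **fmt)
    result.summary.to_csv(out / "summary.csv", **fmt)
    result.flags.to_csv(out / "flags.csv", **fmt)
    if len(result.tumor_jaccard):
        result.tumor_jaccard.to_csv(out / "tumor_jaccard.csv", **fmt)
    (out / "study.json").write_text(json.dumps(
        dataclasses.asdict(result.config), indent=2, sort_keys=True))
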
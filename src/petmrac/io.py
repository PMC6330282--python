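"""NIfTI-1 and JSON I/O for volumes, phantom cases and calibration results."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import PhantomCase, PhantomSpec
from .resolute import SigmoidParams
from .volume import Volume

__all__ = ["read_volume", "write_volume", "write_case", "read_case",
           "save_sigmoid", "load_sigmoid"]


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; int16 where lossless, else float32."""
    path = Path(path)
    data = vol.data
    as_int = np.round(data)
    if (np.all(np.isfinite(data)) and np.all(as_int == data)
            and data.min() >= -32768 and data.max() <= 32767):
        data = as_int.astype(np.int16)
    else:
        data = data.astype(np.float32)
    affine = np.diag(list(vol.voxel_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.voxel_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, units: str = "a.u.") -> Volume:
    img = nib.load(str(path))
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError(f"{path}: orientation metadata missing or invalid")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    return Volume(np.asarray(img.dataobj), tuple(float(z) for z in zooms),
                  units=units)


def _spec_to_json(spec: PhantomSpec) -> dict:
    return dataclasses.asdict(spec)


def write_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """One phantom examination as NIfTI files plus a JSON spec sidecar."""
    out = Path(out_dir) / f"{case.subject_id}_exam-{case.exam_index}"
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.labels, out / "labels.nii.gz")
    write_volume(case.ct_hu, out / "ct.nii.gz")
    write_volume(case.ute1, out / "ute1.nii.gz")
    write_volume(case.ute2, out / "ute2.nii.gz")
    write_volume(case.activity, out / "activity.nii.gz")
    write_volume(case.background_roi.like(
        case.background_roi.data.astype(np.int16)), out / "background_roi.nii.gz")
    write_volume(case.exclusion_mask.like(
        case.exclusion_mask.data.astype(np.int16)), out / "exclusion_mask.nii.gz")
    sidecar = {"spec": _spec_to_json(case.spec), "subject_id": case.subject_id,
               "exam_index": case.exam_index}
    (out / "case.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out


def read_case(case_dir: str | Path) -> PhantomCase:
    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "case.json").read_text())
    spec_kw = meta["spec"]
    spec_kw["grid_shape"] = tuple(spec_kw["grid_shape"])
    spec_kw["tumor_center_mm"] = tuple(spec_kw["tumor_center_mm"])
    spec = PhantomSpec(**spec_kw)
    rd = lambda name, u: read_volume(case_dir / name, units=u)  # noqa: E731
    return PhantomCase(
        labels=rd("labels.nii.gz", "label"),
        ct_hu=rd("ct.nii.gz", "HU"),
        ute1=rd("ute1.nii.gz", "a.u."),
        ute2=rd("ute2.nii.gz", "a.u."),
        activity=rd("activity.nii.gz", "a.u."),
        background_roi=Volume(rd("background_roi.nii.gz", "mask").data.astype(bool),
                              spec.spacing, "mask"),
        exclusion_mask=Volume(rd("exclusion_mask.nii.gz", "mask").data.astype(bool),
                              spec.spacing, "mask"),
        spec=spec, subject_id=meta["subject_id"], exam_index=meta["exam_index"])


def save_sigmoid(params: dict[int, SigmoidParams], path: str | Path) -> None:
    obj = {str(k): dataclasses.asdict(v) for k, v in params.items()}
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_sigmoid(path: str | Path) -> dict[int, SigmoidParams]:
    obj = json.loads(Path(path).read_text())
    return {int(k): SigmoidParams(**v) for k, v in obj.items()}
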
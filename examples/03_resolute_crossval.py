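"""Segmentation-based AC: calibrate the bone sigmoid with 2-fold CV, apply.

Each subject's R2*->HU mapping is fitted on the other fold's subjects, so
no mapping is evaluated on data it was calibrated on.
"""
import numpy as np

from petmrac import (classify_tissue, generate_battery, hu_to_mu, jaccard,
                     resolute_crossval)
from petmrac.resolute import build_nobone_map

cases = generate_battery(4, seed=3, scale="micro")
results, params = resolute_crossval(cases, k=2, seed=1)

for fold, p in params.items():
    print(f"fold {fold}: HU(r) sigmoid L={p.L:.0f} U={p.U:.0f} "
          f"r0={p.r0:.0f}/s k={p.k:.4f}  (fit on {p.n} bone voxels, "
          f"RMSE {p.rmse:.0f} HU)")

print("\nper-case bone-class Jaccard vs reference CT, and mu-map MAE:")
for case in cases:
    mu_res, pct = results[(case.subject_id, case.exam_index)]
    ref_bone = classify_tissue(case.ct_hu).data == 2
    j = jaccard(ref_bone, classify_tissue(pct).data == 2)
    mu_true = hu_to_mu(case.ct_hu).volume.data
    mae_res = np.abs(mu_res.volume.data - mu_true).mean()
    mae_nb = np.abs(build_nobone_map(case)[0].volume.data - mu_true).mean()
    print(f"  {case.subject_id}: bone J={j:.3f}  "
          f"MAE {mae_res:.5f} vs bone-less baseline {mae_nb:.5f} cm^-1")
print("-> recovering bone beats pretending the skull is soft tissue.")
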
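# petmrac

Attenuation correction (AC) for simultaneous PET/MRI of the pediatric
brain, evaluated end to end on synthetic head phantoms with a known
ground-truth CT.

PET quantification needs a map of 511 keV linear attenuation coefficients
(a mu-map), which MRI does not measure. In children this is acute: the
skull is thin, low-density and changes rapidly with age, so adult atlases
fail, and vendor fat/water maps omit bone entirely. This package implements
the two UTE-based (ultrashort echo time) answers and the machinery to judge
them the way a clinic would:

* **Segmentation AC** (`petmrac.resolute`) — classify UTE voxels into
  air / soft / candidate bone using the two-point relaxation-rate map
  R2\* = ln(S1/S2)/(TE2−TE1), and assign bone a continuous pseudo-HU through
  a sigmoid HU(r) = L + (U−L)/(1+e^(−k(r−r0))) calibrated against reference
  CTs of other subjects (2-fold subject-level cross-validation).
* **CNN AC** (`petmrac.deepute`) — a 3D U-net-style encoder-decoder
  (stride-2 convolutions instead of pooling; conv → batch-norm → ReLU →
  dropout 0.1→0.3 through the encoder) regresses HU from 16-slice windows
  of (echo 1, echo 2, R2\*), with dense overlap-averaged inference and
  subject-level k-fold cross-validation. The network and its training
  (He init, Adam, MSE) are implemented in NumPy inside the package.
* **Reference and baseline** — the true CT converted with the bilinear
  HU→mu curve (water 0.096 cm⁻¹), and a bone-less air/soft baseline
  emulating fat/water vendor AC.
* **Evaluation** — a 2D attenuated Radon / filtered-back-projection PET
  simulator propagates each mu-map into reconstructed images; clinical
  read-outs (background B, biological tumor volume BTV at uptake > 1.6 B,
  T_MEAN/B, T_MAX/B, tumor Jaccard, absolute-or-relative acceptance
  limits) and cohort Bland-Altman statistics on the log scale (mean %
  difference, 95% CI, limits of agreement, repeated-measures corrected)
  quantify how each AC method distorts what a reader sees.

Phantoms, methods, simulator and statistics are all seeded and exactly
reproducible.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/03_resolute_crossval.py` calibrates the bone sigmoid with
2-fold cross-validation on four phantoms and applies it out-of-fold:

```
fold 0: HU(r) sigmoid L=426 U=1074 r0=889/s k=0.0112  (fit on 5365 bone voxels, RMSE 176 HU)
fold 1: HU(r) sigmoid L=383 U=891 r0=865/s k=0.0100  (fit on 4429 bone voxels, RMSE 165 HU)

per-case bone-class Jaccard vs reference CT, and mu-map MAE:
  sub-000: bone J=0.837  MAE 0.00206 vs bone-less baseline 0.00264 cm^-1
  sub-001: bone J=0.967  MAE 0.00161 vs bone-less baseline 0.00345 cm^-1
  ...
```

The sigmoid parameters say how bone R2\* maps to density (inflection near
880 s⁻¹, upper asymptote near the subject pool's peak skull HU); Jaccard
close to 1 means the pseudo-CT finds the same bone voxels as the reference
CT, and the mu-map mean absolute error beats the bone-less baseline on
every case. `python examples/06_full_study.py` runs the whole chain and
prints the cohort table; on five phantom subjects the bone-less baseline
biases T_MAX/B by −0.29% (95% CI −0.68 to 0.10) while the calibrated
segmentation method sits at +0.09% (−0.14 to 0.32), with every exam inside
the clinical acceptance limits at this phantom scale.

A thin CLI mirrors the library (`petmrac phantom|r2star|hu2mu|resolute|
deepute|run`), e.g. `petmrac run --config study.yaml --out reports/`.

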
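# wbreg

Whole-body MR→CT deformable image registration and a complete framework
for validating it.

Hybrid PET/MRI needs CT-like attenuation maps that MRI cannot provide
directly; one route is an atlas of whole-body MR/CT pairs brought into
spatial agreement by deformable registration. `wbreg` implements that
registration pipeline and — just as importantly — the point, surface and
volume metrics used to quantify how well it worked, exercised end-to-end
on synthetic paired-modality phantoms whose ground-truth deformation is
known exactly.

## Method

Registration maps points of the fixed (CT) domain into the moving (MR)
domain in two stages:

1. **Rigid pre-alignment** — six parameters (three Euler angles, three
   translations, rotation about the fixed-image centre).
2. **Free-form deformation (FFD)** — a displacement field
   u(x) = Σᵢ cᵢ β³((x − xᵢ)/h) parameterized by cubic B-spline
   coefficients cᵢ on a uniform control grid (spacing h = 8 fixed-image
   voxels), composed after the rigid map.

Both stages maximize **normalized mutual information**,
NMI = (H_F + H_M)/H_FM, estimated from a 32-bin joint histogram over a
few thousand random spatial samples per iteration — NMI rewards a
predictable CT↔MR intensity relationship without assuming a linear one,
which is what makes cross-modality matching possible. The optimizer is
stochastic steepest ascent with the decaying gain

    step(k) = a / (A + k + 1)^α

per multiresolution level (defaults: the clinical whole-body protocol —
five rigid levels 16×→1×, five elastic levels, 7936 iterations per
stage, a = 4000 rigid / 2000…30000 elastic, A = 50, α = 0.6/0.602). The
NMI gradient is analytic (cubic-B-spline Parzen window chained through a
cubic interpolant of the moving image) and is verified against finite
differences in the test suite.

Validation metrics per labelled region r with source mask S (registered
segmentation) and target mask T: target overlap TO = |S∩T|/|T|, Dice
DC = 2|S∩T|/(|S|+|T|), Jaccard JC = |S∩T|/|S∪T| (DC = 2·JC/(1+JC)),
false negative FN = |T∖S|/|T|, false positive FP = |S∖T|/|S|, signed
volume similarity VS = 2(|S|−|T|)/(|S|+|T|); boundary measures from a
Euclidean distance map in physical mm: mean distance error DE and
directed Hausdorff distance HD; plus Euclidean errors of named anatomical
landmarks. Cohort tables report Minimum / Q1 / Median±Δ / Q3 / Maximum
with 1.5·IQR outlier fences and the 95% median notch Δ = 1.57·IQR/√n.

The phantom module synthesizes paired cases: a CT-like volume
(Hounsfield classes, fine grid), an MR-like volume (non-monotone
per-tissue intensity remap, coarser anisotropic grid, multiplicative
bias field, noise), organ labels (body, brain, lungs, kidneys), the
16-site landmark roster, and the exact rigid+FFD chain used to generate
the MR side.

## Worked example

```python
from wbreg.phantom import generate_anatomy, warp_case
from wbreg.registration import RegistrationConfig, register_rigid, register_bspline
from wbreg.evaluation import evaluate_case, records_to_frame

anatomy = generate_anatomy(101)          # 64^3 pseudo-CT with labels + landmarks
case = warp_case(anatomy, 101)           # draw ground-truth warp, render pseudo-MR

config = RegistrationConfig.compact(seed=101)   # schedule for 64^3 volumes
rigid, _ = register_rigid(case.ct, case.mr, config)
chain, trace = register_bspline(case.ct, case.mr, rigid, config)

records, lm = evaluate_case(case.ct_labels, case.mr_labels,
                            case.ct_landmarks, case.mr_landmarks, chain)
print(records_to_frame(records)[["region", "DC", "JC", "DE", "HD"]].round(3))
print(f"mean landmark error: {lm.mean():.2f} mm")
```

prints (about a minute on one CPU):

```
    region     DC     JC     DE   HD
0     body  0.983  0.966  0.677  4.0
1    brain  0.946  0.897  0.659  4.0
2  kidneys  0.916  0.846  0.839  4.0
3    lungs  0.970  0.941  0.657  4.0
mean landmark error: 0.73 mm
```

The case was synthesized with an 8 mm rigid offset plus a smooth FFD of
up to 6 mm; before registration the mean landmark error is ~8 mm.
Dice ≥ 0.8 is conventionally read as excellent volume agreement — here
every region clears it, and the residual DE is below one voxel.

The same pipeline is scriptable from the shell:

```sh
wbreg phantom --seed 101 --out case/
wbreg register case/ct.nii.gz case/mr.nii.gz --seed 101 --out reg/
wbreg evaluate --fixed-labels case/ct_labels.nii.gz --source-labels case/mr_labels.nii.gz \
               --transform reg/transform.txt \
               --fixed-landmarks case/ct_landmarks.txt --moving-landmarks case/mr_landmarks.txt \
               --out eval/
wbreg report eval/metrics.csv --out report/
```

Every run writes a `manifest.json` (command, config, seed, version) so
it can be reproduced bit-exactly.

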
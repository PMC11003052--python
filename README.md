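# leukoseg

Rule-based leukocyte isolation and four-class convolutional classification
for stained blood-smear images.

Differential white-blood-cell counting — telling neutrophils, eosinophils,
lymphocytes and monocytes apart in a smear — is routine but laborious work
for hematology labs. `leukoseg` implements a classic two-stage automation of
it: first isolate the single stained leukocyte in each field of view with
simple color rules and binary morphology, then classify the cropped cell
with a small convolutional network. The package is aimed at image-analysis
researchers who want a transparent, fully seeded reference pipeline whose
every stage is unit-testable, including a synthetic scene generator that
provides ground truth without any external dataset.

## Method

A smear image has three regions: gray background, light-brown erythrocytes,
and one blue/purple leukocyte. With `img[:,:,0] = R`, `img[:,:,1] = G`,
`img[:,:,2] = B`, the masks are

```
background  = (R > t1) & (G > t1) & (B > t1)          t1 = 182 (or per-image Otsu)
erythrocyte = (B < t2) | (R > B)                      t2 = 150 (or per-image Otsu)
leukocyte   = ~background & ~erythrocyte
```

The leukocyte mask is cleaned by morphological **opening** (erosion ∘
dilation with a disk structuring element, outside-image pixels counting as
false), the largest 8-connected component is selected, and a 128×128 window
centered on its bounding box is cropped. Crops are optionally expanded by
seeded augmentation (flips, rotation, shear, contrast, brightness) and fed
to a four-block CNN — 11 convolutional (3×3, valid, stride 1), 8
batch-normalization, 8 ReLU and 4 dropout layers, one 2×2 max-pool, global
average pooling and two dense layers with a 4-way softmax — trained with
Adam at batch size 32 for 12 epochs. Evaluation reports the 4×4 confusion
matrix, per-class precision / sensitivity / specificity / F1, accuracy, and
Cohen's kappa

```
K = (PO − PE) / (1 − PE)
```

with observed agreement `PO = trace/total` and chance agreement
`PE = Σ_c (row_c/total)(col_c/total)`.

The network is implemented directly on numpy (im2col convolutions,
finite-difference-checked backpropagation, Adam), so seeded runs are
bit-reproducible.

## Worked example

```python
>>> from leukoseg import generate_scene, segment_pipeline, mask_iou
>>> scene = generate_scene(seed=1)          # 256x192 synthetic smear
>>> scene.label
<ClassLabel.EOSINOPHIL: 1>
>>> crop, bbox, mask = segment_pipeline(scene.image)
>>> crop.shape
(128, 128, 3)
>>> bbox
BoundingBox(row_min=24, col_min=70, row_max=121, col_max=177)
>>> round(mask_iou(mask, scene.gt_leukocyte), 4)
0.9998
```

The cropped cell is exactly 128×128 and the recovered mask overlaps the
planted ground-truth blob at IoU 0.9998 despite 1% salt noise.

A full pipeline run on 100 synthetic scenes (25 per class, desk-scale
compact network, one augmented variant per training image):

```python
>>> from leukoseg import RunConfig, run_pipeline
>>> from leukoseg.cnn import CnnArchitectureSpec, TrainConfig
>>> cfg = RunConfig(architecture=CnnArchitectureSpec.compact(), seed=0)
>>> cfg.synth.n_per_class = 25
>>> cfg.augmentation.per_image_count = 1
>>> manifest = run_pipeline(cfg)
>>> manifest["stages"]["split"]
{'train': 80, 'test': 20}
>>> manifest["metrics"]["accuracy"], round(manifest["metrics"]["kappa"], 3)
(0.9, 0.858)
```

18 of 20 held-out scenes are classified correctly after 12 epochs; kappa
0.858 means the agreement is far above the 0.25 expected by chance on four
balanced classes. (Accuracy rises to ≥ 0.95 with 100 scenes per class, as
the acceptance script below demonstrates.)

The same pipeline is scriptable from the shell:

```
leukoseg synth --out data --n-per-class 25 --seed 0
leukoseg segment --in data --out crops
leukoseg train --data crops --out model.npz --seed 0
leukoseg evaluate --model model.npz --data crops --out metrics.json
leukoseg run --out manifest.json          # everything in one go
```

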
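# histotile

Headless pre-processing and evaluation toolkit for tile-based deep learning
on histology images.

Convolutional networks for histopathology are trained on small fixed-size
tiles (e.g. 250×250 px) cut from annotated regions of H&E-stained slides.
Before any model sees them, those tiles typically need to be: cut on a
deterministic grid with traceable names, screened for mostly-background
("whitespace") content, balanced across classes, normalised against staining
batch effects, and optionally augmented to accentuate texture. After the
model runs, per-tile probabilities must be aggregated back up to region and
patient level to give clinically meaningful calls. `histotile` implements
that whole pipeline as a scriptable library and CLI — no GUI, no training
loop — for image analysts and ML practitioners who need reproducible,
auditable tile pipelines.

## What it computes

* **Patching** — grid crops at offsets `(r·stride, c·stride)`, named
  `<stem>_r<r>_c<c>`; partial edge tiles dropped by default.
* **Tissue thresholding** — tissue is the dark class of a binary mask:
  fixed (`v < T`, default `T = 220`), Otsu (maximise the between-class
  variance `ω₀ω₁(μ₀−μ₁)²` over integer thresholds), or adaptive
  (`v < local mean − offset`). Tiles whose tissue fraction falls below a
  cutoff are deleted or relocated (boundary tiles survive).
* **Class balancing** — equalise class counts down to the smallest class, up
  to the largest, or to the mean, using the 7 non-identity symmetries of the
  square (mirror `m`, clockwise rotations `r90/r180/r270`, and mirror+rotation)
  as exact pixel permutations. Augmentation modes require that no class hold
  fewer than one eighth of the largest class's samples, which guarantees a
  duplicate-free plan; sampling is seeded and fully reproducible.
* **Stain normalisation** — per-channel cumulative-histogram matching to one
  target image: source value `v` maps to
  `m(v) = min{u : F_target(u) ≥ F_source(v)}`.
* **Augmentation** — emboss as convolution with
  `K = (1−α)·E + α·M(s)`, `M(s) = [[−1−s,−s,0],[−s,1,s],[0,s,1+s]]`
  (kernel sums to 1, so constant regions are fixed points), plus blur,
  sharpen, noise, contrast, pixel/channel dropout, composable in seeded
  pipelines.
* **Evaluation** — tile probability `p ∈ [0,1]` of *immature* stroma is
  classified immature iff `p ≥ 0.5`; tiles→ROI and ROIs→patient by majority
  vote with exact ties called mature; confusion matrices (immature =
  positive class), precision/recall/F1/accuracy/specificity, Clopper–Pearson
  exact CIs, rank-based (Mann–Whitney) ROC AUC with midranks, Fleiss' κ.
* **Synthetic fixtures** — seeded generators for oriented-fibre tiles
  (mature-like parallel texture vs immature-like disorganised texture with
  oedema-like pale blobs), whitespace tiles with controlled coverage, and
  stain-shifted batches, so the full pipeline runs without any dataset.

## Worked example

Confusion-matrix metrics at the patient level, from counts
TN=13, FP=2, TP=11, FN=2 (28 patients):

```python
from histotile import (ConfusionMatrix, precision, recall, f1, accuracy,
                       specificity, exact_binomial_ci)

cm = ConfusionMatrix(tn=13, fp=2, tp=11, fn=2)
print(f"precision   {precision(cm):.3f}")    # 0.846
print(f"recall      {recall(cm):.3f}")       # 0.846
print(f"f1          {f1(cm):.3f}")           # 0.846
print(f"accuracy    {accuracy(cm):.3f}")     # 0.857
print(f"specificity {specificity(cm):.3f}")  # 0.867
print("accuracy 95% CI (%.3f, %.3f)" % exact_binomial_ci(24, 28))
# accuracy 95% CI (0.673, 0.960)
```

Precision = recall here because FP = FN; accuracy is 24/28 correct patients,
and the exact binomial interval reflects the small cohort.

End-to-end on synthetic data from a shell:

```
$ histotile simulate --out ds --patients 4 --rois 2 --tiles 3 --tile-size 64 --seed 1
{"root": "ds", "seed": 1, "class_counts": {"immature": 12, "mature": 12}}
$ histotile patch --src ds --dst patched --size 32
24 source images -> 96 patches under patched
$ histotile aggregate --predictions preds.csv
{
  "tile":    {... "precision": 0.667, "recall": 1.0, "accuracy": 0.8 ...},
  "roi":     {... "accuracy": 1.0 ...},
  "patient": {"tn": 2, ... "precision": null, "accuracy": 1.0 ...}
}
```

In the `aggregate` output, a patient whose immature and mature ROI votes are
exactly tied is called mature; `null` marks metrics whose denominator is
empty (here no patient was predicted immature), which is deliberately
distinct from 0. Every mutating command leaves a
`histotile_manifest.json` recording its parameters, effective seed, and one
entry per file touched.

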
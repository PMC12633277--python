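# cytocluster

Two-stage analysis of multi-channel imaging-flow-cytometry records of
circulating blood-cell clusters. Each record is a co-registered triplet:
a brightfield grayscale frame plus CD61 (green, platelet marker) and CD45
(yellow, leukocyte marker) fluorescence frames. The pipeline

1. **classifies** each frame as cluster vs non-cluster from a classical
   segmentation of the brightfield channel (Otsu binarization, morphological
   filtering, connected components) and shape rules (solidity /
   distance-transform core count) behind a pluggable backend contract, so a
   learned detector can be dropped in;
2. **delineates** the cluster mask and exports it as a normalized polygon
   label file;
3. **extracts** binary stain masks from the fluorescence channels by HSV
   thresholding — green H 35–85, yellow H 20–40 (on the 0–179 half-degree
   hue scale), S 100–255, V X–255 with the brightness lower bound X = 140
   by default;
4. **phenotypes** the cluster from mask overlap: the overlap percentage is
   100 · |cluster ∧ stain| / |cluster|, a channel is *present* at ≥ 15 %
   overlap by default, stain lying wholly outside the contour marks the
   record as an excluded staining artifact, and the decision table maps the
   two channel states to RBC / platelet / WBC / WBC+platelet cluster.

It ships a synthetic-record generator with exact ground truth (scene
taxonomy: blank fields, single cells, separated cells, touching clusters;
staining with controllable coverage and artifact placement), evaluation
metrics (accuracy / precision / recall / F1, mask IoU, AP and mAP@0.5:0.95),
stratified 5-fold splitting with the ×5 augmentation scheme, and a
threshold-sweep harness over V ∈ {100, 140, 170} × overlap ∈
{5, 8, 10, 13, 15, 18, 20, 30} %.

## CLI

All subcommands accept `--config config.yaml` (every pipeline constant —
gray padding value, 224-pixel standard size, augmentation multiplicity,
HSV ranges, X, overlap threshold, sweep grid — is a named key).

```sh
# synthetic labeled dataset with ground truth (images, masks, manifest.csv)
cytocluster generate --out data/ --n 100 --cluster-frac 0.5 --artifact-rate 0.1 --seed 1

# brightfield segmentation: predicted masks + polygon label files
cytocluster segment --manifest data/manifest.csv --out seg/

# HSV stain masks for both fluorescence channels
cytocluster extract --manifest data/manifest.csv --out stains/ --v-lo 140

# full two-stage pipeline, per-record CSV
cytocluster phenotype --manifest data/manifest.csv --out pred.csv

# score predictions against the manifest ground truth
cytocluster evaluate --manifest data/manifest.csv --pred pred.csv --out metrics.csv

# V x overlap-threshold accuracy sweep (24-cell long-format CSV)
cytocluster sweep --manifest data/manifest.csv --out sweep.csv
```

## Layout

| module | role |
| --- | --- |
| `cytocluster.imageio_core` | record/mask/polygon-label data model; PNG/TIFF/label/manifest I/O |
| `cytocluster.preprocess` | gray padding, 224² bilinear resize, ×5 augmentation, stratified k-fold |
| `cytocluster.synth_fixtures` | synthetic scenes + staining with exact ground truth |
| `cytocluster.cluster_segment` | reference brightfield segmenter + cluster rules + backend registry |
| `cytocluster.fluor_extract` | HSV dialect conversion and stain-mask thresholding |
| `cytocluster.phenotype` | overlap percentage, channel states, phenotype decision table |
| `cytocluster.metrics_eval` | confusion metrics, IoU, AP / mAP, CV aggregation |
| `cytocluster.experiments_cli` | pipeline driver, sweep harness, YAML config, CLI |
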
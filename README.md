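# cxrdiff

Toolkit for comparative analysis of longitudinal chest radiographs: given
two X-ray images of the same subject taken at different times, it
segments the lung fields, deformably registers the earlier ("pre",
working) image onto the later ("post", reference) image, computes an
enhanced difference image with heat-map overlays, and classifies thoracic
findings with single- or dual-input networks that can consume the
difference information.

Every stage comes in a classical and a learned flavor:

| Stage | Classical route | Learned route |
|---|---|---|
| Lung segmentation | CLAHE → Otsu → connected components → morphology → ROI box (`seg_classical`) | one-stage anchor detector with focal loss (`seg_detector`) |
| Registration | dense displacement-field gradient ascent on windowed correlation or mutual information (`registration.classical_register`) | U-Net field regressor trained unsupervised (`registration.VoxelMorphNet`) |
| Comparison | `D = post · |post − pre|`, optional sigmoid-like enhancement (k = 6 or 12), heat-map rendering (`comparison`) | — |
| Classification | — | densely connected single-input net; dual-input variant fusing the difference image through a channel-weighting operation block (`classify`) |

Because the original clinical datasets are not redistributable, the
`phantom` module generates synthetic pre/post radiograph pairs with full
ground truth (lung masks, ROI boxes, dense deformation fields, lesion
masks and multi-hot labels); the whole pipeline is developed and tested
against these phantoms. The neural components run on a small NumPy
autodiff engine (`cxrdiff.nn`) — no GPU or deep-learning framework is
required — with reduced "desk-scale" configurations for CPU use alongside
the full-scale configurations.

## Command line

All functionality is exposed through one entry point:

```bash
# generate a synthetic dataset with ground truth
cxrdiff simulate --n-pairs 10 --out-dir data/ --seed 1 --size 128

# lung ROI of one image (classical chain or a trained detector)
cxrdiff segment --method classical --in data/pair0000_pre.png \
    --out-box box.csv --out-mask mask.png

# deformable registration with before/after PSNR/SSIM/NCC
cxrdiff register --method classical --pre pre.png --post post.png \
    --out-warped warped.png --out-field field.bin --report metrics.json

# difference image + heat-map overlay (linear / nl1 / nl2 display modes)
cxrdiff compare --pre warped.png --post post.png --mode nl1 \
    --out-diff d.png --out-overlay o.png

# train/evaluate a desk-scale classifier on a simulated dataset
cxrdiff classify --arch dual --input-mode diff-linear --data-dir data/ \
    --out-preds preds.csv --out-auc auc.json

# IoU / detection-rate report from box CSVs, per fold and averaged
cxrdiff evaluate --pred-boxes pred.csv --truth-boxes data/boxes.csv \
    --out report.json

# the full pipeline on one pair
cxrdiff run --pre pre.png --post post.png --out-dir out/ --size 512
```

`cxrdiff run` writes every intermediate (ROI boxes CSV, crops, warped
image, raw-float displacement field with JSON sidecar, 16-bit difference
PNG, highlighted image, RGB overlay) plus `report.json` with per-stage
timings, before/after similarity metrics and the clipped-pixel fraction.

## Layout

```
src/cxrdiff/
  phantom.py        synthetic pre/post pairs + ground truth, dataset I/O
  preprocess.py     CLAHE, Otsu, histogram matching, resizing, PNG I/O
  seg_classical.py  traditional segmentation chain → lung ROI box
  seg_detector.py   one-stage lung-box detector (focal loss, NMS)
  registration.py   warp, local NCC, mutual information, classical +
                    learned registration
  comparison.py     difference image, nonlinear enhancement, heat maps
  classify.py       single-/dual-input multi-label classifiers
  metrics_cv.py     IoU, detection rate, PSNR, SSIM, NCC, AUC, k-fold
  cli.py            click CLI + pipeline orchestration
  nn/               minimal NumPy autodiff (conv, batch norm, pooling,
                    bilinear warp, Adam, plateau scheduler)
```
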
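# hemoseg

Simultaneous segmentation of leukocytes (WBCs) and erythrocytes (RBCs) in
stained blood-smear microscopy images, using a two-stage marker-controlled
watershed.

Routine differential counts need every cell on a smear delineated, but the
two cell types are usually segmented by separate algorithms. This package
extracts both at once: stained nuclei give away the WBCs, the distance
transform of the binarized smear seeds one marker per cell (including the
cells inside touching clusters), and a watershed of the reconstructed
gradient surface traces the final contours, after which each cell is called
WBC or RBC simply by whether it contains a nucleus. A seeded synthetic-smear
generator with instance-level ground truth and Hoover-style instance-matching
metrics make the whole pipeline testable without any external image data.

## Method

Given an 8-bit RGB smear image:

1. **Nucleus extraction** — convert to HSI; the ratio image `S/I` is bright
   exactly on stained nuclei (high saturation, low intensity). Otsu's
   threshold binarizes it and an area threshold drops platelet-sized
   components. The nucleus map doubles as the WBC marker.
2. **Cell binarization** — Sobel gradient `∇I` of the intensity plane; edges
   above the gradient's Otsu threshold are painted dark into `I` so touching
   cells stay joined; the first valley of the intensity histogram thresholds
   the result, and holes (pale RBC centres) are filled, giving the cell mask
   `∇B`.
3. **Marker generation** — the exact Euclidean distance transform `d` of the
   denoised mask is inverted to the grey topography `I_Dist = 255 − d`.
   Regional maxima of `d` seed one marker per cell; seeds closer than
   `T = multiplier · d_max` to a stronger seed are pruned as pseudo-markers
   (`d_max` estimates the largest cell radius); nucleus components are
   superimposed as protected WBC markers. A first watershed on `I_Dist`
   contributes its ridge lines (plus the frame border) as the background
   marker.
4. **Cell segmentation** — the gradient surface is reconstructed: H-minima
   fills basins shallower than `t_i` (default 3 grey levels, useful range
   2–4), minima imposition pins the remaining minima to the markers, and a
   second watershed yields one labelled region and one closed contour per
   cell.
5. **Classification** — a cell is a WBC iff it contains nucleus pixels; a
   nucleus split across two regions credits only the larger overlap.

All morphological operators (Otsu, Sobel, exact EDT, hole filling, regional
extrema, greyscale reconstruction by erosion, H-minima, minima imposition,
Meyer-flooding watershed) are implemented in the package and verified
against brute-force oracles in the test suite.

## Worked example

```python
from hemoseg import (SmearParams, generate_smear, run_pipeline,
                     match_segments, mean_matched_jaccard)

img, truth = generate_smear(SmearParams(n_rbc=9, n_wbc=1, seed=42))
result = run_pipeline(img)
print(f"cells found: {result.segmentation.n_cells}")
for rec in result.records[:3]:
    print(f"  label {rec.label}: {rec.cell_class:3s}  area={rec.area:.0f} px^2  "
          f"centroid=({rec.centroid[0]:.1f}, {rec.centroid[1]:.1f})  "
          f"nucleus_overlap={rec.nucleus_overlap:.0f}")
report = match_segments(result.segmentation.labels, truth)
print(report.to_frame().to_string(index=False))
print(f"mean matched Jaccard: "
      f"{mean_matched_jaccard(result.segmentation.labels, truth, report):.3f}")
```

prints

```
cells found: 10
  label 1: WBC  area=1368 px^2  centroid=(163.8, 39.6)  nucleus_overlap=691
  label 2: RBC  area=423 px^2  centroid=(56.1, 199.7)  nucleus_overlap=0
  label 3: RBC  area=672 px^2  centroid=(68.9, 141.1)  nucleus_overlap=0
cell_class  n_gt  n_pred  one_to_one  overseg  underseg  fault  spurious_preds
       RBC     9       9         1.0      0.0       0.0    0.0               0
       WBC     1       1         1.0      0.0       0.0    0.0               0
mean matched Jaccard: 0.928
```

All ten cells (nine RBCs, one WBC) are recovered one-to-one against the
generator's ground truth; the mean intersection-over-union of matched pairs
is 0.93. The same pipeline is available from the shell:

```sh
hemoseg synth --out smear/ --seed 42          # image.png + ground truth
hemoseg run smear/image.png --out out/        # labels.tif, overlay.png, cells.csv
hemoseg eval out/labels.tif smear/gt_labels.tif --out report.csv
```

`overlay.png` draws red cell outlines and blue nucleus outlines on the
input; `cells.csv` lists label, class, area, centroid and nucleus overlap
per cell.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates synthetic smears in two regimes — eight well-separated cells and
ten adherent cells at overlap fraction 0.2 (five images each, seeds derived
from `--seed`) — runs the full pipeline on every image, and prints the
one-to-one recovery rate, mean matched Jaccard and class accuracy for each
regime before writing the results file.
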
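# Methods

This note records the model behind `hemoseg`, the parameters that matter,
what the synthetic-smear generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## The segmentation model

A stained blood smear viewed in brightfield has four optical classes:
near-white background, pink-grey erythrocytes (RBCs), leukocyte (WBC)
cytoplasm, and deep purple chromatin (WBC nuclei; platelets stain the same
purple but are far smaller). The pipeline exploits two facts about this
scene:

* **Nuclei are simultaneously saturated and dark.** In HSI coordinates
  (`I = mean(R,G,B)`, `S = 1 − min/mean`) the ratio `S/I` is an order of
  magnitude larger on chromatin than on anything else, so its histogram is
  bimodal and Otsu's threshold isolates the nuclei. Because the ratio is
  computed from relative colour geometry rather than any particular hue,
  a global change of staining scheme (tested as ±20° hue rotations) leaves
  the detection unchanged.
* **Cells are near-circular, so the distance transform counts them.** Every
  disc—even inside a touching cluster—produces one regional maximum of the
  Euclidean distance map of the binarized smear. Those maxima, plus the
  nucleus components, seed a marker-controlled watershed, which cannot
  over-segment (one region per seed, by construction) and splits clusters
  along gradient crest lines.

Two watersheds run. The first floods the inverted distance topography
`I_Dist = 255 − d` and its ridge lines become the background marker; the
second floods the gradient magnitude after H-minima filling and minima
imposition, and its regions are the cells.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `min_nucleus_area` | 200 | px² | smallest component kept as a nucleus; separates nuclei (≥300 px² at scale) from platelets (≤80 px²) |
| `gaussian_sigma` | 1.5 | px | mask denoising before the distance transform |
| `t_i` | 3 | grey levels | H-minima basin-depth threshold; useful range 2–4, values outside warn |
| `pseudo_marker_multiplier` | 0.7 | — | pruning distance `T = multiplier · d_max`; see below |
| `min_marker_area` | 1 | px² | area filter on distance-maxima components |
| `min_marker_distance` | 8 | px | minimum distance peak for a seed; rejects sub-cellular bumps such as platelets fused onto a cell's mask component (8 px = 2 µm radius at the default scale) |
| `min_cell_area` | 150 | px² | platelet-sized mask components are dropped before marker extraction |
| `valley_smoothing` | 5 | bins | moving-average window before the first-valley search |
| `overlap_threshold` | 0.5 | fraction | instance-matching coverage threshold |

All areas and distances are stated at the generator's default rendering
scale of 4 px/µm and should be rescaled together with the imagery.

### Why `T = 0.7 · d_max` and not `2 · d_max`

`d_max`, the largest value of the distance map, estimates the radius of the
largest cell. A pruning threshold of twice that radius removes every seed
within one largest-cell *diameter* of a stronger seed — which includes every
touching neighbour, so dense smears collapse to a handful of cells
(measured: 1 of 11 cells survive). The threshold must instead sit below the
touching distance of the smallest cells, `2·r_min ≈ 0.9·d_max` when RBCs
(3–4 µm radius) coexist with WBCs (5–7 µm): 0.7 leaves margin for the
seed-position jitter of overlapping cells while still deleting duplicate
maxima, which sit a few pixels apart inside one cell. The multiplier is
configurable; setting it to 2.0 reproduces the aggressive variant.

### Marker construction details

* Maxima are detected on the **exact** (float) distance map: integer
  quantization can fuse the peaks of two moderately overlapping cells into
  one plateau across their saddle. The quantized map is used only for the
  inverted topography (a grey-level image by definition) and for `d_max`.
* A distance-map candidate whose peak's inscribed disc `B(p, d(p))` reaches
  a nucleus belongs to the same cell as that nucleus and is absorbed into
  the protected marker; otherwise every WBC would carry two seeds (its own
  distance maximum plus the nucleus) and be split in two.
* Ridge pixels falling inside the cell mask are removed from the background
  marker: ridges crossing the neck of an adherent cluster would otherwise
  seed the background flood *inside* the cluster and steal cell rims. The
  frame border (outside the mask) is always added, since a lone cell
  produces no ridge at all.

### H-minima: what is and is not guaranteed

`h_minima(f, t) = reconstruct_by_erosion(f + t, f)` removes every basin of
dynamics below `t` and raises the bottom of each survivor by `t`. Two
consequences that are easy to get wrong: the operator is **not** idempotent
(a survivor of depth `h` re-emerges with depth `h − t`, so a second
application removes more; the composition law `HMIN_s∘HMIN_t = HMIN_{s+t}`
holds instead and is tested exactly), and a surviving minimum's *residual*
depth may be less than `t` even though its original basin was deep. The test
suite therefore checks survival against a brute-force basin-dynamics oracle
rather than re-measuring depth on the output.

## The synthetic generator

`generate_smear` renders, deterministically per seed: a bright near-uniform
background; `n_rbc` discs of radius 12–16 px (the normal 6–8 µm RBC diameter
at 4 px/µm) with a parabolic central pallor emulating the biconcave profile;
`n_wbc` larger discs (20–26 px) with basophilic cytoplasm and a feathered,
lobed nucleus occupying ~45 % of the cell (lymphocyte-like, realistic for
10–13 µm cells); small dark platelets on free background; a ~1.5 px darker
membrane ring on every cell, drawn after all bodies so that the shared
boundary of overlapping cells stays visible; a global per-image stain jitter
(sd 4 grey levels per channel) and additive Gaussian sensor noise (sd 3).
Placement is rejection sampling under a pairwise disc-overlap bound, with
exact circle-lens geometry recorded as ground truth.

Appearance constants encode premises the method itself relies on, and were
frozen before the test suite was written: chromatin is dark enough to
dominate the `S/I` ratio (bimodal enhancement histogram); membranes are the
dominant gradient walls, while the nucleus–cytoplasm transition is
diffraction-feathered and therefore weaker — in brightfield reality nuclear
boundaries are soft and membranes crisp, and a gradient-flooding watershed
can only hand the cytoplasm to the nucleus seed under that ordering.

What the generator does **not** emulate: rouleaux chains and non-circular
cell shapes, out-of-focus blur and vignetting, local (non-global) stain
variation, debris, and cells cut by the image border. A green synthetic test
therefore establishes that the pipeline logic is correct for isolated and
moderately overlapping circular cells under mild global perturbations — not
that it is robust to every real-world smear.

## Evaluation semantics

Instance matching is Hoover-style on the ground-truth × prediction overlap
matrix with threshold 0.5: over-segmentation (≥2 predictions each covering
≥ 25 % of an instance) and under-segmentation (one prediction covering
≥ 25 % of ≥ 2 instances) are detected first, then one-to-one matches
(exactly one covering prediction, majority-covered in return), and the rest
are faults. Split/merge evidence must outrank the one-to-one test: a merged
prediction still majority-covers its larger constituent. Every ground-truth
instance lands in exactly one category, so the four per-class rates sum
to 1; unmatched predictions are reported separately as spurious rather than
folded into the fault rate. Rates are per-cell, platelet instances are
excluded (the pipeline does not segment them), and reported per class so
WBC and RBC quality can be read separately.

## Known limitations

* The first-valley binarization assumes a bimodal intensity histogram;
  unimodal images raise unless the Otsu fallback is enabled.
* Otsu on the `S/I` ratio can pick the background/RBC valley instead of the
  RBC/nucleus valley when nuclei occupy a very small fraction of a wide
  field; the method is intended for fields comparable to a high-power crop.
* A single global `T` cannot be optimal for strongly heterogeneous cell
  sizes; the multiplier trades duplicate-seed removal against deleting true
  neighbours.
* Cells touching the image border are not specially handled (the generator
  never places them); the frame-border background marker would erode them.
* The pure-Python watershed costs ~1 s per 300×300 image; the pipeline is
  intended for desk-scale images, not whole-slide throughput.
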
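# woundquant

Automated quantification of wound-healing ("scratch") assays from
phase-contrast micrographs, plus the closed-form arithmetic used around that
assay in cell-migration studies (relative migration distance, caliper tumour
volume, normalization to control).

## Who this is for

In a scratch assay a confluent cell monolayer is scratched with a pipette
tip, photographed at 0 h and again after incubation (typically 24 h), and the
narrowing of the denuded gap is the readout of cell migration.  Measuring the
gap by hand is slow and user-dependent; `woundquant` automates it for batches
of images, and ships a synthetic-image generator with exact ground truth so
the whole pipeline can be validated without any microscope.

## The measurement model

Under phase contrast, cell-covered regions are granular (high local texture)
while the denuded wound band is smooth.  The pipeline exploits exactly that:

1. **Segmentation** — a moving-window local-variance map (window 15 px)
   splits the frame into cell and wound regions.  Otsu's method on the
   log-variance identifies the two appearance classes; the final threshold is
   the midpoint of the class variance levels, which places the mask edge on
   the true boundary because local variance mixes linearly with the cell-area
   fraction of the window.  Morphological cleanup keeps the largest
   low-texture component as the wound.
2. **Main axis** — the principal eigenvector of the second central moments of
   the wound mask.
3. **Contours** — subpixel boundary polylines between the compacted cell
   layer and the wound, one per side of the axis.
4. **Width profile** — N (default 5) equally-spaced lines perpendicular to
   the main axis; on each line the wound width is the distance between the
   two contour intersections.  The per-image mean width is the assay
   quantity.

Given widths of a treated/control pair before and after incubation
(A, B and a, b), the migration readout is

    relative migration distance (%) = 100 * (A - B) / (a - b)

and the auxiliary assay formulas are the caliper tumour volume
V = L·W²/2 (mm³) and normalization to control, 100·value/control.

## Worked example

```python
from woundquant import SyntheticSpec, generate_scratch_image, quantify_image

spec = SyntheticSpec(wound_width=120.0, wound_angle=20.0, seed=42)
img, truth = generate_scratch_image(spec)
profile = quantify_image(img, n_lines=5)
print(f"mean measured width: {profile.mean_width_px:.2f} px")
```

prints

```
mean measured width: 119.79 px
```

i.e. the pipeline recovers the 120 px ground-truth band within a fraction of
a pixel; the five individual lines (119.97, 122.16, 120.08, 118.67,
118.09 px in this run) sample the gap at equally-spaced axial positions.
`examples/` contains this script plus a treated-vs-control migration
comparison and a config-driven batch run.

## Command line

```
woundquant simulate --wound-width 120 --angle 20 --seed 42 --out demo/
woundquant measure demo/scratch_t0.tif
woundquant compare --treated-t0 ... --treated-t1 ... --control-t0 ... --control-t1 ...
woundquant batch run.yaml
```

`batch` consumes a YAML config naming treated/control image quadruples and
writes a summary CSV, a line-level CSV, per-image JSON and optional QC
overlays; reruns with the same config are byte-identical.

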
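# grainstereo

Automatic extraction of cereal-grain **thickness** from a two-camera stereo
image pair, using the *shape* of grain edges instead of surface texture.

Grain thickness (the dimension perpendicular to the resting plane) matters
for rice quality grading and phenotyping, but unlike length and width it
cannot be read from a single top-down image, and grains are too smooth and
too similar for texture-based stereo matching. `grainstereo` implements a
photogrammetric alternative for researchers in crop phenotyping and seed
morphometry:

1. **Orient** both cameras by single-image *space resection* from a
   calibration board — a grid of circles with known spacing whose sub-pixel
   centroids provide control points in the board frame (Z = 0).
2. **Segment** the grains in each image (weighted-sum graying
   `0.2989 R + 0.5870 G + 0.1140 B`, median filtering, Otsu binarisation,
   area-based removal of broken and clumped kernels).
3. **Match** corresponding grains through object space, then match
   corresponding *edge points* within each grain pair using the
   polar-distance signature: the centroid-to-edge distance resampled at 1°
   steps, aligned by maximising the Pearson correlation over all 360
   circular shifts. Near-tied alignments of symmetric silhouettes are
   resolved by stereo consistency (smallest reprojection residual).
4. **Reconstruct** the height of every matched edge point by two-ray
   *space intersection* of the collinearity equations

   ```
   x - x0 = -f [a1(X-Xs) + b1(Y-Ys) + c1(Z-Zs)] / [a3(X-Xs) + b3(Y-Ys) + c3(Z-Zs)]
   y - y0 = -f [a2(X-Xs) + b2(Y-Ys) + c2(Z-Zs)] / [a3(X-Xs) + b3(Y-Ys) + c3(Z-Zs)]
   ```

5. **Estimate thickness** from the half-height hypothesis: a grain resting
   on the board exposes its occluding rim at height `h` one way up and
   `H - h` the other; with fair random flips `E[rim height] = H/2`, so

   ```
   H_hat = 2 x mean over grains ( mean over edge points of Z )
   ```

A fully ground-truthed **synthetic stereo-scene generator** (grains of known
thickness and rim asymmetry on a rendered calibration board, imaged by a
configurable two-camera rig) makes the whole pipeline testable without any
real imagery.

## Worked example

Simulate a 10-grain scene (H = 1.8 mm, rim offset δ = 0.15 mm, camera
height 350 mm, baseline 80 mm, ≈0.1 mm/px), orient the cameras from the
rendered board, and measure:

```sh
$ grainstereo simulate --out bundle --n-grains 10 --seed 5
wrote fixture bundle to bundle (10 grains, H=1.8 mm, baseline 80.0 mm)

$ grainstereo orient --left bundle/left.png --right bundle/right.png \
    --board bundle/board.yaml --camera-left bundle/camera_left.yaml \
    --camera-right bundle/camera_right.yaml --out oriented
camera_left_oriented.yaml: 24 control points, RMS 0.0037 px
camera_right_oriented.yaml: 24 control points, RMS 0.0039 px

$ grainstereo measure --left bundle/left.png --right bundle/right.png \
    --board bundle/board.yaml \
    --camera-left oriented/camera_left_oriented.yaml \
    --camera-right oriented/camera_right_oriented.yaml --out report.csv
matched 10 grain pairs (10 left / 10 right regions)
thickness: 1.681 mm -> report.csv
```

The report lists one row per grain (mean edge height, points used, mean
reprojection residual) plus a summary row:

```
left_id,right_id,n_points_used,edge_height_mm,residual_px,n_grains,thickness_mm
7,7,360,1.0167772639769777,0.11424599537873005,,
...
summary,,3600,0.8405966307818329,0.07147388191785807,10.0,1.6811932615636658
```

Reading the numbers: per-grain edge heights cluster near 0.75 mm or
1.05 mm — the two faces of a δ = 0.15 mm asymmetric grain — and the
estimate doubles their mean. For *this* draw of flips (7 down, 3 up) the
estimator's own target is `2 × (0.9 − 0.15·4/10) = 1.680 mm`; the measured
1.681 mm shows the geometric reconstruction error is at the micrometre
level, while the gap to the nominal 1.8 mm is the finite-sample noise of
the random flips, which shrinks as `2δ/√n` with the number of grains.

`grainstereo evaluate --mode samples|baseline` sweeps the sample amount or
the stereo baseline on synthetic scenes and writes error-curve CSVs.

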
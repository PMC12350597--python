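# Methods

## Model

The statistic is topological: at a binarization threshold *t*, a tile of HU
values becomes a binary image whose Betti numbers b0 (connected foreground
components) and b1 (holes: background components not reaching the tile
border) summarize connectivity. Foreground uses 8-adjacency and background
4-adjacency by default — the standard dual pairing, under which the bit-quad
Euler characteristic satisfies χ = b0 − b1 and component/hole counts are
mutually consistent. Both adjacencies are configurable (`ConnectivityRule`),
always as a dual pair.

Binarization polarity is foreground = HU ≥ *t*. Fibrous septa are denser
than aerated lung, so inside the −700…−400 HU sweep the above-threshold
phase is fibrous structure; the opposite polarity is available as a flag.
Pixels outside the lung mask are background at every threshold.

The homology profile of a tile is (b0(t), b1(t)) over the ascending sweep.
Its scalar summary is the maximum of one index (default b0); an `argmax`
summary (the lowest threshold attaining the maximum; ties broken toward the
lowest threshold) is implemented for comparison but is not the default — on
phantom cohorts it carries far weaker class contrast.

The HF map accumulates, for every tile placed on a fixed stride and not
skipped by the mask-coverage rule, the standardized profile summary onto the
tile footprint; overlapping contributions are summed with no coverage
normalization, so interior pixels aggregate up to (tile/shift)² tile
opinions. The slice feature is the map maximum.

## Parameters

| parameter | default | meaning |
|---|---|---|
| threshold_lo/hi | −700 / −400 HU | sweep band; the attenuation range of fibrotic lung tissue |
| threshold_step | 1 HU | sweep resolution; 1 HU is the finest meaningful step for integer HU data |
| tile_size | 32 px | scale of the local texture window |
| shift | 8 px | stride; the analysis resolution of the map |
| skip_fraction | 0.95 | skip a tile when strictly more than 95 % of its pixels are outside the lung mask (a tile at exactly 95 % is kept) |
| standardization | pixel_area | divide each tile summary by Δrow·Δcol mm² so component counts are per-mm², comparable across reconstruction grids; `pixel_spacing`, `tile_pixels` and `none` are selectable |
| index / mode | b0 / max | which Betti sequence and which profile summary feed the map |

The skip rule is phrased as a fraction of pixels *outside* the lung:
skipping lung-rich tiles would discard exactly the signal, so the rule
removes tiles that are essentially all body or background.

Classification: decision direction is fixed (feature ≥ cutoff ⇒ fibrosis);
ROC cutpoints are the midpoints between consecutive distinct sorted tuning
features plus ±∞ sentinels; AUROC is the trapezoidal area (equal to the
Mann–Whitney pair-counting statistic); Youden ties break toward the lowest
cutoff, which maximizes sensitivity at equal J. Splits are patient-wise
(`round(2/3 · n)` patients to tuning), resampled with a logged notice if a
draw leaves a class absent from either side, and reproducible from
(seed, repeat index). Undefined metrics (zero denominators) are reported as
NaN and excluded from means, never silently zeroed.

## Numerical and algorithmic choices

* **Whole-sweep filtration.** Both Betti sequences are computed in one
  incremental union-find pass per phase (pixels inserted in HU order;
  b = inserted − effective merges; a virtual outside node absorbs
  border-touching background), implemented with numba. This replaces
  O(thresholds) independent relabelings and makes the 301-threshold default
  sweep practical; a per-threshold relabeling engine
  (`homology_profile(..., engine="reference")`) is kept and the two are
  asserted exactly equivalent in the tests, on both polarities and both
  adjacency pairings.
* Accumulation is in float64; maps serialize as float NIfTI (16-bit PNG
  export is explicitly lossy and records its scale).
* Tiles are placed only fully inside the raster (no padding); with a
  512×512 slice, 32/8 tiling gives 61×61 origins.
* Degenerate inputs: an empty lung mask yields an all-zero map with a
  warning; a tile with no valid pixel yields a distinct empty-profile signal
  (summarizing it is an error; the map accumulator treats it as a zero
  contribution, reachable only when the skip rule is disabled).
* Coordinates are row-major, 0-based, origin top-left, half-open tile
  footprints; recorded in every output sidecar.

## Lung segmentation

The mask recipe is deliberately classical and fully parameterized:
threshold at −320 HU, clear border-connected air, keep the two largest
components, close with a radius-5 disk, fill holes. It is validated only
against the phantom's analytic ground truth (Dice ≥ 0.95 across lesion
types; interior nodules do not change the mask). Users with curated masks
should supply them and bypass this stage.

## The phantom

The generator renders what the statistic is sensitive to, not CT physics:
a soft-tissue body ellipse (+40 HU) over −1000 HU background, two analytic
lung ellipses (−850 HU, Gaussian noise SD 30 HU — 5σ below the sweep, so
noise alone never crosses it), 15 vessel disks at 0 HU, and one of
three lesion states:

* **fibrosis** — a subpleural band (width 12 mm, a typical depth for
  reticulation on HRCT) tiled with a jittered hexagonal honeycomb
  (4 mm cells, lumina at −820 HU). Each wall segment — the shared wall of
  two adjacent cells — draws one HU from N(−550, 100). At any sweep
  threshold only a subset of segments is foreground, so tiles fragment into
  many components: the high-b0 signature. The per-segment draw is a
  modelling choice that makes b0 the discriminative index by construction,
  not a validated imaging claim.
* **nodule** — a 12 mm-radius disk at +20 HU (one extra component).
* **none** — vessels only.

`overlap_delta` shifts the wall-HU mean; driving it to −100/−200 HU moves
wall attenuation toward and below the sweep floor, eroding the fragmentation
signal — the single dial used for the separability-degradation experiment.
Default image size is 256 px at 0.7 mm spacing (512 available), which keeps
the full test suite and the acceptance run at desk scale.

What passing phantom tests shows: the pipeline's mechanics — topology,
sweep, accumulation, standardization, splitting, ROC — are correct, and the
designed honeycomb contrast is recovered end to end (class means ordered
fibrosis > nodule > normal; perfect separation at default parameters).
What it does not show: performance on real CT, where fibrosis morphology,
ILAs, reconstruction kernels and segmentation errors are far richer than
the phantom's geometry.

## Known limitations

* 2D only; no volumetric homology and no persistence pairing across
  thresholds.
* The analysis resolution is set by the stride (8 px); finer strides cost
  quadratically.
* On a perfectly separable cohort the tuned cutoff is the midpoint between
  the extreme tuning features of the two classes, so it varies with the
  random patient split; its across-repeat SD is small but nonzero whenever
  features vary patient-to-patient.
* The fibrosis-vs-lung-cancer protocol is the same code path with relabeled
  classes; phantom nodules are simpler than real cancers and separate more
  cleanly than clinical data would.
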
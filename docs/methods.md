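# Methods

## Coverage-error model

A reservoir is discretized into a binary occupancy grid `Lo` (`M×N` in plan
view, `M×N×K` as a volume), 1 where fish are present. A survey is a set of
parallel transects; the cells swept by the sonar beam form the coverage
mask `Lf`. The statistics are ratios of cell counts:

* detected-fish fraction `δf = 100·Σ(Lo∧Lf)/ΣLo`,
* covered fraction `pf = 100·ΣLf/(M·N)` (2D) and `pfs` (3D),
* coverage error `δp = |δf − pf|` (3D analogue `δps`),
* extrapolated total `N̂ = Σ(Lo∧Lf)·(M·N·K)/ΣLf` with relative error
  `δpa = 100·|N̂ − ΣLo|/ΣLo`.

`δp` measures how far "fraction of area covered" is from "fraction of fish
seen"; it is identically zero under full coverage or uniformly spread fish,
and `N̂` is exactly the fish count under full coverage and unbiased under
uniform random fish placement (both are asserted exactly, not
approximately, in the tests). One 3D variant of `δps` circulating in print
sums the coverage mask rather than the detected fish in its first term,
which makes it independent of fish locations; the package implements the
detected-fish form as the default and keeps the other behind
`delta_ps(..., as_printed=True)` for auditability.

## Cluster geometry

Fish aggregation is modeled as `s` equal discs (balls in 3D) around
centres drawn uniformly over the grid; every cell of a cluster is
occupied, so the cluster-area fraction `ps` is also the occupied fraction.
Rather than growing disc radii iteratively until the union hits the target
area, the generator occupies exactly the `T = round(ps·M·N)` cells nearest
to any centre — the union of equal discs whose shared radius is the `T`-th
order statistic of the nearest-centre distance field. This makes the
occupied fraction exact by construction, handles overlap and edge clipping
uniformly, and is deterministic per seed. When the implied radius is small
relative to centre spacing the grid contains exactly `s` disc-shaped
components (verified against flood-fill labeling).

The disc model is one reading of an under-specified design: aggregations
could equally be sparse point clouds inside larger home ranges. Solid
equal discs are the simplest geometry consistent with a single `ps`
parameter, and they are the *least* favorable for partial-coverage
sampling because all of a cluster's fish stand or fall together.
Consequences of this choice are discussed under Limitations.

## Transects and the beam cone

Transects are parallel bands (default vertical, i.e. along columns) with
the first track at half a spacing from the edge. The band width is the
beam footprint `2·k·tan(α/2)` at the working depth, converted to cells and
rounded to the nearest cell. The 3D mask widens with depth following the
cone, with an empty surface layer (apex width 0). The spacing rule
`Tm = 9·k·tan(α/2)` is implemented exactly as stated — algebraically it
allots each track 4.5 footprints of spacing — and is not re-derived; the
tests pin its printed reference values (0.24/2.4/7.2 m at 0.1/1/3 m for a
30° cone) and the 4.5× identity.

For a coverage target the planner chooses the track count whose realized
covered fraction is closest to the target; with a footprint of `w` cells
on an `N`-cell extent the realized fraction is quantized in steps of
`100·w/N` %, so targets are met within ±1.5 percentage points when `w/N`
is small (the bundled sweeps use `w = 10`, `N = 200`, giving 5% steps that
match the 5%-spaced targets exactly).

## Monte-Carlo sweeps

`run_sweep` averages `δp` (2D) or `δpa` (3D) over `iters` replicate grids
for every `(s, ps, coverage)` cell. Replicates are seeded from
`SeedSequence([master, s_index, ps_index, replicate])`, so results are
bit-reproducible and parallelizable. Each replicate grid is scored against
the masks of *all* coverage targets (common random numbers): per-cell
means are unchanged in expectation, the error-vs-coverage curves are
smoother, and the sweep generates ~20× fewer grids. Coverage masks are
deterministic and built once per target. Cell means use the per-replicate
absolute deviation `|δf − pf|`; the standard deviation column uses
`ddof=1`.

Default conditions are a 200×200 grid, a 30° cone with fish at 5 m depth,
and a 0.27 m cell edge — a ~54 m pond, comparable to the 56×26 m and
130×22 m verification ponds, with the footprint spanning 10 cells. The
per-cell replicate default is 5000; the bundled replication sweeps and the
acceptance script use 500 replicates per cell, which bounds the Monte-Carlo
standard error of a cell mean near 0.1 percentage points while keeping a
full four-sweep run under a minute on one CPU. Where the cluster area for
the cluster-count sweep is not pinned by the study design it is fixed at
`ps = 0.10`; this is a documented choice.

### Regime behavior of the coverage error

Under disc clusters the per-cluster contribution to `Var(δf)` is governed
by the ratio of disc diameter to the transect period: discs much smaller
than the period are covered all-or-nothing (near-Bernoulli, high
variance), discs spanning several periods are averaged (low variance), and
the total error scales like `g(diameter)/√s`. Two consequences matter for
interpreting sweep output:

* the "more clusters → less error" trend holds where diameters stay at or
  below the transect period so the `1/√s` dilution dominates (the bundled
  trend test runs in this regime); with a single huge cluster spanning
  several transects the trend can invert, because smoothing beats
  dilution;
* error levels at moderate cluster areas remain at a few percent — the
  coherent all-or-nothing component cannot be made arbitrarily small by
  enlarging clusters at fixed `s`, so expectations of sub-0.5% error for
  10 clusters on ≥30% of the surface, or sub-2.6% for >40 clusters on 10%,
  are not reproduced by this geometry (measured ~2.8% and ~4.2% at the
  bundled conditions). These are properties of the disc model, not of the
  sweep machinery; a geometry with intra-cluster point fish would lower
  them but requires a second parameter the model deliberately does not
  have.

## Synthetic echograms

A scene is a `1970×200` 8-bit image: background level 20 plus a slow
brightness trend (amplitude 10: half a linear vertical ramp, half one
horizontal sine period) and Gaussian speckle (sd 4), a near-saturated
surface band (12 rows), a bright below-bottom region with the bottom line
undulating ±25 px around row 295, and fish as soft-edged filled ellipses
(axes 6–14 px, peak 150–230) placed uniformly in the water column. The
bottom default mirrors the ~1.3–1.5 m verification ponds scanned at a
10 m range (1.5/10 of 1970 rows ≈ 295); most of a real frame at that
range setting is below-bottom return, which is what makes a fixed
fraction-of-mean threshold sit far above the noise floor. GPS fixes fall
at ping 0 and then every 10–15 pings (uniform), linearly interpolated
between a start and end position; ping times assume 10 pings/s.

Not modeled: beam-pattern and time-varied-gain physics, crescent-shaped
fish arcs, multiple echoes, and wave-induced artifacts. Passing detection
tests on these scenes therefore demonstrates the pipeline's segmentation
logic (background removal, thresholding, labeling, georeferencing), not
calibrated performance on any particular sonar.

## Detection pipeline

Median 3×3 (reflect padding) → white top-hat with a flat 40×40 element
(reflect padding) → binarize at `0.20 ×` mean brightness → clear rows
within 5 px of the surface band and bottom line → 8-connected components
with `min_area_px = 4` → unweighted centroids, depth `row·range/rows`,
position by linear interpolation of fixes in ping index (clamped to the
nearest fix outside the fix range; absent, with `gps_valid = False`, when
no fixes exist).

Two readings of the classic recipe were rejected as unworkable and are
implemented otherwise:

* *"morphological opening removes uneven brightness"* — a literal 40×40
  opening would erase every fish blob smaller than the element; the
  opening is therefore used as the background estimate and subtracted
  (white top-hat), which removes structures *larger* than the element and
  keeps the fish;
* *the threshold's "total average brightness"* is computed on the
  median-filtered input image, not on the top-hat residual: the residual
  of pure background noise has a positive mean (≈2.5σ of the smoothed
  noise), so one fifth of the *residual's* own mean always sits below the
  noise floor and would binarize essentially the whole frame. The input
  image's mean retains the bright surface/bottom structure and puts the
  threshold well above the noise floor. The standalone `binarize` keeps
  the self-mean contract; the pipeline passes the filtered input as the
  reference explicitly.

Because the threshold tracks the frame mean, the pipeline is invariant to
moderate constant brightness offsets (the top-hat itself is exactly
invariant; the threshold moves but stays between noise floor and target
brightness). 8-connectivity reproduces the known failure mode: fish
closer than one pixel merge into one component, and no splitting is
attempted. Detection quality is scored by greedy one-to-one centroid
matching within a pixel radius; with no detections against non-empty
truth, precision is reported as 1.0 by convention and flagged in the log.

## Numerical conventions

* Ties in cluster-cell selection are broken by flat cell index
  (deterministic); centres use continuous coordinates.
* Band half-width rounding: nearest cell, ties away from the track line.
* Table-style relative counting errors round half-up to integer percent.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; no global state. Derived child seeds are
  reduced below 2³¹.
* CSV writers use fixed 6-decimal floats (detections, sweep results) or
  `repr` round-tripping (ground truth) so identical inputs give identical
  bytes.

## Known limitations

* The disc-cluster geometry is a modeling decision; coverage-error levels
  in the few-percent range at moderate `ps` are intrinsic to it (see
  regime discussion above).
* The relative volume scanned in a real survey depends on bottom
  topography, which is outside the model (flat bottom assumed at a single
  working depth in 2D mode).
* The echogram generator does not emulate acoustic physics; detector
  performance numbers on synthetic scenes are upper bounds.
* Merged adjacent fish are counted as one; the area column is the only
  hint that a component may contain several fish.
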
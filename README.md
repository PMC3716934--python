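# echocount

Tools for **echo-counting fish surveys** of small inland reservoirs and
aquaculture ponds with a downward-looking single-beam sonar towed along
parallel transects (a lawn-mower pattern). The package answers two
questions:

1. **Survey design** — if the beam cone only ensonifies part of the
   reservoir, how wrong is a total fish count extrapolated from partial
   coverage, and how far apart may transects be?
2. **Echogram analysis** — given a sonar echogram (rows = depth samples,
   columns = pings), find the fish, their depths and their GPS positions.

## The model

The reservoir is a binary occupancy grid `Lo` (1 = fish), in plan view
(`M×N`) or as a volume (`M×N×K`); the sonar sweep is a coverage mask `Lf`.
With `Ls = Lo·Lf` the fish actually ensonified, the package computes

- detected-fish fraction `δf = 100·ΣLs/ΣLo` and covered fraction
  `pf = 100·ΣLf/(M·N)` (volume analogue `pfs`),
- the **coverage error** `δp = |δf − pf|` — the sampling error of treating
  "fraction of area covered" as "fraction of fish seen",
- the extrapolated total `N̂ = ΣLs·(M·N·K)/ΣLf` and its relative error
  `δpa = 100·|N̂ − ΣLo|/ΣLo`.

Fish aggregate into `s` equal-disc clusters whose union occupies a chosen
fraction `ps` of the grid; a seeded Monte-Carlo sweep
(`echocount.montecarlo`) averages `δp`/`δpa` over replicate grids across
`s`, `ps` and coverage targets. A beam with cone angle `α` has footprint
`2·k·tan(α/2)` at depth `k`; the practical spacing rule

```
Tm = 9·k·tan(α/2)
```

gives the largest transect spacing that keeps the ensonified volume
fraction near 10% (for `α = 30°`: 0.24, 2.4 and 7.2 m at depths 0.1, 1
and 3 m).

The detection pipeline (`echocount.detect`) is: 3×3 median filter →
white top-hat with a 40×40 element (background removal) → threshold at
20% of mean brightness → water-column masking between the surface band and
the per-ping bottom line → 8-connected labeling with a minimum area →
depth from the row coordinate (197 px/m at a 10 m range with 1970 rows)
and position by interpolating sparse GPS fixes. A synthetic echogram
generator (`echocount.echogen`) provides scenes with known ground truth,
and an NMEA GGA parser (`echocount.io`) converts raw GPS sentences to
decimal-degree fixes.

## Worked example

```python
import echocount as ec

# survey design: how bad is 30% coverage with 10 clusters on 10% of the area?
cfg = ec.SweepConfig(s_values=[10], ps_values=[0.10], pf_targets=[30.0],
                     iters=500, seed=1)
row = ec.run_sweep(cfg).frame.iloc[0]
print(f"pf={row.pf_realized_mean:.1f}%  mean delta_p={row.metric_mean:.2f}%")
# -> pf=30.0%  mean delta_p=4.33%

print(f"Tm at 1.5 m: {ec.transect_spacing(30, 1.5):.1f} m")
# -> Tm at 1.5 m: 3.6 m

# detection on a synthetic scene with known truth
echo, truth = ec.synthesize_echogram(ec.EchogramSpec(n_fish=10, seed=7,
                                                     min_separation_px=30))
table = ec.detect_fish(echo)
recall, precision = ec.score_detections(truth, table.detections, 10.0)
print(len(table), recall, precision)
# -> 10 1.0 1.0
d = table.detections[0]
print(f"fish 1: depth {d.depth_m:.2f} m at ({d.lat:.5f}, {d.lon:.5f})")
# -> fish 1: depth 0.11 m at (50.00029, 19.00043)
```

The first block says that with ten fish clusters covering 10% of a
200×200-cell pond and transects ensonifying 30% of the surface, the
detected-fish fraction deviates from the covered fraction by 4.3
percentage points on average — the counting error one should expect
before extrapolating. The same commands are available from a shell:
`echocount plan-transects`, `echocount simulate`, `echocount synth`,
`echocount detect`, `echocount score`.

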
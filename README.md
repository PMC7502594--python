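# space-stomata

Spatial point-pattern analysis of stomatal positioning on the leaf
epidermis, built around genetic mosaic experiments: clonal sectors
overexpressing a secreted peptide (an inhibitor such as EPF1, or a promoter
such as Stomagen/EPFL9) perturb stomatal development in the surrounding
tissue, and the question is *over what distance*. Starting from 2D
coordinates exported from confocal segmentation — a cotyledon outline,
sector outlines, and the XY position of every stoma, all in µm — the
package quantifies how stomatal placement deviates from spatial randomness
as a function of distance from a sector.

It is aimed at plant developmental biologists quantifying non-cell-
autonomous signaling ranges, and more generally at anyone comparing a 2D
point pattern against structured reference regions inside an irregular
window.

## The statistics

**Offset-ring densities.** The blade is partitioned into the sector
interior, rings bounded by Euclidean dilations of the sector boundary
(e.g. 0–100 µm, 100–200 µm, or consecutive 50 µm bins out to 400 µm), and
the far remainder; each region's stomatal density is count/area, with
multi-sector blades pooled by union so overlap is never double-counted.

**Stoma–sector correlation.** With `S(r_i)` the number of stomata whose
nearest distance to the sector boundary falls in bin `[r_i, r_{i+1})`, and
`⟨R(r_i)⟩` the mean of the same count over an ensemble (default 1000 sets)
of uniform random points drawn inside the same outline with the same total
count,

    ζ(r_i) = S(r_i) / ⟨R(r_i)⟩ − 1,

the bivariate two-point correlation function (differential form of
Ripley's K). ζ > 0 is an excess of stomata at that distance relative to
random placement, ζ < 0 a deficit; the distance at which ζ decays to 0 is
the *effective range* of the sector's influence. Sectors are filtered by
area (default 15,000–40,000 µm²) and mutual separation (≥ 200 µm) before
analysis; confidence bands come from case-resampling the observed distance
list.

**Stoma–stoma autocorrelation.** The Landy–Szalay pair-count estimator
from galaxy clustering statistics,

    ζ(r_i) = (ss − 2·sr + rr) / rr,

with `ss`, `rr`, `sr` the normalized per-bin histograms of stoma–stoma,
random–random and stoma–random pair distances, reveals intrinsic pattern
structure such as the one-cell spacing rule (a hard floor of ζ = −1 below
the minimum spacing, ~40.9 µm).

**Hypothesis tests.** Stomatal index (100·s/(s+n)) comparisons use a
Pearson χ² test on the 2×2 table; density samples use Mann–Whitney U
(exact for small samples) and Kruskal–Wallis.

A simulator provides cotyledon/sector geometries and reference patterns —
uniform (CSR), clustered (exponential intensity off the sector boundary),
ringed (annuli at 200 µm increments) and hard-core spaced — so the whole
pipeline is testable without microscope data.

## Worked example

`examples/02_sector_correlation.py` builds a synthetic blade with one
20,000 µm² sector, places 400 stomata clustered around it, and runs the
sector correlation against a 200-set CSR ensemble:

```
r_mid (µm)      S      <R>     zeta            95% band
      68.8     37     3.62     9.22  [   6.18,   12.54]
      88.3     35     5.41     5.47  [   3.44,    7.50]
     113.3     39     7.62     4.12  [   2.67,    5.56]
     145.4     21    10.16     1.07  [   0.23,    2.00]
     186.7     15    12.53     0.20  [  -0.36,    0.84]
     239.6      8    15.97    -0.50  [  -0.81,   -0.12]
     307.5      4    21.02    -0.81  [  -0.95,   -0.62]
     394.7      0    27.21    -1.00  [  -1.00,   -1.00]
```

At ~69 µm from the sector there are 37 stomata where random placement
predicts 3.6 — a ζ of 9.2, a ten-fold excess. ζ crosses 0 near 190 µm: the
clustering is confined to that range. The other examples cover ring
densities, the hard-core autocorrelation signature, geometric-sector
controls, and the hypothesis tests, each printing a short annotated table.

A thin CLI wraps the same functions, e.g.

```sh
space simulate --kind clustered --n 400 --seed 1 --out demo_map/
space correlate demo_map/ --n-random 200 --seed 2 --out corr.csv
space density demo_map/ --boundaries 100,200 --out density.csv
```

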
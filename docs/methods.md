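# Methods

## Problem and data model

A cotyledon (seed leaf) epidermis is treated as a bounded 2D window — a
simple polygon digitized from a tile-scanned confocal image — containing a
point pattern (stomata centres) and zero or more interior reference
polygons (clonal mosaic sectors). All coordinates are micrometres; the
analysis is strictly planar. Leaf curvature is not corrected: inputs are
assumed to be flattened projections, which is adequate for young
cotyledons and consistent with how such coordinates are exported from
segmentation software. Z coordinates, if present in input files, are
dropped with a warning.

The interchange schema is one directory per cotyledon with
`cotyledon.csv`, `sector_<k>.csv`, `stomata.csv` (header `x_um,y_um`; row
order is vertex order) and a small YAML/JSON manifest carrying a free-text
label. This decouples the pipeline from any particular segmentation
package's export format.

## Geometric conventions

* Outlines are simple closed rings, normalized counter-clockwise; the
  closing vertex is stored once.
* A point exactly on a boundary counts as **inside**. When a stoma sits on
  a boundary shared by two partition regions, the innermost region wins.
  Both rules are arbitrary tie-breaks chosen for determinism; they affect
  only measure-zero configurations of real data.
* Distances from a point to an outline are minimized over boundary
  *segments*, never over sampled vertices — vertex-only distances
  overestimate and depend on digitization density.
* "Expanding" a sector by `d` is a true Euclidean (Minkowski-disk)
  dilation, implemented with polygon buffering at 64 segments per full
  circle (configurable). This guarantees that every point of the offset
  ring is within `d` of the sector boundary, which a radial per-vertex
  shift does not for concave outlines. For convex, roughly isotropic
  sectors the two constructions nearly coincide.

## Region partition and density

Given offsets `b_1 < b_2 < …`, the blade is partitioned into the union of
sector interiors, rings `dilate(b_k) \ dilate(b_{k−1})` (minus sector
interiors, clipped to the blade, unioned across sectors so overlapping
dilations are counted once), and the remainder. Stomata are assigned by
their distance to the sector boundary, which makes count conservation
exact by construction; region areas are exact polygon areas, and the
partition areas sum to the blade area to polygon tolerance. Densities are
per µm² internally, reported per mm² in tables. Multi-sector blades pool
counts and areas *before* dividing, so each cotyledon contributes a single
sample point per region.

## Null ensembles

Complete spatial randomness (CSR) inside the blade is the null model.
Each null set matches the observed stoma count exactly and is drawn by
rejection from the bounding rectangle, generating five times the deficit
per round and topping up until full (the top-up guarantees exact counts
for arbitrarily thin outlines). One master seed spawns per-set child
seeds via `numpy` seed sequences: ensembles are reproducible and sets are
independent. The default ensemble size is 1000 sets.

## Correlation estimators

**Sector mode.** `ζ(r_i) = S(r_i)/⟨R(r_i)⟩ − 1`, with distances binned
logarithmically (default 24 bins over 5–2000 µm, configurable). Stomata
inside a sector are excluded from `S`; random points inside a sector are
excluded from `R` symmetrically — without this the near-boundary bins
would be biased negative by construction. For multiple retained sectors
the distance is the minimum over sectors. Bins with `⟨R⟩ < 1e−12` are
reported as NaN (undefined) rather than ±∞. Sector admission uses an
area window of 15,000–40,000 µm² (upper bound removable) and a 200 µm
minimum boundary-to-boundary separation, both members of a violating pair
being dropped, to avoid size artefacts and cross-talk between nearby
sectors.

**Auto mode.** The Landy–Szalay estimator
`ζ = (ss − 2·sr + rr)/rr`, where `ss = SS/[n(n−1)/2]`,
`rr = ⟨RR⟩/[n(n−1)/2]`, `sr = ⟨SR⟩/n²` are normalized pair-distance
histograms (unordered within-set pairs; ordered cross pairs), ensemble
averaged. Two estimator facts worth knowing: (i) if the "random" sets are
literally the data, ζ collapses to exactly `2/n` per populated bin, not
0, because the cross histogram sees each unordered pair twice among `n²`
ordered pairs; (ii) in bins where `ss = 0`, ζ = 1 − 2·sr/rr can undershoot
−1 by estimator noise. The sector-mode ζ, by contrast, is bounded below by
−1 wherever defined.

**Confidence bands.** 95% percentile bootstrap, case-resampling the
observed stoma–sector distance list with replacement (same N) and
recomputing ζ against the *fixed* ensemble expectation. This measures the
sampling noise of the observed pattern, not of the null ensemble (which
is already averaged over many sets); resampling schemes conditioning on
the ensemble were the open alternative, and the case-resampling choice is
the package's own. Band width scales as `1/√N`.

**Pooling.** Per-genotype curves sum `S` and `⟨R⟩` across cotyledons
before forming ζ, weighting each blade by its stoma count; pooled bands
are recomputed from the concatenated distance list. Doubling the data
narrows the band by about `1/√2`.

## Hypothesis tests

* Stomatal index: `100·s/(s+n)` percent.
* 2×2 χ²: Pearson statistic via the closed form
  `n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]`, df = 1, **no** continuity
  correction (the aggregated counts involved are large; the test is
  cross-checked against `scipy.stats.chi2_contingency` in the suite).
  Zero margins raise.
* Mann–Whitney U: exact enumeration when the combined sample size is ≤ 20
  and tie-free (density samples are typically 6–10 cotyledons per group,
  where exactness matters), otherwise the tie-corrected normal
  approximation with continuity correction; two-sided.
* Kruskal–Wallis: tie-corrected H with the χ² approximation, df = k−1;
  an all-constant input returns H = 0, p = 1.

Calibration checks in the suite drive all three with 10⁴ null simulations
(binomial counts of 150 cells per group at index 30% for χ²; normal
samples of 12 per group for U; three groups of 10 for H) and require the
empirical type-I error at α = 0.05 to lie in [0.04, 0.06].

## Synthetic data

The generator exists so every stage is testable without microscope data;
its defaults emulate the measured scales of the real system.

* **Blade**: ellipse-like polygon, default 2000 × 1200 µm (area ≈ 1.9 mm²,
  a 7-day cotyledon scale), radii modulated by a few percent at low
  angular frequency.
* **Sector**: star-shaped polygon with smoothly perturbed radii, rescaled
  to an exact area target (defaults sit inside the 15,000–40,000 µm²
  filter window), placed uniformly at random fully inside the blade.
* **Patterns** (all exactly `n` points, default 500, inside the blade):
  `uniform` CSR; `clustered` with acceptance probability `exp(−d/λ)` in
  distance `d` from the sector boundary, default λ = 50 µm (the
  functional form is a package choice — the phenomenon emulated is
  aggregation near a stomata-promoting sector, and points are placed
  outside the sector interior since interior stomata are excluded from
  the estimator anyway); `ringed` with points uniform in annuli of width
  40 µm centred at successive multiples of 200 µm from the sector
  boundary, equal allocation per ring; `spaced` by simple sequential
  inhibition with a hard-core distance defaulting to 40.9 µm, the
  measured mean one-cell spacing between stomata. The spaced pattern
  emulates the spacing rule's second-order signature only — it is not a
  model of the developmental process.

What the synthetic data does **not** reproduce: cell-size granularity
(stomata occupy ~22 × 15 µm, not points), anisotropy of the epidermis,
blade-margin effects, measurement noise in segmentation, or biological
clustering beyond the imposed intensity forms. Passing tests therefore
demonstrate estimator correctness and sensitivity on known ground truth,
not biological conclusions about real cotyledons.

## Validation design and problem sizes

The suite checks the estimators against from-scratch double-loop oracles
(exact on ≤ 20 points and ≤ 3 random sets), geometry against closed forms
(square Minkowski dilation `s² + 4sd + πd²`), Monte-Carlo area
integration (10⁶ points), and brute-force ray-casting / per-segment
distance oracles (10⁴ queries). CSR null flatness uses 50 replicate
patterns of n = 500 against 200-set ensembles, requiring |mean ζ| < 3·SE
in every bin with expected count ≥ 20, for both estimators. Pattern
signatures use sign tests over 20 seeds (≥ 16 successes, coin-flip
p < 0.01): clustered ⇒ ζ > 0 in the nearest populated bin; ringed ⇒ at
least two sign changes of ζ below 600 µm, analyzed at 36 log bins so the
bin width near 200–600 µm resolves the 40 µm annuli. The acceptance
script runs scaled-down versions of the same computations (20 CSR
replicates with 100-set ensembles, 10 signature seeds, 3000 calibration
simulations per test) — sizes chosen to keep a single-CPU run at a few
minutes while leaving Monte-Carlo error well inside the decision margins.

## Known limitations

* No edge-corrected Ripley's K/L variants: the ensemble construction
  already conditions on the true window, which is the appropriate
  correction here, but it costs ensemble-size × distance computations.
* The bootstrap band reflects distance-resampling only; uncertainty in
  the sector outline itself (segmentation error) is not propagated.
* Cell-adjacency analyses ("one cell away" classifications) require cell
  outlines, which are not part of the coordinate schema; such counts
  enter only as user-supplied contingency tables.
* Dilation is polygonized (64 segments/circle); closed-form area
  comparisons are accurate to ~0.1–0.5%, configurable upward.
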
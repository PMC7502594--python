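"""Spatial correlation estimators for stomatal patterning.

Two estimators, both referenced to a complete-spatial-randomness (CSR)
ensemble drawn inside the same cotyledon outline with the same point count
as the observed stomata:

**Stoma–sector correlation** (a bivariate two-point correlation function,
equivalently the differential form of Ripley's K):

    zeta(r_i) = S(r_i) / <R(r_i)> - 1

where ``S(r_i)`` counts stomata whose nearest distance to the (filtered)
sector boundary falls in bin ``[r_i, r_{i+1})``, and ``<R(r_i)>`` is the
ensemble mean of the same count over the random sets.  Stomata inside a
sector are excluded; random points inside a sector are excluded
symmetrically.  ``zeta > 0`` means an excess of stomata at that distance
relative to random placement, ``zeta < 0`` a deficit; ``zeta >= -1`` always.

**Stoma–stoma autocorrelation** (Landy–Szalay estimator, the low-bias /
low-variance pair-count estimator from galaxy clustering statistics):

    zeta(r_i) = (ss - 2*sr + rr) / rr

with ``ss = SS(r_i)/N_SS``, ``rr = <RR(r_i)>/N_RR``, ``sr = <SR(r_i)>/N_SR``
— normalized pair-distance histograms of stoma–stoma, random–random (within
one set), and stoma–random pairs, ensemble-averaged.

Distances are binned logarithmically (default 24 bins over 5–2000 µm).
Bins where the random expectation vanishes are reported as NaN rather than
±inf.  Confidence bands come from case-resampling the observed distance
list against the fixed random expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from shapely.ops import unary_union

from .geometry import Outline, boundary_distances, points_in_geometry
from .io_formats import CotyledonMap
from .sampling import RandomEnsemble

__all__ = [
    "SectorFilter",
    "CorrelationFunction",
    "log_bins",
    "filter_sectors",
    "stoma_sector_distances",
    "sector_correlation",
    "stomata_autocorrelation",
    "bootstrap_ci",
    "pool_cotyledons",
]

#: bins with <R> below this are flagged undefined instead of dividing
R_EPS = 1e-12


def log_bins(r_min: float = 5.0, r_max: float = 2000.0, n_bins: int = 24) -> np.ndarray:
    """Logarithmically spaced bin edges (length ``n_bins + 1``), in µm."""
    if not (0 < r_min < r_max) or n_bins < 1:
        raise ValueError("need 0 < r_min < r_max and n_bins >= 1")
    return np.geomspace(r_min, r_max, n_bins + 1)


@dataclass(frozen=True)
class SectorFilter:
    """Sector admission rules for correlation analysis.

    Sectors must have area within ``[area_min, area_max]`` (``area_max=None``
    disables the upper bound) and be at least ``min_separation`` apart
    boundary-to-boundary; both members of a too-close pair are dropped.
    Defaults: 15,000–40,000 µm² and 200 µm.
    """

    area_min: float = 15_000.0
    area_max: float | None = 40_000.0
    min_separation: float = 200.0

    def __post_init__(self) -> None:
        if self.area_max is not None and not (self.area_min < self.area_max):
            raise ValueError("area_min must be < area_max")


@dataclass
class CorrelationFunction:
    """Binned correlation estimates with the counts that produced them.

    ``S`` and ``R_expected`` are the per-bin observed count and ensemble-mean
    random count (sector mode) or the normalized ``ss`` and ``rr`` ingredients
    (auto mode, where ``SS``/``RR``/``SR`` hold the normalized histograms).
    ``zeta`` is NaN where the random expectation vanishes; ``defined`` marks
    usable bins.
    """

    bin_edges: np.ndarray
    S: np.ndarray
    R_expected: np.ndarray
    zeta: np.ndarray
    kind: str = "sector"  # "sector" | "auto"
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    SS: np.ndarray | None = None
    RR: np.ndarray | None = None
    SR: np.ndarray | None = None
    n_stomata: int = 0
    distances: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def r_mid(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.zeta)


def filter_sectors(m: CotyledonMap, f: SectorFilter | None = None) -> list[Outline]:
    """Sectors passing the area window and mutual-separation rule.

    Separation is checked among the sectors that pass the area filter; both
    sectors of a pair closer than ``min_separation`` are removed.
    """
    f = f or SectorFilter()
    by_area = [
        s
        for s in m.sectors
        if s.area >= f.area_min and (f.area_max is None or s.area <= f.area_max)
    ]
    if len(by_area) <= 1:
        return by_area
    drop = set()
    for i in range(len(by_area)):
        for j in range(i + 1, len(by_area)):
            if by_area[i].polygon.distance(by_area[j].polygon) < f.min_separation:
                drop.update((i, j))
    return [s for k, s in enumerate(by_area) if k not in drop]


def _sector_distance_set(xy: np.ndarray, sector_geom) -> np.ndarray:
    """Nearest boundary distances for points outside the sectors; interior points dropped."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        return np.empty(0)
    outside = ~points_in_geometry(xy, sector_geom)
    return boundary_distances(xy[outside], sector_geom)


def stoma_sector_distances(m: CotyledonMap, sectors: Sequence[Outline]) -> np.ndarray:
    """Nearest distance from each stoma to the retained sector boundaries.

    Stomata inside any retained sector are excluded; for the rest, the
    distance is the minimum over all retained sectors.
    """
    if not sectors:
        raise ValueError("no retained sectors")
    geom = unary_union([s.polygon for s in sectors])
    return _sector_distance_set(m.stomata, geom)


def sector_correlation(
    m: CotyledonMap,
    sectors: Sequence[Outline],
    ensemble: RandomEnsemble,
    bins: np.ndarray | None = None,
) -> CorrelationFunction:
    """Stoma–sector correlation ``zeta(r) = S(r)/<R(r)> - 1`` against a CSR ensemble.

    The ensemble must be drawn in the same cotyledon with set size equal to
    the total stoma count.  Random points inside sectors are excluded from
    the R counts exactly as stomata are from S.
    """
    if not sectors:
        raise ValueError("no retained sectors")
    bins = log_bins() if bins is None else np.asarray(bins, dtype=float)
    geom = unary_union([s.polygon for s in sectors])

    d_s = _sector_distance_set(m.stomata, geom)
    S, _ = np.histogram(d_s, bins=bins)

    R_tot = np.zeros(len(bins) - 1)
    for pts in ensemble.sets:
        d_r = _sector_distance_set(pts, geom)
        h, _ = np.histogram(d_r, bins=bins)
        R_tot += h
    R_mean = R_tot / ensemble.n_sets

    zeta = np.full(len(bins) - 1, np.nan)
    ok = R_mean > R_EPS
    zeta[ok] = S[ok] / R_mean[ok] - 1.0
    return CorrelationFunction(
        bin_edges=bins,
        S=S.astype(float),
        R_expected=R_mean,
        zeta=zeta,
        kind="sector",
        n_stomata=m.n_stomata,
        distances=d_s,
    )


def _pair_hist(xy: np.ndarray, bins: np.ndarray) -> np.ndarray:
    return np.histogram(pdist(xy), bins=bins)[0].astype(float)


def stomata_autocorrelation(
    m: CotyledonMap,
    ensemble: RandomEnsemble,
    bins: np.ndarray | None = None,
) -> CorrelationFunction:
    """Landy–Szalay stoma–stoma autocorrelation against a CSR ensemble.

    ``SS`` counts unordered stoma pairs, ``RR`` unordered pairs within each
    random set, ``SR`` stoma–random cross pairs within each set; each is
    normalized by its total pair count and ``RR``/``SR`` are ensemble
    averages.  Bins with vanishing ``rr`` are NaN.
    """
    xy = m.stomata
    n = len(xy)
    if n < 2:
        raise ValueError("autocorrelation requires at least 2 stomata")
    bins = log_bins() if bins is None else np.asarray(bins, dtype=float)
    nb = len(bins) - 1

    n_ss = n * (n - 1) / 2.0
    ss = _pair_hist(xy, bins) / n_ss

    rr_sum = np.zeros(nb)
    sr_sum = np.zeros(nb)
    for pts in ensemble.sets:
        nr = len(pts)
        rr_sum += _pair_hist(pts, bins) / (nr * (nr - 1) / 2.0)
        sr_sum += np.histogram(cdist(xy, pts).ravel(), bins=bins)[0] / (n * nr)
    rr = rr_sum / ensemble.n_sets
    sr = sr_sum / ensemble.n_sets

    zeta = np.full(nb, np.nan)
    ok = rr > R_EPS
    zeta[ok] = (ss[ok] - 2.0 * sr[ok] + rr[ok]) / rr[ok]
    return CorrelationFunction(
        bin_edges=bins,
        S=ss,
        R_expected=rr,
        zeta=zeta,
        kind="auto",
        SS=ss,
        RR=rr,
        SR=sr,
        n_stomata=n,
    )


def bootstrap_ci(
    distances: np.ndarray,
    R_expected: np.ndarray,
    bins: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap band for the stoma–sector ``zeta``.

    Case-resamples the observed distance list with replacement (same length)
    and recomputes ``zeta`` against the *fixed* random expectation, so the
    band reflects sampling noise of the observed pattern, not of the null
    ensemble.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    distances = np.asarray(distances, dtype=float)
    R_expected = np.asarray(R_expected, dtype=float)
    rng = np.random.default_rng(seed)
    nb = len(bins) - 1
    ok = R_expected > R_EPS
    zetas = np.full((n_boot, nb), np.nan)
    nd = len(distances)
    for b in range(n_boot):
        res = distances[rng.integers(0, nd, size=nd)] if nd else distances
        h, _ = np.histogram(res, bins=bins)
        zetas[b, ok] = h[ok] / R_expected[ok] - 1.0
    alpha = (1.0 - level) / 2.0
    lo = np.full(nb, np.nan)
    hi = np.full(nb, np.nan)
    if ok.any():
        lo[ok] = np.percentile(zetas[:, ok], 100 * alpha, axis=0)
        hi[ok] = np.percentile(zetas[:, ok], 100 * (1 - alpha), axis=0)
    return lo, hi


def with_bootstrap_ci(
    cf: CorrelationFunction, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> CorrelationFunction:
    """Return a copy of a sector-mode correlation function with bootstrap bands attached."""
    if cf.kind != "sector" or cf.distances is None:
        raise ValueError("bootstrap bands require a sector-mode correlation with stored distances")
    lo, hi = bootstrap_ci(cf.distances, cf.R_expected, cf.bin_edges, n_boot=n_boot, level=level, seed=seed)
    cf.ci_lo, cf.ci_hi = lo, hi
    return cf


def pool_cotyledons(
    cfs: Sequence[CorrelationFunction],
    n_boot: int = 0,
    level: float = 0.95,
    seed: int = 0,
) -> CorrelationFunction:
    """Pool per-cotyledon sector correlations into one genotype-level curve.

    Observed counts ``S`` and random expectations ``<R>`` are summed across
    cotyledons before forming ``zeta``, which weights each cotyledon by its
    stoma count.  All inputs must share identical bin edges.  With
    ``n_boot > 0`` a bootstrap band is recomputed from the pooled distance
    list against the pooled expectation.
    """
    if not cfs:
        raise ValueError("nothing to pool")
    edges = cfs[0].bin_edges
    for cf in cfs[1:]:
        if cf.n_bins != cfs[0].n_bins or not np.allclose(cf.bin_edges, edges):
            raise ValueError("mismatched bin edges")
    if any(cf.kind != "sector" for cf in cfs):
        raise ValueError("pooling is defined for sector-mode correlation functions")

    S = np.sum([cf.S for cf in cfs], axis=0)
    R = np.sum([cf.R_expected for cf in cfs], axis=0)
    zeta = np.full(len(edges) - 1, np.nan)
    ok = R > R_EPS
    zeta[ok] = S[ok] / R[ok] - 1.0
    dists = (
        np.concatenate([cf.distances for cf in cfs])
        if all(cf.distances is not None for cf in cfs)
        else None
    )
    pooled = CorrelationFunction(
        bin_edges=edges,
        S=S,
        R_expected=R,
        zeta=zeta,
        kind="sector",
        n_stomata=int(sum(cf.n_stomata for cf in cfs)),
        distances=dists,
    )
    if n_boot and dists is not None:
        pooled.ci_lo, pooled.ci_hi = bootstrap_ci(dists, R, edges, n_boot=n_boot, level=level, seed=seed)
    return pooled
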
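"""Synthetic cotyledon geometries and reference stomatal patterns.

Generators for everything needed to exercise the analysis pipeline without
microscope data: an ellipse-like cotyledon blade, irregular cell-cluster
sector outlines, and four reference point patterns with known spatial
signatures relative to a sector —

* ``uniform``   — complete spatial randomness over the blade (null);
* ``clustered`` — intensity decaying exponentially with distance from the
  sector boundary (aggregation near the sector, as around a
  stomagen-overexpressing sector);
* ``ringed``    — points confined to thin annuli at successive multiples of
  a ring spacing from the sector (an oscillating correlation);
* ``spaced``    — sequential-inhibition CSR with a hard-core minimum
  pairwise distance, emulating the one-cell spacing rule (default 40.9 µm,
  a measured mean one-cell spacing).

Every generated point lies inside the cotyledon outline; all generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .geometry import Outline, PlacementError, boundary_distances, points_in_geometry
from .sampling import _uniform_points_rng

__all__ = ["SyntheticPatternSpec", "synth_cotyledon", "synth_sector", "generate_pattern", "PATTERN_KINDS"]

PATTERN_KINDS = ("uniform", "clustered", "ringed", "spaced")

#: measured mean one-cell spacing between stomata, µm
DEFAULT_HARDCORE_UM = 40.9


@dataclass(frozen=True)
class SyntheticPatternSpec:
    """Parameters of a reference pattern generator."""

    kind: str = "uniform"
    n: int = 500
    ring_spacing: float = 200.0  # µm, centre-to-centre annulus spacing
    ring_width: float = 40.0  # µm
    decay_scale: float = 50.0  # µm, e-folding scale of the clustered intensity
    hardcore_distance: float = DEFAULT_HARDCORE_UM  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"kind must be one of {PATTERN_KINDS}, got {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("ring_spacing", "ring_width", "decay_scale", "hardcore_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def synth_cotyledon(width: float = 2000.0, height: float = 1200.0, n_vertices: int = 64, seed: int = 0) -> Outline:
    """A smooth convex ellipse-like polygon approximating a cotyledon blade.

    Radii are gently modulated (a few percent, low angular frequency) so the
    outline is organic rather than a perfect ellipse; area stays within ~2%
    of the ellipse closed form pi*(w/2)*(h/2).
    """
    if width <= 0 or height <= 0:
        raise ValueError("dimensions must be positive")
    if n_vertices < 8:
        raise ValueError("n_vertices must be >= 8")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    mod = 1.0 + 0.015 * np.sin(2 * theta + phase[0]) + 0.01 * np.sin(3 * theta + phase[1])
    x = 0.5 * width * mod * np.cos(theta)
    y = 0.5 * height * mod * np.sin(theta)
    return Outline(np.column_stack([x, y]))


def synth_sector(
    area_target: float,
    cotyledon: Outline,
    seed: int = 0,
    n_vertices: int = 24,
    max_attempts: int = 200,
) -> Outline:
    """An irregular, cell-cluster-like simple polygon inside the cotyledon.

    A star-shaped polygon with smoothly perturbed radii, rescaled so its
    area matches ``area_target`` to well within 10%, placed at a random
    interior position.  Retries placement until the sector is fully inside
    the cotyledon.
    """
    if area_target >= 0.5 * cotyledon.area:
        raise ValueError("area_target must be well below the cotyledon area")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = cotyledon.bounds
    base_r = np.sqrt(area_target / np.pi)
    cot_poly = cotyledon.polygon
    for _ in range(max_attempts):
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        # low-frequency radial noise keeps the ring simple (star-shaped)
        wobble = (
            1.0
            + 0.25 * np.sin(2 * theta + rng.uniform(0, 2 * np.pi))
            + 0.15 * np.sin(3 * theta + rng.uniform(0, 2 * np.pi))
            + 0.08 * np.sin(5 * theta + rng.uniform(0, 2 * np.pi))
        )
        r = base_r * wobble
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        raw_area = Polygon(xy).area
        xy *= np.sqrt(area_target / raw_area)
        cx = rng.uniform(minx + base_r, maxx - base_r)
        cy = rng.uniform(miny + base_r, maxy - base_r)
        cand = xy + np.array([cx, cy])
        if cot_poly.covers(Polygon(cand)):
            return Outline(cand)
    raise PlacementError(f"could not place sector inside cotyledon in {max_attempts} attempts")


def generate_pattern(
    spec: SyntheticPatternSpec,
    cotyledon: Outline,
    sector: Outline | None = None,
) -> np.ndarray:
    """Generate exactly ``spec.n`` points of the requested reference pattern.

    ``clustered`` and ``ringed`` require a sector; ``spaced`` raises a
    :class:`PlacementError` if the hard-core constraint cannot be packed at
    the requested ``n``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "uniform":
        return _uniform_points_rng(spec.n, cotyledon, rng)
    if spec.kind == "spaced":
        return _spaced(spec, cotyledon, rng)
    if sector is None:
        raise ValueError(f"{spec.kind!r} pattern requires a sector outline")
    if spec.kind == "clustered":
        return _clustered(spec, cotyledon, sector, rng)
    return _ringed(spec, cotyledon, sector, rng)


def _clustered(spec, cotyledon, sector, rng) -> np.ndarray:
    """Rejection sampling with acceptance exp(-d/decay) outside the sector."""
    sector_poly = sector.polygon
    out: list[np.ndarray] = []
    have = 0
    while have < spec.n:
        cand = _uniform_points_rng(4 * (spec.n - have), cotyledon, rng)
        cand = cand[~points_in_geometry(cand, sector_poly)]
        if len(cand) == 0:
            continue
        d = boundary_distances(cand, sector_poly)
        keep = cand[rng.random(len(cand)) < np.exp(-d / spec.decay_scale)]
        out.append(keep)
        have += len(keep)
    return np.concatenate(out)[: spec.n]


def _ringed(spec, cotyledon, sector, rng) -> np.ndarray:
    """Uniform points within annuli centred at k*ring_spacing from the sector boundary."""
    sector_poly = sector.polygon
    # how far out can a ring centre sit and still intersect the blade?
    probe = _uniform_points_rng(2000, cotyledon, rng)
    probe = probe[~points_in_geometry(probe, sector_poly)]
    d_max = float(boundary_distances(probe, sector_poly).max())
    n_rings = max(1, int(d_max // spec.ring_spacing))
    per_ring = np.full(n_rings, spec.n // n_rings)
    per_ring[: spec.n % n_rings] += 1

    half_w = spec.ring_width / 2.0
    pts: list[np.ndarray] = []
    for k in range(1, n_rings + 1):
        lo, hi = k * spec.ring_spacing - half_w, k * spec.ring_spacing + half_w
        need = int(per_ring[k - 1])
        got: list[np.ndarray] = []
        have = 0
        attempts = 0
        while have < need:
            cand = _uniform_points_rng(20 * max(need - have, 50), cotyledon, rng)
            cand = cand[~points_in_geometry(cand, sector_poly)]
            d = boundary_distances(cand, sector_poly)
            keep = cand[(d >= lo) & (d <= hi)]
            got.append(keep)
            have += len(keep)
            attempts += 1
            if attempts > 200:
                raise PlacementError(f"ring {k} ({lo:g}-{hi:g} µm) cannot be populated inside the blade")
        pts.append(np.concatenate(got)[:need])
    return np.concatenate(pts)


def _spaced(spec, cotyledon, rng) -> np.ndarray:
    """Simple sequential inhibition (dart throwing) with a hard-core distance."""
    h2 = spec.hardcore_distance**2
    placed = np.empty((spec.n, 2))
    count = 0
    attempts = 0
    max_attempts = 200 * spec.n
    while count < spec.n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {count}/{spec.n} points at hard-core {spec.hardcore_distance} µm"
            )
        cand = _uniform_points_rng(1, cotyledon, rng)[0]
        attempts += 1
        if count:
            diff = placed[:count] - cand
            if np.min(np.einsum("ij,ij->i", diff, diff)) < h2:
                continue
        placed[count] = cand
        count += 1
    return placed
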
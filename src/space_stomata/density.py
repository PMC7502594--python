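"""Region-based stomatal density: sector interiors, offset rings, and the rest.

The cotyledon is partitioned into (i) the union of sector interiors, (ii) a
sequence of offset rings bounded by Euclidean dilations of the sectors at
increasing distances (each ring excludes the sector interiors, inner rings,
and any area beyond the cotyledon), and (iii) the far remainder of the
blade.  Stomata are assigned to exactly one part — a stoma on a shared
boundary goes to the innermost part — so counts over the partition always
sum to the cotyledon total.  Densities are per µm² internally with a per-mm²
convenience scaling for tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.ops import unary_union

from .geometry import Region, boundary_distances, clip_subtract, points_in_geometry, union_regions
from .io_formats import CotyledonMap

__all__ = ["DensityResult", "RegionPartition", "partition_cotyledon", "count_in_region", "assign_partition", "density_table"]


@dataclass(frozen=True)
class DensityResult:
    """One (region, count, area, density) accounting row."""

    label: str
    stoma_count: int
    area: float  # µm²
    cotyledon_label: str = ""

    @property
    def density(self) -> float:
        """Stomata per µm²."""
        return self.stoma_count / self.area if self.area > 0 else float("nan")

    @property
    def density_per_mm2(self) -> float:
        return self.density * 1e6


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint decomposition of a cotyledon around its sectors."""

    sector_region: Region
    ring_regions: list[tuple[float, float, Region]]  # (r_in, r_out, region)
    far_region: Region

    def regions(self) -> list[tuple[str, Region]]:
        out = [("sector", self.sector_region)]
        out += [(f"{int(a)}-{int(b)} um", r) for a, b, r in self.ring_regions]
        out.append(("rest", self.far_region))
        return out


def partition_cotyledon(m: CotyledonMap, boundaries: Sequence[float]) -> RegionPartition:
    """Partition the cotyledon into sector / offset-ring / far regions.

    ``boundaries`` are strictly increasing positive offsets from the sector
    boundary (e.g. ``[100, 200]`` or ``range(50, 401, 50)``).  With an empty
    boundary list the partition is a two-way sector/rest split.  Ring ``k``
    is the union over sectors of the dilation at ``b_k`` minus the dilation
    at ``b_{k-1}``, minus the sector interiors, clipped to the cotyledon —
    overlapping dilations of nearby sectors are counted once.
    """
    if not m.sectors:
        raise ValueError("partition requires at least one sector outline")
    b = [float(x) for x in boundaries]
    if any(x <= 0 for x in b) or any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
        raise ValueError("boundaries must be strictly increasing and positive")

    cot = m.cotyledon
    sector_union = Region(unary_union([s.polygon for s in m.sectors]))
    sector_region = clip_subtract(sector_union, cot)

    rings: list[tuple[float, float, Region]] = []
    prev = sector_union
    prev_d = 0.0
    for d in b:
        dil = Region(sector_union.geom.buffer(d, quad_segs=16))
        ring = clip_subtract(dil, cot, [prev, sector_region])
        rings.append((prev_d, d, ring))
        prev, prev_d = dil, d

    removed = [sector_region] + [r for _, _, r in rings]
    far = clip_subtract(Region(cot.polygon), cot, removed)
    return RegionPartition(sector_region=sector_region, ring_regions=rings, far_region=far)


def count_in_region(stomata: np.ndarray, region: Region) -> int:
    """Number of points in the closed region (boundary counts as inside)."""
    stomata = np.asarray(stomata, dtype=float).reshape(-1, 2)
    if len(stomata) == 0 or region.is_empty:
        return 0
    return int(region.contains_points(stomata).sum())


def assign_partition(m: CotyledonMap, boundaries: Sequence[float]) -> np.ndarray:
    """Assign each stoma to one partition part by distance to the sector boundary.

    Returns an integer label per stoma: 0 = sector interior, 1..k = ring
    index, k+1 = far region.  A stoma exactly on a shared boundary gets the
    innermost part, and every stoma gets exactly one label, so counts are
    conserved by construction.
    """
    if not m.sectors:
        raise ValueError("partition requires at least one sector outline")
    b = np.asarray(list(boundaries), dtype=float)
    sector_geom = unary_union([s.polygon for s in m.sectors])
    labels = np.full(m.n_stomata, len(b) + 1, dtype=int)
    if m.n_stomata == 0:
        return labels
    inside = points_in_geometry(m.stomata, sector_geom)
    labels[inside] = 0
    if len(b):
        d = boundary_distances(m.stomata, sector_geom)
        ring_idx = np.searchsorted(b, d[~inside], side="left") + 1
        labels[~inside] = np.where(ring_idx <= len(b), ring_idx, len(b) + 1)
    return labels


def density_table(
    maps: Sequence[CotyledonMap], boundaries: Sequence[float]
) -> list[DensityResult]:
    """Per-cotyledon, per-region density rows.

    For a cotyledon with several sectors, counts and areas are aggregated
    over the (union) sector and ring regions before dividing, so each
    cotyledon contributes one sample point per region.
    """
    rows: list[DensityResult] = []
    for m in maps:
        part = partition_cotyledon(m, boundaries)
        labels = assign_partition(m, boundaries)
        for idx, (name, region) in enumerate(part.regions()):
            rows.append(
                DensityResult(
                    label=name,
                    stoma_count=int((labels == idx).sum()),
                    area=region.area,
                    cotyledon_label=m.label,
                )
            )
    return rows
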
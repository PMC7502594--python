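"""Complete-spatial-randomness null point generation inside a cotyledon outline.

The null hypothesis for every correlation estimate is that stomata are
placed uniformly at random over the cotyledon blade.  Null sets ("dummy
stomata") match the observed stoma count exactly and are drawn by rejection
sampling from the outline's bounding rectangle: each round draws five times
the remaining deficit, keeps the points falling inside the outline, and
repeats until the set is full.  One master seed deterministically spawns
per-set child seeds, so ensembles are reproducible and sets are independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import InvalidGeometryError, Outline, points_in_geometry

__all__ = ["RandomEnsemble", "generate_uniform_points", "generate_ensemble"]

OVERSAMPLE_FACTOR = 5


@dataclass(frozen=True)
class RandomEnsemble:
    """A reproducible collection of equally sized CSR point sets in one outline."""

    sets: list[np.ndarray]  # each (n, 2)
    seed: int

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_points(self) -> int:
        return len(self.sets[0]) if self.sets else 0


def _uniform_points_rng(n: int, outline: Outline, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = outline.bounds
    poly = outline.polygon
    kept: list[np.ndarray] = []
    have = 0
    while have < n:
        m = OVERSAMPLE_FACTOR * (n - have)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, size=m), rng.uniform(miny, maxy, size=m)]
        )
        inside = cand[points_in_geometry(cand, poly)]
        kept.append(inside)
        have += len(inside)
    return np.concatenate(kept)[:n]


def generate_uniform_points(n: int, cotyledon: Outline, seed: int) -> np.ndarray:
    """Draw exactly ``n`` uniform points inside the outline; deterministic given ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if cotyledon.area <= 0:
        raise InvalidGeometryError("outline has zero area")
    return _uniform_points_rng(n, cotyledon, np.random.default_rng(seed))


def generate_ensemble(n: int, cotyledon: Outline, n_sets: int, seed: int) -> RandomEnsemble:
    """Generate ``n_sets`` independent CSR sets of size ``n`` from one master seed."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if cotyledon.area <= 0:
        raise InvalidGeometryError("outline has zero area")
    children = np.random.SeedSequence(seed).spawn(n_sets)
    sets = [_uniform_points_rng(n, cotyledon, np.random.default_rng(c)) for c in children]
    return RandomEnsemble(sets=sets, seed=seed)
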
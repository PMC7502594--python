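"""Coordinate interchange and result tables.

One directory per cotyledon:

* ``cotyledon.csv`` — the cotyledon outline, header ``x_um,y_um``, one vertex
  per row, row order = ring order;
* ``sector_1.csv``, ``sector_2.csv``, ... — sector outlines, same schema;
* ``stomata.csv`` — one stoma centre per row, same header;
* ``manifest.yaml`` (or ``.json``) — free-text ``label`` (genotype /
  sector type) and optional provenance fields.

Coordinates are micrometres.  A ``z_um`` column, if present (3D segmentation
exports), is dropped with a warning — analysis is strictly two-dimensional.
Result tables (density rows, correlation functions) are written as plain CSV.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import Outline, point_in_polygon

__all__ = ["CotyledonMap", "MapValidationError", "read_cotyledon_map", "write_cotyledon_map", "write_results"]

logger = logging.getLogger(__name__)

_COORD_COLS = ["x_um", "y_um"]
_SECTOR_RE = re.compile(r"^sector_(\d+)\.csv$")


class MapValidationError(ValueError):
    """Raised when an interchange file fails schema or consistency checks."""


@dataclass
class CotyledonMap:
    """One cotyledon's outline, sector outlines, and stomatal positions (µm)."""

    cotyledon: Outline
    sectors: list[Outline] = field(default_factory=list)
    stomata: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    label: str = ""

    def __post_init__(self) -> None:
        self.stomata = np.asarray(self.stomata, dtype=float).reshape(-1, 2)

    @property
    def n_stomata(self) -> int:
        return len(self.stomata)

    def validate(self) -> None:
        """Check every stoma lies on the cotyledon; warn if a sector grazes the edge."""
        for i, (x, y) in enumerate(self.stomata):
            if not point_in_polygon((x, y), self.cotyledon):
                raise MapValidationError(f"stoma {i} at ({x:g}, {y:g}) lies outside the cotyledon outline")
        for k, sec in enumerate(self.sectors, start=1):
            if not self.cotyledon.polygon.covers(sec.polygon):
                logger.warning("sector %d extends beyond the cotyledon outline (label=%r)", k, self.label)


def _read_coords(path: Path) -> np.ndarray:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise MapValidationError(f"{path}: cannot read CSV ({exc})") from exc
    missing = [c for c in _COORD_COLS if c not in df.columns]
    if missing:
        raise MapValidationError(f"{path}: missing column(s) {missing}; expected header x_um,y_um")
    if "z_um" in df.columns:
        logger.warning("%s: dropping z_um column; analysis is two-dimensional", path)
    for col in _COORD_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy()))[0]
        if bad.size:
            raise MapValidationError(f"{path}: non-numeric {col} at data row {bad[0] + 1}")
        df[col] = vals
    return df[_COORD_COLS].to_numpy(dtype=float)


def read_cotyledon_map(directory: str | Path, label: str | None = None) -> CotyledonMap:
    """Read one cotyledon directory into a validated :class:`CotyledonMap`.

    Row order of outline files is preserved as vertex order.  Raises
    :class:`MapValidationError` naming the offending file (and row where
    applicable) on any schema or consistency violation.
    """
    directory = Path(directory)
    cot_path = directory / "cotyledon.csv"
    if not cot_path.exists():
        raise MapValidationError(f"{cot_path}: file not found")
    coords = _read_coords(cot_path)
    if len(coords) < 3:
        raise MapValidationError(f"{cot_path}: outline needs at least 3 vertices, found {len(coords)}")
    cotyledon = Outline(coords)

    sector_paths = sorted(
        (p for p in directory.iterdir() if _SECTOR_RE.match(p.name)),
        key=lambda p: int(_SECTOR_RE.match(p.name).group(1)),  # type: ignore[union-attr]
    )
    sectors = []
    for p in sector_paths:
        sc = _read_coords(p)
        if len(sc) < 3:
            raise MapValidationError(f"{p}: outline needs at least 3 vertices, found {len(sc)}")
        sectors.append(Outline(sc))

    stoma_path = directory / "stomata.csv"
    stomata = _read_coords(stoma_path) if stoma_path.exists() else np.empty((0, 2))

    if label is None:
        label = _read_manifest_label(directory)
    m = CotyledonMap(cotyledon=cotyledon, sectors=sectors, stomata=stomata, label=label)
    m.validate()
    return m


def _read_manifest_label(directory: Path) -> str:
    for name in ("manifest.yaml", "manifest.yml", "manifest.json"):
        p = directory / name
        if p.exists():
            data = yaml.safe_load(p.read_text()) if p.suffix != ".json" else json.loads(p.read_text())
            return str((data or {}).get("label", ""))
    return ""


def write_cotyledon_map(m: CotyledonMap, directory: str | Path) -> Path:
    """Write a map to the interchange schema; inverse of :func:`read_cotyledon_map`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def _dump(arr: np.ndarray, path: Path) -> None:
        pd.DataFrame(arr, columns=_COORD_COLS).to_csv(path, index=False, float_format="%.8g")

    _dump(m.cotyledon.vertices, directory / "cotyledon.csv")
    for k, sec in enumerate(m.sectors, start=1):
        _dump(sec.vertices, directory / f"sector_{k}.csv")
    _dump(m.stomata, directory / "stomata.csv")
    (directory / "manifest.yaml").write_text(yaml.safe_dump({"label": m.label}))
    return directory


def write_results(result, path: str | Path) -> Path:
    """Write density rows or a correlation function to CSV.

    Correlation columns: ``r_lo, r_hi, r_mid, S_count, R_expected, zeta,
    ci_lo, ci_hi``; undefined (NaN) ζ bins are serialized as empty fields.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = results_frame(result)
    df.to_csv(path, index=False, na_rep="")
    return path


def results_frame(result) -> pd.DataFrame:
    """Build the output table for a list of density rows or a correlation function."""
    from .correlation import CorrelationFunction
    from .density import DensityResult

    if isinstance(result, CorrelationFunction):
        edges = result.bin_edges
        nb = len(edges) - 1
        ci_lo = result.ci_lo if result.ci_lo is not None else np.full(nb, np.nan)
        ci_hi = result.ci_hi if result.ci_hi is not None else np.full(nb, np.nan)
        return pd.DataFrame(
            {
                "r_lo": edges[:-1],
                "r_hi": edges[1:],
                "r_mid": np.sqrt(edges[:-1] * edges[1:]),
                "S_count": result.S,
                "R_expected": result.R_expected,
                "zeta": result.zeta,
                "ci_lo": ci_lo,
                "ci_hi": ci_hi,
            }
        )
    rows: Sequence[DensityResult] = list(result)
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "stoma_count": [r.stoma_count for r in rows],
            "area_um2": [r.area for r in rows],
            "density_per_um2": [r.density for r in rows],
            "density_per_mm2": [r.density_per_mm2 for r in rows],
        }
    )
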